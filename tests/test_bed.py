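"""LQ survival, conventional and survival-averaged BED quantities.

Every survival-averaged result is cross-checked against a direct 60-digit
decimal evaluation of the same expression (tests/_oracles.py), which shares
no code with the log-sum-exp implementation under test.
"""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brachybed import (
    DEFAULT_SCHEME,
    ENDPOINTS,
    BEDMethod,
    DifferentialDVH,
    DoseScale,
    EndpointParams,
    FractionationScheme,
    bed_conventional,
    bed_fraction_ivc,
    bed_heterogeneous_cc,
    bed_total_ivc,
    log_survival_uniform,
    neg_log_weighted_survival,
    repopulation_term,
)

from conftest import delta_ddvh, random_ddvh
from _oracles import (
    dec_bed_fraction_ivc,
    dec_bed_heterogeneous_cc,
    dec_bed_total_ivc,
    dec_neg_log_weighted_survival,
    rel_err,
)

FIBROSIS = ENDPOINTS["fibrosis"]
ERYTHEMA = ENDPOINTS["erythema"]


class TestLogSurvival:
    def test_zero_dose_means_full_survival(self):
        assert log_survival_uniform(0.0, 10, FIBROSIS) == 0.0

    def test_hand_value(self):
        # -0.3 * 10 * 3.4 * (1 + 3.4/2) = -0.3 * 34 * 2.7
        assert log_survival_uniform(3.4, 10, FIBROSIS) == pytest.approx(-27.54)

    def test_linear_in_fraction_count(self):
        one = log_survival_uniform(3.4, 1, FIBROSIS)
        assert log_survival_uniform(3.4, 2, FIBROSIS) == pytest.approx(2 * one)


class TestRepopulation:
    def test_zero_elapsed_time(self):
        assert repopulation_term(ERYTHEMA, 0.0) == 0.0

    def test_late_endpoint_has_no_repopulation(self):
        assert repopulation_term(FIBROSIS, 5.5) == 0.0

    def test_hand_value(self):
        # ln2 * 5.5 / (0.3 * 13)
        assert repopulation_term(ERYTHEMA, 5.5) == pytest.approx(0.977515, abs=1e-6)


class TestConventionalBed:
    @pytest.mark.parametrize(
        "endpoint, expected_1dp",
        [
            ("fibrosis", 91.8),
            ("telangiectasia", 62.9),
            ("erythema", 47.5),
            ("desquamation", 43.5),
            ("breast_carcinoma", 62.9),
        ],
    )
    def test_reference_scheme_values(self, endpoint, expected_1dp):
        """34 Gy in 10 fractions reproduces the published per-endpoint BEDs."""
        val = bed_conventional(DEFAULT_SCHEME, ENDPOINTS[endpoint]).value
        assert round(val, 1) == expected_1dp

    def test_elapsed_time_back_derivation(self):
        """T = 5.5 d is the unique half-day elapsed time for which both acute
        endpoints round to their published one-decimal values."""
        matches = []
        for t in np.arange(0.5, 20.01, 0.5):
            scheme = FractionationScheme(10, 3.4, float(t))
            ery = round(bed_conventional(scheme, ENDPOINTS["erythema"]).value, 1)
            des = round(bed_conventional(scheme, ENDPOINTS["desquamation"]).value, 1)
            if (ery, des) == (47.5, 43.5):
                matches.append(float(t))
        assert matches == [5.5]

    def test_repopulation_component_recorded(self):
        res = bed_conventional(DEFAULT_SCHEME, ERYTHEMA)
        assert res.method is BEDMethod.CONVENTIONAL
        assert res.repopulation_component == pytest.approx(0.977515, abs=1e-6)
        assert bed_conventional(DEFAULT_SCHEME, FIBROSIS).repopulation_component == 0.0


class TestEndpointRegistry:
    def test_registry_parameters(self):
        expected = {
            "fibrosis": (2.0, False),
            "telangiectasia": (4.0, False),
            "erythema": (8.0, True),
            "desquamation": (11.0, True),
            "breast_carcinoma": (4.0, False),
        }
        assert set(ENDPOINTS) == set(expected)
        for name, (ab, repop) in expected.items():
            p = ENDPOINTS[name]
            assert (p.alpha_beta, p.includes_repopulation) == (ab, repop)
            assert p.alpha == 0.3 and p.teff == 13.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            EndpointParams("x", alpha_beta=-1.0)
        with pytest.raises(ValueError):
            FractionationScheme(0, 3.4, 0.0)


class TestNegLogWeightedSurvival:
    def test_single_weight_identity(self):
        assert neg_log_weighted_survival(
            np.array([1.0]), np.array([-12.5])
        ) == pytest.approx(12.5, abs=1e-14)

    def test_underflow_regime_stays_finite(self):
        """ln s of -700/-800 would underflow a naive sum; the shifted
        reduction returns 700 - ln(0.5) to better than 1e-6."""
        val = neg_log_weighted_survival(
            np.array([0.5, 0.5]), np.array([-700.0, -800.0])
        )
        assert math.isfinite(val)
        assert val == pytest.approx(700.0 - math.log(0.5), abs=1e-6)
        oracle = dec_neg_log_weighted_survival([0.5, 0.5], [-700.0, -800.0])
        assert rel_err(val, oracle) < 1e-12

    @pytest.mark.parametrize("n_bins, scale", [(3, 10), (100, 500), (1000, 3000)])
    def test_matches_decimal_oracle(self, n_bins, scale):
        rng = np.random.default_rng(n_bins)
        w = rng.random(n_bins)
        w /= w.sum()
        ls = -rng.random(n_bins) * scale
        val = neg_log_weighted_survival(w, ls)
        assert rel_err(val, dec_neg_log_weighted_survival(w, ls)) < 1e-10

    def test_bad_weight_sum_raises_unless_renormalized(self):
        w = np.array([0.6, 0.6])
        ls = np.array([-1.0, -2.0])
        with pytest.raises(ValueError, match="renormalize"):
            neg_log_weighted_survival(w, ls)
        val = neg_log_weighted_survival(w, ls, renormalize=True)
        assert val == pytest.approx(
            neg_log_weighted_survival(w / w.sum(), ls), abs=1e-12
        )


class TestHeterogeneousCC:
    def test_delta_at_prescription_collapses_to_conventional(self):
        dd = prescription_delta(3.4)
        for params in ENDPOINTS.values():
            h = bed_heterogeneous_cc(dd, DEFAULT_SCHEME, params).value
            c = bed_conventional(DEFAULT_SCHEME, params).value
            assert h == pytest.approx(c, abs=1e-9)

    def test_two_bin_value_matches_decimal_oracle(self):
        dd = DifferentialDVH(29, np.array([50.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                                           0.0, 50.0]),
                             0.1, DoseScale.PER_FRACTION)
        # midpoints 2.95 .. 3.75; occupied at 2.95 and 3.75
        val = bed_heterogeneous_cc(dd, DEFAULT_SCHEME, FIBROSIS).value
        oracle = dec_bed_heterogeneous_cc(dd.weights(), dd.midpoints, 10,
                                          0.3, 2.0)
        assert rel_err(val, oracle) < 1e-10

    def test_value_within_per_bin_bed_envelope(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            dd = random_ddvh(rng, int(rng.integers(2, 80)))
            for params in ENDPOINTS.values():
                h = bed_heterogeneous_cc(dd, DEFAULT_SCHEME, params).value
                per_bin = [
                    bed_conventional(
                        FractionationScheme(10, float(m), 5.5), params
                    ).value
                    for m in dd.midpoints[dd.volumes > 0]
                ]
                assert min(per_bin) - 1e-9 <= h <= max(per_bin) + 1e-9

    def test_total_course_axis_rejected(self):
        dd = delta_ddvh(33.95, dose_scale=DoseScale.TOTAL_COURSE)
        with pytest.raises(ValueError, match="rescale_dose_axis"):
            bed_heterogeneous_cc(dd, DEFAULT_SCHEME, FIBROSIS)


def prescription_delta(dose: float = 3.4, width: float = 0.4) -> DifferentialDVH:
    """Single-bin dDVH whose bin midpoint sits exactly on ``dose``."""
    k = round(dose / width - 0.5)
    assert abs((k + 0.5) * width - dose) < 1e-12
    return DifferentialDVH(
        first_bin=k,
        volumes=np.array([100.0]),
        bin_width=width,
        dose_scale=DoseScale.PER_FRACTION,
    )


class TestFractionIVC:
    def test_delta_late_endpoint_is_conventional_over_n(self):
        dd = prescription_delta(3.4)
        f = bed_fraction_ivc(dd, DEFAULT_SCHEME, FIBROSIS).value
        c = bed_conventional(DEFAULT_SCHEME, FIBROSIS).value
        assert f == pytest.approx(c / 10.0, abs=1e-9)

    def test_n_fraction_values_equal_cc_on_delta(self):
        dd = prescription_delta(3.4)
        for params in ENDPOINTS.values():
            f = bed_fraction_ivc(dd, DEFAULT_SCHEME, params).value
            cc = bed_heterogeneous_cc(dd, DEFAULT_SCHEME, params).value
            assert 10 * f == pytest.approx(cc, abs=1e-9)

    def test_two_bin_value_matches_decimal_oracle(self):
        dd = DifferentialDVH(29, np.array([30.0, 0.0, 70.0]), 0.1,
                             DoseScale.PER_FRACTION)
        val = bed_fraction_ivc(dd, DEFAULT_SCHEME, ERYTHEMA).value
        oracle = dec_bed_fraction_ivc(dd.weights(), dd.midpoints, 10, 0.3, 8.0,
                                      teff=13.0, elapsed=5.5,
                                      includes_repop=True)
        assert rel_err(val, oracle) < 1e-10


class TestTotalIVC:
    def test_identical_deltas_recover_conventional(self):
        dd = prescription_delta(3.4)
        for params in ENDPOINTS.values():
            total = bed_total_ivc([dd] * 10, DEFAULT_SCHEME, params).value
            c = bed_conventional(DEFAULT_SCHEME, params).value
            assert total == pytest.approx(c, abs=1e-9)

    def test_identical_multibin_exceeds_constant_case(self):
        """Summing per-fraction BEDs of one multi-bin distribution strictly
        exceeds the constant-case value (power-mean inequality); the two
        agree only for single-bin distributions."""
        rng = np.random.default_rng(77)
        dd = random_ddvh(rng, 30)
        for params in ENDPOINTS.values():
            cc = bed_heterogeneous_cc(dd, DEFAULT_SCHEME, params).value
            ivc = bed_total_ivc([dd] * 10, DEFAULT_SCHEME, params).value
            assert ivc > cc
            oracle_cc = dec_bed_heterogeneous_cc(
                dd.weights(), dd.midpoints, 10, params.alpha, params.alpha_beta,
                params.teff, 5.5, params.includes_repopulation)
            oracle_ivc = dec_bed_total_ivc(
                [dd.weights()] * 10, [dd.midpoints] * 10, params.alpha,
                params.alpha_beta, params.teff, 5.5,
                params.includes_repopulation)
            assert oracle_ivc > oracle_cc
            assert rel_err(ivc, oracle_ivc) < 1e-10

    def test_fraction_order_irrelevant(self):
        rng = np.random.default_rng(8)
        ddvhs = [random_ddvh(rng, 12) for _ in range(5)]
        a = bed_total_ivc(ddvhs, DEFAULT_SCHEME, FIBROSIS).value
        b = bed_total_ivc(ddvhs[::-1], DEFAULT_SCHEME, FIBROSIS).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            bed_total_ivc([], DEFAULT_SCHEME, FIBROSIS)

    def test_missing_fraction_uses_delivered_count_for_repopulation(self):
        """With 9 of 10 fraction dDVHs, the full elapsed-time repopulation
        correction is still subtracted exactly once."""
        dd = prescription_delta(3.4)
        res = bed_total_ivc([dd] * 9, DEFAULT_SCHEME, ERYTHEMA)
        assert res.repopulation_component == pytest.approx(
            repopulation_term(ERYTHEMA, 5.5), abs=1e-12
        )
        # and the dose part is 9 single-fraction BEDs
        expected = 9 * 3.4 * (1 + 3.4 / 8.0) - repopulation_term(ERYTHEMA, 5.5)
        assert res.value == pytest.approx(expected, abs=1e-9)


class TestMonotonicity:
    def test_bed_does_not_decrease_when_a_bin_dose_increases(self):
        """Shifting any occupied bin's volume one bin upward (a pure dose
        increase at fixed volume) never lowers any BED quantity."""
        rng = np.random.default_rng(13)
        dd = random_ddvh(rng, 20)
        occupied = np.flatnonzero(dd.volumes > 0)
        j = int(occupied[len(occupied) // 2])
        shifted = np.append(dd.volumes.copy(), 0.0)
        shifted[j + 1] += shifted[j]
        shifted[j] = 0.0
        dd_up = DifferentialDVH(dd.first_bin, shifted, dd.bin_width,
                                dd.dose_scale)
        for params in ENDPOINTS.values():
            assert (
                bed_heterogeneous_cc(dd_up, DEFAULT_SCHEME, params).value
                >= bed_heterogeneous_cc(dd, DEFAULT_SCHEME, params).value - 1e-12
            )
            assert (
                bed_fraction_ivc(dd_up, DEFAULT_SCHEME, params).value
                >= bed_fraction_ivc(dd, DEFAULT_SCHEME, params).value - 1e-12
            )


class TestOracleEquivalenceRandomized:
    @given(st.integers(0, 2**31 - 1))
    def test_random_dvhs_match_decimal_oracle(self, seed):
        """Randomized dDVHs (up to 200 bins here; the acceptance suite pushes
        to 1000) agree with the 60-digit direct evaluation to 1e-10."""
        rng = np.random.default_rng(seed)
        dd = random_ddvh(rng, int(rng.integers(2, 200)))
        params = list(ENDPOINTS.values())[int(rng.integers(0, 5))]
        cc = bed_heterogeneous_cc(dd, DEFAULT_SCHEME, params).value
        oracle = dec_bed_heterogeneous_cc(
            dd.weights(), dd.midpoints, 10, params.alpha, params.alpha_beta,
            params.teff, 5.5, params.includes_repopulation)
        assert rel_err(cc, oracle) < 1e-10
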