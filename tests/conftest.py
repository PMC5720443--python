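import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brachybed import (
    CohortConfig,
    DifferentialDVH,
    DoseScale,
    PerturbationModel,
    generate_cohort,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def table1_fragment() -> DifferentialDVH:
    """Published four-bin group-average dDVH fragment around the 34 Gy
    prescription (total-course axis): 0.229/0.239/0.251/0.264 % over
    (33.8, 34.2] in 0.1 Gy bins.  Deliberately partial."""
    return DifferentialDVH(
        first_bin=338,
        volumes=np.array([0.229, 0.239, 0.251, 0.264]),
        bin_width=0.1,
        dose_scale=DoseScale.TOTAL_COURSE,
        label="table1_fragment",
        validate_total=False,
    )


def delta_ddvh(dose: float, bin_width: float = 0.1,
               dose_scale: DoseScale = DoseScale.PER_FRACTION) -> DifferentialDVH:
    """Single-bin dDVH whose bin midpoint is exactly ``dose``."""
    k = round(dose / bin_width - 0.5)
    assert abs((k + 0.5) * bin_width - dose) < 1e-9, "dose must sit on a midpoint"
    return DifferentialDVH(
        first_bin=k,
        volumes=np.array([100.0]),
        bin_width=bin_width,
        dose_scale=dose_scale,
    )


def random_ddvh(rng: np.random.Generator, n_bins: int,
                bin_width: float = 0.1, first_bin: int | None = None,
                dose_scale: DoseScale = DoseScale.PER_FRACTION) -> DifferentialDVH:
    if first_bin is None:
        first_bin = int(rng.integers(0, 200))
    v = rng.random(n_bins)
    v = v / v.sum() * 100.0
    return DifferentialDVH(first_bin=first_bin, volumes=v,
                           bin_width=bin_width, dose_scale=dose_scale)


@pytest.fixture(scope="session")
def small_cohort():
    """Five-patient default-geometry cohort at reduced sampling, shared by
    pipeline tests (study conditions otherwise unchanged)."""
    cfg = CohortConfig(n_patients=5, n_samples=20_000, seed=11)
    return generate_cohort(cfg)
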