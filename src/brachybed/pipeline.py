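"""Cohort-level BED comparisons and report generation.

Two comparisons are orchestrated per endpoint across a cohort of patients:

* constant case vs interfraction variation case (CC vs IVC) — how much the
  course BED shifts when each fraction's own dose distribution, rather than
  fraction 1's, enters the calculation;
* heterogeneity-corrected vs conventional (H-method vs C-method) — how much
  accounting for the nonuniform dose distribution shifts the BED away from
  the uniform-prescription-dose value.

Reports carry per-patient rows plus cohort summary statistics (mean, sample
SD, min/max with patient attribution), written as display-rounded CSVs and
an unrounded JSON bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bed import (
    DEFAULT_SCHEME,
    ENDPOINTS,
    EndpointParams,
    FractionationScheme,
    bed_conventional,
    bed_heterogeneous_cc,
    bed_total_ivc,
)
from .dvh import DifferentialDVH

__all__ = [
    "ComparisonRow",
    "SummaryTable",
    "compare_cc_ivc",
    "compare_h_c",
    "summarize",
    "run_study",
    "round_display",
]

#: alpha/beta sweep used for the per-patient BED curves, with the registry
#: endpoint carrying each ratio's repopulation convention
ALPHA_BETA_SWEEP: Mapping[float, str] = {
    2.0: "fibrosis",
    4.0: "telangiectasia",
    8.0: "erythema",
    11.0: "desquamation",
}


def round_display(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComparisonRow:
    """One patient's BED pair and its (b - a) difference."""

    patient_id: str
    endpoint: str
    bed_a: float
    bed_b: float
    diff: float
    rel_diff: float
    n_delivered: int

    @classmethod
    def from_pair(
        cls,
        patient_id: str,
        endpoint: str,
        bed_a: float,
        bed_b: float,
        n_delivered: int,
    ) -> "ComparisonRow":
        diff = bed_b - bed_a
        return cls(
            patient_id=str(patient_id),
            endpoint=endpoint,
            bed_a=bed_a,
            bed_b=bed_b,
            diff=diff,
            rel_diff=100.0 * diff / bed_a,
            n_delivered=n_delivered,
        )


@dataclass(frozen=True)
class SummaryTable:
    """Cohort statistics of one difference metric for one endpoint."""

    endpoint: str
    quantity: str  # "diff_gy" or "rel_diff_pct"
    average: float
    sd: float
    minimum: float
    argmin: str
    maximum: float
    argmax: str

    def __post_init__(self) -> None:
        if not self.minimum <= self.average <= self.maximum:
            raise ValueError("summary must satisfy min <= average <= max")


def compare_cc_ivc(
    ddvhs: Sequence[DifferentialDVH],
    scheme: FractionationScheme,
    endpoint: EndpointParams,
    patient_id: str = "",
) -> ComparisonRow:
    """CC (fraction-1 distribution repeated) vs IVC (per-fraction sum).

    ``ddvhs`` is the fraction-ordered list of delivered-fraction dDVHs; the
    first entry is fraction 1.  If fewer fractions were delivered than the
    scheme specifies, the delivered count replaces n on both sides.
    """
    if not ddvhs:
        raise ValueError("fraction 1 dDVH is required")
    delivered = len(ddvhs)
    eff = replace(scheme, n_fractions=delivered)
    cc = bed_heterogeneous_cc(ddvhs[0], eff, endpoint).value
    ivc = bed_total_ivc(list(ddvhs), eff, endpoint).value
    return ComparisonRow.from_pair(patient_id, endpoint.name, cc, ivc, delivered)


def compare_h_c(
    ddvh_f1: DifferentialDVH,
    scheme: FractionationScheme,
    endpoint: EndpointParams,
    patient_id: str = "",
) -> ComparisonRow:
    """Conventional (C-method) vs heterogeneity-corrected constant-case
    (H-method) BED for one patient's fraction-1 distribution."""
    c = bed_conventional(scheme, endpoint).value
    h = bed_heterogeneous_cc(ddvh_f1, scheme, endpoint).value
    return ComparisonRow.from_pair(patient_id, endpoint.name, c, h, scheme.n_fractions)


def summarize(
    rows: Sequence[ComparisonRow], quantity: str = "diff"
) -> SummaryTable:
    """Mean, sample SD (n-1) and attributed extremes of one metric.

    ``quantity`` is ``"diff"`` (Gy) or ``"rel_diff"`` (percent of bed_a).
    """
    if len(rows) < 2:
        raise ValueError("need >= 2 rows to summarize")
    if quantity not in ("diff", "rel_diff"):
        raise ValueError("quantity must be 'diff' or 'rel_diff'")
    values = np.array([getattr(r, quantity) for r in rows])
    i_min = int(np.argmin(values))
    i_max = int(np.argmax(values))
    return SummaryTable(
        endpoint=rows[0].endpoint,
        quantity="diff_gy" if quantity == "diff" else "rel_diff_pct",
        average=float(values.mean()),
        sd=float(values.std(ddof=1)),
        minimum=float(values[i_min]),
        argmin=rows[i_min].patient_id,
        maximum=float(values[i_max]),
        argmax=rows[i_max].patient_id,
    )


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def _as_patient_map(cohort) -> dict[str, list[DifferentialDVH]]:
    """Accept a SyntheticCohort or a {patient: [ddvh, ...]} mapping."""
    if isinstance(cohort, Mapping):
        return {str(k): list(v) for k, v in cohort.items()}
    return {str(rec.patient_id): list(rec.ddvhs) for rec in cohort.patients}


def _rows_frame(rows: Sequence[ComparisonRow], a: str, b: str) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in rows])
    return df.rename(columns={"bed_a": a, "bed_b": b})


def run_study(
    cohort,
    scheme: FractionationScheme = DEFAULT_SCHEME,
    endpoints: Sequence[str] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run both comparisons for every endpoint over every patient.

    Parameters
    ----------
    cohort
        A :class:`~brachybed.synthetic.SyntheticCohort` or a mapping of
        patient id to a fraction-ordered list of per-fraction dDVHs.
    scheme
        Fractionation scheme; per-patient delivered counts may be smaller.
    endpoints
        Endpoint registry names; defaults to the full registry.
    out_dir
        If given, write ``report.json`` (unrounded) plus display CSVs
        (values rounded half away from zero at one decimal).

    Returns the report as a nested dict.
    """
    patients = _as_patient_map(cohort)
    if endpoints is None:
        endpoints = list(ENDPOINTS)
    params_list = []
    for name in endpoints:
        if name not in ENDPOINTS:
            raise KeyError(
                f"unknown endpoint {name!r}; registry has {sorted(ENDPOINTS)}"
            )
        params_list.append(ENDPOINTS[name])

    report: dict = {
        "scheme": {
            "n_fractions": scheme.n_fractions,
            "fraction_dose_gy": scheme.fraction_dose,
            "elapsed_days": scheme.elapsed_time,
        },
        "endpoints": {
            p.name: {
                "alpha_beta_gy": p.alpha_beta,
                "alpha_per_gy": p.alpha,
                "teff_days": p.teff,
                "includes_repopulation": p.includes_repopulation,
            }
            for p in params_list
        },
        "conventional_bed_gy": {},
        "cc_ivc": {},
        "h_c": {},
        "alpha_beta_curves": [],
    }

    cc_frames: dict[str, pd.DataFrame] = {}
    hc_frames: dict[str, pd.DataFrame] = {}
    for params in params_list:
        report["conventional_bed_gy"][params.name] = bed_conventional(
            scheme, params
        ).value
        cc_rows = [
            compare_cc_ivc(ddvhs, scheme, params, pid)
            for pid, ddvhs in patients.items()
        ]
        hc_rows = [
            compare_h_c(ddvhs[0], scheme, params, pid)
            for pid, ddvhs in patients.items()
        ]
        report["cc_ivc"][params.name] = {
            "rows": [asdict(r) for r in cc_rows],
            "summary_gy": asdict(summarize(cc_rows, "diff")),
            "summary_pct": asdict(summarize(cc_rows, "rel_diff")),
        }
        report["h_c"][params.name] = {
            "rows": [asdict(r) for r in hc_rows],
            "summary_gy": asdict(summarize(hc_rows, "diff")),
            "summary_pct": asdict(summarize(hc_rows, "rel_diff")),
        }
        cc_frames[params.name] = _rows_frame(cc_rows, "bed_cc_gy", "bed_ivc_gy")
        hc_frames[params.name] = _rows_frame(hc_rows, "bed_c_gy", "bed_h_gy")

    # per-patient BED curves over the alpha/beta sweep (CC and IVC)
    for pid, ddvhs in patients.items():
        delivered = len(ddvhs)
        eff = replace(scheme, n_fractions=delivered)
        for ab, ep_name in ALPHA_BETA_SWEEP.items():
            params = ENDPOINTS[ep_name]
            report["alpha_beta_curves"].append(
                {
                    "patient_id": pid,
                    "alpha_beta_gy": ab,
                    "bed_cc_gy": bed_heterogeneous_cc(ddvhs[0], eff, params).value,
                    "bed_ivc_gy": bed_total_ivc(ddvhs, eff, params).value,
                    "n_delivered": delivered,
                }
            )

    if out_dir is not None:
        _write_report(report, cc_frames, hc_frames, Path(out_dir))
    return report


def _round_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda x: round_display(x, 1))
    return out


def _write_report(
    report: dict,
    cc_frames: Mapping[str, pd.DataFrame],
    hc_frames: Mapping[str, pd.DataFrame],
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    summaries = []
    for comparison, frames in (("cc_ivc", cc_frames), ("h_c", hc_frames)):
        for name, df in frames.items():
            _round_frame(df).to_csv(
                out_dir / f"{comparison}_{name}.csv", index=False
            )
            for key in ("summary_gy", "summary_pct"):
                row = dict(report[comparison][name][key])
                row["comparison"] = comparison
                summaries.append(row)
    _round_frame(pd.DataFrame(summaries)).to_csv(
        out_dir / "summaries.csv", index=False
    )
    curves = pd.DataFrame(report["alpha_beta_curves"])
    if not curves.empty:
        _round_frame(curves).to_csv(out_dir / "alpha_beta_curves.csv", index=False)
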