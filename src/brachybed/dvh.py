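"""Differential and cumulative dose-volume histograms.

A differential DVH (dDVH) records, for each fixed-width dose bin, the
percentage of the target volume receiving a dose inside that bin.  Bins
follow the half-open convention ``(lower, upper]``: a dose lying exactly on
a bin edge belongs to the bin below it.  All bins are contiguous and share
one width (default 0.1 Gy), and a complete dDVH sums to 100 % of the target
volume.

Internally a :class:`DifferentialDVH` stores only the integer index of its
first bin plus a volume array; bin edges are exact integer multiples of the
bin width, which makes edge alignment and histogram union/averaging robust
against floating-point drift.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseScale",
    "DoseBin",
    "DifferentialDVH",
    "CumulativeDVH",
    "build_ddvh",
    "fraction_in_range",
    "mean_dose",
    "modal_dose",
    "group_average",
    "cumulative_from_differential",
    "differential_from_cumulative",
    "rescale_dose_axis",
    "read_ddvh_csv",
    "write_ddvh_csv",
    "read_manifest",
    "write_manifest",
]

#: absolute tolerance (percent) on the 100 % volume-conservation invariant
VOLUME_TOL_PCT = 1e-6
#: relative tolerance used when snapping a dose to a bin edge
EDGE_SNAP_REL = 1e-9


class DoseScale(str, enum.Enum):
    """Whether a dose axis is per delivered fraction or for the whole course."""

    PER_FRACTION = "per_fraction"
    TOTAL_COURSE = "total_course"


@dataclass(frozen=True)
class DoseBin:
    """One half-open dose interval ``(lower, upper]`` with its volume share."""

    lower: float
    upper: float
    fractional_volume: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"bin lower {self.lower} must be < upper {self.upper}")
        if self.fractional_volume < 0:
            raise ValueError("fractional_volume must be >= 0")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


def _snap_to_edge_index(dose: float, bin_width: float) -> float:
    """Return dose / bin_width, snapped to the nearest integer if within
    tolerance, so that a dose meant to sit on a bin edge is treated exactly."""
    q = dose / bin_width
    k = round(q)
    if abs(q - k) <= EDGE_SNAP_REL * max(1.0, abs(k)):
        return float(k)
    return q


def _bin_index(dose: float, bin_width: float) -> int:
    """Index of the half-open bin ``(i*w, (i+1)*w]`` containing ``dose``.

    A dose exactly on an edge k*w belongs to bin k-1 (the upper edge of the
    bin below); dose 0 is assigned to bin 0.
    """
    q = _snap_to_edge_index(dose, bin_width)
    if q == int(q):
        return max(int(q) - 1, 0)
    return int(math.floor(q))


@dataclass
class DifferentialDVH:
    """Differential dose-volume histogram on a contiguous integer bin grid.

    Bin ``j`` covers ``((first_bin + j) * bin_width, (first_bin + j + 1) * bin_width]``.

    Parameters
    ----------
    first_bin
        Integer index of the first bin on the global grid.
    volumes
        Fractional volume per bin, in percent of the target volume.
    bin_width
        Common bin width in Gy.
    dose_scale
        Whether the dose axis is per-fraction or total-course.
    label
        Free-text identifier (patient / fraction id).
    validate_total
        If True (default), require the volumes to sum to 100 % within
        tolerance.  Disable only for deliberately partial histograms such as
        published table fragments.
    """

    first_bin: int
    volumes: np.ndarray
    bin_width: float
    dose_scale: DoseScale
    label: str = ""
    validate_total: bool = True

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.dose_scale = DoseScale(self.dose_scale)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.volumes.ndim != 1 or self.volumes.size == 0:
            raise ValueError("volumes must be a non-empty 1-D array")
        if np.any(self.volumes < 0):
            raise ValueError("fractional volumes must be >= 0")
        if self.first_bin < 0:
            raise ValueError("bins must not extend below zero dose")
        if self.validate_total:
            total = float(self.volumes.sum())
            if abs(total - 100.0) > VOLUME_TOL_PCT:
                raise ValueError(
                    f"fractional volumes sum to {total} %, expected 100 % "
                    f"within {VOLUME_TOL_PCT}"
                )

    # -- geometry -----------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return int(self.volumes.size)

    @property
    def lower_edges(self) -> np.ndarray:
        return (self.first_bin + np.arange(self.n_bins)) * self.bin_width

    @property
    def upper_edges(self) -> np.ndarray:
        return (self.first_bin + 1 + np.arange(self.n_bins)) * self.bin_width

    @property
    def midpoints(self) -> np.ndarray:
        return (self.first_bin + 0.5 + np.arange(self.n_bins)) * self.bin_width

    @property
    def bins(self) -> list[DoseBin]:
        lo, hi = self.lower_edges, self.upper_edges
        return [
            DoseBin(float(l), float(h), float(v))
            for l, h, v in zip(lo, hi, self.volumes)
        ]

    def weights(self) -> np.ndarray:
        """Volumes as unit fractions (percent / 100)."""
        return self.volumes / 100.0

    @classmethod
    def from_edges(
        cls,
        lower: Sequence[float],
        upper: Sequence[float],
        volumes: Sequence[float],
        dose_scale: DoseScale,
        label: str = "",
        validate_total: bool = True,
    ) -> "DifferentialDVH":
        """Build from explicit edge arrays, validating the shared-width,
        contiguous, ascending layout."""
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        volumes = np.asarray(volumes, dtype=float)
        if not (lower.size == upper.size == volumes.size) or lower.size == 0:
            raise ValueError("lower, upper, volumes must be equal-length, non-empty")
        widths = upper - lower
        w = float(widths[0])
        if w <= 0 or not np.allclose(widths, w, rtol=1e-9, atol=1e-12):
            raise ValueError("all bins must share one positive bin_width")
        if lower.size > 1 and not np.allclose(
            lower[1:], upper[:-1], rtol=1e-9, atol=1e-12
        ):
            raise ValueError("bins must be contiguous and sorted ascending")
        q0 = _snap_to_edge_index(float(lower[0]), w)
        if q0 != int(q0):
            raise ValueError(
                f"first bin edge {lower[0]} is not an integer multiple of "
                f"bin_width {w}"
            )
        return cls(
            first_bin=int(q0),
            volumes=volumes,
            bin_width=w,
            dose_scale=dose_scale,
            label=label,
            validate_total=validate_total,
        )


@dataclass
class CumulativeDVH:
    """Volume at-or-above each dose threshold (percent), non-increasing."""

    thresholds: np.ndarray
    volume_at_or_above: np.ndarray
    dose_scale: DoseScale = DoseScale.TOTAL_COURSE
    label: str = ""
    validate_total: bool = True

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.volume_at_or_above = np.asarray(self.volume_at_or_above, dtype=float)
        if self.thresholds.size != self.volume_at_or_above.size:
            raise ValueError("thresholds and volumes must have equal length")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly ascending")
        if np.any(np.diff(self.volume_at_or_above) > 1e-12):
            raise ValueError("cumulative volume must be non-increasing")
        if self.validate_total and abs(
            float(self.volume_at_or_above[0]) - 100.0
        ) > VOLUME_TOL_PCT:
            raise ValueError("cumulative DVH must start at 100 %")


# ---------------------------------------------------------------------------
# construction and statistics
# ---------------------------------------------------------------------------

def build_ddvh(
    samples: Iterable[tuple[float, float]] | tuple[np.ndarray, np.ndarray],
    bin_width: float,
    dose_scale: DoseScale,
    label: str = "",
) -> DifferentialDVH:
    """Histogram weighted dose samples into a normalized dDVH.

    ``samples`` is either an iterable of ``(dose_gy, weight)`` pairs or a
    ``(doses, weights)`` array pair.  Each sample's weight is assigned to the
    unique half-open bin containing its dose, and fractional volumes are
    normalized to sum to 100 %.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(samples, tuple) and len(samples) == 2 and np.ndim(samples[0]) == 1:
        doses = np.asarray(samples[0], dtype=float)
        weights = np.asarray(samples[1], dtype=float)
    else:
        pairs = list(samples)
        if not pairs:
            raise ValueError("at least one dose sample is required")
        doses = np.array([p[0] for p in pairs], dtype=float)
        weights = np.array([p[1] for p in pairs], dtype=float)
    if doses.size == 0:
        raise ValueError("at least one dose sample is required")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    total_w = float(weights.sum())
    if total_w <= 0:
        raise ValueError("total sample weight must be > 0")

    # half-open (lo, hi]: snap edge-coincident doses, then ceil-minus-one
    q = doses / bin_width
    k = np.round(q)
    on_edge = np.abs(q - k) <= EDGE_SNAP_REL * np.maximum(1.0, np.abs(k))
    idx = np.where(on_edge, k - 1, np.floor(q)).astype(int)
    idx = np.maximum(idx, 0)

    first = int(idx.min())
    counts = np.bincount(idx - first, weights=weights, minlength=int(idx.max()) - first + 1)
    volumes = counts / total_w * 100.0
    return DifferentialDVH(
        first_bin=first,
        volumes=volumes,
        bin_width=bin_width,
        dose_scale=dose_scale,
        label=label,
    )


def _aligned_index(ddvh: DifferentialDVH, dose: float, name: str) -> int:
    q = _snap_to_edge_index(dose, ddvh.bin_width)
    if q != int(q):
        lo = math.floor(q) * ddvh.bin_width
        hi = math.ceil(q) * ddvh.bin_width
        raise ValueError(
            f"{name}={dose} Gy is not aligned to the {ddvh.bin_width} Gy bin "
            f"grid; nearest aligned edges are {lo:g} and {hi:g} Gy"
        )
    return int(q)


def fraction_in_range(ddvh: DifferentialDVH, low: float, high: float) -> float:
    """Percent of target volume receiving a dose in ``(low, high]``.

    Both limits must lie on bin edges; a misaligned limit raises with the
    nearest aligned edges named.
    """
    if not low < high:
        raise ValueError("low must be < high")
    k_low = _aligned_index(ddvh, low, "low")
    k_high = _aligned_index(ddvh, high, "high")
    # bins fully inside (low, high] have indices k_low .. k_high - 1
    a = max(k_low, ddvh.first_bin) - ddvh.first_bin
    b = min(k_high, ddvh.first_bin + ddvh.n_bins) - ddvh.first_bin
    if b <= a:
        return 0.0
    return float(ddvh.volumes[a:b].sum())


def mean_dose(ddvh: DifferentialDVH) -> float:
    """Volume-weighted mean dose, using bin midpoints as representatives."""
    v = ddvh.volumes
    return float(np.sum(v * ddvh.midpoints) / np.sum(v))


def modal_dose(ddvh: DifferentialDVH) -> float:
    """Midpoint of the most populated bin; ties go to the lowest dose."""
    return float(ddvh.midpoints[int(np.argmax(ddvh.volumes))])


def group_average(ddvhs: Sequence[DifferentialDVH]) -> DifferentialDVH:
    """Per-bin arithmetic mean of several dDVHs (zero-filled union support)."""
    if not ddvhs:
        raise ValueError("need at least one dDVH to average")
    w = ddvhs[0].bin_width
    scale = ddvhs[0].dose_scale
    for d in ddvhs[1:]:
        if not math.isclose(d.bin_width, w, rel_tol=1e-9):
            raise ValueError(
                f"mismatched bin_width: {d.bin_width} vs {w}"
            )
        if d.dose_scale is not scale:
            raise ValueError("cannot average per_fraction with total_course axes")
    first = min(d.first_bin for d in ddvhs)
    last = max(d.first_bin + d.n_bins for d in ddvhs)
    acc = np.zeros(last - first)
    for d in ddvhs:
        a = d.first_bin - first
        acc[a : a + d.n_bins] += d.volumes
    acc /= len(ddvhs)
    return DifferentialDVH(
        first_bin=first,
        volumes=acc,
        bin_width=w,
        dose_scale=scale,
        label=f"group_average(n={len(ddvhs)})",
        validate_total=all(d.validate_total for d in ddvhs),
    )


# ---------------------------------------------------------------------------
# differential <-> cumulative, axis rescaling
# ---------------------------------------------------------------------------

def cumulative_from_differential(ddvh: DifferentialDVH) -> CumulativeDVH:
    """Suffix-sum the differential volumes: threshold = each bin's lower edge."""
    suffix = np.cumsum(ddvh.volumes[::-1])[::-1]
    return CumulativeDVH(
        thresholds=ddvh.lower_edges,
        volume_at_or_above=suffix,
        dose_scale=ddvh.dose_scale,
        label=ddvh.label,
        validate_total=ddvh.validate_total,
    )


def differential_from_cumulative(
    cdvh: CumulativeDVH, bin_width: float
) -> DifferentialDVH:
    """Invert :func:`cumulative_from_differential` on an even threshold grid."""
    steps = np.diff(cdvh.thresholds)
    if steps.size and not np.allclose(steps, bin_width, rtol=1e-9, atol=1e-12):
        raise ValueError("thresholds are not spaced by bin_width")
    vols = np.empty_like(cdvh.volume_at_or_above)
    vols[:-1] = cdvh.volume_at_or_above[:-1] - cdvh.volume_at_or_above[1:]
    vols[-1] = cdvh.volume_at_or_above[-1]
    q0 = _snap_to_edge_index(float(cdvh.thresholds[0]), bin_width)
    if q0 != int(q0):
        raise ValueError("first threshold is not on the bin grid")
    return DifferentialDVH(
        first_bin=int(q0),
        volumes=vols,
        bin_width=bin_width,
        dose_scale=cdvh.dose_scale,
        label=cdvh.label,
        validate_total=cdvh.validate_total,
    )


def rescale_dose_axis(
    ddvh: DifferentialDVH,
    factor: float,
    dose_scale: DoseScale | None = None,
) -> DifferentialDVH:
    """Multiply all bin edges by ``factor`` (volumes untouched).

    Used to convert a total-course axis to per-fraction (factor 1/n) and
    back; pass the new ``dose_scale`` explicitly when the meaning changes.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return replace(
        ddvh,
        bin_width=ddvh.bin_width * factor,
        dose_scale=ddvh.dose_scale if dose_scale is None else DoseScale(dose_scale),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["bin_low_gy", "bin_high_gy", "fractional_volume_pct"]
MANIFEST_COLUMNS = ["patient", "fraction", "path", "dose_scale"]


def write_ddvh_csv(ddvh: DifferentialDVH, path: str | Path) -> None:
    """Write one dDVH as ``bin_low_gy,bin_high_gy,fractional_volume_pct``."""
    df = pd.DataFrame(
        {
            "bin_low_gy": ddvh.lower_edges,
            "bin_high_gy": ddvh.upper_edges,
            "fractional_volume_pct": ddvh.volumes,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_ddvh_csv(
    path: str | Path,
    dose_scale: DoseScale,
    label: str = "",
    validate_total: bool = True,
) -> DifferentialDVH:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return DifferentialDVH.from_edges(
        df["bin_low_gy"].to_numpy(),
        df["bin_high_gy"].to_numpy(),
        df["fractional_volume_pct"].to_numpy(),
        dose_scale=dose_scale,
        label=label or str(path),
        validate_total=validate_total,
    )


def write_manifest(rows: Sequence[dict], path: str | Path) -> None:
    """Write a cohort manifest: ``patient,fraction,path,dose_scale``."""
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return df


def load_cohort_ddvhs(
    manifest_path: str | Path,
) -> dict[str, list[DifferentialDVH]]:
    """Load per-patient, fraction-ordered dDVH lists from a manifest CSV.

    Paths in the manifest are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    out: dict[str, list[DifferentialDVH]] = {}
    for patient, grp in df.groupby("patient", sort=True):
        grp = grp.sort_values("fraction")
        out[str(patient)] = [
            read_ddvh_csv(
                manifest_path.parent / row["path"],
                dose_scale=DoseScale(row["dose_scale"]),
                label=f"{patient}_f{row['fraction']}",
            )
            for _, row in grp.iterrows()
        ]
    return out
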