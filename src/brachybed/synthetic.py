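"""Synthetic balloon-brachytherapy dose distributions and cohorts.

Emulates the dose structure of a MammoSite-style balloon applicator: an
Ir-192 source steps through a short chain of dwell positions inside a
spherical balloon, the prescription dose is delivered at a 1 cm expansion
of the balloon surface, the target (PTV_EVAL) is the 1 cm spherical shell
around the balloon minus a skin/lung exclusion cap, and a cold region runs
along the catheter axis because of line-source geometry.  The physics is a
deliberately simplified inverse-square superposition with equal dwell
weights — no TG-43 radial dose function or anisotropy — because the BED
analysis downstream consumes only differential DVHs, and the qualitative
shell-dose shape (dose above 200 % of prescription at the balloon surface,
falling to prescription at the shell's outer radius, with a sub-prescription
axial tail) is what drives every BED result.

Per-fraction geometric variation (balloon radius change, balloon drift
relative to the catheter, trapped air) is drawn from a seeded perturbation
model; dose normalisation always stays tied to the unperturbed fraction-1
plan, mirroring clinical practice where the fraction-1 dwell times are
reused for every fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dvh import (
    DifferentialDVH,
    DoseScale,
    build_ddvh,
    write_ddvh_csv,
    write_manifest,
)

__all__ = [
    "BalloonGeometry",
    "PerturbationModel",
    "CohortConfig",
    "SyntheticCohort",
    "PatientRecord",
    "dose_at_point",
    "sample_ptv_eval",
    "generate_fraction_ddvh",
    "generate_cohort",
    "write_cohort",
    "shell_mean_dose",
]

SHELL_THICKNESS_CM = 1.0


@dataclass(frozen=True)
class BalloonGeometry:
    """Applicator state: balloon, dwell chain, cold axis and exclusions.

    The balloon is centred at the origin with the catheter along z.  The
    prescription isodose is defined on the sphere 1 cm outside the balloon
    surface.  ``cold_axis_halfangle`` (degrees) opens a double cone about
    the catheter axis whose dose is attenuated by ``cold_axis_factor``,
    emulating the line-source cold spot; ``excluded_volume_fraction`` removes
    a contiguous polar cap of the shell (skin / lung exclusion).
    """

    balloon_radius: float
    prescription_dose: float = 3.4
    dwell_positions: int = 1
    dwell_spacing: float = 0.5
    source_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cold_axis_halfangle: float = 0.0
    cold_axis_factor: float = 0.85
    excluded_volume_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.balloon_radius <= 0:
            raise ValueError("balloon_radius must be > 0")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0")
        if self.dwell_positions < 1:
            raise ValueError("dwell_positions must be >= 1")
        if self.dwell_spacing <= 0:
            raise ValueError("dwell_spacing must be > 0")
        if not 0.0 <= self.excluded_volume_fraction < 0.5:
            raise ValueError("excluded_volume_fraction must be in [0, 0.5)")
        if not 0.0 < self.cold_axis_factor <= 1.0:
            raise ValueError("cold_axis_factor must be in (0, 1]")
        span = (self.dwell_positions - 1) * self.dwell_spacing / 2.0
        if span + abs(self.source_offset[2]) >= self.balloon_radius:
            raise ValueError("dwell chain must stay inside the balloon")

    @property
    def prescription_radius(self) -> float:
        """Radius of the prescription sphere: balloon radius + 1 cm."""
        return self.balloon_radius + SHELL_THICKNESS_CM

    def dwell_coordinates(self) -> np.ndarray:
        """(m, 3) dwell positions, chain centred on source_offset along z."""
        m = self.dwell_positions
        z = (np.arange(m) - (m - 1) / 2.0) * self.dwell_spacing
        pts = np.zeros((m, 3))
        pts[:, 0] = self.source_offset[0]
        pts[:, 1] = self.source_offset[1]
        pts[:, 2] = self.source_offset[2] + z
        return pts


@dataclass(frozen=True)
class PerturbationModel:
    """Per-fraction geometric variation of the applicator.

    Gaussian spreads for balloon radius and centre offset, a uniform range
    for the trapped-air (additional excluded) volume fraction.  Magnitudes
    are study inputs, not measured values; defaults are small.
    """

    radius_sd: float = 0.05
    offset_sd: float = 0.2
    airgap_fraction_range: tuple[float, float] = (0.0, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_sd < 0 or self.offset_sd < 0:
            raise ValueError("spreads must be >= 0")
        lo, hi = self.airgap_fraction_range
        if not 0.0 <= lo <= hi < 0.5:
            raise ValueError("airgap_fraction_range must satisfy 0 <= lo <= hi < 0.5")


# ---------------------------------------------------------------------------
# dose model
# ---------------------------------------------------------------------------

def _spherical_average_inverse_square(r: float, a: float) -> float:
    """Average of 1/|p - s|^2 over the sphere |p| = r, source at |s| = a < r.

    Closed form ``ln((r+a)/(r-a)) / (2 r a)``, with the central limit 1/r^2.
    """
    if a >= r:
        raise ValueError("source must lie inside the averaging sphere")
    if a < 1e-12 * r:
        return 1.0 / (r * r)
    return math.log((r + a) / (r - a)) / (2.0 * r * a)


def _normalization(geom: BalloonGeometry) -> float:
    """Per-dwell strength K so the spherical mean dose at the prescription
    radius equals the prescription dose."""
    r0 = geom.prescription_radius
    avg = sum(
        _spherical_average_inverse_square(r0, float(np.linalg.norm(s)))
        for s in geom.dwell_coordinates()
    )
    return geom.prescription_dose / avg


def dose_at_point(
    geom: BalloonGeometry, point: Sequence[float] | np.ndarray
) -> float | np.ndarray:
    """Inverse-square dose (Gy per fraction) at one point or an (n, 3) array.

    Equal-weight superposition over the dwell positions, normalised so the
    spherical average at the prescription radius equals the prescription
    dose.  A single central dwell therefore reduces to
    ``D(r) = D_rx * (r0 / r)^2``.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    sources = geom.dwell_coordinates()
    diff = pts[:, None, :] - sources[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.any(d2 < 1e-18):
        raise ValueError("point coincides with a dwell position")
    dose = _normalization(geom) * np.sum(1.0 / d2, axis=1)
    if np.ndim(point) == 1:
        return float(dose[0])
    return dose


def shell_mean_dose(geom: BalloonGeometry) -> float:
    """Closed-form mean dose over the ideal shell for a single central dwell:
    ``3 D r0^2 (r0 - R) / (r0^3 - R^3)`` (Gy per fraction)."""
    if geom.dwell_positions != 1 or any(geom.source_offset):
        raise ValueError("closed form applies to a single central dwell only")
    r0, R, D = geom.prescription_radius, geom.balloon_radius, geom.prescription_dose
    return 3.0 * D * r0**2 * (r0 - R) / (r0**3 - R**3)


# ---------------------------------------------------------------------------
# shell sampling
# ---------------------------------------------------------------------------

def _unit_draws(rng: np.random.Generator, n: int) -> tuple[np.ndarray, ...]:
    return rng.random(n), rng.random(n), rng.random(n)


def _shell_points_and_doses(
    plan: BalloonGeometry,
    shell_radius: float,
    center: np.ndarray,
    excluded_fraction: float,
    draws: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> np.ndarray:
    """Map unit draws to shell points around ``center`` and score the dose
    of the (unperturbed) ``plan`` at those points."""
    u_r, u_mu, u_phi = draws
    r_in = shell_radius
    r_out = shell_radius + SHELL_THICKNESS_CM
    # radius with pdf ∝ r^2 (uniform by volume)
    r = np.cbrt(r_in**3 + u_r * (r_out**3 - r_in**3))
    # polar cap of the excluded solid-angle fraction removed at +z
    mu = -1.0 + u_mu * (2.0 - 2.0 * excluded_fraction)
    phi = 2.0 * math.pi * u_phi
    sin_t = np.sqrt(np.clip(1.0 - mu * mu, 0.0, 1.0))
    pts = np.column_stack(
        (r * sin_t * np.cos(phi), r * sin_t * np.sin(phi), r * mu)
    ) + center
    doses = np.asarray(dose_at_point(plan, pts))
    if plan.cold_axis_halfangle > 0:
        cold = np.abs(mu) > math.cos(math.radians(plan.cold_axis_halfangle))
        doses = np.where(cold, doses * plan.cold_axis_factor, doses)
    return doses


def sample_ptv_eval(
    geom: BalloonGeometry,
    n_samples: int,
    seed: int | Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-by-volume dose samples over the 1 cm target shell.

    Returns ``(doses, weights)`` with equal weights.  Points inside the
    cold-axis double cone are attenuated by ``cold_axis_factor``; a polar
    cap of ``excluded_volume_fraction`` of the solid angle is removed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    doses = _shell_points_and_doses(
        geom,
        geom.balloon_radius,
        np.zeros(3),
        geom.excluded_volume_fraction,
        _unit_draws(rng, n_samples),
    )
    weights = np.full(n_samples, 1.0 / n_samples)
    return doses, weights


def generate_fraction_ddvh(
    geom: BalloonGeometry,
    perturbation: PerturbationModel,
    patient_id: int,
    fraction_index: int,
    bin_width: float = 0.1,
    n_samples: int = 200_000,
) -> DifferentialDVH:
    """One fraction's dDVH on the per-fraction dose axis.

    Fraction 1 is the unperturbed planning geometry.  Later fractions draw
    a radius change, a balloon-centre offset and an extra trapped-air
    exclusion from streams seeded by ``(seed, patient_id, fraction_index)``,
    while the dose normalisation (the "plan") stays that of fraction 1.
    The underlying shell sample draws are shared across fractions of a
    patient, so a zero-spread perturbation reproduces fraction 1 exactly.
    """
    pert_rng = np.random.default_rng(
        [perturbation.seed, patient_id, fraction_index]
    )
    if fraction_index == 1:
        radius = geom.balloon_radius
        center = np.zeros(3)
        excluded = geom.excluded_volume_fraction
    else:
        dr = pert_rng.normal(0.0, perturbation.radius_sd) if perturbation.radius_sd else 0.0
        radius = max(geom.balloon_radius + dr, 0.5 * geom.balloon_radius)
        center = (
            pert_rng.normal(0.0, perturbation.offset_sd, size=3)
            if perturbation.offset_sd
            else np.zeros(3)
        )
        lo, hi = perturbation.airgap_fraction_range
        airgap = pert_rng.uniform(lo, hi) if hi > lo else lo
        excluded = min(geom.excluded_volume_fraction + airgap, 0.49)

    sample_rng = np.random.default_rng([perturbation.seed, patient_id, 0])
    doses = _shell_points_and_doses(
        geom, radius, center, excluded, _unit_draws(sample_rng, n_samples)
    )
    weights = np.full(n_samples, 1.0 / n_samples)
    return build_ddvh(
        (doses, weights),
        bin_width=bin_width,
        dose_scale=DoseScale.PER_FRACTION,
        label=f"p{patient_id}_f{fraction_index}",
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults follow the clinical setting emulated here: 19 patients,
    balloon diameters uniform on 4.0-5.5 cm, 7-10 dwell positions scaling
    linearly with diameter, 10 fractions of 3.4 Gy.
    """

    n_patients: int = 19
    diameter_range: tuple[float, float] = (4.0, 5.5)
    n_fractions: int = 10
    bin_width: float = 0.1
    n_samples: int = 200_000
    prescription_dose: float = 3.4
    dwell_spacing: float = 0.5
    cold_axis_halfangle: float = 15.0
    cold_axis_factor: float = 0.85
    excluded_volume_fraction: float = 0.05
    perturbation: PerturbationModel = field(default_factory=PerturbationModel)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range
        if not 0 < lo <= hi:
            raise ValueError("diameter_range must satisfy 0 < lo <= hi")
        if self.n_patients < 1 or self.n_fractions < 1:
            raise ValueError("n_patients and n_fractions must be >= 1")


def dwell_count_for_diameter(
    diameter: float, diameter_range: tuple[float, float] = (4.0, 5.5)
) -> int:
    """Linear map from balloon diameter to dwell-position count, 7 at the
    smallest diameter up to 10 at the largest, rounded to the nearest int."""
    lo, hi = diameter_range
    if hi == lo:
        return 7
    frac = (diameter - lo) / (hi - lo)
    return int(round(7 + 3 * min(max(frac, 0.0), 1.0)))


@dataclass
class PatientRecord:
    patient_id: int
    geometry: BalloonGeometry
    ddvhs: list[DifferentialDVH]


@dataclass
class SyntheticCohort:
    patients: list[PatientRecord]
    n_fractions: int
    bin_width: float
    config: CohortConfig


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Reproducible synthetic cohort: per-patient geometry plus one dDVH per
    fraction, all on the per-fraction dose axis."""
    pert = config.perturbation
    if pert.seed != config.seed:
        pert = PerturbationModel(
            pert.radius_sd, pert.offset_sd, pert.airgap_fraction_range, config.seed
        )
    patients: list[PatientRecord] = []
    for pid in range(1, config.n_patients + 1):
        geo_rng = np.random.default_rng([config.seed, pid])
        diameter = geo_rng.uniform(*config.diameter_range)
        geom = BalloonGeometry(
            balloon_radius=diameter / 2.0,
            prescription_dose=config.prescription_dose,
            dwell_positions=dwell_count_for_diameter(diameter, config.diameter_range),
            dwell_spacing=config.dwell_spacing,
            cold_axis_halfangle=config.cold_axis_halfangle,
            cold_axis_factor=config.cold_axis_factor,
            excluded_volume_fraction=config.excluded_volume_fraction,
        )
        ddvhs = [
            generate_fraction_ddvh(
                geom, pert, pid, f, config.bin_width, config.n_samples
            )
            for f in range(1, config.n_fractions + 1)
        ]
        patients.append(PatientRecord(pid, geom, ddvhs))
    return SyntheticCohort(patients, config.n_fractions, config.bin_width, config)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write per-fraction dDVH CSVs, a manifest, the effective config and a
    per-patient-fraction seed log.  Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    seed_lines = []
    cfg = cohort.config
    for rec in cohort.patients:
        for f, ddvh in enumerate(rec.ddvhs, start=1):
            name = f"{rec.patient_id}_f{f}.csv"
            write_ddvh_csv(ddvh, out_dir / name)
            rows.append(
                {
                    "patient": rec.patient_id,
                    "fraction": f,
                    "path": name,
                    "dose_scale": ddvh.dose_scale.value,
                }
            )
            seed_lines.append(
                f"patient={rec.patient_id} fraction={f} "
                f"seed=({cfg.seed},{rec.patient_id},{f})"
            )
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    pert = cfg.perturbation
    config_lines = [
        f"n_patients = {cfg.n_patients}",
        f"diameter_range = {cfg.diameter_range[0]},{cfg.diameter_range[1]}",
        f"n_fractions = {cfg.n_fractions}",
        f"bin_width = {cfg.bin_width}",
        f"n_samples = {cfg.n_samples}",
        f"prescription_dose = {cfg.prescription_dose}",
        f"dwell_spacing = {cfg.dwell_spacing}",
        f"cold_axis_halfangle = {cfg.cold_axis_halfangle}",
        f"cold_axis_factor = {cfg.cold_axis_factor}",
        f"excluded_volume_fraction = {cfg.excluded_volume_fraction}",
        f"perturbation_radius_sd = {pert.radius_sd}",
        f"perturbation_offset_sd = {pert.offset_sd}",
        f"perturbation_airgap_range = {pert.airgap_fraction_range[0]},{pert.airgap_fraction_range[1]}",
        f"seed = {cfg.seed}",
    ]
    (out_dir / "cohort_config.txt").write_text("\n".join(config_lines) + "\n")
    (out_dir / "seeds.log").write_text("\n".join(seed_lines) + "\n")
    return manifest
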