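# Methods

## Dose-volume histograms

A differential DVH (dDVH) stores, per half-open dose bin `(lower, upper]`,
the percentage of target volume receiving a dose in that bin. The half-open
convention means a dose lying exactly on an edge belongs to the bin below
it. Bins are contiguous, share one width (default 0.1 Gy, configurable),
and live on a global integer grid: bin `k` always covers
`(k·w, (k+1)·w]`. Storing the integer index of the first bin rather than
floating-point edges makes edge alignment, histogram union and group
averaging exact, and protects range queries from accumulated rounding in
`k·w`. A complete dDVH sums to 100 % within 1e-6; deliberately partial
histograms (e.g. a published table fragment) can be constructed with
`validate_total=False`, and every statistic still works on them.

Each dDVH carries a mandatory `dose_scale` flag (`per_fraction` or
`total_course`). The survival-averaging formulas consume per-fraction bin
doses, and silently mixing the two axes is the most dangerous mistake a
user can make, so any BED routine handed a total-course histogram raises
and names the conversion (`rescale_dose_axis`).

Numerical choices:

* **Bin representative dose** is the midpoint. With 0.1 Gy bins, the
  midpoint bounds the quantization error of any bin statistic at 0.05 Gy,
  the minimax choice among lower edge / midpoint / upper edge.
* **Modal dose ties** break to the lowest-dose bin (deterministic).
* **Edge snapping**: a sample dose within a relative 1e-9 of an exact bin
  edge is treated as on the edge. Without the snap, binary representation
  of decimal doses (34.0 / 0.1) could flip bins.
* Cumulative DVHs are suffix sums at the bin lower edges; the
  differential↔cumulative round trip is exact to 1e-9.

## BED quantities

All four quantities follow the linear-quadratic model with survival
`ln S = -α n d (1 + d/(α/β))` and an optional repopulation correction
`ln2·T/(α·T_eff)`:

* conventional: `n d (1 + d/(α/β)) - ln2·T/(α·T_eff)`;
* DVH-weighted constant case (CC): survival is volume-averaged over the
  fraction-1 dDVH raised to the full n-fraction exponent;
* per-fraction: single-fraction exponent with a 1/n share of the
  repopulation term;
* interfraction total (IVC): sum of per-fraction values over the delivered
  fractions.

**Log-domain arithmetic.** In a balloon geometry the per-bin exponent
`α n d_i (1 + d_i/(α/β))` exceeds 2000 for bins near the balloon surface;
naive exponentiation underflows every term to zero. The volume-weighted
survival average is therefore computed as a log-sum-exp
(`scipy.special.logsumexp` with the volumes as linear weights), which is
exact up to machine rounding for arbitrarily large negative exponents. The
test suite verifies every BED routine against a direct 60-significant-digit
`decimal` evaluation of the same expressions (1e-10 relative, dDVHs up to
1000 bins, exponents past −10⁶).

**Weight tolerance.** Bin volumes must sum to 1 (unit fractions) within
1e-6; by default a violation raises, and `renormalize=True` rescales
instead. Rescaling silently would hide truncated histograms.

**Endpoint registry.** fibrosis (α/β = 2 Gy), telangiectasia (4 Gy),
erythema (8 Gy, repopulation), desquamation (11 Gy, repopulation), breast
carcinoma (4 Gy, no repopulation by default — the reference uniform-dose
value for carcinoma equals the no-repopulation formula at α/β = 4; enable
repopulation explicitly via `dataclasses.replace` to study it). All use
α = 0.3 Gy⁻¹ and T_eff = 13 d.

**Elapsed time.** The reference scheme is 34 Gy in 10 fractions. The
elapsed treatment time enters only through the repopulation term; the
package default is T = 5.5 days, the unique half-day value for which the
conventional BED reproduces both reference acute-endpoint values at one
decimal (47.5 and 43.5 Gy) — consistent with a twice-daily schedule over
roughly a week. It is configurable per scheme.

**CC/IVC equality holds only for one bin.** For identical per-fraction
distributions, `Σ_i v_i s_i^n ≥ (Σ_i v_i s_i)^n` (Jensen, convexity of
x↦xⁿ), so the per-fraction sum (IVC) is ≥ the constant-case value, with
equality exactly when one bin is occupied. Both forms are implemented as
written; the strict gap for multi-bin histograms is an invariant of the
formulas, not an implementation artifact, and is covered by tests.

**Missing fractions.** When fewer fraction dDVHs exist than the scheme's n
(a missing pre-fraction CT), the delivered count replaces n both in the
per-fraction repopulation share and in the CC comparator, so the full
elapsed-time repopulation correction is subtracted exactly once and the
comparison stays like-for-like. The delivered count is recorded on every
comparison row.

## Synthetic cohort generator

The generator emulates the dose structure of a balloon applicator, not its
TG-43 physics:

* **Dose model**: equal-weight inverse-square superposition over 7–10
  dwell positions spaced 0.5 cm along the catheter (z) axis, normalised so
  the spherical average at the prescription radius (balloon radius + 1 cm)
  equals the per-fraction prescription (3.4 Gy). A single central dwell
  reduces to `D(r) = D_rx (r0/r)²`, for which the shell-mean has the closed
  form `3 D r0² (r0 − R)/(r0³ − R³)` used as a test oracle (46.7 Gy on the
  10-fraction scale for a 4.6 cm balloon). No radial dose function,
  anisotropy or dwell-time optimisation: the downstream analysis consumes
  only dDVHs, and what drives every BED result is the shape — above 200 %
  of prescription at the balloon surface, prescription at the shell's outer
  radius, a sub-prescription tail.
* **Target sampling**: points uniform by volume in the 1 cm shell; a polar
  cap of `excluded_volume_fraction` (default 0.05) of the solid angle is
  removed to emulate skin/lung exclusions; points within
  `cold_axis_halfangle` (default 15°) of the catheter axis are attenuated
  by `cold_axis_factor` (default 0.85), a one-parameter stand-in for the
  line-source cold spot.
* **Per-fraction perturbation**: balloon radius change ~ N(0, 0.05 cm),
  balloon-centre offset ~ N(0, 0.2 cm) per axis, extra trapped-air
  exclusion ~ U(0, 0.02), all truncated to keep the geometry valid. These
  magnitudes are plausible placeholders — the geometric variation of real
  applicators is not quantified here — and should be set explicitly for any
  study. Dose normalisation always stays tied to the unperturbed fraction-1
  plan, mirroring the clinical reuse of the fraction-1 dwell times.
* **Seeding**: perturbations draw from a stream keyed by
  `(seed, patient, fraction)`; the shell sample draws are keyed by
  `(seed, patient)` and shared across that patient's fractions, so a
  zero-spread perturbation reproduces fraction 1 bit-for-bit and the
  constant-case limit is exact rather than Monte-Carlo-approximate.
* **Cohort defaults**: 19 patients, balloon diameters uniform on
  4.0–5.5 cm, dwell count mapped linearly from diameter (7 at 4.0 cm to 10
  at 5.5 cm, rounded), 10 fractions, 200 000 samples per fraction — enough
  to keep 0.1 Gy-bin volume noise below ~0.05 % while a full cohort
  generates in well under a minute on one core.

What the generator does **not** emulate: real contouring, dwell-time
surface optimisation (weights are equal, so fraction-1 coverage is less
conformal than a clinical plan), CT-derived anatomy, balloon deformation
beyond a radius change, or correlated fraction-to-fraction drift. Passing
tests on this cohort therefore demonstrate the formalism's behaviour on
dose distributions with the right qualitative structure, not agreement
with any real patient statistics.

## Cohort pipeline

`compare_cc_ivc` scores fraction-1-held-constant vs per-fraction-summed
BED per patient; `compare_h_c` scores conventional vs DVH-weighted.
Differences are reported in Gy and as a percent of the first member (CC
for the IVC comparison, the conventional value for the method comparison —
fixed denominators, not configurable, to avoid silent metric drift).
Summaries use the sample SD (n−1) and attribute min/max to patient ids.
Reports are written twice: unrounded JSON (sorted keys, byte-reproducible
under a fixed seed) and display CSVs rounded half away from zero at one
decimal. The per-patient BED curves sweep α/β over {2, 4, 8, 11} Gy with
each ratio's registry repopulation convention.

## Known limitations

* The LQ model itself is calibrated on uniform irradiation; survival
  averaging over a DVH inherits all its assumptions (no dose-rate or
  repair-kinetics terms, no delay before repopulation starts).
* One dDVH stands in for all endpoints: tissue-specific sub-volumes cannot
  be resolved, so the same histogram feeds every α/β.
* The synthetic perturbation magnitudes are not fitted to measured
  applicator motion; cohort-level difference magnitudes from the default
  generator characterise the formalism, not a clinical population.
* Dose bins below bin resolution are not interpolated; all statistics are
  exact at the bin level only.
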