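# brachybed

Biologically effective dose (BED) calculations for multi-fraction HDR
balloon brachytherapy that account for the strongly nonuniform dose the
target actually receives, instead of assuming every cell gets the
prescription dose.

## Who this is for

Medical physicists and radiobiology researchers comparing fractionation
schemes in accelerated partial-breast irradiation with a balloon applicator
(MammoSite-style), where an Ir-192 source steps through dwell positions
inside a balloon and the target is the 1 cm tissue shell around it. The
dose in that shell falls off steeply: the balloon surface sees more than
200 % of the prescription while cold regions along the catheter axis fall
below it, so a uniform-dose BED can be badly misleading for endpoints with
a low α/β ratio.

## The model

Linear-quadratic cell survival for `n` fractions of dose `d`:

    S = exp[ -α n d (1 + d/(α/β)) ]

**Conventional BED (C-method)** assumes a uniform prescription dose:

    BED_C = n d (1 + d/(α/β)) - ln2 · T / (α · T_eff)

with the repopulation subtraction applied only to acute-responding
endpoints (erythema, desquamation); `T` is the elapsed treatment time and
`T_eff` the effective doubling time.

**Heterogeneity-corrected BED (H-method)** averages *survival*, not dose,
over the differential DVH `{v_i, d_i}` (fractional volume `v_i` at
per-fraction bin dose `d_i`):

    BED_H = -(1/α) ln[ Σ_i v_i exp(-α n d_i (1 + d_i/(α/β))) ] - ln2·T/(α·T_eff)

When each delivered fraction `f` has its own distribution (interfraction
variation case, IVC), a per-fraction BED with a 1/n repopulation share is
computed from each fraction's DVH and summed:

    BED_IVC = Σ_f BED_f,   BED_f = -(1/α) ln[ Σ_i v_i exp(-α d_i (1 + d_i/(α/β))) ] - ln2·T/(n α T_eff)

Per-bin exponents reach magnitudes of thousands at the balloon surface, so
all averaging runs in the log domain through a log-sum-exp reduction.

The package registry ships five endpoints: fibrosis (α/β = 2 Gy),
telangiectasia (4 Gy), erythema (8 Gy, with repopulation), desquamation
(11 Gy, with repopulation) and breast carcinoma (4 Gy), all with
α = 0.3 Gy⁻¹ and T_eff = 13 d; the reference scheme is 34 Gy in 10
fractions of 3.4 Gy over 5.5 elapsed days.

Because no clinical DVH data are distributed with the package, a seeded
synthetic generator emulates the balloon dose structure (inverse-square
multi-dwell fall-off, prescription at the 1 cm expansion, cold axial tail,
skin/lung exclusion cap, per-fraction geometric perturbations) and a cohort
pipeline runs the CC-vs-IVC and H-vs-C comparisons across patients.

## Worked example

```python
from brachybed import (BalloonGeometry, DEFAULT_SCHEME, ENDPOINTS, DoseScale,
                       build_ddvh, sample_ptv_eval, mean_dose, modal_dose,
                       bed_conventional, bed_heterogeneous_cc)

geom = BalloonGeometry(balloon_radius=2.3, dwell_positions=8,
                       cold_axis_halfangle=15.0, excluded_volume_fraction=0.05)
doses, weights = sample_ptv_eval(geom, 200_000, seed=1)
ddvh = build_ddvh((doses, weights), bin_width=0.1,
                  dose_scale=DoseScale.PER_FRACTION)
print(f"mean dose (course): {10*mean_dose(ddvh):.1f} Gy, "
      f"modal: {10*modal_dose(ddvh):.1f} Gy")
for name in ("fibrosis", "telangiectasia", "erythema", "desquamation"):
    ep = ENDPOINTS[name]
    c = bed_conventional(DEFAULT_SCHEME, ep).value
    h = bed_heterogeneous_cc(ddvh, DEFAULT_SCHEME, ep).value
    print(f"{name:15s} BED_C = {c:5.1f} Gy   BED_H = {h:5.1f} Gy   "
          f"rel. diff = {100*(h-c)/c:+5.1f} %")
```

prints

```
mean dose (course): 46.2 Gy, modal: 34.5 Gy
fibrosis        BED_C =  91.8 Gy   BED_H =  85.2 Gy   rel. diff =  -7.2 %
telangiectasia  BED_C =  62.9 Gy   BED_H =  61.9 Gy   rel. diff =  -1.6 %
erythema        BED_C =  47.5 Gy   BED_H =  48.7 Gy   rel. diff =  +2.7 %
desquamation    BED_C =  43.5 Gy   BED_H =  45.3 Gy   rel. diff =  +4.1 %
```

The course mean dose (46.2 Gy) sits far above the 34 Gy prescription — the
hot shell near the balloon dominates the volume — yet the fibrosis BED
*drops* by 7 % when heterogeneity is accounted for, because at α/β = 2 Gy
the survival average is controlled by the cold axial tail. For the acute
endpoints (high α/β) the correction goes the other way. That sign flip is
the central behaviour the package computes.

The same operations are available from the shell:

```bash
brachybed bed --endpoint fibrosis            # -> conventional BED[fibrosis] = 91.8 Gy
brachybed simulate --seed 3 --out-dir cohort --n-patients 19
brachybed compare cohort/manifest.csv --out-dir report
```

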