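# vqfv — functional lung volumes from V/Q PET/CT

`vqfv` delineates **functional lung volumes** — the ventilated or
perfused part of the lung — from paired ⁶⁸Ga-V/Q PET/CT images, using a
threshold expressed as a percentage of the maximum PET value inside the
lungs (%max), and provides everything needed to evaluate that method
quantitatively: CT whole-lung segmentation, hot-spot-robust maximum
estimation, threshold sweeps, an adaptive semi-automatic protocol, and
the agreement statistics (volume difference, Dice, Pearson,
Bland-Altman, correlation with pulmonary-function tests).  Because
clinical reference contours are expert-drawn and rarely shareable, the
package ships a digital thoracic phantom generator with known ground
truth on which the full chain is validated.

It is written for medical-imaging researchers working on functional
lung avoidance (radiotherapy planning), pre-surgical lung assessment,
and quantitative V/Q PET methodology.

## The method in brief

For a whole-lung mask *WL* (from CT, HU < −400 plus morphological
cleanup) and a PET activity image *A*, the functional volume at cutoff
*c* is

    V(c) = { v ∈ WL : A(v) ≥ (c/100) · A_max },   reported as 100·|V(c)|/|WL|

where *A_max* is the in-lung maximum **after excluding focal airway
deposition** ("hot spots"), which would otherwise inflate the maximum
and shrink every volume.  The standard sweep is c ∈ {5, 10, 15, 20, 25,
30, 40, 50}; the recommended semi-automatic protocol starts at 15%max
and walks to neighbouring cutoffs while an objective improves.
Agreement with a reference contour is summarised by the signed volume
difference (%WL points), Dice `2|A∩B|/(|A|+|B|)`, Pearson r, and
Bland-Altman bias ± 1.96 SD.

## Worked example

```python
from vqfv import (PhantomSpec, generate_phantom, segment_lungs,
                  estimate_max, sweep, evaluate_case)

# a synthetic case: 70% of the lung functional, AP gradient, PSF blur,
# Poisson noise
pc = generate_phantom(PhantomSpec(functional_fraction=0.7, seed=3))
wl = segment_lungs(pc.case.ct)                      # whole lung from CT
mx = estimate_max(pc.case.pet_vent, wl)             # hot-spot-robust max
sw = sweep(pc.case.pet_vent, wl, mx)                # 8-cutoff sweep
for e in evaluate_case(sw, pc.truth_functional_vent, wl):
    print(f"{e.cutoff_pct:4.0f}%max  vol {e.volume_pct_wl_auto:5.1f} %WL"
          f"  diff {e.volume_diff:+6.2f}  DSC {e.dsc:.3f}")
```

prints

```
   5%max  vol  94.2 %WL  diff +24.17  DSC 0.853
  10%max  vol  90.6 %WL  diff +20.58  DSC 0.872
  15%max  vol  84.0 %WL  diff +14.04  DSC 0.909
  20%max  vol  76.7 %WL  diff  +6.68  DSC 0.954
  25%max  vol  74.3 %WL  diff  +4.35  DSC 0.968
  30%max  vol  72.3 %WL  diff  +2.36  DSC 0.976
  40%max  vol  67.2 %WL  diff  -2.81  DSC 0.968
  50%max  vol  59.0 %WL  diff -10.99  DSC 0.914
```

Each row is one cutoff: the delineated volume as a percentage of the
whole lung, its signed difference from the ground-truth functional
volume (70% of WL here), and the Dice overlap with truth.  Low cutoffs
over-segment (blur fills the defects), high cutoffs under-segment; on
this noisy phantom the best match sits near 30%max — which is exactly
why the package also provides the adaptive per-case protocol
(`vqfv.adaptive_delineate`) instead of trusting one fixed threshold.

A shell workflow is available through the `vqfv` CLI
(`vqfv phantom`, `vqfv segment-lungs`, `vqfv delineate`, `vqfv sweep`,
`vqfv evaluate`, `vqfv cohort-report`, `vqfv run`, `vqfv adaptive`);
see `vqfv --help`.

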