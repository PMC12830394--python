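# vmre — diffusion-weighted virtual MR elastography

Liver fibrosis is staged histologically on the METAVIR scale (F0 no
fibrosis … F4 cirrhosis), but biopsy is invasive and poorly suited to
follow-up. Conventional MR elastography (MRE) measures liver stiffness
non-invasively yet needs a mechanical driver that many centers lack.
**Virtual MR elastography (VMRE)** estimates a surrogate stiffness from a
routine diffusion-weighted MRI (DWI) series instead: the *shifted apparent
diffusion coefficient* between two non-zero b-values (chosen to suppress
perfusion) is mapped to kPa through a linear calibration against MRE.

This package implements that analysis end to end, together with a synthetic
data generator that makes every stage testable without clinical data:

* **Maps** — from paired b = 200 / 1500 s/mm² magnitude volumes,

  `sADC = ln(S200 / S1500) / 1300`  (mm²/s)

  `VMRE [kPa] = α · sADC + β`,  α = −12.740 kPa per 10⁻³ mm²/s, β = 14.0 kPa

* **ROIs** — reader ROIs spanning ≥ 3 consecutive slices for VMRE; 10 mm
  circular ROIs, two per acquisition, with the elastography quality rule
  IQR/median ≤ 30 % for shear-wave ultrasound (USE).
* **Staging** — continuous kPa values classified into F0–F4 with fixed
  per-stage MRE reference means (2.13, 2.49, 2.83, 3.6, 5.2 kPa), boundaries
  at midpoints of consecutive means; exact / within-one-stage / binary
  (F0–1 vs F2–4, F0–2 vs F3–4) concordance against reference stages.
* **Diagnostics** — empirical ROC with the Youden-index cutoff and
  sensitivity/specificity/PPV/NPV/accuracy, ICC(2,1) with F-based CI,
  Bland–Altman, Kruskal–Wallis + Bonferroni-adjusted Dunn post hoc tests,
  one-way ANOVA, Lilliefors-corrected normality screening, per-stage
  descriptives.
* **Synthetic data** — DWI block phantoms with Rician magnitude noise and a
  49-patient cohort (stage mix 8/16/6/12/7, 67 % HBV, two VMRE readers, two
  USE acquisitions per patient).

## Worked example

```bash
vmre run-all --seed 7 --outdir out
```

runs simulate → map → ROI → stage → statistics and writes `out/cohort.csv`,
`out/report.json` and `out/manifest.json`. With seed 7 the report contains
(abridged):

```
imaging_path.F0:      true_mean_kpa 2.1336, measured_median_kpa 2.2129
agreement.vmre_readers.icc:        0.974
roc.F02_vs_F34.use:   auc 0.88, cutoff 10.77 kPa, sensitivity 89 %, specificity 80 %
staging_vs_reference: exact 26/49 (53 %), within one stage 47/49 (96 %)
kruskal_wallis_vmre:  H = 34.39, p < 0.001
```

Reading: the phantom imaging path reconstructs the generated stage-F0
stiffness level to ~0.1 kPa (small Rician bias at SNR 30); the two simulated
readers agree at ICC ≈ 0.97; ultrasound separates advanced from early
fibrosis with AUC ≈ 0.9 at a ~10.8 kPa cutoff; and staging the per-patient
VMRE means against the fixed MRE thresholds matches the generating stage
exactly in about half of the patients.

The same stages are available from Python:

```python
import numpy as np
from vmre import SimulationConfig, generate_phantom, compute_sadc_map, sadc_to_vmre

cfg = SimulationConfig(seed=7, snr=np.inf)
dwi, labels, stiffness = generate_phantom(cfg, "F2")
vmre_map = sadc_to_vmre(compute_sadc_map(dwi))
print(np.abs(vmre_map.values[labels > 0] - stiffness[labels > 0]).max())
# 3.55e-15  (noise-free round-trip is exact to float precision)
```

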