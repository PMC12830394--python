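# Methods

## Signal model and calibration

A diffusion-weighted series acquired at two non-zero b-values
(b₁ = 200 s/mm², b₂ = 1500 s/mm²) is assumed to decay mono-exponentially
between them, so the shifted apparent diffusion coefficient is

    sADC = ln(S_b1 / S_b2) / (b2 − b1).

Starting the decay at b = 200 rather than b = 0 suppresses the perfusion
(pseudo-diffusion) contribution that dominates at low b. Internally sADC is
stored in units of 10⁻³ mm²/s, the scale on which the published linear
calibration to MR-elastography stiffness applies:

    VMRE [kPa] = α · sADC + β,   α = −12.740, β = 14.0.

α < 0 encodes the empirical observation that fibrotic (stiff) liver
restricts diffusion. The transform is affine, so it commutes with ROI
averaging; per-patient statistics can equivalently be taken in either unit.

Voxels with a non-positive signal in either channel are masked invalid
rather than clamped — clamping would fabricate extreme diffusivities.
Negative sADC values (noise-inverted decay) are retained in the map and
flagged in a secondary "physical" mask; ROI statistics use the validity
mask only by default, so noisy ROIs are not silently biased by discarding
their low tail.

## Synthetic data

The generator produces the two kinds of objects the pipeline consumes.

**Phantoms.** A single-organ block phantom draws a voxelwise stiffness
field from a stage's (mean, SD) — defaults are the standard MRE per-stage
references F0 2.13±0.27 … F4 5.2±1.02 kPa — floored at 0.1 kPa, inverts
the calibration line to a sADC field, and synthesizes S200 = S₀ and
S1500 = S₀·exp(−1300·sADC). Stiffness values at or above β = 14 kPa map to
non-positive sADC (the linear calibration admits non-physical values at its
high end); such voxels are excluded from the label volume rather than
clamped. Magnitude noise is Rician — observed = √((S+n₁)² + n₂²) with
n₁, n₂ ~ N(0, σ²) and σ = S₀/SNR — the standard MR magnitude noise model;
no acquisition noise level is prescribed by the design, so SNR is a free
knob with default 30. At SNR 30 the reconstruction carries a small positive
Rician bias (~0.04 kPa at a 4 kPa level, calibrated by replicate
simulation before the main build; the frozen test band is 3.95–4.10 kPa).

**Cohorts.** The default cohort has 49 patients with METAVIR stage counts
8/16/6/12/7 (F0…F4) and a 67 % HBV fraction realized exactly
(round(0.67·49) = 33 patients chosen by a seeded permutation; the remainder
alternate MASLD/other). Per patient: a true virtual stiffness drawn from
the stage's reference distribution; two reader measurements = truth +
independent N(0, σ_r²); and two shear-wave ultrasound acquisition means
drawn independently from per-stage ultrasound distributions (F0 6.0±4.11 …
F4 18.05±4.84 kPa, truncated positive). The reader SD default σ_r = 0.21 kPa
was fixed by a variance-components calibration before the main build: over
200 simulated cohorts it yields a mean ICC(2,1) of ≈ 0.97, and it equals
the per-reader noise implied by an inter-reader difference SD of ≈ 0.3 kPa
(0.3/√2). A single global seed fans out to keyed substreams (component ×
stage) via `SeedSequence(seed, spawn_key=…)`, so adding a stage or
component leaves the other streams untouched; identical config + seed gives
bit-identical volumes and tables.

What the generator does **not** emulate: anatomy (no capsule, vessels or
artifacts, so depth rules are metadata-only), fat/iron confounding of the
diffusion signal, breathing motion, and any correlation between a patient's
ultrasound values and their individual VMRE truth beyond the shared stage.
Because the cohort's VMRE truth is drawn from the same per-stage reference
distributions that define the staging thresholds, fixed-threshold staging
concordance and VMRE AUCs are substantially higher in simulation than in
clinical data, where the two quantities are only weakly linked; passing
tests therefore validate the computational pipeline, not clinical
performance.

## ROI protocol

Virtual-elastography ROI sets must span at least three consecutive axial
slices; the per-patient summary defaults to the mean of per-ROI means
(median optional — whether pooled-voxel or ROI-mean aggregation is used in
practice varies, so both levels use the same selectable statistic).
Ultrasound ROIs are 10 mm circles rasterized by the voxel-center rule with
boundary ties included; the quality rule IQR/median ≤ 0.30 is inclusive at
the boundary and uses linear-interpolation (type-7) quartiles — the
convention is fixed and documented for reproducibility. The two readers
combine by arithmetic mean; the ultrasound protocol takes the mean of the
two ROIs per acquisition, then the mean of the two acquisition means.

## Staging rule

The per-stage reference table gives means (and SDs, carried but unused by
the default rule). The continuous-to-stage assignment places boundaries at
midpoints of consecutive means (2.31, 2.66, 3.215, 4.4 kPa): it partitions
the line completely and preserves order. A nearest-mean rule is provided
for sensitivity analysis; for any strictly increasing means the two rules
coincide. Boundary ties go to the lower (less severe) stage — conservative
staging. Probabilistic assignment from the SD columns is deliberately out
of scope. Reported percentages round half away from zero to integers.

## Statistics

* **ROC / Youden.** Empirical ROC over all distinct thresholds; AUC by the
  trapezoid rule (identical to the Mann–Whitney pairwise-concordance
  statistic with ties counted ½, which the tests verify to 1e−12). The
  operating cutoff is the observed value maximizing J = sensitivity +
  specificity − 1 under the convention "value ≥ cutoff ⇒ positive"
  (positive class = higher stiffness); ties break toward higher
  specificity, then the lower cutoff. The AUC CI is a seeded stratified
  bootstrap (2000 resamples within each class, percentile interval).
* **ICC.** Two-way random effects, absolute agreement, single measures
  (ICC(2,1)) from the ANOVA mean squares, with the standard F-based 95 % CI
  — two fixed raters measuring the same subjects, where agreement rather
  than mere consistency is the clinical question. Identical columns with
  subject variation return 1 with a warning; zero total variance returns
  NaN flagged.
* **Bland–Altman.** Mean and sample SD of differences with both ±1.96 SD
  and ±1 SD bands reported.
* **Kruskal–Wallis / Dunn.** Tie-corrected H with the χ²(k−1) p-value;
  the all-tied degenerate case returns H = 0, p = 1 with a warning. Dunn
  z-statistics on pooled mid-ranks with the tie correction, two-sided
  normal p, Bonferroni adjustment min(1, p·m), m = k(k−1)/2 (10 for five
  stages). A vectorized permutation oracle (`kruskal_wallis_permutation_p`)
  accompanies the test: at very small group sizes (3×3) the χ²
  approximation deviates from the exact permutation p by up to ~0.05, far
  more than the Monte-Carlo error of a 10⁵-resample estimate — a known
  limitation of the asymptotic test at n = 9, surfaced honestly by the
  test suite rather than hidden.
* **ANOVA.** Between/within mean squares; the two-group case equals the
  squared pooled t (verified).
* **Normality.** One-sample KS against a Normal with estimated mean/SD;
  because parameters are estimated, the null distribution is simulated
  (seeded Monte-Carlo Lilliefors, default 1000 replicates, p with the
  (1+#exceed)/(B+1) estimator).

## Pipeline

`run_all` decouples the phantom-imaging path from the cohort-statistics
path: per-patient measurements come directly from the cohort generator,
while the full imaging chain (phantom → NIfTI → sADC → VMRE → ROI) runs on
a configurable number of per-stage phantoms (default small) to validate the
voxel pipeline at modest runtime; default problem sizes are 32³ voxel
phantoms and the 49-patient cohort. The HBV subset is analyzed separately
when present. Statistics blocks that need two classes or two groups fail
gracefully with a named error recorded in the report instead of aborting
the run. Reports are schema-versioned JSON; rerunning with the same config
and seed reproduces byte-identical CSV/JSON payloads (the manifest's
wall-clock timings are the only run-specific output).

## Known limitations

The linear calibration is cohort- and protocol-specific (b-value pair,
breathing scheme and field strength shift it); the package treats α, β as
configurable constants. The χ² Kruskal–Wallis p is unreliable below ~5 per
group — use the permutation oracle there. The ultrasound intra-observer
ICC of the generator is lower than typical clinical values because the two
acquisitions share only their stage, not a patient-level ultrasound truth.
Rician bias is not corrected in map reconstruction.
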