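# Methods

## Forward model

A voxel of tissue class $(\mathrm{CBF}, \mathrm{CBV}, \mathrm{MTT})$
enhances as the convolution of the arterial input function (AIF) with a
mono-exponential residue, scaled by flow:

$$C(t) = \frac{\mathrm{CBF}}{6000}\,(C_a * R)(t), \qquad R(t) = e^{-t/\mathrm{MTT}}.$$

The AIF is a gamma variate $A\,(t-t_0)^{\alpha}e^{-(t-t_0)/\beta}$ with
defaults $t_0 = 5$ s, $\alpha = 3$, $\beta = 1.5$ s and amplitude scaled so
the peak is 300 HU at $t_0+\alpha\beta = 9.5$ s — a typical first-pass
arterial bolus.  The mono-exponential residue is the simplest form
consistent with the central volume principle, which every tissue class
enforces at construction ($|\mathrm{CBV}-\mathrm{CBF}\cdot\mathrm{MTT}/60|
< 10^{-9}$).

Discretisation: the residue is sampled as its average over each 1-s
interval rather than at sample points.  This makes the rectangle-rule
convolution conserve area — the discrete AUC of a tissue curve equals
$\mathrm{CBV}/100$ times the arterial AUC up to the washout tail — so CBV
estimated from AUC ratios is unbiased by construction, and the
deconvolution round trip is exact in the noiseless limit.

Default tissue classes (CBV ml/100 g, MTT s): healthy grey matter (4, 4),
penumbra (3, 8), core (1, 12).  They straddle both segmentation thresholds
with margin, so noiseless segmentation must recover the ground truth
exactly — that is a test, not a tuning target.  A white-matter class
(2.4, 4.8) is provided but not used by the default phantom, keeping the
healthy hemisphere homogeneous.

## Acquisition grid and lesion geometry

The phantom grid is 64 x 64 x 8 voxels at 3 x 3 x 5 mm, 60 s of samples at
1 s — desk-scale, but large enough that millilitre-level volumetry is
meaningful.  The brain mask is an elliptic cylinder through the slab; the
midline plane is the central sagittal index.  Lesions are two nested
ellipsoids (core inside penumbra) sharing a centre placed mid-hemisphere,
with a 1:2 in-plane aspect and the z semi-axis capped at the slab
half-thickness (large stroke lesions extend beyond a 4-cm slab; the
through-plane cap models the limited coverage).  Semi-axes are solved by
bisection so the rasterised, hemisphere-clipped volume matches the sampled
patient volume to within one symmetric voxel shell (~0.5 ml).  Targets
beyond the hemisphere capacity (~250 ml, far above the cohort medians) are
capped and flagged.  Acquisition noise is additive i.i.d. Gaussian HU with
default sigma 2.

## Map estimation

CBV is the AUC ratio (trapezoid rule) scaled by 100 and an optional
correction factor $k$ (default 1).  Voxels with AUC below 0.2 % of the
arterial AUC are invalid: the threshold only rejects voxels with
essentially no contrast arrival, because ischemic core at CBV 1 ml/100 g
sits at 1 % of the arterial AUC and must stay valid.

MTT uses the delay-insensitive block-circulant formulation: the arterial
convolution operator is built from the zero-padded AIF (padding factor 2),
inverted by SVD with singular values below 0.2 of the maximum discarded,
and applied to each voxel curve, giving the flow-scaled residue $k(t)$.
The raw statistic is $\mathrm{AUC}(k)/\max k$ with a trapezoid AUC.

**Operator-response calibration.**  Hard spectral truncation smears the
residue peak, which biases the raw statistic upward by a large,
MTT-dependent factor (a true 4 s reads about 6.3 s at truncation 0.2) and
compresses lesion-to-healthy MTT ratios toward the 1.45 segmentation
threshold.  Because the bias is a deterministic, scale-invariant property
of the operator, it is removed exactly: unit-flow exponential residues of
known transit time are pushed through the identical pipeline once, and the
resulting monotone response $\tau \mapsto \hat\tau$ is inverted by linear
interpolation (clamped outside the tabulated 0.5–30 s range).  The
calibration uses only the AIF and the configuration — no ground truth —
and is on by default.  For real data whose residue is not exponential the
correction is approximate; it can be disabled.

**Noise-adaptive smoothing.**  Per-voxel noise is estimated from second
temporal differences (MAD-based, insensitive to the smooth bolus signal).
When it exceeds 0.1 HU, a Gaussian of 1 voxel sigma is applied in-plane
(never across the 5-mm slices) before map estimation; noiseless data are
left untouched so that noiseless estimates are voxel-exact.

CBF is defined as $60\,\mathrm{CBV}/\mathrm{MTT}$, making the
indicator-dilution identity definitional rather than a statistical
property; the validity mask is the conjunction of the CBV and MTT masks.

## Segmentation and artifact removal

Hypoperfusion: MTT above 1.45 times the contralateral reference, the
median MTT over valid voxels of the opposite hemisphere (median for
robustness to stray voxels).  Core: additionally CBV < 2.0 ml/100 g.  A
voxel with CBV exactly 2.0 goes to penumbra — the published rule uses two
strict inequalities and leaves the boundary open, so the tie-break is a
documented choice.  Invalid voxels join neither mask.

Artifact removal always clips to the brain mask and deletes 26-connected
components of the union mask smaller than 0.5 ml.  For noisy acquisitions
the pipeline additionally applies a morphological repair: one binary
closing pass and enclosed-hole filling (slice-wise, then volumetric), with
the repaired union re-split by the CBV rule.  The rationale: at 2 HU noise
the low-CBV core has per-voxel curve SNR near 1, so its MTT estimate is
unreliable voxel-by-voxel and speckle holes appear inside the lesion; the
core is, however, always enclosed by the penumbra ring, so hole filling
recovers it and the (robust) CBV split assigns it correctly.  Both repair
steps are off in the library defaults, so the pure threshold rule is what
default calls compute — and what the noiseless-exactness tests check.

Mismatch is penumbra over total hypoperfused volume; at total 0 it is
defined as 1.0 with a degenerate flag so lesion-free cases do not break
cohort summaries.

## Final-infarct segmentation

Follow-up CT shows the infarct as a 15 HU hypodensity on a 32 HU
parenchyma with 2 HU noise.  Region growing is breadth-first from the seed
with a running-mean similarity criterion (tolerance 8 HU, 6-connectivity),
deterministic by FIFO order and fixed neighbour ordering.  The clinical
workflow's manual outlining is replaced by a radius-1 closing and a guard
that stops (and flags) growth beyond half the brain volume.  The criterion
and tolerance are documented defaults — the source workflow specifies
neither.

## Cohorts

Each period's preset stores the published medians/IQRs and frequencies.
Continuous volumes are log-normal with $\mu = \ln(\text{median})$ and
$\sigma$ from the quartile ratio; distributions whose printed first
quartile is 0 (core volume in both periods, final infarct in the reference
period) are zero-inflated: a 25 % point mass at zero plus a log-normal
solved so the overall median and third quartile match exactly.  Total,
core and infarct volumes are drawn comonotonically (one uniform per
patient), so larger strokes have larger cores and infarcts and core ≤
total holds by construction.  NIHSS is drawn from a quartile-fitted
log-normal rounded to integers; the NIHSS ≥ 10 flag derives from the score
(the fitted distributions imply prevalences of about 54 % and 30 %,
consistent with the published 57 % / 31 %).  Sex, vessel-occlusion,
unknown-onset and risk-factor flags are Bernoulli with the printed
frequencies.

For the imaging chain the cohort uses median-unbiased quantile
stratification (plotting positions $(i-0.5)/n$ in seeded random order)
instead of i.i.d. draws: with n = 30 and log-sigma 1.6 the i.i.d. sample
median alone varies by about ±40 % across seeds, which would swamp any
statement about the method.  Stratification is variance reduction, not
bias; i.i.d. sampling remains the default of `sample_cohort` and is what
the large-n consistency tests exercise.

## What the phantom does and does not emulate

It emulates first-pass kinetics with realistic parameter contrasts,
additive acquisition noise, nested lesion topology, hemispheric asymmetry,
hypodense follow-up lesions, and cohort-level volume/score distributions.
It does not emulate partial-volume mixtures at tissue interfaces, vascular
pixels, bolus delay/dispersion heterogeneity, beam hardening, motion,
grey/white heterogeneity (by default), or any spatial correlation of
noise.  Passing tests therefore demonstrate correctness of the analysis
chain under the stated model, not clinical-grade performance on scanner
data — in particular, real acquisitions would need AIF selection, motion
correction and vessel exclusion that are out of scope here.

## Numerical choices and degenerate inputs

* Trapezoid rule for all AUCs; interval-averaged residue in the forward
  model (area conservation).
* SVD truncation 0.2 of the largest singular value, padding factor 2;
  truncation 0 reproduces direct inversion of well-conditioned triangular
  systems to 1e-6 (tested).
* Calibration grid 0.5–30 s, 67 nodes; inversion by monotone
  interpolation.
* All-zero voxels: invalid, MTT/CBV 0, never NaN.
* Lesion-free phantoms: empty masks, volume 0, mismatch flagged.
* Mann-Whitney on all-tied data returns p = 1 (the asymptotic formula
  degenerates); separation in the logistic model is detected from the 2x2
  cells and flagged with an infinite CI rather than a diverging fit.
* All randomness flows from one top-level seed via spawned per-patient
  child seeds; identical configuration and seed give byte-identical CSV
  outputs (tested).

## Problem sizes

The cohort recovery runs use 30 and 51 patients at the full 64 x 64 x 8
grid (about 0.5 s per patient end to end); invariance and robustness
suites use a 24 x 24 x 4 or 32 x 32 x 4 grid with 20 seeds, sizes chosen
so the whole test suite completes in well under a minute while keeping
millilitre-scale volumetry meaningful.

## Known limitations

* The operator-response calibration assumes the mono-exponential residue
  family; other residue shapes would need their own response table.
* Sub-millilitre cores (a few voxels) are under-segmented after in-plane
  smoothing — visible in the reference-period cohort whose median core is
  1 ml.
* Total hypoperfused volume carries a small systematic under-estimation
  (about 5–10 % at the noise default) from threshold crossing on smoothed
  boundaries; it is stable across seeds and documented rather than
  corrected, since any correction would be phantom-specific.
* The two-period statistics on synthetic cohorts reproduce the published
  summary structure, not the patient-level p-values, which are not
  recoverable from printed summaries.
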