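# ctpstroke

CT-perfusion (CTP) analysis of hyper-acute ischemic stroke, built as a
reusable, tested pipeline around synthetic data.  The package simulates
dynamic CTP acquisitions of stroke lesions with known tissue kinetics,
estimates perfusion maps by deconvolution, segments ischemic core and
penumbra with classical thresholds, measures the final infarct on follow-up
non-enhanced CT by seeded region growing, and compares two admission-period
patient cohorts (a pandemic-lockdown period versus the same calendar period
one year earlier) with the usual clinical statistics.

It is aimed at readers who want to reproduce, probe, or extend a
perfusion-volumetry analysis when the underlying patient scans cannot be
shared: the synthetic module stands in for the scanner, and every
downstream step is the real analysis code.

## Model

Each tissue voxel follows the indicator-dilution model.  With arterial
input $C_a(t)$ (a gamma variate $A\,(t-t_0)^{\alpha}e^{-(t-t_0)/\beta}$),
residue function $R(t)=e^{-t/\mathrm{MTT}}$ and flow $F =
\mathrm{CBF}/6000\ \mathrm{s^{-1}}$, the tissue enhancement is

$$C(t) = F \int_0^t C_a(s)\, R(t-s)\, ds,$$

and the central volume principle ties the parameters together:
$\mathrm{CBV} = \mathrm{CBF}\cdot\mathrm{MTT}/60$.

The estimation chain inverts this model:

* **CBV** = $100\,k\cdot\mathrm{AUC}(C)/\mathrm{AUC}(C_a)$ (ml/100 g);
* **MTT** from a block-circulant truncated-SVD deconvolution of $C$ against
  $C_a$: the flow-scaled residue $k(t)$ is recovered and
  $\mathrm{MTT} = \mathrm{AUC}(k)/\max k$, mapped through the operator's
  own response function to remove the deterministic regularisation bias
  (see `docs/methods.md`);
* **CBF** = $60\,\mathrm{CBV}/\mathrm{MTT}$ (ml/100 g/min), so the
  indicator-dilution identity holds on every valid voxel by construction.

Lesion volumetry uses the classical relative thresholds: hypoperfused
tissue has MTT above 145 % of the contralateral-hemisphere median; within
it, core has CBV < 2.0 ml/100 g and penumbra CBV ≥ 2.0.  Mismatch is
penumbra as a fraction of the total hypoperfused volume.  The final infarct
on follow-up CT is grown from a seed with a running-mean similarity
criterion (tolerance 8 HU).

Cohort statistics mirror standard clinical reporting: median (IQR) and
Mann-Whitney U / t tests (gated by a Kolmogorov-Smirnov normality screen),
counts with Wald 95 % CIs and chi-square tests, univariate linear
regression (B, 95 % CI) of imaging features on the period indicator, and
binary logistic regression (OR, 95 % CI) for large-vessel occlusion.

## Worked example

```python
from ctpstroke import (ThresholdConfig, build_phantom, estimate_maps, segment_lesion)
from ctpstroke.lesion import repair_config
from ctpstroke.phantom import GridSpec, brain_mask_for_grid, geometry_for_volumes

grid = GridSpec()                       # 64 x 64 x 8 voxels, 3 x 3 x 5 mm, 60 s at 1 s
brain = brain_mask_for_grid(grid)
geom, _ = geometry_for_volumes(83.3, 27.8, grid, brain=brain)
phantom = build_phantom(geom, grid=grid, noise_sigma=2.0, seed=1, brain=brain)

maps = estimate_maps(phantom)
seg, report = segment_lesion(maps, brain, grid.midline_index, "right",
                             grid.spacing, repair_config(ThresholdConfig()))
print(f"reference MTT {seg.reference_mtt:.2f} s")
print(f"total {report.total_ml:.1f} ml, core {report.core_ml:.1f} ml, "
      f"mismatch {report.mismatch:.2f}")
```

prints

```
reference MTT 3.98 s
total 77.4 ml, core 26.6 ml, mismatch 0.66
```

The phantom was built with an 83.2 ml hypoperfused lesion containing a
27.7 ml core (healthy MTT 4 s): at 2 HU acquisition noise the pipeline
recovers the healthy reference almost exactly and the lesion volumes to
within about 8 % (total) and 4 % (core); the mismatch (fraction of the
lesion that is still salvageable penumbra) follows from the two volumes.

The numbered scripts under `analysis/` run the full study: cohort
simulation (`01`), per-patient imaging recovery (`02`), and the two-period
comparison tables and box plots (`03`), writing everything under
`results/`.  The same chain is available as a CLI (`ctp run --seed 0`) and
as a library call (`ctpstroke.pipeline.run_pipeline`).

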