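# rufflekit

Quantitative analysis of **dorsal membrane ruffles** — the sheet-like,
actin-driven protrusions that sweep across the upper surface of cells during
macropinocytosis — as imaged by deconvolved, near-isotropic fluorescence
volumes (e.g. lattice light-sheet data at ~0.1 µm voxels).

Seen from the top, a ruffle's backbone in the membrane plane behaves like a
semiflexible filament.  rufflekit quantifies that analogy end to end:

* **Worm-like-chain mechanics.**  For a 2D worm-like chain the mean squared
  end-to-end distance obeys

  ⟨R²ₑₑ⟩ = 8 l²ₚ [ L/(2 lₚ) − 1 + exp(−L/(2 lₚ)) ],

  where *L* is contour length and *lₚ* the persistence length.  The package
  samples discrete chains with Gaussian turning angles (variance Δs/lₚ per
  step), fits this curve to pooled (L, R²ₑₑ) data by multi-start least
  squares with a bootstrap confidence interval, and decomposes an observed
  persistence length into bending and intrinsic-curvature parts via
  reciprocal additivity, 1/lₚ,obs = 1/lₚ + 1/lₚ,int.
* **Synthetic volumes with ground truth.**  Ruffles are rendered as thin
  vertical sheets (≈0.8 µm thick, 1–4 µm tall) standing on a flat dorsal
  surface above a cytosol slab, then degraded with anisotropic Gaussian blur
  and Poisson noise — so every measurement stage can be validated by
  parameter recovery, no raw data download required.
* **Morphometry.**  Maximum-intensity projection → Otsu segmentation →
  skeleton-graph analysis (contour length, end-to-end distance, branch
  count), FWHM thickness with quadrature PSF correction, and sub-pixel
  ruffle heights from interpolated threshold crossings.
* **Two-channel analysis.**  Enrichment ratios against equal-sized cytosol
  control ROIs and lagged Pearson cross-correlation of paired recruitment
  traces.

## Worked example

Simulate 300 ruffle backbones with a 5 µm persistence length and re-estimate
it from their (L, Rₑₑ) table:

```bash
$ rufflekit simulate-chains --l-p 5 --n 300 --seed 1 --output chains.csv
wrote 300 chains to chains.csv
$ rufflekit fit-wlc --input chains.csv --n-boot 1000 --seed 2 --output fit.json
l_p = 5.124 um  (n=300)
```

`fit.json` then contains

```json
{
  "ci_high_um": 5.905657003762303,
  "ci_low_um": 4.405626188391537,
  "converged": true,
  "l_p_obs_um": 5.123715553259734,
  "n_ruffles": 300,
  "rejected_rows": 0,
  "rss_um4": 421652.0608377984
}
```

i.e. the fit recovers the true 5 µm stiffness within 2.5%, with a 95%
bootstrap interval of [4.41, 5.91] µm over the 300 simulated ruffles.  In
the same way, `decompose_intrinsic(0.8, 5.0)` → 0.95 µm converts an observed
0.8 µm persistence length with 5 µm bending stiffness into the ≈1 µm
intrinsic-curvature length of strongly curved ruffles.

The full pipeline — simulate chains, render a two-channel scene, re-measure
it, fit, and correlate recruitment traces — runs as one benchmark:

```bash
$ rufflekit benchmark --seed 1 --output-dir bench
benchmark PASSED
```

`bench/report.json` lists each recovered quantity (persistence length,
ruffle count, thickness, height and its uniformity, enrichment ratio,
correlation peak lag) next to its ground truth, tolerance and verdict;
intermediate artifacts (chains.csv, volume.tif, records.csv, traces.csv,
correlation.csv) are written alongside.

As a library:

```python
from rufflekit import wlc_sim, wlc_fit

table = wlc_sim.sample_uniform_length_ensemble(300, 2.0, 20.0, l_p=5.0, seed=1)
fit = wlc_fit.fit_persistence_length(table, n_boot=1000, seed=2)
print(fit.l_p_obs)        # 5.12 um
```

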