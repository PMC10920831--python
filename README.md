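# feedscope

Analysis of neural population recordings made during feeding assays:
miniscope calcium imaging and fiber photometry of a GABAergic midbrain
population while a mouse approaches and eats a food source (a cricket or a
walnut), together with the pose tracking and scored behavior that supervise
the analysis.

The package is aimed at systems neuroscientists who have the standard
outputs of that kind of experiment — per-frame body-part coordinates from a
markerless pose tracker, cells × samples df/F matrices from a
source-extraction tool, scored behavior-epoch tables, cross-session cell
co-registration maps, and dual-channel (470/405 nm) photometry — and want
the full behavioral-encoding analysis chain on top of them:

- **behavior** — speed from pose; food-approach epochs (distance to the
  target decreases ≥ 10 cm with speed ≥ 2 cm/s throughout); rearing from
  arena geometry; rasterization of epochs onto any time base.
- **traces** — 10%-of-max variance inclusion filter; peri-event tensors
  around behavior onsets; pre/post-eating modulation (post − pre df/F);
  mean peak amplitude; isosbestic 405-nm photometry correction; epoch-mean
  contrasts.
- **geometry** — PCA embedding of behavior-labeled samples; silhouette
  score with a label-permutation chance distribution; cross-assay cluster
  conservation over co-registered cells via Mahalanobis distances
  d_M(y) = √((y − μ)ᵀ Σ⁻¹ (y − μ)) and distances to cluster centres,
  compared by two-tailed rank-sum.
- **models** — matched-sample behavior decoding (multinomial logistic
  regression, five-fold cross-validation with a 10-s train/validation gap,
  50% chance); per-cell behavior GLM with an onset-randomization bootstrap
  null (100 shuffles, 95% rule) classifying cells as +, − or ns; cross-assay
  weight and profile correlations with Fisher r-to-z comparison.
- **synth** — a generator that emulates all five input kinds with planted
  ground truth (behavior-modulated Poisson firing through a slow indicator
  kernel, pose tracks that physically realize the behavioral schedule,
  shared photometry artifacts), so every stage is testable without
  animal data.
- **report** — a seeded end-to-end pipeline producing machine-readable
  results, tables, a summary figure and Benjamini–Hochberg-adjusted
  statistics in declared families.

See `docs/methods.md` for the models, conventions and known limitations.

## Worked example

```python
import feedscope as fs

cfg = fs.PipelineConfig()
cfg.seed = 7
cfg.silhouette_shuffles = 200
cfg.generator = fs.GeneratorConfig(n_cells=30, duration=600.0)
res = fs.run_pipeline(cfg, out_dir="demo")

g = res["geometry"]["A"]
print(f"silhouette (assay A):      {g['silhouette']:.3f}  "
      f"(chance {g['chance_mean']:+.3f}, percentile {g['percentile']:.0f})")
d = res["decoding"]
print(f"decoding accuracy, eat:    {d['A:eat']['mean_accuracy']:.3f}  (chance 0.500)")
print(f"decoding accuracy, appr.:  {d['A:approach']['mean_accuracy']:.3f}")
c = res["conservation"]
print(f"cross-assay median d_M:    eat {c['median_mahalanobis_eat']:.2f} vs "
      f"approach {c['median_mahalanobis_approach']:.2f}  -> {c['direction']}"
      f" (rank-sum p = {c['rank_sum_p']:.2e})")
k = res["cell_classes"]["A:eat"]
print(f"eating-modulated cells:    {k['-']} suppressed (-), {k['+']} activated (+), {k['ns']} ns")
w = res["correlations"]
print(f"eat GLM-weight correlation across assays:      rho = {w['weights_eat']['rho']:.2f} "
      f"(p = {w['weights_eat']['p_value']:.1e})")
print(f"approach GLM-weight correlation across assays: rho = {w['weights_approach']['rho']:.2f} "
      f"(p = {w['weights_approach']['p_value']:.2f})")
```

This generates a pair of synthetic assays whose eating ensemble is shared
between the two sessions while approach encoding is assay-specific,
re-detects approach epochs from the generated pose, and runs the complete
analysis. The run prints:

```text
silhouette (assay A):      0.275  (chance -0.011, percentile 100)
decoding accuracy, eat:    0.753  (chance 0.500)
decoding accuracy, appr.:  0.672
cross-assay median d_M:    eat 7.38 vs approach 10.51  -> eat more conserved (rank-sum p = 4.27e-105)
eating-modulated cells:    9 suppressed (-), 3 activated (+), 18 ns
eat GLM-weight correlation across assays:      rho = 0.64 (p = 1.3e-04)
approach GLM-weight correlation across assays: rho = 0.37 (p = 0.04)
```

Reading the numbers: the three behaviors occupy distinct clusters in PC
space (silhouette well above its permutation chance of ≈ 0); both
behaviors decode above the 50% matched-sample chance; eating clusters from
the two assays overlap far more than approach clusters (smaller
cross-assay Mahalanobis distance — the planted conserved-eating
structure); eating suppresses three times as many cells as it recruits;
and eating GLM weights correlate across assays while approach weights
barely do.

`demo/` then contains `results.json`, `cell_classes.csv`, `summary.png`
and `run.log`.

The same stages are scriptable from the shell:

```bash
feedscope synth --seed 3 --out session/
feedscope behavior classify --pose session/pose.csv --arena circular:0,0,25 --out epochs.csv
feedscope pipeline run --out report/
```

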