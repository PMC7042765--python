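# nicheshift

Climatic niche-shift analysis and reciprocal distribution modelling for
species with a native and an invaded range.

When a species invades a new region, a central question is whether it
occupies the same environmental conditions as at home (niche conservatism)
or has moved into genuinely novel climate (niche shift).  `nicheshift`
implements the standard analysis pipeline for that question on paired
occurrence + climate-raster data:

- **Environmental space (PCA-env).**  A PCA is fitted to the pooled,
  standardized background climates of both ranges; every occurrence and
  background point is projected onto the first two axes, and each range's
  occupancy is estimated on a shared R×R grid as a kernel density of
  occurrences corrected by the kernel density of available climate,
  `z ∝ o/e`, normalized to unit mass.
- **Overlap statistics.**  Schoener's `D = 1 − ½ Σ|z₁ − z₂|` and the
  Hellinger-based `I = 1 − ½ Σ(√z₁ − √z₂)²`, both in [0, 1].
- **Permutation tests.**  A niche *equivalency* test (pool the occurrences,
  re-split at the observed sample sizes, rebuild the grids, lower-tail p on
  the overlap) and a niche *similarity* / background test (relocate one
  range's occupancy surface uniformly within its available environment,
  upper-tail p).
- **Niche dynamics.**  The expansion / stability / unfilling decomposition:
  the invasive occupancy mass outside the native occupied envelope (E), its
  complement (S = 1 − E), and the native mass outside the invasive envelope
  (U).
- **Reciprocal maximum-entropy SDMs.**  A from-scratch presence–background
  maxent model — Gibbs distribution `p_λ(x) ∝ exp(λ·f(x))` over background
  with L1-penalized feature-mean constraints; L/Q/H/P/T feature classes; an
  AICc-tuned grid of 6 feature-class combinations × 8 regularization
  multipliers (48 candidates); 4-block spatial cross-validation — trained in
  each range and projected onto the other, evaluated with AUC, the
  continuous Boyce index, and TSS.  A niche shift shows up as models that
  discriminate well at home and fail to transfer.
- **Synthetic data.**  A generator of paired landscapes with correlated,
  spatially coherent climate layers and a Gaussian niche whose centroid is
  displaced between ranges by a chosen Mahalanobis distance, so every stage
  can be validated against a known ground truth without any downloads.

## Worked example

```python
import nicheshift as ns

cfg = ns.SyntheticConfig(shape=(80, 80), n_native=79, n_invasive=500,
                         n_background=2000, shift_sigma=4.0, seed=42)
sc = ns.make_scenario(cfg)

res = ns.NicheComparison(
    sc.occurrences["native"].env,  sc.backgrounds["native"].env,
    sc.occurrences["invasive"].env, sc.backgrounds["invasive"].env,
).fit(n_reps=99, seed=0)
print(res.summary())
```

```
Niche comparison (environmental space, 2 PCA axes)
======================================================
PCA variance explained (2 axes): 82.67%
Overlap:      D = 0.0609   I = 0.1451
Equivalency:  p(D) = 0.0100   p(I) = 0.0100   (n_reps=99)
Similarity native->invasive:  p(D) = 0.2600   p(I) = 0.2800
Similarity invasive->native:  p(D) = 0.2600   p(I) = 0.2500
Dynamics:     expansion = 0.9453   stability = 0.0547   unfilling = 0.9093
```

The programmed 4σ centroid displacement is recovered: overlap is near zero,
equivalency is rejected at the minimum attainable p (1/(n_reps+1) = 0.01),
the similarity tests are non-significant (the niches are no more similar
than random placement), and the dynamics say the invasive niche is ~95%
novel climate while ~91% of the native niche is left unfilled.

The reciprocal models tell the same story from the SDM side:

```python
rep = ns.reciprocal_report(
    ns.RangeData("native",  sc.occurrences["native"].env,  sc.backgrounds["native"].env),
    ns.RangeData("invasive", sc.occurrences["invasive"].env, sc.backgrounds["invasive"].env),
    classes="LQHP", rm=0.5)
print(rep.table().to_string(float_format="%.3f"))
```

```
             native -> native  native -> invasive  invasive -> invasive  invasive -> native
AUC                     0.941               0.420                 0.928               0.436
Boyce index             0.928              -0.909                 0.985              -0.807
TSS                     0.795               0.070                 0.720               0.151
```

Within-range models discriminate well (AUC ≈ 0.93–0.94); projected across
the shifted niche they drop to worse-than-random AUC and strongly negative
Boyce indices.

## Command line

A thin CLI wraps the same library calls, driven by one YAML config:

```bash
nicheshift simulate --out data/ --seed 1 --shift 4.0   # synthetic scenario + config.yaml
nicheshift niche    --config data/config.yaml          # overlap, tests, dynamics, plots
nicheshift sdm      --config data/config.yaml          # tuning grids + reciprocal report
nicheshift report   --out data/results                 # combined summary
```

Each stage writes CSV/JSON results, PNG niche-space plots, ASCII-grid
suitability maps, and a manifest with the config hash, seeds and SHA-256 of
every output, so runs are exactly reproducible.

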