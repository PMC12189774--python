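# nucleotex

Dual-feature classification of Philadelphia chromosome-negative
myeloproliferative neoplasm (MPN) subtypes — essential thrombocythemia
(ET), polycythemia vera (PV), primary myelofibrosis (MF) — from bone
marrow histopathology tiles. Diagnosis of these subtypes rests on
bone-marrow morphology with substantial interobserver variability; this
package implements a reproducible pipeline for pathology researchers
that combines two feature branches and a stacked ensemble:

1. **Handcrafted branch** — mask-aware texture descriptors per segmented
   nucleus: first-order statistics, gray-level co-occurrence (GLCM,
   distances D = {1,2,3}, angles Θ = {0°,45°,90°,135°}), run-length
   (GLRLM) and size-zone (GLSZM, 4/8-connectivity) features, aggregated
   per tile (mean + sd over nuclei; 173 values).
2. **Embedded branch** — 1536-dim tile embeddings through a pluggable
   contract (H-optimus-0 adapter, precomputed CSV tables, or a
   deterministic offline surrogate).
3. **Stacked block** — a classifier trained on the concatenated class
   probabilities of the first two, with out-of-fold cross-fitting to
   avoid stacking leakage.

Each block is a scaler → selector → classifier pipeline tuned by a
tree-structured Parzen estimator (TPE) to maximize the composite
weighted-average metric

    composite = (precision + recall + F1 + accuracy + specificity) / 5

where each term is support-weighted one-vs-rest (specificity is
TN/(TN+FP) per class). A multi-run statistics module computes means,
sample standard deviations, one-sample t-tests, Cohen's d / Hedges' g,
and Shapiro–Wilk / Jarque–Bera / Kolmogorov–Smirnov normality tests
over per-run metrics. A seeded synthetic generator produces
histology-like tiles with exact nucleus masks in three separable texture
regimes, so the whole pipeline is testable without any downloads.

See `docs/methods.md` for the full model description and conventions.

## Worked example

```python
import numpy as np
import nucleotex as nx
from nucleotex.pipeline import handcrafted_table, embedding_table, feature_matrices

# a 2-level quantized patch: co-occurrence counts at distance 1, angle 0°
levels = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]])
m = nx.glcm(levels, d=1, theta=0, n_levels=2)
print("GLCM counts:", m.counts.tolist())
print("features:", {k: round(v, 4) for k, v in nx.glcm_features(m).as_dict().items()})

# synthetic 3-class benchmark: 30 tiles/class, ground-truth masks
records = nx.generate_dataset_arrays(n_per_class=30, side=256, seed=7)
h = handcrafted_table(records)                                  # 90 x 173
e = embedding_table(records, nx.SurrogateEmbedder(dim=64, seed=7))
Xh, Xe, y, ids = feature_matrices(h, e)
table = nx.run_experiment(Xh, Xe, y, seeds=[0, 1, 2], n_trials=25)
print(table[table.metric == "composite"]
      .pivot(index="run", columns="block", values="value").round(4))
```

Output:

```
GLCM counts: [[1, 2], [0, 3]]
features: {'contrast': 0.3333, 'correlation': 0.4472, 'energy': 0.3889, 'homogeneity': 0.8333}
block  embedded  handcrafted  stacked
run
0        0.8749       1.0000   1.0000
1        0.6925       0.8698   0.8698
2        1.0000       1.0000   1.0000
```

The six horizontal pixel pairs of the patch distribute as counts
[[1,2],[0,3]]; contrast 1/3 is the off-diagonal mass, energy 7/18 the
squared-probability sum. On the synthetic benchmark the handcrafted
block separates the three texture regimes at composite ≈ 0.87–1.0 per
run and the stacked block matches or exceeds the weaker single block —
the surrogate embedder is deliberately much cruder than a real
foundation model, which is why the embedded block trails.

## Command line

```sh
nucleotex synth --out data/ --n 30 --seed 7          # synthetic dataset + masks
nucleotex run   --data data/ --segmenter file:mask \
                --embedder surrogate --trials 25 --runs 10 --seed 0 --out results/
nucleotex stats --metrics results/metrics.csv --ref mean
```

`--segmenter {stardist,builtin,file:<suffix>}` and
`--embedder {surrogate,file:<csv>,hoptimus}` select the pluggable
backends; `run` writes feature tables, a tidy per-run metrics CSV, and
the statistical report.

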