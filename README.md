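# osadx

Tabular sleep-apnea classification toolkit: preprocessing, demographic
grouping, binary particle-swarm (BPSO) wrapper feature selection, and a
ranked multi-metric evaluation suite, with a synthetic clinical-table
generator so the whole pipeline is testable without any private data.

## What's inside

| Module | Purpose |
| --- | --- |
| `osadx.synthetic` | 31-column clinical-style table generator: imbalanced binary outcome, race/sex/age demographics, planted informative features with per-group effect modulation, MCAR missingness |
| `osadx.preprocessing` | sparse row/column removal (>50% missing), mean/mode imputation, min–max normalization to [0,1], Epworth-score banding, race/sex/age grouping |
| `osadx.fs` | binary PSO with four S-shaped transfer functions, fitness = 0.99·(CV error) + 0.01·(selected fraction), plus an exhaustive-subset oracle for small dimensions |
| `osadx.classifiers` | first-class kNN (6 distances × 3 weightings, optional standardization), random-subspace discriminant ensemble, scikit-learn preset adapters |
| `osadx.evaluation` | seeded stratified K-fold CV with pooled confusion counts, grid/random kNN tuning |
| `osadx.metrics` | accuracy, TPR, TNR, balanced "AUC" = (TPR+TNR)/2, precision, F-score, G-mean, Friedman-style mean ranks, Wilcoxon signed-rank |
| `osadx.experiment` / `osadx.cli` | end-to-end orchestration: compare classifiers per group, repeat feature selection over seeds, write metric tables, masks, selection frequencies and improvement summaries |

## CLI

```sh
# synthetic table (CSV + .meta.json sidecar with types and planted mask)
osadx generate --out data.csv --n 274 --missing-rate 0.05 --seed 1

# clean: drop sparse, impute, normalize
osadx preprocess --data data.csv --out clean.csv

# classifier roster comparison per demographic group
osadx classify --data clean.csv --group race --out results/cls --seed 1

# swarm feature selection, 10 seeded runs
osadx select --data clean.csv --tf S1 --runs 10 --seed 1 --out results/fs

# full experiment from a YAML config
osadx report --config experiment.yml --out results/exp --seed 1
```

## Library example

```python
import osadx

schema = osadx.default_schema()
config = osadx.GeneratorConfig(planted_features=(4, 7, 21),
                               effect_sizes=(1.5, 1.5, 1.5), seed=0)
table = osadx.generate_dataset(schema, config)
clean, _ = osadx.preprocess(table)

result = osadx.run_bpso(clean,
                        osadx.SwarmConfig(n_particles=10, n_iterations=100, seed=0),
                        osadx.KNNSpec(n_neighbors=5, weighting="squared_inverse"))
print(result.fitness, result.mask.astype(int))
```

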