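# qsarflow

Curation, stacked-ensemble QSAR modeling, and Shapley interpretation for
receptor-affinity (pKi) data.

Public bioactivity repositories overlap: the same ligand is often deposited
in two sources with slightly — or wildly — different measured affinities.
Before any structure–activity model can be trusted, those records must be
reconciled into one curated structure→pKi table. qsarflow implements that
reconciliation, the descriptor-based modeling that follows it, and the
attribution analysis that explains the fitted model, as a tested, seeded,
fully scriptable pipeline. It is aimed at computational / medicinal
chemists building affinity-prediction models from multi-source ligand data
(the motivating use case is serotonin-receptor ligands, but nothing is
receptor-specific).

## What it computes

**Curation.** Within each source, same-structure repeats are averaged when
their pKi spread is within a threshold t (default 0.1 log units) and removed
when discordant. Across sources, each shared structure forms a duplicate
pair with ΔpKi = |pKi_A − pKi_B|:

* ΔpKi > t → both measurements are discarded,
* ΔpKi ≤ t → the designated priority source's value is kept,

so the final count obeys `|A| + |B| − pairs − discordant_pairs`, which the
audit object verifies on every run. Compounds are identified by canonical
SMILES after salt stripping and neutralization, with stereochemistry
retained.

**Modeling.** 2D molecular descriptors (RDKit backend built in, Mordred
optional) are preprocessed (boolean encoding, mean imputation, constant /
empty column removal) and fed to a four-stage automated workflow: importance
screening, six base-learner families (DRF, XRT, GBM, XGBoost, elastic-net
GLM, neural net) tuned by random hyperparameter search, and a **super
learner**: on out-of-fold predictions f̂_j(x) the metalearner fits

    ŷ(x) = β₀ + Σⱼ βⱼ f̂ⱼ(x),   βⱼ ≥ 0,

with Lasso or elastic-net regularization, λ chosen by inner CV. Performance
is reported as 10-fold cross-validated RMSE = √(Σ(predᵢ−obsᵢ)²/n) and
R² = 1 − SS_res/SS_tot, next to an OLS baseline on the same features and
folds.

**Interpretation.** Per-record, per-feature Shapley values under marginal
(background-sample) expectations: exact coalition enumeration up to 12
features, a seeded permutation-sampling estimator beyond, mean-|SHAP|
feature ranking and dependence profiles.

**Synthetic ground truth.** Generators for overlapping source pairs,
valid SMILES libraries from a fragment grammar, and descriptor→pKi
regression benchmarks with known informative features — every stage is
testable without downloading anything. See `docs/methods.md` for the full
model documentation.

## Worked example

```python
import qsarflow as qf
from qsarflow.explain import background_sample

# a regression benchmark with 3 informative of 15 features, noise sd 0.5
X, y, truth = qf.gen_qsar_dataset(
    qf.QsarBenchSpec(n=500, d=15, k=3, noise_sd=0.5, seed=7))

res = qf.run_automl(X, y, qf.AutoMLConfig(
    model_budget=2, n_try=3, fs_threshold=0.1, k=10, seed=7))
base = qf.fit_linear_baseline(X[res.features.names], y, k=10, folds=res.folds)
print("selected:", res.features.names)
print(f"stacked  CV RMSE = {res.model.cv_metrics.rmse:.4f}  R2 = {res.model.cv_metrics.r2:.4f}")
print(f"baseline CV RMSE = {base.rmse:.4f}  R2 = {base.r2:.4f}")

Xs = X[res.features.names]
shap = qf.shap_values(res.model, background_sample(Xs, 0.1, seed=7),
                      Xs.iloc[:25], n_samples=300, seed=7)
print(qf.aggregate_importance(shap).to_string(index=False))
```

Output (about 15 s on one CPU):

```
selected: ['x001', 'x002', 'x003']
stacked  CV RMSE = 0.5044  R2 = 0.8010
baseline CV RMSE = 0.8015  R2 = 0.4977
feature  mean_abs_shap  fraction_positive
   x001       0.500409               0.44
   x003       0.488923               0.44
   x002       0.466228               0.48
```

The screen recovered exactly the three informative features; the stacked
ensemble explains ~80% of held-out variance against ~50% for ordinary least
squares on the same features (the remaining gap is the nonlinear part of
the signal), and each feature's mean absolute Shapley value is its average
contribution to a prediction, in pKi units. With the noise level of 0.5
pKi units used here, the stacked RMSE of 0.50 is close to the irreducible
floor.

Curation of a synthetic two-source pair, with the audit bookkeeping:

```python
spec = qf.SourcePairSpec(n_a=100, n_b=50, n_shared=20, n_discordant=5,
                         threshold=0.1, seed=7)
a, b, truth = qf.gen_sources(spec)
db = qf.resolve_duplicates(a, b, threshold=0.1, priority="ZINC")
print(db.audit.as_dict())
# {'uniques_a': 100, 'uniques_b': 50, 'pooled_total': 150,
#  'duplicate_records': 40, 'pairs_total': 20, 'pairs_kept': 15,
#  'pairs_dropped': 5, 'final_uniques': 125, 'threshold': 0.1,
#  'priority': 'ZINC'}
```

150 pooled records minus 20 duplicate pairs minus 5 discordant pairs leaves
125 unique compounds, as the closed form predicts.

## Command line

Every stage is also a subcommand of the `qsarflow` console script:
`simulate`, `curate`, `descriptors`, `profile`, `train`, `predict`,
`explain`, and `run-all --config pipeline.yaml` for the whole chain with a
single global seed.

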