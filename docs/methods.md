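# Methods

This note documents the models, procedures and design choices behind
qsarflow, in the order the pipeline runs them.

## Problem setting

The pipeline targets ligand-affinity regression for a single receptor.
Activity is expressed as pKi = −log10(Ki), with Ki the inhibition constant
in molar units, so one pKi unit is a tenfold change in affinity; curated
collections for aminergic receptors typically span pKi ≈ 4–11. Input data
are per-source measurement records (SMILES structure + pKi), usually from
two public repositories whose compound sets overlap and occasionally
disagree.

## Structure identity

All stages identify a compound by its canonical SMILES, computed by RDKit
after (by default) keeping the largest organic fragment (salt stripping) and
neutralizing formal charges. Stereochemistry is retained by default, so
enantiomers and diastereomers are distinct database entries — Tanimoto-1.0
pairs in a 2D-fingerprint profile are then exactly the stereoisomer pairs.
A stereo-agnostic mode collapses them. The keying function is idempotent;
re-keying a key is a no-op.

We deliberately do not attempt registry-ID matching between sources; the
identity of a record is its standardized structure, nothing else.

## Curation

Within a source, same-structure repeats whose pKi spread (max − min) is at
most the concordance threshold collapse to their arithmetic mean; wider
groups are removed outright under the default "consistent" policy (a
"median" policy is available for users who prefer keeping a robust center).

Across the two deduplicated sources, every shared structure forms exactly
one duplicate pair with ΔpKi = |pKi_a − pKi_b|. Resolution uses one
threshold, default **0.1 pKi units**:

* ΔpKi > 0.1 — the measurement is considered unreliable; **both** members
  are removed;
* ΔpKi ≤ 0.1 (boundary inclusive) — the member from the designated
  priority source is kept.

Unpaired records pass through unchanged. The audit object tracks per-source
uniques, pooled total, duplicate records (= 2 × pairs), pairs kept/dropped
and final uniques, and the implementation asserts the closed form

    final = |A| + |B| − pairs_total − pairs_discordant

on every run. Swapping the priority source changes which member's value
survives, never the count.

## Descriptors and preprocessing

Descriptors are 2D only — functions of the molecular graph, independent of
conformer generation. Two backends sit behind one interface: RDKit's full
2D descriptor list (~210 columns, always available) and the Mordred 2D set
(1613 columns, used when the optional mordred package is installed).
Per-cell computation failures become missing values, never exceptions.

Preprocessing runs in a fixed order: (1) booleans → {1, 0}; (2) per-column
mean imputation of missing cells; (3) removal of columns that are entirely
missing ("empty") or have max == min ("constant"). Encoding precedes the
constant test so a constant boolean column is still dropped; imputation
precedes it so all-missing columns are reported as empty rather than
constant-after-fill. The operation is idempotent and records dropped columns
and imputation means as provenance.

Imputing from the full matrix before cross-validation leaks a small amount
of held-out information. The `Preprocessor` class therefore offers a
fold-safe variant (means learned on training rows only), which is also what
`run_automl` uses internally when the input still contains missing values;
the global variant remains available for reproducing single-pass pipelines.
For mean imputation the leakage affects only column means and is practically
negligible, but the default inside model evaluation is the safe one.

## Profiling

* **Lipinski's rule of five**: MW < 500 Da (strict), logP < 5 (strict),
  H-bond donors ≤ 5, acceptors ≤ 10. **Veber rules**: topological PSA ≤
  140 Å², rotatable bonds < 10 (strict). Aggregate percentages are reported
  per rule and for the two composites.
* **Similarity**: Tanimoto coefficient |A∩B|/|A∪B| on Morgan fingerprints
  (radius 2, 2048 bits by default; the fingerprint choice is reported in the
  output because similarity distributions are fingerprint-dependent).
  All pairs are computed exactly up to 2000 compounds; above that, a seeded
  random sample of distinct pairs (default 10⁶) is used, since n(n−1)/2
  exceeds 4×10⁷ for ~10⁴ compounds.
* **Correlations**: Pearson r over named descriptor columns; zero-variance
  columns are listed as undefined and their entries set to NaN explicitly.

## Modeling workflow

Performance metrics are RMSE = √(Σ(pred_i − obs_i)²/n) and
R² = 1 − SS_res/SS_tot with SS_tot about the observed mean, both computed
from pooled out-of-fold predictions of seeded 10-fold cross-validation
(fold sizes differ by at most one).

**Feature selection.** A stochastic gradient-boosting screen (300 trees,
depth 3, subsample 0.7) is fit `n_try` times (default 5) with different
seeds; per-feature importances are averaged and normalized so the top
feature scores exactly 1.000. Features with relative importance ≥ the
threshold (default 0.05) are kept; the top feature is always kept.
Subsampling matters here: later trees in a stochastic ensemble pick up weak
components after strong ones are exhausted, which a single deterministic fit
often misses.

**Base learners.** Six families: random forest, extremely randomized trees,
gradient boosting, extreme gradient boosting (xgboost), regularized linear
models (elastic net), and a small fully connected neural network (1–3 hidden
layers of 16–64 units). Hyperparameters are drawn by random search,
log-uniformly for scale-like parameters (learning rates, regularization
strengths). The search budget is a **model count per family** (default 10)
rather than wall-clock time, so runs are bit-reproducible; every candidate
is fit once per fold to produce out-of-fold predictions and refit on the
full training set for downstream prediction.

**Stacking.** The super learner regresses y on the matrix of base-model
out-of-fold predictions using a linear metalearner constrained to
**non-negative weights**, with Lasso (default) or elastic-net (mixing 0.5)
regularization solved by coordinate descent under the positivity constraint.
The penalty strength is chosen by inner 5-fold cross-validation over a grid
of 0 plus 20 log-spaced values in [10⁻⁵, 1]; λ = 0 gives the non-negative
least-squares limit, in which a single perfect base model receives weight 1
and intercept 0 exactly. Two ensembles are formed — all candidates, and the
best candidate per family (≤ 6 bases) — and the lower-RMSE one is returned.
Leaderboard ties break by fewer base models, then lexical id.

**Linear baseline.** Ordinary least squares on the same selected features
and the same folds, with a minimally-ridge fallback (α = 10⁻⁶, warned) on
rank-deficient training splits. The ensemble-vs-OLS gap measures how much of
the structure–activity signal is nonlinear.

## Shapley attributions

For a model f and record x, the attribution of feature j is its Shapley
value over feature coalitions, with absent features marginalized by
substituting values from a background sample (the interventional/marginal
expectation): v(S) = mean over background rows b of f(x_S, b_{\bar S}).
The base value φ0 is the mean model output on the background, and for exact
enumeration local accuracy holds: φ0 + Σ_j φ_ij = f(x_i) to ≤ 10⁻⁹.

Exact enumeration is capped at 12 features (4096 coalitions × background
evaluations); beyond that a permutation-sampling estimator draws seeded
random feature orderings and averages marginal contributions, caching
coalition values per record so repeated prefixes cost one model call. The
estimator is unbiased for the exact values; its Monte-Carlo error shrinks
as 1/√(number of permutations). The default background is a seeded random
10% of the provided dataset. Rankings use mean absolute attribution with
lexical tie-breaks; dependence profiles are (feature value, attribution)
pairs sorted by value.

## Synthetic data: what it emulates and what it does not

`gen_sources` emulates the two-source overlap structure: configurable
per-source unique counts, shared structures, and a designated number of
discordant duplicates whose |ΔpKi| is drawn strictly above the threshold and
up to 4.46 pKi units (the upper end observed in real two-source merges);
concordant duplicates differ by at most the threshold. pKi values are
normal(7.0, 1.0) clipped to [4.2, 11.0], matching the roughly symmetric
distributions of curated aminergic-receptor sets. Structures come from a
fragment grammar (aryl/heteroaryl rings, piperazine and piperidine linkers,
alkyl chains, carbonyl/amide groups, halogens) echoing arylpiperazine-like
serotonergic chemotypes; every output is RDKit-valid, canonical, and
distinct by construction.

`gen_qsar_dataset` draws standard-normal features and builds the response
from k informative columns through a linear, additive-nonlinear
(sin/square/tanh/absolute-value components) or interaction form. Each
component is standardized to unit variance before a signed amplitude in
[1, 2] is applied, so every informative feature carries a meaningful,
bounded-below share of signal variance — "informative" is true by
construction, which is what a selection-recovery benchmark needs. The summed
signal is standardized, mapped to pKi scale (mean 7, sd 1), noised with
Gaussian sd `noise_sd`, and clipped to [4.2, 11.0].

These generators are designed for *known ground truth*, not realism: real
descriptor matrices are heavy-tailed, highly collinear and block-structured,
real activity cliffs are not Gaussian noise, and the fragment grammar does
not reproduce a real library's scaffold distribution or descriptor
covariance. Passing tests on synthetic data therefore demonstrates that the
machinery is correct under controlled conditions, not that any particular
real-data accuracy will be achieved.

## Problem sizes used by the test suite

The headline modeling check runs the additive-nonlinear benchmark at
n = 2000 records, d = 50 features, k = 5 informative, noise sd 0.5, with a
10-models-per-family budget and 10-fold CV; on this benchmark the stacked
ensemble reaches CV-R² ≈ 0.79 against an OLS baseline of ≈ 0.21. Selection
recovery uses n = 500, d = 50, k = 5 across ten seeds. Sampling-estimator
convergence uses a 3-feature tree model, 5000 permutations, 50 seeded
reruns. Curation arithmetic is exercised at full two-source scale
(8025 + 3624 uniques, 1997 shared, 212 discordant → 9440 curated).

## Known limitations

* The default RDKit descriptor backend computes ~210 descriptors, not the
  full 1613-column Mordred 2D set; the Mordred backend requires the optional
  `mordred`/`mordredcommunity` package.
* The curation key is exact structure identity after standardization;
  tautomer merging and fuzzy matching are out of scope.
* The metalearner is linear by design (interpretable, non-negative); it
  cannot repair base models that are all biased in the same direction.
* Exact Shapley enumeration is exponential in features and hard-capped at
  12; above that only the sampling estimator is available, and TreeSHAP-style
  model-specific fast paths are not implemented.
* Neural-network candidates use a fixed iteration budget (200 epochs) for
  reproducibility; on very small datasets they may underperform tree
  ensembles and are simply down-weighted by the metalearner.
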