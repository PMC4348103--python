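# Methods

## Model

Traits are modelled as linear in two standardized covariate blocks,
markers X₁ (n × m, dominant presence/absence scored 1/0) and metabolites
X₂ (n × m*, nonnegative abundances), with ridge (L2) shrinkage applied to
each block through its own penalty:

RSS(b, b*) + λ_a‖b‖² + λ_b‖b*‖².

The two-penalty fit is realized by rescaling the blocks and solving a
single-penalty ridge. Two scaling conventions are implemented:

* **sqrt-w** (default): columns of X₁ scaled by √w, of X₂ by √(1−w).
  Substituting b = √w·β₁, b* = √(1−w)·β₂ shows that ridge(λ) on the
  rescaled matrix minimizes the two-penalty objective *exactly*, with
  λ_a = λ/w and λ_b = λ/(1−w).
* **paper-w**: scales w and 1−w, the way the rescaling idea is usually
  narrated ("a regression on wx with coefficient b/w"); implied penalties
  λ/w² and λ/(1−w)². Both conventions sweep the same family of
  (λ_a, λ_b) ratios, only parametrized differently, so grid searches under
  either reach the same models; tests verify prediction identity at
  matched penalty pairs to 1e−8.

At w = 1 (or 0) the zero-weight block is dropped from the design rather
than divided by a vanishing scale, so the boundary reductions to
single-block ridge are exact. At w = 0.5, sqrt-w ridge(λ) equals pooled
ridge(2λ) (paper-w: 4λ); tests assert this across the whole default
penalty grid.

The intercept is handled by centering the trait with the training mean
(covariates are standardized); predictions add the mean back, so they are
on the original trait scale. The trait is deliberately *not* variance
scaled — the CVC is scale-invariant and centering suffices for the
algebra.

## Estimation and the fast drop-one evaluator

For m > n the estimator uses the dual form b = X′(XX′ + λI)⁻¹y; for
m ≤ n the primal normal equations. Leave-one-out predictions come from the
exact hat-matrix identity e₍ᵢ₎ = eᵢ/(1 − hᵢᵢ) with
H = X(X′X + λI)⁻¹X′ = K(K + λI)⁻¹, K = XX′. Eigendecomposing K once gives
H's spectrum d/(d + λ) for *every* λ, so one n × n `eigh` evaluates the
whole penalty ladder. For the two-block search, K(w) = c₁²K₁ + c₂²K₂ with
K₁ = X₁X₁′ and K₂ = X₂X₂′ precomputed, so a full 21 × 25 (w, λ) grid costs
21 eigendecompositions of an n × n matrix. This is what makes the nested
protocol at panel scale (n = 151, ~1,400 columns) run in tens of seconds
on one CPU; the equality of the shortcut with n explicit refits is the
module's central oracle test (1e−8).

## Hyperparameter search and tie-breaking

* w grid: 0 to 1 in steps of 0.05 (21 values) by default; a finer step
  buys little.
* λ grid: 25 points, log-uniform on [10⁻³·m, 10³·m] where m is the active
  column count — scaling by m keeps per-column shrinkage comparable
  between single-block, pooled and two-block searches.
* λ is re-searched at every w (full 2-D grid).
* Selection maximizes the drop-one CVC. Ties (rare, exact float equality)
  break deterministically: larger λ first (prefer the more-shrunk model),
  then w nearest 0.5, then smaller w. `select_lambda` for single-block
  ridge breaks ties toward larger λ the same way.
* A grid cell whose LOO predictions are constant has an undefined CVC and
  scores −∞; if the *entire* grid is undefined the search raises
  `AllUndefinedError`, which the nested evaluator converts to a
  mean-prediction fold, and an all-constant outcome is surfaced as the
  `failed` status — undefined correlations are data, not crashes.

## Nested (drop-one within drop-one) evaluation

For each of the n samples: standardize covariates on the remaining n − 1
(per-fold mode, the default — applied to the held-out row with training
statistics, so there is no leakage), center the trait, run the grid search
by drop-one CV on the n − 1, refit at the selected (w, λ), predict the
held-out sample. The n collated predictions are correlated with the
observations. Within any fixed training fold the searched CVC dominates
the w ∈ {0, 0.5, 1} special cases by grid membership — an exact guarantee
the tests assert — but no such inequality holds for the collated nested
result, and the evaluator does not enforce one. The comparison methods
(markers-only, metabolites-only, pooled) are the w = 1 / 0 / 0.5
restrictions of the same machinery, so every method shares folds and
protocol exactly. Per-fold (w, λ) are recorded; the reported mean w
averages over outer folds. A `full-data` standardization mode (statistics
computed once on all n) is provided because published analyses are often
ambiguous on this point; it changes results only marginally but is not
leakage-free.

The outer and inner folds are leave-one-out and therefore deterministic:
the CV protocol contains no randomness at all, which is what makes the
evaluation reports byte-identical across reruns.

## Preprocessing

Markers: QC order is fixed — MAF filter (frequency over non-missing calls;
drop if minor-state frequency < 0.01), then greedy left-to-right
near-duplicate removal (drop a column whose pairwise-complete r² with any
*retained* earlier column exceeds 0.95; the earlier column wins —
deterministic where any one of a duplicate pair would do). QC runs once on
the full data before cross-validation: both filters are unsupervised with
respect to the trait, so they leak nothing. Standardization uses the
sample SD (n − 1 denominator; configurable) — "variance one" leaves the
denominator open and ddof = 1 pairs with the statistics being re-estimated
per fold. Missing entries are set to zero *after* rescaling, i.e. imputed
at the column mean; constant columns are zeroed and flagged rather than
dividing by zero.

## Distances and the Mantel test

Variety-by-variety distances are Euclidean on the standardized block; an
average-linkage (UPGMA) cophenetic variant is offered because
clustering-based workflows sometimes correlate tree-derived distances
instead, and the two choices can give different Mantel correlations —
the package provides both and asserts nothing about which a given
published table used. The Mantel statistic is the Pearson correlation of
upper-triangle distances; the permutation null jointly relabels rows and
columns of the second matrix with a seeded generator, and the one-sided
p-value uses the +1 correction, p = (#{r_perm ≥ r_obs} + 1)/(B + 1), so
p ≥ 1/(B + 1). Default B = 10,000, configurable (e.g. 100,000). The r
statistic is cross-checked against scikit-bio's independent implementation
in the tests; type-I error calibration is checked by simulation.

## Synthetic data generator

The generator emulates a diversity-panel experiment: markers are Bernoulli
with per-column presence frequencies uniform on (0.05, 0.5] and 2 %
missing calls by default (a realistic call-failure rate for dominant
marker platforms); metabolite features are a lag-1 correlated Gaussian
(ρ = 0.6, mimicking the smoothness of adjacent NMR buckets) exponentiated
to positive, right-skewed abundances. The trait is a linear combination of
a few causal columns from each standardized block plus Gaussian noise;
block contributions and noise are rescaled to their exact target sample
variances, so the realized heritability h2 and the block-1 signal share
are controlled (recorded in the dataset's truth file; cross-covariances
make the realized shares deviate slightly at small n). All randomness
flows from one seed through spawned child streams, so a dataset is
bit-reproducible.

What the generator does **not** emulate: linkage disequilibrium or
pedigree structure among markers, genotype-by-environment interaction,
non-additive genetics, and NMR artefacts (baseline drift, peak shifts).
Passing tests therefore demonstrate correctness of the algebra, the CV
protocol and the qualitative behaviour (w tracks the informative block;
combining can beat pooling), not the accuracy the method attains on any
particular real panel.

Named fixtures: `tiny` (30 × 20 + 15; fast tests and docs) and `wheat`
(151 varieties, 843 markers pre-QC, 620 metabolite features — the
dimensions of the HEALTHGRAIN wheat panel this kind of analysis is built
for).

## Problem sizes used in the checks

The acceptance-style tests run the w-recovery study at n = 150 with
200 + 200 features, 100 replicates per signal share on a thinned 11 × 9
grid, and one full-scale nested evaluation on the `wheat` fixture with the
complete 21 × 25 grid; the acceptance script evaluates a 120-line panel
with full grids. These sizes make the whole suite complete in a few
minutes on one CPU while keeping the panel-scale path exercised end to
end.

## Known limitations

* Exactly two covariate blocks; the multi-block extension needs a
  multidimensional weight search that is out of scope.
* L2 penalties only — no lasso/elastic-net variant.
* No mixed-model / multiple-kinship formulation; penalties come from CV,
  never from variance-component ratios.
* The inner selection criterion is the CV correlation uniformly (not CV
  squared error), for single-block ridge as well as DiPR.
* Mantel here is the plain test: no partial Mantel, correlograms, or tree
  export.
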