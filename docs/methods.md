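# Methods

## Problem

A gene producing several mRNA isoforms through alternative splicing carries
functional annotations (GO terms) at the gene level, while the biological
function may belong to only one of its isoforms.  Given a gene expression
matrix `Xg` (n_g genes × n_f RNA-seq experiments), the matching isoform
matrix `Xiso` (n_iso × n_f), and a binary gene label vector `y_g` for one GO
term, the package scores every isoform for how likely it is to carry that
function.  Single-isoform genes (SIGs) pass their label to their isoform
directly; multi-isoform genes (MIGs) are ambiguous bags in the
multiple-instance sense: a negative MIG has only negative isoforms, a
positive MIG has at least one positive isoform.

Each RNA-seq experiment (one column) is a *feature*.  Feature relevance
varies per GO term, so the pipeline selects a per-term feature subset before
fitting the predictor.

## The MdiPLS predictor

Domain-invariant PLS extracts latent directions `w` minimizing

    ||X_src − y_src wᵀ||²_F + λ·|var(t_src) − var(t_tgt)|,  t = Xw,

where the source domain is the labelled gene side and the target domain the
isoform side.  Column centering each matrix by its own means aligns the
domain means; the penalty aligns the latent-score variances, so a regression
learned on gene labels transfers to isoform rows.

Labelled isoforms are added to the source side as a second PLS term sharing
`w`; row-stacking the labelled isoform rows under `Xg` (and their labels
under `y_g`) is algebraically identical to that sum of Frobenius terms.  The
stack holds all SIG isoforms (gene label inherited), all isoforms of
negative MIGs (label 0), and one isoform per positive MIG chosen by the MIL
loop below (label 1).

### Solver

The absolute value makes the objective piecewise smooth.  On each branch
the stationary condition is the linear system

    (yᵀy·I + λ·s·D)·w = Xᵀy,   s ∈ {+1, −1},

with `D` the difference between the source and target column covariance
matrices (each with denominator n−1, symmetrized for numerical safety).
Both branch solutions are computed; the one with the lower true objective
(including the |·|) is kept and normalized to unit Euclidean norm (the
objective fixes `w` only up to scale; unit norm is the usual PLS
convention).  At λ=0 this reduces exactly to the PLS1 weight `Xᵀy/||Xᵀy||`.
Singular systems fall back to least-squares; a weight with norm below 1e−14
(response orthogonal to the features, typically from over-deflation) raises
an error advising fewer components.

### Deflation and regression vector

For k = 1…n_k: extract `w_k` on the current residuals, compute source
scores `t = X w_k`, loading `p_k = Xᵀt/tᵀt`, inner coefficient
`q_k = yᵀt/tᵀt`, then deflate `X ← X − t p_kᵀ`, `y ← y − t q_k`, and the
isoform matrix with its own scores against the shared loading,
`Xiso ← Xiso − (Xiso w_k) p_kᵀ`, which keeps both domains in the same
residual space.  The gene and stacked-isoform responses are deflated
jointly (they form one stacked response).  The regression vector is
`b = W(PᵀW)⁻¹q`; a condition number above 1e12 on `PᵀW` is treated as
singular.  Scores are `y_pred = (Xiso − column_means)·b`; higher means more
likely positive.

### MIL loop

Iteratively: fit `w0` on the current stack; project the isoform rows of
positive SIGs onto `w0` and take the mean as reference (if a dataset has no
positive SIGs the positive gene rows substitute, with a warning); score
every positive-MIG isoform by |projection − reference mean|; pick the
minimum-distance isoform per positive MIG, replacing the previous pick.
The loop stops at a fixed point or after `max_mil_iterations` (default
100).  Oscillation between near-tied isoforms is possible on weak signal;
the cap bounds it and a warning reports non-convergence.  The reference is
built from isoform rows rather than gene rows because the projection
distances being compared are isoform projections.

### Probabilities

Classification uses a two-class softmax on logits `(s, −s)`:
`p = exp(s)/(exp(s)+exp(−s)) = sigmoid(2s)`, so `p > 0.5 ⇔ s > 0` and
`s = 0` maps to exactly 0.5.  An optional standardization (zero mean, unit
variance over the score vector) is exposed for use when raw score
magnitudes are arbitrary, as in cross-validated reporting; it is off by
default so the score sign alone determines the call.

## Feature-importance search

A single stochastic chain over feature subsets, in the random-frog family:
no prior over models, no detailed-balance correction, acceptance driven by
cross-validated performance.

Per iteration, with incumbent `V0` of size `Q0`:

1. **Cardinality proposal.** `Q' = round(u)`, `u ~ N(Q0, α·Q0)` re-drawn
   until it lies in `[Q0 − h, Q0 + h]` with `h = max(1, α·Q0)`, clamped to
   `[1, p]`.  The rejection (rather than clipping) keeps the interval a
   support instead of accumulating mass at its endpoints.  The half-width
   floor of one feature keeps the chain irreducible: restricting the
   rounded integer to `±α·Q0` would make `Q0` the only reachable value
   whenever `α·Q0 < 1`, so a chain started at the recommended `Q = 2` with
   `α = 0.3` could never change dimension and cardinality 1 would be an
   absorbing trap.  Because the proposal spread stays `α·Q0`, the α→0 limit
   still pins the dimension, and for `α·Q0 ≥ 1` the support is exactly the
   nominal interval.
2. **Candidate subset.** Equal cardinality: `V' = V0`.  Shrinking: top `Q'`
   features of `V0` ranked by |b_j| of an MdiPLS fit on `V0` (ties broken
   by ascending column index).  Growing: pool `V0` with
   `min(⌈μ(Q'−Q0)⌉, p−Q0)` features drawn uniformly from outside, rank the
   pool, keep the top `Q'`.
3. **Scoring.** 3-fold gene-stratified CV AUC of MdiPLS on each subset,
   both subsets on the same folds (per-iteration fold seed derived from the
   master seed) so the comparison is not confounded by fold noise.  The CV
   scores held-out SIG isoforms plus max-aggregated held-out MIGs, pooled
   over folds.
4. **Acceptance.** `P' = 1` if the candidate improves the AUC, else
   `P' = ω(AUC'+0.001)/(AUC0+0.001) ≤ ω`; accept if a uniform draw falls
   below `P'`.

The incumbent *after* the accept/reject step is the iteration's recorded
model; after N iterations each feature's selection probability is
`sp_i = N_i/N`, its fraction of recorded subsets.  Defaults `N = 2000`,
`Q = 2`, `α = 0.3`, `μ = 10`, `ω = 0.1` follow the random-frog
recommendations; tests and the acceptance script run N in the
120–300 range, which is where the synthetic problems below converge.
Re-scoring the incumbent every iteration (rather than caching its AUC)
keeps the within-iteration comparison fair; a `cache_auc0` flag trades
that for speed.

## Threshold scan

Candidate cutoffs are the distinct positive `sp` values — exactly the
points where the surviving set `{i : sp_i ≥ t}` changes, making the scan
exhaustive over distinct subsets; zero is excluded since never-selected
features should not be able to enter the final subset.  Every cutoff's
subset is scored by the same 3-fold CV (one shared fold seed across
cutoffs); the best AUC wins and ties break toward the larger cutoff (fewer
features).  Subsets are nested and shrink as the cutoff grows.

## Evaluation protocol

Outer cross-validation (default 5-fold) assigns homolog groups — sets of
duplicated genes given in an optional two-column table, singletons for
unlisted genes — to folds by greedy largest-group-first bin-packing, so
near-identical paralog profiles never straddle the train/test split.  Per
fold, the training task (column centering included) is built from training
genes only; feature selection and model fitting never see held-out genes.
Held-out isoforms are centered with training-fold means at prediction time.

Metrics: Mann–Whitney AUC with half credit for ties (computed from
midranks), and AUPRC by precision-at-recall-change step summation (no
trapezoid interpolation).  SIG-level metrics use held-out SIG isoforms
against gene labels; MIG-level metrics use the maximum isoform score per
held-out MIG; pooled metrics use the union of both unit sets, each unit
once.  A fold whose held-out units lack a class records NaN for the
affected level and is excluded from the mean.

Per-feature relevance analysis: Welch two-sample t-test of positive- vs
negative-gene expression per feature, Benjamini–Hochberg adjustment across
features (Welch because class sizes are typically very unbalanced).

## Synthetic data

The generator plants exactly the structure the method assumes: isoform
rows are N(0, noise_sd²) noise; function-carrying isoforms (every isoform
of a positive SIG, exactly one responsible isoform per positive MIG) get
`+effect_size·noise_sd` on a random set of informative columns; decoy
isoforms of positive MIGs draw from the negative noise distribution, making
the MIL ground truth unambiguous; gene rows are the column-wise sum of
their isoforms' rows (TPM-like additivity); an optional `domain_shift`
factor rescales the isoform matrix after gene rows are formed, planting a
gene-vs-isoform variance gap.  Positives are allocated stratified:
`round(positive_fraction·n_sig)` positive SIGs and
`round(positive_fraction·n_mig)` positive MIGs, so planted counts are
exact.

Defaults — 100 SIGs, 50 MIGs at 3 isoforms each, 50 features of which 10
informative, effect size 1.5 noise-sd units, positive fraction 0.3, no
domain shift — describe a moderately easy recognition problem at a size
where the full pipeline runs in seconds.  What the generator does *not*
emulate: count-distribution realism (negative-binomial noise, library-size
and length biases), correlated experiments, hierarchically related GO
terms, or annotation noise.  Passing tests therefore demonstrate the
machinery recovers planted structure under its own assumptions, not
performance on real RNA-seq compendia.

## Numerical and design notes

- Centering: each domain by its own column means; subsetting re-centers
  (a no-op in exact arithmetic, a guard in practice).
- Feature subsets keep original column order regardless of construction
  order, for reproducibility.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; child seeds (per fold, per iteration) derive
  from the master stream, so end-to-end runs are bit-reproducible.
- `mil_enabled=False` yields plain diPLS: no isoform rows are stacked and
  no relabeling runs — this is the ablation baseline, and with λ=0 it
  collapses to ordinary PLS1.
- Genes without annotation rows are negatives for every term (closed-world
  assumption); a term annotating none or all dataset genes is rejected as
  degenerate.
- Isoforms present in the expression matrix but absent from the
  gene–isoform map are rejected at task assembly rather than silently
  dropped.

## Known limitations

- The chain is a heuristic search; `sp` values are not posterior
  probabilities and depend on N, especially for N below ~10·p.
- MIL selection can oscillate on weak signal; the iteration cap (100)
  bounds the cost, but the returned selection is then the last iterate,
  not a fixed point.
- With few positive SIGs the MIL reference distribution is poorly
  estimated; the gene-row fallback changes the projection scale.
- The threshold scan optimizes inner-CV AUC and can overfit it when the
  chain is short, occasionally choosing very small subsets; the outer CV
  reports this honestly as reduced held-out performance.
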