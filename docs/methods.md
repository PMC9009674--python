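# Methods

## Model

A mutation-type count matrix `V` (P types × N tumors; canonically the 96
pyrimidine-centred single-base-substitution trinucleotide classes, but any
non-negative integer type-by-sample matrix such as 83-class INDEL counts is
accepted) is modelled as independent Poisson counts,

    v_pn ~ Poisson( Σ_j  w_pj · h_jn ),      w_pj ≥ 0,  h_jn ≥ 0,

where the r columns of `W` are unit-sum signature profiles and the columns
of `H` carry the per-tumor signature activities on the mutation-count
scale.  Maximizing the Poisson likelihood is equivalent to minimizing the
generalized Kullback–Leibler divergence

    D_KL(V | WH) = Σ_pn [ v log(v/m) + m − v ],   m = (WH)_pn,

so the fitted model is a KL non-negative matrix factorization.  All
likelihood values in this package are reported as −D_KL over the relevant
cells: the additive log-factorial constant is never computed, and only
differences and orderings of these values are meaningful.

## Choosing the number of signatures

The number of signatures r is chosen by unsupervised cross-validation over
*cells* of the matrix.  A balanced K-fold scheme (default K = 10) holds
out, in fold k, the mutation-type indices `p = base + a·K` (a = 0, 1, …)
of tumor n, with `base = ((n + k − 2) mod K) + 1`: every tumor loses
⌊P/K⌋–⌈P/K⌉ types per fold, the K folds partition the matrix, and the
pattern depends only on indices — never on the counts — so the held-out
data are missing completely at random and training-cell estimates are
unbiased.  (The rotation is defined by its worked example: with P = 96,
K = 10, tumor 1 loses types 1, 11, …, 91 in fold 1 and 2, 12, …, 92 in
fold 2.)

For each candidate r and fold k the model is fitted on the training cells
(below), and the fold's prediction error is the KL divergence between the
held-out counts and the fitted means on those cells,
`ERR_{r,k} = D_KL(V_held | (ŴĤ)_held)`.  The curve `ERR_r = Σ_k ERR_{r,k}`
is typically U-shaped — too few signatures underfit, too many fit the
training noise — and the selected rank r\* is its argmin, with ties broken
to the smaller rank; a warning is emitted when r\* sits at the top of the
grid.  Final profiles and activities are then extracted by refitting the
full matrix (no held-out cells) at r\*.

## Fitting with held-out cells (ECM)

Held-out cells are treated as missing data and the factorization is fitted
by expectation/conditional maximization:

1. **Initialization.** The held-out cells are imputed with the per-type
   median of that row's training cells, giving a completed matrix `V0`.
   `W0` is i.i.d. uniform(0,1) with columns normalized to sum 1; `H0` is
   i.i.d. uniform(0,1) with each column rescaled to the corresponding
   column total of `V0`.  The uniform law and the column rescaling are this
   package's choices; rescaling starts the fit on the correct overall count
   scale, which matters at high mutation burdens.
2. **E-step.** Completed matrix `V*`: observed cells copied from `V`,
   held-out cells set to the current means `(W·H)_pn`.
3. **CM-steps.** One pass of the generalized-KL multiplicative updates on
   `V*`: `W` first, then `H` against the already-updated `W`.  With no
   held-out cells this is exactly the classic Lee–Seung KL-NMF update, and
   the tests assert that equivalence to 1e-10.
4. **Convergence.** The observed-data log-likelihood `ℓ = −D_KL` over
   training cells is evaluated at every iterate; EM theory guarantees it is
   non-decreasing (property-tested with 1e-9 slack).  Iteration stops when
   `|ℓ_t − ℓ_{t−1}| / (|ℓ_{t−1}| + 1) < tol` (the +1 makes the criterion
   scale-robust near zero) or at `max_iterations`.

Because multiplicative updates stall in local optima and saddle points,
each (rank, fold) fit is repeated from `n_starts` random initializations
and the fit with the largest observed log-likelihood is kept.  Per-start
seeds are a pure function of (master seed, fold, rank, start index) via
`numpy` SeedSequence spawning, so results are reproducible and independent
of execution order or thread count (joblib threading is available through
`n_jobs`; selection ties go to the lowest start index).

Defaults follow the method's standard parameterization: rank grid 1–10,
K = 10 folds, 300 starts, tolerance 1e-5, at most 2000 ECM iterations.
All are configurable; pan-genome-scale cohorts can need a larger rank
grid.

### Numerical choices

Model means, denominators and logarithm arguments are floored at 1e-12, so
degenerate rows/columns decay toward the floor instead of producing NaNs;
`0·log 0` is taken as 0.  The inner loop touches only the two informative
cell classes — observed cells with positive counts (which carry the
`v log(v/m)` terms) and held-out cells (which need imputation) — through
flat index arrays, while means come from dense BLAS products and the
total-mean term from factor sums; observed zero-count cells contribute
only through those factor sums.  One loop pass is asserted in the tests to
equal the documented `e_step` + `cm_update` composition.

## Annotation against a reference catalog

De novo profiles are compared with a reference catalog (e.g. COSMIC SBS)
by cosine similarity after aligning mutation-type rows.  Each de novo
signature reports its argmax catalog entry and is flagged matched when the
similarity exceeds the threshold (default 0.8; 0.9 as a stringent
alternative).  Matching is deliberately not a one-to-one assignment:
several de novo signatures may map to the same catalog entry (flat
look-alikes such as SBS5/SBS40 do this in practice), and unmatched
signatures are candidate novel ones.  Extracted signatures are ordered by
descending total activity; the ordering is cosmetic.

Cohorts can be pre-filtered by mutation burden: samples exceeding 10
mutations/Mb (hypermutators) are dropped by default, with the genome size
configurable (default 3,000 Mb, human whole genome; the appropriate value
is cohort-specific, so it is exposed rather than fixed).

## Synthetic data

Three benchmark designs are built in, all sampling Poisson counts from a
known `W·H`:

* **single** — one signature, 500 tumors, activities uniform on
  [20000, 40000].  With this high burden any second signature found is a
  false positive.  The default profile is a seeded spiky stand-in
  (symmetric Dirichlet with concentration 0.05 over the 96 types).
* **bootstrap** — activities of N tumors resampled tumor-wise (uniform
  with replacement) from a reference activity matrix with the profile
  matrix fixed; 200 tumors by default.  Correlated signature pairs (e.g.
  SBS1 with SBS5, SBS2 with SBS13 in breast cancer) are resampled jointly
  when listed as groups; all remaining signatures are resampled
  independently of each other, which is the reading we adopt of
  "sampled individually".
* **errors** — eight signatures spanning the six substitution classes,
  300 tumors, activities uniform on [0, 100] with a fraction (default 0.3,
  configurable) set to zero; after sampling the error-free counts `V0`,
  every cell of tumor n receives an extra "calling error" count uniform on
  [0, a·b_n] rounded to the nearest integer, where b_n is the per-type
  mean of `V0`'s column n and a ∈ {0, 0.4, 0.8, 1.2} is the error level.

When no reference catalog is supplied, seeded stand-in profiles with the
same qualitative structure are generated: each concentrates 85% of its
mass in one of the six 16-type substitution blocks (cycling so all classes
are covered) with a flat-ish remainder, giving pairwise cosine
similarities well below the 0.8 matching threshold.  The generators are
pure functions of their parameters and seed.

What the generators deliberately do not emulate: mutation-opportunity
differences between trinucleotide contexts, inter-tumor burden
heterogeneity beyond the activity laws, signature profile uncertainty, and
any error structure concentrated on specific mutation types (the noise
model is uniform by design).  Passing tests on these designs therefore
demonstrate the selection mechanism under the stated sampling models, not
performance on any particular cancer cohort.

## Problem sizes used in the checked examples

The automated checks run the full matrix sizes of the designs (96×500 and
96×300) with 20 random starts per fit and an ECM iteration cap of 300
inside the cross-validation loop (extraction refits use a 1000-iteration
cap).  Replicate counts are 20 for the single-signature selection count in
`scripts/acceptance.py`, and reduced in the test suite (4 replicates for
that design; one replicate per error level for the eight-signature
design; a 100-tumor stand-in analogue of the bootstrap design with six
common and three rare signatures).  At overfit ranks the multiplicative
updates crawl toward the tolerance long after the fit is qualitatively
settled; capping those iterations inflates the validation error of exactly
the ranks that are already disfavoured, so the selection outcome is
unaffected while the runtime stays desk-scale.  The bootstrap design's
original form (COSMIC profiles with a published breast-cancer activity
table) needs external downloads; users with those files can reproduce it
directly with `sim_bootstrap_activities` plus `SignatureCatalog`.

## Known limitations

* The 90/5/5 train/validation/test split utility fixes fold K−1 as
  validation and fold K as test; `test_error` evaluates the final model
  with training+validation observed and test missing (set
  `include_validation=False` for the stricter variant).
* Rank selection refuses grids exceeding min(P, N); very small cohorts
  should reduce K.
* No sparsity or ARD priors, no alternative divergences, and no signature
  refitting against fixed reference profiles — annotation is similarity
  reporting only.
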