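# Methods

`markernet` analyses a genes × samples matrix of log-scale expression
values (log2 microarray intensities or log2(RPKM+1)) labelled with K ≥ 2
disease subtypes, and produces four linked results: per-class ranked gene
lists, a minimum gene subset that separates the classes, a multiclass SVM
classifier with a reject option, and per-class gene association networks.

## Gene ranking: hierarchical normal mixture

Within a group of exchangeable samples, gene *g*'s observations are
modelled as

    x_i = mu_g + eps_i,  mu_g ~ N(mu0, tau2),  eps_i ~ N(0, sigma2) i.i.d.

so the group's marginal is an n-variate normal with mean `mu0·1` and
covariance `sigma2·I + tau2·J` (the lognormal-normal, LNN, model on the
log scale). Its log density has the closed form

    -1/2 [ n log 2π + (n-1) log sigma2 + log(sigma2 + n tau2)
           + SS_within/sigma2 + n (x̄ - mu0)² / (sigma2 + n tau2) ]

which depends on the data only through (n, group mean, within-group sum of
squares); all EM passes work from these sufficient statistics.

Each gene follows one of K+1 *patterns*: pattern 0, equivalent expression
(one latent mean across all samples), or pattern k, a one-versus-rest
contrast (class-k samples draw one latent mean, the pooled remainder
another). A single joint mixture with shared hyperparameters (mu0, tau2,
sigma2) and mixing proportions π over the K+1 patterns is fitted by
generalized EM:

* E-step: pattern responsibilities ∝ π_k × pattern marginal likelihood.
* M-step: π in closed form; (mu0, log tau2, log sigma2) by L-BFGS-B ascent
  of the expected complete log-likelihood, started at the current point and
  accepted only if it improves, so the observed log-likelihood never
  decreases.
* Stopping: relative log-likelihood change < 1e-6 or 250 iterations.

The per-gene responsibility of pattern k is the posterior probability that
the gene marks class k; responsibilities sum to 1 per gene by construction.

**Ranking construction.** Per class, genes are ordered by posterior
(descending), ties broken by |expression difference to the closest other
class| (the other class whose mean is nearest for that gene), remaining
ties by gene id so rankings are reproducible. Each gene is then assigned
only to the class where its position is best (ties: higher posterior, then
larger |difference|), so per-class lists never overlap. Genes whose most
probable pattern is equivalent expression are filtered out. The
`significant` flag marks posterior > 0.95 (configurable). Direction is UP
when the expression difference is positive, DOWN otherwise.

## Minimum-subset selection

A wrapper forward selection around the classifier, under repeated
stratified cross-validation (8 folds by default, capped at the smallest
class size; 6 repeats). Within a repeat, one genes-per-class counts vector
is maintained, starting at one gene per class. Each step trains the
one-vs-one SVM on every fold with the union of per-class ranking prefixes
and scores the vector by the aggregate cross-validated error; every class
with at least one misclassified held-out sample (in any fold) receives its
next ranked gene. Growth stops at zero error (or continues to the
`max_genes_train` cap when `continue_zero_error` is set, in which case all
classes below the cap grow). The repeat keeps the smallest vector (by
total, then lexicographically) attaining the minimum observed error.

The final per-class count is a trimmed maximum over repeats: counts
strictly above Q3 + 1.5·IQR are treated as outliers and discarded, then
the maximum of the remainder is taken; a minimum of one gene per class is
enforced. Selection evaluates most-likely-class predictions only (one-vs-one
voting), so the reject option cannot influence which genes are chosen.

## Classifier, probabilities and the reject option

One linear binary SVM (C = 1) per unordered class pair, trained on
genes standardized to the training mean/sd (zero-variance genes dropped
with a warning). Each machine's decision values on its own training
samples are calibrated with a Platt sigmoid using Platt's prior-corrected
targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2), fitted by Newton
iterations with backtracking; the smoothed targets keep the sigmoid finite
on separable data, and fitting on training decision values (rather than an
internal resampling) makes training fully deterministic. The K(K-1)/2
calibrated pairwise probabilities are combined into one class-probability
vector by pairwise coupling (the iterative second method of Wu, Lin &
Weng); for K = 2 this reduces to the single machine's sigmoid.

**Assignment.** With random probability r = 1/K, a query is assigned to
its most likely class only when p(1) ≥ 2r and p(1) − p(2) > 0.8r (both
multipliers configurable); otherwise it is reported Not-Assigned. The
most-likely class is always the argmax of the coupled probabilities.

**Discriminant power.** For gene *g* and class *c*, the pile is the sum
over machines involving *c* and over that machine's support vectors with
label *c* of |dual coefficient| × standardized expression of *g*. The
gene's class is the most extreme pile (tallest bar in either direction —
a repressed marker's own pile is strongly negative); |dp| is the distance
from that pile to the closest other pile, which for an up-regulated marker
is simply largest minus second-largest; the sign is positive for genes
over-expressed in their class and negative for repressed ones.

## Networks

For each class, the top-30 ranked genes (configurable) form the node set;
two edge types are computed among them over **all** samples:

* co-expression: Pearson correlation, edge kept when |r| ≥ 0.8
  (Spearman available behind a flag);
* mutual information: each gene is discretized into ⌈√n⌉ equal-frequency
  bins, the plug-in MI of the joint histogram is normalized by the smaller
  marginal entropy (so a deterministic monotone relation scores 1 and the
  0.5 default threshold is scale-free), edge kept when NMI ≥ 0.5.

When both estimators fire for a pair the edge carries both weights. Nodes
are annotated with posterior, expression difference, direction, membership
in the minimum subset, and discriminant power; a gene is flagged redundant
iff it has at least one edge of either type to another gene of its list.
Exports: SIF, GraphML and a node-attribute TSV.

## Validation statistics

Confusion matrices have true classes as rows and predicted classes plus a
Not-Assigned column. Per class (one-vs-rest among assigned samples):
sensitivity, specificity and MCC, with MCC defined as 0 when any
denominator factor vanishes; call rate is the assigned fraction of the
class. Global accuracy is correct/assigned (reported as 1.0 with a
`degenerate` flag if nothing is assigned); global call rate is
assigned/total. `external_validation` repeats (10×) a stratified 50/50
split, re-runs the whole pipeline (rank → select → train) on the training
part, queries the rest, and averages percentage matrices and rates, in
both the all-assigned and with-Not-Assigned modes.

## Synthetic data and test regimes

The generator emulates exactly the hierarchy the ranking model assumes:
baseline gene means ~ N(mu0 = 7, tau2 = 4), noise sd sigma = 0.5
(sigma2 = 0.25), values on a log2-like scale. Per class it plants
`de_per_class` differential genes shifted by ±effect·sigma in that class
only (directions alternating so UP/DOWN handling is exercised both ways),
one block of 5 genes sharing a latent factor (loading 4.5σ, centered
within each class so co-expression perturbs residuals rather than class
means; implied pairwise correlation ≈ 0.95), and one non-differential gene
pair with a purely quadratic dependency (near-zero linear correlation).
An RNA-Seq-flavoured variant shifts the matrix in log2 space to a
nonnegative RPKM range and re-applies log2(x+1).

Two regimes are used deliberately:

* **recovery regime** — effect 4σ, 5 classes × 12 samples, 2 000 genes,
  50 planted genes/class: hard enough that ranking precision/recall ≈ 1 is
  informative, but adjacent marker distributions still overlap
  (Φ(−2) ≈ 2.3% per pair), so single-gene classifiers cannot be perfect.
* **separable regime** (`separable_dataset`) — effect 10σ, no blocks:
  class-conditional marker distributions have disjoint 5σ envelopes, the
  premise for end-to-end claims such as 100% validated accuracy, ≥ 95%
  call rate and ≥ 80% rejection of signal-free queries.

Network experiments use 3 classes × 25 planted genes so an entire class
list (including its 5-gene block) fits inside a top-30 network.

What the generator does **not** emulate: probe-level microarray noise,
batch or library-size effects, heavy-tailed or count-distributed
expression, correlated noise beyond the planted blocks, and class overlap
structure of real cohorts. Passing tests therefore demonstrate
correctness of the algorithms under the model's own assumptions, not
performance on real clinical data.

## Numerical and design choices

* All randomness flows from one seed; sub-seeds are derived per stage via
  `SeedSequence` spawn keys, so stage reordering cannot reuse a stream.
  SVM training itself is deterministic (no internal resampling).
* EM tolerance 1e-6 (relative), max 250 iterations; variance parameters
  optimized on the log scale with bounds ±30.
* Ranking tie-breaks end with gene id; coupling iterates to 1e-12 residual,
  capped at 200 sweeps; pairwise probabilities are clipped to
  [1e-7, 1 − 1e-7] before coupling.
* Degenerate inputs: constant genes are excluded from SVMs and networks
  with warnings; classes need ≥ 3 samples; folds are capped at the
  smallest class size.
* Model files are JSON bundles storing the selected-gene training
  submatrix and parameters; loading refits the deterministic machines and
  reproduces probabilities exactly.

## Known limitations

* Per-sample pile contributions use |dual coefficient| × standardized
  expression; the exact split of dual weight among tied support vectors is
  not unique, so discriminant-power piles are reproducible only up to the
  QP solver's degeneracy (observed ≲ 0.05 under sample reordering).
* The joint K+1-pattern mixture assumes one shared (tau2, sigma2) for all
  genes; strongly heteroskedastic genes (e.g. the co-regulated blocks) get
  slightly optimistic posteriors.
* With fewer than ~6 samples per class the Platt targets are heavily
  smoothed and coupled probabilities rarely clear the assignment
  thresholds; call rates drop before accuracy does.
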