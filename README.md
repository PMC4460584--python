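# markernet

Marker-gene discovery, minimum-subset classification and gene-network
construction for studies that profile **several disease subtypes together**
with genome-wide expression data (microarrays or RNA-Seq).

Given a genes × samples matrix of log-scale expression values and a label
per sample (≥ 2 classes, ≥ 3 samples each), `markernet`:

1. **ranks genes per class** — an empirical-Bayes mixture model assigns
   each gene a posterior probability of following a one-versus-rest
   differential-expression pattern for each class; genes are ordered by
   posterior (ties broken by the expression difference to the closest
   class) and assigned only to the class where they rank best, so the
   per-class lists never overlap;
2. **selects the minimum gene subset** — wrapper forward selection around
   a multiclass SVM under repeated 8-fold cross-validation grows each
   class's prefix of top-ranked genes until the classes are perfectly
   predicted, then takes an outlier-trimmed consensus across repeats;
3. **classifies queries with a reject option** — a one-vs-one linear SVM
   with Platt-calibrated, pairwise-coupled class probabilities assigns a
   sample only when `p(1) ≥ 2/K` and `p(1) − p(2) > 0.8/K`; doubtful
   samples are reported `NOT_ASSIGNED`;
4. **quantifies each marker's discriminant power** — per class, the
   |Lagrange coefficients| of the class's support vectors weighted by the
   gene's standardized expression are piled up; the DP is the signed gap
   between the dominant pile and the closest other pile;
5. **builds per-class gene networks** — co-expression edges (|Pearson r|
   ≥ 0.8) and mutual-information edges (equal-frequency-binned NMI ≥ 0.5)
   among each class's top-30 ranked genes, annotated with posterior,
   expression difference, direction, subset membership, DP and a
   redundancy flag; exported as SIF/GraphML/TSV.

## The model in brief

On the log scale a gene's observations within an exchangeable group follow
`x_i = μ + ε_i` with `μ ~ N(μ₀, τ²)`, `ε_i ~ N(0, σ²)`, i.e. an n-variate
normal with covariance `σ²I + τ²J`. Each gene follows one of K+1 patterns —
equivalent expression, or "class k differs from the rest" — and an EM
algorithm fits the pattern proportions and shared hyperparameters; the
per-gene pattern responsibilities are the ranking posteriors. See
`docs/methods.md` for the full account, including the assignment rule,
the DP definition, the MI estimator and all numerical choices.

## Worked example

Simulate a small 3-class dataset with 10 planted marker genes per class,
build the classifier, and query the training samples:

```bash
markernet simulate --classes 3 --n-per-class 8 --genes 300 \
    --de-per-class 10 --effect 8 --block-size 0 --seed 5 --out-dir sim
markernet build sim/matrix.tsv sim/labels.tsv --seed 5 \
    --cv-repeats 2 --cv-folds 4 --out-dir model
markernet predict sim/matrix.tsv --model model/model.json --out-dir pred
```

which prints

```
wrote 300x24 dataset to sim
selected genes per class: C1=1, C2=1, C3=1
queried 24 samples; 0 not assigned
```

One strongly planted gene per class suffices here (the minimum subset is
1/1/1), and every training sample clears the assignment thresholds. The
ranking table (`model/ranking.tsv`) lists each gene's class, rank,
posterior, expression difference and direction:

```
gene    class  rank  posterior_prob  expr_diff      direction  significant
g00003  C1     1     1               4.20941615641  UP         True
g00009  C1     2     1               4.06383001604  UP         True
```

posterior 1 means the gene almost surely follows C1's one-versus-rest
pattern; `expr_diff` ≈ 4.2 is its log2 mean difference to the closest
other class. `pred/query.tsv` carries the per-sample class probabilities
and the decision:

```
sample  prob_C1         prob_C2          prob_C3          most_likely  second  assigned
C1_s01  0.804438406796  0.095168707167   0.100392886037   C1           C3      C1
```

`assigned` would read `NOT_ASSIGNED` for a sample whose top probability is
below 2/K = 0.667 or whose lead over the runner-up is below 0.8/K ≈ 0.267.
`markernet validate` reports sensitivity, specificity, MCC and call rate
per class plus global accuracy/call rate over repeated stratified splits,
and `markernet network` writes the per-class association networks.

The same functionality is available as scikit-learn-style estimators:

```python
from markernet import MarkerPipelineClassifier, RunConfig, generate

dataset, truth = generate(seed=7)          # 5 classes x 12 samples
X, y = dataset.to_xy()
pipe = MarkerPipelineClassifier(config=RunConfig(seed=7)).fit(X, y)
pipe.ranking_                              # per-class ranked gene lists
pipe.selection_.final_counts               # minimum subset sizes
pipe.predict(X[pipe.classifier_.feature_names_])  # classes or NOT_ASSIGNED
nets = pipe.networks()                     # networkx graphs per class
```

## File formats

Expression: TSV/CSV (gene ids in the first column, sample ids in the
header) or GCT 1.2; `--log2-rpkm` applies log2(x+1) to raw RPKM input.
Labels: two-column TSV `sample_id <tab> class`. All outputs are TSV/JSON;
networks additionally as SIF (`geneA <tab> type <tab> geneB`, type ∈
{correlation, mutual_information}) and GraphML with node attributes
`posterior_prob, expr_diff, direction, selected_for_classification, dp`
and edge attributes `correlation, mutual_information, types`.
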