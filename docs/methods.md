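# Methods

This note records the model, the estimation choices and their
rationale, what the synthetic data generator does and does not
emulate, and the package's known limitations.

## Candidate filtering and identifier harmonisation

The candidate pool **S** contains exactly the (miRNA, mRNA) pairs that
(a) appear in at least one of the four engine tables and (b) have both
endpoints measured in the expression matrix. Gene symbols are the
canonical gene namespace: engine tables and expression columns are both
mapped through a GENCODE-style annotation (only `gene` feature lines,
attributes `gene_id`/`gene_name`) before matching, because real engines
disagree on gene identifier conventions and symbols are the common
denominator. Ensembl version suffixes are always stripped first.
miRNA identifiers are matched case-insensitively with the dataset's
spelling as canonical. Feature roles (miRNA vs mRNA) come from an
explicit mapping when supplied, else from the `hsa-` prefix rule.
Unmapped gene identifiers pass through unchanged and are counted, not
fatal; an empty pool is an explicit error suggesting a namespace check.

## Structural information score

Pairwise engine similarity uses the chance-corrected consistency index
generalised to unequal set sizes,
`I(A,B) = (r·n − |A||B|) / (min(|A|,|B|)·n − |A||B|)`, clipped below at
0. The universe size *n* defaults to the number of distinct pairs in
the union of the four engine tables: the chance correction needs a
finite universe, and the union is the smallest set in which every
observed interaction is possible. The six unordered-pair indices are
normalised to sum to 1 and an interaction's SI is the sum of the
normalised indices of the engine pairs containing it. This unordered
reading of the double sum is the only one under which the two endpoint
identities hold simultaneously (single-engine support ⇒ 0, all-engine
support ⇒ 1). Numerically, SI is computed as a ratio of raw-index sums
taken in identical order so the all-engine case yields exactly 1.0
rather than 1 − ε. Predicted and validated engines carry identical
weight. A panel in which every pairwise index clips to zero yields
all-zero SI and a warning; no hierarchy can be built from it.

## Functional information score

FI is the class-conditional mutual information of the two expression
columns, estimated per class by Gaussian kernel density estimation and
integrated with the trapezoidal rule on a `precision × precision` grid
(default 100) spanning each class's data range ± 3 bandwidths.
Marginals are the exact marginals of the joint kernel estimate, so the
log-ratio is internally consistent and mismatched-grid bias is avoided.
Densities are floored at 1e−12 inside the logarithm and grid cells with
joint density below the floor contribute nothing, avoiding −∞·0
artifacts. Natural logarithm throughout; a negative numerical result is
clipped to 0, since true CMI is nonnegative and negativity is pure
discretisation error.

**Bandwidth.** The default bandwidth is the full-covariance matrix
`H = c²·Σ̂` with Scott's factor `c = n^(−1/6)` per class. The choice is
deliberate: an axis-aligned product kernel (e.g. per-axis Silverman)
inflates both marginal variances without touching the covariance, so
the smoothed correlation shrinks by `1/(1+h²)` and the mutual
information of strongly dependent pairs is systematically
underestimated — at n = 2000 per class the bias reaches ≈ −0.13 nats
for ρ = 0.9, an order of magnitude larger than the sampling error. A
covariance-proportional kernel preserves the correlation of the
smoothed density exactly, making the plug-in integral nearly unbiased
for Gaussian-like data (measured |bias| ≤ 0.02 nats at ρ = 0.9,
≤ 0.01 at ρ = 0). The per-axis Silverman rule remains available as
`bandwidth_rule="silverman"` for comparison. Degenerate strata
(near-zero variance or singular covariance) fall back to a floored
diagonal bandwidth with a warning.

FI is computed only for interactions with SI > 0; the rest never enter
the hierarchy. Estimation requires at least 3 samples per class and is
deterministic given data and configuration.

## Interaction hierarchy

Interactions are ranked separately by SI and FI (descending) and
merged. The default `alternative` mode picks the next unused
interaction alternately from the two rankings, starting with the
functional one — the ranking driven by the data at hand. The
`weighted` mode sorts by `w·pos_struct + (1−w)·pos_func` on 1-based
rank positions; rank positions rather than raw scores are combined
because SI and FI live on incomparable scales. Ties resolve by the
`isolated` policy (ascending sum of the endpoints' occurrence counts
in the pool, preferring molecules in few candidate interactions) with
lexicographic (mirna, gene) order as the universal final tiebreak, so
every ranking is bit-reproducible regardless of input order.
Interactions whose FI is computed but equals 0 are retained and simply
rank last; excluding them would make the hierarchy's length depend on
estimator noise.

## Conditional linear Gaussian classifier

The top-k interactions define the network: the class is a parent of
every included expression node and each interaction contributes a
miRNA → mRNA edge; an mRNA targeted by several top-k miRNAs has all of
them as parents. Parameters are maximum-likelihood: empirical class
prior, per-class mean and variance for miRNA nodes, per-class ordinary
least squares with MLE residual variance (divide by n_c) for mRNA
nodes. MLE rather than unbiased variances keeps all parameters the
joint maximiser of the likelihood the classifier evaluates; with the
sample sizes involved the difference is far below the reported
precision. Variances are floored at 1e−8. A constant parent column
within a class makes the design singular and is reported as an error
naming the node and class rather than silently regularised.

Prediction evaluates the two log-joints (log prior plus per-node
Gaussian log densities), subtracts the row maximum, and normalises —
the softmax in log space never overflows. A posterior tie at exactly
0.5 resolves to class 0, for determinism. Only network nodes enter the
likelihood; all other expression columns are ignored at predict time.

**Cross-validated size sweep.** Network sizes k = 1..k_max are scored
under stratified 3-fold CV repeated 3 times by default, each repeat
reshuffling with a seed derived from the master seed. Functional
scores (hence the ranking) are recomputed from each training fold
alone, so the interaction selection never sees test samples;
structural scores depend only on the databases and are split-invariant.
The best k is the arg-max of mean accuracy. Metrics are accuracy and
ROC-AUC over folds × repeats.

Models serialise to JSON (topology and all parameters at full float
precision), and fitted networks export to GraphML, DOT or node-link
JSON with per-edge SI/FI/rank annotations; the rendered figure colours
miRNAs green and mRNAs blue and omits the class node, which is a
parent of everything and adds no visual information (it is retained in
the JSON model document).

## Synthetic data generator

The generator draws from exactly the model family the classifier
assumes: per-class Gaussian miRNAs, linear-Gaussian target mRNAs
(ancestral order respected), balanced classes, and background features
that are class-independent noise at typical log-expression levels
(means ≈ 5 for miRNAs and ≈ 8 for mRNAs, unit variances, on the
log2(x+1) scale of prepared RNA-seq data). Engine membership is
Bernoulli per engine: planted interactions enter each engine with
probability 0.9 (and are guaranteed at least one engine), decoy pairs
with probability 0.3; with the default 60 decoys this yields a
candidate pool of ≈ 50 pairs of which roughly 20 carry SI > 0.
Default study size is 5 planted interactions among 10 miRNAs ×
20 mRNAs with 300 samples per class — small enough to run everywhere,
large enough that class-informative CMI separates cleanly from noise.
Setting `effect=0` produces a strict null study whose class-conditional
distributions are identical.

What passing tests on these fixtures shows: the scoring, ranking and
fitting machinery is correct under its own assumptions. What it does
not show: robustness to heavy-tailed counts, batch effects, unbalanced
classes, miRNAs regulating many genes simultaneously, or model
mismatch (non-linear regulation) — real RNA-seq data has all of these.
Differential-expression pre-filtering is intentionally not
reimplemented; the generator instead controls which features are
informative.

## Preprocessing helpers

Raw-count filtering drops mRNAs with more than 25% of samples under 5
counts and miRNAs with more than 25% under 1 count; "more than" is
strict, so a feature at exactly the threshold fraction is kept.
Normalisation is elementwise log2(x+1). Survival-based class
assignment puts the 75% (rounded down) shortest-surviving uncensored
samples in the short class; the remaining uncensored samples seed the
long class, topped up with the longest-follow-up censored samples —
eligible only if their follow-up exceeds the maximum survival observed
in the short class — until the classes balance. Ties in survival time
break by sample identifier. When the eligible censored pool is too
small the classes stay unbalanced with a warning and reported counts.

## Problem sizes used in the test and acceptance runs

Oracle checks of the CMI estimator use 2000 samples per class at grid
precision 100; parameter-recovery checks use 5000 samples per class
over 10 seeds; null-classification and end-to-end recovery runs use
400–600 samples over 10 seeds with one CV repeat. These sizes put
sampling error well inside the asserted tolerances while keeping the
full suite around a minute of compute.

## Known limitations

- The consistency index is applied with the engine-union universe;
  other defensible universe choices change intermediate SI values
  (never the 0 and 1 endpoints), so SI values are comparable only
  within one panel.
- The CMI estimator is a plug-in KDE integral: it is biased upward for
  very small strata and its covariance-scaled bandwidth is tuned to
  roughly Gaussian data; heavy multimodality within a class would
  favour a smaller bandwidth than the default rule.
- Regulation direction (up vs down) is not modelled; edges are
  unsigned, and miRNA–miRNA or mRNA–mRNA dependencies are outside the
  model family.
- The CLG assumes within-class linearity and Gaussian residuals;
  strong departures degrade both the ranking (through CMI) and the
  classifier, and no goodness-of-fit diagnostic is currently emitted.
- `download()` is a stub interface for fetching real engine releases;
  column mappings cover their layouts, but no release-specific parsing
  or confidence-score thresholding is implemented.
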