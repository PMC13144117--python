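# Methods

`panselect` extracts a non-redundant set of discriminative gene families
from a pangenome presence/absence matrix whose genomes are labeled into
two groups (for example, taxa frequently reported as probiotics versus
reference gut-associated bacteria). This note documents the model, the
parameters that matter, the synthetic data the package validates itself
on, and the numerical choices and limitations a user should know about.

## The feature space

The input is a binary matrix **X** ∈ {0,1}^(n×p): n genomes by p gene
families, X_gf = 1 when family f has a member in genome g. Families are
the clusters produced upstream by a pangenome tool (PPanGGOLiN-style,
typically at 80% identity / 80% coverage), so each column is already a
homology class. The label vector y assigns each genome to one of exactly
two groups; the second group level supplied is coded 1.

## Exploratory stage (visualization only)

PCA is run on the raw 0/1 matrix with mean-centered, unscaled columns —
the standard treatment for presence/absence data, where unit scaling
would inflate rare families. Reported are the per-component explained
variance ratios, the smallest number of components whose cumulative
ratio reaches a target (default 0.90), and the 2-D projection on the top
two components. The projection is clustered with k-means; the cluster
count is picked at the elbow of the within-cluster dispersion curve,
i.e. the k with the largest positive second difference of inertia over
the candidate range. Flat dispersion curves fall back to the smallest
candidate k, and k = 1 is supported as a degenerate input. Nothing in
this stage feeds selection; it exists to let a user eyeball group
structure.

## Selection stage

Three classifiers rank families, each with its own retention rule.

**Random forest (rf).** `rf_external_iterations` (default 100) refits of
a 100-tree Gini forest, each on a stratified random subsample of 90% of
the genomes (group proportions preserved; the first group's count is
rounded down on fractional ties). Within one fit, a family *appears*
when the z-score of its Gini importance against that fit's importance
distribution exceeds `rf_per_iteration_zscore` (default 3). A family is
retained when it appears in at least `appearance_threshold` (default
0.40, inclusive) of the external iterations.

The appearance rule deserves a comment. The obvious alternative — count
any strictly positive importance as an appearance — is available as
`rf_appearance_rule="positive_importance"`, but it is far too permissive
at realistic scales: a 100-tree forest touches hundreds of weakly
informative families per fit, each collecting a sliver of positive
importance, so families with no group association clear the 40%
frequency bar (on the planted-marker benchmark below it yields ~35%
contamination of the retained set). Because normalized Gini importances
are a dense score vector, the same distributional outlier rule used for
the SVM weights is applied by default; on the benchmark it retains all
planted markers and nothing else.

**Linear SVM (svm).** Same external-iteration scheme, fitting a linear
SVM by stochastic gradient descent on the hinge loss with an L2
penalty. L2-penalized linear weights are dense, so a per-iteration
magnitude cutoff is required: a family appears when the z-score of its
absolute weight against the fit's weight distribution exceeds
`svm_per_iteration_zscore` (default 3). Retention is the same ≥ 40%
appearance-frequency rule.

**Logistic regression (lr).** A single L2-penalized fit on the full
matrix (LBFGS, solver cap 300 iterations; a fit that hits the cap is
kept with a warning). Families are scored by their contribution share
|β_f| / Σ|β|. Two retention readings are offered because "cumulative
contribution exceeding 0.3%" is ambiguous:

* `individual_share` (default): retain families whose own share exceeds
  `lr_contribution_threshold` (default 0.003). At most ⌊1/0.003⌋ = 333
  families can ever qualify, since shares sum to 1.
* `cumulative_prefix`: sort by decreasing |β| and retain the shortest
  prefix whose summed share exceeds the threshold — a much smaller set
  when the signal is concentrated.

Both modes are exposed; pipelines that need the larger, more inclusive
set should use `individual_share`.

All randomness flows from one integer seed: each external iteration
draws from an independent stream derived from (seed, iteration index),
so a run is bit-reproducible and iterations are order-independent.

## Consensus

The three retained sets are combined by set algebra into the seven
regions of a three-set Venn diagram; the union is the final feature set
and the three-way intersection is the highest-confidence subset. When
protein sequences are supplied, the union is deduplicated by exact
sequence identity (families with byte-identical protein strings collapse
to the lexicographically smallest ID — the inputs are already similarity
clusters, so a second similarity pass would be redundant). Without
sequences, deduplication is the identity.

## Evaluation

Each method is scored over `n_iterations` (default 100) random
stratified partitions with 90% training / 10% test. Per iteration:
ROC AUC (from the continuous decision score — class probability for
lr/rf, margin for svm — since AUC on hard labels collapses to balanced
accuracy), F1 (positive class = second group level), accuracy, and
k-fold cross-validation accuracy on the training portion (k = 10 by
default; the fold count is a convention, chosen to keep folds
class-balanced at the tested sizes, and is configurable; `cv_folds=None`
skips the column). Summary values are arithmetic means over iterations.

## Functional summary

eggNOG-mapper annotation files are parsed with an inclusive maximum
e-value of 6e-5 (ties at the threshold are kept). A protein annotated
with several COG letters contributes 1/len to each letter, so category
percentages over the annotated total sum to 100; a whole-count mode is
available since either convention appears in practice. Proteins whose
description contains "hypothetical protein" (case-insensitive) are
counted separately.

## Synthetic pangenomes

The generator emulates a partitioned two-group pangenome: `n_core`
families present with probability `p_core` (default 0.99) in both
groups, `n_cloud` sparse group-independent families (`p_cloud` = 0.10),
and `n_markers` planted discriminative families with presence
probability `p_marker_a` in group A and `p_marker_b` in group B. After
Bernoulli sampling every cell is flipped with probability `flip_noise` —
one symmetric-error knob controlling separability. Defaults (100 + 100
genomes, 500 core, 2,000 cloud, 50 markers at 0.95 / 0.05, 1% flip
noise) are the package's benchmark conditions: large enough that markers
are a realistic ~2% of families, small enough for desk-scale runs. The
500/2,000 core/cloud split is a plumbing choice, not an empirical
estimate of any real pangenome's composition.

What the generator deliberately omits: phylogenetic correlation between
genomes (within a group they are exchangeable), gene linkage, sequence
content, and copy number. Consequently, passing the planted-marker
benchmark shows the selection machinery recovers conditionally
independent group-associated families under cell-level noise — it says
nothing about confounding by population structure, which real pangenome
data has and this package does not model or correct for.

## Numerical choices

* SVM optimizer: `SGDClassifier(loss="hinge", penalty="l2",
  learning_rate="adaptive", eta0=0.01)`. The default 'optimal' schedule
  takes large early steps on high-dimensional binary rows and its final
  iterate occasionally misclassifies a training-fold point even on
  perfectly separable data (~1 fold in 1,000); the adaptive schedule
  decays the step size when progress stalls and is exact on the
  separable benchmark.
* Per-iteration z-scores use the population standard deviation of the
  fit's score vector; a zero-variance vector selects nothing.
* Stratified subsampling/splitting guarantees at least one genome per
  group in every test split; a split that still degenerates is redrawn
  once and then raised as an error.
* The elbow pick breaks ties toward the smallest k (numpy argmax).
* Retention comparisons at thresholds are inclusive (≥ for appearance
  frequency, > for the LR share, matching "at least 40%" / "exceeded
  0.3%").

## Known limitations

* **Null behavior of stability selection.** Retention under a fixed but
  uninformative labeling is *not* empty: with n = 200 genomes and 2,550
  families, the families that correlate with a shuffled label vector by
  chance (|r| up to ≈ 0.28) are re-selected in nearly every 90%
  subsample, because subsamples share the labeling that produced the
  chance correlation. Both rf and svm typically retain ~15–30 such
  families per shuffled replicate, while evaluation AUC stays correctly
  at ≈ 0.5 and LR retains none. Users should therefore calibrate an
  empirical null (shuffle labels, rerun selection) for their own matrix
  rather than assuming an uninformative labeling yields an empty set;
  chance-correlation selection shrinks with the number of genomes.
* The z-score appearance rules assume discriminative families are a
  small fraction of the matrix. If a large share of families separates
  the groups (as in tiny toy matrices), the outliers inflate the score
  distribution's spread and markers can fall under the cutoff.
* Exact-identity deduplication will not merge near-identical sequences;
  that is by design, since the inputs are cluster representatives.
* Strictly two-group problems only; no class weighting, hyperparameter
  search, or multiclass support.
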