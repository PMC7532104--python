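# Methods

## Composition model

The pipeline treats drug–disease association strength as path
multiplicity in a heterogeneous network. All primary networks are
binary: any score column in a source export (e.g. a co-expression
weight) is discarded on load, because the only weighting in the model is
the count of distinct connecting paths produced by composition. Primary
edge sets are deduplicated and, for the undirected gene–gene networks,
canonicalized (`left <= right`, self-loops dropped) so that a path is
never counted twice through different orientations of the same edge.

A composed weight is defined as

- direct (length-2) recipes: `w(d,s) = |genes(d) ∩ genes(s)|`;
- bridged (length-3) recipes: the number of ordered pairs `(g1, g2)`,
  `g1 ≠ g2`, with `(d,g1)` in the drug–gene network, `{g1,g2}` in the
  middle network (usable in either direction) and `(s,g2)` in the
  disease–gene network.

The `g1 ≠ g2` restriction is a modelling choice: allowing an identity
hop would make every bridged network contain a copy of its direct
counterpart, and the nine networks are intended as distinct evidence
channels. Implementation is sparse binary matrix multiplication with the
middle matrix symmetrized and its diagonal zeroed; the test suite holds
it to exact agreement with exhaustive path enumeration on random
instances.

The nine default recipes are the factorization 3 disease–gene networks ×
{direct, PPI bridge, co-expression bridge}. With three disease–gene
sources and two gene–gene bridges this is the only arrangement that
yields nine networks from six primaries; the recipe list is configurable
for users who want other chains of the same two shapes (longer chains
and similarity layers are out of scope).

## Feature encoding and negative sampling

A drug–disease pair's feature vector is its weight in each composed
network, in recipe order, 0 where absent. Absence is genuine evidence of
no connectivity, not missingness, so vectors are dense integers and no
transformation is applied by default (`make_classifier(...,
standardize=True)` optionally z-scores columns for scale-sensitive
families such as SVM and logistic regression).

When the labeled set contains positives only, negatives are sampled
uniformly without replacement from the complement of the positive set
over the drug × disease grid, `ceil(ratio × n_positives)` of them
(default ratio 1.0), under a fixed seed. Uniform complement sampling is
the least-assuming treatment of unlabeled pairs; it is isolated in one
function (`sample_negatives`) so a different scheme can be swapped in.

## Classifiers and evaluation

The five families are standard scikit-learn estimators: Gaussian naive
Bayes; random forest with 100 trees and unlimited depth; L2-penalized
logistic regression; CART decision tree with Gini impurity; RBF-kernel
SVM with sigmoid (Platt) probability calibration via internal 3-fold CV.
These are conventional defaults for the families, not a bit-for-bit
reproduction of any other toolkit's settings; the contract of the
package is the families plus the evaluation protocol, not particular
hyperparameters, and no hyperparameter search is performed.

Evaluation is stratified tenfold cross-validation. Stratification is
used (rather than plain folds) to prevent single-class folds on
imbalanced data. Confusion counts are taken at a 0.5 threshold on the
positive-class score; the threshold is the conventional default and is a
parameter of `cross_validate`. Metrics follow their defining ratios on
the aggregate counts — recall `TP/(TP+FN)`, precision `TP/(TP+FP)`,
accuracy `(TP+TN)/total`, and F-measure as the harmonic mean of
precision and recall. A metric with a zero denominator is reported as
NaN with a warning, never silently as 0. AUC is computed threshold-free:
the headline value pools out-of-fold scores into one ranking (stabler at
the sample sizes the synthetic conditions use), per-fold AUCs are kept
alongside, and a gap above 0.05 between the two conventions is logged.

For prediction, the default classifier is the most sensitive
(highest-recall) family from the evaluation round, overridable by
configuration. Candidates for a query disease are restricted to drugs
with at least one nonzero composed weight for that disease; all-zero
vectors carry no evidence and would only pad the ranking. Ties in score
break lexicographically by (drug, disease) so rankings are
deterministic.

## Synthetic study conditions

The generator emulates the one statistical property the method needs:
truly associated pairs accumulate more connecting paths than random
pairs. Background edges are independent Erdős–Rényi draws per network
(degree-skewed backgrounds are deliberately out of scope). Each planted
pair receives `shared_genes_per_planted` signal genes; each signal gene
is linked to the drug, and either directly to the disease or — with
probability `bridge_fraction` — through a random second gene via a
PPI/co-expression edge (coin flip). Disease-side links are recorded by
each of the three disease–gene networks independently with probability
0.8, so the three direct feature channels are correlated but not
identical, mimicking overlapping curation of real disease–gene
databases. If every probabilistic disease-side draw fails for a pair,
one direct disease–gene edge is added deterministically, so every
planted pair is guaranteed at least one path in at least one composed
network.

Defaults: 50 drugs, 30 diseases, 200 genes, background density 0.01 per
role, 40 planted pairs, 4 shared genes per pair, bridge fraction 0.3,
seed 42, with an equal number of sampled negative truth pairs. At these
sizes composition, encoding and five-family tenfold CV complete in
seconds on one core, while planted pairs carry roughly 5–6× the mean
composed weight of background pairs — strong but not degenerate signal.

What passing tests on these conditions show: the machinery recovers a
planted multiplicative path signal and stays calibrated under a null.
What they do not show: performance on real databases, whose degree
distributions are heavy-tailed, whose positives are biased toward
well-studied drugs, and whose unlabeled pairs are not missing at random.
The acceptance checks are therefore properties of the algorithms, not
claims about clinical benchmarks.

## Structural similarity

Distances between drugs are Euclidean on per-column z-scored descriptor
rows — descriptor tables mix scales by orders of magnitude, and without
standardization a single large-scale descriptor dominates. Correlation
is the plain Pearson coefficient between raw rows, reported in [−1, 1]
(multiply by 100 for percentage-style display). A constant descriptor
row has no defined correlation and is rejected by name. The dendrogram
uses average linkage by default (complete and single are available;
the choice is not dictated by the model) and exports Newick with branch
lengths assigned so a node's root-to-leaf path length equals the root
merge height.

## Numerical and degenerate-input choices

- Identifiers are case-sensitive, matched exactly; an optional mapping
  table renames gene-namespace identifiers at load time (e.g. protein
  accessions to gene symbols) without guessing any mapping.
- Composed weights are raw integer counts, never normalized.
- An empty drug–gene network composes to nine empty networks rather than
  erroring; an empty candidate set yields an empty ranking.
- Cross-validation requires `2 ≤ n_folds ≤ min class count`; violations
  raise configuration errors rather than silently degrading.
- All randomness (generation, negative sampling, fold shuffling, tree
  seeds) flows from explicit integer seeds; reruns are byte-identical.

## Known limitations

- Path semantics stop at one bridging edge; longer chains and
  drug–drug/disease–disease similarity layers are not modelled.
- Negative sampling assumes non-associations are missing completely at
  random, which real benchmarks violate.
- The synthetic generator does not imitate the size or degree structure
  of real source databases, only the planted-signal property.
- Descriptor computation from chemical structures is out of scope; the
  similarity module consumes a precomputed numeric table.
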