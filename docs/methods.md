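# Methods

## Corpus model

The corpus is four tables: gene–disease associations tagged with one of
eight source databases, drug–target pairs, drug–indication pairs with a
status (`CLINICAL` or `APPROVED`; approval implies clinical support in
every ratio computation), and unordered ohnolog gene pairs. Identifiers
are opaque strings — no vocabulary normalization is attempted, which keeps
the tool usable on any corpus that can be expressed in these four tables.
Duplicate rows are dropped with a logged count rather than rejected, since
real database dumps contain them. All orderings (drug index i = 1..n,
disease index l = 1..q) are lexicographic, so every derived matrix is
reproducible across loads.

The sample universe is the set of *eligible pairs*: (drug, disease) with
at least one targeted disease-associated gene. Indications outside this
universe are retained in the corpus but excluded from training and
evaluation; their count is reported in the run manifest. This keeps the
positive/negative partition exactly complementary within the universe.

## Druggability score

Each source database carries an integer quality point value; the default
table (ClinVar 8, OMIM 7, HGMD 6, Orphanet 5, GWASdb 4, INTREPID 3, GAD 2,
DisGeNET 1) follows the empirical ranking of how often each database's
genetics-implicated activities are clinically supported. The score of a
(gene, disease) pair is the sum over the *distinct* databases recording
it — duplicates count once, because the sum runs over databases, not
records. The table is configurable (`points.tsv`) for corpora with fewer
sources; ties in an externally re-derived ranking are not given shared
points — the default is the strict permutation 8..1. A pair absent from
the corpus is a lookup error, never score 0, which the scheme cannot
produce (minimum is 1).

## Features

Feature vectors are disease-indexed: a drug's instance vector has one
entry per disease, zero wherever it targets no gene of that disease. With
T the targeted disease genes of a cell:

| feature | definition | range |
|---|---|---|
| f1 | Σ_{g∈T} score(g, d) | 0, 1, 2, … |
| f2 | f1 / (|T| × 36) | [0, 1] |
| f3 | |T ∩ ohnolog members| | 0, 1, 2, … |
| f4 | f3 / |T| | [0, 1] |

36 is the maximum attainable single-gene score (8 + 7 + … + 1). 0/0 cells
return 0 rather than erroring: the negative class legitimately includes
low-evidence pairs. f4's denominator is the number of targeted *disease*
genes, paralleling f2's denominator; a variant dividing by all targets is
available (`denominator="all_targets"`) for sensitivity analysis. Ohnolog
membership serves as the high-confidence ("top gene") proxy throughout;
curated per-disease top-gene lists are out of scope.

## MLKNN

For each disease l, fitting computes the smoothed prior
P(H₁) = (s + n₊(l))/(2s + n) and two posterior tables over the neighbour
count j ∈ {0..k}: P(Eⱼ|H₁) = (s + c_l[j])/(s(k+1) + Σᵢ c_l[i]) and the
H₀ analogue with c′_l[j], where c_l[j] counts training drugs *carrying* l
with exactly j positive neighbours among their k nearest, and c′_l[j]
those *not carrying* l. These are the count tables of the classifier's
original formulation; conditioning on the instance's own label is what
gives the two hypotheses different likelihoods (an unconditioned table
would make the posterior independent of the hypothesis and invert scores
for rare labels). Consequently Σⱼ c_l[j] = n₊(l), Σⱼ c′_l[j] = n − n₊(l),
and each posterior row sums to 1 exactly.

Prediction reports the normalized two-hypothesis posterior
P(H₁)P(E_C|H₁) / (P(H₁)P(E_C|H₁) + P(H₀)P(E_C|H₀)), a [0, 1] score whose
0.5 cutoff reproduces the MAP decision; a probability-scaled score is
needed because downstream calls use a fixed 0.5 threshold.

Numerical and procedural choices:

* defaults k = 10, s = 1 — the canonical MLKNN settings; both are flags.
* Euclidean distance on the feature vectors; squared distances are
  computed by broadcast subtraction so the per-cell summation order
  matches a plain loop, keeping neighbour orderings reproducible against
  a literal reference implementation.
* distance ties at the k-th neighbour break by ascending training index —
  determinism over symmetry.
* during fitting each instance is excluded from its own neighbourhood
  (leave-one-out), preventing label leakage; test-time neighbourhoods use
  the full training set.

## Ensemble

Per feature kind, five MLKNN models are fitted on the five internal
training folds; their out-of-fold predictions give one score matrix per
feature. Weights live on the 4-simplex and are tuned by exhaustive grid
search (step 0.1 → 286 candidates) maximizing the pooled AUPR over
eligible cells of the weighted out-of-fold matrix. A grid is deterministic
and exactly reproducible, and because it contains the corner vectors the
tuned fitness can never fall below any single-feature predictor's AUPR on
the same folds. Ties break toward the vector nearest the uniform weights,
then lexicographically. Internal folds are stratified by per-drug positive
count bands (0, 1–2, ≥3) to balance positive mass; a fold whose held-out
eligible cells contain no positive is re-drawn once, then errors.

At deployment the five fold models are kept and their ensemble scores
averaged (no refit on 100% of the data); the cross-fold standard deviation
is reported per cell as an uncertainty indicator but never affects calls.
AUPR is pooled over all eligible cells, not averaged per disease, matching
how merged activity predictions are evaluated in this setting.

## Metrics

Binary metrics are exact transcriptions of their confusion-count formulas;
a zero denominator yields NaN, never an exception. AUPR is the
precision–recall step integral over distinct thresholds
(scikit-learn's `average_precision_score`); AUC is available but AUPR is
the primary metric because negatives outnumber positives by orders of
magnitude. Multi-label metrics: hamming loss at the 0.5 cutoff; one-error;
coverage reported 0-based (steps beyond the first, the convention of the
MLKNN literature); ranking loss; average precision. Within-instance score
ties use the average-rank convention for the pairwise metrics (a tied
relevant/irrelevant pair contributes ½ to ranking loss), while coverage
uses the guaranteed depth (max-rank) so it remains an integer count.
Instances with no relevant label are skipped for rank-based metrics with a
logged count.

## Validation statistics

* **Tanimoto**: n_AB / (n_A + n_B − n_AB) from set sizes; symmetric, 1 iff
  the sets are identical.
* **Lin similarity**: IC(lcs)/(IC(c₁) + IC(c₂)) with IC = −log p and the
  least common subsumer taken as the common ancestor of maximal IC. The
  default follows the printed form of the measure as used here, under
  which self-similarity is 0.5; `canonical=True` restores the usual
  2·IC(lcs) numerator. Concepts with no common ancestor return NaN.
* **Czekanowski–Dice**: |A △ B| / (|A ∪ B| + |A ∩ B|); NaN when both sets
  are empty.
* **Permutation test**: the gene column of the drug–target table is
  permuted, preserving each drug's number of target slots and the global
  target multiset — the conservative, degree-preserving reading of
  "randomly assigned targets". The clinically-active ratio over eligible
  pairs is recomputed per permutation (vectorized via a gene × disease
  incidence matrix and segmented reduction, so 10,000 permutations take
  seconds), and p = (1 + #{null ≥ obs})/(1 + n_perm): the +1 correction
  means p is never 0 — at 10,000 permutations the floor is 1/10,001.
* **Stratified ratio curves**: eligible pairs are binned by targeted
  disease-gene count, f1 druggability, or ohnolog coverage (which also
  serves as the top-gene proxy); each bin reports its clinically-active
  and approved ratios (approved ≤ clinical by construction), and the
  monotone trend is summarized as the Spearman correlation of bin index
  versus clinical ratio over non-empty bins. Empty bins emit n = 0 points
  with NaN ratios.
* **Disease profile correlation**: Spearman over the union of the two
  diseases' scored genes, absent genes scored 0; NaN below 3 genes.

## Synthetic corpora

The generator emulates the tripartite structure the pipeline consumes.
Gene–disease associations are drawn independently per database, with
inclusion probabilities (0.005 … 0.05) *increasing* as quality points
decrease: curated sources are selective, text-mined ones prolific, which
yields mostly 1-database pairs with occasional high-score multi-database
pairs, as in real provenance. 30% of genes form ohnolog pairs; each of the
200 drugs targets 2–10 genes uniformly. Indications are drawn for eligible
pairs from the planted logistic model

P(indicated) = σ(base_logit + β₁ · f1/36 + β₃ · f3),

defaults base_logit = −3.5, β₁ = 6, β₃ = 1, chosen so the
clinically-active ratio runs from a few percent in the lowest druggability
stratum to beyond 15% in high strata — the magnitude regime reported for
real genetics-implicated activity corpora. Only f1 and f3 drive the link:
f2/f4 are deterministic transforms whose inclusion would confound recovery
checks. 30% of indicated pairs are marked approved.

Because the planted model places indications only on *eligible* pairs,
even a zero-slope corpus couples activity to real drug–target links — and
the permutation test rightly rejects on it. The `random_indications` mode
therefore draws indications for every (drug, disease) pair at the base
rate, independent of targets; this is the null corpus used to check the
permutation test's type-I error calibration.

What passing tests on synthetic corpora do **not** show: real corpora have
correlated database memberships, heavy-tailed target-set sizes,
disease-specific gene-set sizes, and indication biases from trial design —
none of which the generator models. Synthetic results demonstrate
correctness of the machinery and recoverability of a planted signal, not
expected performance on real data.

## Problem sizes

Test and example corpora use 60–200 drugs, 10–20 diseases and 100–300
genes; calibration checks run 500 null corpora at 99 permutations each,
and the floor-of-p check runs the full 10,000 permutations once. These
sizes give stable statistics while keeping the full suite fast enough to
run on every change.

## Known limitations

* The druggability point table is ordinal made cardinal: summing ranks is
  a modelling choice inherited from the scoring scheme, not a calibrated
  probability.
* MLKNN on 1-dimensional per-disease features discards cross-disease
  signal except through the neighbour structure; feature vectors are the
  full q-length profiles, which partially recovers it.
* The grid-tuned weights are global, not per disease.
* Lin similarity and the GO distance operate on user-supplied ontologies
  and annotation tables; no ontology is bundled.
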