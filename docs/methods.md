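# Methods

This note documents the statistical model behind `diaclust`, the defaults it
ships, the design decisions taken where the analysis recipe is genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Problem setting

The input is a protein × sample matrix of label-free DIA/SWATH intensities
from a matched cohort: each patient contributes one primary tumor sample and
one or more distant metastases. FFPE material yields heavy, intensity-
dependent missingness, and patients contribute unequal numbers of
metastases. The analysis asks two complementary questions: which proteins
differ between pooled primaries and pooled metastases (supervised), and
what sample structure exists regardless of the labels (unsupervised), with
candidates nominated from the agreement of the two views.

## Preprocessing

**Valid-value filter.** A protein is kept when its quantified fraction over
*all* samples is ≥ `min_valid_fraction` (default 0.5, inclusive — "at
least half"). The filter is computed over the whole cohort rather than per
group; with matched designs the group imbalance (14 vs 24 here) makes
per-group filtering ambiguous and the pooled rule is the simpler contract.

**log2 transform.** All modelling happens on the log2 scale; raw intensities
must be strictly positive where present.

**Invariant-protein median normalization.** Per-sample depth offsets are
estimated from a panel of `n_invariant` (default 100) proteins that are
quantified in *every* sample and have the smallest cross-sample variance of
log2 intensity (ties break by protein id; if fewer complete proteins exist
than requested, all are used with a warning). The offset of sample *j* is
the median of its panel values minus the grand median of all samples' panel
medians, subtracted on the log2 scale (equivalently raw-scale division).
Anchoring at the median (not the mean) makes the estimate robust to a few
unstable panel members and makes the operation idempotent. The invariance
ranking is a pluggable strategy: low variance is the default, and callers
can supply any scoring of the complete sub-matrix (e.g. a correlation-based
ranking) without touching the offset arithmetic.

**Imputation policy.** Missing values are replaced by the *per-protein* mean
of valid values — a deliberately conservative choice that shrinks group
contrasts rather than inventing low values — and imputation feeds **only**
PCA and consensus clustering. Differential expression and GSEA always
operate on unimputed values; the pipeline wiring enforces this and the
integration tests assert it. A global-mean variant exists behind a flag for
sensitivity analysis. Rows with no valid values cannot be imputed and must
be filtered first.

## Differential expression

Pooled primaries vs pooled metastases are compared per protein with the
two-sided Mann–Whitney U test on valid values only. The unpaired test is the
conservative choice for this design: a paired test would weight patients by
their metastasis count. The statistic is the midrank U for the primary
group; p-values are

- **exact** for combined sample sizes ≤ 12: full enumeration of all
  C(n₁+n₂, n₁) group-label assignments of the pooled values with test
  statistic |U − n₁n₂/2|, which handles ties without approximation;
- **asymptotic** otherwise: normal approximation with tie correction and
  continuity correction (matches the standard two-sided form).

Fold change is the difference of per-group means of log2 intensities
(log2FC = primary − metastasis; negative = up in metastases). A mean-of-log
estimator is the common convention and keeps the volcano symmetric; a
median-based estimator can be swapped in by configuration. Proteins with
fewer than two valid values in either group are reported but not tested
(U-statistics are degenerate below that). Benjamini–Hochberg adjusted
p-values are emitted alongside, but volcano classification uses the
unadjusted p (default threshold 0.05) together with |log2FC| ≥ 0.5, so the
supervised call can be compared against the orthogonal unsupervised view
rather than standing alone.

## Consensus NMF

**Input conditioning.** NMF consumes the imputed log2 matrix with its global
minimum subtracted, anchoring the smallest entry at exactly zero. This is
more than a nonnegativity fix: log2 DIA intensities sit far above zero
(≈14–27), and with such a large shared offset the nonnegativity constraints
never bind, leaving the factorization a family of rotated solutions with
equal reconstruction error but different dominant-component assignments —
consensus matrices then stay diffuse at every rank and rank selection is
uninformative. Anchoring the minimum at zero preserves every between-sample
and between-protein difference while making the parts-based decomposition
identifiable. The applied shift is recorded in the run manifest.

**Factorization.** Lee–Seung multiplicative updates for the squared
Frobenius objective, with uniform random initialization scaled to the data
mean. The per-iteration error sequence is returned and is non-increasing (a
tested property); iteration stops at a relative improvement below `tol`
(default 1e-6) or `max_iter` (default 500). A small additive constant
(1e-12) in the update denominators guards against division by zero.

**Consensus.** For each rank k, `n_runs` (default 50) restarts with seeds
`seed + run` are fitted. Each run assigns every sample to its dominant
component — after normalizing W columns to unit norm and absorbing the scale
into H, so the diagonal rescaling freedom of (W, H) cannot flip the argmax.
The consensus matrix is the run-average co-assignment indicator; sample
labels come from an average-linkage cut of 1 − C into k groups, which is
robust to component label switching across runs. The basis/coefficient
matrices of the lowest-error run are kept. Degenerate runs in which a
component dominates no sample are retained; fewer than k distinct labels can
result and is documented behavior.

**Rank selection.** Two stability summaries per rank: the cophenetic
correlation between the consensus dissimilarities 1 − C and the cophenetic
distances of their average-linkage dendrogram, and the dispersion
coefficient (1/n²)ΣΣ4(C<sub>ij</sub> − ½)², both equal to 1 for a perfectly
reproducible clustering. The selected rank is the smallest interior k of the
sweep (default 2…10) that is a *strict local maximum of both* sequences;
when no such k exists the global cophenetic maximum is returned with a
warning (ties → smallest k). The full sweep table is always written so the
rule can be audited.

**Relevance scores.** For protein i with basis profile
p(i,q) = W<sub>iq</sub>/Σ<sub>q'</sub>W<sub>iq'</sub>, the score is one
minus the normalized entropy, 1 + (1/log₂k)Σ<sub>q</sub>p log₂ p (0·log 0
:= 0): 1 for a one-hot (fully cluster-specific) profile, 0 for a uniform
one, invariant to row rescaling. All-zero rows score 0 with a warning.
Scores are computed from the lowest-error run's W at the selected rank.
"Cluster-relevant" proteins are those *strictly above* the
linear-interpolation 90th percentile of all scores.

**PCA.** Sample-space PCA on the imputed matrix, with an unimputed variant
restricted to 100%-valid proteins for comparison (the run manifest records
that complete-protein count). Component signs are fixed by making the
largest-magnitude loading positive, so embeddings are deterministic.

## GSEA

Genes are ranked by a pooled-variance two-sample t statistic (primary −
metastasis), with a variance floor of 1e-8 to keep near-constant genes
finite, descending order, ties broken by gene id; genes with under two valid
values in a group are dropped with a warning. The enrichment score is the
classic weighted Kolmogorov–Smirnov running sum (hits add |t|^weight
normalized by total hit weight, misses subtract 1/(N − N_hits); weight
default 1). Significance is by phenotype permutation: tissue labels are
shuffled `n_perm` times (default 100) and the whole ranking and every ES are
recomputed. Nominal p = (1 + b)/(1 + m) over same-sign permutation scores —
never zero at finite n_perm; NES divides ES by the mean same-sign permuted
magnitude; FDR q follows the standard sign-stratified pooling of permuted
NES. Sets are filtered to 5–500 members after intersection with measured
genes (conventional bounds, configurable). Protein ids double as gene
symbols unless a two-column mapping table is supplied.

## Candidates and immunoblot statistics

Candidates are the proteins present in both the DE-significant set (default:
all proteins at p ≤ 0.05; a |log2FC|-gated pool is available by flag) and
the cluster-relevant set, ordered by ascending p. Densitometric immunoblot
values are normalized as (raw band / mean of same-gel bridging standards) /
loading control — the standard division makes gels directly comparable —
with technical replicates averaged after normalization, and compared between
tissue groups with the same Mann–Whitney machinery as the discovery stage.

## Synthetic cohorts

The generator emulates the matched-cohort regime: `n_patients` (default 14)
each contribute one primary and a per-patient metastasis count drawn
uniformly from `metastases_per_patient` (default 1–4), nudged to
`total_metastases` (default 24, i.e. 38 samples). Protein log2 abundances
are Gaussian, base N(20, 2²), with per-sample depth offsets N(0, 0.3²) and
residual noise sd 0.5 — magnitudes typical of log2 DIA intensity matrices.
DE effects (default +1 log2 unit in metastases) are planted additively on a
dedicated protein block; cluster structure (default 3 clusters, +2 log2
units) on a disjoint block, so the two truths stay separable for testing.
Dropout is applied after effect planting and combines a random component
(`mar_rate`, default 0.03) with logistic intensity-dependent dropout
p = mar + (1 − mar)·σ(−slope·(x − midpoint)), defaults slope 2.5 per log2
unit and midpoint 18.7. These dropout defaults were calibrated once so the
default cohort reproduces the coverage regime of a real 38-sample FFPE
cohort — a median of ~1000 of 1405 proteins quantified per sample and
~1050 proteins at the 50% filter; the *mechanism* (MNAR/MAR split) is a
modelling choice, not an estimate, since the real mechanism is unobserved.

What the generator does **not** emulate: peptide-level roll-up, batch blocks
or chromatographic drift beyond per-sample scalar offsets, correlated
protein modules beyond the planted blocks, and heavy-tailed or
batch-structured missingness. Passing recovery tests therefore shows the
pipeline's machinery is correct and calibrated under this generative model,
not that real FFPE cohorts will yield equally clean rank selection.

## Problem sizes used in tests and the acceptance script

Calibration checks run at desk scale: type-I control on 50 cohorts of 200
proteins (null effect), sensitivity on 20 cohorts of 150 proteins with 30
planted unit effects at 14-vs-24 group sizes, GSEA null calibration on 10
cohorts × 100 permutations × 20 random sets, and cluster recovery on 20
cohorts of 100 proteins with 30 cluster-carrying proteins (rank sweep 2–6,
20 NMF restarts per rank). The acceptance script additionally pushes one
full default-regime cohort (1405 proteins, 38 samples) through the entire
pipeline with a 2–10 rank sweep at 20 restarts per rank.

## Known limitations

- Rank selection requires a strict joint peak; plateaus fall back to the
  global cophenetic maximum, which on weakly structured data tends toward
  the sweep edges.
- The exact Mann–Whitney path enumerates all label assignments and is
  intended for combined sample sizes ≤ 12 (the default switch point).
- Consensus NMF assumes the imputed matrix is meaningful; under extreme
  missingness mean imputation flattens samples toward protein means and
  cluster recovery degrades before the DE branch does.
- FDR q for GSEA pools permuted NES across sets of the same sign; with very
  few sets the pool is small and q is coarse.
- On full-regime synthetic cohorts (1405 proteins, 60 cluster-carrying)
  the planted-rank peak can shift by one (e.g. k = 4 for 3 planted
  clusters) because mean-imputed MNAR missingness blurs the block
  structure; the dedicated recovery simulations quantify this.
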