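# diaclust

Differential expression and consensus-NMF clustering for label-free DIA
proteomic intensity matrices from matched tumor cohorts.

`diaclust` implements the complete downstream analysis of a protein × sample
intensity matrix from a matched primary-tumor / distant-metastasis cohort
(e.g. FFPE lung adenocarcinoma tissue profiled by DIA/SWATH mass
spectrometry): valid-value filtering, invariant-protein median
normalization, unpaired Mann–Whitney differential expression with volcano
classification, stochastic consensus non-negative matrix factorization with
cophenetic/dispersion rank selection and entropy-based feature relevance,
phenotype-permutation gene set enrichment, and intersection-based candidate
nomination. A synthetic-cohort generator with known ground truth (planted
effects, planted clusters, MNAR + MAR dropout) makes every stage testable
without access to a real proteomics deposit.

It is aimed at computational proteomics practitioners who have a quantified
protein matrix (e.g. from Spectronaut/DIA-NN) plus a sample sheet and want a
reproducible, seeded, manifest-recorded version of this analysis.

## Methods at a glance

**Filtering and normalization.** Proteins quantified in ≥ 50 % of samples
are retained. Per-sample depth offsets are estimated from the *n* = 100
lowest-variance fully-quantified ("invariant") proteins: for sample *j*,
δ<sub>j</sub> = median<sub>i∈inv</sub>(x<sub>ij</sub>) − median<sub>j'</sub>(median<sub>i∈inv</sub>(x<sub>ij'</sub>)),
and the normalized matrix is x<sub>ij</sub> − δ<sub>j</sub> on the log2 scale.

**Differential expression.** Pooled primaries vs pooled metastases by the
two-sided Mann–Whitney U test (exact enumeration for small samples,
tie-corrected normal approximation otherwise), fold change
log2FC = mean<sub>primary</sub> − mean<sub>metastasis</sub> (negative ⇒ up in
metastases), Benjamini–Hochberg adjustment alongside, and volcano classes at
p ≤ 0.05 and |log2FC| ≥ 0.5. Tests always run on *unimputed* values.

**Consensus NMF.** On the mean-imputed, zero-anchored log2 matrix *V*,
Lee–Seung multiplicative updates minimize ‖V − WH‖²<sub>F</sub> for
k = 2…10. For each rank, many random restarts are summarized in a consensus
matrix C (fraction of runs in which two samples share the dominant
component); rank selection takes the smallest interior k that is a strict
local maximum of both the cophenetic correlation of C and the dispersion
coefficient (1/n²)ΣΣ4(C<sub>ij</sub> − ½)². Per-protein cluster relevance is
1 + (1/log₂k) Σ<sub>q</sub> p(i,q) log₂ p(i,q) with
p(i,q) = W<sub>iq</sub>/Σ<sub>q'</sub>W<sub>iq'</sub>; proteins above the
90th percentile are "cluster-relevant".

**GSEA.** Genes are ranked by a pooled two-sample t statistic; the weighted
Kolmogorov–Smirnov running sum yields ES per set, with significance from
phenotype-label permutation (default 100 permutations, p = (1+b)/(1+m)).

**Candidates.** The intersection of the DE-significant set with the
cluster-relevant set, ordered by p-value.

## Worked example

Simulate a small matched cohort with 30 planted differentially expressed
proteins and 3 planted sample clusters, then run the full pipeline:

```sh
$ cat sim.yaml
n_patients: 8
total_metastases: null
metastases_per_patient: [1, 2]
n_proteins: 300
n_de_proteins: 30
de_effect: 1.0
n_cluster_proteins: 45
n_clusters: 3
cluster_effect: 2.0

$ diaclust simulate --config sim.yaml --seed 1 --out cohort
wrote 300 proteins x 21 samples to cohort (median 208 valid per sample)

$ cat run.yaml
matrix_path: cohort/matrix.tsv
sheet_path: cohort/samples.tsv
output_dir: analysis
n_invariant: 50
k_min: 2
k_max: 6
n_runs: 25
seed: 7

$ diaclust run-all --config run.yaml
selected k = 3; 4 candidates; outputs in analysis
```

The rank sweep shows why k = 3 wins — both stability metrics peak exactly at
the planted cluster count:

```
$ head -5 analysis/nmf_sweep.tsv
k       cophenetic              dispersion              mean_reconstruction_error
2       0.9581008956113608      0.4206621315192744      35.52769378283412
3       1.0                     1.0                     30.536260040544825
4       0.998159516695036       0.8481414965986395      28.63854428347807
5       0.9938173709166213      0.7644916099773242      27.279962030202324
```

`analysis/candidates.tsv` lists the proteins that are both significantly
differentially expressed and cluster-relevant, e.g.

```
protein_id  log2fc  p_value  p_bh   de_class    relevance  direction
PROT00036   1.095   0.0034   0.050  up_primary  0.187      up_primary
```

(positive log2FC = higher in primaries). `analysis/manifest.json` records
the resolved configuration, stage order and record counts; rerunning the
same config and seed reproduces every numeric table byte for byte.
`diaclust report` renders the volcano plot, consensus heatmap, rank-sweep
curves, z-scored relevance heatmap and PCA scatter from a finished run.

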