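# ctclsc

Single-cell analysis toolkit for cutaneous T cell lymphoma (CTCL) skin
lesions profiled with paired scRNA-seq and scTCR-seq.

CTCL lesions mix clonal malignant T cells with reactive T cells of the same
lineages, so neither expression nor clonotype alone identifies the tumor.
This package implements the combined decision rule and the downstream
analyses built on it, for computational biologists working with lymphoma
(or other clonal T-cell) single-cell data:

- **Malignant-cell identification.** A T-cell cluster is called malignant
  when it shows *both* large-scale expression-inferred CNVs (aneuploidy)
  *and* clonal TCR expansion. CNV profiles are estimated infercnv-style:
  log-normalized expression is centered on reactive reference cells,
  clipped at ±3, smoothed by a 101-gene moving average along each
  chromosome, recentered per cell at its median, and summarized per cell as
  a burden `b_i = mean_p x_ip²`. Clonotypes are paired αβ CDR3-nucleotide
  keys (dual-TRA clones keep both α chains); a clonotype with frequency
  > 50 cells in a sample is its dominant clone, ≥ 3 is clonally expanded,
  2–49 is the low-level expansion band. Clusters with < 20% productive
  αβ pairs whose residual pairs match the dominant clone are flagged as
  TCR-loss malignant subclusters. Double-negative reactive cells (no CD4,
  no CD8B) are excluded, and samples need > 80 malignant cells to enter
  malignant-cell analyses.
- **Intratumor expression programs.** Per sample, malignant-cell expression
  (genes with SD ≥ 0.5, centered, negatives clamped to 0) is factorized by
  rank-5 NMF (multiplicative updates, NNDSVD initialization); each factor's
  50 top-scoring genes define a program. Programs from different patients
  sharing ≥ 10 top genes are clustered into meta-programs whose signatures
  are the unions of member top-gene lists.
- **Molecular subtyping and survival.** Per-sample DEGs (two-sided rank-sum,
  log2FC > 1.5, p < 0.05) drive hierarchical clustering of samples into a
  cytotoxic effector-memory-like group (T_CyEM) and a central-memory-like
  group (T_CM); group signatures are the DEG intersections (log2FC > 0.25)
  across a group's samples. Signature scores (expression-bin-matched
  control scheme) stratify survival cohorts at the median, compared by the
  log-rank test.
- **Tumor–microenvironment interactions.** CellPhoneDB-style permutation
  test: the score of a ligand–receptor pair for an ordered (sender,
  receiver) type pair is the average of the ligand's mean in senders and
  the receptor's mean in receivers; p is the fraction of label-shuffled
  scores at least as high.
- **Inter-lesion phylogenies.** Somatic variants are partitioned into
  stem/shared and lesion-private sets, and small maximum-parsimony trees
  (exhaustive topology search with Fitch small parsimony, germline root)
  are built with branch lengths counting nonsynonymous mutations.
- **Synthetic cohorts.** Because comparable patient data are
  access-controlled, `ctclsc.simulate` generates cohorts with planted
  ground truth — negative-binomial counts over cell-type profiles,
  multiplicative CNV segments, a monoclonal malignant population with
  dominant clonotype, TCR-loss subcluster and dual-TRA clones, shared
  intratumor programs, stem/private variants, and survival times tied to a
  planted signature — so every stage is testable against known truth.

## Worked example

```
$ ctclsc simulate --out demo/cohort --patients 2 --cells 400 --seed 7
cohort written to demo/cohort
$ ctclsc run --cohort demo/cohort --out demo/calls --seed 0
P01-L1: 200/400 malignant, dominant=True
P02-L1: 200/400 malignant, dominant=True
calls written to demo/calls
$ ctclsc programs --cohort demo/cohort --calls demo/calls/cell_calls.tsv \
      --out demo/programs --seed 0
10 programs -> 4 meta-programs
$ ctclsc survival --table demo/cohort/survival.csv
log-rank p = 0.006556 (median survival low=38.6, high=7.3 months)
```

The `run` lines report, per sample, how many cells were called malignant
(here each 400-cell sample planted a 200-cell malignant clone — all
recovered) and whether a dominant clonotype (> 50 cells) was found.
`programs` extracted 5 NMF programs per sample; the four planted
cross-patient programs clustered into exactly 4 meta-programs, while each
sample's private program stayed a singleton. The survival command split the
49-patient synthetic cohort at the median planted-signature score: the
high-score arm progressed earlier (median 7.3 vs 38.6 months, log-rank
p = 0.0066), as planted (hazard ∝ exp(score)).

Per-cell calls land in `demo/calls/cell_calls.tsv` (status, cluster,
evidence flags, CNV burden) and `demo/calls/sample_summary.csv` holds the
per-sample malignant counts and the > 80-cell retention flag.

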