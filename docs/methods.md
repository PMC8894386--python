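# Methods

This note records the models, parameter choices and numerical conventions
behind `ctclsc`, and what the synthetic cohort does and does not emulate.

## Preprocessing and clustering

Quality control drops genes detected in fewer than 10 cells first, then
cells outside the 500–5000 detected-gene band (boundaries retained) or with
mitochondrial fraction strictly above 10% (prefix `MT-`, configurable).
Normalization is `ln(1 + 10,000·c/total)` per cell. Nuisance regression
takes per-gene OLS residuals against cell-cycle scores, mitochondrial
fraction, total counts and detected genes (intercept always included;
constant or collinear covariates dropped with a warning), followed by
per-gene z-scaling clipped at ±10 — the clip bounds PCA inputs, standard
practice. Genes whose variance is numerically zero (< 1e-10 SD) map to 0
rather than amplifying float noise.

Highly variable genes are ranked by variance over a local mean–variance
trend (running mean of gene variances in mean-expression order, window 31);
several dispersion flavors are in common use, and this simple criterion is
the package's choice, configurable, with a default of 3,000 genes. PCA keeps 30 components with a fixed sign
convention (largest-magnitude loading positive) so embeddings are
reproducible. Clustering builds a k=20 shared-nearest-neighbor graph
(Jaccard weights, pruned below 1/15) and optimizes RB-configuration
modularity with the Leiden algorithm at a given resolution, seeded;
labels are renumbered by first appearance. Whole-biopsy clustering uses
resolution 0.2; T-cell subclustering — the granularity at which malignancy
is called, and the one relevant to the nearly-all-T synthetic cohort —
uses 0.6.

## CNV inference and aneuploidy

Steps: order genes by (chromosome, start); center each gene on its mean
over reference cells; clip to ±3; moving average of 101 genes within each
chromosome (window shrinks with a warning on short chromosomes); subtract
each cell's median smoothed value; finally re-center every position on the
reference cells so the reference mean profile is exactly zero (as the
reference-based tools themselves do — per-cell median recentering alone
would leave a small reference offset). Window and clip are the upstream
tool's documented defaults, exposed as flags. Sex chromosomes are excluded
by default to avoid sex-driven artifacts. Burden is the mean squared
smoothed value per cell.

A cluster is called aneuploid when its median burden reaches 2× the 90th
percentile of the reference cells' burdens. The upper-quantile reference
(rather than the reference median) keeps tiny noise clusters and
heterogeneous reactive subtypes from tripping the call; aneuploidy calls
of this kind are often resolved by manual review, so this explicit rule is
the package's codification and both knobs (`fold`, `burden_quantile`) are
exposed.

In the full pipeline the reference set is bootstrapped from clonality:
cells carrying a productive paired clonotype *different* from the dominant
clone (and outside TCR-loss clusters). Cells with no productive pair are
deliberately excluded from the reference — they may be malignant cells
with TCR dropout, and including them contaminates the burden calibration.

## Clonotypes and expansion classes

Clonotype identity is CDR3 *nucleotide* sequence (sorted productive-TRA
list plus the productive TRB); nucleotide-level matching tracks clonal
descent more strictly than amino-acid matching and is configurable. Cells
with > 2 productive TRA or > 1 productive TRB are ambiguous and excluded
from frequency counts. Classes: dominant > 50, expanded ≥ 3, low-level
expansion band 2–49 (surfaced alongside the classes), singleton = 1.
TCR-loss clusters: productive-pair rate over *all* cells of the cluster
< 20%, and the modal key among the residual pairs equals the dominant
clone. A cluster whose residual pairs all dropped out cannot be confirmed
and is conservatively left unflagged — on the default synthetic cohort
this affects roughly one 38-cell cluster in thirteen samples.

## Malignancy calls

A cluster is malignant iff aneuploid AND ≥ 50% of its paired cells carry
the dominant clonotype (cluster-level modal matching; per-cell matching
would fragment calls under TCR dropout). TCR-loss clusters are
malignant_tcr_loss when aneuploid. The conjunction is deliberate: an
aneuploid-looking but polyclonal cluster stays reactive, and removing TCR
evidence can only shrink the malignant set. Reactive cells with zero CD4
and CD8B counts are excluded as double-negative; samples are retained for
malignant-cell analyses iff malignant count > 80 (strict).

## Expression programs and scoring

NMF is Frobenius multiplicative updates with deterministic NNDSVD
initialization (zeros filled at 1% of the matrix mean; seeded random init
available); the objective is non-increasing every iteration and iteration
stops at relative change < 1e-6 or 2,000 iterations (500 in the per-sample
pipeline, ample for these sizes). Per sample: SD ≥ 0.5 gene filter on
log-normalized values (computed pre-centering; configurable), per-gene
centering, negatives to 0, rank 5, top 50 genes per factor.

Meta-programs: average-linkage hierarchical clustering on distance
1 − overlap/50 provides display ordering; the actual cut is single-link
connectivity at overlap ≥ 10, components with ≥ 2 members become
meta-programs, singletons are dropped, and the signature is the union of
member top-gene lists. The output is invariant to program input order.

Signature scores are expression-bin-matched control scores: genes are
ranked by mean expression into 25 bins; each signature gene draws up to 100
control genes from its bin (signature genes excluded from the pool,
widening to neighboring bins if a bin is exhausted); score = mean signature
expression − mean control expression. This widely used scheme is the
package's scoring choice. Cell
cycle uses the shipped 43 G1/S and 54 G2/M gene lists; phase is the argmax
of (S, G2M) when positive, else G1.

## Subtyping, exhaustion split, survival, interactions

DEGs use the two-sided Mann–Whitney test (exact on small untied samples)
with log2FC on de-logged means plus pseudocount 1; raw p is thresholded by
default, with BH-adjusted p reported alongside.
Sample grouping: correlation-distance average-linkage clustering of
per-sample average DEG expression, cut at two; the group with higher mean
cytotoxic-gene expression is labeled T_CyEM. Group signatures intersect
up-regulated genes (log2FC > 0.25, p < 0.05) across a group's samples; an
optional `min_degs` cutoff excludes DEG-poor samples (no default claimed).
The CD8 exhaustion split re-clusters reactive CD8 cells and labels a
cluster Ex_high when its mean exhaustion score is above the cohort median
and TCF7 below — an explicit rule standing in for manual inspection.

Survival stratification splits at the median score (ties to the low arm),
fits Kaplan–Meier curves per arm (lifelines) and compares them with the
two-sample log-rank test (1 df chi-square).

The ligand–receptor test scores ordered type pairs as the average of the
ligand's sender mean and the receptor's receiver mean, requires each gene
expressed in ≥ 10% of its respective type and ≥ 3 cells per type, shuffles
labels n_perm times (one shuffle serves all pairs), and reports
p = (1 + #{null ≥ observed})/(1 + n_perm) — the floor keeps p valid, at the
cost of mild conservatism visible in null calibrations.

## Lesion phylogenies

Variants are keyed by (chromosome, position, ref, alt), nonsynonymous-only
by default (indels/synonymous selectable). Trees use binary
presence/absence characters rather than flanking-sequence alignments: for
point mutations these carry the same parsimony-relevant signal as the
20-bp-context sequences fed to alignment tools — an explicit
simplification. All rooted topologies (≤ 8 lesions; (2n−3)!! of them) are
scored by Fitch small parsimony vectorized over collapsed presence
patterns, with the germline as an all-reference root taxon (matched-blood
control). The first optimum in deterministic enumeration order is
returned; all co-optimal newicks are reported. Branch lengths come from a
Fitch traceback with the root forced to the germline state, so for two
lesions the stem carries exactly the shared mutations and each leaf its
private ones.

## The synthetic cohort

Defaults: 13 patients × 1 lesion × 500 cells, 1500 genes on six
chromosomes (named marker/signature genes on the last, fillers elsewhere),
gamma-Poisson (NB, dispersion 2) counts around cell-type mean profiles,
lognormal(σ=0.3) library factors, 5% extra dropout. Planted structure:
50% malignant cells per sample with three arm-scale CNV segments (+1,
−1, +0.58 log2 over 60% of chr1–3), a dominant paired-αβ clonotype
(dual-TRA in the first ~20% of samples, a plausible rate given that a
sizable minority of mature αβ T cells escape TRA allelic exclusion), a 15%
TCR-loss subcluster (10% residual pair rate, CD3E/TOX
down, private program), four shared 50-gene programs (≈4-fold in active
cells, round-robin assignment) plus one sample-private program drawn from
a dedicated disjoint pool, reactive Tconv/Treg/CD8 Ex-low/Ex-high
populations (40/20/25/15%) each with canonical markers (8-fold) and a
broad 40-gene type module (3-fold) — cell types differ across many genes,
not just markers, and clustering relies on that breadth — plus a
long-tailed reactive repertoire with 2–49-cell expansions covering 20% of
reactive cells. Variant tables have exact stem/private sizes
(30 per lesion, stem fraction 0.3). The survival generator draws
exponential times with hazard ∝ exp(effect·score), score ~ N(0,1),
independent uniform censoring on 12–72 months, n=49.

What it does **not** emulate: batch effects, ambient RNA, doublets,
non-T microenvironment populations (B/myeloid/stromal compartments appear
only through their marker genes), continuous differentiation gradients,
realistic gene–gene correlation beyond the planted modules, and genomic
waviness in expression. Passing recovery tests therefore demonstrates the
pipeline's correctness under its stated assumptions — clonal dominance,
arm-scale dosage effects, program-structured heterogeneity — not
robustness to every artifact of real droplet data.

Problem sizes in the tests (500-cell samples, 1500 genes, 10 cohort seeds
for meta-program recovery) were chosen as the smallest cohorts at which
the planted effects are comfortably detectable, keeping the whole suite
desk-scale.

## Known limitations

- Aneuploidy calling needs a clonality-clean reference; in samples where
  reactive cells are scarce the bootstrap falls back to all cells and
  burden contrast degrades.
- TCR-loss detection is bounded by residual-pair sampling: clusters with
  zero surviving pairs are unconfirmable by design.
- The exhaustive parsimony search is limited to 8 lesions; larger patients
  need a heuristic search that is out of scope.
- The permutation p floor makes the LR test slightly conservative at small
  n_perm.
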