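"""End-to-end orchestration: from counts + contigs to malignancy calls.

Chains the per-sample analysis the way the lesion workflow runs it:
QC -> log-normalization -> scaling -> PCA -> SNN clustering -> CNV
inference against reactive references -> clonotype assembly -> TCR-loss
detection -> the malignant decision rule -> double-negative exclusion.

The reactive reference for CNV inference is bootstrapped from clonality:
cells outside the sample's dominant clonotype (or all cells when no
dominant clone exists) seed the reference, mirroring the use of reactive
T cells and non-T cells as controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import malignant as mal_mod
from . import preprocess as pp
from . import tcr as tcr_mod
from .io import ContigRecord, ExpressionMatrix


@dataclass
class SampleResult:
    """Everything the per-sample chain produces."""

    sample: str
    norm: pp.NormalizedMatrix
    scaled: pp.NormalizedMatrix
    embedding: np.ndarray
    clusters: np.ndarray
    clonotypes: tcr_mod.ClonotypeTable
    dominant_key: str | None
    cnv: cnv_mod.CNVMatrix
    aneuploid_clusters: set
    tcr_loss_clusters: set
    calls: mal_mod.MalignancyCall


def analyze_sample(
    counts: ExpressionMatrix,
    contigs: list[ContigRecord],
    coords: pd.DataFrame,
    sample: str,
    resolution: float = 0.6,
    n_pcs: int = 30,
    k_neighbors: int = 20,
    seed: int = 0,
    qc: bool = True,
) -> SampleResult:
    """Run the full malignant-identification chain on one sample."""
    mask = counts.sample_of_cell == sample
    sub = counts.subset(cell_mask=mask)
    if qc:
        sub, _report = pp.qc_filter(sub)
    norm = pp.normalize_log(sub)
    scaled = pp.NormalizedMatrix(
        pp.z_scale(norm.values), norm.gene_ids, norm.barcodes,
        norm.sample_of_cell, scaled=True,
    )
    emb, _, _ = pp.run_pca(scaled, n_components=min(n_pcs, norm.n_cells - 1,
                                                    norm.n_genes - 1))
    clusters = pp.cluster_cells(
        emb, resolution=resolution,
        k_neighbors=min(k_neighbors, norm.n_cells - 1), seed=seed,
    )

    sample_contigs = [c for c in contigs if c.sample == sample]
    clonotypes = tcr_mod.build_clonotypes(sample_contigs)
    dominant = clonotypes.dominant_key(sample)

    cluster_series = pd.Series(clusters, index=pd.Index(
        [b.split(":", 1)[1] if ":" in b else b for b in norm.barcodes],
        name="barcode",
    ))
    tcr_loss = (
        tcr_mod.detect_tcr_loss_clusters(clonotypes, cluster_series, dominant)
        if dominant is not None else set()
    )

    # reference cells need positive reactive evidence: a productive paired
    # clonotype different from the dominant clone (cells with no pair could
    # be malignant TCR dropout), and not in a TCR-loss cluster
    keyed = clonotypes.cells.reset_index().set_index("barcode")["key"]
    bc_short = pd.Index([b.split(":", 1)[1] if ":" in b else b
                         for b in norm.barcodes])
    keys = keyed.reindex(bc_short)
    polyclonal = keys.notna() & (keys != dominant)
    in_loss_cluster = np.isin(clusters, sorted(tcr_loss))
    ref_mask = polyclonal.to_numpy() & ~in_loss_cluster
    if dominant is None or not ref_mask.any():
        ref_mask = np.ones(norm.n_cells, dtype=bool)
    refs = norm.barcodes[ref_mask]

    cnv = cnv_mod.infer_cnv(norm, coords, refs)
    aneuploid, _report = cnv_mod.call_aneuploid_clusters(cnv, clusters)

    annotation = pp.CellAnnotation(pd.DataFrame(
        {"cluster": clusters.astype(int), "cell_type": "T cells", "status": ""},
        index=pd.Index(bc_short, name="cell"),
    ))
    calls = mal_mod.call_malignant(
        annotation, aneuploid, clonotypes, tcr_loss,
        sample_of_cell=pd.Series(sample, index=annotation.cells),
    )
    if _has_genes(sub, ("CD4", "CD8B")):
        counts_short = ExpressionMatrix(
            sub.values, sub.gene_ids, bc_short.to_numpy(object),
            sub.sample_of_cell,
        )
        calls = mal_mod.exclude_dnt(calls, counts_short)
    return SampleResult(
        sample=sample, norm=norm, scaled=scaled, embedding=emb,
        clusters=clusters, clonotypes=clonotypes, dominant_key=dominant,
        cnv=cnv, aneuploid_clusters=aneuploid, tcr_loss_clusters=tcr_loss,
        calls=calls,
    )


def _has_genes(matrix: ExpressionMatrix, genes) -> bool:
    present = set(matrix.gene_ids)
    return all(g in present for g in genes)


def malignant_norm_by_sample(
    results: dict[str, SampleResult], min_malignant: int = 80
) -> dict[str, pp.NormalizedMatrix]:
    """Per-sample log-normalized matrices restricted to malignant cells,
    for samples retained by the >min_malignant rule (program extraction
    input)."""
    out: dict[str, pp.NormalizedMatrix] = {}
    for sample, res in results.items():
        cells = res.calls.cells
        mal = cells["status"].isin(mal_mod.MALIGNANT_STATUSES)
        if mal.sum() <= min_malignant:
            continue
        bc_short = pd.Index([b.split(":", 1)[1] if ":" in b else b
                             for b in res.norm.barcodes])
        mask = bc_short.isin(cells.index[mal])
        out[sample] = pp.NormalizedMatrix(
            res.norm.values[:, mask], res.norm.gene_ids,
            res.norm.barcodes[mask], res.norm.sample_of_cell[mask],
        )
    return out
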