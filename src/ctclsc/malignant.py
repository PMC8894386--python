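"""The central decision rule: malignant = clonal expansion + aneuploidy.

A T-cell cluster is called malignant when it is aneuploid (CNV evidence)
AND its cells' modal paired clonotype is the sample's dominant clonotype
(clonality evidence).  TCR-loss clusters — transcriptional loss of the TCR
chains with residual pairs matching the dominant clone — are called
malignant_tcr_loss when aneuploid.  Everything else stays reactive;
double-negative reactive cells (no CD4, no CD8B expression) are excluded
from downstream analysis, and samples need more than 80 malignant cells to
be retained for malignant-cell analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .preprocess import CellAnnotation
from .tcr import ClonotypeTable

logger = logging.getLogger(__name__)

MALIGNANT_STATUSES = {"malignant", "malignant_tcr_loss"}


@dataclass
class MalignancyCall:
    """Per-cell malignancy status with supporting evidence."""

    cells: pd.DataFrame     # index cell; columns: sample, cluster, status,
                            # aneuploid_cluster, in_dominant_clonotype,
                            # tcr_loss_cluster
    per_sample: pd.DataFrame  # index sample; columns: malignant_cells, retained

    def malignant_cells(self) -> pd.Index:
        return self.cells.index[self.cells["status"].isin(MALIGNANT_STATUSES)]


def call_malignant(
    annotation: CellAnnotation,
    aneuploid_clusters: set[int],
    clonotypes: ClonotypeTable,
    tcr_loss_clusters: set[int] | None = None,
    sample_of_cell: pd.Series | None = None,
    modal_fraction_min: float = 0.5,
) -> MalignancyCall:
    """Combine CNV and clonality evidence into per-cell malignancy calls.

    ``annotation`` provides cluster ids per cell; ``sample_of_cell`` maps
    cells to samples (required when cells span samples).  A cluster is
    malignant when aneuploid and at least ``modal_fraction_min`` of its
    paired TCR-covered cells carry the sample's dominant clonotype.
    """
    tcr_loss_clusters = tcr_loss_clusters or set()
    table = annotation.table
    cells = table.index
    if sample_of_cell is None:
        found = clonotypes.cells.index.get_level_values("sample").unique()
        if len(found) != 1:
            raise ValueError(
                "sample_of_cell is required when cells span multiple samples"
            )
        sample_of_cell = pd.Series(found[0], index=cells)
    samples = sample_of_cell.reindex(cells)
    if samples.isna().any():
        raise ValueError("sample_of_cell does not cover all annotated cells")

    # per-cell clonotype keys, indexed to the annotation cells by barcode
    keyed = clonotypes.cells.reset_index()
    key_of_cell = pd.Series(keyed["key"].values, index=keyed["barcode"]).reindex(cells)

    dominant = {s: clonotypes.dominant_key(s) for s in samples.unique()}

    status = pd.Series("reactive", index=cells, dtype=object)
    in_dom = key_of_cell.to_numpy(dtype=object) == np.array(
        [dominant[s] for s in samples], dtype=object
    )
    in_dom &= key_of_cell.notna().to_numpy()

    for sample in samples.unique():
        dom_key = dominant[sample]
        s_mask = (samples == sample).to_numpy()
        s_clusters = set(table.loc[s_mask, "cluster"])
        if dom_key is None and not (s_clusters & aneuploid_clusters):
            warnings.warn(
                f"sample {sample}: no dominant clonotype and no aneuploid "
                "cluster; all cells reactive"
            )
            continue
        for cl in sorted(s_clusters):
            cl_mask = s_mask & (table["cluster"] == cl).to_numpy()
            if cl not in aneuploid_clusters:
                continue
            if cl in tcr_loss_clusters:
                status[cl_mask] = "malignant_tcr_loss"
                continue
            if dom_key is None:
                continue
            paired = cl_mask & key_of_cell.notna().to_numpy()
            if not paired.any():
                continue
            modal_frac = in_dom[paired].mean()
            if modal_frac >= modal_fraction_min:
                status[cl_mask] = "malignant"
            else:
                logger.info(
                    "sample %s cluster %s: aneuploid but polyclonal "
                    "(dominant fraction %.2f); left reactive", sample, cl, modal_frac
                )

    out = pd.DataFrame(
        {
            "sample": samples.to_numpy(dtype=object),
            "cluster": table["cluster"].to_numpy(),
            "status": status.to_numpy(dtype=object),
            "aneuploid_cluster": table["cluster"].isin(aneuploid_clusters).to_numpy(),
            "in_dominant_clonotype": in_dom,
            "tcr_loss_cluster": table["cluster"].isin(tcr_loss_clusters).to_numpy(),
        },
        index=cells,
    )
    return MalignancyCall(cells=out, per_sample=_sample_summary(out))


def _sample_summary(cells: pd.DataFrame, min_malignant: int = 80) -> pd.DataFrame:
    mal = cells["status"].isin(MALIGNANT_STATUSES)
    counts = cells.loc[mal].groupby("sample").size()
    all_samples = pd.Index(sorted(cells["sample"].unique()), name="sample")
    counts = counts.reindex(all_samples, fill_value=0)
    return pd.DataFrame(
        {"malignant_cells": counts, "retained": counts > min_malignant}
    )


def exclude_dnt(
    calls: MalignancyCall,
    counts: ExpressionMatrix,
    cd4_gene: str = "CD4",
    cd8_gene: str = "CD8B",
) -> MalignancyCall:
    """Exclude double-negative reactive T cells (no CD4, no CD8B counts).

    Malignant cells are untouched; only reactive cells with zero raw counts
    for both genes become ``excluded_dnt``.
    """
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    missing = [g for g in (cd4_gene, cd8_gene) if g not in gene_pos]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    dense_cd4 = np.asarray(counts.values[gene_pos[cd4_gene], :].todense()).ravel()
    dense_cd8 = np.asarray(counts.values[gene_pos[cd8_gene], :].todense()).ravel()
    expr = pd.Series(
        (dense_cd4 > 0) | (dense_cd8 > 0), index=pd.Index(counts.barcodes)
    )
    cells = calls.cells.copy()
    expressed = expr.reindex(cells.index)
    if expressed.isna().any():
        raise ValueError("count matrix does not cover all called cells")
    dnt = (cells["status"] == "reactive") & ~expressed.astype(bool)
    cells.loc[dnt, "status"] = "excluded_dnt"
    return MalignancyCall(cells=cells, per_sample=_sample_summary(cells))


def filter_samples(calls: MalignancyCall, min_malignant: int = 80) -> list[str]:
    """Samples retained for malignant-cell analyses (count > min_malignant)."""
    summary = _sample_summary(calls.cells, min_malignant=min_malignant)
    return list(summary.index[summary["retained"]])
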