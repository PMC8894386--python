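"""Expression-inferred copy-number profiles against reactive references.

Large-scale CNVs are estimated from log-normalized expression: each gene is
centered on its mean over reference (reactive / non-tumor) cells, centered
values are clipped, a moving average along genomic gene order smooths
within each chromosome, each cell is recentered by its median smoothed
value, and finally positions are re-centered on the reference cells so the
reference mean profile is exactly zero.  A per-cell CNV burden (mean
squared deviation from zero) summarizes aneuploidy; clusters whose median
burden exceeds a fold of the reference median are called aneuploid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass
class CNVMatrix:
    """Cells x genomically ordered positions of smoothed relative expression."""

    values: np.ndarray           # cells x positions
    cells: np.ndarray
    gene_order: list[str]        # genes in (chromosome, start) order
    chromosomes: np.ndarray      # chromosome per position
    burden: np.ndarray           # per-cell mean squared deviation
    reference_cells: np.ndarray

    def burden_series(self) -> pd.Series:
        return pd.Series(self.burden, index=pd.Index(self.cells, name="cell"))


def _moving_average_rows(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean along axis 1 with edge windows truncated."""
    n = x.shape[1]
    w = min(window, n)
    half = w // 2
    cs = np.cumsum(np.pad(x, ((0, 0), (1, 0))), axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def infer_cnv(
    norm: NormalizedMatrix,
    coords: pd.DataFrame,
    reference_cell_ids,
    window: int = 101,
    clip: float = 3.0,
    exclude_sex_chromosomes: bool = True,
) -> CNVMatrix:
    """Infer smoothed relative copy-number profiles for every cell.

    ``coords`` maps gene ids to (chrom, start, end, strand); genes missing
    coordinates are dropped (count logged).  ``reference_cell_ids`` are the
    barcodes of reactive/control cells; they are also scored.
    """
    ref_ids = set(reference_cell_ids)
    if not ref_ids:
        raise ValueError("reference set is empty")
    ref_mask = np.array([b in ref_ids for b in norm.barcodes])
    if not ref_mask.any():
        raise ValueError("no reference cell found in the matrix")

    have = [g for g in norm.gene_ids if g in coords.index]
    dropped = norm.n_genes - len(have)
    if dropped:
        logger.info("dropped %d genes without coordinates", dropped)
    sub = coords.loc[have]
    if exclude_sex_chromosomes:
        sub = sub[~sub["chrom"].isin(SEX_CHROMS)]
    sub = sub.sort_values(["chrom", "start"], kind="stable")
    gene_order = list(sub.index)
    if not gene_order:
        raise ValueError("no genes left after coordinate filtering")

    pos = {g: i for i, g in enumerate(norm.gene_ids)}
    expr = norm.values[[pos[g] for g in gene_order], :]  # genes x cells

    centered = expr - expr[:, ref_mask].mean(axis=1, keepdims=True)
    centered = np.clip(centered, -clip, clip)

    chrom_arr = sub["chrom"].to_numpy()
    smooth = np.empty_like(centered.T)  # cells x positions
    ct = centered.T
    for chrom in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == chrom)
        if len(cols) < window:
            warnings.warn(
                f"{chrom}: only {len(cols)} genes, shrinking window from {window}"
            )
        smooth[:, cols] = _moving_average_rows(ct[:, cols], window)

    smooth = smooth - np.median(smooth, axis=1, keepdims=True)
    # final reference re-centering so the reference mean profile is exactly 0
    smooth = smooth - smooth[ref_mask, :].mean(axis=0, keepdims=True)

    burden = (smooth**2).mean(axis=1)
    return CNVMatrix(
        values=smooth,
        cells=np.asarray(norm.barcodes),
        gene_order=gene_order,
        chromosomes=chrom_arr,
        burden=burden,
        reference_cells=np.asarray(sorted(ref_ids), dtype=object),
    )


def call_aneuploid_clusters(
    cnv: CNVMatrix,
    cluster_labels: np.ndarray,
    burden_quantile: float = 0.9,
    fold: float = 2.0,
) -> tuple[set[int], pd.DataFrame]:
    """Flag clusters with elevated CNV burden.

    A cluster is aneuploid when its median burden reaches ``fold`` times the
    ``burden_quantile``-th quantile of the reference cells' burdens (the
    upper-quantile reference keeps small noisy clusters from tripping the
    call).  Returns the flagged cluster ids and a per-cluster report.
    """
    labels = np.asarray(cluster_labels)
    if labels.shape[0] != cnv.values.shape[0]:
        raise ValueError("cluster labels do not cover all scored cells")
    ref_ids = set(cnv.reference_cells)
    ref_mask = np.array([c in ref_ids for c in cnv.cells])
    if not ref_mask.any():
        raise ValueError("no reference cells present")
    ref_level = float(np.quantile(cnv.burden[ref_mask], burden_quantile))

    rows = []
    flagged: set[int] = set()
    for cl in np.unique(labels):
        med = float(np.median(cnv.burden[labels == cl]))
        aneuploid = bool(med >= fold * ref_level)
        if aneuploid:
            flagged.add(int(cl))
        rows.append({"cluster": int(cl), "median_burden": med,
                     "reference_level": ref_level, "aneuploid": aneuploid})
    return flagged, pd.DataFrame(rows).set_index("cluster")
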