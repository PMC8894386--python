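"""QC, normalization, covariate regression, HVG/PCA and graph clustering.

The pipeline mirrors standard droplet scRNA-seq practice: genes detected in
too few cells are dropped first, then cells outside the 500-5000 detected
gene band or above 10% mitochondrial content; library-size normalization to
10,000 counts with log transform; per-gene OLS residuals against nuisance
covariates followed by z-scaling clipped at +-10; dispersion-ranked highly
variable genes; PCA with a fixed sign convention; and shared-nearest-
neighbor graph clustering by seeded modularity optimization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources as _ilres

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """All cells (or genes) were removed by a filter."""


@dataclass
class NormalizedMatrix:
    """Real-valued genes x cells matrix with provenance flags."""

    values: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    sample_of_cell: np.ndarray
    normalized: bool = True
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite normalized values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_row(self, gene: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_ids == gene)
        if len(idx) == 0:
            raise KeyError(gene)
        return self.values[idx[0]]


@dataclass
class CellAnnotation:
    """Per-cell cluster / type / malignancy status container."""

    table: pd.DataFrame  # columns: cluster, cell_type, status

    def __post_init__(self) -> None:
        required = {"cluster", "cell_type", "status"}
        if not required <= set(self.table.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")

    @property
    def cells(self) -> pd.Index:
        return self.table.index


def default_marker_sets() -> dict[str, list[str]]:
    with _ilres.files("ctclsc.resources").joinpath("markers.json").open() as fh:
        return json.load(fh)


def qc_filter(
    counts: ExpressionMatrix,
    min_cells_per_gene: int = 10,
    min_genes: int = 500,
    max_genes: int = 5000,
    max_mito: float = 0.10,
    mito_prefix: str = "MT-",
):
    """Apply gene then cell quality filters.

    Cells with fewer than ``min_genes`` or more than ``max_genes`` detected
    genes are removed (both boundaries retained), as are cells whose
    mitochondrial fraction strictly exceeds ``max_mito``.  Returns the
    filtered matrix and a report dict of removal counts.
    """
    v = counts.values.tocsc()
    detected_cells_per_gene = np.asarray((v > 0).sum(axis=1)).ravel()
    gene_mask = detected_cells_per_gene >= min_cells_per_gene
    v = v[gene_mask, :]
    gene_ids = counts.gene_ids[gene_mask]

    detected = np.asarray((v > 0).sum(axis=0)).ravel()
    totals = np.asarray(v.sum(axis=0)).ravel()
    mito_rows = np.array([g.startswith(mito_prefix) for g in gene_ids])
    mito_counts = (
        np.asarray(v[mito_rows, :].sum(axis=0)).ravel() if mito_rows.any()
        else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)

    cell_mask = (detected >= min_genes) & (detected <= max_genes) & (mito_frac <= max_mito)
    report = {
        "genes_removed": int((~gene_mask).sum()),
        "cells_removed_gene_band": int(((detected < min_genes) | (detected > max_genes)).sum()),
        "cells_removed_mito": int((mito_frac > max_mito).sum()),
        "cells_retained": int(cell_mask.sum()),
    }
    if report["cells_retained"] == 0:
        raise EmptyResultError("QC removed every cell")
    out = ExpressionMatrix(
        sp.csr_matrix(v[:, cell_mask]),
        gene_ids,
        counts.barcodes[cell_mask],
        counts.sample_of_cell[cell_mask],
    )
    logger.info("QC: %s", report)
    return out, report


def normalize_log(counts: ExpressionMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Library-size normalize to ``scale_factor`` counts and log-transform.

    value = ln(1 + count * scale_factor / cell_total).
    """
    v = counts.values.tocsc().astype(float)
    totals = np.asarray(v.sum(axis=0)).ravel()
    if (totals <= 0).any():
        raise EmptyResultError("cell with zero total counts; run QC first")
    dense = v.toarray()
    dense = np.log1p(dense * (scale_factor / totals)[None, :])
    return NormalizedMatrix(dense, counts.gene_ids, counts.barcodes,
                            counts.sample_of_cell, normalized=True)


def z_scale(values: np.ndarray, clip: float = 10.0, sd_floor: float = 1e-10) -> np.ndarray:
    """Per-gene z-scaling with clipping; (numerically) constant genes map
    to 0 rather than amplifying float noise."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    ok = sd > sd_floor
    out = np.where(ok, (values - mu) / np.where(ok, sd, 1.0), 0.0)
    return np.clip(out, -clip, clip)


def regress_covariates(
    norm: NormalizedMatrix, covariates: pd.DataFrame, clip: float = 10.0
) -> NormalizedMatrix:
    """Per-gene OLS residuals against nuisance covariates, then z-scale.

    Covariates are aligned to cells by position (or by barcode if the frame
    index matches).  Constant or collinear covariates are dropped with a
    warning; the intercept is always included.
    """
    cov = covariates
    if not cov.index.equals(pd.RangeIndex(len(cov))):
        cov = cov.reindex(pd.Index(norm.barcodes))
        if cov.isna().any().any():
            raise ValueError("covariate table does not cover all cells")
    X = cov.to_numpy(dtype=float)
    if X.shape[0] != norm.n_cells:
        raise ValueError("covariate rows do not match cells")

    design = [np.ones(norm.n_cells)]
    kept = []
    for j, name in enumerate(cov.columns):
        candidate = np.column_stack(design + [X[:, j]])
        if np.linalg.matrix_rank(candidate) > len(design):
            design.append(X[:, j])
            kept.append(name)
        else:
            warnings.warn(f"dropping collinear/constant covariate {name!r}")
    D = np.column_stack(design)
    # residual = Y - D (D^+ Y), computed once for all genes
    coef, *_ = np.linalg.lstsq(D, norm.values.T, rcond=None)
    resid = norm.values.T - D @ coef
    out = z_scale(resid.T, clip=clip)
    return NormalizedMatrix(out, norm.gene_ids, norm.barcodes,
                            norm.sample_of_cell, normalized=True, scaled=True)


def select_hvg(norm: NormalizedMatrix, n: int = 3000, window: int = 31) -> list[str]:
    """Rank genes by dispersion: variance over a local mean-variance trend.

    The trend is a running mean of gene variances in order of gene mean
    expression (a loess-like local regression); the ratio variance/trend is
    the ranking statistic.
    """
    if n > norm.n_genes:
        raise ValueError(f"requested {n} HVGs from {norm.n_genes} genes")
    mu = norm.values.mean(axis=1)
    var = norm.values.var(axis=1)
    order = np.argsort(mu, kind="stable")
    w = min(window, len(mu))
    kernel = np.ones(w)
    sums = np.convolve(var[order], kernel, mode="same")
    counts = np.convolve(np.ones_like(var), kernel, mode="same")
    trend_sorted = sums / counts
    trend = np.empty_like(trend_sorted)
    trend[order] = trend_sorted
    disp = np.where(trend > 1e-12, var / np.maximum(trend, 1e-12), 0.0)
    disp = np.where(var > 0, disp, -np.inf)
    ranked = np.argsort(-disp, kind="stable")
    return [norm.gene_ids[i] for i in ranked[:n]]


def run_pca(scaled: NormalizedMatrix, n_components: int = 30):
    """PCA of cells over genes with a deterministic sign convention.

    Each component is flipped so its largest-magnitude loading is positive.
    Returns (embedding cells x k, loadings genes x k, explained variance).
    """
    k = min(n_components, scaled.n_genes, scaled.n_cells)
    if n_components > min(scaled.n_genes, scaled.n_cells):
        raise ValueError("n_components exceeds matrix dimensions")
    pca = PCA(n_components=k, svd_solver="full")
    emb = pca.fit_transform(scaled.values.T)
    load = pca.components_.T  # genes x k
    for j in range(k):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1.0
            emb[:, j] *= -1.0
    return emb, load, pca.explained_variance_ratio_


def snn_graph(embedding: np.ndarray, k_neighbors: int = 20, prune: float = 1 / 15):
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = embedding.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(f"{n} cells < k_neighbors+1 ({k_neighbors + 1})")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neighbor_sets = [set(row) for row in idx]
    seen: set[tuple[int, int]] = set()
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j == i:
                continue
            pair = (i, j) if i < j else (j, i)
            if pair in seen:
                continue
            seen.add(pair)
            shared = len(neighbor_sets[pair[0]] & neighbor_sets[pair[1]])
            jac = shared / (2 * k_neighbors - shared)
            if jac >= prune:
                edges.append(pair)
                weights.append(jac)
    return n, edges, weights


def cluster_cells(
    embedding: np.ndarray,
    resolution: float = 0.2,
    k_neighbors: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """SNN-graph modularity clustering (Leiden refinement of Louvain).

    Deterministic given ``seed``; labels are renumbered in order of first
    appearance along the cell index.
    """
    import igraph
    import leidenalg

    n, edges, weights = snn_graph(embedding, k_neighbors=k_neighbors)
    graph = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=4,
    )
    raw = np.array(part.membership)
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return labels


def annotate_clusters(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    marker_sets: dict[str, list[str]] | None = None,
) -> CellAnnotation:
    """Assign each cluster the cell type with highest mean marker z-score.

    Ties go to the first-listed type (with a warning); types with no marker
    present in the matrix are unassignable and warned about.
    """
    if marker_sets is None:
        marker_sets = default_marker_sets()
    z = norm.values if norm.scaled else z_scale(norm.values)
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    usable: dict[str, list[int]] = {}
    for ctype, genes in marker_sets.items():
        rows = [gene_pos[g] for g in genes if g in gene_pos]
        if not rows:
            warnings.warn(f"no marker genes present for type {ctype!r}; unassignable")
            continue
        usable[ctype] = rows
    if not usable:
        raise ValueError("no marker set has any gene in the matrix")

    types = list(usable)
    cell_type = np.empty(len(labels), dtype=object)
    for cl in np.unique(labels):
        mask = labels == cl
        scores = np.array([z[usable[t], :][:, mask].mean() for t in types])
        best = np.flatnonzero(scores == scores.max())
        if len(best) > 1:
            warnings.warn(f"cluster {cl}: marker-score tie, taking first-listed type")
        cell_type[mask] = types[best[0]]
    table = pd.DataFrame(
        {"cluster": labels.astype(int), "cell_type": cell_type, "status": ""},
        index=pd.Index(norm.barcodes, name="cell"),
    )
    return CellAnnotation(table)
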