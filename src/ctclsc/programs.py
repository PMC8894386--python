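"""Intratumor expression programs by per-sample NMF and meta-programs.

Within each sample, malignant-cell expression is filtered to genes with
standard deviation >= 0.5, centered per gene (relative expression), negative
values are clamped to zero, and rank-k NMF (multiplicative updates, NNDSVD
initialization) yields k programs per sample; each program is summarized by
its 50 top-scoring genes.  Programs are clustered across samples into
meta-programs by top-gene overlap: any two programs sharing at least 10 of
their top 50 genes are connected, connected components with two or more
members form meta-programs, and the union of member top-gene lists is the
meta-signature.

Signature scoring (used for meta-program, cytotoxicity, exhaustion and
cell-cycle scores) is the expression-bin-matched control scheme: the mean
expression of the signature genes minus the mean of control genes sampled
from the same average-expression bins.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources as _ilres
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import average
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


def default_gene_sets() -> dict[str, list[str]]:
    with _ilres.files("ctclsc.resources").joinpath("signatures.json").open() as fh:
        return json.load(fh)


def default_cell_cycle_genes() -> tuple[list[str], list[str]]:
    """The shipped core cell-cycle lists: 43 G1/S and 54 G2/M genes."""
    with _ilres.files("ctclsc.resources").joinpath("cell_cycle.json").open() as fh:
        d = json.load(fh)
    return d["g1s"], d["g2m"]


# ---------------------------------------------------------------------------
# NMF


def _nndsvd(V: np.ndarray, k: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD initialization (deterministic, zeros filled
    with the matrix mean to avoid stuck zero entries)."""
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    W = np.zeros((V.shape[0], k))
    H = np.zeros((k, V.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        norm_p, norm_n = np.linalg.norm(up) * np.linalg.norm(vp), np.linalg.norm(un) * np.linalg.norm(vn)
        if norm_p >= norm_n:
            w, h, sigma = up / max(np.linalg.norm(up), 1e-12), vp / max(np.linalg.norm(vp), 1e-12), norm_p
        else:
            w, h, sigma = un / max(np.linalg.norm(un), 1e-12), vn / max(np.linalg.norm(vn), 1e-12), norm_n
        W[:, j] = np.sqrt(S[j] * sigma) * w
        H[j, :] = np.sqrt(S[j] * sigma) * h
    mean = V.mean()
    W[W <= 0] = mean * 1e-2 * (1 + rng.random(np.count_nonzero(W <= 0)))
    H[H <= 0] = mean * 1e-2 * (1 + rng.random(np.count_nonzero(H <= 0)))
    return W, H


def nmf_factorize(
    matrix: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    init: str = "nndsvd",
    return_objective: bool = False,
):
    """Rank-k NMF by Frobenius multiplicative updates.

    The objective ||V - WH||_F^2 is non-increasing at every iteration;
    iteration stops when the relative objective change drops below ``tol``.
    ``init`` is "nndsvd" (deterministic) or "random" (seeded).
    """
    V = np.asarray(matrix, dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative")
    if k > min(V.shape):
        raise ValueError(f"rank {k} exceeds matrix dimensions {V.shape}")
    rng = np.random.default_rng(seed)
    if init == "nndsvd":
        W, H = _nndsvd(V, k, rng)
    elif init == "random":
        scale = np.sqrt(V.mean() / k)
        W = scale * (0.5 + rng.random((V.shape[0], k)))
        H = scale * (0.5 + rng.random((k, V.shape[1])))
    else:
        raise ValueError(f"unknown init {init!r}")

    eps = 1e-12
    objective = [float(((V - W @ H) ** 2).sum())]
    for _ in range(max_iter):
        H *= (W.T @ V) / np.maximum(W.T @ W @ H, eps)
        W *= (V @ H.T) / np.maximum(W @ (H @ H.T), eps)
        obj = float(((V - W @ H) ** 2).sum())
        objective.append(obj)
        prev = objective[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            break
    if return_objective:
        return W, H, np.array(objective)
    return W, H


# ---------------------------------------------------------------------------
# Programs and meta-programs


@dataclass
class Program:
    """One NMF factor of one sample, summarized by its top-scoring genes."""

    sample: str
    factor: int
    gene_scores: pd.Series
    top_genes: list[str]

    @property
    def name(self) -> str:
        return f"{self.sample}:{self.factor}"


@dataclass
class MetaProgram:
    """A cluster of overlapping programs across samples."""

    members: list[Program]
    signature: list[str]
    label: str = ""

    @property
    def member_names(self) -> list[str]:
        return [p.name for p in self.members]


def extract_programs(
    norm_by_sample: dict[str, NormalizedMatrix],
    sd_min: float = 0.5,
    k: int = 5,
    top_n: int = 50,
    seed: int = 0,
    max_iter: int = 500,
) -> list[Program]:
    """Per-sample NMF expression programs from malignant-cell matrices.

    For each sample: drop genes with expression SD < ``sd_min``, center per
    gene, clamp negatives to zero, factorize at rank ``k`` and emit one
    program per factor with its ``top_n`` top-scoring genes.  Samples with
    too few eligible genes or cells are skipped with a warning.
    """
    programs: list[Program] = []
    for sample in sorted(norm_by_sample):
        norm = norm_by_sample[sample]
        sd = norm.values.std(axis=1)
        keep = sd >= sd_min
        if keep.sum() < top_n or norm.n_cells < k:
            warnings.warn(
                f"sample {sample}: {int(keep.sum())} eligible genes / "
                f"{norm.n_cells} cells; skipped"
            )
            continue
        X = norm.values[keep]
        genes = norm.gene_ids[keep]
        rel = X - X.mean(axis=1, keepdims=True)
        rel[rel < 0] = 0.0
        W, _H = nmf_factorize(rel, k=k, seed=seed, max_iter=max_iter)
        for j in range(k):
            scores = pd.Series(W[:, j], index=genes)
            top = list(scores.sort_values(ascending=False, kind="stable").index[:top_n])
            programs.append(Program(sample=sample, factor=j + 1,
                                    gene_scores=scores, top_genes=top))
    return programs


def overlap(p1: Program, p2: Program) -> int:
    """Number of shared top genes between two programs."""
    return len(set(p1.top_genes) & set(p2.top_genes))


def overlap_matrix(programs: Sequence[Program]) -> pd.DataFrame:
    names = [p.name for p in programs]
    n = len(programs)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            mat[i, j] = mat[j, i] = overlap(programs[i], programs[j])
    return pd.DataFrame(mat, index=names, columns=names)


def cluster_meta(
    programs: Sequence[Program],
    min_shared: int = 10,
    top_n: int = 50,
) -> list[MetaProgram]:
    """Cluster programs into meta-programs by top-gene overlap.

    Hierarchical average-linkage clustering on distance 1 - overlap/top_n
    orders the programs; the actual cut keeps groups connected through
    pairwise overlaps >= ``min_shared`` (single-link connectivity), and
    programs connected to nothing are dropped as singletons.  The
    meta-signature is the union of member top-gene lists.  Output is
    invariant to program input order.
    """
    if len(programs) < 2:
        warnings.warn("fewer than 2 programs; no meta-programs")
        return []
    progs = sorted(programs, key=lambda p: p.name)
    ov = overlap_matrix(progs).to_numpy()
    n = len(progs)
    # average-linkage tree for display ordering (overlap heatmaps); the
    # meta-program cut itself is the min_shared connectivity below
    dist = 1.0 - ov / float(top_n)
    np.fill_diagonal(dist, 0.0)
    _tree = average(squareform(dist, checks=False))

    adj = sp.csr_matrix((ov >= min_shared) & ~np.eye(n, dtype=bool))
    n_comp, comp = connected_components(adj, directed=False)
    metas: list[MetaProgram] = []
    for c in range(n_comp):
        members = [progs[i] for i in np.flatnonzero(comp == c)]
        if len(members) < 2:
            continue
        signature = sorted(set().union(*(set(p.top_genes) for p in members)))
        metas.append(MetaProgram(members=members, signature=signature))
    metas.sort(key=lambda m: (-len(m.members), m.member_names[0]))
    for i, m in enumerate(metas):
        m.label = m.label or f"meta-program {i + 1}"
    return metas


# ---------------------------------------------------------------------------
# Signature scoring


def score_signature(
    norm: NormalizedMatrix,
    gene_set: Sequence[str],
    n_control: int = 100,
    n_bins: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Bin-matched control signature score per cell.

    Genes are binned by average expression into ``n_bins`` bins; for each
    signature gene, ``n_control`` control genes are drawn from its bin.
    Score = mean expression of signature genes - mean of controls.
    """
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    sig_idx = [gene_pos[g] for g in gene_set if g in gene_pos]
    if not sig_idx:
        raise ValueError("no signature gene present in the matrix")
    rng = np.random.default_rng(seed)
    avg = norm.values.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    ranks = np.empty(len(avg), dtype=int)
    ranks[order] = np.arange(len(avg))
    bins = np.minimum((ranks * n_bins) // len(avg), n_bins - 1)

    sig_set = set(sig_idx)
    control_idx: list[int] = []
    for gi in sig_idx:
        pool = np.array([j for j in np.flatnonzero(bins == bins[gi])
                         if j not in sig_set])
        width = 1
        while len(pool) == 0 and width < n_bins:  # widen to neighboring bins
            pool = np.array([
                j for j in np.flatnonzero(np.abs(bins - bins[gi]) <= width)
                if j not in sig_set
            ])
            width += 1
        if len(pool) == 0:
            raise ValueError("no control genes available outside the signature")
        take = min(n_control, len(pool))
        control_idx.extend(rng.choice(pool, size=take, replace=False))
    sig_mean = norm.values[sig_idx].mean(axis=0)
    ctrl_mean = norm.values[sorted(set(control_idx))].mean(axis=0)
    return sig_mean - ctrl_mean


def score_cell_cycle(
    norm: NormalizedMatrix,
    g1s_genes: Optional[Sequence[str]] = None,
    g2m_genes: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell S and G2M scores plus a discrete phase call.

    Phase is the argmax of (S, G2M) when that score is positive, else G1.
    """
    if g1s_genes is None or g2m_genes is None:
        d_g1s, d_g2m = default_cell_cycle_genes()
        g1s_genes = g1s_genes or d_g1s
        g2m_genes = g2m_genes or d_g2m
    s = score_signature(norm, g1s_genes, seed=seed)
    g2m = score_signature(norm, g2m_genes, seed=seed + 1)
    phase = np.where(
        (s <= 0) & (g2m <= 0), "G1", np.where(s >= g2m, "S", "G2M")
    )
    return pd.DataFrame(
        {"S": s, "G2M": g2m, "phase": phase},
        index=pd.Index(norm.barcodes, name="cell"),
    )
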