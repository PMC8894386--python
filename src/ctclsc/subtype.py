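"""Molecular subtyping of malignant cells and survival stratification.

Per-sample DEGs (malignant vs lineage-matched reactive T cells, two-sided
rank-sum test on log-normalized values) feed three analyses: hierarchical
clustering of samples into the cytotoxic effector-memory-like (T_CyEM) and
central-memory-like (T_CM) groups; intersection-based group signatures
(genes up-regulated in every contributing sample of a group); and a split
of reactive CD8 cells into exhaustion-low/high states.  Survival cohorts
are stratified at the median signature score and compared by the log-rank
test (Kaplan-Meier estimates via lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix, run_pca, cluster_cells
from .programs import default_gene_sets, score_signature


def differential_expression(
    malignant: NormalizedMatrix, reactive: NormalizedMatrix
) -> pd.DataFrame:
    """Per-gene rank-sum test and fold change, malignant vs matched reactive.

    log2FC uses de-logged means with a pseudocount of 1; p-values are
    two-sided Mann-Whitney (exact on small untied samples), with
    Benjamini-Hochberg adjusted values reported alongside.  Thresholds are
    applied downstream, not here.
    """
    if malignant.n_cells < 1 or reactive.n_cells < 1:
        raise ValueError("empty group")
    if not np.array_equal(malignant.gene_ids, reactive.gene_ids):
        raise ValueError("gene indices differ between groups")
    a, b = malignant.values, reactive.values
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    pvals = np.ones(malignant.n_genes)
    for i in range(malignant.n_genes):
        if np.ptp(np.concatenate([a[i], b[i]])) == 0:
            continue
        pvals[i] = mannwhitneyu(a[i], b[i], alternative="two-sided",
                                method="auto").pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "adj_pvalue": adj,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "flat")),
        },
        index=pd.Index(malignant.gene_ids, name="gene"),
    )


def subtype_samples(
    avg_expression: pd.DataFrame,
    cytotox_genes: list[str] | None = None,
) -> pd.Series:
    """Split samples into T_CyEM / T_CM by hierarchical clustering.

    ``avg_expression`` is samples x genes (average expression of the DEG
    union per sample).  Correlation-distance average-linkage clustering is
    cut at two groups; the group with the higher mean cytotoxic-gene
    expression is labeled T_CyEM.  Invariant to sample order.
    """
    if len(avg_expression) < 2:
        raise ValueError("need at least 2 samples")
    if cytotox_genes is None:
        cytotox_genes = default_gene_sets()["cytotoxicity"]
    df = avg_expression.sort_index()
    dist = pdist(df.to_numpy(), metric="correlation")
    groups = fcluster(average(dist), t=2, criterion="maxclust")
    labels = pd.Series(groups, index=df.index)

    present = [g for g in cytotox_genes if g in df.columns]
    if not present:
        warnings.warn("no cytotoxic gene in matrix; group labels arbitrary")
        scores = pd.Series(0.0, index=df.index)
    else:
        scores = df[present].mean(axis=1)
    mean_by_group = scores.groupby(labels).mean()
    cyem_group = mean_by_group.idxmax()
    return labels.map(lambda g: "T_CyEM" if g == cyem_group else "T_CM")


def derive_group_signature(
    deg_tables: dict[str, pd.DataFrame],
    fc_min: float = 0.25,
    p_max: float = 0.05,
    min_degs: int | None = None,
) -> list[str]:
    """Intersection of up-regulated DEGs across a group's samples.

    A gene enters the signature only if it passes log2FC > ``fc_min`` and
    p < ``p_max`` in every contributing sample.  Samples with fewer than
    ``min_degs`` passing genes are excluded (logged via warning).
    """
    if len(deg_tables) < 2:
        raise ValueError("need at least 2 samples in the group")
    per_sample: dict[str, set[str]] = {}
    for sample, table in deg_tables.items():
        up = set(table.index[(table["log2fc"] > fc_min) & (table["pvalue"] < p_max)])
        if min_degs is not None and len(up) < min_degs:
            warnings.warn(f"sample {sample}: only {len(up)} DEGs; excluded")
            continue
        per_sample[sample] = up
    if len(per_sample) < 2:
        warnings.warn("fewer than 2 samples contribute; empty signature")
        return []
    signature = set.intersection(*per_sample.values())
    if not signature:
        warnings.warn("empty group signature")
    return sorted(signature)


def split_exhaustion(
    cd8_norm: NormalizedMatrix,
    exhaustion_genes: list[str] | None = None,
    tcf7_gene: str = "TCF7",
    resolution: float = 0.4,
    k_neighbors: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Label reactive CD8 cells Ex_low / Ex_high by re-clustering.

    CD8 cells are re-clustered (PCA + SNN modularity); a cluster is Ex_high
    when its mean exhaustion score is above the cohort median AND its mean
    TCF7 expression is below the cohort median.
    """
    if exhaustion_genes is None:
        exhaustion_genes = default_gene_sets()["exhaustion"]
    exh = score_signature(cd8_norm, exhaustion_genes, seed=seed)
    try:
        tcf7 = cd8_norm.gene_row(tcf7_gene)
    except KeyError:
        warnings.warn(f"{tcf7_gene} absent; using exhaustion score only")
        tcf7 = -exh
    n_pcs = min(20, cd8_norm.n_genes - 1, cd8_norm.n_cells - 1)
    from .preprocess import z_scale

    scaled = NormalizedMatrix(
        z_scale(cd8_norm.values), cd8_norm.gene_ids, cd8_norm.barcodes,
        cd8_norm.sample_of_cell, scaled=True,
    )
    emb, _, _ = run_pca(scaled, n_components=n_pcs)
    labels = cluster_cells(emb, resolution=resolution,
                           k_neighbors=min(k_neighbors, cd8_norm.n_cells - 1),
                           seed=seed)
    if len(np.unique(labels)) < 2:
        warnings.warn("CD8 cells form a single cluster; single-label output")
        return pd.Series("Ex_low", index=pd.Index(cd8_norm.barcodes, name="cell"))
    exh_med, tcf7_med = np.median(exh), np.median(tcf7)
    out = np.empty(len(labels), dtype=object)
    for cl in np.unique(labels):
        mask = labels == cl
        high = exh[mask].mean() > exh_med and tcf7[mask].mean() < tcf7_med
        out[mask] = "Ex_high" if high else "Ex_low"
    return pd.Series(out, index=pd.Index(cd8_norm.barcodes, name="cell"))


def exhaustion_composition_test(labels: pd.Series, groups: pd.Series):
    """Chi-square test of Ex_low/Ex_high composition between subtype groups.

    Pearson chi-square without continuity correction (textbook form).
    Returns (contingency table, chi2, p).
    """
    table = pd.crosstab(labels, groups.reindex(labels.index))
    chi2, p, _dof, _exp = chi2_contingency(table.to_numpy(), correction=False)
    return table, float(chi2), float(p)


@dataclass
class SurvivalResult:
    groups: pd.Series          # per patient: "low" | "high"
    logrank_p: float
    statistic: float
    curves: dict               # group -> KM survival function DataFrame
    median_times: dict


def km_logrank(survival: pd.DataFrame, scores: pd.Series | None = None) -> SurvivalResult:
    """Median-split survival stratification with a log-rank test.

    ``survival`` has columns patient/time/event(/score); ``scores``
    overrides the score column.  Ties at the median go to the low arm.
    """
    df = survival.copy()
    if scores is not None:
        df["score"] = scores.reindex(df["patient"]).to_numpy()
    med = df["score"].median()
    group = np.where(df["score"] > med, "high", "low")
    df["group"] = group
    n_low, n_high = (group == "low").sum(), (group == "high").sum()
    if n_low < 2 or n_high < 2:
        raise ValueError("degenerate arm after median split")

    low = df[df["group"] == "low"]
    high = df[df["group"] == "high"]
    res = logrank_test(low["time"], high["time"],
                       event_observed_A=low["event"], event_observed_B=high["event"])
    curves, medians = {}, {}
    for name, arm in [("low", low), ("high", high)]:
        km = KaplanMeierFitter()
        km.fit(arm["time"], event_observed=arm["event"], label=name)
        curves[name] = km.survival_function_
        medians[name] = float(km.median_survival_time_)
    return SurvivalResult(
        groups=pd.Series(group, index=df["patient"]),
        logrank_p=float(res.p_value),
        statistic=float(res.test_statistic),
        curves=curves,
        median_times=medians,
    )
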