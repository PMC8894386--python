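"""Paired alpha/beta clonotype assembly and clonal expansion classes.

A clonotype is identified by CDR3 nucleotide sequence: the sorted list of
productive TRA CDR3s joined with the productive TRB CDR3 (dual-TRA cells
therefore carry both alpha chains in their key).  Frequency classes follow
the lesion-repertoire conventions: >50 cells = dominant clonotype, >=3 =
clonally expanded, 2-49 = low-level expansion band, 1 = singleton.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .io import ContigRecord

logger = logging.getLogger(__name__)

CLASS_ORDER = ["singleton", "low_expanded", "expanded", "dominant"]


@dataclass
class ClonotypeTable:
    """Per-cell clonotype keys plus per-(sample, clonotype) frequencies."""

    cells: pd.DataFrame        # index (sample, barcode); columns: key,
                               # has_any_productive, productive_pair, ambiguous
    frequencies: pd.DataFrame  # index (sample, key); columns: frequency, cls,
                               # low_expanded_band

    def dominant_key(self, sample: str) -> Optional[str]:
        """The sample's dominant clonotype key (frequency > 50), or None."""
        freqs = self.frequencies.loc[
            self.frequencies.index.get_level_values("sample") == sample
        ]
        if freqs.empty:
            return None
        top = freqs["frequency"].idxmax()
        if freqs.loc[top, "cls"] == "dominant":
            return top[1]
        return None


def build_clonotypes(contigs: Iterable[ContigRecord]) -> ClonotypeTable:
    """Collapse per-cell contigs into paired alpha/beta clonotype keys.

    Keys use productive chains only; a cell needs at least one productive
    TRA and exactly one productive TRB for a key.  Cells with more than two
    productive TRA or more than one productive TRB chains are flagged
    ambiguous and excluded from frequency counts.
    """
    per_cell: dict[tuple[str, str], dict[str, list[str]]] = {}
    any_chain: set[tuple[str, str]] = set()
    for rec in contigs:
        cell = (rec.sample, rec.barcode)
        any_chain.add(cell)
        if rec.productive:
            per_cell.setdefault(cell, {"TRA": [], "TRB": []})[rec.chain].append(
                rec.cdr3_nt
            )

    rows = []
    n_ambiguous = 0
    for cell in sorted(any_chain):
        chains = per_cell.get(cell, {"TRA": [], "TRB": []})
        tras, trbs = chains["TRA"], chains["TRB"]
        ambiguous = len(tras) > 2 or len(trbs) > 1
        n_ambiguous += ambiguous
        key = None
        if not ambiguous and tras and len(trbs) == 1:
            key = ",".join(sorted(tras)) + "|" + trbs[0]
        rows.append(
            {
                "sample": cell[0],
                "barcode": cell[1],
                "key": key,
                "has_any_productive": bool(tras or trbs),
                "productive_pair": bool(tras and trbs) and not ambiguous,
                "ambiguous": ambiguous,
            }
        )
    if n_ambiguous:
        logger.info("excluded %d cells with ambiguous chain counts", n_ambiguous)

    cells = pd.DataFrame(
        rows, columns=["sample", "barcode", "key", "has_any_productive",
                       "productive_pair", "ambiguous"]
    ).set_index(["sample", "barcode"])

    keyed = cells[cells["key"].notna() & ~cells["ambiguous"]]
    if keyed.empty:
        freq = pd.DataFrame(
            columns=["frequency", "cls", "low_expanded_band"],
            index=pd.MultiIndex.from_arrays([[], []], names=["sample", "key"]),
        )
    else:
        counts = (
            keyed.groupby(level="sample")["key"].value_counts().rename("frequency")
        )
        freq = counts.to_frame()
        freq.index = freq.index.set_names(["sample", "key"])
        freq["cls"] = [classify_frequency(f) for f in freq["frequency"]]
        freq["low_expanded_band"] = freq["frequency"].between(2, 49)
        freq = freq.sort_index()
    return ClonotypeTable(cells=cells, frequencies=freq)


def classify_frequency(freq: int) -> str:
    """Expansion class of a clonotype frequency.

    dominant > 50 cells; expanded >= 3; low_expanded = 2; singleton = 1.
    (Frequencies 2-49 are additionally surfaced as the low-level expansion
    band in :func:`build_clonotypes`.)
    """
    if not float(freq).is_integer() or freq < 1:
        raise ValueError(f"frequency must be a positive integer, got {freq!r}")
    freq = int(freq)
    if freq > 50:
        return "dominant"
    if freq >= 3:
        return "expanded"
    if freq == 2:
        return "low_expanded"
    return "singleton"


def productive_stats(table: ClonotypeTable) -> dict[str, float]:
    """Fractions of TCR-covered cells with any productive chain / a pair."""
    cells = table.cells
    if cells.empty:
        raise ValueError("empty clonotype table")
    n = len(cells)
    return {
        "fraction_any_productive": float(cells["has_any_productive"].sum() / n),
        "fraction_both_chains": float(cells["productive_pair"].sum() / n),
    }


def detect_tcr_loss_clusters(
    table: ClonotypeTable,
    cluster_labels: pd.Series,
    dominant_key: str,
    max_pair_rate: float = 0.20,
) -> set[int]:
    """Flag clusters with a TCR-loss signature.

    A cluster is flagged when fewer than ``max_pair_rate`` of its cells
    harbor a productive alpha/beta pair AND the modal clonotype among its
    paired cells equals the sample's dominant key.  ``cluster_labels``
    covers every cell of the sample, indexed by barcode (or
    (sample, barcode)); cells absent from the contig table count as
    unpaired.  Clusters with no TCR-covered cell at all are skipped.
    """
    if dominant_key is None:
        raise ValueError("dominant_key is required")
    cells = table.cells.reset_index()
    labels = cluster_labels.rename("cluster")
    if isinstance(labels.index, pd.MultiIndex):
        lab = labels.reset_index()
        lab.columns = ["sample", "barcode", "cluster"]
        joined = cells.merge(lab, on=["sample", "barcode"], how="right")
    else:
        lab = labels.rename_axis("barcode").reset_index()
        joined = cells.merge(lab, on="barcode", how="right")
    joined["productive_pair"] = (
        joined["productive_pair"].where(joined["productive_pair"].notna(), False)
        .astype(bool)
    )
    flagged: set[int] = set()
    for cl, grp in joined.groupby("cluster"):
        covered = grp[grp["ambiguous"].notna() & (grp["ambiguous"] != True)]  # noqa: E712
        if covered.empty:
            logger.warning("cluster %s has no TCR-covered cells; skipped", cl)
            continue
        pair_rate = grp["productive_pair"].mean()  # over all cells
        if pair_rate >= max_pair_rate:
            continue
        paired = grp[grp["productive_pair"] == True]  # noqa: E712
        if paired.empty:
            continue
        modal = paired["key"].mode()
        if len(modal) and modal.iloc[0] == dominant_key:
            flagged.add(int(cl))
    return flagged


def frequency_summary(table: ClonotypeTable) -> pd.DataFrame:
    """Per-sample cell counts by expansion class (pie-chart-ready)."""
    cells = table.cells
    keyed = cells[cells["key"].notna()]
    merged = keyed.join(table.frequencies["cls"], on=["sample", "key"])
    out = (
        merged.groupby(["sample", "cls"]).size().rename("cells").reset_index()
    )
    return out.pivot(index="sample", columns="cls", values="cells").fillna(0).astype(int)
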