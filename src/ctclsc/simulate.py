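"""Synthetic CTCL cohort generator with planted ground truth.

Emulates the statistical structure the downstream stages assume: a
monoclonal malignant CD4 T population per sample carrying chromosome-arm
scale expression shifts and one dominant paired-alpha/beta clonotype
(optionally with dual TRA chains and a TCR-loss subcluster), polyclonal
reactive Tconv/Treg/CD8 populations with low-level expansions, intratumor
expression programs shared across patients, marker-gene structure for
annotation, somatic variants with stem/private structure between lesions of
a patient, and a bulk survival cohort whose hazard is linked to a planted
signature score.

Counts are negative-binomial (gamma-Poisson) around cell-type mean
profiles, with an extra Bernoulli dropout; copy-number segments act
multiplicatively on malignant means (2**shift).  All randomness flows
through one seeded generator, so a config with a fixed seed reproduces the
cohort exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    ContigRecord,
    ExpressionMatrix,
    write_bed,
    write_contigs,
    write_counts,
    write_survival,
    write_variants,
)


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


def _load_resource(name: str) -> dict:
    with _ilres.files("ctclsc.resources").joinpath(name).open() as fh:
        return json.load(fh)


# extra planted subtype signature genes beyond the core state sets; the
# labels are effector-memory / central-memory associated symbols
CYEM_EXTRA = ["GZMH", "KLRG1", "CX3CR1", "FGFBP2", "TBX21"]
CM_EXTRA = ["BACH2", "CD28", "ICOS", "TNFRSF4", "TNFRSF9", "IL6R", "MAL",
            "NELL2", "PASK", "SATB1", "FOXP1", "KLF2", "S1PR1", "CD5",
            "CD6", "ITGB7", "SESN3", "CAMK4", "PLAC8L1", "RCAN3",
            "TSHZ2", "AQP3"]

T_CORE = ["PTPRC", "CD3E", "CD3D", "CD3G"]
CD4_GENES = ["CD4", "IL7R"]
CD8_GENES = ["CD8A", "CD8B"]
TREG_GENES = ["FOXP3", "IL2RA", "IKZF2"]
MITO_GENES = [f"MT-G{i}" for i in range(1, 6)]

DEFAULT_REACTIVE = {
    "Tconv": 0.40,
    "Treg": 0.20,
    "CD8_ex_low": 0.25,
    "CD8_ex_high": 0.15,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults give a detectable but noisy
    cohort comparable to a tumor-stage CTCL lesion."""

    n_patients: int = 13
    samples_per_patient: int = 1
    cells_per_sample: int = 500
    n_genes: int = 1500
    malignant_fraction: float = 0.5
    #: (chromosome, start gene index, end gene index, log2 shift); indices
    #: are global positions in genomic gene order, end exclusive
    cnv_segments: Optional[list[tuple[str, int, int, float]]] = None
    #: minimum number of cells the dominant clonotype must reach per sample
    dominant_clonotype_frequency: int = 100
    tcr_loss_fraction: float = 0.15
    dual_tra_fraction: float = 0.2
    reactive_composition: dict = field(default_factory=lambda: dict(DEFAULT_REACTIVE))
    #: planted shared programs: name -> gene list; None plants 4 disjoint
    #: 50-gene programs drawn from the filler gene pool
    planted_programs: Optional[dict[str, list[str]]] = None
    program_fold: float = 4.0
    marker_fold: float = 8.0
    library_sigma: float = 0.3
    base_mean: float = 3.0
    dispersion: float = 2.0
    dropout: float = 0.05
    pair_rate_malignant: float = 0.92
    pair_rate_reactive: float = 0.85
    tcr_loss_pair_rate: float = 0.10
    tcr_coverage: float = 0.95
    expanded_cell_fraction: float = 0.20
    variants_per_lesion: int = 30
    stem_fraction: float = 0.30
    survival_n: int = 49
    survival_effect: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "malignant_fraction": self.malignant_fraction,
            "tcr_loss_fraction": self.tcr_loss_fraction,
            "dual_tra_fraction": self.dual_tra_fraction,
            "dropout": self.dropout,
            "stem_fraction": self.stem_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        total = sum(self.reactive_composition.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(f"reactive composition sums to {total}, not 1")
        if any(v < 0 for v in self.reactive_composition.values()):
            raise ConfigError("negative reactive composition entry")
        if self.cnv_segments is not None:
            for seg in self.cnv_segments:
                if not np.isfinite(seg[3]):
                    raise ConfigError("non-finite CNV shift")
        n_mal = int(round(self.cells_per_sample * self.malignant_fraction))
        if n_mal > 0:
            expected_dom = n_mal * (
                (1 - self.tcr_loss_fraction) * self.pair_rate_malignant
                + self.tcr_loss_fraction * self.tcr_loss_pair_rate
            ) * self.tcr_coverage
            if expected_dom < self.dominant_clonotype_frequency * 0.5:
                raise ConfigError(
                    "dominant_clonotype_frequency infeasible for the malignant "
                    f"population size ({n_mal} cells)"
                )


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    cell_type: pd.Series           # per cell: malignant|malignant_tcr_loss|reactive types
    clonotype_of_cell: pd.Series   # per cell: planted clonotype key or None
    dominant_key: dict             # sample -> clonotype key (None if no malignant)
    dominant_frequency: dict       # sample -> planted cell count of the dominant key
    cnv_segments: list             # (chrom, start_idx, end_idx, shift, gene_ids)
    program_genes: dict            # program name -> gene list (shared programs)
    program_of_cell: pd.Series     # per cell: program name or None
    subtype_of_patient: dict       # patient -> T_CyEM | T_CM
    signature_genes: dict          # subtype -> planted DEG signature gene list
    stem_variants: dict            # patient -> set of variant keys
    private_variants: dict         # (patient, lesion) -> set of variant keys
    survival_effect: float
    seed: int

    @property
    def partition_label(self) -> pd.Series:
        """Planted partition at cluster granularity: reactive types as-is,
        malignant cells split by planted program, TCR-loss separate."""
        prog = self.program_of_cell.fillna("")
        lab = self.cell_type.copy()
        is_mal = lab == "malignant"
        lab[is_mal] = "malignant:" + prog[is_mal]
        return lab


def _gene_universe(cfg: SimulationConfig) -> tuple[list[str], pd.DataFrame]:
    """Build the gene list in genomic order plus BED-convention coordinates.

    Named marker/signature genes are placed on the last chromosome so the
    default CNV segments (early chromosomes) never overlap them.
    """
    markers = _load_resource("markers.json")
    sigs = _load_resource("signatures.json")
    named: list[str] = []
    for genes in markers.values():
        named.extend(genes)
    for genes in sigs.values():
        named.extend(genes)
    named.extend(CYEM_EXTRA + CM_EXTRA + CD4_GENES + CD8_GENES + TREG_GENES)
    named.extend(["TOX", "MYC", "CD69"])
    named.extend(MITO_GENES)
    seen: set[str] = set()
    named = [g for g in named if not (g in seen or seen.add(g))]
    n_filler = cfg.n_genes - len(named)
    if n_filler < 100:
        raise ConfigError(
            f"n_genes={cfg.n_genes} leaves fewer than 100 filler genes"
        )
    filler = [f"FIL{i:04d}" for i in range(n_filler)]
    genes = filler + named  # named genes at the end of the genome
    chroms = [f"chr{i}" for i in range(1, 7)]
    per = int(np.ceil(len(genes) / len(chroms)))
    rows = []
    for i, g in enumerate(genes):
        ci, off = divmod(i, per)
        start = 10_000 * off
        rows.append((chroms[ci], start, start + 1_000, g, "+"))
    coords = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])
    coords = coords.set_index("gene_id")[["chrom", "start", "end", "strand"]]
    return genes, coords


def _default_segments(coords: pd.DataFrame) -> list[tuple[str, int, int, float]]:
    """Arm-scale default CNV segments on the first three chromosomes."""
    chroms = coords["chrom"].to_numpy()
    segs = []
    for chrom, shift in [("chr1", 1.0), ("chr2", -1.0), ("chr3", 0.58)]:
        idx = np.flatnonzero(chroms == chrom)
        n = len(idx)
        segs.append((chrom, int(idx[0]), int(idx[0] + max(1, int(0.6 * n))), shift))
    return segs


def _default_programs(cfg, genes, segment_idx: set[int]) -> dict[str, list[str]]:
    """Four disjoint 50-gene programs from filler genes outside CNV segments."""
    pool = [g for i, g in enumerate(genes)
            if g.startswith("FIL") and i not in segment_idx]
    need = 4 * 50
    if len(pool) < need + 60:
        raise ConfigError("too few filler genes to plant 4 programs")
    out = {}
    for p in range(4):
        out[f"MP{p + 1}"] = pool[p * 50:(p + 1) * 50]
    return out


def _random_nt(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_cdr3(rng) -> tuple[str, str]:
    aa = "C" + "".join(np.array(list("ARNDCQEGHILKMFPSTWYV"))[rng.integers(0, 20, 11)]) + "F"
    return aa, _random_nt(rng, 39)


def simulate_cohort(cfg: SimulationConfig):
    """Generate a full synthetic cohort.

    Returns ``(counts, contigs, coords, variants, survival, truth)`` where
    ``counts`` is an :class:`~ctclsc.io.ExpressionMatrix`, ``contigs`` a list
    of :class:`~ctclsc.io.ContigRecord`, ``coords`` a BED-style coordinate
    frame, ``variants``/``survival`` pandas tables and ``truth`` the planted
    :class:`SyntheticTruth`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, coords = _gene_universe(cfg)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    segments = cfg.cnv_segments
    if segments is None:
        segments = _default_segments(coords)
    chrom_arr = coords["chrom"].to_numpy()
    seg_records = []
    seg_idx: set[int] = set()
    for chrom, lo, hi, shift in segments:
        if not (0 <= lo < hi <= n_genes):
            raise ConfigError(f"CNV segment [{lo},{hi}) outside gene range")
        if not (chrom_arr[lo:hi] == chrom).all():
            raise ConfigError(f"CNV segment [{lo},{hi}) crosses out of {chrom}")
        seg_records.append((chrom, lo, hi, shift, [genes[i] for i in range(lo, hi)]))
        seg_idx.update(range(lo, hi))

    programs = cfg.planted_programs
    if programs is None:
        programs = _default_programs(cfg, genes, seg_idx)
    for name, gl in programs.items():
        unknown = [g for g in gl if g not in gene_index]
        if unknown:
            raise ConfigError(f"program {name} references unknown genes {unknown[:3]}")

    markers = _load_resource("markers.json")
    sigs = _load_resource("signatures.json")
    cyem_sig = sigs["cytotoxicity"] + CYEM_EXTRA          # 13 genes
    cm_sig = sigs["central_memory"] + CM_EXTRA            # 27 genes

    # baseline mean profile, mildly long-tailed
    base = rng.gamma(shape=2.0, scale=cfg.base_mean / 2.0, size=n_genes) + 0.05
    base[[gene_index[g] for g in MITO_GENES]] = cfg.base_mean * 6.0

    def boosted(gene_list, fold, profile):
        for g in gene_list:
            if g in gene_index:
                profile[gene_index[g]] *= fold

    # each reactive type carries a broad 40-gene expression module on top of
    # its markers -- cell types differ across many genes, not just canonical
    # markers, and clustering relies on that breadth
    module_pool = [g for i, g in enumerate(genes)
                   if g.startswith("FIL") and i not in seg_idx
                   and not any(g in gl for gl in programs.values())]
    module_pool = list(rng.permutation(module_pool))
    type_modules = {
        ctype: module_pool[40 * i:40 * (i + 1)]
        for i, ctype in enumerate(["Tconv", "Treg", "CD8_ex_low", "CD8_ex_high"])
    }
    # sample-private programs come from a dedicated pool, disjoint across
    # samples so private intratumor axes never look like shared programs
    private_pool = module_pool[160:]

    # per-cell-type mean profiles (before CNV / programs / library factor)
    profiles: dict[str, np.ndarray] = {}
    t_base = base.copy()
    boosted(T_CORE, cfg.marker_fold, t_base)
    for ctype in ["Tconv", "Treg", "CD8_ex_low", "CD8_ex_high"]:
        p = t_base.copy()
        boosted(type_modules[ctype], 3.0, p)
        if ctype in ("Tconv", "Treg"):
            boosted(CD4_GENES, cfg.marker_fold, p)
        else:
            boosted(CD8_GENES, cfg.marker_fold, p)
        if ctype == "Treg":
            boosted(TREG_GENES, cfg.marker_fold, p)
        if ctype == "CD8_ex_high":
            boosted(sigs["exhaustion"], 6.0, p)
            boosted(["TCF7"], 0.3, p)
            boosted(sigs["cytotoxicity"], 2.0, p)
        if ctype == "CD8_ex_low":
            boosted(["TCF7"], cfg.marker_fold, p)
            boosted(sigs["cytotoxicity"], 2.0, p)
        profiles[ctype] = p

    sample_ids = []
    patient_of_sample = {}
    for p in range(cfg.n_patients):
        patient = f"P{p + 1:02d}"
        for s in range(cfg.samples_per_patient):
            sid = f"{patient}-L{s + 1}"
            sample_ids.append(sid)
            patient_of_sample[sid] = patient

    subtype_of_patient = {
        f"P{p + 1:02d}": ("T_CyEM" if p % 2 == 0 else "T_CM")
        for p in range(cfg.n_patients)
    }

    n_mal = int(round(cfg.cells_per_sample * cfg.malignant_fraction))
    n_reac = cfg.cells_per_sample - n_mal
    n_loss = int(round(n_mal * cfg.tcr_loss_fraction))
    n_dual = int(np.ceil(cfg.dual_tra_fraction * len(sample_ids)))
    program_names = list(programs)

    cols, barcodes, samples_col = [], [], []
    cell_type_l, clono_l, program_l = [], [], []
    contigs: list[ContigRecord] = []
    dominant_key: dict[str, Optional[str]] = {}
    dominant_freq: dict[str, int] = {}

    seg_mult = np.ones(n_genes)
    for _, lo, hi, shift, _gl in seg_records:
        seg_mult[lo:hi] = 2.0 ** shift

    for si, sid in enumerate(sample_ids):
        patient = patient_of_sample[sid]
        subtype = subtype_of_patient[patient]
        mal_base = t_base.copy()
        boosted(CD4_GENES, cfg.marker_fold, mal_base)
        if subtype == "T_CyEM":
            boosted(cyem_sig, 6.0, mal_base)
        else:
            boosted(cm_sig, 6.0, mal_base)
        mal_base = mal_base * seg_mult

        # sample-private program carried by the TCR-loss subcluster (and used
        # as a fifth, non-shared axis of intratumor heterogeneity)
        if (si + 1) * 50 <= len(private_pool):
            private_genes = private_pool[si * 50:(si + 1) * 50]
        else:  # pool exhausted for very large cohorts: draw with overlap
            private_genes = list(rng.choice(private_pool, size=50, replace=False))

        # --- TCR keys for this sample ---
        dual = si < n_dual
        aa_b, nt_b = _random_cdr3(rng)
        tras = [_random_cdr3(rng) for _ in range(2 if dual else 1)]
        tra_nts = sorted(nt for _aa, nt in tras)
        dom_key = ",".join(tra_nts) + "|" + nt_b if n_mal > 0 else None
        dominant_key[sid] = dom_key
        dom_count = 0

        # --- malignant cells ---
        for ci in range(n_mal):
            loss = ci >= n_mal - n_loss
            mean = mal_base.copy()
            if loss:
                # transcriptional TCR down-modulation plus a private program
                for g in ["CD3E", "TOX"]:
                    mean[gene_index[g]] *= 0.3
                for g in private_genes:
                    mean[gene_index[g]] *= cfg.program_fold
                prog = None
            else:
                prog = program_names[ci % len(program_names)]
                act = rng.normal(1.0, 0.2)
                for g in programs[prog]:
                    mean[gene_index[g]] *= 1.0 + max(0.0, act) * (cfg.program_fold - 1.0)
            cols.append(mean)
            bc = f"BC{ci:05d}"
            barcodes.append(f"{sid}:{bc}")
            samples_col.append(sid)
            cell_type_l.append("malignant_tcr_loss" if loss else "malignant")
            program_l.append(prog)
            covered = rng.random() < cfg.tcr_coverage
            pair_rate = cfg.tcr_loss_pair_rate if loss else cfg.pair_rate_malignant
            key = None
            if covered:
                if rng.random() < pair_rate:
                    for aa, nt in tras:
                        contigs.append(ContigRecord(bc, sid, "TRA", aa, nt, True))
                    contigs.append(ContigRecord(bc, sid, "TRB", aa_b, nt_b, True))
                    key = dom_key
                    dom_count += 1
                elif rng.random() < 0.5:
                    # beta chain detected but nonproductive
                    contigs.append(ContigRecord(bc, sid, "TRB", "", nt_b[:-1], False))
            clono_l.append(key)

        dominant_freq[sid] = dom_count

        # --- reactive repertoire: a few 2-49 expansions plus singletons ---
        reac_types = list(cfg.reactive_composition)
        reac_counts = np.floor(
            np.array([cfg.reactive_composition[t] for t in reac_types]) * n_reac
        ).astype(int)
        while reac_counts.sum() < n_reac:
            reac_counts[int(np.argmin(reac_counts / max(n_reac, 1)))] += 1
        type_seq = [t for t, c in zip(reac_types, reac_counts) for _ in range(c)]

        n_exp_cells = int(round(cfg.expanded_cell_fraction * n_reac))
        exp_sizes = []
        while sum(exp_sizes) < n_exp_cells:
            exp_sizes.append(int(min(49, 2 + rng.geometric(0.35))))
        clone_seq: list[int] = []
        for k, size in enumerate(exp_sizes):
            clone_seq.extend([k] * size)
        clone_seq = clone_seq[:n_exp_cells]
        clone_seq += list(range(len(exp_sizes), len(exp_sizes) + (n_reac - len(clone_seq))))
        rng.shuffle(clone_seq)

        clone_keys: dict[int, tuple] = {}
        for ci in range(n_reac):
            ctype = type_seq[ci]
            mean = profiles[ctype]
            cols.append(mean)
            bc = f"BC{n_mal + ci:05d}"
            barcodes.append(f"{sid}:{bc}")
            samples_col.append(sid)
            cell_type_l.append(ctype)
            program_l.append(None)
            cid = clone_seq[ci]
            if cid not in clone_keys:
                dual_r = rng.random() < cfg.dual_tra_fraction
                ntras = [_random_cdr3(rng) for _ in range(2 if dual_r else 1)]
                clone_keys[cid] = (ntras, _random_cdr3(rng))
            ntras, (r_aa_b, r_nt_b) = clone_keys[cid]
            key = None
            if rng.random() < cfg.tcr_coverage:
                if rng.random() < cfg.pair_rate_reactive:
                    for aa, nt in ntras:
                        contigs.append(ContigRecord(bc, sid, "TRA", aa, nt, True))
                    contigs.append(ContigRecord(bc, sid, "TRB", r_aa_b, r_nt_b, True))
                    key = ",".join(sorted(nt for _a, nt in ntras)) + "|" + r_nt_b
                else:
                    aa, nt = ntras[0]
                    contigs.append(ContigRecord(bc, sid, "TRA", aa, nt, True))
            clono_l.append(key)

    # --- draw counts: gamma-Poisson with per-cell library factor + dropout ---
    mean_mat = np.stack(cols, axis=1)  # genes x cells
    n_cells = mean_mat.shape[1]
    lib = np.exp(rng.normal(0.0, cfg.library_sigma, size=n_cells))
    lam = mean_mat * lib[None, :]
    r = cfg.dispersion
    shape_gamma = rng.gamma(shape=r, scale=lam / r)
    counts = rng.poisson(shape_gamma)
    if cfg.dropout > 0:
        counts = counts * (rng.random(counts.shape) >= cfg.dropout)

    matrix = ExpressionMatrix(
        sp.csr_matrix(counts),
        np.array(genes, dtype=object),
        np.array(barcodes, dtype=object),
        np.array(samples_col, dtype=object),
    )

    variants, stem_map, private_map = _simulate_variants(cfg, rng, patient_of_sample)
    survival = simulate_survival_cohort(cfg.survival_n, cfg.survival_effect,
                                        rng=rng)

    idx = pd.Index(barcodes, name="cell")
    truth = SyntheticTruth(
        cell_type=pd.Series(cell_type_l, index=idx),
        clonotype_of_cell=pd.Series(clono_l, index=idx, dtype=object),
        dominant_key=dominant_key,
        dominant_frequency=dominant_freq,
        cnv_segments=seg_records,
        program_genes={k: list(v) for k, v in programs.items()},
        program_of_cell=pd.Series(program_l, index=idx, dtype=object),
        subtype_of_patient=subtype_of_patient,
        signature_genes={"T_CyEM": list(cyem_sig), "T_CM": list(cm_sig)},
        stem_variants=stem_map,
        private_variants=private_map,
        survival_effect=cfg.survival_effect,
        seed=cfg.seed,
    )
    return matrix, contigs, coords, variants, survival, truth


def _simulate_variants(cfg, rng, patient_of_sample):
    """Stem + private somatic variant tables per lesion (exact set sizes)."""
    n_stem = int(round(cfg.stem_fraction * cfg.variants_per_lesion))
    n_priv = cfg.variants_per_lesion - n_stem
    rows = []
    stem_map, private_map = {}, {}
    lesions_by_patient: dict[str, list[str]] = {}
    for sid, pat in patient_of_sample.items():
        lesions_by_patient.setdefault(pat, []).append(sid)
    for pat, lesions in lesions_by_patient.items():
        used_pos: set[int] = set()

        def fresh_variant():
            while True:
                pos = int(rng.integers(1, 10_000_000))
                if pos not in used_pos:
                    used_pos.add(pos)
                    break
            chrom = f"chr{int(rng.integers(1, 7))}"
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            u = rng.random()
            effect = ("nonsynonymous" if u < 0.7
                      else "synonymous" if u < 0.9 else "indel")
            flank = _random_nt(rng, 20) + ref + _random_nt(rng, 20)
            return (chrom, pos, str(ref), str(alt), effect, flank)

        stem = [fresh_variant() for _ in range(n_stem)]
        stem_map[pat] = {(v[0], v[1], v[2], v[3]) for v in stem
                         if v[4] == "nonsynonymous"}
        for sid in lesions:
            priv = [fresh_variant() for _ in range(n_priv)]
            private_map[(pat, sid)] = {(v[0], v[1], v[2], v[3]) for v in priv
                                       if v[4] == "nonsynonymous"}
            for chrom, pos, ref, alt, effect, flank in stem + priv:
                rows.append((sid, chrom, pos, ref, alt, effect, flank))
    return (
        pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                    "effect", "flank"]),
        stem_map,
        private_map,
    )


def simulate_survival_cohort(n_patients: int = 49, effect: float = 1.0,
                             seed: Optional[int] = None, rng=None) -> pd.DataFrame:
    """Bulk survival cohort: exponential times with hazard ∝ exp(effect*score).

    Scores are standard normal; censoring is independent uniform on
    (12, 72) months.  Returns a table with columns patient/time/event/score.
    """
    if n_patients < 2:
        raise ConfigError("need at least 2 patients")
    if rng is None:
        rng = np.random.default_rng(seed)
    score = rng.normal(0.0, 1.0, size=n_patients)
    base_rate = 1.0 / 36.0  # median PFS on the order of two years
    rate = base_rate * np.exp(effect * score)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(12.0, 72.0, size=n_patients)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "patient": [f"S{i + 1:03d}" for i in range(n_patients)],
            "time": np.maximum(time, 1e-6),
            "event": event,
            "score": score,
        }
    )


def write_cohort(outdir, matrix, contigs, coords, variants, survival,
                 truth: Optional[SyntheticTruth] = None) -> None:
    """Write a cohort in exactly the formats the IO module reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(matrix, out / "matrix.mtx", out / "genes.tsv", out / "barcodes.tsv")
    pd.Series(matrix.sample_of_cell).to_csv(
        out / "samples.tsv", sep="\t", index=False, header=["sample"]
    )
    write_contigs(contigs, out / "contigs.csv")
    write_bed(coords, out / "genes.bed")
    write_variants(variants, out / "variants.tsv")
    write_survival(survival, out / "survival.csv")
    if truth is not None:
        labels = pd.DataFrame(
            {
                "cell": truth.cell_type.index,
                "cell_type": truth.cell_type.values,
                "clonotype": truth.clonotype_of_cell.fillna("").values,
                "program": truth.program_of_cell.fillna("").values,
            }
        )
        labels.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
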