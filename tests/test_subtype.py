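"""DEGs, subtype grouping, signatures, exhaustion split and survival."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2
from sklearn.metrics import adjusted_rand_score

from ctclsc.preprocess import NormalizedMatrix
from ctclsc.subtype import (
    derive_group_signature,
    differential_expression,
    exhaustion_composition_test,
    km_logrank,
    split_exhaustion,
    subtype_samples,
)


def make_norm(values, genes=None):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values,
        np.array(genes if genes is not None
                 else [f"G{i}" for i in range(values.shape[0])], dtype=object),
        np.array([f"B{i}" for i in range(values.shape[1])], dtype=object),
        np.array(["s"] * values.shape[1], dtype=object),
    )


class TestDifferentialExpression:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(0)
        values = rng.random((15, 10))
        a, b = make_norm(values), make_norm(values.copy())
        deg = differential_expression(a, b)
        assert np.allclose(deg["log2fc"], 0.0)
        assert (deg["pvalue"] > 0.9).all()

    def test_constructed_eightfold_effect(self):
        """Gene expressed 8x in malignant shows log2FC ~3 and small p."""
        rng = np.random.default_rng(1)
        base = rng.normal(0.1, 0.02, size=(5, 60)).clip(min=0)
        mal = base.copy()
        mal[0] = np.log1p(8 * 40.0 + rng.normal(0, 2, size=60).clip(-5, 5))
        base[0] = np.log1p(40.0 + rng.normal(0, 2, size=60).clip(-5, 5))
        deg = differential_expression(make_norm(mal), make_norm(base))
        assert deg["log2fc"].iloc[0] == pytest.approx(3.0, abs=0.15)
        assert deg["pvalue"].iloc[0] < 0.05

    def test_ranksum_p_matches_exact_enumeration_5v5(self):
        """Two-sided rank-sum p equals brute-force permutation enumeration."""
        rng = np.random.default_rng(2)
        a_vals = rng.normal(0, 1, 5)
        b_vals = rng.normal(1.0, 1, 5)
        deg = differential_expression(
            make_norm(a_vals[None, :]), make_norm(b_vals[None, :])
        )
        pooled = np.concatenate([a_vals, b_vals])

        def u_stat(sel):
            ga = pooled[list(sel)]
            gb = pooled[[i for i in range(10) if i not in sel]]
            return sum(x > y for x in ga for y in gb)

        u_obs = u_stat(tuple(range(5)))
        stats = np.array([u_stat(s) for s in itertools.combinations(range(10), 5)])
        p_exact = (np.abs(stats - 12.5) >= abs(u_obs - 12.5) - 1e-12).mean()
        assert deg["pvalue"].iloc[0] == pytest.approx(p_exact, abs=1e-12)

    def test_empty_group_rejected(self):
        norm = make_norm(np.ones((3, 4)))
        with pytest.raises(ValueError):
            differential_expression(norm, make_norm(np.ones((3, 0))))


class TestSubtypeSamples:
    def _cohort_profiles(self, rng, n_per_group=4, n_genes=40):
        cyto = ["GZMA", "GZMB", "NKG7", "PRF1"]
        genes = cyto + [f"G{i}" for i in range(n_genes - len(cyto))]
        rows = {}
        for i in range(n_per_group):
            prof = rng.normal(1.0, 0.05, n_genes)
            prof[:4] += 2.0          # cytotoxic-high group
            rows[f"cyem{i}"] = prof
        for i in range(n_per_group):
            prof = rng.normal(1.0, 0.05, n_genes)
            prof[10:20] += 2.0       # distinct central-memory-like profile
            rows[f"cm{i}"] = prof
        return pd.DataFrame.from_dict(rows, orient="index", columns=genes)

    def test_planted_two_group_partition_recovered(self):
        df = self._cohort_profiles(np.random.default_rng(3))
        labels = subtype_samples(df)
        truth = ["T_CyEM" if s.startswith("cyem") else "T_CM" for s in labels.index]
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
        # label orientation: the cytotoxic-high samples are T_CyEM
        assert (labels[[s for s in labels.index if s.startswith("cyem")]]
                == "T_CyEM").all()

    def test_duplicated_sample_coclusters(self):
        df = self._cohort_profiles(np.random.default_rng(4))
        df.loc["cyem0_dup"] = df.loc["cyem0"]
        labels = subtype_samples(df)
        assert labels["cyem0_dup"] == labels["cyem0"]

    def test_sample_order_invariance(self):
        df = self._cohort_profiles(np.random.default_rng(5))
        a = subtype_samples(df)
        b = subtype_samples(df.iloc[::-1])
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_single_sample_rejected(self):
        df = self._cohort_profiles(np.random.default_rng(6)).iloc[:1]
        with pytest.raises(ValueError):
            subtype_samples(df)


class TestGroupSignature:
    def _deg(self, up_genes, p=0.01, fc=1.0, others=("X1", "X2")):
        genes = list(up_genes) + list(others)
        return pd.DataFrame(
            {"log2fc": [fc] * len(up_genes) + [0.0] * len(others),
             "pvalue": [p] * len(up_genes) + [0.9] * len(others),
             "adj_pvalue": 1.0, "direction": "up"},
            index=pd.Index(genes, name="gene"),
        )

    def test_shared_genes_intersected(self):
        tables = {"s1": self._deg(["A", "B", "C"]), "s2": self._deg(["A", "B"])}
        assert derive_group_signature(tables) == ["A", "B"]

    def test_disjoint_lists_give_empty_signature(self):
        tables = {"s1": self._deg(["A"]), "s2": self._deg(["B"])}
        with pytest.warns(UserWarning, match="empty"):
            assert derive_group_signature(tables) == []

    def test_gene_failing_threshold_in_one_sample_excluded(self):
        tables = {"s1": self._deg(["A", "B"]),
                  "s2": pd.concat([self._deg(["A"]),
                                   self._deg(["B"], p=0.2, others=())])}
        assert derive_group_signature(tables) == ["A"]

    def test_planted_13_gene_signature_recovered(self):
        rng = np.random.default_rng(7)
        planted = [f"SIG{i}" for i in range(13)]
        tables = {}
        for s in range(4):
            extra = [f"N{s}_{i}" for i in range(rng.integers(3, 8))]
            tables[f"s{s}"] = self._deg(planted + extra)
        assert derive_group_signature(tables) == sorted(planted)

    def test_low_deg_sample_excluded_with_warning(self):
        tables = {"s1": self._deg(["A", "B", "C"]), "s2": self._deg(["A", "B"]),
                  "s3": self._deg(["Z"])}
        with pytest.warns(UserWarning, match="excluded"):
            out = derive_group_signature(tables, min_degs=2)
        assert out == ["A", "B"]


class TestExhaustionSplit:
    def test_planted_exhausted_population_labeled(self):
        rng = np.random.default_rng(8)
        ex_genes = ["PDCD1", "LAG3", "TIGIT", "HAVCR2", "CTLA4"]
        genes = ex_genes + ["TCF7"] + [f"G{i}" for i in range(200)]
        n = 120
        values = rng.normal(1.0, 0.2, size=(len(genes), n)).clip(min=0)
        # first 60 cells: exhausted (checkpoints up, TCF7 down) + a broad
        # 30-gene module so clustering separates the populations
        values[:5, :60] += 1.5
        values[5, 60:] += 1.5
        values[6:36, :60] += 1.0
        norm = NormalizedMatrix(
            values, np.array(genes, dtype=object),
            np.array([f"B{i}" for i in range(n)], dtype=object),
            np.array(["s"] * n, dtype=object),
        )
        labels = split_exhaustion(norm, seed=0)
        assert (labels.iloc[:60] == "Ex_high").mean() > 0.95
        assert (labels.iloc[60:] == "Ex_low").mean() > 0.95

    def test_uniform_cells_single_label(self):
        rng = np.random.default_rng(9)
        genes = ["PDCD1", "LAG3", "TIGIT", "HAVCR2", "CTLA4", "TCF7"] \
            + [f"G{i}" for i in range(50)]
        values = rng.normal(1.0, 0.05, size=(len(genes), 60)).clip(min=0)
        norm = NormalizedMatrix(
            values, np.array(genes, dtype=object),
            np.array([f"B{i}" for i in range(60)], dtype=object),
            np.array(["s"] * 60, dtype=object),
        )
        labels = split_exhaustion(norm, seed=0)
        assert labels.nunique() == 1

    def test_chi_square_matches_closed_form(self):
        """Pearson chi-square on a 2x2 equals the textbook formula."""
        labels = pd.Series(["Ex_high"] * 30 + ["Ex_low"] * 70,
                           index=[f"c{i}" for i in range(100)])
        groups = pd.Series(["T_CM"] * 20 + ["T_CyEM"] * 10
                           + ["T_CM"] * 20 + ["T_CyEM"] * 50,
                           index=labels.index)
        table, stat, p = exhaustion_composition_test(labels, groups)
        a, b, c, d = 20, 10, 20, 50
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(expected, abs=1e-10)
        assert p == pytest.approx(chi2.sf(expected, 1), abs=1e-12)


class TestKMLogrank:
    def test_identical_arms_give_p_one(self):
        df = pd.DataFrame({
            "patient": [f"p{i}" for i in range(8)],
            "time": [5.0, 10.0, 15.0, 20.0] * 2,
            "event": [1, 1, 0, 1] * 2,
            "score": [-1, -1, -1, -1, 1, 1, 1, 1],
        })
        res = km_logrank(df)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_logrank(self):
        """Two-arm log-rank statistic agrees with the O-E/V arithmetic."""
        t_low = [6, 6, 6, 7, 10, 13, 16, 22, 23, 6]
        e_low = [1, 1, 1, 1, 1, 1, 1, 1, 1, 0]
        t_high = [1, 1, 2, 2, 3, 4, 4, 5, 5, 8]
        e_high = [1] * 10
        df = pd.DataFrame({
            "patient": [f"p{i}" for i in range(20)],
            "time": t_low + t_high,
            "event": e_low + e_high,
            "score": [-1.0] * 10 + [1.0] * 10,
        })
        res = km_logrank(df)
        o_minus_e = var = 0.0
        for t in sorted({t for t, e in zip(t_low + t_high, e_low + e_high) if e}):
            n_a = sum(1 for x in t_low if x >= t)
            n_b = sum(1 for x in t_high if x >= t)
            d_a = sum(1 for x, e in zip(t_low, e_low) if x == t and e)
            d_b = sum(1 for x, e in zip(t_high, e_high) if x == t and e)
            n, d = n_a + n_b, d_a + d_b
            if n < 2:
                continue
            o_minus_e += d_a - d * n_a / n
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
        stat = o_minus_e**2 / var
        assert res.statistic == pytest.approx(stat, abs=1e-6)
        assert res.logrank_p == pytest.approx(float(chi2.sf(stat, 1)), abs=1e-6)
        # the high-score arm clearly fares worse
        assert res.median_times["high"] < res.median_times["low"]

    def test_median_split_ties_go_low(self):
        df = pd.DataFrame({
            "patient": [f"p{i}" for i in range(6)],
            "time": [1.0, 2, 3, 4, 5, 6], "event": [1] * 6,
            "score": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
        })
        res = km_logrank(df)
        assert (res.groups[["p0", "p1", "p2"]] == "low").all()

    def test_degenerate_arm_rejected(self):
        df = pd.DataFrame({
            "patient": ["a", "b", "c"], "time": [1.0, 2.0, 3.0],
            "event": [1, 1, 1], "score": [0.0, 0.0, 0.0],
        })
        with pytest.raises(ValueError):
            km_logrank(df)
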