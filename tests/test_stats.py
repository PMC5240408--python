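"""Downstream statistics: specificity, clustering, widths, chi-squared, X:A."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tilechrom as tc
from tilechrom import sim, stats
from tilechrom.containers import Cher, Segmentation


class TestSpecificity:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([1, 1, 1, 1], 0.0),
            ([0, 5, 0, 0], 1.0),
            ([1, 1, 0, 0], 0.5),
        ],
    )
    def test_closed_forms(self, vec, expected):
        assert stats.specificity(vec) == pytest.approx(expected)

    def test_all_zero_missing(self):
        assert np.isnan(stats.specificity([0.0, 0.0]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.specificity([1.0])
        with pytest.raises(ValueError):
            stats.specificity([1.0, -1.0])

    @given(
        st.lists(st.floats(0.01, 100), min_size=2, max_size=10),
        st.floats(0.1, 50),
    )
    def test_scale_invariance(self, vec, factor):
        a = stats.specificity(vec)
        b = stats.specificity([v * factor for v in vec])
        assert a == pytest.approx(b, abs=1e-9)

    def test_spreading_mass_decreases_specificity(self):
        assert stats.specificity([4, 0, 0, 0]) > stats.specificity([2, 2, 0, 0])

    def test_vectorized_matches_scalar(self, rng):
        df = pd.DataFrame(rng.random((20, 5)), index=[f"g{i}" for i in range(20)])
        scores = stats.specificity_scores(df)
        for g in df.index[:5]:
            assert scores[g] == pytest.approx(stats.specificity(df.loc[g]))

    @pytest.mark.parametrize("score,expected", [(0.0, "low"), (0.95, "high"), (0.5, "mid"),
                                                (0.2, "low"), (0.9, "high")])
    def test_classification_cuts(self, score, expected):
        assert stats.classify_specificity(pd.Series([score])).iloc[0] == expected


class TestClustering:
    def test_identical_rows_cluster_together(self):
        t = pd.DataFrame([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
        labels = stats.cluster_enrichments(t)
        assert labels[0] == labels[1] != labels[2]

    def test_anticorrelated_rows_split(self):
        t = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
        labels = stats.cluster_enrichments(t)
        assert labels[0] != labels[1]

    def test_three_row_hand_linkage(self, rng):
        # two tightly correlated rows, one decorrelated (d > 1): two clusters
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        r2 = base + rng.normal(0, 0.1, base.size)
        r3 = np.array([2.0, -1.0, 3.0, -2.0, 1.0, -3.0])  # slightly anticorrelated
        t = pd.DataFrame([base, r2, r3])
        labels = stats.cluster_enrichments(t)
        assert labels[0] == labels[1] != labels[2]
        assert labels.nunique() == 2

    def test_row_order_invariance(self, rng):
        t = pd.DataFrame(rng.random((6, 5)))
        a = stats.cluster_enrichments(t)
        perm = [3, 0, 5, 1, 4, 2]
        b = stats.cluster_enrichments(t.iloc[perm])
        # same partition regardless of row order
        for i in range(6):
            for j in range(6):
                assert (a[i] == a[j]) == (b[i] == b[j])

    def test_affine_transform_invariance(self, rng):
        t = pd.DataFrame(rng.random((4, 6)))
        a = stats.cluster_enrichments(t)
        b = stats.cluster_enrichments(t * 3.0 + 7.0)
        assert a.tolist() == b.tolist()


class TestWidths:
    @pytest.mark.parametrize("w,expected", [(130, 200), (200, 200), (250, 400), (1, 200)])
    def test_ceiling(self, w, expected):
        assert stats.adjust_widths([w])[0] == expected

    def test_idempotent_and_monotone(self, rng):
        w = rng.integers(1, 5000, 200)
        adj = stats.adjust_widths(w)
        assert np.array_equal(stats.adjust_widths(adj), adj)
        order = np.argsort(w)
        assert np.all(np.diff(adj[order]) >= 0)

    def test_identical_samples_u_half(self):
        a = np.arange(1, 30, dtype=float) * 200
        res = stats.compare_width_distributions(a, a)
        assert res.u_statistic == pytest.approx(a.size * a.size / 2)
        assert res.p_value > 0.9

    def test_complete_separation(self):
        a = np.arange(1, 101, dtype=float) * 200
        b = np.arange(101, 201, dtype=float) * 200
        res = stats.compare_width_distributions(a, b)
        assert res.u_statistic in (0.0, a.size * b.size)
        assert res.p_value < 1e-15
        assert res.median_ratio == pytest.approx(np.median(b) / np.median(a))

    def test_symmetric_under_swap(self, rng):
        a = rng.integers(1, 50, 60) * 200.0
        b = rng.integers(1, 80, 70) * 200.0
        r1 = stats.compare_width_distributions(a, b)
        r2 = stats.compare_width_distributions(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)
        assert r1.u_statistic + r2.u_statistic == pytest.approx(a.size * b.size)


class TestChiSquared:
    def test_worked_example(self):
        res = stats.pearson_chi2([[10, 90], [30, 70]])
        assert res.statistic == pytest.approx(12.5)
        assert res.df == 1

    def test_identical_proportions_zero(self):
        res = stats.pearson_chi2([[20, 80], [40, 160]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            r, c = int(rng.integers(2, 6)), int(rng.integers(2, 5))
            obs = rng.integers(1, 60, size=(r, c)).astype(float)
            res = stats.pearson_chi2(obs)
            row = obs.sum(1, keepdims=True)
            col = obs.sum(0, keepdims=True)
            exp = row @ col / obs.sum()
            brute = ((obs - exp) ** 2 / exp).sum()
            assert res.statistic == pytest.approx(brute, rel=1e-12)
            assert res.df == (r - 1) * (c - 1)


class TestTeBimodal:
    def _c(self, s, e, chrom="y"):
        return Cher(chrom, s, e, 2, 1.0, 0.95, "s")

    def mini_genome(self, tes):
        chroms = pd.DataFrame(
            {"length": [100_000], "chrom_class": ["Y"]}, index=pd.Index(["y"], name="chrom")
        )
        genes = pd.DataFrame(
            columns=["chrom", "strand", "start", "end", "tss", "tes", "operon_id", "trans_spliced"]
        )
        genes.index.name = "gene_id"
        return tc.GenomeAnnotation(chroms, genes, tes)

    def test_enriched_order_has_positive_residual(self, rng):
        # order "DIRS" doubly likely to be bimodal by construction
        rows = []
        het, act = [], []
        pos = 0
        for i in range(300):
            order = "DIRS" if i < 100 else "LTR"
            rows.append(dict(chrom="y", start=pos, end=pos + 100, order=order))
            p = 0.6 if order == "DIRS" else 0.3
            if rng.random() < p:
                het.append(self._c(pos, pos + 50))
                act.append(self._c(pos + 50, pos + 100))
            pos += 200
        tes = pd.DataFrame(rows)
        res, table = stats.te_bimodal_test(tes, het, act, genome=self.mini_genome(tes))
        assert res.df == 1
        assert table.loc["DIRS", "std_residual"] > 0
        assert res.statistic > 3.84  # significant at 5%

    def test_requires_both_marks_for_bimodal(self):
        rows = [
            dict(chrom="y", start=0, end=100, order="DIRS"),
            dict(chrom="y", start=200, end=300, order="LTR"),
        ]
        tes = pd.DataFrame(rows * 3).reset_index(drop=True)
        het = [self._c(0, 50)]
        act = []  # no active mark -> nothing is bimodal -> degenerate table
        with pytest.raises(ValueError, match="degenerate"):
            stats.te_bimodal_test(tes, het, act, genome=self.mini_genome(tes))


class TestXaRatio:
    def test_scaling_and_symmetry(self):
        expr, cls = sim.simulate_dosage_expression(n_per_class=400, x_factor=2.0, sigma=0.0, seed=1)
        assert stats.xa_ratio(expr, cls) == pytest.approx(2.0)

    def test_downregulation_recovered(self):
        expr, cls = sim.simulate_dosage_expression(n_per_class=500, x_factor=0.5, seed=3)
        assert stats.xa_ratio(expr, cls) == pytest.approx(0.5, rel=0.10)

    def test_constitutive_subset(self):
        expr, cls = sim.simulate_dosage_expression(n_per_class=200, x_factor=1.0, seed=4)
        expr.iloc[0, 0] = 0.0  # no longer constitutive
        r = stats.xa_ratio(expr, cls, constitutive_only=True)
        assert np.isfinite(r)

    def test_empty_class_missing(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"])
        cls = pd.Series(["A", "A"], index=["g1", "g2"])
        assert np.isnan(stats.xa_ratio(expr, cls))

    def test_log_scale_option(self):
        expr, cls = sim.simulate_dosage_expression(n_per_class=300, x_factor=0.5, sigma=0.0, seed=5)
        assert stats.xa_ratio(expr, cls, log_scale=True) == pytest.approx(0.5)


class TestPausedPromoters:
    def _promoters(self, n):
        return pd.DataFrame(
            {"chrom": "c", "start": np.arange(n) * 1000, "end": np.arange(n) * 1000 + 400},
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )

    def test_no_rnapii_empty(self):
        genes, frac = stats.paused_promoter_genes([], ["g0", "g1"], self._promoters(2))
        assert genes == set() and frac == 0.0

    def test_full_cover_fraction_one(self):
        proms = self._promoters(3)
        chers = [Cher("c", 0, 3000, 10, 1.0, 0.95, "s")]
        genes, frac = stats.paused_promoter_genes(chers, [f"g{i}" for i in range(3)], proms)
        assert frac == 1.0

    def test_tissue_comparison_uses_pearson(self):
        res = stats.compare_paused_fractions(1106, 6912, 1389, 7717)
        brute = stats.pearson_chi2(
            [[1106, 6912 - 1106], [1389, 7717 - 1389]]
        ).statistic
        assert res.statistic == pytest.approx(brute)
        assert res.df == 1


class TestGoSubsets:
    def test_size_gates(self):
        genes = [f"g{i}" for i in range(120)]
        go = pd.DataFrame(
            {"gene_id": genes + genes[:30], "go_term": ["GO:A"] * 120 + ["GO:B"] * 30}
        )
        activity = {"ovary": {"active": set(genes[:60]), "silent": set(genes[60:65])}}
        subsets = stats.build_go_subsets(go, activity, min_parent_genes=50, min_subset_genes=10)
        keys = {(s.go_term, s.activity) for s in subsets}
        assert ("GO:A", "active") in keys  # 60 >= 10
        assert ("GO:A", "silent") not in keys  # 5 < 10
        assert not any(s.go_term == "GO:B" for s in subsets)  # parent < 50

    def test_promoter_enrichment_ratio(self):
        # all subset promoters inside state E1; E1 covers 10% of genome
        n_w = 200
        states = np.zeros(n_w, dtype=int)
        states[20:] = 1  # E1 = windows 0..19 (10%)
        chroms = pd.DataFrame(
            {"length": [n_w * 50], "chrom_class": ["A"]}, index=pd.Index(["c"], name="chrom")
        )
        rows = []
        for i in range(12):
            start = 400 + i * 40
            rows.append(
                dict(gene_id=f"g{i}", chrom="c", strand="+", start=start, end=start + 30,
                     tss=start, tes=start + 30, operon_id=None, trans_spliced=False)
            )
        genes = pd.DataFrame(rows).set_index("gene_id")
        ann = tc.GenomeAnnotation(
            chroms, genes, pd.DataFrame(columns=["chrom", "start", "end", "order"])
        )
        seg = Segmentation("ovary", 2, 50, {"c": states})
        subsets = [stats.GoSubset("GO:X", "ovary", "active", set(genes.index))]
        enr = stats.go_state_enrichment(subsets, {"ovary": seg}, ann, anchors=("promoter",))
        fold = enr.iloc[0]["E1"]
        # promoters all inside E1 -> fold = genome_windows / state_windows = 10
        assert fold == pytest.approx(10.0)
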