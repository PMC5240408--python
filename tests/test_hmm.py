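"""Bernoulli HMM: binarization grid, forward-backward correctness against
brute-force path enumeration, EM behaviour, enrichment arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest

import tilechrom as tc
from tilechrom import hmm, sim
from tilechrom.containers import BinaryMatrix, Cher, Segmentation
from tilechrom.hmm import (
    BernoulliHMM,
    _emission_loglik,
    _forward_backward,
    _scaled_b,
    binarize,
    fold_enrichment,
    match_states,
    state_coverage,
)


def brute_force_loglik(x, pi, a, e):
    """Exhaustive sum over all K^T paths."""
    t_len = x.shape[0]
    k = pi.size
    total = 0.0
    for path in itertools.product(range(k), repeat=t_len):
        p = pi[path[0]]
        for t in range(1, t_len):
            p *= a[path[t - 1], path[t]]
        for t, s in enumerate(path):
            p *= np.prod(e[s] ** x[t] * (1 - e[s]) ** (1 - x[t]))
        total += p
    return np.log(total)


def random_model(rng, k, m):
    pi = rng.dirichlet(np.ones(k))
    a = rng.dirichlet(np.ones(k), size=k)
    e = rng.uniform(0.05, 0.95, size=(k, m))
    return pi, a, e


def make_matrix(x, tissue="t", chrom="c", window=50, marks=None):
    x = np.asarray(x, dtype=np.uint8)
    marks = marks or [f"m{i}" for i in range(x.shape[1])]
    return BinaryMatrix(tissue=tissue, window_bp=window, mark_names=marks, data={chrom: x})


class TestBinarize:
    def _cher(self, chrom, s, e):
        return Cher(chrom, s, e, 2, 1.0, 0.95, "s")

    def test_overlap_sets_spanning_windows(self, small_genome):
        bm = binarize({"m": [self._cher("chr1", 120, 180)]}, small_genome, window_bp=50)
        col = bm.data["chr1"][:, 0]
        assert col[2] == 1 and col[3] == 1
        assert col[[0, 1, 4]].sum() == 0

    def test_half_open_boundary(self, small_genome):
        bm = binarize({"m": [self._cher("chr1", 50, 100)]}, small_genome, window_bp=50)
        col = bm.data["chr1"][:, 0]
        assert col[1] == 1 and col[0] == 0 and col[2] == 0

    def test_empty_chers_all_zero(self, small_genome):
        bm = binarize({"m": []}, small_genome, window_bp=50, mark_names=["m"])
        assert all(a.sum() == 0 for a in bm.data.values())

    def test_beyond_chromosome_end_raises(self, small_genome):
        L = int(small_genome.chromosomes.loc["chr1", "length"])
        with pytest.raises(ValueError):
            binarize({"m": [self._cher("chr1", 0, L + 10)]}, small_genome)


class TestForwardBackward:
    def test_likelihood_matches_path_enumeration(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 4))
            m = int(rng.integers(1, 4))
            t_len = int(rng.integers(1, 9))
            pi, a, e = random_model(rng, k, m)
            x = (rng.random((t_len, m)) < 0.5).astype(np.uint8)
            b, shift = _scaled_b(x, e)
            _, _, ll = _forward_backward(b, pi, a)
            expected = brute_force_loglik(x, pi, a, e)
            assert ll + shift == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_posteriors_sum_to_one(self, rng):
        pi, a, e = random_model(rng, 3, 4)
        x = (rng.random((200, 4)) < 0.4).astype(np.uint8)
        res = hmm.HMMResults(model=None, pi=pi, transitions=a, emissions=e,
                             mark_names=[f"m{i}" for i in range(4)])
        gamma = res.posterior(x)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


class TestLearn:
    def test_k1_fixed_point_is_marginal(self, rng):
        x = (rng.random((500, 3)) < [0.2, 0.5, 0.8]).astype(np.uint8)
        res = BernoulliHMM([make_matrix(x)], 1).fit(seed=0, n_restarts=1)
        assert np.allclose(res.emissions[0], x.mean(axis=0), atol=1e-9)
        assert res.transitions.shape == (1, 1) and res.transitions[0, 0] == 1.0
        # independent-Bernoulli log-likelihood
        p = np.clip(x.mean(axis=0), 1e-6, 1 - 1e-6)
        expected = float((x * np.log(p) + (1 - x) * np.log(1 - p)).sum())
        assert res.loglik == pytest.approx(expected, abs=1e-3)

    def test_em_loglik_nondecreasing_over_random_seeds(self, rng):
        for seed in range(30):
            x = (rng.random((80, 3)) < 0.5).astype(np.uint8)
            res = BernoulliHMM([make_matrix(x)], 2).fit(seed=seed, n_restarts=1, max_iter=25)
            gains = np.diff(res.train_log)
            assert gains.min() >= -1e-8

    def test_planted_two_state_recovery(self):
        cfg = tc.SimConfig(
            chrom_names=("c",), chrom_lengths=(200_000,), chrom_classes=("A",),
            n_states_true=2, n_marks=2,
            true_emissions=np.array([[1.0, 0.0], [0.0, 1.0]]), seed=9,
        )
        truth = sim.plant_states(cfg)
        bm = make_matrix(truth.mark_presence["c"], marks=list(cfg.mark_names))
        res = BernoulliHMM([bm], 2).fit(seed=0, n_restarts=2)
        perm, dist = match_states(cfg.true_emissions, res.emissions)
        assert np.abs(cfg.true_emissions - res.emissions[perm]).max() < 1e-3

    def test_input_validation(self):
        x = np.zeros((5, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            BernoulliHMM([make_matrix(np.zeros((0, 2)))], 2)
        with pytest.raises(ValueError):
            BernoulliHMM([make_matrix(x)], 10)
        with pytest.raises(ValueError):
            BernoulliHMM([], 2)


class TestSegment:
    def test_zero_noise_recovery_with_deterministic_emissions(self):
        cfg = tc.SimConfig(
            chrom_names=("c",), chrom_lengths=(100_000,), chrom_classes=("A",),
            n_states_true=3, n_marks=3, true_emissions=np.eye(3), seed=2,
        )
        truth = sim.plant_states(cfg)
        bm = make_matrix(truth.mark_presence["c"], marks=list(cfg.mark_names))
        res = hmm.HMMResults(
            model=None, pi=np.full(3, 1 / 3), transitions=cfg.true_transitions,
            emissions=np.eye(3), mark_names=list(cfg.mark_names),
        )
        seg = res.segment(bm)
        assert np.array_equal(seg.states["c"], truth.state_path["c"])

    def test_k1_posterior_one(self, rng):
        x = (rng.random((50, 2)) < 0.5).astype(np.uint8)
        res = BernoulliHMM([make_matrix(x)], 1).fit(seed=0, n_restarts=1)
        seg = res.segment(make_matrix(x))
        assert (seg.states["c"] == 0).all()
        assert np.allclose(seg.posterior["c"], 1.0)

    def test_uniform_model_ties_break_low(self):
        x = np.zeros((10, 2), dtype=np.uint8)
        res = hmm.HMMResults(
            model=None, pi=np.full(4, 0.25), transitions=np.full((4, 4), 0.25),
            emissions=np.full((4, 2), 0.5), mark_names=["m0", "m1"],
        )
        seg = res.segment(make_matrix(x, marks=["m0", "m1"]))
        assert (seg.states["c"] == 0).all()

    def test_mark_set_mismatch_raises(self, rng):
        x = (rng.random((20, 2)) < 0.5).astype(np.uint8)
        res = BernoulliHMM([make_matrix(x)], 2).fit(seed=0, n_restarts=1)
        other = make_matrix(x, marks=["a", "b"])
        with pytest.raises(ValueError):
            res.segment(other)


class TestCoverageAndEnrichment:
    def test_state_coverage_counts(self):
        seg = Segmentation("t", 2, 50, {"c": np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])})
        cov = state_coverage(seg)
        assert cov == pytest.approx([0.4, 0.6])

    def test_coverage_sums_to_one(self, rng):
        seg = Segmentation("t", 5, 50, {"c": rng.integers(0, 5, 300)})
        assert state_coverage(seg).sum() == pytest.approx(1.0)

    def _mini_genome(self, length=500):
        chroms = pd.DataFrame(
            {"length": [length], "chrom_class": ["A"]}, index=pd.Index(["c"], name="chrom")
        )
        genes = pd.DataFrame(
            columns=["chrom", "strand", "start", "end", "tss", "tes", "operon_id", "trans_spliced"]
        )
        genes.index.name = "gene_id"
        return tc.GenomeAnnotation(chroms, genes, pd.DataFrame(columns=["chrom", "start", "end", "order"]))

    def test_direct_counting_example(self):
        genome = self._mini_genome(500)  # 10 windows
        states = np.array([0] * 5 + [1] * 5)
        seg = Segmentation("t", 2, 50, {"c": states})
        feats = {"f": {"c": [(0, 100)]}}  # 2 windows inside state 0
        fold = fold_enrichment(seg, feats, genome)
        assert fold.loc["E1", "f"] == pytest.approx((2 / 5) / (2 / 10))
        assert fold.loc["E2", "f"] == 0.0

    def test_whole_genome_state_and_feature(self):
        genome = self._mini_genome(500)
        seg = Segmentation("t", 1, 50, {"c": np.zeros(10, dtype=int)})
        fold = fold_enrichment(seg, {"all": {"c": [(0, 500)]}, "half": {"c": [(0, 250)]}}, genome)
        assert fold.loc["E1", "all"] == pytest.approx(1.0)
        assert fold.loc["E1", "half"] == pytest.approx(1.0)

    def test_matches_per_window_counting_oracle(self, rng):
        for _ in range(40):
            n_w = int(rng.integers(4, 40))
            k = int(rng.integers(1, 4))
            genome = self._mini_genome(n_w * 50)
            states = rng.integers(0, k, n_w)
            seg = Segmentation("t", k, 50, {"c": states})
            s, e = sorted(rng.choice(n_w * 50, size=2, replace=False).tolist())
            fold = fold_enrichment(seg, {"f": {"c": [(s, e)]}}, genome)
            fwin = np.zeros(n_w, dtype=bool)
            for w in range(n_w):
                fwin[w] = (w * 50 < e) and ((w + 1) * 50 > s)
            for kk in range(k):
                nk = (states == kk).sum()
                if nk == 0:
                    assert np.isnan(fold.loc[f"E{kk + 1}", "f"])
                    continue
                expect = ((states == kk) & fwin).sum() / nk / (fwin.sum() / n_w)
                assert fold.loc[f"E{kk + 1}", "f"] == pytest.approx(expect)

    def test_out_of_bounds_feature_raises(self):
        genome = self._mini_genome(500)
        seg = Segmentation("t", 1, 50, {"c": np.zeros(10, dtype=int)})
        with pytest.raises(ValueError):
            fold_enrichment(seg, {"f": {"c": [(0, 600)]}}, genome)


class TestEmissionSummaryAndMatching:
    def test_threshold_rules(self):
        res = hmm.HMMResults(
            model=None, pi=np.array([0.5, 0.5]),
            transitions=np.array([[0.9, 0.1], [0.1, 0.9]]),
            emissions=np.array([[0.9, 0.4], [0.2, 0.3]]),
            mark_names=["mark1", "mark2"],
        )
        enr = pd.DataFrame({"f": [2.0, 1.5]}, index=["E1", "E2"])
        summ = hmm.emission_summary(res, enr)
        assert summ.loc["E1", "main_marks"] == "mark1"
        assert summ.loc["E2", "main_marks"] == ""  # weak-signal state
        assert summ.loc["E1", "assigned_features"] == "f"  # >= 2 inclusive
        assert summ.loc["E2", "assigned_features"] == ""

    def test_match_identity_and_permutation(self, rng):
        e = rng.uniform(0, 1, size=(4, 6))
        perm, d = match_states(e, e)
        assert np.array_equal(perm, np.arange(4)) and d == 0.0
        p = np.array([2, 0, 3, 1])
        perm, d = match_states(e, e[p])
        assert d == 0.0
        assert np.array_equal(p[perm], np.arange(4))  # inverse recovered

    def test_independent_refits_agree(self):
        cfg = tc.SimConfig(seed=13)
        truth = sim.plant_states(cfg)
        bm = make_matrix(truth.mark_presence["chr1"], marks=list(cfg.mark_names))
        r1 = BernoulliHMM([bm], 5).fit(seed=1, n_restarts=2)
        r2 = BernoulliHMM([bm], 5).fit(seed=101, n_restarts=2)
        _, d = match_states(r1, r2)
        assert d < 0.1


def test_joint_learning_across_tissues(rng):
    """Two tissues sharing one parameter set: both matrices contribute."""
    cfg = tc.SimConfig(
        chrom_names=("c",), chrom_lengths=(100_000,), chrom_classes=("A",),
        n_states_true=2, n_marks=3, seed=21,
    )
    t0 = sim.plant_states(cfg, tissue_index=0)
    t1 = sim.plant_states(cfg, tissue_index=1)
    m0 = make_matrix(t0.mark_presence["c"], tissue="ovary", marks=list(cfg.mark_names))
    m1 = make_matrix(t1.mark_presence["c"], tissue="testis", marks=list(cfg.mark_names))
    res = BernoulliHMM([m0, m1], 2).fit(seed=0, n_restarts=2)
    perm, d = match_states(cfg.true_emissions, res.emissions)
    assert d < 0.05
    seg0, seg1 = res.segment(m0), res.segment(m1)
    assert seg0.tissue == "ovary" and seg1.tissue == "testis"


def test_summary_and_json_round_trip(rng):
    x = (rng.random((300, 3)) < 0.4).astype(np.uint8)
    res = BernoulliHMM([make_matrix(x)], 2).fit(seed=0, n_restarts=1)
    text = res.summary()
    assert "K=2" in text and "Emission probabilities" in text
    back = hmm.HMMResults.from_json(res.to_json())
    assert np.allclose(back.emissions, res.emissions)
    assert np.allclose(back.transitions, res.transitions)
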