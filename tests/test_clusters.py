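"""Maximal segments, Karlin-Altschul statistics, permutation null."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tssclust as tc
from tssclust.block import CoordinateMap
from tssclust.clusters import Segment
from tssclust.motifs import ColumnScores


def brute_force_maximal_segments(x, g):
    """Independent oracle: enumerate all segments, apply the maximality
    characterization (strict cumulative min at the left endpoint, strict
    max at the right, not contained in a longer such segment)."""
    y = np.asarray(x, dtype=float) - g
    n = len(y)
    c = np.concatenate([[0.0], np.cumsum(y)])
    cands = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            inner = c[i:j + 1]
            if c[i] < inner[1:].min() and c[j] > inner[:-1].max():
                cands.append((i, j, c[j] - c[i]))
    keep = []
    for i, j, s in cands:
        if not any((a <= i and j <= b) and (b - a > j - i)
                   for a, b, _ in cands):
            keep.append((i, j, s))
    return sorted(keep)


def make_scores(x, hit_cols=(), hit_scores=(), strand="+"):
    return ColumnScores(
        "TF", strand, 1, np.asarray(x, dtype=float),
        np.zeros(len(hit_cols), dtype=np.int64),
        np.asarray(hit_cols, dtype=np.int64),
        np.asarray(hit_scores, dtype=float),
    )


class TestGapPenalty:
    def test_arithmetic(self):
        assert tc.gap_penalty([1, 1, 1, 1], 1.4) == pytest.approx(1.4)

    def test_rho_one_is_mean(self):
        x = np.array([0.0, 2.0, 4.0, 2.0])
        assert tc.gap_penalty(x, 1.0) == pytest.approx(x.mean())

    @given(st.floats(min_value=0.1, max_value=10))
    def test_homogeneous_in_scale(self, c):
        x = np.array([1.0, 0.0, 3.0])
        assert tc.gap_penalty(c * x, 1.4) == pytest.approx(c * tc.gap_penalty(x, 1.4))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tc.gap_penalty(np.zeros(5), 1.4)


class TestRuzzoTompa:
    def test_join_beats_parts(self):
        # (0,4] scores 4-1-1+3 = 5, more than either part alone
        segs = tc.ruzzo_tompa(np.array([5.0, 0, 0, 4]), 1.0)
        assert segs == [Segment(0, 4, pytest.approx(5.0))]

    def test_all_below_gap_empty(self):
        assert tc.ruzzo_tompa(np.array([0.5, 0.9, 0.0]), 1.0) == []

    def test_interior_segment(self):
        segs = tc.ruzzo_tompa(np.array([0.0, 3, 3, 0]), 1.0)
        assert segs == [Segment(1, 3, pytest.approx(4.0))]

    def test_zero_extensions_excluded(self):
        # trailing element exactly cancels the gap: extending through it
        # leaves the score unchanged, so the shorter segment is reported
        segs = tc.ruzzo_tompa(np.array([3.0, 1.0]), 1.0)
        assert [(s.start, s.stop) for s in segs] == [(0, 1)]

    def test_merge_across_break_even_gap(self):
        # a zero increment inside a profitable join does not split it
        segs = tc.ruzzo_tompa(np.array([3.0, 1.0, 3.0]), 1.0)
        assert segs == [Segment(0, 3, pytest.approx(4.0))]

    @given(st.lists(st.floats(min_value=0, max_value=5, allow_nan=False),
                    min_size=1, max_size=50),
           st.floats(min_value=0.1, max_value=3))
    def test_matches_brute_force(self, x, g):
        x = np.asarray(x)
        got = sorted((s.start, s.stop, s.score) for s in tc.ruzzo_tompa(x, g))
        expected = brute_force_maximal_segments(x, g)
        assert [(i, j) for i, j, _ in got] == [(i, j) for i, j, _ in expected]
        for (_, _, a), (_, _, b) in zip(got, expected):
            assert a == pytest.approx(b, abs=1e-9)

    def test_segment_scores_recompute(self):
        rng = np.random.default_rng(5)
        x = rng.exponential(1.0, size=200)
        g = 1.4 * x.mean()
        for s in tc.ruzzo_tompa(x, g):
            assert s.score == pytest.approx((x[s.start:s.stop] - g).sum())
            assert s.score > 0


class TestKarlinLambda:
    @pytest.mark.parametrize("p, n", [(0.25, 16), (0.125, 16), (0.4, 20)])
    def test_two_point_closed_form(self, p, n):
        g = 2.0
        k = int(p * n)
        x = np.array([g + 1.0] * k + [g - 1.0] * (n - k))
        params = tc.karlin_lambda(x, g)
        assert params.lam == pytest.approx(np.log((1 - p) / p), abs=1e-6)

    def test_moment_equation_satisfied(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(1.0, size=500)
        g = 1.4 * x.mean()
        params = tc.karlin_lambda(x, g)
        assert np.mean(np.exp(params.lam * (x - g))) == pytest.approx(1.0,
                                                                     abs=1e-9)

    def test_nonnegative_drift_rejected(self):
        x = np.array([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="logarithmic"):
            tc.karlin_lambda(x, 1.0)  # mean(x-g) = 1 >= 0

    def test_no_positive_excursion_rejected(self):
        with pytest.raises(ValueError, match="excursion"):
            tc.karlin_lambda(np.array([0.0, 0.5]), 1.0)

    def test_scale_equivariance(self):
        x = np.array([3.0, 0, 0, 0, 1.0, 0, 0, 0])
        g = 1.0
        lam = tc.karlin_lambda(x, g).lam
        lam2 = tc.karlin_lambda(2 * x, 2 * g).lam
        assert lam2 == pytest.approx(lam / 2, rel=1e-9)


class TestClusterPvalue:
    def test_monotone_decreasing_and_limits(self):
        params = tc.KarlinParams(lam=1.0, n=1000, g=1.0)
        ps = [tc.cluster_pvalue(s, params) for s in (1, 5, 10, 50, 200)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-60

    def test_half_at_log2_point(self):
        params = tc.KarlinParams(lam=1.0, n=100, g=1.0)
        s = (np.log(100) - np.log(np.log(2))) / 1.0
        assert tc.cluster_pvalue(s, params, K=1.0) == pytest.approx(0.5)


class TestPermutationPvalue:
    def test_zero_observed_is_one(self):
        cs = make_scores(np.zeros(50), [3, 7], [1.0, 1.0])
        assert tc.permutation_pvalue(cs, 0.5, 0.0, 99, seed=1) == 1.0

    def test_no_hits_is_one(self):
        cs = make_scores(np.zeros(50))
        assert tc.permutation_pvalue(cs, 0.5, 1.0, 99, seed=1) == 1.0

    def test_add_one_rule_far_above_null(self):
        # one huge hit: every replicate max equals the observed score only
        # when the single hit lands anywhere -> always ties; use many tiny
        # hits plus an observed score no replicate can reach
        rng = np.random.default_rng(2)
        scores = rng.exponential(0.2, size=60)
        cs = make_scores(np.zeros(500), np.arange(60), scores)
        p = tc.permutation_pvalue(cs, 0.5, observed_max_score=1e9,
                                  n_perm=99, seed=3)
        assert p == pytest.approx(1 / 100)

    def test_reproducible(self):
        rng = np.random.default_rng(4)
        scores = rng.exponential(1.0, size=40)
        cs = make_scores(np.zeros(300), np.arange(40), scores)
        a = tc.permutation_pvalue(cs, 0.8, 3.0, 49, seed=9)
        b = tc.permutation_pvalue(cs, 0.8, 3.0, 49, seed=9)
        assert a == b


class TestDescribeCluster:
    def test_multiple_motifs_fraction(self):
        cmap = CoordinateMap(tss_col=10, length=40)
        # one sequence contributes 3 motifs -> 2 multiple motifs
        cs = ColumnScores("TF", "+", 1, np.zeros(40),
                          np.array([0, 0, 0]), np.array([12, 13, 14]),
                          np.array([1.0, 1.0, 1.0]))
        c = tc.describe_cluster(Segment(12, 15, 3.0), cs, cmap)
        assert c.pct_multiple_motifs == pytest.approx(2 / 3)
        assert c.n_hits == 3

    def test_no_multiples_when_one_each(self):
        cmap = CoordinateMap(tss_col=10, length=40)
        cs = ColumnScores("TF", "+", 1, np.zeros(40),
                          np.array([0, 1, 2]), np.array([12, 13, 14]),
                          np.array([1.0, 1.0, 1.0]))
        c = tc.describe_cluster(Segment(12, 15, 3.0), cs, cmap)
        assert c.pct_multiple_motifs == 0.0

    def test_spread_from_bp_coordinates(self):
        # From -78, To -36 -> spread 43 columns
        cmap = CoordinateMap(tss_col=2000, length=3001)
        start, stop = cmap.coord_to_col(-78), cmap.coord_to_col(-36) + 1
        cs = ColumnScores("SP1", "+", 1, np.zeros(3001),
                          np.array([], dtype=int), np.array([], dtype=int),
                          np.array([]))
        c = tc.describe_cluster(Segment(start, stop, 5.0), cs, cmap)
        assert (c.from_bp, c.to_bp) == (-78, -36)
        assert c.spread == 43 == c.to_bp - c.from_bp + 1

    def test_empty_segment_rejected(self):
        cmap = CoordinateMap(tss_col=10, length=40)
        cs = ColumnScores("TF", "+", 1, np.zeros(40),
                          np.array([], dtype=int), np.array([], dtype=int),
                          np.array([]))
        with pytest.raises(ValueError):
            tc.describe_cluster(Segment(5, 5, 1.0), cs, cmap)

    def test_key_grammar_round_trip(self):
        cmap = CoordinateMap(tss_col=10, length=40)
        cs = ColumnScores("NFKB1", "-", 1, np.zeros(40),
                          np.array([0]), np.array([16]), np.array([2.0]))
        c = tc.describe_cluster(Segment(16, 21, 2.0), cs, cmap)
        assert c.key == "NFKB1:+7:+11:-"
        assert tc.Cluster.parse_key(c.key) == ("NFKB1", 7, 11, "-")


class TestDetectClusters:
    def test_rank_agreement_with_permutation(self, planted_study):
        """Karlin and permutation p-values order candidate segments alike."""
        from scipy.stats import spearmanr
        block = planted_study.block
        bg = tc.fit_background(block)
        cmap = block.coords
        rows = []
        for member in planted_study.rm_spec.members:
            pssm = tc.counts_to_pssm(member.matrix)
            sc = tc.scan_block(block, pssm, bg, "+")
            found, params = tc.detect_clusters(sc, cmap)
            g = params.g
            for c in found[:6]:
                perm = tc.permutation_pvalue(sc, g, c.score, 99, seed=5)
                rows.append((c.p_value, perm))
        if len(rows) >= 4:
            rho = spearmanr([r[0] for r in rows], [r[1] for r in rows]).statistic
            assert rho >= 0.9

    def test_empty_scores_yield_nothing(self):
        cmap = CoordinateMap(tss_col=10, length=40)
        cs = make_scores(np.zeros(40))
        clusters, params = tc.detect_clusters(cs, cmap)
        assert clusters == [] and params is None
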