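"""Mini-Rank-Norm boundary search: thresholds, ranking, optimal selection."""

import numpy as np
import pytest
from scipy.stats import norm

from conftest import toy_model
from helpers import brute_force_optimal, random_window, track_from_se
from parclipper.errors import MrnError
from parclipper.ingest import CoverageTrack
from parclipper.model import TransitionSite
from parclipper.mrn import (
    MrnConfig,
    call_clusters,
    enumerate_candidates,
    estimate_noise,
    fit_noise,
    global_threshold,
    local_threshold,
    nonzero_window,
    rank_candidates,
    select_optimal,
)


def make_track(C, S=None, E=None, chrom="chr1", strand="+"):
    C = np.asarray(C, dtype=np.int64)
    S = np.zeros_like(C) if S is None else np.asarray(S, dtype=np.int64)
    E = np.zeros_like(C) if E is None else np.asarray(E, dtype=np.int64)
    return CoverageTrack(chrom=chrom, strand=strand, C=C, S=S, E=E)


class TestNonzeroWindow:
    def test_run_extraction(self):
        t = make_track([0, 1, 2, 2, 1, 0])
        assert nonzero_window(t, 2) == (1, 4)

    def test_whole_track(self):
        t = make_track([1, 2, 3, 2, 1])
        assert nonzero_window(t, 0) == (0, 4)

    def test_singleton(self):
        t = make_track([0, 0, 1, 0])
        assert nonzero_window(t, 2) == (2, 2)

    def test_uncovered_position_raises(self):
        t = make_track([0, 1, 0])
        with pytest.raises(MrnError):
            nonzero_window(t, 0)


class TestNoise:
    def test_crossover_on_planted_gaussians(self):
        """50/50 draws from N(0.05, 0.01^2) and N(0.8, 0.1^2): the fitted
        crossover sits in [0.2, 0.5], above the analytic responsibility
        crossover of the true mixture, and is stable across seeds."""

        def analytic_crossover():
            xs = np.linspace(0.01, 0.99, 4901)
            r = 0.5 * norm.pdf(xs, 0.8, 0.1) - 0.5 * norm.pdf(xs, 0.05, 0.01)
            return xs[np.argmax(r >= 0)]

        cross = analytic_crossover()
        cs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d = np.concatenate(
                [rng.normal(0.05, 0.01, 5000), rng.normal(0.8, 0.1, 5000)]
            )
            noise = fit_noise(np.clip(d, 1e-4, 1.0))
            assert noise.mu1 < noise.mu2
            assert noise.c >= cross
            assert 0.2 <= noise.c <= 0.5
            cs.append(noise.c)
        assert max(cs) - min(cs) <= 0.1

    def test_single_tight_gaussian_degenerate(self):
        rng = np.random.default_rng(0)
        d = np.abs(rng.normal(0.5, 0.01, 2000))
        with pytest.raises(MrnError, match="degenerate"):
            fit_noise(d)

    def test_insufficient_data(self):
        with pytest.raises(MrnError, match="insufficient"):
            fit_noise([0.5] * 5)

    def test_estimate_noise_uses_all_hcts_when_few(self):
        """|hcTs| < N: every hcT window contributes, no resampling."""
        rng = np.random.default_rng(1)
        n = 400
        S = rng.poisson(0.5, n)
        E = rng.poisson(0.5, n)
        hcts = []
        for pos in range(20, n - 20, 40):
            S[pos - 5] += 12
            E[pos + 5] += 12
            hcts.append(TransitionSite("chr1", "+", pos, y=5, z=20))
        tracks = {("chr1", "+"): make_track(np.ones(n), S, E)}
        noise = estimate_noise(tracks, hcts, MrnConfig(n_sample=1000, seed=0))
        assert 0 < noise.c <= 1
        # seeded determinism
        again = estimate_noise(tracks, hcts, MrnConfig(n_sample=1000, seed=0))
        assert again.c == noise.c


class TestThresholds:
    def test_local_threshold_formula(self):
        noise = type("N", (), {"c": 0.3})()
        S = np.zeros(20, dtype=np.int64)
        E = np.zeros(20, dtype=np.int64)
        S[4] = 10
        E[15] = 20
        t = make_track(np.ones(20), S, E)
        assert local_threshold(noise, t, (0, 19)) == (3, 6)

    def test_local_threshold_clamps_to_one(self):
        noise = type("N", (), {"c": 0.05})()
        t = make_track(np.ones(10), np.ones(10), np.ones(10))
        assert local_threshold(noise, t, (0, 9)) == (1, 1)

    def test_local_threshold_c_one_keeps_maxima_only(self):
        noise = type("N", (), {"c": 1.0})()
        S = np.array([3, 7, 2, 0, 0, 0], dtype=np.int64)
        E = np.array([0, 0, 0, 1, 5, 2], dtype=np.int64)
        t = make_track(np.ones(6), S, E)
        ds, de = local_threshold(noise, t, (0, 5))
        assert ds == 7 and de == 5
        cands = enumerate_candidates(t, 2, (0, 5), ds, de)
        assert {(c.k, c.l) for c in cands} == {(1, 4)}

    @pytest.mark.parametrize(
        "m1,m2,expected", [(20, 47, 4), (100, 20, 10), (5, 5, 1)]
    )
    def test_global_threshold(self, m1, m2, expected):
        assert global_threshold(m1, m2) == expected


def spec_toy():
    """The worked boundary example: S=[5,0,0,3,...], E=[...,2,0,0,4,0]."""
    S = np.array([5, 0, 0, 3, 0, 0, 0, 0, 0, 0], dtype=np.int64)
    E = np.array([0, 0, 0, 0, 0, 2, 0, 0, 4, 0], dtype=np.int64)
    return make_track(np.ones(10), S, E)


class TestEnumerate:
    def test_toy_enumeration(self):
        cands = enumerate_candidates(spec_toy(), 4, (0, 9), 2, 2)
        assert {(c.k, c.l) for c in cands} == {(0, 5), (0, 8), (3, 5), (3, 8)}
        assert sorted(c.width for c in cands) == [3, 6, 6, 9]

    def test_fallback_to_window_edges(self):
        cands = enumerate_candidates(spec_toy(), 4, (0, 9), 99, 99)
        assert [(c.k, c.l) for c in cands] == [(0, 9)]

    def test_hct_can_be_both_boundaries(self):
        S = np.zeros(9, dtype=np.int64)
        E = np.zeros(9, dtype=np.int64)
        S[4] = 5
        E[4] = 5
        t = make_track(np.ones(9), S, E)
        cands = enumerate_candidates(t, 4, (0, 8), 2, 2)
        assert {(c.k, c.l) for c in cands} == {(4, 4)}
        assert cands[0].width == 1


class TestRankAndSelect:
    def test_toy_rank_vectors(self):
        cands = enumerate_candidates(spec_toy(), 4, (0, 9), 2, 2)
        rank_candidates(cands)
        vectors = {(c.k, c.l): c.rank_vector for c in cands}
        assert vectors == {
            (0, 5): (0, 1, 1),
            (0, 8): (0, 0, 3),
            (3, 5): (1, 1, 0),
            (3, 8): (1, 0, 1),
        }

    def test_toy_selection_prefers_shortest_among_norm_ties(self):
        cands = rank_candidates(enumerate_candidates(spec_toy(), 4, (0, 9), 2, 2))
        assert sorted(c.norm2 for c in cands) == [2, 2, 2, 9]
        best = select_optimal(cands)
        assert (best.k, best.l) == (3, 5)

    def test_single_candidate_is_origin(self):
        cands = rank_candidates(enumerate_candidates(spec_toy(), 4, (0, 9), 99, 99))
        assert cands[0].rank_vector == (0, 0, 0)
        assert select_optimal(cands).rank_vector == (0, 0, 0)

    def test_start_ties_ranked_five_prime_first(self):
        S = np.array([4, 0, 4, 0, 0], dtype=np.int64)
        E = np.array([0, 0, 0, 0, 4], dtype=np.int64)
        t = make_track(np.ones(5), S, E)
        cands = rank_candidates(enumerate_candidates(t, 3, (0, 4), 2, 2))
        ranks = {c.k: c.r_s for c in cands}
        assert ranks == {0: 0, 2: 1}

    def test_origin_vector_always_wins(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            S, E, i_t, ds, de = random_window(rng)
            S[max(0, i_t - 1)] = 100
            E[min(len(E) - 1, i_t + 1)] = 100
            t = track_from_se(S, E)
            cands = rank_candidates(
                enumerate_candidates(t, i_t, (0, len(S) - 1), ds, de)
            )
            best = select_optimal(cands)
            origin = [c for c in cands if c.rank_vector == (0, 0, 0)]
            if origin:
                assert best is origin[0]

    def test_lower_rank_beats_higher_at_same_positions(self):
        # a (0,1,0)-style vector always beats (0,2,0) at equal width
        from parclipper.mrn import CandidateCluster

        a = CandidateCluster(k=0, l=9, n_s=5, n_e=4)
        b = CandidateCluster(k=0, l=9, n_s=5, n_e=2)
        a.r_s, a.r_e, a.r_w = 0, 1, 0
        b.r_s, b.r_e, b.r_w = 0, 2, 0
        assert select_optimal([a, b]) is a


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_windows(self):
        """Library selection equals exhaustive minimization with the stated
        tie rules on 600 random windows, exactly."""
        rng = np.random.default_rng(123)
        for _ in range(600):
            S, E, i_t, ds, de = random_window(rng)
            t = track_from_se(S, E)
            cands = rank_candidates(
                enumerate_candidates(t, i_t, (0, len(S) - 1), ds, de)
            )
            best = select_optimal(cands)
            assert (best.k, best.l) == brute_force_optimal(S, E, i_t, ds, de)


def rectangular_peak(track_len, start, end, depth, rng=None):
    """S/E/C tracks of a rectangle of `depth` reads spanning [start, end]."""
    C = np.zeros(track_len, dtype=np.int64)
    S = np.zeros(track_len, dtype=np.int64)
    E = np.zeros(track_len, dtype=np.int64)
    C[start : end + 1] = depth
    S[start] = depth
    E[end] = depth
    return C, S, E


class TestCallClusters:
    def _genome(self, n=400):
        rng = np.random.default_rng(0)
        return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))}

    def _scored(self, pos, y=10, z=40):
        s = TransitionSite("chr1", "+", pos, y=y, z=z)
        s.posterior2, s.log_odds = 0.99, 3.0
        return s

    def test_two_hcts_one_peak_merge(self):
        C, S, E = rectangular_peak(400, 100, 129, 50)
        tracks = {("chr1", "+"): make_track(C, S, E)}
        hcts = [self._scored(110), self._scored(120)]
        cfg = MrnConfig(threshold_mode="global", m1=20, m2=50)
        clusters = call_clusters(tracks, hcts, None, self._genome(), cfg)
        assert len(clusters) == 1
        cl = clusters[0]
        assert (cl.start, cl.end) == (100, 130)
        assert len(cl.hcts) == 2
        assert cl.rel_log_odds == pytest.approx(6.0 / cl.n_crosslinkable)

    def test_empty_hcts(self):
        assert call_clusters({}, [], None, self._genome(), MrnConfig()) == []

    def test_adjacent_peaks_resolved_separately(self):
        """Two rectangles separated by a shallow valley come out as two
        clusters, not one."""
        C = np.zeros(400, dtype=np.int64)
        S = np.zeros(400, dtype=np.int64)
        E = np.zeros(400, dtype=np.int64)
        # peak 1: [100,129], peak 2: [140,169], valley covered by 2 reads
        C[100:170] += 2
        S[98] = 2
        E[171] = 2
        C[100:130] += 48
        S[100] = 48
        E[129] = 48
        C[140:170] += 48
        S[140] = 48
        E[169] = 48
        C[98:172] += 0
        C[98] = C[99] = C[170] = C[171] = 2
        tracks = {("chr1", "+"): make_track(C, S, E)}
        hcts = [self._scored(110), self._scored(150)]
        cfg = MrnConfig(threshold_mode="global", m1=20, m2=50)
        clusters = call_clusters(tracks, hcts, None, self._genome(), cfg)
        intervals = sorted((c.start, c.end) for c in clusters)
        assert intervals == [(100, 130), (140, 170)]

    def test_every_hct_assigned_exactly_once(self):
        C, S, E = rectangular_peak(400, 50, 89, 30)
        C2, S2, E2 = rectangular_peak(400, 200, 239, 30)
        tracks = {("chr1", "+"): make_track(C + C2, S + S2, E + E2)}
        hcts = [self._scored(60), self._scored(70), self._scored(210)]
        cfg = MrnConfig(threshold_mode="global", m1=20, m2=30)
        clusters = call_clusters(tracks, hcts, None, self._genome(), cfg)
        assigned = [id(h) for cl in clusters for h in cl.hcts]
        assert sorted(assigned) == sorted(id(h) for h in hcts)
        assert all(
            cl.start <= h.pos < cl.end for cl in clusters for h in cl.hcts
        )

    def test_determinism(self):
        C, S, E = rectangular_peak(400, 100, 129, 50)
        tracks = {("chr1", "+"): make_track(C, S, E)}
        genome = self._genome()
        cfg = MrnConfig(threshold_mode="global", m1=20, m2=50, seed=3)
        out1 = call_clusters(tracks, [self._scored(110)], None, genome, cfg)
        out2 = call_clusters(tracks, [self._scored(110)], None, genome, cfg)
        assert [(c.start, c.end, c.rel_log_odds) for c in out1] == [
            (c.start, c.end, c.rel_log_odds) for c in out2
        ]
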