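import math
from fractions import Fraction

import numpy as np
import pytest

from scaledmr import (
    CallerConfig,
    call_dmrs,
    scan_layer,
    score_region,
    adjust_and_select,
    merge_adjacent,
    integrate_layers,
)
from scaledmr.core import (
    ScoredWindow,
    _by_harmonic,
    _gamma_logsf_int,
    _hyper_logsf,
    _score_rank_rows,
    _sequential_log_product,
)

from conftest import make_probes, make_track


def exact_chain_product(ranks, n_total):
    """Independent exact-rational recomputation of the sequential product."""
    ranks = sorted(ranks)[1:]  # exclude the most significant member
    m = len(ranks)
    if m == 0:
        return Fraction(1)
    members = ranks[::-1]  # least -> most significant
    prod = Fraction(1)
    k_prev = None
    K_prev = None
    for i, K in enumerate(members):
        k = sum(1 for r in members if r <= K)
        n = m if i == 0 else k_prev - 1
        N = n_total if i == 0 else K_prev - 1
        succ = min(K, N)
        k_eff = min(k, n, succ)
        # upper-tail hypergeometric as an exact rational
        tail = Fraction(0)
        for x in range(k_eff, min(n, succ) + 1):
            tail += Fraction(math.comb(succ, x) * math.comb(N - succ, n - x), math.comb(N, n))
        prod *= tail
        k_prev, K_prev = k, K
    return prod


class TestScoreRegion:
    def test_single_member_scores_one(self):
        assert score_region([7], 1000) == 1.0
        assert score_region([], 1000) == 1.0

    def test_two_member_region_is_single_tail(self):
        # ranks {1,2}, N=10: P(X>=1) with 1 draw, 2 successes in 10 -> 0.2
        assert score_region([1, 2], 10) == pytest.approx(0.2, rel=1e-12)

    def test_raw_product_three_members(self):
        # C(50,2)/C(100,2) * 5/49
        expected = (1225 / 4950) * (5 / 49)
        assert score_region([1, 5, 50], 100, calibrate=False) == pytest.approx(
            expected, rel=1e-12
        )

    def test_raw_product_matches_exact_rational(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(3, 200))
            m = int(rng.integers(1, min(7, N)))
            ranks = sorted(rng.choice(np.arange(1, N + 1), size=m, replace=False))
            got = score_region(ranks, N, calibrate=False)
            want = float(exact_chain_product(ranks, N))
            assert got == pytest.approx(want, rel=1e-11)

    def test_invalid_ranks_rejected(self):
        with pytest.raises(ValueError):
            score_region([0, 5], 100)
        with pytest.raises(ValueError):
            score_region([5, 200], 100)
        with pytest.raises(ValueError, match="inconsistent"):
            score_region([1, 1, 1], 100)

    def test_extreme_region_never_underflows_to_zero(self):
        p = score_region(list(range(1, 200)), 500000)
        assert p > 0.0

    def test_tied_block_reduces_to_single_tail(self):
        # all members tied at rank K: only the first factor is informative,
        # so the calibrated score equals the raw product
        N, K = 5000, 120
        raw = score_region([K] * 5, N, calibrate=False)
        cal = score_region([K] * 5, N)
        assert cal <= 2 * raw + 1e-15  # combination factor only


class TestFastTails:
    def test_hyper_logsf_matches_scipy(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(2)
        N = rng.integers(5, 3000, 2000)
        K = np.array([rng.integers(0, x + 1) for x in N])
        n = np.array([rng.integers(1, x + 1) for x in N])
        k = np.array([rng.integers(0, min(a, b) + 2) for a, b in zip(K, n)])
        mine = _hyper_logsf(k, N, K, n)
        ref = hypergeom.logsf(k - 1, N, K, n)
        both_inf = np.isinf(mine) & np.isinf(ref)
        np.testing.assert_allclose(mine[~both_inf], ref[~both_inf], rtol=1e-9)

    def test_gamma_tail_matches_scipy(self):
        from scipy.stats import gamma as gamma_dist

        x = np.array([0.5, 3.0, 10.0, 50.0, 200.0])
        for m in (1, 2, 5, 20):
            ref = gamma_dist.logsf(x, m)
            got = _gamma_logsf_int(np.full(x.size, m), x)
            np.testing.assert_allclose(got, ref, rtol=1e-10, atol=1e-14)


class TestScanLayer:
    def test_window_count_before_significance_filter(self):
        probes = make_probes(10)
        track = make_track(np.full(10, 1e-6))
        ws = scan_layer(track, probes, 4, locs_pval_cutoff=1e-3)
        assert len(ws) == 7  # stride-1 placements on 10 probes

    def test_no_subthreshold_probe_no_candidates(self):
        probes = make_probes(50)
        track = make_track(np.linspace(0.2, 1.0, 50))
        assert scan_layer(track, probes, 4, locs_pval_cutoff=1e-3) == []

    def test_short_chromosome_skipped(self):
        probes = make_probes(3)
        track = make_track(np.full(3, 1e-6))
        assert scan_layer(track, probes, 4, locs_pval_cutoff=1e-3) == []

    def test_top_ranked_block_attains_minimal_window_score(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.01, 1.0, 50)
        p[20:24] = [1e-9, 2e-9, 3e-9, 4e-9]  # ranks 1..4 in one window
        probes = make_probes(50)
        track = make_track(p)
        ws = scan_layer(track, probes, 4, locs_pval_cutoff=0.5)
        best = min(ws, key=lambda w: w.p_region)
        assert (best.idx_first, best.idx_last) == (20, 23)


class TestAdjustAndSelect:
    def _win(self, p):
        return ScoredWindow("chr1", 0, 3, p, math.log(p))

    def test_bonferroni_arithmetic(self):
        cfg = CallerConfig(correction="bonferroni")
        sel = adjust_and_select([self._win(1e-6)], cfg, n_tests=1000)
        assert len(sel) == 1
        assert sel[0].p_adjusted == pytest.approx(1e-3)

    def test_large_p_never_retained(self):
        for corr in ("bonferroni", "benjamini-yekutieli"):
            cfg = CallerConfig(correction=corr)
            assert adjust_and_select([self._win(0.5)], cfg, n_tests=10) == []

    def test_by_step_up_with_placeholder_tests(self):
        # candidates (1e-8, 1e-8, 0.5) against n_tests=100: the BY factor is
        # 100 * H_100; first two pass at 0.01, third does not
        cfg = CallerConfig(correction="benjamini-yekutieli")
        wins = [self._win(1e-8), self._win(1e-8), self._win(0.5)]
        sel = adjust_and_select(wins, cfg, n_tests=100)
        assert len(sel) == 2
        expected = 100 * _by_harmonic(100) * 1e-8 / 2
        assert sel[0].p_adjusted == pytest.approx(expected, rel=1e-9)

    def test_zero_tests_selects_nothing(self):
        cfg = CallerConfig()
        assert adjust_and_select([self._win(1e-12)], cfg, n_tests=0) == []


class TestMergeAdjacent:
    def _setup(self, n=60):
        probes = make_probes(n)
        p = np.full(n, 0.9)
        p[:40] = 1e-8  # everything significant in the merge zone
        return probes, make_track(p)

    def test_overlapping_and_abutting_windows_union(self):
        probes, track = self._setup()
        cfg = CallerConfig()
        wins = [
            ScoredWindow("chr1", 0, 3, 1e-9, -20.7),
            ScoredWindow("chr1", 2, 5, 1e-9, -20.7),
            ScoredWindow("chr1", 6, 9, 1e-9, -20.7),  # abuts [2,5]
            ScoredWindow("chr1", 15, 18, 1e-9, -20.7),  # separate
        ]
        dmrs = merge_adjacent(wins, track, probes, 1, 100, cfg)
        assert [(d.idx_first, d.idx_last) for d in dmrs] == [(0, 9), (15, 18)]

    def test_gap_of_one_probe_keeps_regions_apart(self):
        probes, track = self._setup()
        cfg = CallerConfig()
        wins = [
            ScoredWindow("chr1", 0, 3, 1e-9, -20.7),
            ScoredWindow("chr1", 5, 8, 1e-9, -20.7),
        ]
        dmrs = merge_adjacent(wins, track, probes, 1, 100, cfg)
        assert len(dmrs) == 2

    def test_chain_of_abutting_windows_collapses(self):
        probes, track = self._setup()
        cfg = CallerConfig()
        wins = [ScoredWindow("chr1", 4 * i, 4 * i + 3, 1e-9, -20.7) for i in range(5)]
        dmrs = merge_adjacent(wins, track, probes, 1, 100, cfg)
        assert len(dmrs) == 1
        assert (dmrs[0].idx_first, dmrs[0].idx_last) == (0, 19)


class TestIntegration:
    def _layer_inputs(self, strong_remainders):
        """Candidate of 30 probes overlapping two previous DMRs.

        With ``strong_remainders`` every probe outside the two previous DMRs
        is highly ranked, so both subtraction remainders stay significant;
        otherwise the remainders are null and the candidate must be
        rejected in favor of its children.
        """
        n = 2000
        p = np.random.default_rng(9).uniform(0.2, 1.0, n)
        p[100:110] = 1e-9  # prev A
        p[115:125] = 1e-9  # prev B
        if strong_remainders:
            p[95:130] = 1e-9
        probes = make_probes(n)
        track = make_track(p)
        cfg = CallerConfig()
        prev = merge_adjacent(
            [ScoredWindow("chr1", 100, 109, 1e-12, -27.6),
             ScoredWindow("chr1", 115, 124, 1e-12, -27.6)],
            track, probes, 1, 50, cfg,
        )
        cand = merge_adjacent(
            [ScoredWindow("chr1", 95, 129, 1e-15, -34.5)], track, probes, 2, 50, cfg
        )
        return prev, cand, track, probes, cfg

    def test_candidate_kept_when_every_remainder_significant(self):
        prev, cand, track, probes, cfg = self._layer_inputs(True)
        layer, links = integrate_layers(prev, cand, track, probes, cfg, 50, 2)
        assert len(layer) == 1
        assert (layer[0].idx_first, layer[0].idx_last) == (95, 129)
        assert links == {0: 0, 1: 0}

    def test_candidate_replaced_by_child_when_remainder_fails(self):
        # candidate whose entire signal sits in one previous DMR: the
        # remainder after subtracting it is null, so the broad candidate is
        # rejected and the child propagates
        n = 2000
        p = np.random.default_rng(9).uniform(0.2, 1.0, n)
        p[100:110] = 1e-9
        probes = make_probes(n)
        track = make_track(p)
        cfg = CallerConfig()
        prev = merge_adjacent(
            [ScoredWindow("chr1", 100, 109, 1e-12, -27.6)], track, probes, 1, 50, cfg
        )
        cand = merge_adjacent(
            [ScoredWindow("chr1", 95, 129, 1e-15, -34.5)], track, probes, 2, 50, cfg
        )
        layer, links = integrate_layers(prev, cand, track, probes, cfg, 50, 2)
        assert [(d.idx_first, d.idx_last) for d in layer] == [(100, 109)]
        assert links == {0: 0}

    def test_identical_prev_propagates_unchanged(self):
        prev, cand, track, probes, cfg = self._layer_inputs(True)
        layer, links = integrate_layers(prev[:1], prev[:1], track, probes, cfg, 50, 2)
        assert len(layer) == 1
        assert (layer[0].idx_first, layer[0].idx_last) == (
            prev[0].idx_first,
            prev[0].idx_last,
        )

    def test_prev_without_candidate_carries_through(self):
        prev, cand, track, probes, cfg = self._layer_inputs(True)
        layer, links = integrate_layers(prev, [], track, probes, cfg, 50, 2)
        assert len(layer) == len(prev)


class TestCallDmrs:
    def test_null_track_yields_empty_layers(self):
        probes = make_probes(500)
        track = make_track(np.ones(500))
        res = call_dmrs(track, probes, CallerConfig(window_sizes=(4, 8)),
                            locs_pval_cutoff=0.05)
        assert all(layer == [] for layer in res.layers)

    def test_single_block_called_in_all_layers(self):
        rng = np.random.default_rng(1)
        n = 5000
        p = rng.uniform(0.2, 1.0, n)
        p[1000:1006] = np.linspace(1e-9, 6e-9, 6)  # ranks 1..6
        probes = make_probes(n)
        track = make_track(p)
        res = call_dmrs(track, probes, CallerConfig(window_sizes=(4, 8)),
                            locs_pval_cutoff=1e-4)
        for layer in res.layers:
            assert len(layer) == 1
            assert layer[0].idx_first <= 1000 and layer[0].idx_last >= 1005
        assert res.parent_links == [{0: 0}]

    def test_uniformly_significant_chromosome_consolidates(self):
        # models chromosome-wide differential methylation: the top layer
        # should cover the whole chromosome as one feature
        rng = np.random.default_rng(2)
        n_bg, n_sig = 3000, 200
        p = np.concatenate([
            rng.uniform(0.3, 1.0, n_bg),
            10 ** rng.uniform(-12, -5, n_sig),
        ])
        probes_all = make_probes(n_bg + n_sig, chrom="chr1")
        chroms = np.array(["chr1"] * n_bg + ["chrX"] * n_sig, dtype=object)
        from scaledmr import ProbeSet
        probes = ProbeSet(probes_all.probe_id, chroms, probes_all.pos)
        track = make_track(p)
        res = call_dmrs(track, probes, CallerConfig(window_sizes=(4, 8, 16, 32)),
                            locs_pval_cutoff=1e-3)
        top_x = [d for d in res.top_layer if d.chrom == "chrX"]
        assert len(top_x) == 1
        assert top_x[0].n_cpgs == n_sig

    def test_determinism(self):
        rng = np.random.default_rng(3)
        n = 2000
        p = rng.uniform(1e-6, 1.0, n)
        probes = make_probes(n)
        cfg = CallerConfig(window_sizes=(4, 8, 16))
        a = call_dmrs(make_track(p), probes, cfg, locs_pval_cutoff=0.01)
        b = call_dmrs(make_track(p), probes, cfg, locs_pval_cutoff=0.01)
        assert [(d.chrom, d.start, d.end, d.p_region) for l in a.layers for d in l] == [
            (d.chrom, d.start, d.end, d.p_region) for l in b.layers for d in l
        ]

    def test_auto_cutoff_requires_explicit_value(self):
        probes = make_probes(100)
        track = make_track(np.ones(100))
        with pytest.raises(ValueError, match="auto"):
            call_dmrs(track, probes, CallerConfig())


def test_config_validation():
    with pytest.raises(ValueError):
        CallerConfig(window_sizes=(8, 4))
    with pytest.raises(ValueError):
        CallerConfig(window_sizes=(1, 4))
    with pytest.raises(ValueError):
        CallerConfig(region_signif_cutoff=1.5)
    with pytest.raises(ValueError):
        CallerConfig(correction="holm")
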