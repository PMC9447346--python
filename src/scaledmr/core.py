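"""Scale-aware DMR calling by iterative adjacent-CpG windowing.

The caller slides windows of a fixed *count of adjacent CpGs* (not a fixed
genomic width) over each chromosome, scores each candidate window with a
sequential hypergeometric rank-enrichment statistic, corrects for multiple
testing within the layer, merges adjacent significant windows, and then
integrates the layer with the layers built from smaller windows.  The result
is a nested hierarchy of DMRs: every region called with a smaller window is
contained in exactly one region of the next layer, and the top layer is the
primary output.

Region score
------------
For a window of CpGs with significance ranks drawn from a track of
``N_total`` probes (rank = number of probes at least as significant), the
single most significant member is excluded as the conditioning draw, and the
remaining m members are processed from least to most significant
(i = 1..m, K_i = rank of the i-th member):

    p_region = prod_i  P(X >= k_i),   X ~ Hypergeometric(N_i, K_i, n_i)

with k_i the number of remaining members at least as significant as member
i, n_1 = m, n_i = k_{i-1} - 1, N_1 = N_total, N_i = K_{i-1} - 1.  The
variable updates condition each factor on the information already spent,
which makes the factors independent: each one is the conditional
distribution of the next order statistic, evaluated at its observed value,
and is therefore Uniform(0,1) (sub-uniform for discrete ranks) under the
null of randomly assigned ranks.  The raw product of independent uniforms
concentrates near e^-m, so it is not itself a p-value; the score
calibrates it against its null law, -log(product) ~ Gamma(m', 1) with the
shape m' counting the informative (non-unit) factors — a Fisher-style
combination, exact for integer shape, that reduces to the raw product for
a single informative factor and is conservative under the null.  A second
valid statistic, the Bonferroni-combined minimum over unconditional
prefix-enrichment tails (robust where the chain's population update is
brittle), is combined with the chain as p_region = min(1, 2 min(both)).
See docs/methods.md for the full derivation.  All accumulation is in log
space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import gammaln, logsumexp

from .data import DMRRecord, ProbeSet
from .significance import SignificanceTrack, rank_cpgs

logger = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "ScoredWindow",
    "LayerHierarchy",
    "score_region",
    "scan_layer",
    "adjust_and_select",
    "merge_adjacent",
    "integrate_layers",
    "call_dmrs",
]

_TINY = np.finfo(float).tiny

DEFAULT_WINDOW_SIZES = (4, 8, 16, 32, 64)


@dataclass
class CallerConfig:
    """Tunable parameters of the caller.

    window_sizes
        Increasing counts of adjacent CpGs, one per layer.
    locs_pval_cutoff
        Individual-CpG p threshold defining "significant" probes (or
        ``"auto"``: estimate by label permutation at ``locs_fdr``).
    region_signif_cutoff
        Adjusted region-level threshold below which a window is significant.
    correction
        ``benjamini-yekutieli`` (FDR) or ``bonferroni`` (FWER), applied
        within each layer with the number of tests set to the number of
        probes below the individual-CpG cutoff.
    """

    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    locs_pval_cutoff: float | str = "auto"
    locs_fdr: float = 0.10
    region_signif_cutoff: float = 0.01
    correction: str = "benjamini-yekutieli"

    def __post_init__(self) -> None:
        ws = tuple(int(w) for w in self.window_sizes)
        if any(w < 2 for w in ws) or any(b <= a for a, b in zip(ws, ws[1:])):
            raise ValueError("window sizes must be strictly increasing and >= 2")
        self.window_sizes = ws
        if not (0.0 < self.region_signif_cutoff < 1.0):
            raise ValueError("region_signif_cutoff must lie in (0, 1)")
        if self.locs_pval_cutoff != "auto" and not (
            0.0 < float(self.locs_pval_cutoff) < 1.0
        ):
            raise ValueError("locs_pval_cutoff must lie in (0, 1) or be 'auto'")
        if self.correction not in ("benjamini-yekutieli", "bonferroni"):
            raise ValueError("correction must be benjamini-yekutieli or bonferroni")


@dataclass
class ScoredWindow:
    """A window of adjacent CpGs with its region score (global probe indices)."""

    chrom: str
    idx_first: int
    idx_last: int
    p_region: float
    log_p_region: float
    p_adjusted: float = np.nan


@dataclass
class LayerHierarchy:
    """All layers of called DMRs plus the child->parent links between layers.

    ``parent_links[i][j] = k`` means DMR j of ``layers[i]`` is contained in
    DMR k of ``layers[i + 1]``.  The top layer is the primary output.
    """

    layers: list[list[DMRRecord]]
    parent_links: list[dict[int, int]]
    window_sizes: tuple[int, ...]
    locs_pval_cutoff: float
    n_tests: int

    @property
    def top_layer(self) -> list[DMRRecord]:
        return self.layers[-1] if self.layers else []

    def edges(self) -> list[tuple[int, int, int, int]]:
        """(child_layer, child_id, parent_layer, parent_id) rows, 1-based layers."""
        out = []
        for i, links in enumerate(self.parent_links):
            for child, parent in sorted(links.items()):
                out.append((i + 1, child, i + 2, parent))
        return out


def _hyper_logpmf(x, N, K, n):
    return (
        gammaln(K + 1.0)
        - gammaln(x + 1.0)
        - gammaln(K - x + 1.0)
        + gammaln(N - K + 1.0)
        - gammaln(n - x + 1.0)
        - gammaln(N - K - n + x + 1.0)
        + gammaln(n + 1.0)
        + gammaln(N - n + 1.0)
        - gammaln(N + 1.0)
    )


def _hyper_logsf(k: np.ndarray, N: np.ndarray, K: np.ndarray, n: np.ndarray) -> np.ndarray:
    """log P(X >= k), X ~ Hypergeometric(N pop, K successes, n draws).

    Exact tail summation of the pmf in log space.  When the mean n*K/N is at
    or above k the complementary lower tail (k terms, all below the mode, no
    cancellation since P >= 1/2) is summed; otherwise the upper tail is
    summed directly — its terms decrease from x = k, so summation stops once
    increments no longer move the total.  Orders of magnitude faster than
    generic library survival functions at the array shapes the window scan
    produces, and accurate to float precision.
    """
    k = np.asarray(k, dtype=np.int64)
    shape = k.shape
    N, K, n = (
        np.broadcast_to(np.asarray(a, dtype=np.int64), shape).ravel() for a in (N, K, n)
    )
    k = k.ravel()
    out = np.zeros(k.shape, dtype=float)
    hi = np.minimum(n, K)
    lo_support = np.maximum(0, n - (N - K))
    out[k > hi] = -np.inf
    todo = (k > lo_support) & (k <= hi)  # below support: P = 1 exactly
    if not todo.any():
        return out.reshape(shape)

    mean = n * K / np.maximum(N, 1)
    use_lower = todo & (mean >= k)
    use_upper = todo & ~use_lower

    for mask, direction in ((use_lower, -1), (use_upper, +1)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        kk, NN, KK, nn = k[idx], N[idx], K[idx], n[idx]
        start = kk - 1 if direction < 0 else kk
        stop = np.maximum(lo_support[idx], 0) if direction < 0 else np.minimum(nn, KK)
        x = start.astype(np.int64)
        total = np.full(idx.size, -np.inf)
        active = np.ones(idx.size, dtype=bool)
        while active.any():
            a = np.flatnonzero(active)
            term = _hyper_logpmf(x[a].astype(float), NN[a], KK[a], nn[a])
            new = np.logaddexp(total[a], term)
            # upper side: terms decrease, stop when they no longer contribute
            if direction > 0:
                done = (term < new - 45.0) | (x[a] >= stop[a])
            else:
                done = x[a] <= stop[a]
            total[a] = new
            active[a[done]] = False
            x[a[~done]] += direction
        if direction < 0:
            with np.errstate(divide="ignore"):
                out[idx] = np.log1p(-np.exp(np.minimum(total, 0.0)))
        else:
            out[idx] = np.minimum(total, 0.0)
    return out.reshape(shape)


def _gamma_logsf_int(m: np.ndarray, x: np.ndarray) -> np.ndarray:
    """log P(Gamma(m_i, 1) > x_i), exact finite series for integer shapes.

    Stable for arbitrarily large x (no underflow to -inf before the floor
    applied by callers); x = 0 or m = 0 gives 0 (p = 1).
    """
    x = np.asarray(x, dtype=float)
    m = np.broadcast_to(np.asarray(m, dtype=np.int64), x.shape)
    out = np.zeros_like(x)
    nz = np.flatnonzero((x > 0) & (m > 0))
    if nz.size == 0:
        return out
    m_max = int(m[nz].max())
    k = np.arange(m_max)
    lgk = gammaln(k + 1)
    for chunk in np.array_split(nz, max(1, nz.size * m_max // 2_000_000)):
        if chunk.size == 0:
            continue
        lw = k[None, :] * np.log(x[chunk, None]) - lgk[None, :]
        lw[k[None, :] >= m[chunk, None]] = -np.inf  # series has m_i terms
        out[chunk] = -x[chunk] + logsumexp(lw, axis=1)
    return np.minimum(out, 0.0)


def _sequential_log_product(ranks: np.ndarray, n_total: int) -> np.ndarray:
    """log of the raw sequential hypergeometric product, per row of ranks."""
    ranks = np.asarray(ranks, dtype=np.int64)
    if ranks.ndim != 2:
        raise ValueError("expected a 2-D rank matrix")
    if ranks.size and ((ranks < 1).any() or (ranks > n_total).any()):
        raise ValueError("ranks must lie in [1, N_total]")
    B, w = ranks.shape
    if w <= 1:
        # empty product after excluding the top member
        return np.zeros(B), np.zeros(B, dtype=np.int64)
    asc = np.sort(ranks, axis=1)
    K = asc[:, :0:-1]  # remaining members, least -> most significant
    m = w - 1
    # k_j = number of remaining members with rank <= K_j; with rows sorted
    # descending this is m minus the first occurrence of the value K_j
    first_occ = np.zeros_like(K)
    if m > 1:
        change = K[:, 1:] != K[:, :-1]
        first_occ[:, 1:] = np.maximum.accumulate(
            np.where(change, np.arange(1, m), 0), axis=1
        )
    k = m - first_occ
    n_draws = np.empty_like(K)
    n_draws[:, 0] = m
    n_draws[:, 1:] = k[:, :-1] - 1
    N_pop = np.empty_like(K)
    N_pop[:, 0] = n_total
    N_pop[:, 1:] = K[:, :-1] - 1
    if (N_pop <= 0).any() or (n_draws <= 0).any():
        raise ValueError("inconsistent ranks: population or draw count fell to zero")
    # degenerate tie guard: successes cannot exceed the conditioned population,
    # nor observed successes the draw count
    succ = np.minimum(K, N_pop)
    k_eff = np.minimum(np.minimum(k, n_draws), succ)
    logs = _hyper_logsf(k_eff, N_pop, succ, n_draws)
    return logs.sum(axis=1), (logs < 0).sum(axis=1)


def _prefix_min_log(ranks: np.ndarray, n_total: int) -> np.ndarray:
    """log of the Bonferroni-combined prefix enrichment tests, per row.

    The j-th prefix test asks whether at least j of the w window members
    rank within the j-th smallest observed rank a_j: P(X >= j),
    X ~ Hypergeometric(N, a_j, w).  Prefixes run over the full member set
    but start at j = 2, so no window can fire on a single extreme CpG; the
    minimum over the w - 1 tests is Bonferroni-corrected.  Unlike the
    sequential chain, whose population update conditions away everything
    above the previous member's rank, these unconditional tails are
    unaffected by a stray moderate rank interleaved with a strongly
    significant block, and rank ties cost nothing.
    """
    asc = np.sort(np.asarray(ranks, dtype=np.int64), axis=1)
    B, w = asc.shape
    if w < 2:
        return np.zeros(B)
    j = np.broadcast_to(np.arange(2, w + 1)[None, :], (B, w - 1))
    logs = _hyper_logsf(j, n_total, asc[:, 1:], w)
    return np.minimum(logs.min(axis=1) + np.log(w - 1), 0.0)


def _score_rank_rows(ranks: np.ndarray, n_total: int) -> np.ndarray:
    """Calibrated log p_region for each row of a (B, w) matrix of member ranks.

    Two valid member-rank enrichment p-values are combined (Bonferroni
    factor 2, skipped when they coincide at m = 1):

    * the sequential-product chain, calibrated against its Gamma null with
      shape equal to the number of informative (non-unit) factors — rank
      ties collapse their trailing factors to exactly 1, and counting those
      degenerate factors would only dilute the combination.  For a window
      whose members all share one tied rank this reduces to the single
      hypergeometric tail, which is exactly uniform under a null of randomly
      placed tied ranks;
    * the prefix enrichment minimum, which is robust to a moderate null
      rank interleaved with the significant block.
    """
    logq, m_eff = _sequential_log_product(ranks, n_total)
    chain = _gamma_logsf_int(m_eff, -logq)
    if ranks.shape[1] <= 2:
        return chain
    prefix = _prefix_min_log(ranks, n_total)
    return np.minimum(np.log(2.0) + np.minimum(chain, prefix), 0.0)


def score_region(member_ranks, n_total: int, calibrate: bool = True) -> float:
    """Sequential hypergeometric region score for one set of member ranks.

    Excludes the most significant member (smallest rank; the leftmost at
    ties) as the conditioning draw; an empty or single-member region scores
    1.0.  With ``calibrate=False`` the raw product of the hypergeometric
    upper-tail factors is returned instead of the Gamma-calibrated p-value
    (the two coincide for two-member regions).  Never underflows to exactly
    zero.
    """
    ranks = np.atleast_1d(np.asarray(member_ranks, dtype=np.int64))
    if ranks.size == 0:
        return 1.0
    if calibrate:
        logp = _score_rank_rows(ranks[None, :], n_total)[0]
    else:
        logp = _sequential_log_product(ranks[None, :], n_total)[0][0]
    return float(max(np.exp(logp), _TINY))


def scan_layer(
    track: SignificanceTrack,
    probes: ProbeSet,
    window_size: int,
    locs_pval_cutoff: float,
) -> list[ScoredWindow]:
    """Score all candidate windows of ``window_size`` adjacent CpGs, stride 1.

    Windows never cross chromosome boundaries; chromosomes with fewer probes
    than the window are skipped.  A window is a candidate only if it contains
    at least one probe with p below the individual-CpG cutoff.
    """
    if track.rank is None:
        rank_cpgs(track)
    n_total = track.n_total
    windows: list[ScoredWindow] = []
    for chrom, sl in probes.chrom_slices.items():
        n_c = sl.stop - sl.start
        if n_c < window_size:
            logger.debug("chrom %s has %d < %d probes; skipped", chrom, n_c, window_size)
            continue
        sig = track.p[sl] < locs_pval_cutoff
        csum = np.concatenate(([0], np.cumsum(sig)))
        starts = np.arange(n_c - window_size + 1)
        cand = csum[starts + window_size] - csum[starts] > 0
        cand_starts = starts[cand]
        if cand_starts.size == 0:
            continue
        rank_rows = sliding_window_view(track.rank[sl], window_size)[cand_starts]
        logp = _score_rank_rows(rank_rows, n_total)
        for s, lp in zip(cand_starts, logp):
            windows.append(
                ScoredWindow(
                    chrom=chrom,
                    idx_first=sl.start + int(s),
                    idx_last=sl.start + int(s) + window_size - 1,
                    p_region=float(max(np.exp(lp), _TINY)),
                    log_p_region=float(lp),
                )
            )
    return windows


def _by_harmonic(m: int) -> float:
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def adjust_single(p: float, n_tests: int, correction: str) -> float:
    """Correction for one region tested among n_tests (used for retests)."""
    if n_tests < 1:
        return 1.0
    factor = n_tests * (_by_harmonic(n_tests) if correction == "benjamini-yekutieli" else 1.0)
    return float(min(1.0, max(p * factor, p)))


def adjust_and_select(
    windows: list[ScoredWindow],
    config: CallerConfig,
    n_tests: int,
) -> list[ScoredWindow]:
    """Multiple-testing correction within a layer, then threshold.

    The number of tests is the number of probes below the individual-CpG
    cutoff, not the number of candidate windows: stride-1 windows are almost
    wholly overlapping, and each sub-cutoff probe spawns at most one
    window's worth of independent evidence.  Bonferroni multiplies by
    n_tests; Benjamini-Yekutieli applies the step-up formula with the
    n_tests-based factor over the observed candidate ranks (p = 1
    placeholders fill unused slots when candidates are fewer).  Windows with
    adjusted p below ``region_signif_cutoff`` are retained.
    """
    if n_tests < 1 or not windows:
        return []
    p = np.array([w.p_region for w in windows])
    if config.correction == "bonferroni":
        p_adj = np.minimum(1.0, p * n_tests)
    else:
        order = np.argsort(p, kind="mergesort")
        ranks = np.arange(1, len(p) + 1)
        stepped = n_tests * _by_harmonic(n_tests) * p[order] / ranks
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        p_adj = np.empty_like(p)
        p_adj[order] = np.minimum(1.0, stepped)
    selected = []
    for w, adj in zip(windows, p_adj):
        if adj < config.region_signif_cutoff:
            w.p_adjusted = float(max(adj, w.p_region))
            selected.append(w)
    selected.sort(key=lambda w: (w.chrom, w.idx_first))
    return selected


def _merge_index_intervals(
    intervals: list[tuple[str, int, int, float]], allow_abut: bool
) -> list[tuple[str, int, int, float]]:
    """Union (chrom, first, last, p_adj_hint) intervals in probe-index space
    that overlap (or abut, if asked); merged hints take the minimum."""
    merged: list[tuple[str, int, int, float]] = []
    slack = 1 if allow_abut else 0
    for chrom, a, b, hint in sorted(intervals):
        if merged and merged[-1][0] == chrom and a <= merged[-1][2] + slack:
            c, pa, pb, ph = merged[-1]
            merged[-1] = (c, pa, max(pb, b), min(ph, hint))
        else:
            merged.append((chrom, a, b, hint))
    return merged


def _make_record(
    chrom: str,
    idx_first: int,
    idx_last: int,
    track: SignificanceTrack,
    probes: ProbeSet,
    layer: int,
    n_tests: int,
    config: CallerConfig,
    locs_cutoff: float | None = None,
    p_adjusted_hint: float = np.inf,
) -> DMRRecord:
    if locs_cutoff is not None:
        # trim to the outermost individually significant member: windows pad
        # up to w-1 non-significant probes on each side, which in sparse
        # regions would inflate the genomic extent by tens of kilobases
        sig = np.flatnonzero(track.p[idx_first : idx_last + 1] < locs_cutoff)
        if sig.size:
            idx_first, idx_last = idx_first + int(sig[0]), idx_first + int(sig[-1])
    ranks = track.rank[idx_first : idx_last + 1]
    p_region = score_region(ranks, track.n_total)
    # a merged region's claim to significance comes from its selected
    # windows: report the best step-up-adjusted constituent if that beats
    # the (stricter, rank-one) adjustment of the merged rescore
    p_adj = min(adjust_single(p_region, n_tests, config.correction), p_adjusted_hint)
    return DMRRecord(
        chrom=chrom,
        start=int(probes.pos[idx_first]),
        end=int(probes.pos[idx_last]),
        idx_first=int(idx_first),
        idx_last=int(idx_last),
        p_region=p_region,
        p_adjusted=float(max(p_region, p_adj)),
        layer=layer,
        mean_delta_beta=float(np.mean(track.delta_beta[idx_first : idx_last + 1])),
    )


def merge_adjacent(
    selected: list[ScoredWindow],
    track: SignificanceTrack,
    probes: ProbeSet,
    layer: int,
    n_tests: int,
    config: CallerConfig,
    locs_cutoff: float | None = None,
) -> list[DMRRecord]:
    """Union overlapping or abutting significant windows into tentative DMRs.

    Merged regions are trimmed to their outermost individually significant
    CpG and rescored, so that downstream integration retests work on a score
    comparable with single-window scores.
    """
    intervals = [
        (w.chrom, w.idx_first, w.idx_last, float(w.p_adjusted)) for w in selected
    ]
    merged = _merge_index_intervals(intervals, allow_abut=True)
    return [
        _make_record(c, a, b, track, probes, layer, n_tests, config, locs_cutoff, h)
        for c, a, b, h in merged
    ]


def integrate_layers(
    prev_layer: list[DMRRecord],
    next_candidates: list[DMRRecord],
    track: SignificanceTrack,
    probes: ProbeSet,
    config: CallerConfig,
    n_tests: int,
    layer: int,
    locs_cutoff: float | None = None,
    retest_bar: float | None = None,
) -> tuple[list[DMRRecord], dict[int, int]]:
    """Integrate a tentative layer with the previous layer.

    Each candidate is retested after removing, one at a time, the member
    CpGs of every overlapping previous-layer DMR.  The candidate survives
    only if every such remainder is still significant on its own — i.e. no
    single previous-layer DMR is responsible for the candidate's score.
    Surviving candidates absorb their overlapping previous DMRs; failed
    candidates are replaced by them.  Previous DMRs overlapping no candidate
    carry through unchanged, so regions are expanded, added or consolidated
    but never lost.

    The retest is a conditional decomposition check on one already-selected
    candidate, not a genome-wide scan, so each remainder's rescore is
    compared directly against the region significance threshold (at most a
    handful of retests per candidate); ``retest_bar`` can tighten this to
    the layer's realized step-up critical value when given.

    Returns the integrated layer and the map from previous-layer DMR index
    to its containing record in the integrated layer.
    """
    cutoff = config.region_signif_cutoff

    def _remainder_significant(p_rem: float) -> bool:
        bar = cutoff if retest_bar is None else max(cutoff, retest_bar)
        return p_rem < bar

    intervals: list[tuple[str, int, int, float]] = []
    prev_used = np.zeros(len(prev_layer), dtype=bool)

    for cand in sorted(next_candidates, key=lambda d: (d.chrom, d.idx_first)):
        overlapping = [
            (i, p)
            for i, p in enumerate(prev_layer)
            if p.chrom == cand.chrom
            and p.idx_first <= cand.idx_last
            and p.idx_last >= cand.idx_first
        ]
        if not overlapping:
            intervals.append(
                (cand.chrom, cand.idx_first, cand.idx_last, cand.p_adjusted)
            )
            continue
        cand_idx = np.arange(cand.idx_first, cand.idx_last + 1)
        retained = True
        for _, p in overlapping:
            keep = (cand_idx < p.idx_first) | (cand_idx > p.idx_last)
            remainder = cand_idx[keep]
            if remainder.size == 0:
                retained = False
                break
            p_rem = score_region(track.rank[remainder], track.n_total)
            if not _remainder_significant(p_rem):
                retained = False
                break
        if retained:
            lo = min([cand.idx_first] + [p.idx_first for _, p in overlapping])
            hi = max([cand.idx_last] + [p.idx_last for _, p in overlapping])
            hint = min([cand.p_adjusted] + [p.p_adjusted for _, p in overlapping])
            intervals.append((cand.chrom, lo, hi, hint))
            for i, _ in overlapping:
                prev_used[i] = True
        else:
            for i, p in overlapping:
                intervals.append((p.chrom, p.idx_first, p.idx_last, p.p_adjusted))
                prev_used[i] = True

    for i, p in enumerate(prev_layer):
        if not prev_used[i]:
            intervals.append((p.chrom, p.idx_first, p.idx_last, p.p_adjusted))

    # a previous DMR may bridge two candidates (or be emitted twice as a
    # replacement); union any records that share CpGs so the layer stays
    # internally non-overlapping
    final = _merge_index_intervals(sorted(set(intervals)), allow_abut=False)
    records = [
        _make_record(c, a, b, track, probes, layer, n_tests, config, locs_cutoff, h)
        for c, a, b, h in final
    ]
    links: dict[int, int] = {}
    for i, p in enumerate(prev_layer):
        for j, r in enumerate(records):
            if (
                r.chrom == p.chrom
                and r.idx_first <= p.idx_first
                and r.idx_last >= p.idx_last
            ):
                links[i] = j
                break
        else:
            raise AssertionError("previous-layer DMR lost during integration")
    return records, links


def call_dmrs(
    track: SignificanceTrack,
    probes: ProbeSet,
    config: CallerConfig,
    locs_pval_cutoff: float | None = None,
) -> LayerHierarchy:
    """Run the full iterative windowing procedure over all window sizes.

    ``locs_pval_cutoff`` overrides the config value (used when the cutoff was
    estimated by permutation); the config value must then be numeric.
    """
    if track.n_total != len(probes):
        raise ValueError("track and probes must align")
    if track.rank is None:
        rank_cpgs(track)
    cutoff = locs_pval_cutoff
    if cutoff is None:
        if config.locs_pval_cutoff == "auto":
            raise ValueError(
                "locs_pval_cutoff='auto' requires an explicit cutoff estimated "
                "via permutation_fdr_cutoff"
            )
        cutoff = float(config.locs_pval_cutoff)
    n_tests = int(np.sum(track.p < cutoff))
    logger.info("%d probes below individual-CpG cutoff %g", n_tests, cutoff)

    layers: list[list[DMRRecord]] = []
    parent_links: list[dict[int, int]] = []
    prev: list[DMRRecord] = []
    for li, w in enumerate(config.window_sizes, start=1):
        windows = scan_layer(track, probes, w, cutoff)
        selected = adjust_and_select(windows, config, n_tests)
        retest_bar = max((x.p_region for x in selected), default=None)
        candidates = merge_adjacent(selected, track, probes, li, n_tests, config, cutoff)
        if li == 1:
            layer = candidates
        else:
            layer, links = integrate_layers(
                prev, candidates, track, probes, config, n_tests, li, cutoff,
                retest_bar=retest_bar,
            )
            parent_links.append(links)
        layers.append(layer)
        prev = layer
        logger.info("layer %d (window %d): %d DMRs", li, w, len(layer))
    return LayerHierarchy(
        layers=layers,
        parent_links=parent_links,
        window_sizes=config.window_sizes,
        locs_pval_cutoff=float(cutoff),
        n_tests=n_tests,
    )
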