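"""Per-CpG two-group testing, significance ranks, and the permutation cutoff.

The region score downstream consumes only a vector of p-values and their
significance ranks, so any per-CpG test can feed it; this module provides a
vectorized exact Wilcoxon rank-sum (the natural choice at rare-disease sample
sizes), a Welch t-test, and a loader for externally computed p-values.

The significance rank of probe i is ``K_i = #{j : p_j <= p_i}``: rank 1 is
the uniquely most significant probe, and tied p-values share the maximal
count.  This convention makes the rank double as the number of "success"
CpGs at or above that significance level in the whole dataset, which is what
the sequential hypergeometric region score conditions on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .data import BetaMatrix, ProbeSet, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceTrack",
    "CutoffEstimate",
    "wilcoxon_per_cpg",
    "ttest_per_cpg",
    "rank_cpgs",
    "permutation_fdr_cutoff",
    "track_to_frame",
    "load_pvalue_track",
]

_TINY = np.finfo(float).tiny

# exact test only while the enumeration stays cheap and well-calibrated
_EXACT_MAX_GROUP = 10


@dataclass
class SignificanceTrack:
    """Per-probe p-values, group-mean beta differences, and significance ranks."""

    p: np.ndarray
    delta_beta: np.ndarray
    rank: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.delta_beta = np.asarray(self.delta_beta, dtype=float)
        if self.p.shape != self.delta_beta.shape:
            raise ValueError("p and delta_beta must align")
        if (self.p <= 0).any() or (self.p > 1).any():
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def n_total(self) -> int:
        return self.p.size


@dataclass
class CutoffEstimate:
    """Permutation-estimated individual-CpG p-value cutoff."""

    cutoff: float
    target_fdr: float
    n_perm: int
    n_below: int
    seed: int


@lru_cache(maxsize=None)
def _ranksum_pmf(n1: int, n: int) -> np.ndarray:
    """Null pmf of the rank sum W of n1 ranks drawn from 1..n (no ties).

    Returned array is indexed by W - Wmin with Wmin = n1(n1+1)/2.
    """
    wmin = n1 * (n1 + 1) // 2
    wmax = n1 * (2 * n - n1 + 1) // 2
    # dp[k, s] = number of k-subsets of {1..v} with sum s, grown over v
    dp = np.zeros((n1 + 1, wmax + 1))
    dp[0, 0] = 1.0
    for v in range(1, n + 1):
        dp[1:, v:] += dp[:-1, :-v].copy()
    counts = dp[n1, wmin : wmax + 1]
    return counts / counts.sum()


def _exact_two_sided(w: np.ndarray, n1: int, n: int) -> np.ndarray:
    pmf = _ranksum_pmf(n1, n)
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(W >= w)
    idx = np.round(w).astype(int) - n1 * (n1 + 1) // 2
    return np.minimum(1.0, 2.0 * np.minimum(cdf[idx], sf[idx]))


def _tie_terms(x: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per row of a sorted matrix."""
    out = np.zeros(x.shape[0])
    eq = x[:, 1:] == x[:, :-1]
    for i in np.flatnonzero(eq.any(axis=1)):
        _, counts = np.unique(x[i], return_counts=True)
        out[i] = float(np.sum(counts**3 - counts))
    return out


def wilcoxon_per_cpg(beta: BetaMatrix, groups: SampleSheet) -> SignificanceTrack:
    """Two-sided Wilcoxon rank-sum test per probe, vectorized over probes.

    Uses the exact null distribution of the rank sum (two-sided by doubling
    the smaller tail) when the smaller group has <= 10 samples and the probe
    has no tied values; otherwise a tie-corrected normal approximation with
    continuity correction.  A probe constant across all samples gets p = 1.
    """
    ai, bi = groups.group_columns(beta)
    A, B = beta.values[:, ai], beta.values[:, bi]
    n1, n2 = A.shape[1], B.shape[1]
    n = n1 + n2
    X = np.concatenate([A, B], axis=1)
    r = stats.rankdata(X, axis=1)
    W = r[:, :n1].sum(axis=1)

    xs = np.sort(X, axis=1)
    tie_term = _tie_terms(xs)
    has_ties = tie_term > 0
    constant = xs[:, 0] == xs[:, -1]

    p = np.ones(X.shape[0])
    exact_ok = min(n1, n2) <= _EXACT_MAX_GROUP
    exact_rows = ~has_ties if exact_ok else np.zeros(X.shape[0], bool)
    approx_rows = ~exact_rows & ~constant

    if exact_rows.any():
        p[exact_rows] = _exact_two_sided(W[exact_rows], n1, n)
    if approx_rows.any():
        mu = n1 * (n + 1) / 2.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term[approx_rows] / (n * (n - 1)))
        z = (np.abs(W[approx_rows] - mu) - 0.5) / np.sqrt(np.maximum(var, _TINY))
        p[approx_rows] = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    p = np.maximum(p, _TINY)
    return SignificanceTrack(p=p, delta_beta=A.mean(axis=1) - B.mean(axis=1))


def ttest_per_cpg(beta: BetaMatrix, groups: SampleSheet) -> SignificanceTrack:
    """Two-sided Welch t-test per probe (same output contract as the Wilcoxon)."""
    ai, bi = groups.group_columns(beta)
    A, B = beta.values[:, ai], beta.values[:, bi]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    delta = A.mean(axis=1) - B.mean(axis=1)
    # zero variance in both groups: p=1 at equal means, else p -> 0 (floored)
    degenerate = ~np.isfinite(p)
    p[degenerate & (delta == 0)] = 1.0
    p[degenerate & (delta != 0)] = _TINY
    p = np.clip(p, _TINY, 1.0)
    return SignificanceTrack(p=p, delta_beta=delta)


def rank_cpgs(track: SignificanceTrack) -> SignificanceTrack:
    """Assign significance ranks K_i = #{j : p_j <= p_i} (idempotent, order-free)."""
    sorted_p = np.sort(track.p)
    track.rank = np.searchsorted(sorted_p, track.p, side="right").astype(np.int64)
    return track


_TESTS = {"wilcoxon": wilcoxon_per_cpg, "ttest": ttest_per_cpg}


def permutation_fdr_cutoff(
    beta: BetaMatrix,
    groups: SampleSheet,
    test: str = "wilcoxon",
    target_fdr: float = 0.10,
    n_perm: int = 20,
    seed: int = 0,
) -> CutoffEstimate:
    """Estimate the individual-CpG p-value cutoff achieving a target FDR.

    Group labels are permuted across samples n_perm times and the test rerun;
    for each candidate cutoff c (the observed p-values) the FDR is estimated
    as mean permuted exceedance / observed exceedance, monotonized by a
    running maximum from small c.  The largest c with estimated FDR <= target
    is returned; if no c qualifies the minimum observed p is returned with
    n_below = 0 (the caller then selects nothing).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10 for a usable FDR estimate")
    test_fn = _TESTS[test]
    obs = np.sort(test_fn(beta, groups).p)

    rng = np.random.default_rng(seed)
    n_g1 = sum(g == groups.groups[0] for g in groups.group)
    samples = list(groups.sample_id)
    perm_sorted = []
    for _ in range(n_perm):
        shuffled = rng.permutation(samples)
        sheet = SampleSheet(
            list(shuffled), ["g1"] * n_g1 + ["g2"] * (len(samples) - n_g1)
        )
        perm_sorted.append(np.sort(test_fn(beta, sheet).p))

    candidates = np.unique(obs)
    n_obs_below = np.searchsorted(obs, candidates, side="left").astype(float)
    n_perm_below = np.zeros_like(candidates)
    for ps in perm_sorted:
        n_perm_below += np.searchsorted(ps, candidates, side="left")
    n_perm_below /= n_perm
    fdr = n_perm_below / np.maximum(1.0, n_obs_below)
    fdr = np.maximum.accumulate(fdr)

    ok = np.flatnonzero(fdr <= target_fdr)
    if ok.size == 0 or n_obs_below[ok[-1]] == 0:
        return CutoffEstimate(float(obs[0]), target_fdr, n_perm, 0, seed)
    cutoff = float(candidates[ok[-1]])
    return CutoffEstimate(cutoff, target_fdr, n_perm, int(n_obs_below[ok[-1]]), seed)


def track_to_frame(track: SignificanceTrack, probes: ProbeSet) -> pd.DataFrame:
    """Tabular export of a significance track (probe_id, p, delta_beta, rank)."""
    if track.rank is None:
        rank_cpgs(track)
    return pd.DataFrame(
        {
            "probe_id": probes.probe_id,
            "p": track.p,
            "delta_beta": track.delta_beta,
            "rank": track.rank,
        }
    )


def load_pvalue_track(path, probes: ProbeSet) -> SignificanceTrack:
    """Load a precomputed per-probe p-value TSV (probe_id, p[, delta_beta])."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if not {"probe_id", "p"} <= set(df.columns):
        raise ValueError("p-value table needs columns probe_id and p")
    df = df.set_index("probe_id")
    missing = pd.Index(probes.probe_id).difference(df.index)
    if len(missing):
        raise ValueError(f"p-value table missing probes: {list(missing[:5])}")
    df = df.loc[probes.probe_id]
    delta = (
        df["delta_beta"].to_numpy(float)
        if "delta_beta" in df.columns
        else np.zeros(len(df))
    )
    return rank_cpgs(SignificanceTrack(p=df["p"].to_numpy(float), delta_beta=delta))
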