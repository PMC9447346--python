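"""Interval arithmetic on 1-based inclusive (chrom, start, end) frames.

Region sets are small (hundreds to low thousands), so per-chromosome
broadcasting keeps this simple and dependency-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def as_regions(df: pd.DataFrame) -> pd.DataFrame:
    out = df[["chrom", "start", "end"]].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] > out["end"]).any():
        raise ValueError("region start > end")
    return out


def merge_regions(df: pd.DataFrame) -> pd.DataFrame:
    """Union overlapping or abutting intervals (per chromosome)."""
    rows = []
    for chrom, g in as_regions(df).groupby("chrom", sort=True):
        g = g.sort_values(["start", "end"])
        cur_s = cur_e = None
        for s, e in zip(g["start"], g["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def total_length(df: pd.DataFrame) -> int:
    m = merge_regions(df)
    return int((m["end"] - m["start"] + 1).sum()) if len(m) else 0


def overlap_matrix(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean (len(a), len(b)) matrix of >=1 bp overlap."""
    out = np.zeros((len(a), len(b)), dtype=bool)
    if not len(a) or not len(b):
        return out
    a = as_regions(a).reset_index(drop=True)
    b = as_regions(b).reset_index(drop=True)
    for chrom in set(a["chrom"]) & set(b["chrom"]):
        ia = np.flatnonzero((a["chrom"] == chrom).to_numpy())
        ib = np.flatnonzero((b["chrom"] == chrom).to_numpy())
        sa = a["start"].to_numpy()[ia][:, None]
        ea = a["end"].to_numpy()[ia][:, None]
        sb = b["start"].to_numpy()[ib][None, :]
        eb = b["end"].to_numpy()[ib][None, :]
        out[np.ix_(ia, ib)] = (sa <= eb) & (ea >= sb)
    return out


def intersect_length_matrix(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """(len(a), len(b)) matrix of pairwise overlap lengths in bp."""
    out = np.zeros((len(a), len(b)), dtype=np.int64)
    if not len(a) or not len(b):
        return out
    a = as_regions(a).reset_index(drop=True)
    b = as_regions(b).reset_index(drop=True)
    for chrom in set(a["chrom"]) & set(b["chrom"]):
        ia = np.flatnonzero((a["chrom"] == chrom).to_numpy())
        ib = np.flatnonzero((b["chrom"] == chrom).to_numpy())
        sa = a["start"].to_numpy()[ia][:, None]
        ea = a["end"].to_numpy()[ia][:, None]
        sb = b["start"].to_numpy()[ib][None, :]
        eb = b["end"].to_numpy()[ib][None, :]
        out[np.ix_(ia, ib)] = np.maximum(
            0, np.minimum(ea, eb) - np.maximum(sa, sb) + 1
        )
    return out


def covered_length_per_region(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """bp of each a-region covered by the union of b-regions."""
    bm = merge_regions(b) if len(b) else b
    if not len(a):
        return np.zeros(0, dtype=np.int64)
    if not len(bm):
        return np.zeros(len(a), dtype=np.int64)
    return intersect_length_matrix(a, bm).sum(axis=1)


def complement(regions: pd.DataFrame, span: pd.DataFrame) -> pd.DataFrame:
    """Maximal intervals of ``span`` not covered by ``regions``."""
    span = merge_regions(span)
    regions = merge_regions(regions) if len(regions) else regions
    rows = []
    for sp in span.itertuples():
        cur = sp.start
        if len(regions):
            sub = regions[
                (regions["chrom"] == sp.chrom)
                & (regions["end"] >= sp.start)
                & (regions["start"] <= sp.end)
            ].sort_values("start")
        else:
            sub = regions
        for r in sub.itertuples():
            if r.start > cur:
                rows.append((sp.chrom, cur, min(r.start - 1, sp.end)))
            cur = max(cur, r.end + 1)
        if cur <= sp.end:
            rows.append((sp.chrom, cur, sp.end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def membership(
    chrom: np.ndarray, pos: np.ndarray, regions: pd.DataFrame
) -> np.ndarray:
    """True where a point (chrom, pos) falls in some region (1-based inclusive)."""
    out = np.zeros(len(pos), dtype=bool)
    if not len(regions):
        return out
    regions = merge_regions(regions)
    for c, g in regions.groupby("chrom", sort=False):
        sel = np.flatnonzero(chrom == c)
        if sel.size == 0:
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        ok[ok] = pos[sel][ok] <= ends[idx[ok]]
        out[sel] = ok
    return out
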