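"""Benchmark statistics for called regions against simulated truth.

Feature-level precision and recall follow the range-aware framing used for
interval (time-series-style) predictions: each called region contributes the
fraction of its span overlapping any truth region (its true-positive
attribute), and each truth region contributes the fraction of its span
covered by the union of included called regions.  Every truth region gets
equal weight regardless of its size, so megabase features do not dominate
the score.  The precision-recall curve is traced by including called regions
one at a time in order of significance; AUCPR is the trapezoidal area over
the recall axis.

Base-pair and CpG-probe level metrics are ordinary confusion-count metrics
over an explicit evaluable domain.

The mapping value diagnoses fragmentation/agglomeration per truth region:
``a`` called regions overlapping one truth give value ``a`` (> 1 =
fragmentation); a single called region shared by ``b`` truths gives ``1/b``
(< 1 = agglomeration); exactly one-to-one recovery gives 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _intervals as iv
from .data import ProbeSet

__all__ = [
    "WidthPairs",
    "MappingResult",
    "PRCurve",
    "MetricSet",
    "pair_widths",
    "mapping_values",
    "feature_pr_curve",
    "confusion_metrics",
    "evaluate_calls",
]


@dataclass
class WidthPairs:
    """Truth/called width pairs (one per overlapping combination)."""

    truth_width: np.ndarray
    called_width: np.ndarray
    pearson_r_log10: float
    pearson_r_raw: float


@dataclass
class MappingResult:
    values: np.ndarray  # one per truth region with >= 1 overlapping called region
    n_truth: int
    n_unmatched: int
    one_to_one_fraction: float


@dataclass
class PRCurve:
    precision: np.ndarray
    recall: np.ndarray
    included: np.ndarray  # row index of the called region added at each step
    aucpr: float


@dataclass
class MetricSet:
    level: str
    precision: float
    recall: float
    specificity: float
    fdr: float
    f1: float
    mcc: float
    counts: dict = field(default_factory=dict)


def _widths(df: pd.DataFrame) -> np.ndarray:
    return (df["end"] - df["start"] + 1).to_numpy(dtype=float)


def pair_widths(truth: pd.DataFrame, called: pd.DataFrame) -> WidthPairs:
    """Form all (truth, called) pairs with any overlap; correlate widths.

    Pearson r is reported on log10 widths (the scale the size classes span)
    and on raw widths; both are NaN with fewer than two pairs.
    """
    ov = iv.overlap_matrix(truth, called)
    ti, ci = np.nonzero(ov)
    tw = _widths(truth)[ti]
    cw = _widths(called)[ci]
    if len(tw) >= 2 and np.std(tw) > 0 and np.std(cw) > 0:
        r_log = float(stats.pearsonr(np.log10(tw), np.log10(cw)).statistic)
        r_raw = float(stats.pearsonr(tw, cw).statistic)
    else:
        r_log = r_raw = math.nan
    return WidthPairs(tw, cw, r_log, r_raw)


def mapping_values(truth: pd.DataFrame, called: pd.DataFrame) -> MappingResult:
    """Per-truth fragmentation/agglomeration statistic.

    For each truth region with >= 1 overlapping called region, ``a`` is the
    number of called regions overlapping it and ``b`` the largest number of
    truth regions sharing one of those called regions; the value is ``a`` if
    |log10 a| >= |log10(1/b)| else ``1/b``.  Truth regions with no overlap
    are excluded from the distribution but kept in the one-to-one
    denominator.
    """
    ov = iv.overlap_matrix(truth, called)
    a = ov.sum(axis=1)
    truths_per_called = ov.sum(axis=0)
    values = []
    for t in np.flatnonzero(a > 0):
        b = int(truths_per_called[ov[t]].max())
        at = int(a[t])
        values.append(float(at) if np.log10(at) >= np.log10(b) else 1.0 / b)
    values = np.asarray(values)
    n_truth = len(truth)
    one_to_one = float(np.sum(values == 1.0) / n_truth) if n_truth else math.nan
    return MappingResult(
        values=values,
        n_truth=n_truth,
        n_unmatched=int(np.sum(a == 0)),
        one_to_one_fraction=one_to_one,
    )


def _order_by_significance(called: pd.DataFrame, rank_col: str | None) -> np.ndarray:
    if rank_col is not None and rank_col in called.columns:
        return np.argsort(called[rank_col].to_numpy(), kind="mergesort")
    return np.arange(len(called))


def feature_pr_curve(
    truth: pd.DataFrame,
    called: pd.DataFrame,
    rank_col: str | None = "p_adjusted",
) -> PRCurve:
    """Stepwise-inclusion precision-recall curve with equal truth weighting.

    Called regions are included most significant first (ascending
    ``rank_col`` when present, else input order).  The curve is prepended
    with (recall 0, precision of the first step) before the trapezoid.
    """
    if not len(called):
        return PRCurve(np.empty(0), np.empty(0), np.empty(0, int), 0.0)
    order = _order_by_significance(called, rank_col)
    truth = iv.as_regions(truth).reset_index(drop=True)
    called_ord = iv.as_regions(called).reset_index(drop=True).iloc[order].reset_index(drop=True)

    cw = _widths(called_ord)
    tw = _widths(truth)
    # per-called overlap with the union of truth
    tp_called = (
        iv.intersect_length_matrix(called_ord, iv.merge_regions(truth)).sum(axis=1) / cw
        if len(truth)
        else np.zeros(len(called_ord))
    )
    precision = np.cumsum(tp_called) / np.arange(1, len(called_ord) + 1)

    # per-truth coverage by the growing union of called regions
    seg = iv.intersect_length_matrix(truth, called_ord)  # pairwise, not union
    covered: list[list[tuple[int, int]]] = [[] for _ in range(len(truth))]
    coverage = np.zeros(len(truth))
    recall = np.zeros(len(called_ord))
    ts = truth["start"].to_numpy()
    te = truth["end"].to_numpy()
    cs = called_ord["start"].to_numpy()
    ce = called_ord["end"].to_numpy()
    for n in range(len(called_ord)):
        for t in np.flatnonzero(seg[:, n] > 0):
            covered[t].append((max(ts[t], cs[n]), min(te[t], ce[n])))
            # union length of accumulated segments for this truth
            segs = sorted(covered[t])
            length, cur_s, cur_e = 0, segs[0][0], segs[0][1]
            for s, e in segs[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    length += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
            length += cur_e - cur_s + 1
            coverage[t] = length / tw[t]
        recall[n] = coverage.mean() if len(truth) else 0.0

    r = np.concatenate(([0.0], recall))
    p = np.concatenate(([precision[0]], precision))
    aucpr = float(np.trapezoid(p, r))
    return PRCurve(precision=precision, recall=recall, included=order, aucpr=aucpr)


def _mcc_from_counts(tp: float, fp: float, tn: float, fn: float) -> float:
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom > 0 else 0.0


def _metricset(level, tp, fp, tn, fn) -> MetricSet:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MetricSet(
        level=level,
        precision=precision,
        recall=recall,
        specificity=specificity,
        fdr=1.0 - precision,
        f1=f1,
        mcc=_mcc_from_counts(tp, fp, tn, fn),
        counts={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


def confusion_metrics(
    truth: pd.DataFrame,
    called: pd.DataFrame,
    domain,
    level: str,
    probes: ProbeSet | None = None,
) -> MetricSet:
    """Confusion metrics at one evaluation level over an explicit domain.

    level="bp"
        Each evaluable basepair of ``domain`` (a regions frame) is one unit.
    level="cpg"
        Each probe of ``probes`` falling in ``domain`` is one unit.
    level="feature"
        Precision/recall are the equal-weight range statistics of
        :func:`feature_pr_curve` at the full called set; specificity and the
        negative side of MCC are computed over the complement gap features of
        the truth within the domain (each gap weighted equally, like each
        truth region), and MCC is assembled from the four rates
        sqrt(TPR*TNR*PPV*NPV) - sqrt(FNR*FPR*FDR*FOR).
    """
    if domain is None or not len(domain):
        raise ValueError("an evaluable domain is required")
    if level == "bp":
        tm, cm = iv.merge_regions(truth), iv.merge_regions(called) if len(called) else called
        t_len = iv.total_length(truth)
        c_len = iv.total_length(called) if len(called) else 0
        tp = int(iv.intersect_length_matrix(tm, cm).sum()) if len(called) else 0
        d_len = iv.total_length(domain)
        fp = c_len - tp
        fn = t_len - tp
        tn = d_len - t_len - fp
        return _metricset(level, tp, fp, tn, fn)
    if level == "cpg":
        if probes is None:
            raise ValueError("cpg level needs a ProbeSet")
        in_domain = iv.membership(probes.chrom, probes.pos, domain)
        t_mem = iv.membership(probes.chrom, probes.pos, truth) & in_domain
        c_mem = (
            iv.membership(probes.chrom, probes.pos, called) & in_domain
            if len(called)
            else np.zeros(len(probes), bool)
        )
        tp = int(np.sum(t_mem & c_mem))
        fp = int(np.sum(~t_mem & c_mem))
        fn = int(np.sum(t_mem & ~c_mem))
        tn = int(np.sum(in_domain & ~t_mem & ~c_mem))
        return _metricset(level, tp, fp, tn, fn)
    if level == "feature":
        m = len(truth)
        if len(called):
            cw = _widths(iv.as_regions(called))
            ppv = float(
                np.mean(
                    iv.intersect_length_matrix(called, iv.merge_regions(truth)).sum(axis=1)
                    / cw
                )
            )
            tpr = float(
                np.mean(iv.covered_length_per_region(truth, called) / _widths(truth))
            ) if m else 0.0
        else:
            ppv = 0.0
            tpr = 0.0
        gaps = iv.complement(truth, domain)
        if len(gaps):
            gap_cov = iv.covered_length_per_region(gaps, called) / _widths(gaps)
            tnr = float(np.mean(1.0 - gap_cov))
            tn_mass = float(np.sum(1.0 - gap_cov))
        else:
            tnr, tn_mass = 1.0, 0.0
        fn_mass = float(m * (1.0 - tpr))
        npv = tn_mass / (tn_mass + fn_mass) if tn_mass + fn_mass > 0 else 1.0
        pos = tpr * tnr * ppv * npv
        neg = (1 - tpr) * (1 - tnr) * (1 - ppv) * (1 - npv)
        mcc = math.sqrt(pos) - math.sqrt(neg)
        f1 = 2 * ppv * tpr / (ppv + tpr) if ppv + tpr > 0 else 0.0
        return MetricSet(
            level=level,
            precision=ppv,
            recall=tpr,
            specificity=tnr,
            fdr=1.0 - ppv,
            f1=f1,
            mcc=mcc,
            counts={"n_truth": m, "n_called": len(called), "n_gap_features": len(gaps)},
        )
    raise ValueError(f"unknown level {level!r}")


def evaluate_calls(
    truth: pd.DataFrame,
    called: pd.DataFrame,
    domain: pd.DataFrame,
    probes: ProbeSet | None = None,
    rank_col: str | None = "p_adjusted",
    levels: tuple[str, ...] = ("feature", "bp", "cpg"),
) -> dict:
    """One-stop benchmark: widths, mapping, PR curve, and per-level metrics."""
    out: dict = {
        "widths": pair_widths(truth, called),
        "mapping": mapping_values(truth, called),
        "pr_curve": feature_pr_curve(truth, called, rank_col=rank_col),
        "levels": {},
    }
    for level in levels:
        if level == "cpg" and probes is None:
            continue
        out["levels"][level] = confusion_metrics(truth, called, domain, level, probes)
    return out
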