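"""CpG-membership contingency analyses.

Two uses: (i) testing whether CpGs falling in the *gaps* between DMRs at a
given layer are enriched for an annotation (e.g. genes escaping
X-inactivation, which lack the chromosome-wide differential-methylation
signal and so appear as holes in a chromosome-scale DMR), and (ii) testing
whether CpG membership in DMRs of one condition predicts membership in
another condition's DMRs.

Odds ratios are reported both as the sample cross-ratio ad/bc and as the
conditional maximum-likelihood estimate with an exact (central Fisher) 95%
confidence interval — the convention of R's ``fisher.test``, which produces
very wide intervals for sparse tables rather than degenerate ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from . import _intervals as iv
from .data import DMRRecord, ProbeSet

__all__ = [
    "ContingencyResult",
    "GapSet",
    "cpg_membership",
    "fisher_or",
    "layer_gap_regions",
    "condition_overlap",
]


@dataclass
class ContingencyResult:
    """2x2 CpG-membership table with Fisher's exact test and odds ratios.

    Table layout: a = in both, b = in A only, c = in B only, d = in neither.
    """

    a: int
    b: int
    c: int
    d: int
    or_sample: float
    or_estimate: float
    ci_low: float
    ci_high: float
    p_fisher: float

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class GapSet:
    """Complement intervals between consecutive DMRs within a span."""

    gaps: pd.DataFrame  # chrom, start, end (1-based inclusive)
    span: pd.DataFrame

    def __len__(self) -> int:
        return len(self.gaps)


def cpg_membership(probes: ProbeSet, regions: pd.DataFrame) -> np.ndarray:
    """Boolean vector: probe position falls inside some region (inclusive ends)."""
    return iv.membership(probes.chrom, probes.pos, regions)


def fisher_or(
    membership_a: np.ndarray,
    membership_b: np.ndarray,
    universe_mask: np.ndarray | None = None,
) -> ContingencyResult:
    """Fisher's exact test of association between two CpG memberships.

    ``universe_mask`` restricts which probes enter the table (e.g. only
    X-chromosome CpGs overlapping genes).  Zero margins yield degenerate
    odds-ratio estimates (0 or inf) with a finite p-value, not an error.
    """
    a_vec = np.asarray(membership_a, dtype=bool)
    b_vec = np.asarray(membership_b, dtype=bool)
    if a_vec.shape != b_vec.shape:
        raise ValueError("membership vectors must align")
    if universe_mask is not None:
        mask = np.asarray(universe_mask, dtype=bool)
        a_vec, b_vec = a_vec[mask], b_vec[mask]
    a = int(np.sum(a_vec & b_vec))
    b = int(np.sum(a_vec & ~b_vec))
    c = int(np.sum(~a_vec & b_vec))
    d = int(np.sum(~a_vec & ~b_vec))
    table = [[a, b], [c, d]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    or_sample = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else math.nan
    res = _cmle_odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return ContingencyResult(
        a=a,
        b=b,
        c=c,
        d=d,
        or_sample=or_sample,
        or_estimate=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_fisher=p,
    )


def layer_gap_regions(layer: list[DMRRecord] | pd.DataFrame, span: pd.DataFrame) -> GapSet:
    """Maximal intervals within ``span`` not covered by any DMR of the layer."""
    if isinstance(layer, pd.DataFrame):
        regions = layer
    else:
        regions = pd.DataFrame(
            {
                "chrom": [d.chrom for d in layer],
                "start": [d.start for d in layer],
                "end": [d.end for d in layer],
            }
        )
    span = iv.merge_regions(span)
    if len(regions):
        clipped = []
        for r in iv.merge_regions(regions).itertuples():
            for sp in span[span["chrom"] == r.chrom].itertuples():
                if r.start <= sp.end and r.end >= sp.start:
                    clipped.append((r.chrom, max(r.start, sp.start), min(r.end, sp.end)))
        regions = pd.DataFrame(clipped, columns=["chrom", "start", "end"])
    gaps = iv.complement(regions, span)
    return GapSet(gaps=gaps, span=span)


def condition_overlap(
    dmrs_a: pd.DataFrame,
    dmrs_b: pd.DataFrame,
    genes: pd.DataFrame | None = None,
) -> dict:
    """Cross-condition DMR and gene-set overlap report.

    Counts region pairs with >= 1 bp overlap and, when gene intervals are
    given, genes overlapped by at least one DMR in *each* condition — which
    catches genes hit in the two conditions through non-overlapping parts of
    the gene that the direct region overlap would miss.  Percentages are
    relative to each condition's totals.
    """
    ov = iv.overlap_matrix(dmrs_a, dmrs_b)
    pair_idx = np.argwhere(ov)
    a_hit = int(ov.any(axis=1).sum())
    b_hit = int(ov.any(axis=0).sum())
    report = {
        "n_pairs": int(len(pair_idx)),
        "pairs": [(int(i), int(j)) for i, j in pair_idx],
        "n_a": len(dmrs_a),
        "n_b": len(dmrs_b),
        "n_a_overlapping": a_hit,
        "n_b_overlapping": b_hit,
        "pct_a_overlapping": 100.0 * a_hit / len(dmrs_a) if len(dmrs_a) else math.nan,
        "pct_b_overlapping": 100.0 * b_hit / len(dmrs_b) if len(dmrs_b) else math.nan,
    }
    if genes is not None:
        ga = iv.overlap_matrix(genes, dmrs_a).any(axis=1)
        gb = iv.overlap_matrix(genes, dmrs_b).any(axis=1)
        shared = np.flatnonzero(ga & gb)
        names = (
            genes["name"].to_numpy()
            if "name" in genes.columns
            else np.array([f"gene_{i}" for i in range(len(genes))])
        )
        report.update(
            {
                "n_genes_a": int(ga.sum()),
                "n_genes_b": int(gb.sum()),
                "n_genes_shared": int(shared.size),
                "shared_genes": [str(names[i]) for i in shared],
                "pct_genes_a_shared": 100.0 * shared.size / ga.sum() if ga.sum() else math.nan,
                "pct_genes_b_shared": 100.0 * shared.size / gb.sum() if gb.sum() else math.nan,
            }
        )
    return report
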