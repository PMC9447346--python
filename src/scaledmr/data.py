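"""Data model and I/O for methylation-array probes, beta values, and DMR output.

Conventions
-----------
* Probe coordinates are stored 1-based inclusive (array manifests are
  1-based); BED is emitted/consumed 0-based half-open.
* Probes are globally ordered by (chrom, pos).  The global row index is the
  1-D axis that beta matrices, significance tracks and window scans share.
* All readers accept plain or gzip-compressed text (pandas infers).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeSet",
    "BetaMatrix",
    "SampleSheet",
    "DMRRecord",
    "load_probe_manifest",
    "load_beta_matrix",
    "load_sample_sheet",
    "filter_probes",
    "write_dmrs",
    "read_dmr_table",
    "read_bed",
    "write_bed",
]


class ProbeSet:
    """Ordered genomic CpG probe coordinates.

    Probes are sorted by (chrom, pos) with strictly increasing positions
    within each chromosome and unique probe ids.  ``index_in_chrom`` is a
    dense 0..n-1 rank within each chromosome.
    """

    def __init__(self, probe_id: Sequence[str], chrom: Sequence[str], pos: Sequence[int]):
        df = pd.DataFrame(
            {
                "probe_id": np.asarray(probe_id, dtype=object),
                "chrom": np.asarray(chrom, dtype=object),
                "pos": np.asarray(pos, dtype=np.int64),
            }
        )
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].unique()
            raise ValueError(f"duplicate probe_id(s): {', '.join(map(str, dups[:5]))}")
        if (df["pos"] < 1).any():
            raise ValueError("probe positions must be >= 1 (1-based)")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        # collapse duplicated (chrom, pos): keep the first probe at the site
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            logger.warning("collapsing %d probes at duplicated positions", int(dup.sum()))
            df = df.loc[~dup].reset_index(drop=True)
        self._df = df
        self._finalize()

    def _finalize(self) -> None:
        df = self._df
        self.probe_id = df["probe_id"].to_numpy(dtype=object)
        self.chrom = df["chrom"].to_numpy(dtype=object)
        self.pos = df["pos"].to_numpy(dtype=np.int64)
        self.index_in_chrom = df.groupby("chrom", sort=False).cumcount().to_numpy()
        # contiguous global-row slice per chromosome
        self.chrom_slices: dict[str, slice] = {}
        if len(df):
            change = np.flatnonzero(self.chrom[1:] != self.chrom[:-1]) + 1
            starts = np.concatenate(([0], change))
            stops = np.concatenate((change, [len(df)]))
            for s, e in zip(starts, stops):
                self.chrom_slices[self.chrom[s]] = slice(int(s), int(e))

    def __len__(self) -> int:
        return len(self._df)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_slices)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def subset(self, rows: np.ndarray) -> "ProbeSet":
        """New ProbeSet from an integer row index (or boolean mask) over global rows."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return ProbeSet(self.probe_id[rows], self.chrom[rows], self.pos[rows])


@dataclass
class BetaMatrix:
    """Beta values per probe x sample, rows aligned to a ProbeSet."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("beta values must be a 2-D matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample_ids")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError("column count does not match sample_ids")
        if np.isnan(self.values).any() or (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]


@dataclass
class SampleSheet:
    """Sample -> group assignment; exactly two groups for differential calling."""

    sample_id: list[str]
    group: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_id) != len(self.group):
            raise ValueError("sample_id and group must have equal length")
        if len(set(self.sample_id)) != len(self.sample_id):
            raise ValueError("duplicated sample_ids in sample sheet")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def group_columns(self, beta: BetaMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Column indices into ``beta`` for the two groups (order of appearance)."""
        groups = self.groups
        if len(groups) != 2:
            raise ValueError(f"exactly two groups required, found {len(groups)}")
        col = {s: i for i, s in enumerate(beta.sample_ids)}
        missing = [s for s in self.sample_id if s not in col]
        if missing:
            raise ValueError(f"samples absent from beta matrix: {missing[:5]}")
        idx = {g: [] for g in groups}
        for s, g in zip(self.sample_id, self.group):
            idx[g].append(col[s])
        a, b = (np.asarray(idx[g], dtype=int) for g in groups)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs >= 2 samples")
        return a, b


@dataclass
class DMRRecord:
    """A called differentially methylated region.

    ``start``/``end`` are 1-based inclusive genomic coordinates spanning the
    first to last member CpG; ``idx_first``/``idx_last`` are global probe row
    indices (inclusive).
    """

    chrom: str
    start: int
    end: int
    idx_first: int
    idx_last: int
    p_region: float
    p_adjusted: float
    layer: int
    mean_delta_beta: float = math.nan

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("DMR start > end")
        if self.idx_first > self.idx_last:
            raise ValueError("DMR has no member CpGs")
        if not (0.0 < self.p_region <= 1.0):
            raise ValueError("p_region must lie in (0, 1]")

    @property
    def n_cpgs(self) -> int:
        return self.idx_last - self.idx_first + 1

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def member_indices(self) -> np.ndarray:
        return np.arange(self.idx_first, self.idx_last + 1)


def _normalize_chrom(chrom: pd.Series, genome_style: str) -> pd.Series:
    if genome_style == "ucsc":
        return chrom.map(lambda c: c if str(c).startswith("chr") else f"chr{c}")
    if genome_style == "ensembl":
        return chrom.map(lambda c: str(c)[3:] if str(c).startswith("chr") else str(c))
    return chrom


def load_probe_manifest(path, genome_style: str = "as-is") -> ProbeSet:
    """Read a probe manifest (TSV with header probe_id/chrom/pos, or 3/4-column BED).

    BED starts (0-based) are converted to 1-based positions.  ``genome_style``
    is one of ``as-is``, ``ucsc`` (force chr prefix) or ``ensembl`` (strip it).
    """
    try:
        head = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty probe manifest: {path}")
    first_row = [str(v) for v in head.iloc[0].tolist()]
    is_tsv = "probe_id" in first_row
    if is_tsv:
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
        missing = {"probe_id", "chrom", "pos"} - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        pos = pd.to_numeric(df["pos"], errors="coerce")
    else:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 3:
            raise ValueError("BED manifest needs at least 3 columns")
        df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "probe_id"})
        if "probe_id" not in df.columns:
            df["probe_id"] = [f"probe_{i}" for i in range(len(df))]
        start = pd.to_numeric(df["start"], errors="coerce")
        pos = start + 1  # BED 0-based start -> 1-based position
    bad = pos.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"malformed position at data row {line} of {path}")
    if len(df) == 0:
        raise ValueError(f"empty probe manifest: {path}")
    chrom = _normalize_chrom(df["chrom"].astype(str), genome_style)
    return ProbeSet(df["probe_id"].astype(str), chrom, pos.astype(np.int64))


def load_beta_matrix(path, probes: ProbeSet) -> BetaMatrix:
    """Read a TSV beta matrix (probe_id rows x sample columns), row-aligned to probes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    extra = df.index.difference(pd.Index(probes.probe_id))
    if len(extra):
        logger.warning("dropping %d matrix probes absent from manifest", len(extra))
        df = df.drop(index=extra)
    missing = pd.Index(probes.probe_id).difference(df.index)
    if len(missing):
        raise ValueError(f"manifest probes absent from beta matrix: {list(missing[:5])}")
    df = df.loc[probes.probe_id]
    values = df.to_numpy()
    bad = ~np.isfinite(values) | (values < 0) | (values > 1)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"beta value out of [0,1] or non-numeric at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return BetaMatrix(values, [str(c) for c in df.columns])


def load_sample_sheet(path) -> SampleSheet:
    """Read a CSV/TSV sample sheet with columns sample_id, group."""
    sep = "\t" if str(path).replace(".gz", "").endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return SampleSheet(df["sample_id"].tolist(), df["group"].tolist())


def filter_probes(
    probes: ProbeSet,
    beta: BetaMatrix,
    exclude_ids: Iterable[str] = (),
    exclude_chroms: Iterable[str] = (),
) -> tuple[ProbeSet, BetaMatrix]:
    """Drop probes by id (e.g. SNP-overlapping) or chromosome (e.g. chrX/chrY).

    Rows are removed consistently from both structures and the global/within-
    chromosome indices re-densified.  Unknown ids are ignored with a log line.
    """
    exclude_ids = set(exclude_ids)
    unknown = exclude_ids - set(probes.probe_id)
    if unknown:
        logger.info("ignoring %d exclude_ids not present in manifest", len(unknown))
    exclude_chroms = set(exclude_chroms)
    keep = ~(
        np.isin(probes.probe_id, list(exclude_ids))
        | np.isin(probes.chrom, list(exclude_chroms))
    )
    if not keep.any():
        logger.warning("probe filter removed every probe")
    kept_idx = np.flatnonzero(keep)
    new_probes = ProbeSet(
        probes.probe_id[kept_idx], probes.chrom[kept_idx], probes.pos[kept_idx]
    )
    new_beta = BetaMatrix(beta.values[kept_idx], list(beta.sample_ids))
    return new_probes, new_beta


_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "idx_first",
    "idx_last",
    "n_cpgs",
    "p_region",
    "p_adjusted",
    "layer",
    "mean_delta_beta",
]


def _bed_score(p_adjusted: float) -> int:
    """-log10 adjusted p, capped at 1000 (BED score convention)."""
    if p_adjusted <= 0:
        return 1000
    return int(min(1000, round(-math.log10(p_adjusted))))


def write_dmrs(dmrs: Sequence[DMRRecord], path_bed, path_table) -> None:
    """Write DMRs as BED (0-based half-open) and a full TSV table.

    BED name is ``layer:rank`` with rank assigned after the deterministic
    (chrom, start) sort; score is -log10(p_adjusted) capped at 1000.
    """
    ordered = sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end))
    with open(path_bed, "w") as bed:
        for rank, d in enumerate(ordered, start=1):
            bed.write(
                f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.layer}:{rank}\t"
                f"{_bed_score(d.p_adjusted)}\t.\n"
            )
    rows = [
        {
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "idx_first": d.idx_first,
            "idx_last": d.idx_last,
            "n_cpgs": d.n_cpgs,
            "p_region": d.p_region,
            "p_adjusted": d.p_adjusted,
            "layer": d.layer,
            "mean_delta_beta": d.mean_delta_beta,
        }
        for d in ordered
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path_table, sep="\t", index=False)


def read_dmr_table(path) -> list[DMRRecord]:
    """Re-read a TSV written by :func:`write_dmrs`."""
    df = pd.read_csv(path, sep="\t")
    return [
        DMRRecord(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            idx_first=int(r.idx_first),
            idx_last=int(r.idx_last),
            p_region=float(r.p_region),
            p_adjusted=float(r.p_adjusted),
            layer=int(r.layer),
            mean_delta_beta=float(r.mean_delta_beta),
        )
        for r in df.itertuples()
    ]


def read_bed(path) -> pd.DataFrame:
    """Read a BED file into a frame with 1-based inclusive start/end columns.

    Returns columns chrom, start, end (1-based inclusive), name, score where
    present.  Used for truth regions, annotations, and third-party caller output.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str}, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": pd.to_numeric(df[1]) + 1,
            "end": pd.to_numeric(df[2]),
        }
    )
    if df.shape[1] > 3:
        out["name"] = df[3].astype(str)
    if df.shape[1] > 4:
        out["score"] = pd.to_numeric(df[4], errors="coerce")
    return out


def write_bed(regions: pd.DataFrame, path) -> None:
    """Write a frame with 1-based inclusive chrom/start/end (+optional name, score)."""
    has_name = "name" in regions.columns
    has_score = "score" in regions.columns
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fields = [str(r["chrom"]), str(int(r["start"]) - 1), str(int(r["end"]))]
            if has_name or has_score:
                fields.append(str(r["name"]) if has_name else ".")
            if has_score:
                fields.append(str(r["score"]))
            fh.write("\t".join(fields) + "\n")
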