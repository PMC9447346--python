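"""DMR-injection simulation on an array-like synthetic methylation backbone.

The benchmark design: randomly split samples into two groups, pick
non-overlapping genomic regions in four order-of-magnitude size classes
(0.1-1 kb, 1-10 kb, 10-100 kb, 0.1-1 Mb, requiring at least 3/6/9/12 member
CpGs respectively and >= 10 probes of spacing between regions), optionally
mask a fraction of each region's interior CpGs (the *noise* parameter, which
models the methylation heterogeneity of neighboring CpGs in real data), and
inflate the beta values of the group with the higher regional mean by a
fixed delta-beta at every non-masked member CpG.  Probes pushed above 1 are
rescaled by dividing all of that probe's beta values by the probe maximum.

The synthetic backbone emulates the salient features of a normalized
450K/EPIC beta matrix: probe spacing mixing dense CpG-island clusters with a
sparse background, a bimodal beta distribution with modes near 0 and 1, and
modest between-sample dispersion per probe.  It is a synthetic stand-in for
a real normalized matrix, which can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BetaMatrix, ProbeSet, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "BackboneConfig",
    "SimulationConfig",
    "SimulatedDMR",
    "generate_backbone",
    "assign_groups",
    "sample_dmr_regions",
    "inject_dmrs",
    "simulate_dataset",
    "SimulatedDataset",
]

DEFAULT_SIZE_CLASSES = (
    (100, 1_000, 3),
    (1_000, 10_000, 6),
    (10_000, 100_000, 9),
    (100_000, 1_000_000, 12),
)


@dataclass
class BackboneConfig:
    """Synthetic array backbone parameters.

    Probe spacing mimics an Illumina-array design as a three-component
    mixture of probe "units" separated by long background gaps: dense CpG
    islands (tens-of-bp internal spacing), gene-body/shore runs
    (kilobase-scale internal spacing), and solitary open-sea probes.  Beta
    baselines come from a Beta-mixture with modes near 0 and 1; per-sample
    values jitter around the baseline with a per-probe Gaussian sd drawn
    around ``mean_sample_sd`` and are clipped to [0, 1].
    """

    n_probes: int = 50_000
    n_samples: int = 53
    n_chroms: int = 4
    island_weight: float = 0.35
    island_mean_probes: float = 14.0
    island_min_probes: int = 3
    island_gap_median: float = 30.0
    island_gap_sigma: float = 0.5
    body_weight: float = 0.35
    body_mean_probes: float = 5.0
    body_min_probes: int = 2
    body_gap_median: float = 1_500.0
    body_gap_sigma: float = 0.7
    background_gap_median: float = 30_000.0
    background_gap_sigma: float = 1.0
    low_mode_shape: tuple[float, float] = (1.5, 12.0)
    high_mode_shape: tuple[float, float] = (12.0, 1.5)
    high_mode_weight: float = 0.5
    mean_sample_sd: float = 0.03


@dataclass
class SimulationConfig:
    """Study conditions for one DMR-injection run."""

    n_per_group: int = 8
    size_classes: tuple[tuple[float, float, int], ...] = DEFAULT_SIZE_CLASSES
    n_dmrs_per_class: int = 25
    spacing_cpgs: int = 10
    noise: float = 0.5
    delta_beta: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise < 1.0):
            raise ValueError("noise must lie in [0, 1)")
        if not (0.0 < self.delta_beta < 1.0):
            raise ValueError("delta_beta must lie in (0, 1)")
        spans = sorted((lo, hi) for lo, hi, _ in self.size_classes)
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo < hi:
                raise ValueError("size classes must not overlap")


@dataclass
class SimulatedDMR:
    """One injected truth region."""

    chrom: str
    start: int
    end: int
    member_indices: np.ndarray  # global probe rows, ascending
    size_class: str
    masked_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    inflated_group: str | None = None

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def n_cpgs(self) -> int:
        return self.member_indices.size


def generate_backbone(
    config: BackboneConfig | None = None, seed: int = 0
) -> tuple[ProbeSet, BetaMatrix]:
    """Generate a synthetic probe layout and beta matrix."""
    cfg = config or BackboneConfig()
    rng = np.random.default_rng(seed)
    per_chrom = np.full(cfg.n_chroms, cfg.n_probes // cfg.n_chroms)
    per_chrom[: cfg.n_probes % cfg.n_chroms] += 1

    chroms, positions = [], []
    for ci, n_c in enumerate(per_chrom, start=1):
        gaps: list[int] = []
        while len(gaps) < n_c:
            gaps.append(
                max(
                    50,
                    int(rng.lognormal(np.log(cfg.background_gap_median), cfg.background_gap_sigma)),
                )
            )
            u = rng.random()
            if u < cfg.island_weight:
                size = cfg.island_min_probes + rng.poisson(
                    max(cfg.island_mean_probes - cfg.island_min_probes, 0.0)
                )
                med, sig = cfg.island_gap_median, cfg.island_gap_sigma
            elif u < cfg.island_weight + cfg.body_weight:
                size = cfg.body_min_probes + rng.poisson(
                    max(cfg.body_mean_probes - cfg.body_min_probes, 0.0)
                )
                med, sig = cfg.body_gap_median, cfg.body_gap_sigma
            else:
                continue  # solitary probe
            intra = rng.lognormal(np.log(med), sig, size - 1)
            gaps.extend(np.maximum(2, intra).astype(int))
        pos = 1 + np.cumsum(np.asarray(gaps[:n_c], dtype=np.int64))
        chroms.extend([f"chr{ci}"] * n_c)
        positions.append(pos)
    pos = np.concatenate(positions)
    probe_ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    probes = ProbeSet(probe_ids, chroms, pos)

    n_high = rng.random(cfg.n_probes) < cfg.high_mode_weight
    baseline = np.where(
        n_high,
        rng.beta(*cfg.high_mode_shape, cfg.n_probes),
        rng.beta(*cfg.low_mode_shape, cfg.n_probes),
    )
    if cfg.mean_sample_sd > 0:
        sd = rng.gamma(4.0, cfg.mean_sample_sd / 4.0, cfg.n_probes)
        noise = rng.normal(0.0, 1.0, (cfg.n_probes, cfg.n_samples)) * sd[:, None]
    else:
        noise = np.zeros((cfg.n_probes, cfg.n_samples))
    values = np.clip(baseline[:, None] + noise, 0.0, 1.0)
    sample_ids = [f"S{j:02d}" for j in range(cfg.n_samples)]
    return probes, BetaMatrix(values, sample_ids)


def assign_groups(sample_ids, n_per_group: int, seed: int = 0) -> SampleSheet:
    """Draw two disjoint groups of ``n_per_group`` samples without replacement."""
    sample_ids = list(sample_ids)
    if len(sample_ids) < 2 * n_per_group:
        raise ValueError(
            f"pool of {len(sample_ids)} samples cannot supply two groups of {n_per_group}"
        )
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(sample_ids, size=2 * n_per_group, replace=False))
    groups = ["Group1"] * n_per_group + ["Group2"] * n_per_group
    return SampleSheet(chosen, groups)


def sample_dmr_regions(
    probes: ProbeSet,
    config: SimulationConfig,
    seed: int | None = None,
    max_tries: int = 5_000,
) -> list[SimulatedDMR]:
    """Place non-overlapping truth regions satisfying the size-class constraints.

    Region sizes are drawn log-uniformly within each class and anchored at a
    random probe, then snapped to the first/last probe they span; a
    placement is accepted only if the snapped extent stays within the class
    size range, meets the class's minimum CpG count, and sits at least
    ``spacing_cpgs`` probes away from every previously accepted region.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    placed: list[SimulatedDMR] = []
    occupied: list[tuple[int, int]] = []  # global index ranges, kept sorted

    def _spacing_ok(f: int, l: int) -> bool:
        for f0, l0 in occupied:
            if not (f > l0 + config.spacing_cpgs or l < f0 - config.spacing_cpgs):
                return False
        return True

    # place the large classes first: they are the hardest to fit
    for lo, hi, min_cpgs in sorted(config.size_classes, reverse=True):
        label = f"{int(lo)}-{int(hi)}bp"
        for _ in range(config.n_dmrs_per_class):
            for attempt in range(max_tries):
                size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                anchor = int(rng.integers(0, len(probes)))
                chrom = probes.chrom[anchor]
                start = int(probes.pos[anchor]) - int(rng.integers(0, size))
                if start < 1:
                    continue
                end = start + size - 1
                sl = probes.chrom_slices[chrom]
                cpos = probes.pos[sl]
                f_local = int(np.searchsorted(cpos, start, side="left"))
                l_local = int(np.searchsorted(cpos, end, side="right")) - 1
                f, l = sl.start + f_local, sl.start + l_local
                if l - f + 1 < min_cpgs:
                    continue
                snap_start = int(cpos[f_local])
                snap_end = int(cpos[l_local])
                if not (lo <= snap_end - snap_start + 1 <= hi):
                    continue
                if not _spacing_ok(f, l):
                    continue
                members = np.arange(f, l + 1)
                placed.append(
                    SimulatedDMR(
                        chrom=chrom, start=snap_start, end=snap_end,
                        member_indices=members, size_class=label,
                    )
                )
                occupied.append((f, l))
                break
            else:
                raise RuntimeError(
                    f"could not place {config.n_dmrs_per_class} regions of class "
                    f"{label} after {max_tries} tries each (placed "
                    f"{sum(r.size_class == label for r in placed)})"
                )
    placed.sort(key=lambda r: (r.chrom, r.start))
    return placed


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def inject_dmrs(
    beta: BetaMatrix,
    groups: SampleSheet,
    regions: list[SimulatedDMR],
    noise: float,
    delta_beta: float,
    seed: int = 0,
) -> tuple[BetaMatrix, list[SimulatedDMR]]:
    """Inflate the higher-mean group's beta at non-masked member CpGs.

    Per region: mask round(noise x interior) interior probes (the first and
    last member CpGs are never masked); the group with the greater mean beta
    over member probes gets +delta_beta at every non-masked member; any probe
    whose maximum beta exceeds 1 has all of its beta values divided by that
    maximum.  Masked probes are untouched.  Regions are updated in place with
    masked indices and the inflated group and also returned.
    """
    rng = np.random.default_rng(seed)
    values = beta.values.copy()
    ai, bi = groups.group_columns(beta)
    names = groups.groups
    touched: list[np.ndarray] = []
    for region in regions:
        members = region.member_indices
        interior = members[1:-1]
        n_mask = _round_half_up(noise * interior.size) if interior.size else 0
        masked = (
            np.sort(rng.choice(interior, size=n_mask, replace=False))
            if n_mask
            else np.empty(0, dtype=int)
        )
        non_masked = np.setdiff1d(members, masked)
        mean_a = values[np.ix_(members, ai)].mean()
        mean_b = values[np.ix_(members, bi)].mean()
        cols, gname = (ai, names[0]) if mean_a >= mean_b else (bi, names[1])
        values[np.ix_(non_masked, cols)] += delta_beta
        region.masked_indices = masked
        region.inflated_group = gname
        touched.append(non_masked)
    if touched:
        rows = np.unique(np.concatenate(touched))
        row_max = values[rows].max(axis=1)
        over = row_max > 1.0
        values[rows[over]] /= row_max[over, None]
    return BetaMatrix(values, list(beta.sample_ids)), regions


@dataclass
class SimulatedDataset:
    """A complete injected dataset plus its ground truth."""

    beta: BetaMatrix
    samples: SampleSheet
    truth: list[SimulatedDMR]
    config: SimulationConfig

    def truth_frame(self) -> pd.DataFrame:
        """Truth regions as a 1-based inclusive frame (BED-writable)."""
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.truth],
                "start": [r.start for r in self.truth],
                "end": [r.end for r in self.truth],
                "name": [r.size_class for r in self.truth],
            }
        )

    def params(self) -> dict:
        return {
            "n_per_group": self.config.n_per_group,
            "size_classes": [list(c) for c in self.config.size_classes],
            "n_dmrs_per_class": self.config.n_dmrs_per_class,
            "spacing_cpgs": self.config.spacing_cpgs,
            "noise": self.config.noise,
            "delta_beta": self.config.delta_beta,
            "seed": self.config.seed,
            "n_truth": len(self.truth),
        }


def simulate_dataset(
    probes: ProbeSet,
    beta: BetaMatrix,
    config: SimulationConfig,
) -> SimulatedDataset:
    """Compose group assignment, region placement, and injection.

    The backbone may be synthetic (:func:`generate_backbone`) or a real
    normalized beta matrix; the injection pipeline is identical.
    """
    ss = np.random.SeedSequence(config.seed)
    s_groups, s_regions, s_inject = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    samples = assign_groups(beta.sample_ids, config.n_per_group, seed=s_groups)
    regions = sample_dmr_regions(probes, config, seed=s_regions)
    injected, regions = inject_dmrs(
        beta, samples, regions, config.noise, config.delta_beta, seed=s_inject
    )
    return SimulatedDataset(beta=injected, samples=samples, truth=regions, config=config)
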