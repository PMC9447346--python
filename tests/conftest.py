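import numpy as np
import pytest

from scaledmr import (
    BackboneConfig,
    BetaMatrix,
    ProbeSet,
    SampleSheet,
    SignificanceTrack,
    SimulationConfig,
    generate_backbone,
    rank_cpgs,
    simulate_dataset,
)


def make_probes(n, chrom="chr1", spacing=100, start=1000):
    """Evenly spaced probes on one chromosome."""
    pos = start + spacing * np.arange(n)
    return ProbeSet([f"cg{i:06d}" for i in range(n)], [chrom] * n, pos)


def make_track(p, seed_delta=0.0):
    p = np.asarray(p, dtype=float)
    return rank_cpgs(SignificanceTrack(p=p, delta_beta=np.full(p.size, seed_delta)))


def two_group_sheet(n1=4, n2=4):
    ids = [f"s{i}" for i in range(n1 + n2)]
    return SampleSheet(ids, ["A"] * n1 + ["B"] * n2)


@pytest.fixture(scope="session")
def small_backbone():
    """A small synthetic backbone shared across tests (4,000 probes)."""
    cfg = BackboneConfig(n_probes=4_000, n_samples=24, n_chroms=2)
    return generate_backbone(cfg, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_backbone):
    """An injected dataset on the small backbone (5 truth DMRs per class)."""
    probes, beta = small_backbone
    cfg = SimulationConfig(n_per_group=8, n_dmrs_per_class=5, seed=7)
    return probes, simulate_dataset(probes, beta, cfg)
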