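import numpy as np
import pytest

from scaledmr import (
    BackboneConfig,
    BetaMatrix,
    SimulationConfig,
    assign_groups,
    generate_backbone,
    inject_dmrs,
    sample_dmr_regions,
    simulate_dataset,
)


class TestBackbone:
    def test_beta_distribution_is_bimodal(self, small_backbone):
        probes, beta = small_backbone
        v = beta.values.ravel()
        assert np.mean(v < 0.25) > 0.25
        assert np.mean(v > 0.75) > 0.25
        assert np.mean((v > 0.4) & (v < 0.6)) < 0.15

    def test_same_seed_reproduces(self):
        cfg = BackboneConfig(n_probes=500, n_samples=5)
        p1, b1 = generate_backbone(cfg, seed=3)
        p2, b2 = generate_backbone(cfg, seed=3)
        np.testing.assert_array_equal(p1.pos, p2.pos)
        np.testing.assert_array_equal(b1.values, b2.values)

    def test_zero_dispersion_gives_identical_samples(self):
        cfg = BackboneConfig(n_probes=200, n_samples=4, mean_sample_sd=0.0)
        _, beta = generate_backbone(cfg, seed=1)
        assert np.all(beta.values == beta.values[:, :1])

    def test_positions_strictly_increasing_per_chromosome(self, small_backbone):
        probes, _ = small_backbone
        for sl in probes.chrom_slices.values():
            assert np.all(np.diff(probes.pos[sl]) > 0)


class TestAssignGroups:
    def test_two_disjoint_groups_from_pool(self):
        pool = [f"s{i}" for i in range(53)]
        sheet = assign_groups(pool, 8, seed=1)
        g1 = [s for s, g in zip(sheet.sample_id, sheet.group) if g == "Group1"]
        g2 = [s for s, g in zip(sheet.sample_id, sheet.group) if g == "Group2"]
        assert len(g1) == len(g2) == 8
        assert not set(g1) & set(g2)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            assign_groups([f"s{i}" for i in range(15)], 8)

    def test_seed_reproducibility(self):
        pool = [f"s{i}" for i in range(20)]
        assert assign_groups(pool, 8, seed=5).sample_id == assign_groups(pool, 8, seed=5).sample_id


class TestRegionSampling:
    def test_constraints_hold_for_every_region(self, small_dataset):
        probes, ds = small_dataset
        mins = {f"{int(lo)}-{int(hi)}bp": (lo, hi, mc) for lo, hi, mc in ds.config.size_classes}
        spans = sorted(
            (r.member_indices[0], r.member_indices[-1]) for r in ds.truth
        )
        for r in ds.truth:
            lo, hi, min_cpgs = mins[r.size_class]
            assert r.n_cpgs >= min_cpgs
            assert lo <= r.width <= hi
            # extent snapped to member probes
            assert r.start == probes.pos[r.member_indices[0]]
            assert r.end == probes.pos[r.member_indices[-1]]
        for (f1, l1), (f2, l2) in zip(spans, spans[1:]):
            assert f2 - l1 > ds.config.spacing_cpgs

    def test_zero_regions_requested(self, small_backbone):
        probes, _ = small_backbone
        cfg = SimulationConfig(n_dmrs_per_class=0)
        assert sample_dmr_regions(probes, cfg, seed=0) == []

    def test_impossible_request_errors_with_class(self, small_backbone):
        probes, _ = small_backbone
        cfg = SimulationConfig(n_dmrs_per_class=10_000)
        with pytest.raises(RuntimeError, match="could not place"):
            sample_dmr_regions(probes, cfg, seed=0, max_tries=20)


class TestInjection:
    def _tiny(self):
        # 5 probes, 2 samples per group; region covers probes 1..3
        vals = np.array(
            [
                [0.50, 0.50, 0.50, 0.50],
                [0.85, 0.95, 0.30, 0.35],
                [0.40, 0.45, 0.20, 0.25],
                [0.60, 0.65, 0.30, 0.35],
                [0.50, 0.50, 0.50, 0.50],
            ]
        )
        beta = BetaMatrix(vals, ["a1", "a2", "b1", "b2"])
        from scaledmr import SampleSheet
        sheet = SampleSheet(["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"])
        from scaledmr import SimulatedDMR
        region = SimulatedDMR("chr1", 100, 300, np.array([1, 2, 3]), "toy")
        return beta, sheet, region

    def test_max_rescale_divides_whole_probe_row(self):
        beta, sheet, region = self._tiny()
        out, regs = inject_dmrs(beta, sheet, [region], noise=0.0, delta_beta=0.2, seed=0)
        # probe 1: group A (higher mean) inflated to (1.05, 1.15) then the
        # entire row is divided by the row max 1.15
        np.testing.assert_allclose(
            out.values[1], [1.05 / 1.15, 1.0, 0.30 / 1.15, 0.35 / 1.15]
        )
        assert regs[0].inflated_group == "A"

    def test_noise_zero_masks_nothing(self):
        beta, sheet, region = self._tiny()
        _, regs = inject_dmrs(beta, sheet, [region], noise=0.0, delta_beta=0.1, seed=0)
        assert regs[0].masked_indices.size == 0

    def test_two_probe_region_has_nothing_to_mask(self):
        beta, sheet, region = self._tiny()
        region.member_indices = np.array([1, 2])
        _, regs = inject_dmrs(beta, sheet, [region], noise=0.9, delta_beta=0.1, seed=0)
        assert regs[0].masked_indices.size == 0

    def test_first_and_last_member_never_masked(self, small_dataset):
        _, ds = small_dataset
        for r in ds.truth:
            assert r.member_indices[0] not in r.masked_indices
            assert r.member_indices[-1] not in r.masked_indices
            interior = r.member_indices.size - 2
            expected = int(np.floor(ds.config.noise * max(interior, 0) + 0.5))
            assert r.masked_indices.size == expected

    def test_masked_probes_unchanged_and_beta_bounded(self, small_backbone):
        probes, beta = small_backbone
        cfg = SimulationConfig(n_per_group=8, n_dmrs_per_class=5, seed=13)
        ds = simulate_dataset(probes, beta, cfg)
        assert ds.beta.values.min() >= 0.0 and ds.beta.values.max() <= 1.0
        for r in ds.truth:
            if r.masked_indices.size:
                np.testing.assert_array_equal(
                    ds.beta.values[r.masked_indices], beta.values[r.masked_indices]
                )

    def test_mean_delta_near_target_at_nonmasked_probes(self, small_dataset):
        probes, ds = small_dataset
        ai, bi = ds.samples.group_columns(ds.beta)
        diffs = []
        for r in ds.truth:
            live = np.setdiff1d(r.member_indices, r.masked_indices)
            d = ds.beta.values[np.ix_(live, ai)].mean(1) - ds.beta.values[np.ix_(live, bi)].mean(1)
            if r.inflated_group == ds.samples.groups[1]:
                d = -d
            diffs.append(d)
        mean_shift = float(np.mean(np.concatenate(diffs)))
        # rescaling of probes pushed above 1 shrinks the realized shift a bit
        assert 0.6 * ds.config.delta_beta <= mean_shift <= 1.05 * ds.config.delta_beta


class TestDataset:
    def test_truth_count_and_reproducibility(self, small_backbone):
        probes, beta = small_backbone
        cfg = SimulationConfig(n_per_group=8, n_dmrs_per_class=5, seed=21)
        d1 = simulate_dataset(probes, beta, cfg)
        d2 = simulate_dataset(probes, beta, cfg)
        assert len(d1.truth) == 4 * 5
        assert d1.truth_frame().equals(d2.truth_frame())
        np.testing.assert_array_equal(d1.beta.values, d2.beta.values)
        assert d1.samples.sample_id == d2.samples.sample_id

    def test_params_record_study_conditions(self, small_dataset):
        _, ds = small_dataset
        p = ds.params()
        assert p["noise"] == 0.5 and p["delta_beta"] == 0.2
        assert p["n_truth"] == len(ds.truth)
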