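"""Synthetic cohort generator: determinism, calibration, rendering."""
import json

import numpy as np
import pytest

import fluctica as fl
from fluctica.cohort import (
    CohortConfig,
    ComponentSpec,
    build_cohort,
    make_component_map,
    render_cohort,
    simulate_timecourses,
)
from fluctica.design import IMAGERY, SUPPRESSION


def small_config(n_subjects=2, n_runs=2, **kw):
    return CohortConfig(n_subjects=n_subjects, n_runs=n_runs, **kw)


class TestComponentSpec:
    def test_negative_fluct_sd_rejected(self):
        with pytest.raises(ValueError, match="fluct_sd"):
            ComponentSpec("x", 1, fluct_sd={IMAGERY: -0.1})

    def test_coupling_weight_bound(self):
        with pytest.raises(ValueError, match="coupling"):
            ComponentSpec("x", 1, coupling={"y": 1.5})

    def test_artifact_carries_no_task_structure(self):
        with pytest.raises(ValueError, match="artifact"):
            ComponentSpec(
                "x", 1, baseline={IMAGERY: 1.0}, spectral_band=(0.15, 0.25)
            )

    def test_mutual_coupling_rejected(self):
        a = ComponentSpec("a", 1, coupling={"b": 0.5})
        b = ComponentSpec("b", 2, coupling={"a": 0.5})
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="symmetrizable"):
            simulate_timecourses(fl.build_block_design(), (a, b), rng)


class TestSimulateTimecourses:
    def test_zero_fluct_sd_gives_identical_trials(self):
        design = fl.build_block_design()
        spec = ComponentSpec(
            "net", 1, {IMAGERY: 1.0, SUPPRESSION: 0.0}, {IMAGERY: 0.0, SUPPRESSION: 0.0}
        )
        tc, latent = simulate_timecourses(design, (spec,), np.random.default_rng(0))
        assert np.all(latent == 0)
        segs = [
            tc[idx, 0]
            for _, idx in design.phase_volume_indices(IMAGERY, drop_initial=4)
        ]
        for s in segs[1:]:
            assert np.allclose(s, segs[0], atol=1e-12)

    def test_coupling_weight_recovered_at_large_n(self):
        """Latent correlation of a +0.8-coupled pair converges to 0.8."""
        design = fl.build_block_design(24.0, 100, 1, 2.0, 0.0)  # 200 blocks
        specs = (
            ComponentSpec("hub", 1, fluct_sd={IMAGERY: 1.0, SUPPRESSION: 1.0}),
            ComponentSpec(
                "spoke",
                2,
                fluct_sd={IMAGERY: 1.0, SUPPRESSION: 1.0},
                coupling={"hub": 0.8},
            ),
        )
        _, latent = simulate_timecourses(design, specs, np.random.default_rng(3))
        r = np.corrcoef(latent[:, 0], latent[:, 1])[0, 1]
        assert abs(r - 0.8) < 0.05

    def test_artifact_power_confined_to_band(self):
        design = fl.build_block_design()
        spec = ComponentSpec("art", 1, spectral_band=(0.15, 0.25))
        tc, _ = simulate_timecourses(design, (spec,), np.random.default_rng(1))
        power = np.abs(np.fft.rfft(tc[:, 0] - tc[:, 0].mean())) ** 2
        freqs = np.fft.rfftfreq(tc.shape[0], d=2.0)
        assert power[freqs >= 0.15].sum() / power.sum() > 0.95

    def test_fluct_sd_calibration(self):
        """Empirical within-block sd converges to fluct_sd (<5% rel. error
        over >= 1e4 pooled samples)."""
        design = fl.build_block_design(24.0, 110, 2, 2.0, 0.0)  # 2640 vols/cond
        spec = ComponentSpec("net", 1, fluct_sd={IMAGERY: 0.5, SUPPRESSION: 1.0})
        rng = np.random.default_rng(7)
        samples = {IMAGERY: [], SUPPRESSION: []}
        for _ in range(4):
            _, latent = simulate_timecourses(design, (spec,), rng)
            conds = design.volume_conditions()
            for c in (IMAGERY, SUPPRESSION):
                samples[c].append(latent[conds == c, 0])
        for c, target in ((IMAGERY, 0.5), (SUPPRESSION, 1.0)):
            pooled = np.concatenate(samples[c])
            assert pooled.size >= 10_000
            assert abs(pooled.std() - target) / target < 0.05


class TestGroundTruth:
    def test_linear_mixing_identity_without_noise(self):
        spec = ComponentSpec("net", 5, {IMAGERY: 1.0}, {IMAGERY: 0.3, SUPPRESSION: 0.3})
        cfg = small_config(voxel_noise_sd=0.0, specs=(spec,), control_component="net")
        gt = build_cohort(cfg, master_seed=0)
        data = gt.data(0, 0)
        expected = np.outer(gt.timecourses[0, 0][:, 0], gt.true_maps[:, 0])
        assert np.allclose(data, expected, atol=1e-12)

    def test_rank_equals_component_count_without_noise(self):
        cfg = CohortConfig(n_subjects=1, n_runs=1, voxel_noise_sd=0.0)
        gt = build_cohort(cfg, master_seed=0)
        sv = np.linalg.svd(gt.data(0, 0) - gt.data(0, 0).mean(0), compute_uv=False)
        rank = int((sv > sv[0] * 1e-8).sum())
        assert rank == len(gt.specs)

    def test_report_median_split_nonempty_groups(self, cohort):
        assert set(np.unique(cohort.reports)) == {0, 1}
        assert cohort.reports.sum() == cohort.config.n_subjects // 2

    def test_determinism_of_timecourses(self):
        cfg = small_config()
        a = build_cohort(cfg, master_seed=11)
        b = build_cohort(cfg, master_seed=11)
        assert np.array_equal(a.timecourses, b.timecourses)
        assert np.array_equal(a.data(1, 0), b.data(1, 0))
        c = build_cohort(cfg, master_seed=12)
        assert not np.array_equal(a.timecourses, c.timecourses)


class TestRenderCohort:
    def test_file_inventory_and_sidecar_determinism(self, tmp_path):
        cfg = small_config()
        gt = build_cohort(cfg, master_seed=3)
        paths = render_cohort(gt, tmp_path / "a")
        assert len(paths["bold"]) == 4  # 2 subjects x 2 runs
        assert len(paths["events"]) == 4
        sidecar_a = (tmp_path / "a" / "ground_truth.json").read_bytes()
        render_cohort(build_cohort(cfg, master_seed=3), tmp_path / "b")
        sidecar_b = (tmp_path / "b" / "ground_truth.json").read_bytes()
        assert sidecar_a == sidecar_b
        payload = json.loads(sidecar_a)
        assert payload["schema_version"].startswith("fluctica-ground-truth")

    def test_roundtrip_via_load_cohort(self, tmp_path):
        cfg = small_config()
        gt = build_cohort(cfg, master_seed=3)
        render_cohort(gt, tmp_path)
        datasets, index, design, mask, participants = fl.load_cohort(tmp_path)
        assert len(datasets) == 4
        assert design.run_length_s == 408.0
        assert design.tr == 2.0
        assert len(design.blocks) == 16
        assert mask.sum() == gt.mask.sum()
        assert list(participants["report_success"]) == list(gt.reports)
        # float32 round-trip of the voxel data
        assert np.allclose(datasets[0], gt.data(0, 0), atol=1e-3)

    def test_events_table_contents(self, tmp_path):
        gt = build_cohort(small_config(), master_seed=3)
        render_cohort(gt, tmp_path)
        import pandas as pd

        ev = pd.read_csv(tmp_path / "sub-01_run-1_events.tsv", sep="\t")
        assert set(ev["trial_type"]) == {IMAGERY, SUPPRESSION, "cue"}
        assert (ev[ev.trial_type == "cue"]["duration"] == 2.0).all()
        assert ev["onset"].min() == 24.0


class TestComponentMap:
    def test_map_is_deterministic_compact_normalised(self):
        spec = ComponentSpec("net", 42, anchor=(8.0, 8.0, 4.0))
        a = make_component_map(spec)
        b = make_component_map(spec)
        assert np.array_equal(a, b)
        assert a.max() == 1.0
        assert (a > 0).sum() < a.size * 0.25  # compact support
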