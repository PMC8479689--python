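"""Synthetic cohort generator: determinism, defaults, round-trip identity."""
import dataclasses

import numpy as np
import pytest

from rbctweezer import (CohortConfig, FluidConfig, StageMotion, drag_force,
                        evaluate_cell)
from rbctweezer.errors import ConfigError
from rbctweezer.synthetic import (generate_elasticity_cohort,
                                  generate_morphology_cohort,
                                  default_cohort_configs, subgroup_drag_targets,
                                  subgroup_speeds)


class TestDefaults:
    def test_default_cohort_means(self, defaults):
        assert defaults.hbas.trap_force_mean_pN == 0.26
        assert defaults.hbss.trap_force_mean_pN == 0.33
        assert defaults.sct.diameter_mean == 4.02
        assert defaults.sca.diameter_mean == 6.60
        assert defaults.hbas.stiffness_mean == 1.08
        assert defaults.hbss.stiffness_mean == 4.47
        assert defaults.hbas.radius_range == (3.84, 5.38)
        assert defaults.hbss.radius_range == (4.45, 6.12)

    def test_default_configs_validate(self, defaults):
        # construction already runs validation; double-check key invariants
        for cfg in (defaults.sct, defaults.sca, defaults.hbas, defaults.hbss):
            assert cfg.n_cells >= 1
        assert defaults.hbas.n_cells == defaults.hbss.n_cells == 49

    def test_subgroup_targets_mean_equals_cohort_mean(self, defaults):
        targets = subgroup_drag_targets(defaults.hbas)
        assert np.mean(targets) == pytest.approx(1.20, rel=1e-12)

    def test_speeds_reproduce_targets_at_mean_radius(self, defaults, fluid):
        speeds = subgroup_speeds(defaults.hbss, fluid)
        targets = subgroup_drag_targets(defaults.hbss)
        for v, f in zip(speeds, targets):
            got = drag_force(fluid, defaults.hbss.radius_mean * 1e-6,
                             StageMotion(speed=v * 1e-6)) * 1e12
            assert got == pytest.approx(f, rel=1e-9)


class TestValidation:
    def test_morphology_config_requires_diameter(self):
        with pytest.raises(ConfigError, match="diameter_mean"):
            CohortConfig(label="X", mode="morphology", n_cells=10)

    def test_elasticity_needs_subgroup_divisibility(self, defaults):
        with pytest.raises(ConfigError, match="7 subgroups"):
            dataclasses.replace(defaults.hbas, n_cells=50)

    def test_radius_range_must_bracket_mean(self, defaults):
        with pytest.raises(ConfigError, match="radius_range"):
            dataclasses.replace(defaults.hbas, radius_range=(5.0, 6.0))

    def test_mode_mismatch_rejected(self, defaults):
        with pytest.raises(ConfigError):
            generate_elasticity_cohort(defaults.sct)
        with pytest.raises(ConfigError):
            generate_morphology_cohort(defaults.hbas)


class TestMorphologyCohort:
    def test_same_seed_identical_dataset(self, defaults):
        a = generate_morphology_cohort(defaults.sct, seed=5)
        b = generate_morphology_cohort(defaults.sct, seed=5)
        assert a.latent.equals(b.latent)
        assert all(x.free == y.free for x, y in zip(a.records, b.records))

    def test_zero_sd_gives_identical_diameters(self, defaults):
        cfg = dataclasses.replace(defaults.sct, diameter_sd=0.0, noise=0.0,
                                  n_cells=10)
        ds = generate_morphology_cohort(cfg, seed=1)
        assert ds.latent["diameter_um"].nunique() == 1

    def test_latent_mean_converges_to_configured_mean(self, defaults):
        cfg = dataclasses.replace(defaults.sct, n_cells=10_000)
        ds = generate_morphology_cohort(cfg, seed=2)
        assert ds.latent["diameter_um"].mean() == pytest.approx(4.02, rel=0.01)

    def test_rendered_images_present_and_deterministic(self, defaults):
        cfg = dataclasses.replace(defaults.sct, n_cells=3)
        a = generate_morphology_cohort(cfg, render_images=True, seed=9)
        b = generate_morphology_cohort(cfg, render_images=True, seed=9)
        assert len(a.images) == 3
        for x, y in zip(a.images, b.images):
            assert np.array_equal(x.pixels, y.pixels)


class TestElasticityCohort:
    def test_round_trip_identity_at_zero_noise(self, defaults):
        cfg = dataclasses.replace(defaults.hbss, noise=0.0)
        ds = generate_elasticity_cohort(cfg, seed=11)
        for rec, (_, latent) in zip(ds.records, ds.latent.iterrows()):
            res = evaluate_cell(rec)
            assert res.stiffness == pytest.approx(
                latent["stiffness_uN_per_m"], rel=1e-6)
            assert rec.free.r_max == pytest.approx(latent["free_rmax_um"], rel=1e-12)
            compression = 100 * (1 - latent["trapped_rmax_um"] / latent["free_rmax_um"])
            assert res.pct_dr_free == pytest.approx(compression, rel=1e-6)

    def test_physical_consistency_every_record(self, defaults):
        for cfg in (defaults.hbas, defaults.hbss):
            ds = generate_elasticity_cohort(cfg, seed=13)
            for rec in ds.records:
                assert rec.stretched.r_max > rec.trapped.r_max
                assert rec.drag_force_pN > rec.trap_force_pN

    def test_subgroup_structure(self, defaults):
        ds = generate_elasticity_cohort(defaults.hbas, seed=3)
        groups = [r.subgroup for r in ds.records]
        assert sorted(set(groups)) == list(range(1, 8))
        assert all(groups.count(g) == 7 for g in range(1, 8))
        # one stage speed per subgroup
        speed_by_group = {}
        for r in ds.records:
            speed_by_group.setdefault(r.subgroup, set()).add(r.stage_speed_um_s)
        assert all(len(v) == 1 for v in speed_by_group.values())

    def test_same_seed_identical_records(self, defaults):
        a = generate_elasticity_cohort(defaults.hbas, seed=21)
        b = generate_elasticity_cohort(defaults.hbas, seed=21)
        assert a.latent.equals(b.latent)
        assert all(x == y for x, y in zip(a.records, b.records))

    def test_cohort_means_recover_configuration(self, defaults):
        cfg = dataclasses.replace(defaults.hbas, n_cells=9996)
        ds = generate_elasticity_cohort(cfg, seed=7)
        assert ds.latent["free_rmax_um"].mean() == pytest.approx(4.67, rel=0.03)
        assert ds.latent["trap_force_pN"].mean() == pytest.approx(0.26, rel=0.02)
        assert ds.latent["stiffness_uN_per_m"].mean() == pytest.approx(1.08, rel=0.02)

    def test_physical_force_model_runs(self, defaults):
        cfg = dataclasses.replace(defaults.hbas, force_model="physical")
        ds = generate_elasticity_cohort(cfg, seed=5)
        assert all(r.trap_force_pN >= 0 for r in ds.records)
        assert all(r.drag_force_pN > r.trap_force_pN for r in ds.records)
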