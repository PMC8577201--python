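"""Coupled simulation: water demand, voxel reach, uptake kinetics, sweeps."""

import math
from dataclasses import replace

import numpy as np
import pytest

from rhizosim.architecture import ArchitectureParams, RootSegmentRecord, grow, new_root_system
from rhizosim.engine import (
    PlantState,
    ScenarioConfig,
    reachable_voxels,
    run_simulation,
    run_sweep,
    transpiration_demand,
    uptake_step,
)
from rhizosim.soil import SoilGrid


def make_segment(base, tip, radius=0.05, seg_id=0):
    base, tip = np.asarray(base, float), np.asarray(tip, float)
    return RootSegmentRecord(
        segment_id=seg_id, parent_id=None, axis_class="primary",
        base=base, tip=tip, radius_cm=radius, t_created_d=0.0,
        length_cm=float(np.linalg.norm(tip - base)), axis_id=0,
        arc_mid_cm=0.0)


def bare_grid(nx=5, ny=5, nz=5, h=1.0, c0=0.0):
    g = SoilGrid(nx, ny, nz, h, species={"no3": {"d_e": 0.2, "b": 2.0}})
    g.conc["no3"][:] = c0
    g.mark_initial()
    return g


class TestTranspirationDemand:
    def test_zero_fraction_means_pure_diffusion(self):
        assert transpiration_demand(PlantState(0.7), 0.0, 100.0) == 0.0

    def test_linear_form(self):
        assert transpiration_demand(PlantState(0.5), 1.0, 100.0) == pytest.approx(50.0)

    def test_homogeneous_in_fraction(self):
        p = PlantState(0.31)
        assert transpiration_demand(p, 0.5, 100.0) == pytest.approx(
            0.5 * transpiration_demand(p, 1.0, 100.0))


class TestReachableVoxels:
    def test_hairless_axis_reaches_only_containing_voxel(self):
        g = bare_grid()
        seg = make_segment([0, 0, 2.1], [0, 0, 2.9])
        idx, w = reachable_voxels(seg, 0.0, g)
        assert list(idx) == [(2 * 5 + 2) * 5 + 2]
        assert w.sum() == pytest.approx(seg.length_cm)

    def test_long_hairs_reach_superset_of_short(self):
        g = bare_grid()
        seg = make_segment([0.3, 0.1, 2.0], [0.4, 0.2, 3.4])
        short, _ = reachable_voxels(seg, 0.1, g)
        long_, _ = reachable_voxels(seg, 1.0, g)
        assert set(short) <= set(long_)

    def test_wide_reach_includes_lateral_neighbours(self):
        g = bare_grid()
        seg = make_segment([0, 0, 2.0], [0, 0, 3.0], radius=0.1)
        idx, w = reachable_voxels(seg, 10.0, g)  # reach = 1.1 cm
        assert w.sum() == pytest.approx(1.0)
        ii = np.array([divmod(f // 5, 5) + (f % 5,) for f in idx])
        xs = {(int(a), int(b)) for a, b, _ in ii}
        assert {(2, 2), (1, 2), (3, 2), (2, 1), (2, 3)} <= xs

    def test_weights_sum_to_in_grid_length_random_segments(self, rng):
        g = bare_grid()
        for _ in range(25):
            base = rng.uniform([-2, -2, 0.2], [2, 2, 4.5])
            tip = base + rng.uniform(-0.4, 0.4, 3)
            tip[2] = abs(tip[2])
            seg = make_segment(base, tip)
            if seg.length_cm == 0:
                continue
            _, w = reachable_voxels(seg, float(rng.uniform(0, 1)), g)
            assert w.sum() == pytest.approx(seg.length_cm, rel=1e-9)

    def test_segment_outside_grid_contributes_nothing(self):
        g = bare_grid()
        seg = make_segment([40, 40, 2], [40, 40, 3])
        idx, w = reachable_voxels(seg, 1.0, g)
        assert len(idx) == 0 and len(w) == 0


def single_segment_setup(c0, km=0.05, f_t=1.0, rhl=0.0, imax=1.0):
    cfg = ScenarioConfig(nx=3, ny=3, nz=3, h_cm=2.0, rhl_mm=rhl,
                         rhd_per_cm=100.0, km=km, imax=imax,
                         transpiration_fraction=f_t, seed=0)
    p = cfg.arch_params()
    p.seminal_count = 0
    p.branching_interval_cm = 1e9
    state = new_root_system(p, seed=0)
    grow(state, p, 0.25)  # one 0.5 cm vertical segment at the box centre
    cfg = replace(cfg, architecture=p)
    grid = SoilGrid(3, 3, 3, 2.0, species={"no3": {"d_e": cfg.d_e, "b": cfg.buffer}})
    grid.conc["no3"][:] = c0
    grid.mark_initial()
    plant = PlantState(shoot_biomass_g=0.05)
    return state, grid, plant, cfg


class TestUptakeStep:
    def test_no_nitrogen_no_uptake(self):
        state, grid, plant, cfg = single_segment_setup(c0=0.0)
        uptake_step(state, grid, plant, cfg, 0.25)
        assert plant.n_uptake_umol == 0.0

    def test_hand_computed_mm_plus_massflow(self):
        c0 = 0.5
        state, grid, plant, cfg = single_segment_setup(c0=c0)
        uptake_step(state, grid, plant, cfg, 0.25)
        area = 2 * math.pi * 0.05 * 0.5
        d_mm = 1.0 * c0 / (0.05 + c0) * area * 0.25
        d_mf = 1.0 * 100.0 * 0.05 * 0.25 * c0
        assert plant.n_uptake_diffusive_umol == pytest.approx(d_mm, rel=1e-12)
        assert plant.n_uptake_massflow_umol == pytest.approx(d_mf, rel=1e-12)

    def test_saturating_kinetics_limit(self):
        state, grid, plant, cfg = single_segment_setup(c0=5.0, km=1e-12, f_t=0.0)
        uptake_step(state, grid, plant, cfg, 0.25)
        area = 2 * math.pi * 0.05 * 0.5
        assert plant.n_uptake_umol == pytest.approx(1.0 * area * 0.25, rel=1e-9)

    def test_never_negative_concentration_under_overdraw(self):
        state, grid, plant, cfg = single_segment_setup(c0=1e-4, imax=1e6)
        uptake_step(state, grid, plant, cfg, 0.25)
        assert grid.conc["no3"].min() >= 0.0
        assert grid.conservation_residual("no3") < 1e-10


class TestRunSimulation:
    def test_zero_rate_floor(self, tiny_cfg):
        res = run_simulation(replace(tiny_cfg, n_kg_ha=0.0))
        assert res.final_plant.n_uptake_umol == 0.0
        # biomass pinned to what the seed N reserve can support
        cap = tiny_cfg.shoot_b0_g + tiny_cfg.seed_n_reserve_umol / tiny_cfg.tissue_n_umol_per_g
        assert res.final_plant.shoot_biomass_g <= cap + 1e-12

    def test_zero_duration_echoes_initial_state(self, tiny_cfg):
        res = run_simulation(replace(tiny_cfg, duration_d=0.0))
        assert res.final_plant.n_uptake_umol == 0.0
        assert res.final_plant.shoot_biomass_g == tiny_cfg.shoot_b0_g
        assert res.root_length_cm == 0.0

    def test_uptake_equals_ledger_audit(self, tiny_cfg):
        res = run_simulation(tiny_cfg)
        audit_diff = sum(e[1] for e in res.uptake_ledger)
        audit_mf = sum(e[2] for e in res.uptake_ledger)
        assert res.final_plant.n_uptake_diffusive_umol == pytest.approx(audit_diff, rel=1e-12)
        assert res.final_plant.n_uptake_massflow_umol == pytest.approx(audit_mf, rel=1e-12)
        assert res.final_plant.n_uptake_umol > 0

    def test_ledger_split_sums_exactly(self, tiny_cfg):
        res = run_simulation(tiny_cfg)
        fp = res.final_plant
        assert fp.n_uptake_umol == fp.n_uptake_diffusive_umol + fp.n_uptake_massflow_umol

    def test_massflow_ledger_zero_without_transpiration(self, tiny_cfg):
        res = run_simulation(replace(tiny_cfg, transpiration_fraction=0.0))
        assert res.final_plant.n_uptake_massflow_umol == 0.0
        assert res.final_plant.n_uptake_diffusive_umol > 0.0

    def test_conservation_of_total_nitrogen(self, tiny_cfg):
        assert run_simulation(tiny_cfg).conservation_residual < 1e-8

    def test_deterministic_given_seed(self, tiny_cfg):
        a = run_simulation(tiny_cfg)
        b = run_simulation(tiny_cfg)
        assert a.final_plant.n_uptake_umol == b.final_plant.n_uptake_umol
        assert a.root_length_cm == b.root_length_cm

    def test_depletion_zone_forms_near_roots(self, tiny_cfg):
        # pure diffusion, sluggish soil: uptake outpaces resupply around roots
        cfg = replace(tiny_cfg, transpiration_fraction=0.0, d_e=0.02,
                      duration_d=6.0, rhl_mm=0.0)
        res = run_simulation(cfg)
        assert res.final_plant.n_uptake_umol > 0
        grid = res.final_grid
        root_vox = set()
        for s in res.final_state.segments:
            idx = grid.voxel_of_point((s.base + s.tip) / 2)
            if grid.in_bounds(idx):
                root_vox.add(idx)
        assert root_vox
        mask = np.zeros(grid.shape, dtype=bool)
        for idx in root_vox:
            mask[idx] = True
        c = grid.conc[cfg.species]
        assert c[mask].mean() < c[~mask].mean()


class TestRunSweep:
    def test_single_cell_single_row(self, tiny_cfg):
        df = run_sweep((0.5,), (500.0,), (104.0,), (1.0,), base_config=tiny_cfg)
        assert len(df) == 1
        assert df.loc[0, "uptake_umol"] > 0

    def test_two_by_two_design_complete(self, tiny_cfg):
        df = run_sweep((0.0, 1.0), (100.0,), (62.4,), (0.25, 1.0),
                       base_config=tiny_cfg)
        assert len(df) == 4
        assert df[["rhl_mm", "transpiration_pct"]].drop_duplicates().shape[0] == 4
        assert df["uptake_umol"].notna().all()

    def test_rejects_empty_factor_list(self, tiny_cfg):
        with pytest.raises(ValueError):
            run_sweep((), (100.0,), (62.4,), (1.0,), base_config=tiny_cfg)

    def test_resume_reuses_cached_cells(self, tiny_cfg, tmp_path):
        kw = dict(rhl_levels=(0.5,), rhd_levels=(500.0,), n_levels=(104.0,),
                  transpiration_levels=(1.0,), base_config=tiny_cfg,
                  cache_dir=tmp_path / "cache")
        a = run_sweep(**kw)
        b = run_sweep(**kw)
        assert a.loc[0, "uptake_umol"] == b.loc[0, "uptake_umol"]
        assert list((tmp_path / "cache").glob("*.json"))
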