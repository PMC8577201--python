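"""Coupled root-soil simulation of nitrogen uptake.

Each scenario grows a seedling root system for a fixed duration (default
15 d) inside a closed soil box, moving N to the root by two routes that are
ledgered separately:

* **diffusive/active uptake** — Michaelis-Menten kinetics per unit of
  absorptive surface (root cylinder plus hairs),
  ``I = Imax * C / (Km + C) * A * dt``, evaluated against the
  reach-weighted mean concentration around each segment;
* **mass flow** — transpiration-driven convective delivery,
  ``w_seg * C * dt``, where each segment's water share is proportional to
  its absorptive area and total water demand is ``f_T * W * shoot biomass``
  (W = 100 cm^3 of water per g shoot per day at full transpiration).

Root hairs act twice: they enlarge the absorptive area, and they enlarge
the radius of the depletion cylinder a segment can draw on within a day,
which weakens self-shading of the root by its own uptake (the sub-voxel
depletion factor below).  Hair-hair competition is emergent: segments
sharing voxels are capped by the same finite pool.

Shoot growth follows a logistic potential trajectory throttled by N
sufficiency: biomass increments are granted only as far as accumulated
plant N (seed reserve + uptake) can support them at a fixed tissue N
concentration.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import architecture as arch
from . import soil as soil_mod
from .soil import SoilGrid, StabilityError

__all__ = [
    "ScenarioConfig",
    "PlantState",
    "SimulationResult",
    "transpiration_demand",
    "reachable_voxels",
    "uptake_step",
    "run_simulation",
    "run_sweep",
    "SWEEP_COLUMNS",
]

log = logging.getLogger(__name__)

SWEEP_COLUMNS = [
    "rhl_mm", "rhd_per_cm", "n_kg_ha", "transpiration_pct", "replicate",
    "seed", "uptake_umol", "uptake_massflow_umol", "uptake_diffusive_umol",
    "root_length_cm", "area_cm2", "area_hairs_cm2", "conservation_residual",
]


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulated plant."""

    rhl_mm: float = 0.5  # max root hair length l_max
    rhd_per_cm: float = 500.0  # root hair density rho_h
    n_kg_ha: float = 104.0  # N application rate
    transpiration_fraction: float = 1.0  # f_T in [0, 1]
    duration_d: float = 15.0
    dt_d: float = 0.25
    # grid geometry: default 5 mm voxels over a 20 x 20 x 40 cm box
    nx: int = 40
    ny: int = 40
    nz: int = 80
    h_cm: float = 0.5
    species: str = "no3"
    d_e: float = 0.5  # cm^2 d^-1
    buffer: float = 2.0
    theta: float = 0.3
    depth_profile: str = "uniform"
    # uptake kinetics (per unit absorptive area, root and hair alike)
    imax: float = 1.0  # umol cm^-2 d^-1
    km: float = 0.05  # umol cm^-3 (soil-volume basis)
    water_use: float = 100.0  # W, cm^3 water per g shoot per day
    # shoot logistic potential and N coupling
    shoot_b0_g: float = 0.05
    shoot_rate_per_d: float = 0.25
    shoot_bmax_g: float = 1.5
    seed_n_reserve_umol: float = 150.0
    tissue_n_umol_per_g: float = 2000.0  # ~2.8 % N by dry weight
    seed: int = 0
    architecture: arch.ArchitectureParams = field(default_factory=arch.ArchitectureParams)

    def validate(self) -> None:
        if not (0.0 <= self.transpiration_fraction <= 1.0):
            raise ValueError("transpiration_fraction must be in [0, 1]")
        if self.duration_d < 0:
            raise ValueError("duration_d must be >= 0")
        if self.dt_d <= 0:
            raise ValueError("dt_d must be > 0")
        if self.km <= 0:
            raise ValueError("km must be > 0")
        if self.imax < 0 or self.water_use < 0 or self.n_kg_ha < 0:
            raise ValueError("imax, water_use and n_kg_ha must be >= 0")
        if self.rhl_mm < 0 or self.rhd_per_cm < 0:
            raise ValueError("hair phenotype values must be >= 0")
        if not (0.0 <= self.rhl_mm <= 1.0):
            warnings.warn("rhl_mm outside the calibrated 0-1 mm range", stacklevel=2)
        if self.rhd_per_cm > 0 and not (100.0 <= self.rhd_per_cm <= 1000.0):
            warnings.warn("rhd_per_cm outside the calibrated 100-1000 range", stacklevel=2)
        self.architecture.validate()

    def arch_params(self) -> arch.ArchitectureParams:
        return self.architecture.with_hair_phenotype(self.rhl_mm, self.rhd_per_cm)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        ap = d.pop("architecture", None)
        cfg = cls(**d)
        if ap:
            cfg = replace(cfg, architecture=arch.ArchitectureParams(**ap))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass
class PlantState:
    shoot_biomass_g: float
    n_uptake_diffusive_umol: float = 0.0
    n_uptake_massflow_umol: float = 0.0
    plant_n_umol: float = 0.0  # seed reserve + cumulative uptake
    time_d: float = 0.0

    @property
    def n_uptake_umol(self) -> float:
        return self.n_uptake_diffusive_umol + self.n_uptake_massflow_umol


@dataclass
class SimulationResult:
    config: ScenarioConfig
    daily: pd.DataFrame  # one row per day: time, biomass, uptake ledgers
    final_plant: PlantState
    root_length_cm: float
    area_cm2: float
    area_hairs_cm2: float
    conservation_residual: float
    uptake_ledger: list  # (time, diffusive, massflow) per step, audit trail
    final_grid: SoilGrid | None = None  # in-memory only, not serialised
    final_state: "arch.RootSystemState | None" = None

    def to_json(self, path=None) -> dict:
        out = {
            "config": self.config.to_dict(),
            "final": {
                "time_d": self.final_plant.time_d,
                "shoot_biomass_g": self.final_plant.shoot_biomass_g,
                "uptake_umol": self.final_plant.n_uptake_umol,
                "uptake_diffusive_umol": self.final_plant.n_uptake_diffusive_umol,
                "uptake_massflow_umol": self.final_plant.n_uptake_massflow_umol,
                "root_length_cm": self.root_length_cm,
                "area_cm2": self.area_cm2,
                "area_hairs_cm2": self.area_hairs_cm2,
                "conservation_residual": self.conservation_residual,
            },
            "daily": self.daily.to_dict(orient="list"),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(out, fh, indent=2)
        return out


def transpiration_demand(plant: PlantState, f_t: float, water_use: float) -> float:
    """Water demand (cm^3 d^-1): f_T x W x shoot biomass."""
    return f_t * water_use * plant.shoot_biomass_g


def reachable_voxels(segment: arch.RootSegmentRecord, hair_length_mm: float,
                     grid: SoilGrid, n_samples: int | None = None):
    """Voxels a segment can draw on, weighted by intersected axis length.

    A voxel is reachable when its centre lies within ``radius + l_h/10`` cm
    of the segment axis.  The axis is sampled densely; each sample carries an
    equal share of the segment length, split equally among the voxels it
    reaches.  A sample reaching no voxel centre falls back to its containing
    voxel, so hairless thin segments reach exactly the voxel(s) holding the
    axis and weights always sum to the in-grid segment length.

    Returns ``(flat_indices, weights)`` (possibly empty for segments fully
    outside the grid).
    """
    reach = segment.radius_cm + hair_length_mm / 10.0
    if n_samples is None:
        n_samples = max(1, int(math.ceil(segment.length_cm / (grid.h / 4.0))))
    frac = (np.arange(n_samples) + 0.5) / n_samples
    pts = segment.base[None, :] + frac[:, None] * (segment.tip - segment.base)[None, :]
    flat, w, _, _ = _samples_to_voxels(
        pts, np.full(n_samples, segment.length_cm / n_samples),
        np.full(n_samples, reach), np.zeros(n_samples, dtype=np.int64), grid)
    if len(flat) == 0:
        return flat, w
    order = np.argsort(flat, kind="stable")
    flat, w = flat[order], w[order]
    uniq, start = np.unique(flat, return_index=True)
    return uniq, np.add.reduceat(w, start)


_NEIGHBOR_OFFSETS = np.array(list(itertools.product((-1, 0, 1), repeat=3)))


def _samples_to_voxels(pts: np.ndarray, lengths: np.ndarray, reach: np.ndarray,
                       owner: np.ndarray, grid: SoilGrid):
    """Map axis sample points to reachable flat voxel indices.

    ``pts`` are (n, 3) sample positions carrying length shares ``lengths``;
    ``reach`` is the per-sample reach radius and ``owner`` the per-sample
    segment index.  A sample reaches the voxels whose centres lie within its
    reach radius, splitting its length share equally among them; a sample
    reaching no centre falls back to its containing voxel.  Samples outside
    the grid are dropped.  Returns ``(flat_idx, weights, owner_idx)``.
    """
    h = grid.h
    fx = pts[:, 0] / h + grid.nx / 2.0
    fy = pts[:, 1] / h + grid.ny / 2.0
    fz = pts[:, 2] / h
    base = np.stack([np.floor(fx), np.floor(fy), np.floor(fz)], axis=1).astype(np.int64)
    inb = ((base[:, 0] >= 0) & (base[:, 0] < grid.nx)
           & (base[:, 1] >= 0) & (base[:, 1] < grid.ny)
           & (base[:, 2] >= 0) & (base[:, 2] < grid.nz))
    if not inb.all():
        pts, lengths, base = pts[inb], lengths[inb], base[inb]
        reach, owner = reach[inb], owner[inb]
    if len(pts) == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0),
                np.empty(0, dtype=np.int64), bool((~inb).any()))
    cand = base[:, None, :] + _NEIGHBOR_OFFSETS[None, :, :]  # (npts, 27, 3)
    centers = (cand + 0.5).astype(float) * h
    centers[:, :, 0] -= grid.nx * h / 2.0
    centers[:, :, 1] -= grid.ny * h / 2.0
    d2 = ((centers - pts[:, None, :]) ** 2).sum(axis=2)
    valid = ((cand[:, :, 0] >= 0) & (cand[:, :, 0] < grid.nx)
             & (cand[:, :, 1] >= 0) & (cand[:, :, 1] < grid.ny)
             & (cand[:, :, 2] >= 0) & (cand[:, :, 2] < grid.nz))
    within = valid & (d2 <= (reach * reach)[:, None])
    nhit = within.sum(axis=1)
    none = nhit == 0
    if none.any():  # fallback: offset 13 is (0, 0, 0), the containing voxel
        within[none, 13] = True
        nhit[none] = 1
    share = lengths / nhit
    p_idx, o_idx = np.nonzero(within)
    flat = (cand[p_idx, o_idx, 0] * grid.ny + cand[p_idx, o_idx, 1]) * grid.nz \
        + cand[p_idx, o_idx, 2]
    return flat, share[p_idx], owner[p_idx], bool((~inb).any())


class _EngineState:
    """Per-run scratch: segment arrays and the daily depletion window."""

    def __init__(self):
        self.u_day: dict[int, float] = {}  # segment id -> uptake this day

    def reset_window(self):
        self.u_day.clear()


def uptake_step(state: arch.RootSystemState, grid: SoilGrid, plant: PlantState,
                config: ScenarioConfig, dt: float,
                engine_state: _EngineState | None = None):
    """One uptake step: MM uptake plus mass-flow delivery, capped by supply.

    Mutates ``grid`` and ``plant`` and returns ``(grid, plant)``.  The
    effective concentration a segment sees is the reach-weighted voxel mean
    scaled by the sub-voxel depletion factor
    ``max(0, 1 - U_day / (b * Cbar * V_reach))`` where ``U_day`` is the
    segment's cumulative uptake since the last daily reset and ``V_reach``
    is its depletion-cylinder volume ``pi (r + l_h)^2 L``; a bigger hair
    cylinder therefore depletes more slowly.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if engine_state is None:
        engine_state = _EngineState()
    params = config.arch_params()
    sp = grid.species[config.species]
    conc_flat = grid.conc[config.species].ravel()
    segs = state.segments
    if not segs:
        return grid, plant
    nseg = len(segs)
    base = np.array([s.base for s in segs])
    tip = np.array([s.tip for s in segs])
    length = np.array([s.length_cm for s in segs])
    radius = np.array([s.radius_cm for s in segs])
    seg_ids = np.array([s.segment_id for s in segs])
    # vectorised current hair length (mm) per segment
    dist_tip = np.array([state.axis_arc(s.axis_id) - s.arc_mid_cm for s in segs])
    age = state.time - np.array([s.t_created_d for s in segs])
    rate = np.array([params.elongation_rate[s.axis_class] for s in segs])
    lmax = params.max_root_hair_length_mm
    if lmax > 0:
        t_zone = np.where(rate > 0, params.hair_free_tip_zone_cm / np.maximum(rate, 1e-300), 0.0)
        hair_mm = np.minimum(
            lmax, params.root_hair_growth_rate_mm_d * np.maximum(0.0, age - t_zone))
        hair_mm[dist_tip < params.hair_free_tip_zone_cm] = 0.0
    else:
        hair_mm = np.zeros(nseg)
    hl_cm = hair_mm / 10.0
    area = 2.0 * math.pi * radius * length \
        + params.root_hair_density_per_cm * length \
        * 2.0 * math.pi * params.hair_radius_cm * hl_cm
    # dense axis sampling, all segments at once
    nsamp = np.maximum(1, np.ceil(length / (grid.h / 4.0)).astype(np.int64))
    owner = np.repeat(np.arange(nseg), nsamp)
    cum = np.concatenate([[0], np.cumsum(nsamp)])
    within_seg = np.arange(cum[-1]) - cum[owner]
    frac = (within_seg + 0.5) / nsamp[owner]
    pts = base[owner] + frac[:, None] * (tip - base)[owner]
    all_idx, all_w, all_seg, clipped = _samples_to_voxels(
        pts, (length / nsamp)[owner], (radius + hl_cm)[owner], owner, grid)
    if clipped and not engine_state_warned(engine_state):
        log.warning("segment sample(s) outside the soil grid contribute no uptake")
    if len(all_idx) == 0:
        return grid, plant
    # reach-weighted mean concentration per segment
    wsum = np.zeros(nseg)
    cwsum = np.zeros(nseg)
    np.add.at(wsum, all_seg, all_w)
    np.add.at(cwsum, all_seg, all_w * conc_flat[all_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        cbar = np.where(wsum > 0, cwsum / np.maximum(wsum, 1e-300), 0.0)
    vreach = math.pi * (radius + hl_cm) ** 2 * length
    u_day = np.array([engine_state.u_day.get(int(sid), 0.0) for sid in seg_ids])
    pool = sp.b * cbar * vreach
    with np.errstate(divide="ignore", invalid="ignore"):
        depl = np.where(pool > 0, np.maximum(0.0, 1.0 - u_day / np.maximum(pool, 1e-300)), 0.0)
    c_eff = cbar * depl
    # demands per segment
    d_mm = config.imax * c_eff / (config.km + c_eff) * area * dt
    total_area = area.sum()
    q = transpiration_demand(plant, config.transpiration_fraction, config.water_use) * dt
    w_seg = q * area / total_area if total_area > 0 else np.zeros_like(area)
    d_mf = w_seg * c_eff
    demand = d_mm + d_mf
    # distribute each segment's demand over its reach voxels, weighted by
    # local available N, then apply the shared per-voxel cap
    local = all_w * conc_flat[all_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(cwsum[all_seg] > 0, local / np.maximum(cwsum[all_seg], 1e-300), 0.0)
    want = demand[all_seg] * share
    got = soil_mod.withdraw_flat(grid, all_idx, want, config.species)
    got_seg = np.zeros(nseg)
    np.add.at(got_seg, all_seg, got)
    # split the granted uptake between the two routes in demand proportion
    with np.errstate(divide="ignore", invalid="ignore"):
        mf_share = np.where(demand > 0, d_mf / np.maximum(demand, 1e-300), 0.0)
    got_mf = got_seg * mf_share
    got_mm = got_seg - got_mf
    plant.n_uptake_diffusive_umol += float(got_mm.sum())
    plant.n_uptake_massflow_umol += float(got_mf.sum())
    plant.plant_n_umol += float(got_seg.sum())
    nz = np.nonzero(got_seg)[0]
    for i in nz:
        sid = int(seg_ids[i])
        engine_state.u_day[sid] = engine_state.u_day.get(sid, 0.0) + float(got_seg[i])
    return grid, plant


def engine_state_warned(es: _EngineState) -> bool:
    """Log the outside-grid condition only once per run."""
    if getattr(es, "_warned", False):
        return True
    es._warned = True
    return False


def run_simulation(config: ScenarioConfig) -> SimulationResult:
    """Run one scenario end to end; deterministic given ``config.seed``."""
    config.validate()
    params = config.arch_params()
    state = arch.new_root_system(params, seed=config.seed)
    grid = soil_mod.init_from_application_rate(
        config.n_kg_ha, config.nx, config.ny, config.nz, config.h_cm,
        profile=config.depth_profile, species=config.species,
        species_params={config.species: {"d_e": config.d_e, "b": config.buffer}},
        theta=config.theta,
    )
    plant = PlantState(shoot_biomass_g=config.shoot_b0_g,
                       plant_n_umol=config.seed_n_reserve_umol)
    n_allocated = config.shoot_b0_g * config.tissue_n_umol_per_g
    es = _EngineState()
    ledger: list[tuple[float, float, float]] = []
    daily_rows = [_daily_row(plant)]
    limit = grid.stability_limit(config.species)
    n_sub = max(1, int(math.ceil(config.dt_d / limit))) if np.isfinite(limit) else 1
    t = 0.0
    next_day = 1.0
    nsteps = int(round(config.duration_d / config.dt_d))
    for _ in range(nsteps):
        arch.grow(state, params, config.dt_d)
        for _ in range(n_sub):
            soil_mod.diffuse(grid, config.dt_d / n_sub, species=config.species)
        before = (plant.n_uptake_diffusive_umol, plant.n_uptake_massflow_umol)
        uptake_step(state, grid, plant, config, config.dt_d, es)
        ledger.append((state.time,
                       plant.n_uptake_diffusive_umol - before[0],
                       plant.n_uptake_massflow_umol - before[1]))
        # shoot growth: logistic potential, throttled by N sufficiency
        b = plant.shoot_biomass_g
        db_pot = config.shoot_rate_per_d * b * max(0.0, 1.0 - b / config.shoot_bmax_g) * config.dt_d
        n_free = max(0.0, plant.plant_n_umol - n_allocated)
        db = min(db_pot, n_free / config.tissue_n_umol_per_g)
        plant.shoot_biomass_g = b + db
        n_allocated += db * config.tissue_n_umol_per_g
        t = state.time
        plant.time_d = t
        if t + 1e-9 >= next_day:
            es.reset_window()
            daily_rows.append(_daily_row(plant))
            next_day += 1.0
    residual = grid.conservation_residual(config.species) if config.n_kg_ha > 0 else 0.0
    return SimulationResult(
        config=config,
        daily=pd.DataFrame(daily_rows),
        final_plant=plant,
        root_length_cm=state.total_length(),
        area_cm2=arch.absorptive_surface_area(state, params, include_hairs=False),
        area_hairs_cm2=arch.absorptive_surface_area(state, params, include_hairs=True),
        conservation_residual=residual,
        uptake_ledger=ledger,
        final_grid=grid,
        final_state=state,
    )


def _daily_row(plant: PlantState) -> dict:
    return {
        "time_d": plant.time_d,
        "shoot_biomass_g": plant.shoot_biomass_g,
        "uptake_umol": plant.n_uptake_umol,
        "uptake_diffusive_umol": plant.n_uptake_diffusive_umol,
        "uptake_massflow_umol": plant.n_uptake_massflow_umol,
        "plant_n_umol": plant.plant_n_umol,
    }


def run_sweep(
    rhl_levels=(0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
    rhd_levels=(100.0, 500.0, 1000.0),
    n_levels=(62.4, 104.0, 145.6),
    transpiration_levels=(0.25, 0.5, 0.75, 1.0),
    replicates: int = 1,
    base_config: ScenarioConfig | None = None,
    cache_dir=None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Full factorial sweep over hair and environment levels (tidy output).

    Every cell gets an independent seed derived from ``master_seed``; cells
    are cached by config hash when ``cache_dir`` is given, so interrupted
    sweeps resume.  Per-cell failures are recorded (``error`` column) and
    the sweep continues.
    """
    for name, levels in (("rhl", rhl_levels), ("rhd", rhd_levels),
                         ("n", n_levels), ("transpiration", transpiration_levels)):
        if len(levels) == 0:
            raise ValueError(f"empty factor list for {name}")
    base = base_config or ScenarioConfig()
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    cells = list(itertools.product(rhl_levels, rhd_levels, n_levels,
                                   transpiration_levels, range(1, replicates + 1)))
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(cells))]
    for (rhl, rhd, n_rate, ft, rep), seed in zip(cells, seeds):
        cfg = replace(base, rhl_mm=rhl, rhd_per_cm=rhd, n_kg_ha=n_rate,
                      transpiration_fraction=ft, seed=seed)
        row = {
            "rhl_mm": rhl, "rhd_per_cm": rhd, "n_kg_ha": n_rate,
            "transpiration_pct": 100.0 * ft, "replicate": rep, "seed": seed,
        }
        cache_file = cache / f"{cfg.config_hash()}.json" if cache else None
        if cache_file and cache_file.exists():
            row.update(json.loads(cache_file.read_text()))
            rows.append(row)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_simulation(cfg)
            payload = {
                "uptake_umol": res.final_plant.n_uptake_umol,
                "uptake_massflow_umol": res.final_plant.n_uptake_massflow_umol,
                "uptake_diffusive_umol": res.final_plant.n_uptake_diffusive_umol,
                "root_length_cm": res.root_length_cm,
                "area_cm2": res.area_cm2,
                "area_hairs_cm2": res.area_hairs_cm2,
                "conservation_residual": res.conservation_residual,
            }
            row.update(payload)
            if cache_file:
                cache_file.write_text(json.dumps(payload))
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad cells
            log.error("scenario %s failed: %s", row, exc)
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in SWEEP_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[SWEEP_COLUMNS + [c for c in df.columns if c not in SWEEP_COLUMNS]]
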