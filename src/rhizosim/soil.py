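"""Voxelized soil nitrogen state: buffered explicit diffusion and sinks.

The soil is a closed box of cubic voxels.  Each N species (nitrate,
ammonium) carries a solution concentration field ``C`` (umol per cm^3 of
soil volume), a dimensionless buffer capacity ``b >= 1`` (ratio of total to
dissolved N, held constant), and an effective diffusion coefficient ``D_e``
(cm^2 d^-1).  Transport follows

    b dC/dt = D_e laplacian(C)

integrated with an explicit 6-neighbour finite-difference scheme under
zero-flux boundaries on every face (closed-pot semantics), which makes mass
conservation exactly auditable: initial N = soil N + cumulative withdrawals
at all times, to floating-point accuracy.

Field-style applications (kg N ha^-1) are converted to grid concentrations
with the identity 1 kg ha^-1 = 0.01 mg N cm^-2 of ground area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SoilGrid",
    "SpeciesParams",
    "StabilityError",
    "init_from_application_rate",
    "diffuse",
    "withdraw",
    "UMOL_PER_MG_N",
]

#: umol of N per mg of N (atomic weight 14.0067)
UMOL_PER_MG_N = 1000.0 / 14.0067

#: default transport parameters per species.  Literature-typical magnitudes
#: for effective diffusion in moist soil: nitrate moves freely (small buffer
#: power), ammonium is strongly sorbed (large b, small D_e).  Assumptions,
#: not measurements; overridable everywhere.
DEFAULT_SPECIES = {
    "no3": {"d_e": 0.5, "b": 2.0},
    "nh4": {"d_e": 0.05, "b": 20.0},
}


class StabilityError(RuntimeError):
    """Explicit diffusion step exceeds the stability bound b h^2 / (6 D_e)."""


@dataclass
class SpeciesParams:
    d_e: float  # effective diffusivity, cm^2 d^-1
    b: float  # buffer capacity (total : dissolved), >= 1

    def validate(self):
        if self.d_e < 0:
            raise ValueError("d_e must be >= 0")
        if self.b < 1:
            raise ValueError("buffer capacity b must be >= 1")


class SoilGrid:
    """Closed box of ``nx x ny x nz`` cubic voxels with edge ``h`` (cm).

    The x/y origin is at the box centre (the seed position); z runs from the
    surface (0) downward.  Concentrations are stored per species in
    ``conc[species]`` as float64 arrays of shape ``(nx, ny, nz)``.
    """

    def __init__(self, nx, ny, nz, h, species=None, theta=0.3):
        if min(nx, ny, nz) < 1 or h <= 0:
            raise ValueError("grid must have positive dimensions and voxel size")
        if not (0 < theta < 1):
            raise ValueError("volumetric water content theta must be in (0, 1)")
        self.nx, self.ny, self.nz, self.h = int(nx), int(ny), int(nz), float(h)
        self.theta = theta
        self.conc: dict[str, np.ndarray] = {}
        self.species: dict[str, SpeciesParams] = {}
        self.withdrawn: dict[str, float] = {}
        self.withdrawal_log: list[tuple[str, float]] = []
        self._initial_total: dict[str, float] = {}
        for name, pars in (species or DEFAULT_SPECIES).items():
            sp = SpeciesParams(**pars) if isinstance(pars, dict) else pars
            sp.validate()
            self.species[name] = sp
            self.conc[name] = np.zeros((self.nx, self.ny, self.nz))
            self.withdrawn[name] = 0.0
            self._initial_total[name] = 0.0

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self):
        return (self.nx, self.ny, self.nz)

    @property
    def voxel_volume(self) -> float:
        return self.h ** 3

    def ground_area_cm2(self) -> float:
        return self.nx * self.ny * self.h ** 2

    def depth_cm(self) -> float:
        return self.nz * self.h

    def voxel_of_point(self, p) -> tuple[int, int, int]:
        """Voxel index containing a point (cm; x/y centred, z from surface)."""
        i = int(np.floor(p[0] / self.h + self.nx / 2.0))
        j = int(np.floor(p[1] / self.h + self.ny / 2.0))
        k = int(np.floor(p[2] / self.h))
        return (i, j, k)

    def in_bounds(self, idx) -> bool:
        i, j, k = idx
        return 0 <= i < self.nx and 0 <= j < self.ny and 0 <= k < self.nz

    def voxel_centers_z(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.h

    # -- bookkeeping -------------------------------------------------------
    def total_n(self, species: str) -> float:
        """Total N (umol) including the buffered fraction."""
        sp = self.species[species]
        return float(self.conc[species].sum() * sp.b * self.voxel_volume)

    def mark_initial(self) -> None:
        for name in self.species:
            self._initial_total[name] = self.total_n(name)
            self.withdrawn[name] = 0.0
        self.withdrawal_log.clear()

    def conservation_residual(self, species: str) -> float:
        init = self._initial_total[species]
        now = self.total_n(species) + self.withdrawn[species]
        return abs(init - now) / max(abs(init), 1e-300)

    def stability_limit(self, species: str) -> float:
        sp = self.species[species]
        if sp.d_e == 0:
            return np.inf
        return sp.b * self.h ** 2 / (6.0 * sp.d_e)

    # -- I/O ---------------------------------------------------------------
    def snapshot_frame(self) -> pd.DataFrame:
        rows = []
        zc = self.voxel_centers_z()
        for name, c in self.conc.items():
            ii, jj, kk = np.indices(c.shape)
            rows.append(pd.DataFrame({
                "i": ii.ravel(), "j": jj.ravel(), "k": kk.ravel(),
                "z_cm": zc[kk.ravel()], "species": name, "C": c.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)

    def header_json(self, path=None) -> dict:
        info = {
            "dims": [self.nx, self.ny, self.nz],
            "h_cm": self.h,
            "theta": self.theta,
            "species": {k: {"d_e": v.d_e, "b": v.b} for k, v in self.species.items()},
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(info, fh, indent=2)
        return info


def init_from_application_rate(
    rate_kg_ha: float,
    nx: int, ny: int, nz: int, h: float,
    profile: str = "uniform",
    species: str = "no3",
    species_params: dict | None = None,
    theta: float = 0.3,
    z_decay_cm: float = 15.0,
) -> SoilGrid:
    """Build a grid holding ``rate_kg_ha`` of N distributed over depth.

    The areal density is ``rate * 0.01`` mg N per cm^2 of ground area; the
    full amount is placed in the grid exactly (re-summing the voxels gives
    the applied mass to machine precision).  ``profile`` is ``uniform`` or
    ``exponential`` (surface-enriched with decay length ``z_decay_cm``).
    """
    if rate_kg_ha < 0:
        raise ValueError("application rate must be >= 0")
    grid = SoilGrid(nx, ny, nz, h, species=species_params, theta=theta)
    if species not in grid.species:
        raise ValueError(f"unknown species {species!r}")
    areal_umol = rate_kg_ha * 0.01 * UMOL_PER_MG_N  # umol per cm^2 ground
    col_total = areal_umol * h * h  # umol per voxel column
    if profile == "uniform":
        weights = np.full(nz, 1.0 / nz)
    elif profile == "exponential":
        w = np.exp(-grid.voxel_centers_z() / z_decay_cm)
        weights = w / w.sum()
    else:
        raise ValueError(f"unknown depth profile {profile!r}")
    sp = grid.species[species]
    per_voxel_n = col_total * weights  # umol per voxel, by layer
    grid.conc[species][:, :, :] = per_voxel_n[None, None, :] / (sp.b * grid.voxel_volume)
    grid.mark_initial()
    return grid


def _laplacian_zero_flux(c: np.ndarray) -> np.ndarray:
    p = np.pad(c, 1, mode="edge")
    return (
        p[:-2, 1:-1, 1:-1] + p[2:, 1:-1, 1:-1]
        + p[1:-1, :-2, 1:-1] + p[1:-1, 2:, 1:-1]
        + p[1:-1, 1:-1, :-2] + p[1:-1, 1:-1, 2:]
        - 6.0 * c
    )


def diffuse(grid: SoilGrid, dt: float, species: str | None = None) -> SoilGrid:
    """One explicit diffusion step of length ``dt`` d (mutates ``grid``).

    Raises :class:`StabilityError` if ``dt`` exceeds the explicit-scheme
    bound for any species stepped; callers that need larger steps must
    subcycle (the simulation engine does).
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    names = [species] if species is not None else list(grid.species)
    for name in names:
        sp = grid.species[name]
        if sp.d_e == 0 or dt == 0:
            continue
        limit = grid.stability_limit(name)
        if dt > limit * (1 + 1e-12):
            raise StabilityError(
                f"dt={dt} exceeds stability bound {limit:.6g} d for species {name!r}"
            )
        lam = sp.d_e * dt / (sp.b * grid.h ** 2)
        c = grid.conc[name]
        c += lam * _laplacian_zero_flux(c)
    return grid


def withdraw(grid: SoilGrid, voxel, amount: float, species: str = "no3"):
    """Remove up to ``amount`` umol of N (dissolved + buffered) from a voxel.

    Returns ``(grid, actually_withdrawn)``; never drives C negative.
    """
    if amount < 0:
        raise ValueError("withdrawal amount must be >= 0")
    if not grid.in_bounds(voxel):
        raise IndexError(f"voxel index {voxel} outside grid {grid.shape}")
    sp = grid.species[species]
    c = grid.conc[species]
    avail = c[tuple(voxel)] * sp.b * grid.voxel_volume
    taken = min(amount, avail)
    c[tuple(voxel)] -= taken / (sp.b * grid.voxel_volume)
    if c[tuple(voxel)] < 0:  # guard against rounding
        c[tuple(voxel)] = 0.0
    grid.withdrawn[species] += taken
    grid.withdrawal_log.append((species, taken))
    return grid, float(taken)


def withdraw_flat(grid: SoilGrid, flat_idx: np.ndarray, amounts: np.ndarray,
                  species: str = "no3") -> np.ndarray:
    """Vectorised capped withdrawal on flattened voxel indices.

    ``flat_idx`` may contain duplicates; per-voxel demand is aggregated and,
    where it exceeds the available pool, every contributor is scaled down
    proportionally.  Returns the amount actually granted per entry.
    """
    sp = grid.species[species]
    c = grid.conc[species].ravel()
    vol = sp.b * grid.voxel_volume
    demand = np.zeros_like(c)
    np.add.at(demand, flat_idx, amounts)
    avail = c * vol
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(demand > 0, np.minimum(1.0, avail / np.maximum(demand, 1e-300)), 0.0)
    granted = amounts * scale[flat_idx]
    taken = np.zeros_like(c)
    np.add.at(taken, flat_idx, granted)
    c -= taken / vol
    np.maximum(c, 0.0, out=c)
    total = float(taken.sum())
    grid.withdrawn[species] += total
    grid.withdrawal_log.append((species, total))
    return granted
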