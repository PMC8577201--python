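"""Seedling root-system architecture: growth, root hairs, absorptive surface.

A simplified maize seedling is grown as a set of axes (one primary, a
configurable number of seminals, and first-order laterals) that elongate at
class-specific rates, bend toward the vertical under gravitropism, and emit
laterals behind the tip at a fixed branching interval after an emergence
delay.  The axes are discretised into short straight segments, one per
internal time step, so that downstream consumers (soil coupling, export)
see a plain segment table.

Root hairs are represented statistically per segment — a density (hairs per
cm of axis) and a current hair length that ramps up behind a hair-free tip
zone — never as individual geometric objects.

Unit conventions: lengths in cm internally, the soil surface is z = 0 with
z increasing downward, times in days.  Root hair length is the single
user-facing quantity kept in mm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ArchitectureParams",
    "RootSegmentRecord",
    "RootSystemState",
    "new_root_system",
    "grow",
    "hair_length_at",
    "absorptive_surface_area",
    "export_segments_csv",
    "summary_json",
]

#: internal integration step (d); ``grow`` always advances in chunks of this
#: so that splitting a call into smaller calls reproduces the same geometry.
INTERNAL_DT = 0.25

_CLASSES = ("primary", "seminal", "lateral")

# golden-angle spacing keeps deterministic lateral azimuths well spread
_GOLDEN_DEG = 137.50776405003785


@dataclass
class ArchitectureParams:
    """Growth parameterization of the simulated seedling.

    The defaults describe a plausible maize seedling (primary plus three
    seminal axes, first-order laterals only); they are assumptions, not
    measured values, and every field is overridable from scenario config.
    """

    elongation_rate: dict = field(
        default_factory=lambda: {"primary": 2.0, "seminal": 1.5, "lateral": 0.5}
    )  # cm d^-1
    seminal_count: int = 3
    branching_interval_cm: float = 0.8  # cm of parent axis between laterals
    lateral_delay_d: float = 2.0  # emergence delay behind the passing tip
    insertion_angle_deg: dict = field(
        default_factory=lambda: {"primary": 0.0, "seminal": 35.0, "lateral": 70.0}
    )  # degrees from vertical at emission
    gravitropism_deg_per_cm: dict = field(
        default_factory=lambda: {"primary": 0.0, "seminal": 8.0, "lateral": 4.0}
    )  # bending toward vertical per cm grown
    radius_cm: dict = field(
        default_factory=lambda: {"primary": 0.05, "seminal": 0.04, "lateral": 0.02}
    )
    max_root_hair_length_mm: float = 0.5  # l_max
    root_hair_growth_rate_mm_d: float = 0.5  # g_h
    hair_free_tip_zone_cm: float = 0.5
    root_hair_density_per_cm: float = 500.0  # rho_h, hairs per cm of axis
    hair_radius_cm: float = 0.0005  # 5 um
    azimuth_jitter_deg: float = 180.0  # 0 => fully deterministic azimuths

    def validate(self) -> None:
        for cls in _CLASSES:
            for name, d in (
                ("elongation_rate", self.elongation_rate),
                ("insertion_angle_deg", self.insertion_angle_deg),
                ("gravitropism_deg_per_cm", self.gravitropism_deg_per_cm),
                ("radius_cm", self.radius_cm),
            ):
                if cls not in d:
                    raise ValueError(f"{name} missing class {cls!r}")
                if d[cls] < 0:
                    raise ValueError(f"{name}[{cls!r}] must be >= 0")
        if self.seminal_count < 0 or int(self.seminal_count) != self.seminal_count:
            raise ValueError("seminal_count must be a non-negative integer")
        for name in (
            "branching_interval_cm",
            "lateral_delay_d",
            "max_root_hair_length_mm",
            "root_hair_growth_rate_mm_d",
            "hair_free_tip_zone_cm",
            "root_hair_density_per_cm",
            "hair_radius_cm",
            "azimuth_jitter_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_root_hair_length_mm > 0 and self.root_hair_growth_rate_mm_d <= 0:
            raise ValueError(
                "root_hair_growth_rate_mm_d must be > 0 when "
                "max_root_hair_length_mm > 0 (hair length otherwise unreachable)"
            )
        if self.branching_interval_cm == 0:
            raise ValueError("branching_interval_cm must be > 0")

    def with_hair_phenotype(
        self, rhl_mm: float, rhd_per_cm: float
    ) -> "ArchitectureParams":
        """Return a copy with the hair phenotype (length, density) swapped in.

        Hair length contrasts are realised by varying the hair growth rate so
        that ``l_max`` is reached within one day, mirroring how hair-length
        treatments are imposed on an otherwise fixed plant.
        """
        return replace(
            self,
            max_root_hair_length_mm=rhl_mm,
            root_hair_growth_rate_mm_d=max(rhl_mm, 1e-9),
            root_hair_density_per_cm=rhd_per_cm,
        )


@dataclass
class RootSegmentRecord:
    """One straight piece of a root axis."""

    segment_id: int
    parent_id: Optional[int]  # previous segment on the same axis, or the
    # parent-axis segment a lateral emerges from; None at the seed
    axis_class: str
    base: np.ndarray  # (3,) cm, z positive downward
    tip: np.ndarray
    radius_cm: float
    t_created_d: float
    length_cm: float
    axis_id: int
    arc_mid_cm: float  # arc position of the segment midpoint along its axis


@dataclass
class _Axis:
    axis_id: int
    axis_class: str
    tip: np.ndarray
    heading: np.ndarray  # unit vector
    t_created: float
    arc_cm: float = 0.0
    last_segment_id: Optional[int] = None
    parent_segment_id: Optional[int] = None
    next_branch_arc: float = 0.0  # arc position of the next lateral to emit


@dataclass(eq=False)
class _PendingLateral:
    t_emerge: float
    origin: np.ndarray
    azimuth_deg: float
    parent_segment_id: Optional[int]
    order_key: tuple


class RootSystemState:
    """Segments plus per-axis tip bookkeeping at the current time."""

    def __init__(self, params: ArchitectureParams, seed: int = 0):
        params.validate()
        self.time = 0.0
        self.segments: list[RootSegmentRecord] = []
        self.rng = np.random.default_rng(seed)
        self._seed = seed
        self._axes: list[_Axis] = []
        self._pending: list[_PendingLateral] = []
        self._next_seg = 0
        self._next_axis = 0
        origin = np.zeros(3)
        self._spawn_axis("primary", origin, params.insertion_angle_deg["primary"], 0.0, 0.0, None)
        for k in range(params.seminal_count):
            az = 360.0 * k / max(params.seminal_count, 1)
            self._spawn_axis("seminal", origin, params.insertion_angle_deg["seminal"], az, 0.0, None)

    # -- helpers -----------------------------------------------------------
    def _spawn_axis(self, cls, origin, angle_deg, azimuth_deg, t, parent_segment_id):
        a = math.radians(angle_deg)
        b = math.radians(azimuth_deg)
        heading = np.array(
            [math.sin(a) * math.cos(b), math.sin(a) * math.sin(b), math.cos(a)]
        )
        self._axes.append(
            _Axis(self._next_axis, cls, origin.copy(), heading, t,
                  parent_segment_id=parent_segment_id)
        )
        self._next_axis += 1

    def _add_segment(self, axis: _Axis, new_tip, t, seg_len, radius):
        rec = RootSegmentRecord(
            segment_id=self._next_seg,
            parent_id=(axis.last_segment_id
                       if axis.last_segment_id is not None
                       else axis.parent_segment_id),
            axis_class=axis.axis_class,
            base=axis.tip.copy(),
            tip=new_tip.copy(),
            radius_cm=radius,
            t_created_d=t,
            length_cm=seg_len,
            axis_id=axis.axis_id,
            arc_mid_cm=axis.arc_cm + seg_len / 2.0,
        )
        self.segments.append(rec)
        axis.last_segment_id = rec.segment_id
        self._next_seg += 1
        return rec

    # -- queries -----------------------------------------------------------
    def total_length(self) -> float:
        return float(sum(s.length_cm for s in self.segments))

    def axis_arc(self, axis_id: int) -> float:
        return self._axes[axis_id].arc_cm

    def segment_frame(self) -> pd.DataFrame:
        rows = [
            {
                "segment_id": s.segment_id,
                "parent_id": -1 if s.parent_id is None else s.parent_id,
                "class": s.axis_class,
                "x0": s.base[0], "y0": s.base[1], "z0": s.base[2],
                "x1": s.tip[0], "y1": s.tip[1], "z1": s.tip[2],
                "radius_cm": s.radius_cm,
                "t_created_d": s.t_created_d,
                "length_cm": s.length_cm,
            }
            for s in self.segments
        ]
        return pd.DataFrame(
            rows,
            columns=["segment_id", "parent_id", "class", "x0", "y0", "z0",
                     "x1", "y1", "z1", "radius_cm", "t_created_d", "length_cm"],
        )


def new_root_system(params: ArchitectureParams, seed: int = 0) -> RootSystemState:
    return RootSystemState(params, seed)


def _bend_toward_vertical(heading: np.ndarray, bend_deg: float) -> np.ndarray:
    """Rotate ``heading`` toward +z by ``bend_deg`` in their common plane."""
    if bend_deg <= 0:
        return heading
    z = np.array([0.0, 0.0, 1.0])
    cosang = float(np.clip(np.dot(heading, z), -1.0, 1.0))
    ang = math.degrees(math.acos(cosang))
    if ang < 1e-12:
        return z.copy()
    bend = min(bend_deg, ang)
    # orthonormal basis in the heading-z plane
    perp = z - cosang * heading
    perp /= np.linalg.norm(perp)
    t = math.radians(bend)
    out = math.cos(t) * heading + math.sin(t) * perp
    return out / np.linalg.norm(out)


def grow(state: RootSystemState, params: ArchitectureParams, dt: float) -> RootSystemState:
    """Advance the root system by ``dt`` days (in fixed internal substeps).

    Mutates and returns ``state``.  Geometry is deterministic given the
    construction seed; lateral azimuths are the only stochastic element.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    params.validate()
    remaining = dt
    while remaining > 1e-12:
        step = min(INTERNAL_DT, remaining)
        _substep(state, params, step)
        remaining -= step
    return state


def _substep(state: RootSystemState, params: ArchitectureParams, dt: float) -> None:
    t0 = state.time
    t1 = t0 + dt
    # emit pending laterals whose emergence time falls in this substep
    ready = [p for p in state._pending if p.t_emerge <= t1 + 1e-12]
    for p in sorted(ready, key=lambda p: p.order_key):
        state._spawn_axis("lateral", p.origin,
                          params.insertion_angle_deg["lateral"],
                          p.azimuth_deg, p.t_emerge, p.parent_segment_id)
        state._pending.remove(p)

    for axis in list(state._axes):
        t_start = max(t0, axis.t_created)
        dt_eff = t1 - t_start
        if dt_eff <= 1e-12:
            continue
        rate = params.elongation_rate[axis.axis_class]
        seg_len = rate * dt_eff
        if seg_len <= 0:
            continue
        axis.heading = _bend_toward_vertical(
            axis.heading, params.gravitropism_deg_per_cm[axis.axis_class] * seg_len
        )
        new_tip = axis.tip + axis.heading * seg_len
        if new_tip[2] < 0.0:  # never pierce the soil surface
            new_tip[2] = 0.0
        rec = state._add_segment(axis, new_tip, t_start, seg_len, params.radius_cm[axis.axis_class])
        # schedule laterals as the tip passes successive branch points
        if axis.axis_class in ("primary", "seminal"):
            if axis.next_branch_arc <= 0.0:
                axis.next_branch_arc = params.branching_interval_cm
            arc0, arc1 = axis.arc_cm, axis.arc_cm + seg_len
            k = int(round(axis.next_branch_arc / params.branching_interval_cm)) - 1
            while axis.next_branch_arc <= arc1 + 1e-12:
                frac = (axis.next_branch_arc - arc0) / seg_len
                pos = axis.tip + axis.heading * (frac * seg_len)
                t_pass = t_start + frac * dt_eff
                k += 1
                base_az = (k * _GOLDEN_DEG) % 360.0
                jit = params.azimuth_jitter_deg
                az = base_az + (state.rng.uniform(-jit, jit) if jit > 0 else 0.0)
                state._pending.append(_PendingLateral(
                    t_emerge=t_pass + params.lateral_delay_d,
                    origin=pos, azimuth_deg=az,
                    parent_segment_id=rec.segment_id,
                    order_key=(axis.axis_id, k),
                ))
                axis.next_branch_arc += params.branching_interval_cm
        axis.tip = new_tip
        axis.arc_cm += seg_len
    state.time = t1


def hair_length_at(
    distance_from_tip_cm: float,
    segment_age_d: float,
    params: ArchitectureParams,
    axis_class: str = "primary",
) -> float:
    """Current root hair length (mm) at a point on an axis.

    Hairs are absent within the hair-free zone behind the tip; beyond it they
    elongate at ``g_h`` from the moment the point left the zone, saturating
    at ``l_max``.
    """
    if distance_from_tip_cm < 0 or segment_age_d < 0:
        raise ValueError("distance and age must be >= 0")
    lmax = params.max_root_hair_length_mm
    if lmax <= 0 or distance_from_tip_cm < params.hair_free_tip_zone_cm:
        return 0.0
    rate = params.elongation_rate[axis_class]
    t_in_zone = params.hair_free_tip_zone_cm / rate if rate > 0 else 0.0
    t_growing = max(0.0, segment_age_d - t_in_zone)
    return min(lmax, params.root_hair_growth_rate_mm_d * t_growing)


def segment_hair_lengths(state: RootSystemState, params: ArchitectureParams) -> np.ndarray:
    """Per-segment current hair length (mm) at ``state.time``."""
    out = np.zeros(len(state.segments))
    for i, s in enumerate(state.segments):
        dist = state.axis_arc(s.axis_id) - s.arc_mid_cm
        out[i] = hair_length_at(dist, state.time - s.t_created_d, params, s.axis_class)
    return out


def absorptive_surface_area(
    state: RootSystemState, params: ArchitectureParams, include_hairs: bool = True
) -> float:
    """Root surface area (cm^2), optionally adding the root hair lateral area.

    Hairs contribute ``rho_h * L * 2 pi r_h * l_h`` per segment with the
    segment's current hair length ``l_h`` (converted mm -> cm).
    """
    bare = sum(2.0 * math.pi * s.radius_cm * s.length_cm for s in state.segments)
    if not include_hairs:
        return float(bare)
    hl_cm = segment_hair_lengths(state, params) / 10.0
    lengths = np.array([s.length_cm for s in state.segments])
    hair = params.root_hair_density_per_cm * 2.0 * math.pi * params.hair_radius_cm * float(
        np.sum(lengths * hl_cm)
    )
    return float(bare + hair)


def export_segments_csv(state: RootSystemState, path) -> None:
    state.segment_frame().to_csv(path, index=False)


def summary_json(state: RootSystemState, params: ArchitectureParams, path=None) -> dict:
    info = {
        "time_d": state.time,
        "n_segments": len(state.segments),
        "total_length_cm": state.total_length(),
        "area_cm2": absorptive_surface_area(state, params, include_hairs=False),
        "area_with_hairs_cm2": absorptive_surface_area(state, params, include_hairs=True),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(info, fh, indent=2)
    return info
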