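"""Synthetic RIL trial generators with known, recoverable effect structure.

Three generators emulate the empirical datasets the statistics chain is
meant to analyse, so the whole generate -> analyze pipeline can be tested
by parameter recovery without any external data:

* ``gen_greenhouse`` — 6 RILs x 4 blocks x 2 N levels in an RCBD (two
  variants: ammonium as the sole N source, nitrate as the sole N source);
* ``gen_field`` — 9 RILs x 3 replicates x 2 N levels in a split-plot
  layout with yield and leaf area;
* ``gen_soil_profile`` — 4 soil depth layers x {ammonium, nitrate} x 2 N
  treatments.

Effects are encoded as ratios and multipliers in packaged scenario files
(``ghI``, ``ghII``, ``field``, ``soil``): a treatment multiplier moves a
trait (or RHL) mean between N levels, and an *endpoint ratio* fixes how
steeply a trait climbs across the realized RHL range — the slope and
intercept of the generating line are solved so that the predicted trait at
the maximum RHL divided by the predicted trait at the minimum RHL equals
the ratio, anchored at the treatment mean.  Noise is multiplicative
lognormal (unit mean) on traits and RHL, plus additive normal block and
whole-plot effects; traits therefore stay positive and all configured
effects are recovered exactly when noise is switched off.

Absolute trait scales and per-RIL baselines are invented (evenly spread
RHL baselines over 0.2-1.0 mm); the encoded *effects* are the quantities
of interest.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RilProfile",
    "TrialScenario",
    "GeneratedTrial",
    "load_scenario",
    "gen_greenhouse",
    "gen_field",
    "gen_soil_profile",
    "generate",
]

GREENHOUSE_TRAITS = ["shoot_g", "root_g", "root_length_cm", "n_content_mg"]
FIELD_TRAITS = ["leaf_area_cm2", "shoot_g", "yield_g", "n_content_mg"]
SOIL_LAYERS = ["0-15", "15-30", "30-45", "45-60"]


@dataclass
class RilProfile:
    name: str
    baseline_rhl_mm: float

    def __post_init__(self):
        if self.baseline_rhl_mm <= 0:
            raise ValueError("baseline RHL must be > 0")


@dataclass
class TrialScenario:
    """One trial's generative structure, loaded from a scenario YAML."""

    name: str
    kind: str  # greenhouse | field | soil
    n_form: str = "nitrate"
    n_rils: int = 6
    n_blocks: int = 4  # blocks (greenhouse) or replicates (field)
    baseline_rhl_range_mm: tuple = (0.2, 1.0)
    treatments: tuple = ("HN", "LN")
    rhl_treatment_multiplier: dict = dc_field(default_factory=lambda: {"HN": 1.0, "LN": 1.0})
    trait_means_hn: dict = dc_field(default_factory=dict)
    trait_treatment_multiplier: dict = dc_field(default_factory=dict)  # {trt: {trait: m}}
    endpoint_ratio: dict = dc_field(default_factory=dict)  # {trt: {trait: R}}
    noise: dict = dc_field(default_factory=dict)
    # soil-profile fields
    soil: dict = dc_field(default_factory=dict)
    raw: dict = dc_field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialScenario":
        d = dict(d)
        if "baseline_rhl_mm" in d:
            d["baseline_rhl_range_mm"] = d.pop("baseline_rhl_mm")
        known = {f for f in cls.__dataclass_fields__ if f != "raw"}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "baseline_rhl_range_mm" in kwargs:
            kwargs["baseline_rhl_range_mm"] = tuple(kwargs["baseline_rhl_range_mm"])
        if "treatments" in kwargs:
            kwargs["treatments"] = tuple(kwargs["treatments"])
        sc = cls(**kwargs, raw=d)
        sc.validate()
        return sc

    def validate(self) -> None:
        if self.kind not in ("greenhouse", "field", "soil"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        for trt, m in self.rhl_treatment_multiplier.items():
            if m <= 0:
                raise ValueError(f"RHL multiplier for {trt} must be > 0")
        for trt, d in self.trait_treatment_multiplier.items():
            for trait, m in d.items():
                if m <= 0:
                    raise ValueError(f"trait multiplier {trt}/{trait} must be > 0")
        for key in ("trait_cv", "rhl_cv", "block_sd_frac", "whole_plot_sd_frac"):
            v = self.noise.get(key, 0.0)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x < 0 for x in vals):
                raise ValueError(f"noise {key} must be >= 0")
        lo, hi = self.baseline_rhl_range_mm
        if not (0 < lo <= hi):
            raise ValueError("baseline RHL range must be positive and ordered")

    # -- derived structure -------------------------------------------------
    def rils(self) -> list[RilProfile]:
        lo, hi = self.baseline_rhl_range_mm
        vals = np.linspace(lo, hi, self.n_rils)
        return [RilProfile(f"RIL{i + 1:02d}", float(v)) for i, v in enumerate(vals)]

    def traits(self) -> list[str]:
        return FIELD_TRAITS if self.kind == "field" else GREENHOUSE_TRAITS

    def rhl_endpoints(self, treatment: str) -> tuple[float, float]:
        """Noiseless realized RHL range in a treatment (the regression
        endpoints used for percent-change readings)."""
        lo, hi = self.baseline_rhl_range_mm
        m = self.rhl_treatment_multiplier.get(treatment, 1.0)
        return lo * m, hi * m

    def trait_cv(self, trait: str) -> float:
        cv = self.noise.get("trait_cv", 0.0)
        return float(cv.get(trait, 0.0)) if isinstance(cv, dict) else float(cv)

    def generating_line(self, treatment: str, trait: str) -> tuple[float, float]:
        """Solve (intercept, slope) of the trait-vs-RHL generating line.

        The line is anchored so the predicted trait at the treatment's mean
        RHL equals the treatment trait mean, and the ratio of predictions at
        the RHL endpoints equals the configured endpoint ratio.
        """
        mu = self.trait_means_hn[trait] * \
            self.trait_treatment_multiplier.get(treatment, {}).get(trait, 1.0)
        ratio = self.endpoint_ratio.get(treatment, {}).get(trait, 1.0)
        x_min, x_max = self.rhl_endpoints(treatment)
        x_bar = float(np.mean([r.baseline_rhl_mm for r in self.rils()])) \
            * self.rhl_treatment_multiplier.get(treatment, 1.0)
        if ratio == 1.0:
            return mu, 0.0
        span = x_max - x_min
        denom = span / (ratio - 1.0) + (x_bar - x_min)
        if denom <= 0:
            raise ValueError(
                f"endpoint ratio {ratio} for {treatment}/{trait} implies a "
                "non-positive anchor; infeasible")
        slope = mu / denom
        y_min = slope * span / (ratio - 1.0)
        if y_min <= 0:
            raise ValueError(
                f"endpoint ratio {ratio} for {treatment}/{trait} implies a "
                f"non-positive predicted trait at the minimum RHL ({y_min:.4g})")
        return y_min - slope * x_min, slope

    def truth(self) -> dict:
        """Generative effect values as percent, for recovery testing."""
        out = {}
        for trt in self.treatments:
            if trt == "HN":
                continue
            out[f"rhl_pct_{trt}"] = 100.0 * (self.rhl_treatment_multiplier.get(trt, 1.0) - 1.0)
            for trait in self.traits():
                m = self.trait_treatment_multiplier.get(trt, {}).get(trait, 1.0)
                out[f"{trait}_treatment_pct_{trt}"] = 100.0 * (m - 1.0)
                r = self.endpoint_ratio.get(trt, {}).get(trait, 1.0)
                out[f"{trait}_endpoint_pct_{trt}"] = 100.0 * (r - 1.0)
        return out


@dataclass
class GeneratedTrial:
    table: pd.DataFrame
    scenario: TrialScenario
    seed: int

    def rhl_endpoints(self, treatment: str) -> tuple[float, float]:
        return self.scenario.rhl_endpoints(treatment)


def _scenario_dir():
    return importlib.resources.files("rhizosim") / "scenarios"


def load_scenario(name_or_path) -> TrialScenario:
    """Load a packaged scenario by name (``ghI``, ``ghII``, ``field``,
    ``soil``) or any YAML file by path."""
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text()
    else:
        res = _scenario_dir() / f"{p.stem if p.suffix else p.name}.yaml"
        try:
            text = res.read_text()
        except FileNotFoundError:
            raise FileNotFoundError(f"no packaged scenario named {name_or_path!r}")
    return TrialScenario.from_dict(yaml.safe_load(text))


def _lognormal_factor(rng, cv, size):
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _gen_blocked(scenario: TrialScenario, seed: int, unit_col: str) -> GeneratedTrial:
    rng = np.random.default_rng(seed)
    rils = scenario.rils()
    traits = scenario.traits()
    n_units = scenario.n_blocks
    rhl_cv = float(scenario.noise.get("rhl_cv", 0.0))
    block_sd = float(scenario.noise.get("block_sd_frac", 0.0))
    wp_sd = float(scenario.noise.get("whole_plot_sd_frac", 0.0))
    lines = {(trt, trait): scenario.generating_line(trt, trait)
             for trt in scenario.treatments for trait in traits}
    # additive design effects, drawn once per trait
    block_eff = {trait: rng.normal(0.0, block_sd * scenario.trait_means_hn[trait], n_units)
                 for trait in traits}
    wp_eff = {trait: rng.normal(0.0, wp_sd * scenario.trait_means_hn[trait],
                                (n_units, len(scenario.treatments)))
              for trait in traits}
    rows = []
    for ti, trt in enumerate(scenario.treatments):
        mult = scenario.rhl_treatment_multiplier.get(trt, 1.0)
        for ril in rils:
            rhl = ril.baseline_rhl_mm * mult * _lognormal_factor(rng, rhl_cv, n_units)
            row_traits = {}
            for trait in traits:
                a, b = lines[(trt, trait)]
                noise = _lognormal_factor(rng, scenario.trait_cv(trait), n_units)
                y = (a + b * rhl) * noise + block_eff[trait] + wp_eff[trait][:, ti]
                row_traits[trait] = np.maximum(y, 1e-9)
            for u in range(n_units):
                rec = {"ril": ril.name, unit_col: u + 1, "treatment": trt,
                       "rhl_mm": rhl[u]}
                rec.update({trait: row_traits[trait][u] for trait in traits})
                rows.append(rec)
    cols = ["ril", unit_col, "treatment", "rhl_mm"] + traits
    return GeneratedTrial(pd.DataFrame(rows)[cols], scenario, seed)


def gen_greenhouse(scenario: TrialScenario, seed: int = 0) -> GeneratedTrial:
    """Generate one RCBD greenhouse trial table (RIL x block x N level)."""
    if scenario.kind != "greenhouse":
        raise ValueError("scenario is not a greenhouse scenario")
    return _gen_blocked(scenario, seed, unit_col="block")


def gen_field(scenario: TrialScenario, seed: int = 0) -> GeneratedTrial:
    """Generate one split-plot field trial table (RIL x rep x N level)."""
    if scenario.kind != "field":
        raise ValueError("scenario is not a field scenario")
    return _gen_blocked(scenario, seed, unit_col="rep")


def gen_soil_profile(scenario: TrialScenario, seed: int = 0) -> GeneratedTrial:
    """Generate a soil N depth profile (layer x species x treatment).

    Top-layer totals and ammonium fractions come from the scenario;
    concentrations decay geometrically with each deeper layer.  With the
    default zero noise the table is fully deterministic.
    """
    if scenario.kind != "soil":
        raise ValueError("scenario is not a soil scenario")
    rng = np.random.default_rng(seed)
    decay = float(scenario.soil.get("depth_decay", 0.55))
    cv = float(scenario.soil.get("noise_cv", 0.0))
    layers = scenario.soil.get("layers", SOIL_LAYERS)
    rows = []
    for trt, pars in scenario.soil["treatments"].items():
        total_top = float(pars["topsoil_total_n"])
        frac = float(pars["nh4_fraction_top"])
        if not (0.0 < frac < 1.0):
            raise ValueError(f"nh4 fraction for {trt} must be in (0, 1)")
        for li, layer in enumerate(layers):
            total = total_top * decay ** li
            for species, conc in (("NH4", total * frac), ("NO3", total * (1 - frac))):
                rows.append({
                    "treatment": trt, "depth_layer": layer, "species": species,
                    "concentration": conc * float(_lognormal_factor(rng, cv, 1)[0]),
                })
    return GeneratedTrial(pd.DataFrame(rows), scenario, seed)


_GENERATORS = {"greenhouse": gen_greenhouse, "field": gen_field, "soil": gen_soil_profile}


def generate(scenario: TrialScenario | str, seed: int = 0) -> GeneratedTrial:
    """Dispatch to the right generator for the scenario kind."""
    if isinstance(scenario, str):
        scenario = load_scenario(scenario)
    return _GENERATORS[scenario.kind](scenario, seed)
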