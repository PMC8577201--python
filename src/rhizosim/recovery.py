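"""End-to-end effect recovery: generate trials, analyse them, average.

Runs the packaged trial scenarios through the generate -> analyze pipeline
over a set of seeds and reports the recovered headline effects (endpoint
percent changes from the RHL regressions, treatment percent differences,
and the topsoil ammonium share).  This is the quantitative check that the
statistics chain reads back the effect sizes the generators encode under
realistic noise.
"""

from __future__ import annotations

import numpy as np

from . import stats as st
from . import synthetic as syn

__all__ = ["recover_effects", "dataset_seeds"]


def dataset_seeds(master_seed: int, n_seeds: int) -> list[int]:
    """Per-dataset seeds derived deterministically from one master seed."""
    return [(master_seed * 100_003 + i) % (2 ** 31) for i in range(1, n_seeds + 1)]


def _endpoint_pct(table, scenario, trait, treatment="LN"):
    sub = table[table.treatment == treatment]
    fit = st.fit_linear(sub["rhl_mm"], sub[trait])
    return st.percent_change_from_fit(fit, *scenario.rhl_endpoints(treatment)).value


def recover_effects(master_seed: int = 1, n_seeds: int = 20) -> dict:
    """Mean recovered effects over ``n_seeds`` generated datasets.

    Returns ``{name: {"value": float, "n": int}}`` where ``n`` is the total
    number of observations analysed for that effect.  Treatment percent
    *reductions* are reported as magnitudes.
    """
    seeds = dataset_seeds(master_seed, n_seeds)
    gh1 = syn.load_scenario("ghI")
    gh2 = syn.load_scenario("ghII")
    fld = syn.load_scenario("field")

    acc: dict[str, list[float]] = {k: [] for k in (
        "ghII_ln_biomass_endpoint_pct", "ghII_ln_n_content_endpoint_pct",
        "ghI_ln_biomass_endpoint_pct", "ghI_ln_n_content_endpoint_pct",
        "ghII_rhl_low_n_pct", "field_rhl_reduction_pct",
        "field_biomass_reduction_pct", "field_yield_reduction_pct",
        "field_ln_yield_endpoint_pct",
    )}
    rows = {"gh": 0, "field": 0}
    for s in seeds:
        t1 = syn.gen_greenhouse(gh1, seed=s).table
        t2 = syn.gen_greenhouse(gh2, seed=s).table
        tf = syn.gen_field(fld, seed=s).table
        rows["gh"] += len(t2)
        rows["field"] += len(tf)
        acc["ghII_ln_biomass_endpoint_pct"].append(_endpoint_pct(t2, gh2, "shoot_g"))
        acc["ghII_ln_n_content_endpoint_pct"].append(_endpoint_pct(t2, gh2, "n_content_mg"))
        acc["ghI_ln_biomass_endpoint_pct"].append(_endpoint_pct(t1, gh1, "shoot_g"))
        acc["ghI_ln_n_content_endpoint_pct"].append(_endpoint_pct(t1, gh1, "n_content_mg"))
        acc["ghII_rhl_low_n_pct"].append(
            st.treatment_percent_difference(t2, "rhl_mm", "HN", "LN").value)
        acc["field_rhl_reduction_pct"].append(
            abs(st.treatment_percent_difference(tf, "rhl_mm", "HN", "LN").value))
        acc["field_biomass_reduction_pct"].append(
            abs(st.treatment_percent_difference(tf, "shoot_g", "HN", "LN").value))
        acc["field_yield_reduction_pct"].append(
            abs(st.treatment_percent_difference(tf, "yield_g", "HN", "LN").value))
        acc["field_ln_yield_endpoint_pct"].append(_endpoint_pct(tf, fld, "yield_g"))

    out = {}
    for key, vals in acc.items():
        n = rows["field"] if key.startswith("field") else rows["gh"]
        out[key] = {"value": float(np.mean(vals)), "n": n}

    # deterministic soil-profile share (packaged defaults, zero noise)
    soil = syn.gen_soil_profile(syn.load_scenario("soil"), seed=master_seed)
    top = soil.table[(soil.table.treatment == "LN")
                     & (soil.table.depth_layer == "0-15")]
    nh4 = float(top[top.species == "NH4"].concentration.iloc[0])
    no3 = float(top[top.species == "NO3"].concentration.iloc[0])
    out["soil_ln_topsoil_nh4_pct"] = {
        "value": 100.0 * nh4 / (nh4 + no3), "n": len(soil.table)}
    return out
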