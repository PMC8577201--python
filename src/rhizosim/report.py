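"""Figure-style summaries and run manifests.

Renders the two standard views of this package's outputs:

* sweep panels — cumulative N uptake against root hair length, one panel
  per (hair density, N rate) combination with one series per transpiration
  level, each with its quadratic fit;
* trial panels — a trait against root hair length per N treatment with the
  fitted regression line.

Every rendered panel is accompanied by a CSV of exactly the plotted values
so the figures are auditable, and every CLI run writes a manifest that
allows the tabular outputs to be replayed byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from . import __version__  # noqa: E402
from .stats import fit_linear, fit_quadratic  # noqa: E402

__all__ = ["RunManifest", "report_sweep", "report_trial"]


def stable_hash(obj) -> str:
    """Hash of a JSON-able object, invariant to key order."""
    return hashlib.sha1(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: list
    inputs: list
    outputs: list = field(default_factory=list)
    version: str = __version__
    timestamp: str = ""

    def write(self, path) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat()
        payload = {
            "tool_version": self.version,
            "command": self.command,
            "argv": sys.argv,
            "config_hash": stable_hash(self.config),
            "config": self.config,
            "seeds": self.seeds,
            "inputs": [str(p) for p in self.inputs],
            "outputs": [str(p) for p in self.outputs],
            "timestamp": self.timestamp,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def report_sweep(sweep: pd.DataFrame, out_dir) -> list[Path]:
    """Uptake-vs-RHL panels from a tidy sweep table.

    One panel per (density, N rate); series per transpiration level with a
    quadratic fit when enough levels are present.  Writes
    ``panel_<rhd>_<n>.csv`` (plotted values, bit-identical to the table
    subset) and ``panel_<rhd>_<n>.png``.  Returns the written paths.
    """
    if sweep.empty:
        raise ValueError("empty sweep table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    cols = ["rhl_mm", "rhd_per_cm", "n_kg_ha", "transpiration_pct", "uptake_umol"]
    for (rhd, n_rate), panel in sweep.groupby(["rhd_per_cm", "n_kg_ha"]):
        stem = f"panel_rhd{rhd:g}_n{n_rate:g}"
        csv_path = out / f"{stem}.csv"
        panel[cols].to_csv(csv_path, index=False)
        fig, ax = plt.subplots(figsize=(4.2, 3.4))
        for pct, series in panel.groupby("transpiration_pct"):
            s = series.sort_values("rhl_mm")
            ax.plot(s["rhl_mm"], s["uptake_umol"], "o",
                    label=f"{pct:g} % transpiration")
            if s["rhl_mm"].nunique() >= 4:
                fit = fit_quadratic(s["rhl_mm"], s["uptake_umol"])
                xs = np.linspace(s["rhl_mm"].min(), s["rhl_mm"].max(), 50)
                ax.plot(xs, fit.predict(xs), "-", lw=1)
        ax.set_xlabel("root hair length (mm)")
        ax.set_ylabel("cumulative N uptake (umol)")
        ax.set_title(f"density {rhd:g} cm$^{{-1}}$, {n_rate:g} kg N ha$^{{-1}}$")
        ax.legend(fontsize=7)
        fig.tight_layout()
        png_path = out / f"{stem}.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        written += [csv_path, png_path]
    return written


def report_trial(table: pd.DataFrame, traits, out_dir, rhl_col="rhl_mm") -> list[Path]:
    """Trait-vs-RHL regression panels per treatment for a trial table."""
    if table.empty:
        raise ValueError("empty trial table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for trait in traits:
        stem = f"regression_{trait}"
        csv_path = out / f"{stem}.csv"
        table[["ril", "treatment", rhl_col, trait]].to_csv(csv_path, index=False)
        fig, ax = plt.subplots(figsize=(4.2, 3.4))
        for trt, sub in table.groupby("treatment"):
            ax.plot(sub[rhl_col], sub[trait], "o", ms=3, label=trt)
            fit = fit_linear(sub[rhl_col], sub[trait])
            xs = np.linspace(sub[rhl_col].min(), sub[rhl_col].max(), 20)
            ax.plot(xs, fit.predict(xs), "-", lw=1)
        ax.set_xlabel("root hair length (mm)")
        ax.set_ylabel(trait)
        ax.legend(fontsize=8)
        fig.tight_layout()
        png_path = out / f"{stem}.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        written += [csv_path, png_path]
    return written
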