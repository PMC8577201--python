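# rhizosim

Root hairs — tubular extensions of root epidermal cells — enlarge a root's
absorptive surface and push its reach beyond the nutrient depletion zone
that forms where uptake outpaces resupply. Their value for phosphorus
capture is well established; their value for **nitrogen** is subtler,
because nitrate moves freely by transpiration-driven mass flow while
ammonium is diffusion-limited. `rhizosim` is a toolkit for studying that
question at desk scale, aimed at root biologists and quantitative
agronomists. It provides:

* a **functional–structural simulation** of a maize seedling: an explicit
  primary/seminal/lateral architecture grown for 15 d, coupled to a
  voxelized soil in which each N species follows buffered diffusion
  b·∂C/∂t = D_e∇²C in a closed box, with per-segment uptake
  I = I_max·C̄/(K_m + C̄)·A plus mass-flow delivery w_seg·C̄, where the
  water demand f_T·W·B (W = 100 cm³ g⁻¹ d⁻¹) dials the mass-flow route.
  Root hairs (length ℓ_max ∈ [0, 1] mm, density ρ_h ∈ [100, 1000] cm⁻¹)
  act through absorptive area and depletion-cylinder reach. Factorial
  sweeps over ℓ_max × ρ_h × N rate × f_T emit tidy tables, and every run
  carries an exact N-conservation ledger;
* **synthetic RIL trial generators** for greenhouse (RCBD, 6 RILs × 4
  blocks, ammonium or nitrate), field (split-plot, 9 RILs × 3 reps) and
  soil depth-profile datasets with effects encoded as multipliers and
  endpoint ratios, so the analysis chain is testable by parameter
  recovery;
* the matching **statistics chain**: blocked two-way ANOVA with
  interaction, Fisher's protected LSD (D = 0.05) with letter display,
  per-treatment OLS of traits on root hair length with endpoint percent
  change 100·(ŷ(x_max) − ŷ(x_min))/ŷ(x_min), treatment percent
  differences, and quadratic fits for sweep output.

See `docs/methods.md` for the model, its assumptions and its limits.

## Worked example

Generate a nitrate greenhouse trial, regress shoot biomass on root hair
length within the low-N treatment, and read the endpoint percent change:

```python
from rhizosim import synthetic as syn, stats as st

sc = syn.load_scenario("ghII")
trial = syn.gen_greenhouse(sc, seed=42)
low_n = trial.table[trial.table.treatment == "LN"]

fit = st.fit_linear(low_n.rhl_mm, low_n.shoot_g)
pc = st.percent_change_from_fit(fit, *sc.rhl_endpoints("LN"))
print(f"slope={fit.slope:.2f} g/mm, R2={fit.r_squared:.2f}, "
      f"change={pc.value:.0f}% over {pc.x_min:.2f}-{pc.x_max:.2f} mm")
print("RHL low-N shift:",
      round(st.treatment_percent_difference(trial.table, "rhl_mm", "HN", "LN").value, 1), "%")
```

prints

```
slope=7.97 g/mm, R2=0.95, change=284% over 0.24-1.21 mm
RHL low-N shift: 21.9 %
```

i.e. in this draw, plants at the long end of the hair range are predicted
to carry ~284 % more shoot biomass than the shortest-haired plants under
low N (the scenario encodes +216 %; single seeds scatter around it, the
20-seed mean recovers it), and low nitrate raised realized RHL by ~22 %
against the encoded +21 %.

One simulation, long dense hairs under low N with suppressed
transpiration:

```python
from rhizosim import ScenarioConfig, run_simulation
res = run_simulation(ScenarioConfig(rhl_mm=1.0, rhd_per_cm=1000,
                                    n_kg_ha=62.4, transpiration_fraction=0.25,
                                    seed=42))
```

yields 196.6 µmol cumulative N uptake (192.3 diffusive, 4.3 mass-flow)
from a 428 cm root system whose hairs raise absorptive area from 67.9 to
179.8 cm², with a conservation residual of 6e-16. The same scenario with
hairless roots takes up 97.7 µmol — the hair benefit is largest exactly
where mass flow is weakest.

The same flows are scriptable from the shell:

```bash
rhizosim generate --scenario ghII --seed 42 --out trial.csv
rhizosim analyze --in trial.csv --design rcbd --out report.json
rhizosim simulate --seed 42 --out result.json
rhizosim sweep --seed 1 --out sweep.csv --resume
rhizosim report --sweep sweep.csv --out panels/
rhizosim reproduce --seed 1 --out repro/
```

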