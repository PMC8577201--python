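# Methods

## Scope and intent

`rhizosim` has two coupled halves. The first is a desk-scale
functional–structural simulation of a maize seedling taking up nitrogen
from soil, built to expose how root hair length (RHL), root hair density
(RHD), soil N availability and transpiration-driven mass flow interact in
setting N capture. The second is a statistical workbench for blocked RIL
trials — synthetic greenhouse/field data generators with known effect
structure, and the ANOVA / protected-LSD / regression chain used to
analyse such trials — wired so that the analysis chain can be validated by
parameter recovery against the generators.

The simulator is heuristic: it is meant to reproduce mechanisms and
orderings (depletion zones, the hair-length signal, the mass-flow dial),
not calibrated field numbers.

## Root system model

A seedling is one primary axis, `seminal_count` seminal axes (default 3)
and first-order laterals. Axes elongate at class-specific constant rates
(default 2.0 / 1.5 / 0.5 cm d⁻¹ for primary / seminal / lateral), bend
toward the vertical at a class-specific rate (degrees per cm grown), and
are discretised into one straight segment per internal time step (fixed at
0.25 d, so splitting a growth call into smaller calls reproduces identical
geometry). Parent axes emit a lateral each 0.8 cm of arc; the lateral
emerges 2 d after the tip passes the branch point, with a golden-angle
azimuth sequence plus uniform jitter drawn from the scenario seed (the
only stochastic element; set `azimuth_jitter_deg: 0` for fully
deterministic geometry). Coordinates are cm, origin at the seed, z
positive downward; tips are clamped at the soil surface.

Root hairs are statistical properties of a segment, never geometry: a
density ρ_h (hairs cm⁻¹ of axis) and a current length that is zero within
a 0.5 cm hair-free zone behind the tip and otherwise ramps at g_h (mm d⁻¹)
to a ceiling ℓ_max (mm). Hair-length treatments are imposed by varying
g_h so ℓ_max is reached within one day. Hairs contribute
ρ_h·L·2π·r_h·ℓ_h to a segment's absorptive area (r_h = 5 µm) and extend
its depletion-cylinder radius by ℓ_h.

These architecture defaults are stated as plausible for a maize seedling,
not reproduced from measurements; every value is a config field.

## Soil model

A closed box of cubic voxels (default 20 × 20 × 40 cm at 5 mm; a 1 mm grid
is configurable but far slower) carries per-species solution concentration
C (µmol per cm³ of soil), constant buffer capacity b (total : dissolved)
and effective diffusivity D_e. Transport is b·∂C/∂t = D_e∇²C, integrated
with the explicit 6-neighbour scheme under zero-flux boundaries; the
engine subcycles below the stability bound b·h²/(6·D_e) and a single
over-long step raises rather than silently subcycling. Closed-box
semantics make conservation exact: initial N = soil N + ledgered
withdrawals to ~10⁻¹⁵ relative in practice (10⁻⁸ is the enforced bound).

Field-style applications convert as 1 kg ha⁻¹ = 0.01 mg N cm⁻², placed
uniformly over depth by default (an exponential surface-enriched profile
is available). Two species are parameterized: nitrate (D_e = 0.5 cm² d⁻¹,
b = 2) and ammonium (D_e = 0.05, b = 20). These magnitudes are
literature-typical assumptions — mobile, weakly buffered nitrate versus
strongly sorbed ammonium — not fitted values. The factorial sweep uses
nitrate; ammonium is exercised by tests and the soil-profile generator.
Mineralization and leaching are off by default so the N budget is closed.

## Uptake coupling

Each daily loop step: grow the architecture, diffuse (subcycled), take up,
then grow the shoot. Uptake per segment has two ledgered routes:

* **Active/diffusive**: Michaelis–Menten per unit absorptive area,
  I = I_max·C̄/(K_m + C̄)·A·dt, with one (I_max, K_m) pair for root and
  hair surface alike (defaults I_max = 1 µmol cm⁻² d⁻¹, K_m = 0.05 µmol
  cm⁻³ — magnitudes chosen to put the default scenarios in a
  diffusion-limited regime).
* **Mass flow**: w_seg·C̄·dt, where total water demand is
  f_T·W·(shoot biomass) with W = 100 cm³ g⁻¹ d⁻¹ at full transpiration and
  each segment's share w_seg is proportional to its absorptive area. C̄ is
  used on the soil-volume basis, mirroring the simple conceptual reading
  of transpiration as a dial on convective delivery; a solution-basis
  variant would scale by 1/θ.

C̄ is the reach-weighted mean concentration over the voxels whose centres
lie within (segment radius + ℓ_h) of the axis; the axis is sampled at
≤ h/4 spacing, each sample's length share split equally over the voxel
centres it reaches, falling back to the containing voxel so hairless roots
draw only on the voxel holding the axis and weights always total the
in-grid length.

Because 5 mm voxels are far coarser than a hair cylinder, a **sub-voxel
depletion factor** keeps the hair-length signal: each segment's effective
concentration is C̄·max(0, 1 − U_day/(b·C̄·V_reach)), where U_day is its
uptake since the last daily reset and V_reach = π(r + ℓ_h)²·L its
depletion-cylinder volume. Longer hairs enlarge the cylinder and slow
self-depletion; hair–hair competition needs no explicit term because
co-located segments are capped by the same finite voxel pools (withdrawals
are granted proportionally when a voxel is oversubscribed, and never drive
C negative).

Shoot biomass follows a logistic potential trajectory (B₀ = 0.05 g,
r = 0.25 d⁻¹, B_max = 1.5 g) throttled by N sufficiency: an increment is
granted only as far as unallocated plant N (seed reserve 150 µmol plus
cumulative uptake) covers it at 2000 µmol N per g of new tissue (~2.8 % N
by dry weight). This deliberately collapses a full carbon/water budget
into one scalar coupling — cumulative uptake, not growth realism, is the
quantity of interest.

Each sweep cell draws an independent seed stream from the master seed, so
replicate variance is valid and any cell is reproducible in isolation.

## Synthetic trial generators

The generators emulate the statistical structure of blocked RIL trials;
their packaged defaults *are* the study conditions:

* `ghI` / `ghII`: 6 RILs × 4 blocks × {high N, low N} in an RCBD, with
  ammonium (`ghI`) or nitrate (`ghII`) as the N source. Encoded effects:
  RHL plasticity ×1.00 (`ghI`) or ×1.21 (`ghII`) under low N; low-N trait
  multipliers (e.g. shoot ×0.77 `ghI`, ×0.45 `ghII`); low-N endpoint
  ratios 1.44/1.71 (`ghI` shoot/plant N) and 3.16/3.37 (`ghII`).
* `field`: 9 RILs × 3 replicates × {high N, low N} in a split-plot layout
  (N on whole plots). RHL ×0.70, shoot ×0.55, yield ×0.88 under low N;
  low-N endpoint ratios 3.50 (shoot), 3.00 (plant N), 3.67 (yield).
* `soil`: 4 depth layers × {NH₄, NO₃} × 2 treatments; topsoil ammonium
  share 11 % (high N) and 21 % (low N), geometric decay 0.55 per layer.

An *endpoint ratio* R fixes the generating line y = a + b·x of a trait on
RHL by two constraints: the prediction at the treatment's mean RHL equals
the treatment trait mean, and prediction(x_max)/prediction(x_min) = R over
the noiseless realized RHL range. Ratios with a non-positive implied
anchor are rejected. Noise is multiplicative lognormal with unit mean on
RHL (CV 0.08) and traits, plus additive normal block effects (SD 3 % of
the trait mean) and, in the field, whole-plot (rep × N) effects (SD 3 %).
Per-RIL RHL baselines are spread evenly over 0.2–1.0 mm, maximising
regression leverage within the natural range; absolute trait scales are
invented and marked as such in the scenario files.

Greenhouse trait CVs default to 0.10. In the field scenario the
shoot-biomass CV (0.55) is deliberately calibrated so the emergent low-N
regression R² averages inside 0.2–0.35, the band such field trials
typically show; yield (0.10), leaf area (0.50) and plant N (0.30) CVs are
set at agronomically typical values without calibration.

What passing recovery tests shows — and does not. Zero-noise round trips
prove the analysis chain inverts the generative model exactly; noisy
recovery proves near-unbiasedness at realistic n. Because the generators
share the linear-in-RHL form the analysis assumes, these tests cannot
detect misspecification against real data (nonlinear dose–response,
heteroscedasticity beyond the lognormal form, genotype × block
interactions, missing plots).

## Statistics

* OLS (`fit_linear`, `fit_quadratic`) via statsmodels; R² defined as 0
  for a constant response; two-sided slope t-test (linear) or model F
  (quadratic). Percent change reads the fitted line at the RHL range
  endpoints: 100·(ŷ(x_max) − ŷ(x_min))/ŷ(x_min), defaulting to the
  observed range and erroring on a non-positive baseline.
* Two-way blocked ANOVA (genotype, treatment, interaction, block,
  residual) on balanced complete designs only; unbalanced input is an
  explicit error. Block is treated as a fixed additive factor — in a
  balanced layout the genotype/treatment F-tests coincide with the
  random-block mixed-model tests, which removes the mixed-model machinery
  without changing the inferences. The split-plot variant re-tests the N
  main effect against the rep × N whole-plot mean square and removes that
  component from the residual.
* Protected LSD at α = 0.05: no letters unless the omnibus F is
  significant; LSD = t(1 − α/2, df_res)·√(2·MS_res/n); letters by an
  insert-and-absorb sweep over descending means, ties at exactly the LSD
  counted as non-significant. No multiple-testing correction beyond the
  protection step, matching common agronomic practice.

## Numerical choices and degenerate inputs

Explicit diffusion raises `StabilityError` above the stability bound
(engine subcycles; callers must not). Withdrawals cap at available N and
are shared proportionally under contention. Zero-variance traits short-
circuit the ANOVA with a flag instead of 0/0 F ratios. Zero-duration
simulations echo the initial state; zero N rate yields exactly zero
uptake. Hair phenotypes outside the calibrated ranges (ℓ_max 0–1 mm,
ρ_h 100–1000 cm⁻¹) warn rather than fail.

## Problem sizes

Default single runs are 15 d at dt = 0.25 d on a 40 × 40 × 80 voxel grid
(~1 s each). The packaged reduced factorial used by the property and trend
checks is 3 RHL × 2 RHD × 2 N × 2 transpiration levels (24 runs); the full
7 × 3 × 3 × 4 factorial is available through `run_sweep`/`rhizosim sweep`.
Effect-recovery runs average 20 generated datasets per scenario; the
type-I-rate experiment uses 500 null datasets.

## Known limitations

No second-order laterals, crown/brace flushes, root mortality, exudation
or mechanical impedance; no water PDE (mass flow is convective delivery at
the root surface, not a Darcy/Richards solution); constant-b sorption
only; one kinetic constant pair for all surfaces; shoot growth is a scalar
N-throttled logistic, not a carbon budget. The simulator's absolute uptake
numbers are therefore not comparable to field measurements; its intended
outputs are orderings and relative effects.
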