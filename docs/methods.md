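# Methods

This note records the model as implemented, the parameter choices and their
rationale, the numerical schemes, and what the synthetic test conditions do
and do not establish.

## State variables and governing balances

Four state variables per reactor compartment:

| symbol | meaning | units |
|---|---|---|
| m | biomass density in the cage | gDW l⁻¹ |
| N_int | internal (tissue) nitrogen quota | % gN gDW⁻¹ |
| N_ext | dissolved N inside the cage | μmol-N l⁻¹ |
| N_env | ambient dissolved N below the cage | μmol-N l⁻¹ |

Biomass grows at μ = μ_max·f and decays at λ(T) = λ20·θ^(T−20). The
combined growth function is f = f_T·f_S·min{f_N, f_P, f_I}: temperature and
salinity scale multiplicatively, while internal N, internal P and light
compete under Liebig's law of the minimum. Phosphorus is not modelled
(f_P ≡ 1); the min() slot is kept so a P quota model can plug in later.
The quota is replenished by uptake ψ (converted to quota units by
14·10⁻⁴ % gN gDW⁻¹ per μmol-N gDW⁻¹) and diluted by growth at rate
N_int·μ. The printed form of the quota-dilution term in some statements of
this model family carries a bare biomass factor; dimensional analysis of a
per-gDW quota requires the specific growth rate, and −N_int·μ is what is
implemented. Cage N is set by pump exchange Q_p·(N_env − N_ext)/V_cage
(V_cage in litres) minus uptake ψ·m.

Growth, losses and quota dilution act only during light hours (an hour
counts as lit when I0 exceeds a configurable 1 μmol photons m⁻² s⁻¹
threshold); uptake and water exchange run all 24 h, since uptake depends on
nitrogen availability rather than light and pumping is continuous. Loss
rates quoted per day convert to per-light-hour by dividing by the light
hours of the day; the default λ20 = 0.0016 h⁻¹ is the per-light-hour
equivalent of ≈2.2 % day⁻¹.

## Limitation factor forms

* **Temperature** — beta-type (Yan–Hunt) response,
  f_T = [u·e^(1−u)]^n with u = (T_max − T)/(T_max − T_opt): exactly 1 at
  T_opt, exactly 0 at and above T_max (clamped — growth factors are
  fractions), unimodal, with n shaping the shoulder. Chosen over the
  exp(−k·((T−T_opt)/(T_max−T_opt))²) family because it honours both anchor
  constraints (unit optimum, zero lethal bound) without extra constants.
* **Salinity** — Gaussian, f_S = exp(−((S − S_opt)/σ_S)²), symmetric and
  maximal at the optimum. With the broad default width (σ_S = 20 PSU around
  S_opt = 25) the factor is 0.94 at the 30 PSU operating salinity: salinity
  modulates, but never dominates, growth in the simulated estuary — the
  regime the model targets.
* **Internal N** — normalized Droop quota,
  f_N = (1 − N_min/N_int)/(1 − N_min/N_max): 0 at the subsistence quota,
  1 at the storage quota. The critical quota N_int_crit (default 2 %) is
  descriptive — the level below which f_N is small enough to take over the
  Liebig minimum — and does not enter the algebra as a breakpoint.
* **Light** — Monod scaled by the photosynthetically active fraction,
  f_I = I/(K_I + I)·0.43, saturating at 0.43, applied to the
  reactor-averaged irradiance. Photoinhibition and hyperbolic-tangent
  alternatives are out of scope.

## Parameters

Calibration-anchored values (reactor-scale experiments): T_opt = 18 °C,
T_max = 31.5 °C, K_I = 20 μmol photons m⁻² s⁻¹, λ20 = 0.16 % per light
hour, K_a = 0.15 m² gDW⁻¹, PAR = 0.43, V_cage = 1.785 m³, illuminated area
2 m², Q_p = 460 l h⁻¹ (≈11 m³ day⁻¹), 14-day harvest cycles, stocking
1 kg FW m⁻³ (0.15 gDW l⁻¹ at the 0.15 gDW/gFW dry-matter fraction, a
config default).

Constants not pinned by that calibration were fixed once from
literature-typical *Ulva* values and kept: μ_max = 0.025 h⁻¹, n = 2,
θ = 1.05, quota bounds 1.0/5.5 % gN gDW⁻¹ (subsistence/storage),
V_max = 80 μmol-N gDW⁻¹ h⁻¹ (reported *Ulva* N uptake spans roughly
20–200), K_S = 5 μM, K_0 = 0.4 m⁻¹ (coastal water), Z = V_cage/area
≈ 0.89 m. Together these place the model in the regime the reactor data
describe: ~10 gDW m⁻² day⁻¹ spring productivity, tissue N climbing from 2
to ~5 % within a cycle, and whole-farm ambient-N drawdown on the scale of
several hundred reactors.

Farm hydrodynamics: the stream flow defaults to
Q_s = velocity × narrow-side cross-section with a sluggish estuarine
current of 0.005 m s⁻¹ through a 1 m × Z section, ≈1.6·10⁴ l h⁻¹; both
factors are config. Dilution d (fraction of upstream ambient N lost to
mixing between consecutive cells) is a pure loss factor (1 − d) on the
advected concentration — the printed balance mixes in no replacement water.

## Numerical schemes

* **Reactor states** (m, N_int, N_ext): forward Euler at the model's native
  1-hour step. A fine-step reference (the same right-hand side at
  dt = 0.01 h, forcing frozen within the hour) exists purely as a test
  oracle; the hourly step tracks it to <1 % in final biomass over a 14-day
  cycle.
* **Ambient field N_env**: the two fluxes are operator-split each hour.
  The pump exchange is forward Euler with start-of-step values — the exact
  mirror of the cage-side exchange term, so the nitrogen swapped between
  cage and environment cancels identically and total N in a closed
  reactor–environment pair is conserved up to the O(dt) Euler error of the
  biology (≈0.3 % of the pool over 48 h at dt = 1 h, shrinking linearly
  with dt). The stream advection is stiff — a cell is flushed
  Q_s/V_cage ≈ 9 times per hour — so it is solved per cell with the exact
  integrating factor over sub-steps chosen to keep the sub-step Courant
  number ≤ 1, with upstream neighbours frozen per sub-step
  (upstream-to-downstream information then travels at the physical
  advection speed; a single frozen-neighbour update per hour would cap it
  at one cell per hour and spuriously decouple farms longer than a few
  hundred cells from their inflow within a cycle).
* **Clamping**: Euler overshoot at the quota bounds or at zero
  concentration is clamped (and logged), not raised — overshoot near
  saturation is an expected discretization artefact.
* **Boundary condition**: Dirichlet inflow at x = 0, either a fixed
  concentration or the forcing's hourly upstream-N column.
* **Harvest**: every cycle resets all four state variables to the initial
  conditions in every reactor (no quota carry-over), matching an
  intensive harvest-and-restock operation.
* **Farm sizing**: the 10 μM criterion is evaluated on the final hour of
  the cycle at the most downstream reactor; the search doubles the reactor
  count, then bisects (the outlet concentration is monotone in count).
  A run whose ambient floor stays above the threshold raises an explicit
  "unreachable" signal rather than returning a count.

## Calibration

Step 1 estimates K_a by scanning a grid and minimizing RMSRE₁ between
final-biomass predictions driven by the in-situ light record (the
irradiance measured inside the reactor — used directly as the light the
thalli see) and by the ex-situ surface record (attenuated through the
extinction law at the candidate K_a). On simulator-generated experiments
this recovers the generating K_a exactly: the in-situ record of a return
generated with K_a* reproduces the ex-situ prediction only at K_a = K_a*.
Step 2 scans the growth parameters with K_a fixed, minimizing RMSRE₂
against measured final biomass.

RMSRE is implemented exactly as this model family defines it — the square
root of the **mean absolute relative error** (not squared); a `squared=`
switch provides the conventional form. Note the consequence: under 10 %
multiplicative measurement noise the metric's natural scale is
√0.08 ≈ 28 %, even at the true parameters.

The final selection replaces a manual choice with a deterministic rule:
keep combinations with every RMSRE < 15 % **and** every per-experiment
relative error < 20 % (both criteria prevent one well-fit experiment from
masking a poorly-fit one), then minimize the largest RMSRE, breaking ties
by lexicographic parameter order. An empty feasible set returns the
best-effort minimum flagged `criteria_met=False`. Scan sizes are properties
of the configured grids; the shipped default grids are kept small (tens to
low hundreds of combinations) so scans complete in seconds — production
use passes larger `ParameterGrid`s.

## Sensitivity analysis

Saltelli cross-sampling (blocks A, B, AB_i, BA_i; N·(2k+2) rows for k
parameters and base size N, scrambled Sobol' sequence, mandatory seed)
drives the farm model — one 14-day cycle per season on a 100-reactor farm —
and the Saltelli-2010 (S1) and Jansen (ST) estimators decompose the
variance of total biomass, total N removed and mean final ambient N.
Estimates are reported raw (small negative values are Monte-Carlo noise);
a clipped [0, 1] view is provided for summaries, and bootstrap over base
samples gives confidence half-widths. The estimators reproduce the
closed-form indices of a linear additive model and of the Ishigami
function to within 0.05 at N = 1024.

Parameter ranges are literature-plausible spans around the defaults; with
them, dilution d dominates the final ambient N (total index ≈0.7–0.97 —
it forces ambient attenuation regardless of biology), the light-related
parameters K_a and K_I carry most of the biomass variance, uptake kinetics
(V_max, K_S) are negligible in N-rich conditions, and temperature/salinity
parameters are inert in the simulated climate. The μ_max index is
range-sensitive: over a wide (5×) span it is large; a narrow span around
the calibrated value demotes it below K_a.

## Synthetic forcing: what it emulates, and what it does not

The generator produces a semi-arid Mediterranean annual cycle: water
temperature 15–29.5 °C (sinusoid through the 18 °C growth optimum in early
spring and late autumn and near the lethal bound in August), half-sine
diurnal light with 10–14 h day length and 1000–2000 μmol photons m⁻² s⁻¹
clear-sky noon peaks, constant 30 PSU, and seasonal upstream N presets of
350/250/150/300 μM (winter/spring/summer/autumn — richest after winter
rains, poorest in the dry season). Optional lognormal noise (seeded) stands
in for weather variability and sensor error.

It does **not** emulate: cloud sequences or storms, flood-driven salinity
drops and sandbar events, tidal or 2-D/3-D currents, grazing, sporulation
or biomass fragmentation, phosphorus (or carbon) limitation, or night
growth from stored photosynthate. Tests passing under synthetic forcing
therefore establish the internal consistency of the kinetics, the
integrators, the calibration machinery and the sensitivity estimators —
and the qualitative seasonal structure (spring maximum, summer collapse,
winter farms larger than spring farms, dilution cutting N sequestration
far more than production) — but not quantitative agreement with any
specific field site, which requires measured forcing and site-specific
initial conditions via `read_forcing_table` and the config file.

## Known limitations

* Nitrogen is the only modelled nutrient; in P-limited waters the model
  will overestimate growth.
* The loss term excludes grazing, sporulation and storm losses; realized
  yields will be lower in exposed sites.
* One row of reactors is simulated; multi-row farms are treated as
  replicates (no cross-row interaction).
* The compartment advection is first-order upwind in space by
  construction (each cage is one well-mixed cell); sharp spatial gradients
  are numerically diffused at the cell scale.
* Biomass production can be negative in summer cycles (losses exceed
  growth near T_max); summaries report it as computed.
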