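# Methods

This note records the model's scientific content, the choices made where
the formulation was genuinely open, the numerical scheme, and what the
synthetic-forcing tests do and do not demonstrate.

## Model structure

The simulator tracks the symbiont population of a single polyp as eleven
areal pools: structural biomass `CS` (mg N m⁻²); internal reserves `R_N`,
`R_C`, `R_P` whose maxima equal the structural equivalent of each element
(R_N^max = CS, R_C^max = CS·(106/16)·(12.01/14.01),
R_P^max = CS·(1/16)·(30.97/14.01)); pigments `Chl`, `X_p`
(diadinoxanthin), `X_h` (diatoxanthin); photosystem-II reaction-centre
pools `Q_ox`, `Q_red`, `Q_in`; and areal ROS.  Per-cell quantities divide
by cell density `CS/m_N`.  The host is represented only through the
two-layer gastrodermal packing constraint; host biomass, feeding and
host-side antioxidants are out of scope.

### Photon pathway

Downwelling PAR `E_d` (converted to mol photon m⁻² d⁻¹) crosses a pigment
bed with photochemical optical depth τ_pq = a_Chl·Chl + a_Xp·X_p and
photoprotective depth τ_h = a_Xh·X_h.  The bed absorbs
E_d·(1 − e^−(τ_pq+τ_h)).  The two absorber classes are treated as
optically mixed (*competitive* placement): diatoxanthin dissipates the
fraction τ_h/(τ_pq+τ_h) of the absorbed light as heat and the reaction
centres receive the rest (`k_I`).  The alternative *sequential* placement
(photochemical pigments first, diatoxanthin intercepting only transmitted
light) is selectable via `photophysiology.npq_optics`.  Competitive
placement is the default because it makes the xanthophyll switch a true
photoprotection: when stress drives the pool into diatoxanthin, the photon
flux reaching the reaction centres — and with it ROS production — falls.
Under sequential placement the switch has no effect on `k_I` at all, which
contradicts its biological role as non-photochemical quenching.

Absorbed photons land on reaction-centre states in proportion to the
normalised state fractions.  A hit on an oxidised centre fixes carbon with
probability a\*·(1 − R_C\*) — active RuBisCO and room in the carbon
reserve — and otherwise reduces the centre; a hit on a reduced centre
inhibits it; a hit on an inhibited centre produces ROS at stoichiometry
1/(m_RCII·m_P2R).  The four sinks sum to `k_I` identically (a tested
invariant).  RuBisCO activity follows the clamped exponential
a\*(ΔT) = (1 − e^−(2−ΔT))/(1 − e^−2) of the instantaneous temperature
anomaly against the MMM climatology (28.6 °C); repair of inhibited centres
is first-order with constant 268·m_RCII, the constant deriving from the
10 mol photon m⁻² d⁻¹ light level whose damage repair is assumed to match.
An optional multiplicative temperature factor on repair
(`repair_temp_factor`) defaults to the identity.

### ROS balance

Generation: (Q_in/Q_T)·k_I/m_RCII/m_P2R, all of it entering the pool
(no diffusion loss).  Detoxification (revised law): zero at or below half
the bleaching threshold θ = 1.42 × 10⁻¹⁴ mg O cell⁻¹, proportional to the
per-cell excess above θ/2 up to θ, and capped at
μ_CS^max·R_N\*·R_C\*·R_P\*·(θ/2)·(CS/m_N) above it — continuous at both
breakpoints.  The legacy proportional law
μ_CS^max·R_N\*·R_C\*·R_P\*·[ROS], which lets ROS decay to zero, is kept
behind `simulator.legacy_detox` for comparison.  ROS is stored areally;
the per-cell concentration is a diagnostic.  Growth therefore dilutes
per-cell ROS, while expulsion — which removes the same fraction of every
areal pool — leaves it unchanged, as it must if expelled cells carry their
contents with them.

### Population dynamics

Growth μ = μ_CS^max·R_N\*·R_C\*·R_P\*, damped by the smooth packing factor
max(0, 1 − (layers/2)⁴) where layers = (CS/m_N)·π·r_cell².  Building
structure consumes reserves at the Redfield ratio; because the reserve
maxima scale with CS, normalised reserves dilute automatically on
division (the discrete 2→3-cell bookkeeping leaves each normalised
reserve at 1/3 from a full start).  Nutrient uptake is diffusion-limited:
linear in ambient concentration (µmol l⁻¹ converted to mg element m⁻³)
and in cell density, shut off as the reserve fills.  Carbon enters only
through fixation, `fix_yield` mg C per mol photon routed to fixation.
Chlorophyll synthesis follows the incremental-benefit rule
`chl_synth_rate`·CS·(1 − R_C\*)·(1 − Q_in\*)·e^−τ; new xanthophyll
accompanies it at the fixed total-xanthophyll:Chl mass ratio 0.2448
(entering X_p), and new reaction centres enter the oxidised pool at the
Q_T:Chl ratio implied by the initial conditions, keeping the photosystem
scale-consistent as the population grows.  Expulsion is zero at or below
θ and rises as `expulsion_gain`·μ_CS^max·([ROS] − θ)/θ above it.

## Parameters

Printed constants (tests assert these exactly): m_P2R = 3500 (legacy
7000) mol photon (mg O₂)⁻¹; θ = 1.42 × 10⁻¹⁴ mg O cell⁻¹; MMM = 28.6 °C;
repair constant 268; the Redfield reserve ratios; initial conditions
CS = 1 mg N m⁻², reserves at half maximum, Chl = CS·5.6786/30,
X_p : X_h = 33 : 67 of 0.2448·Chl, Q_ox/Q_red/Q_in =
1.0607 × 10⁻⁷ / 7.1695 × 10⁻⁹ / 1.0108 × 10⁻⁷ mg m⁻², per-cell ROS at θ/2.

Calibrated constants (tagged `[calibrated]` in `params.py`; derived once
with `scripts/calibrate.py` against the published scenario summaries —
ambient biomass ~3-fold and Chl ~2-fold in 23 d with a sub-threshold
mid-run ROS peak relaxing to ~1.03 × 10⁻¹⁴; heat-unshaded onset ~14.5 d
with 1.8-fold growth to day 14.5; heat-shaded reaching ~1.34 × 10⁻¹⁴
without crossing; shading lowering the ambient ROS peak by
~0.3–0.5 × 10⁻¹⁴):

| parameter | value | units | role |
|---|---|---|---|
| μ_CS^max | 0.085 | d⁻¹ | maximum growth (and detox) rate |
| m_N | 4.78 × 10⁻¹⁰ | mg N cell⁻¹ | structural N per cell (≈0.5 pg) |
| m_RCII | 233 | mol photon (mol RC)⁻¹ | photons per RC state change |
| a_Chl | 8.5 | m² (mg Chl)⁻¹ | photochemical absorption |
| a_Xp | 4.2 | m² (mg X_p)⁻¹ | diadinoxanthin absorption |
| a_Xh | 21.5 | m² (mg X_h)⁻¹ | NPQ absorption strength |
| fix_yield | 1.21 | mg C (mol photon)⁻¹ | carbon fixation yield |
| chl_synth_rate | 0.086 | mg Chl (mg N)⁻¹ d⁻¹ | pigment synthesis scale |
| xanth_switch_rate | 15 | d⁻¹ | xanthophyll interconversion (~1.5 h) |
| uptake_N, uptake_P | 3.8 / 4.1 × 10⁻¹¹ | m³ cell⁻¹ d⁻¹ | mass-transfer coefficients |
| expulsion_gain | 1 | — | expulsion slope above θ |

With these values the ambient scenario holds internal N and P reserves
near 0.97–0.99 and carbon limited (R_C\* fluctuating below ~0.5), the
daytime quasi-steady reaction-centre distribution shifts from oxidised at
dawn to inhibited at noon, and photochemistry re-equilibrates within the
3-day spin-up window.

## Forcing generator

Temperature: constant 26.4 °C (ambient) or a linear ramp at
0.443 °C d⁻¹ — the endpoint-consistent rate, chosen so the hold at
32.6 °C begins exactly at day 14 — followed by the 9-day hold.  An
optional AR(1) jitter is off by default, so the nominal ambient series
accumulates no DHW (the real tanks briefly exceeded the MMM; a
fluctuating-ambient preset is deliberately not shipped).  Light: a 12-h
truncated sinusoid peaking at 818 µmol photon m⁻² s⁻¹ at solar noon,
scaled per day by lognormal cloudiness multipliers whose mean and spread
target a DLI of 7.21 ± 2.99 mol photon m⁻² d⁻¹; the multipliers are
rescaled so the realised 23-day sample-mean DLI equals the target exactly
for every seed (the sd remains approximate), which keeps the total photon
dose — the dominant driver — identical across seeds.  Shade multiplies
every PAR value by 0.70, so shaded equals 0.70 × unshaded bitwise under a
shared seed.  Nutrients: truncated-normal draws every 2 days, held
constant between draws.  DHW at time t sums daily-mean anomalies of at
least 1 °C above the MMM over the completed days of the trailing 12
weeks, divided by 7 (°C-weeks).  One scenario seed derives separate
light and nutrient streams, so treatments share weather when intended.

The generator emulates the *statistics* of the tank experiment, not its
logged series: it has no multi-day weather autocorrelation, no within-day
cloud structure, no temperature excursions in the ambient treatment and a
perfectly flat hold.  Consequently scenario-level results reproduce the
published summaries only to synthetic-forcing accuracy.  In particular
the bleaching-onset day responds to which days happen to be bright while
per-cell ROS sits near the threshold: across weather seeds it moves by
roughly ±2–3 days around day 14–15, and the nominal heat profile
accumulates ~7.6 DHW where the logged tanks, which approached 32.6 °C
more gradually, accumulated 4.4.  Passing scenario tests therefore show
that the process model plus realistic forcing statistics reproduce the
experiment's qualitative structure and quantitative summaries at 10–20 %
tolerances — not that the simulator retraces the measured trajectories.

## Numerics

Operator splitting at a fixed step (default 1 min; output every 15 min).
The reaction-centre subsystem is linear in (Q_ox, Q_red, Q_in) once its
drivers are frozen over a step, and stiff by construction — the repair
constant 268·m_RCII and the photon-driven transition constants
k_I/(m_RCII·Q_T) are both thousands of d⁻¹ for any m_RCII consistent with
the repair-balance reading above, since Q_T ~ 10⁻⁷ mg m⁻².  It is
therefore advanced with the exact 3 × 3 matrix exponential
(eigendecomposition, with a scaling-and-squaring fallback and a scalar
closed form in the dark), which is unconditionally stable, reproduces the
pure-repair closed form to machine precision at any step, and relaxes the
fractions to their light-dependent quasi-steady state within a step —
exactly the physical regime.  The slow pools use explicit Euler with
donor-controlled flux limiting: any pool that would cross zero is clamped
(reserves also capped at their maxima) and the event is counted and
reported on the trajectory (`flux_limit_events`), flux limiting being the
most likely silent-error source.  Halving the step changes 23-day
endpoints by well under 0.1 %.  Bleaching onset is the linearly
interpolated first crossing of per-cell ROS above θ.  Runs are
deterministic given the forcing and configuration; a trajectory's sidecar
metadata (resolved configuration plus scenario seed) reproduces it
bitwise.

## Design choices where the formulation was open

* **ROS bookkeeping** is areal; per-cell ROS is areal ROS over cell
  density.  This makes generation (areal), detoxification (per-cell
  excess × density) and the dilution/expulsion phenomenology mutually
  consistent.
* **NPQ optics** default to competitive placement (rationale above).
* **m_RCII** is not printed anywhere; it is a first-class calibrated
  parameter.  Its calibrated value (233) puts the repair-balance flux
  268·m_RCII²·Q_T near the observed mid-morning absorbed flux, so the
  inhibited fraction tracks the diel light cycle rather than saturating
  at dawn.
* **Expulsion law**: only threshold-gated positivity is specified; the
  proportional-excess form with a μ_CS^max scale is dimensionally
  consistent, zero at threshold and configurable.
* **Area cap smoothing** uses a quartic factor; any steep monotone cap
  would do, and at the simulated densities (≤0.2 layers) it never binds.
* **Reaction-centre biosynthesis** is tied to chlorophyll at the initial
  Q_T:Chl ratio; nothing else in the formulation grows the photosystem.
* **ΔT for RuBisCO** uses the instantaneous forcing temperature; DHW uses
  daily means.

## Known limitations

* Scenario-level agreement is statistical, not trajectory-level (above);
  onset timing carries a ±2–3 day weather sensitivity.
* The heat-shaded treatment ends within a few percent of the bleaching
  threshold; under unlucky synthetic weather it can cross late in the
  run, unlike the published (logged-forcing) run.
* The discrete-division worked example yields 1/3 residual normalised
  reserves for *every* element; the element-asymmetric residual sometimes
  quoted for phosphorus (1/6) is not reproducible from this stoichiometry,
  in which consumption and reserve maxima are both Redfield-proportional.
* Oligotrophic nutrient regimes, host-side ROS handling, ROS speciation,
  PAM-fluorometry observables (F_v/F_m, E_k, rETR^MAX, α) and spatial or
  multi-colony coupling are out of scope.
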