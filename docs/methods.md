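# Methods

This note documents the model equations as implemented, the default
parameter set, the design of the synthetic forcing scenarios, and the
numerical choices — including the decisions taken where the design was
genuinely open.

## State and versions

The pelagic ecosystem is described by five compartments and 12 or 17
state variables (µmol L⁻¹; chlorophyll-a in µg L⁻¹):

| # | Variable | Meaning |
|---|----------|---------|
| 1–3 | Cb, Nb, Chla | phytoplankton carbon, nitrogen, chlorophyll-a |
| 4–5 | Cba, Nba | bacterial carbon, nitrogen |
| 6–7 | DPOC, DPON | detrital particulate organic C, N |
| 8–9 | LDOC, LDON | labile dissolved organic C, N |
| 10–12 | NO3, NH4, O | nitrate, ammonium, oxygen |
| 13–17 | Pb, Pba, DPOP, LDOP, PO4 | the phosphorus cycle (P version only) |

The `noP` version integrates variables 1–12; the `P` version all 17.
The P cycle is built in strict structural parallel to the N cycle, so
that with phosphorus held saturating the P version collapses exactly
onto the `noP` version (verified to machine precision by the test
suite; see "Phosphorus-saturated limit" below).

There is no DIC pool: carbon enters by gross primary production and
leaves by respiration, and the carbon budget is checked against those
accumulated fluxes rather than against a closed total. Internal time is
days; rates are d⁻¹.

## Phytoplankton

A single functional group parameterized as diatoms, with Droop-type
internal quotas Q_N = Nb/Cb, Q_P = Pb/Cb and a dynamic chlorophyll-to-
carbon ratio θ = Chla/Cb.

* Limitation: lim_X = clamp((Q_X − Q_X_min)/(Q_X_max − Q_X_min), 0, 1),
  Q\* = min(lim_N, lim_P) (lim_P ≡ 1 under `noP`). Ties in the
  limiting-element report go to N so outputs are deterministic.
* Carbon fixation: GPP = Cb · P^C_m · Q\* ·
  (1 − exp(−α_chl·θ·E/(P^C_m·Q\*))). The Q\*→0 limit (zero flux) is
  taken explicitly; the E→∞ limit is Cb·P^C_m·Q\*.
* Uptake: V = Cb · V_max · S/(S+K) · clamp((Q_max−Q)/(Q_max−Q_min)),
  i.e. Michaelis–Menten down-regulated to zero at a full quota.
  Ammonium inhibition of nitrate uptake is available
  (`phyto.nh4_inhibition`) but off by default.
* Chlorophyll: synthesis = Q\* · ρ_chl · (NO3- plus NH4-uptake), with
  ρ_chl = θ^N_max·P^C/(α_chl·θ·E) capped at θ^N_max (the dark limit).
  Scaling by Q\* extends the classical N-driven regulation so that
  phosphorus starvation also suppresses pigment synthesis — at equal
  nitrogen assimilation, the equilibrium θ scales like √Q\*.
  Non-grazing chlorophyll losses mirror the linear carbon losses at the
  same specific rate, so they leave θ unchanged by themselves.
* Linear losses on Cb: respiration (0.05 d⁻¹, a carbon sink consuming
  oxygen), exudation to LDOC (0.05 d⁻¹, carbon only), mortality to
  detritus (0.05 d⁻¹, element-parallel: Cb→DPOC, Nb→DPON, Pb→DPOP).

## Heterotrophic bacteria

Bacteria carry C, N and P biomass. Their quotas are Q_N^BA = Nba/Cba,
Q_P^BA = Pba/Cba and — a design decision, since no published definition
was available for the carbon quota — Q_C^BA = Cba/Nba, the cell C:N
ratio, which is low precisely when the cell is carbon(energy)-starved.
One ratio thus encodes the C-vs-N competition from both sides, and all
three elements compete in the same formal frame.

* Stress ratios r_X = Q_X_min/Q_X rise to 1 as element X runs out.
  The limiting element is the argmax of r_X (ties broken C→N→P).
* Production limitation: f = min over elements of
  clamp((1 − r_X)/(1 − r_X_sat)) with r_X_sat = Q_X_min/Q_X_max, so
  f = 1 for a replete cell and f = 0 when any quota is at its minimum.
  Bacterial production BP = Cba·µ^BA_max·f, hard-capped by Cba·µ^BA_max.
* Uptake of LDOC/DPOC (regulated by the C quota), LDON/DPON/NH4 (N
  quota) and LDOP/DPOP/PO4 (P quota) is Michaelis–Menten with quota
  satiation, so inorganic nutrients are only drawn to correct a
  stoichiometric deficit. Detrital consumption uses a single effective
  hydrolysis-plus-uptake rate (no separate hydrolysate pool).
* Respiration = basal (0.05 d⁻¹·Cba) + growth-linked (BP·(1−GE)/GE,
  GE = 0.3) + carbon-overflow (excess C:N respired at `adj_rate`).
  Quotas above their maxima are vented: N to NH4, P to PO4
  (bacterial remineralization), at `adj_rate` = 1 d⁻¹.

## Closure, remineralization, oxygen

Zooplankton and higher trophic levels are implicit: grazing is an
explicit loss g·f(T)·prey applied to phytoplankton and bacteria, with
f(T) = min(1, Q10^((T−T_ref)/10)), Q10 = 2, T_ref = 24 °C — grazing
pressure is halved at 14 °C, reproducing the weak winter / strong
summer grazing seasonality. A Holling-II saturating response is
available (`closure.holling_K`) but the default is linear. Every prey
constituent is removed at the same specific rate, so grazed fluxes
follow prey stoichiometry exactly and chlorophyll is removed in
proportion to phytoplankton carbon.

Grazed matter is redistributed per element by fixed fractions — POM
(egestion), DOM (sloppy feeding), DIM (excretion to NH4/PO4; for
carbon, consumer respiration with stoichiometric O2 consumption). The
default split is equal thirds, config-overridable; by construction the
returned fluxes sum exactly to the grazed flux for every element.

First-order remineralization chains run element-parallel:
DPOC→LDOC→(CO2), DPON→LDON→NH4, DPOP→LDOP→PO4 (hydrolysis 0.05 d⁻¹;
DOM mineralization 0.05 d⁻¹ for N and P, 0.01 d⁻¹ for C), optionally
Q10-scaled with temperature (off by default). Nitrification NH4→NO3 at
0.05 d⁻¹ is parameter-gated and may be zeroed. Oxygen follows the
stoichiometric sum +γ_OC·GPP − γ_OC·(all respiration) − γ_ON·nitrif
with γ_OC = 138/106 and γ_ON = 2.

## Default parameters

The exact parameter values of the source configuration were not
available, so the defaults are field-typical values for a
diatom-dominated NW-Mediterranean coastal system, fixed once and
recorded here (units: d⁻¹ for rates, mol:mol for quotas):

* Phytoplankton: P^C_m = 2.0; α_chl = 0.6 µmol C (µg Chl)⁻¹ (W m⁻²)⁻¹ d⁻¹
  (≈0.07 mg C (mg Chl)⁻¹ h⁻¹ per µE m⁻² s⁻¹); θ ∈ [0.012, 0.7]
  µg Chl (µmol C)⁻¹ (Chl:C mass ratio 0.001–0.06); θ^N_max = 2.5
  µg Chl (µmol N)⁻¹; Q_N ∈ [0.05, 0.20], Q_P ∈ [0.002, 0.0125]
  (optimal N:P = 16 at full quotas); V_max(NO3) = V_max(NH4) = 0.5
  mol N (mol C)⁻¹ d⁻¹ (K = 0.5, 0.3 µM); V_max(PO4) = 0.15
  mol P (mol C)⁻¹ d⁻¹ (K = 0.05 µM) — several-fold the maximal P
  demand, reflecting the surge/luxury phosphate uptake characteristic
  of P-starved phytoplankton.
* Bacteria: µ^BA_max = 2.0; GE = 0.3; Q_C^BA ∈ [4, 8] (C:N),
  Q_N^BA ∈ [0.125, 0.25], Q_P^BA ∈ [0.005, 0.02]; uptake V_max 4.0
  (LDOC), 0.5 (DPOC), 0.6 (LDON), 0.1 (DPON), 0.3 (NH4), 0.05 (LDOP),
  0.01 (DPOP), 0.02 (PO4).
* Optics: k_w = 0.04 m⁻¹, k_chl = 0.03 m⁻¹ (µg Chl L⁻¹)⁻¹, so
  k(z) = k_w + k_chl·Chla(z), the chlorophyll–light feedback the column
  mode exercises.

Parameter sets serialize to a flat dotted-key YAML (`phyto.PCm: 2.0`,
one key per constant) via `ParameterSet.to_yaml`/`from_yaml`.

Initial-condition presets: `oligotrophic-summer` matches the observed
summer surface means of the study area (Chla 0.4 µg L⁻¹, PO4 0.03
µmol L⁻¹, DIN 1 µmol L⁻¹); `winter-mixed` is the nutrient-replete mixed
winter column (NO3 2.5, PO4 0.12 µmol L⁻¹).

## Forcing construction

Riverine organic matter enters only as its labile share: LDOC = 0.20
DOC, LDON = 0.20 DON, LDOP = 0.88 DOP, DPOC = 0.18 POC, DPOP = 0.88
POP. For particulate nitrogen two published readings exist; the default
is DPON = 0.20 PON (the element-parallel reading), with
`LabilityRules(pon_basis="poc")` implementing the alternative tabulated
reading DPON = 0.20 POC. Re-applying the rules to already-labile inputs
is an error, never a silent re-scaling.

The main-river loader scales gauged discharge by 0.90 (the share
carried by the branch inside the domain); the lagoon channel is a
constant source (20 m³ s⁻¹, fixed concentrations); the sewage outfall
uses measured daily NO3/NH4 with PO4 fixed at 13.4 µmol L⁻¹ and
constant organics; small urban rivers borrow the main river's daily
nutrient concentrations and use constant organics. Urban particulate
loads that were originally tied to discharge by an unpublished relation
load as zero with a warning. Plankton variables are zero in every
terrestrial input.

Dry atmospheric deposition is spread as a mean flux between consecutive
sample dates (integrated mass is conserved exactly); wet deposition is
concentration × rainfall (1 mm at 1 µmol L⁻¹ = 1 µmol m⁻²). Units must
be declared explicitly by the caller. Surface fluxes convert to
concentration tendencies by dilution over a caller-chosen mixed-layer
depth — the box-model stand-in for a 3-D grid, and a documented
convention rather than a physical result.

## Synthetic scenarios

`synthetic_forcing(seed, duration, scenario)` generates daily forcing
emulating the regional seasonal cycle:

* `seasonal` — sinusoidal temperature 13–25 °C (coldest mid-February),
  daily-mean PAR 20–120 W m⁻², winter-intensified dilution (0.005–0.105
  d⁻¹) against a deep reservoir (NO3 3, PO4 0.25, NH4 0.1 µmol L⁻¹ —
  N:P = 12, below the phytoplankton optimal ratio, consistent with
  nitrogen-limiting sub-surface water), small seeded weather noise, and
  a chronic terrestrial background load with NO3:PO4 = 72 (inside the
  65–80 band of the river source) that makes the surface layer
  phosphorus-limited outside mixing periods, as observed.
* `upwelling_pulse` — summer episodes (5 days) of 5 °C cooling plus
  strong entrainment (0.3 d⁻¹) of the deep reservoir.
* `rhone_intrusion` — summer episodes (4 days) of freshening (−4
  salinity) with boundary inputs at an NO3:PO4 ratio drawn uniformly in
  [65, 80].

Scenarios are bitwise reproducible per seed. The generator emulates the
*structure* of the regional forcing — seasonal amplitude, event timing
and stoichiometry — not its day-to-day meteorology, horizontal
gradients, or the co-variability of light, wind and river discharge.
Passing tests therefore demonstrate the model's mechanistic responses
(bloom phenology, P-damping of high-N:P events, the N-limitation switch
under upwelling) under controlled conditions; they do not validate the
model against field observations, which requires the full 3-D transport
this package deliberately omits.

## Numerics

* **Integration**: forward Euler at dt = 20 min (the operational SMS
  cadence), daily saving by default. The scheme is first-order;
  dt-halving against a dt/8 reference verifies the error decay.
* **Positivity by flux limiting**: the SMS is assembled as a ledger of
  (source pool → destination pool) transfers. If the sinks of a pool
  would drive it below zero within a step, *all* its outgoing transfers
  are scaled by the same factor — donors and recipients stay
  consistent, so the limiter preserves element conservation exactly,
  unlike clipping. Closed-box N and P drift is at rounding level
  (~1e-14 relative) over 5 years.
* **Quota degeneracy**: below a biomass floor of 1e-8 µmol C L⁻¹ quotas
  are undefined; the standalone quota operation raises a
  degenerate-state error naming the pool, while the integrator freezes
  quotas at their last valid value (all quota-scaled fluxes vanish with
  the biomass, so the frozen value is inert). A never-alive pool uses
  the inert mid-range quota set.
* **θ bounds**: chlorophyll is prognostic; after each accepted step it
  is clamped into [θ_min·Cb, θ_max·Cb]. The clamp touches only the
  pigment (not element-conserved) and is inactive in resolved regimes.
* **Column mode**: fixed z-levels, explicit conservative flux-form
  diffusion with a CFL check (dt·K/Δz² ≤ 0.5, rejected with a
  diagnostic otherwise), per-level irradiance from the cumulative
  chlorophyll-dependent optical depth evaluated at level centres.
  Sigma coordinates and advection are out of scope.
* **Phosphorus-saturated limit**: `BoxConfig(pin_P_quotas=True)` pins
  the P quotas at their maxima and holds PO4 at its initial value,
  realizing the saturated limit exactly; the P version then reproduces
  the `noP` trajectories bitwise. Without pinning, finite uptake
  kinetics keep the P quota marginally below its maximum, which is the
  physically expected (but not exactly degenerate) behaviour.
* **Statistics**: sample (n−1) standard deviations throughout
  (switchable); OSPAR bins closed on the right ([0,1] very good,
  (1,2] good, (2,3] reasonable, >3 poor); the target-diagram identity
  Bias*² + uRMSD*² = (RMSD/σ_O)² is asserted inside `skill_report`.
  Percentage bias is computed on raw pairs, not monthly means.

## Known limitations

* Single phytoplankton group; no silica cycle despite the
  diatom parameterization; no carbonate system.
* No explicit higher trophic levels, fecal-pellet sinking or vertical
  particle flux; losses other than grazing are lumped linear terms.
* The exponential (non-photoinhibited) saturating P–E curve is the only
  light response shipped; the limitation and bacterial co-limitation
  forms are single implementations of a pluggable design.
* Box/column delivery of boundary mass depends on a prescribed volume
  or mixed-layer depth; absolute concentrations in forced runs carry
  that convention.
* Euler + flux limiting degrades to below first order exactly at
  pool-exhaustion events (the limiter is a projection); conservation is
  unaffected.
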