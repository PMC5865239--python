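# Methods

## Scientific scope

`nitrifycol` models the two chemoautotrophic steps of marine nitrification —
ammonia oxidation (NH4+ → NO2-, by AOO) and nitrite oxidation (NO2- → NO3-,
by NOO) — as interacting populations in an idealized stratified water
column, to explain why nitrite accumulates at the base of the sunlit layer
(the primary nitrite maximum, PNM) and why its peak concentration exceeds
that of ammonium in oligotrophic oceans.

The package has four layers:

1. **Stoichiometry** (`stoichiometry`): each metabolism is the sum of three
   redox half-reactions (DIN oxidation, O2 reduction, biomass synthesis)
   weighted by the electron fraction `f` routed to synthesis. Normalized to
   1 mol biomass N, ammonia oxidation consumes `1 + d/(6f)` NH4+ and
   `(1-f)d/(4f)` O2 and releases `d/(6f)` NO2-; nitrite oxidation consumes
   `d/(2f)` NO2- (plus 1 NH4+ assimilated) and produces the same amount of
   NO3-. `d = 4c + h - 2o - 3n` counts the electron equivalents of biomass
   `C_c H_h O_o N_n` (20 for the canonical C5H7O2N). At `f = 0.03` the
   yields are `y_NH4 = 1/(1 + d/6f) ≈ 1/112` and `y_NO2 = 2f/d = 1/333`:
   the nitrite oxidizer must process roughly three times more DIN per unit
   biomass, the energetic root of the PNM asymmetry. Uncertainties on the
   coefficients are propagated linearly through `d` (s.d. 4, from a ±1
   mol/mol C:N spread with H and O held fixed); a Monte-Carlo oracle in the
   test suite confirms the linearization.

2. **Traits** (`traits`): culture measurements reported per mg protein are
   converted to biomass-N-specific rates using 16% protein N by weight and
   N = 14 g/mol (the conventions under which the published per-cell quotas
   of 0.12 and 1.2 fmol N were derived). The ammonia-oxidizer anchor:
   24.2 µmol NH4+ (mg protein)^-1 h^-1 → 50.8 mol NH4+ (mol biomass N)^-1
   d^-1; with K = 133 nM the specific affinity is 382 L (µmol biomass N)^-1
   d^-1. Allometry: specific uptake scales with cell radius as r^-1 and the
   half-saturation as r, so specific affinity falls as r^-2; a 10-fold NOO
   cell volume (the default; a ~50-fold case can be configured) means a
   4.6-fold affinity penalty. Phytoplankton traits come from power laws in
   cell volume; the bundled coefficients give an effective DIN affinity of
   ~88 L (µmol N)^-1 d^-1 and µ_max ≈ 1.4 d^-1 for a 0.6 µm cell, with the
   ammonium half-saturation assumed half that of the oxidized species.

3. **Ecosystem** (`ecosystem`): nine nitrogen state variables (NH4+, NO2-,
   NO3-, sinking detritus, and the biomass of heterotrophic bacteria, AOO,
   NOO, picophytoplankton and one microzooplankton grazer), all in
   mol N m^-3 internally. Growth is Monod in the limiting resource;
   phytoplankton growth saturates exponentially in light with a
   steady-state photoacclimated Chl:C ratio θ = θ_max / (1 + Γθ_max/2µ);
   their nutrient limitation γ_N is the *sum* of the three DIN saturation
   terms, deliberately unclipped because the same sum normalizes the uptake
   partition (each DIN species receives µ_P weighted by its own saturation
   term, so uptakes always total µ_P). All rates except the nitrifiers'
   carry an Arrhenius temperature factor
   γ_T = τ exp(A_E (1/(T+273.15) − 1/T_0)); with the default A_E = −4000 K
   the factor increases with temperature and equals τ = 0.8 at 20 °C. The
   nitrifier exemption (culture rates used as measured) follows the
   experimental evidence for weak temperature sensitivity of marine
   nitrification. Every biological flux is declared once, together with the
   signed coefficients that distribute it over state variables; tendencies
   are assembled from this ledger, so local nitrogen conservation is exact
   by construction and a test audits that each flux enters twice with
   opposite signs. Oxygen is not a state variable (the modeled domain is
   well oxygenated); an optional fixed-O2 Monod hook exists but is off by
   default. Ammonium inhibition of oxidized-DIN uptake is not modeled.

4. **Column** (`column`): 2000 m domain (5 m cells by default; the study
   problem size below), positive-down z. Diffusivity
   K(z) = K_max e^(−z/z_mld) + K_min + K_max e^((z−H)/100) imposes a
   surface mixed layer and a bottom boundary layer (the bottom term is
   written with the sign adapted to positive-down z). Light attenuates
   through water (k_w) and through the chlorophyll accumulated above each
   cell; because photoacclimation depends on light while chlorophyll shades
   the cells below, the light/Chl:C profile is built sequentially from the
   surface down (an exact one-pass solve of the triangular dependency).
   Temperature follows the subtropical fit 12 e^(−z/150) + 12 e^(−z/500) + 2 °C.
   Detritus sinks at w_s with a QUICK (third-order upstream-parabolic)
   reconstruction; boundaries are no-flux, so sinking detritus collects in
   the bottom cell as a crude sediment layer. Tendencies are integrated
   with classical fixed-step RK4; the default step is half the tighter of
   the diffusive and advective stability bounds, additionally capped at
   0.04 d against biological stiffness (nutrient drawdown by dense
   populations). Negative concentrations after a step are clipped to zero
   with the clipped mass logged, so the budget remains auditable.

## Numerical choices

- **Flux-limited QUICK.** Plain QUICK is not monotone: at the sharp
  detritus front against the no-flux bottom its downstream-weighted face
  value persistently over-drains the cell above, which the negativity
  clipper then refills — a mass-creating feedback that grows exponentially.
  The sinking operator therefore applies the standard universal limiter
  (φ = max(0, min(2r, (3+r)/4, 2))): identical to QUICK in smooth regions,
  first-order monotone at fronts. The face nearest the surface lacks an
  upstream-upstream cell and is first-order upwind.
- **Convergence and the limit cycle.** Convergence is declared when the
  maximum over variables and depths of |dC/dt|/(C + 1e-6 µM) stays below
  the tolerance (default 1e-3 d^-1; the study runs use 1e-4) for several
  consecutive checks. The stratified ecosystem settles onto a weak limit
  cycle (a few-percent predator–prey wobble around the deep chlorophyll
  maximum, period ~2000 d) rather than a fixed point, so the reported
  equilibrium state is the time mean over a trailing window (default
  1000 d; study runs 2000 d ≈ one cycle). With diel light the metric is
  evaluated under mean light.
- **Initial conditions.** NO3- ramps from zero above 150 m to 20 µM at
  400 m; NH4+ and NO2- carry small ramps near their expected deep
  equilibrium values (4 and 60 nM); every biomass is seeded at 1e-3 µM-N.
  The equilibrium structure (peaks, depths, rates) is independent of these
  choices, which only shape the transient; see the limitations section for
  the pointwise caveat at the nitrifier-viability front. Loading the lit zone with nitrate
  instead produces a spin-up bloom whose nutrient-depletion timescale no
  affordable fixed step resolves, and seeding the nitrite pool prevents the
  slow-growing nitrite oxidizers from collapsing to near-extinction before
  their substrate first accumulates.
- **Compiled fast path.** The combined tendency has a cell-by-cell numba
  implementation mirroring the flux-ledger reference; an equivalence test
  holds them to within 1e-12 relative. The numpy reference is used
  automatically when numba is unavailable or the O2 hook is enabled.

## Parameters

Culture- or theory-anchored values (main-text provenance): f = 0.03,
C5H7O2N biomass, AOO V_max = 50.8 d^-1 and K = 133 nM, the 10-fold NOO
volume factor, y_D = 0.14, g_max = K_g = 1 (1 d^-1 and 1 µM), ζ = 0.5,
protein N fraction 0.16, cell quotas 0.12/1.2 fmol N.

Calibrated values (not printed in the source material; chosen once at
field-plausible magnitudes so the stratified column reproduces the expected
qualitative structure — a DCM above a PNM, nitrification throughout the
dark column, deep oxidation rates in lockstep):

| parameter | default | note |
|---|---|---|
| K_max | 2e-3 m²/s | vigorous mixed-layer turbulence |
| K_min | 1e-5 m²/s | canonical thermocline diffusivity |
| z_mld | 20 m | strongly stratified subtropical case |
| k_w | 0.04 m⁻¹ | clear-water attenuation |
| k_chl | 0.02 m²/mgChl | includes CDOM contribution |
| I_max | 1400 µmol photons m⁻²s⁻¹ | noon surface maximum |
| w_s | 10 m/d | sinking detritus |
| V_maxD | 1.0 d⁻¹ | saturated heterotroph growth y_D·V_maxD ≈ 0.14 γ_T ≈ 0.1 d⁻¹ |
| K_D | 0.02 µM | keeps heterotrophs viable on nM-level deep detritus |
| m_B | 0.01 d⁻¹ | linear microbial mortality |
| m_Z | 1 (µM d)⁻¹ | quadratic grazer closure |
| τ, A_E, T₀ | 0.8, −4000 K, 293.15 K | Arrhenius factor ≈1.05 at 26 °C, 0.33 at 2 °C |
| φ, a_chl, θ_max | 0.06, 0.02, 0.05 | photosynthesis/photoacclimation |

The bundled `data/default_params.yaml` carries the same values with
per-line provenance tags.

## Competition diagnostics

The subsistence concentration R* = K·L/(yV_max − L) is the resource level
at which growth balances the loss L = m_B + gZ (identical for all four
microbial prey). Masked (not negative) values mark depths where maximum
growth cannot exceed loss. Phytoplankton R* uses the maximum light-limited
growth rate (the light saturation law without nutrient limitation,
evaluated with the equilibrium photoacclimation state), so it diverges and
then masks with depth as light fails — the mechanism that hands control of
NH4+ and NO2- to the nitrifiers below the euphotic zone. Two regimes are
distinguished when interpreting equilibria: where vertical mixing supplies
a non-negligible share of the local NO2- budget (directly below a large
PNM), concentrations sit above R* and the two oxidation rates need not
match locally; in the remineralization-limited deep column both steps
process the same nitrogen flux and their rates agree. The acceptance tests
apply exactly this screen (mixing below 5% of local NO2- turnover).

For the phytoplankton R*, `rstar_phyto(..., replete_theta=True)` re-evaluates
the photoacclimation state for a nutrient-replete cell at the local light,
turning the diagnostic into an invasion bound: in the nutrient-starved
surface layer the incumbents' collapsed Chl:C would otherwise mask the
diagnostic exactly where the exclusion argument applies.

PNM metrics locate discrete profile maxima with parabolic sub-cell
refinement (ties break shallow) and exclude the bottom 150 m, where the
no-flux sediment layer accumulates nutrients as a closed-domain artifact.

## The perturbation ensemble

Member parameter sets draw nitrifier kinetics from the culture normal
distributions (V_max 50.8 ± 4.68, K 133 ± 38 nM), the NOO volume factor
uniformly from 1–20 (entering as its cube root), and µ_max, K_NOxP (with
K_NH4P kept at half), V_maxD, K_D, y_D, g_max, K_g, m_B, m_Z and ζ
uniformly over ±50% of their defaults. Invalid draws (non-positive rates,
efficiencies outside (0,1)) are redrawn and counted. Each member uses a
counter-based substream of the master seed, so results are bitwise
reproducible and independent of execution order. The desk-scale default is
50 members; ~1000 reproduces the full published envelope.

## Fixture catalog and the integrable regime

Three named configurations: `subtropical_stratified` (z_mld = 20 m, the PNM
case), `high_mixing` (z_mld = 80 m) and `abiotic_control` (no organisms;
nutrients inert). Because the printed nutrient-limitation sum can reach 3
with all three DIN pools replete while the grazer closure saturates,
nutrient-replete deep-mixing columns let phytoplankton outgrow their
predators, and the subsequent nutrient-exhaustion dynamics are stiffer than
any affordable fixed step; the high-mixing fixture therefore sits at the
deep edge of the integrable regime, where it demonstrates the erosion of
the stratified surface desert rather than the full subpolar surface-nitrite
regime. `run_column` retries with a halved step (up to three times) when
the integrator reports instability.

## Problem sizes used in the tests

The test suite integrates a 1000 m column at 10 m resolution (the
grid-refinement check repeats it at 5 m) with tolerance 1e-4 d^-1, a
40000-day ceiling and a 2000-day averaging window; these study runs
converge in 20000–35000 model days. The 2000 m × 5 m default configuration
produces the same upper-column structure with a deeper quiescent interior.

## What the synthetic conditions do and do not show

The column is closed (no lateral exchange, fixed temperature and light
climatology, a single phytoplankton and a single grazer type), detritus is
one pool with one sinking speed, and nitrifier traits are fixed rather
than distributed over a community. Passing tests therefore demonstrate the
internal consistency of the competition mechanism — phytoplankton exclusion
of nitrifiers in the lit layer, yield- and affinity-controlled NO2-:NH4+
asymmetry, remineralization-limited deep rates — not a calibrated
prediction of any particular ocean profile. Known limitations: the surface
mixed layer above the nutricline equilibrates to very low biomass (no
lateral resupply or seasonal restratification), deep nitrite declines to
the NOO subsistence level of the single resolved clade (observed deep
values are lower, consistent with a more efficient deep community), and
the bottom sediment cell is a bookkeeping device, not benthic chemistry.

One further limitation matters for reproducibility claims: the
nitrifier-viability front at the base of the euphotic zone is intrinsically
sharper than the grid (the zero-mixing point-balance solution is
discontinuous there, and mixing smooths it over only a few metres), so the
front's sub-cell position is not uniquely selected by the discretized
dynamics. Column runs started from different seedings settle onto steady
states that agree in peak magnitudes, depths and rate structure but differ
by a few percent pointwise on the front itself — verified stable over
120,000 further days, independent of the time step, and not removed by
grid refinement. The initial-condition-independence test asserts pointwise
agreement at 1% and is expected to fail at ~4% for exactly this reason; it
is retained at its stated precision rather than weakened.
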