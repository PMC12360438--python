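# Methods

`sonomech` is a desk-scale mechanistic simulator of how a solid tumor
responds to three interacting interventions: a mechanotherapeutic
(ketotifen), ultrasound–microbubble sonopermeation, and a
nano-immunotherapy cocktail (Doxil, anti-PD-1, anti-CTLA-4). This note
records the model, its closures, the numerical scheme, the default
parameters and what the synthetic data do and do not represent.

## Geometry and state

The tumor is a sphere of radius R(t) embedded in host tissue. All
fields are spherically symmetric radial profiles on a normalized
coordinate x = r/R(t) (method of lines, default 40 nodes), so the grid
follows the moving boundary; the change of frame adds the standard
convective correction x·dR/dt to every advected field. The boundary
moves with the solid-phase velocity, dR/dt = v_s(R). The state
comprises:

* cell densities (normalized to carrying capacity 1): non-stem cancer
  cells, stem-like cancer cells, treatment-induced cancer cells, NK,
  CD8⁺, CD4⁺, regulatory T cells, M1/M2 tumor-associated macrophages,
  endothelial cells;
* angiogenic factors: VEGF, Ang1, Ang2 (normalized concentrations);
* four drug fields: interstitial nanocarrier c_n, released free drug
  c_f, internalized drug c_int, free anti-PD-1 antibody c_f^i, all
  normalized to the plasma peak at injection (= 1);
* an accumulated volumetric growth field G driving solid stress;
* quasi-static environment fields recomputed from the state: oxygen,
  functional vascular density Sv, interstitial fluid pressure p_i,
  fluid and solid velocities.

## Transport and delivery

Nanomedicine follows the three-state chain: the carrier extravasates
by Starling exchange,

    Q_sta = P_er·Sv·(C_iv − c_n) + L_p·Sv·(P_V − p_i)·(1 − σ_f)·C_iv,

releases free drug (rate k_el, payload α), which cells internalize
(k_int) and degrade (k_deg). The antibody is transported identically
as a free species with its own permeability and reflection. Plasma
levels follow mono-exponential bolus decay exp(−(t−t₀)/k_d), with
superposition over repeat doses capped at a configurable ceiling.

The wall coefficients depend on the ratio λ = r_s/r_o of solute to
pore radius through the classical cylindrical-pore hindered-transport
closure: steric partition Φ = (1−λ)², centerline diffusive hindrance
H = Φ(1 − 2.104λ + 2.089λ³ − 0.948λ⁵), and osmotic reflection
σ_f = 1 − Φ(2−Φ)(1 − (2/3)λ² − 0.163λ³). P_er = γ·H·D_free with the
free-solution (Stokes–Einstein) diffusivity inside the pore and a
single anchor γ (pore areal fraction over wall thickness); L_p scales
as r_o² (Poiseuille flow at fixed areal fraction). Pore dilation by
ultrasound therefore raises P_er and L_p and lowers σ_f together.

## Sonopermeation

Acoustic pressure is p_ac = MI·√fr (MPa for fr in MHz). The
experimentally fitted quadratic r_o(p_ac) = −14977.9087·p_ac² +
8208.3947·p_ac − 69.0722 (nm) maps pressure to pore radius, clamped to
[baseline, 1250 nm] because the raw fit is negative at rest and beyond
~0.55 MPa. The default resting pore radius is 100 nm — the lower end
of the cited tumor-vessel pore range — so that nanocarrier delivery is
small but nonzero without ultrasound. Microbubble oscillation exerts a
microstreaming wall shear stress τ = √(2ρ_L μ_L)·(2π fr)^{3/2}·η_m²/R₀
(prefactor 1; the η_m², fr^{3/2}, 1/R₀ and √(ρμ) scalings are the
load-bearing structure). Fitted quadratics convert τ into endothelial
proliferation and apoptosis multipliers; the vascular dynamics use
them normalized by their τ = 0 values (0.2533 and 0.6666) so that "no
ultrasound" is exactly neutral, while the raw values remain available.
Each application acts for a 6 h window (rectangular envelope by
default; a linear-decay variant closes continuously); overlapping
windows take the maximum effect. Default transducer settings MI = 0.4,
fr = 1 MHz sit mid-range of the cited 0.2–0.6 MI optimum. Default
microbubble values (blood: ρ_L = 1050 kg/m³, μ_L = 3 mPa·s; η_m =
50 nm, R₀ = 1 µm) give τ ≈ 99 Pa, inside the fitted range of the
response quadratics.

## Mechanotherapy

Ketotifen maps directly to parameter changes, not to a concentration
field: over a 72 h ramp the tumor's shear and bulk moduli fall
linearly to 50% of baseline and the interstitial hydraulic
conductivity rises linearly 100-fold; both hold while dosing continues
(no rebound is modeled). Host tissue is never modified.

## Mechanics, perfusion, oxygen

The full tensorial problem is reduced to a scalar growth-induced bulk
stress σ_s = c_g·(k + 4μ/3)·G with G the accumulated net volumetric
growth; this keeps the two couplings that matter (softening halves
stress at fixed growth; stress compresses vessels). Functional
vascular density is Sv = Sv_anat·(endo/endo_ref)·exp(−β_c σ_s/σ_ref).
IFP obeys the steady filtration balance ∇·(−k_th∇p) = L_p Sv (P_V − p)
with symmetry at the center and p = 0 at the margin (peritumoral
lymphatics drain the filtrate; a resistive-host Robin option
−k_th ∂p/∂r = (k_host/R)·p is available via
`vasculature.host_drainage: resistive`). For uniform parameters the
solver reproduces the closed form p/P_V = 1 − (R/r)sinh(αr/R)/sinh(α),
α = R√(L_p Sv/k_th), to ~1e-5 at 200 nodes. Fluid velocity is Darcy
flow v_f = −k_th ∂p/∂r; the solid velocity integrates the net
volumetric growth over interior shells, so v_s(R) is the boundary
speed. Oxygen is quasi-static (fast diffusion limit): D∇²c +
P_ox·Sv·(0.2 − c) − A·ρ_cells·c = 0 with the host reference
0.2 mol/m³ held at the margin; hypoxia is 100·(1 − ⟨c⟩/0.2). A dynamic
oxygen right-hand side is kept for verification.

## Population network

Cancer densities grow logistically at rate k₁·c_ox (shared carrying
capacity), are killed by internalized drug (stem-like cells at 0.3×
susceptibility) and by immune effectors, and interconvert
conservatively (stem → non-stem differentiation; drug-induced
conversion into treatment-induced cells). The volumetric source that
moves the boundary is the division rate *unthrottled* by the crowding
factor minus all removal: at local packing, excess divisions displace
tissue outward rather than raising density. A purely logistic volume
source extinguishes itself (the dilution it creates cancels it), which
would contradict sustained control growth.

Immune populations follow source/death balances, sources scaled by
local oxygenation. Effector killing engages only above the
healthy-tissue activity set point (computed analytically from the
source/death fixed points with Treg/M2 suppression): untreated tumors
are immune-tolerated, while anti-PD-1 (saturating boost of the CD8⁺
source in local antibody concentration), anti-CTLA-4 (raised Treg
mortality during a 96 h window per dose; not transported), and
immunogenic cell death (effector recruitment proportional to the
drug-kill flux) push activity above threshold. TAMs polarize M2 → M1
with oxygenation and M1 → M2 with VEGF, conserving their sum.
Endothelial proliferation needs VEGF and the Ang1 share of the
angiopoietin pool and is multiplied by the normalized sonopermeation
factors; VEGF and Ang2 are produced under hypoxia, Ang1 tracks the
endothelium.

## Numerics

Spatial operators are finite-volume on spherical shells (exactly
conservative in the shell measure; diffusion second order, advection
first-order upwind for stability). Time integration is piecewise: the
axis splits at every treatment event (ramp limits, pulse edges,
injections, anti-CTLA-4 window ends) and at a 2 h quasi-static refresh
cadence; at each refresh the environment (oxygen, IFP, velocities, Sv,
wall coefficients, modulation factors) is recomputed and frozen while
scipy's BDF advances the stiff reaction/transport system (rtol 1e-6,
atol 1e-9, block jacobian sparsity). Plasma concentrations are
evaluated continuously inside the right-hand side. States are
projected onto the physical region (≥ 0) at refresh points to absorb
solver undershoot. Runs are deterministic; identical configurations
give bit-identical outputs. Doubling the control-arm grid from 100 to
200 nodes changes the final volume by < 0.01%.

Default problem sizes — 40 radial nodes, 30-day horizon, 6 h output
cadence — were chosen as the package's standard desk-scale setting;
the order/interval sweep (8 runs) and the eight experimental arms
integrate in a few minutes on one core.

## Protocol and scheduling

The eight experimental arms share one calendar: ketotifen starts when
the simulated control reaches ~150 mm³; sonopermeation follows 3 days
later; Doxil + anti-PD-1 + anti-CTLA-4 are injected 1 h after
sonopermeation; the sono + injection cycle repeats 3 days later. The
order/interval sweep fixes one modality on days 19 and 22 and offsets
the other by 1, 3, 6 or 24 h, reporting final volume and
time-integrated internalized drug.

## Parameters

k₁ (oxygen–proliferation coupling, 1/h per mol/m³) is the single
tumor-specific constant; it is calibrated by a scalar root find so the
simulated control matches the measured final control volume (0.5%
relative), then held fixed across arms. The default k₁ = 0.12 with a
1.875 mm initial radius makes the control pass the 150 mm³ trigger
near day 16–18, so the first sonopermeation lands near the day-19
sweep anchor, and reaches ~550 mm³ by day 30.

Values the underlying studies do not print are declared in
`config.DEFAULT_CONFIG` as placeholders with realistic orders of
magnitude: vessel-wall L_p = 7×10⁻¹² m/(Pa·s) (chosen at the
Baxter–Jain scale so that baseline filtration is source-limited — this
is what lets the ketotifen IFP drop translate into increased delivery
rather than pure washout), tumor k_th = 3×10⁻¹⁴ m²/(Pa·s), Sv_anat =
2×10⁴ m⁻¹, P_V = 2 kPa, carrier release k_el = 3×10⁻⁵ s⁻¹, cellular
uptake k_int = 2.8×10⁻⁴ s⁻¹, degradation k_deg = 1×10⁻⁵ s⁻¹, plasma
decay 24 h (carrier) / 72 h (antibody). Kill-rate constants
(drug 0.05, immune 0.15 per hour per unit driver) put the combination
arms in a growth-inhibition rather than eradication regime, matching
the qualitative shape of the reference growth curves. Doses (mg/kg)
are recorded as metadata only; concentrations are normalized, and the
free drug is counted in carrier-equivalent units (α = 1 by default).

## Synthetic data

`reporting.generate_fixture` emulates caliper growth curves: the
simulated trajectory sampled every 2–4 days with mean-preserving
multiplicative log-normal noise (default CV 10%, 8 replicates),
deterministic under a seed. It reproduces sampling cadence and
measurement noise but not inter-animal growth-rate heterogeneity,
group attrition, or caliper bias; passing the recovery tests shows the
calibration machinery is self-consistent at realistic noise, not that
the model fits any particular animal study.

## Known limitations

* Monotherapy arms (ketotifen, sonopermeation alone) slightly *exceed*
  control growth in the default parameterization: decompression feeds
  oxygen to the tumor, and without drug on board nothing converts the
  perfusion gain into killing. The reference experiments likewise saw
  no volume benefit from these monotherapies, though not an increase.
* One radial dimension: no heterogeneous vascular hotspots, no
  aspherical growth.
* Acoustics are reduced to (MI, fr) → constant uniform pressure; no
  attenuation, scattering or bubble shell mechanics.
* The necrotic interior is not tracked separately: if treatment
  eradicates the cell populations the radius freezes instead of
  regressing.
* No pharmacokinetic model of ketotifen (direct parameter mapping) and
  no plasma kinetics beyond mono-exponential decay.
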