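# Methods

`nanotherm` simulates nanoparticle-mediated magnetic hyperthermia in a
vascularised tumour microenvironment in 2D. It couples three models on a
structured bilinear-quadrilateral FEM grid: (i) interstitial nanoparticle
transport with transvascular exchange and lymphatic drainage, (ii) a
single-temperature bioheat equation with SAR-proportional heating and a
choice of perfusion-cooling models, and (iii) an optional explicit 1D
microvascular network embedded in the tissue by Dirac line-source
coupling. The microenvironment (porosity, saturations, vascular fraction,
pressures) is a *frozen* synthetic state: tumour growth itself is out of
scope, and the generators reproduce the hallmark features of a grown
solid tumour instead.

Units are g-mm-s-K-W throughout, so 1 Pa = 1 g/(mm s^2) and
1 mmHg = 133.322 Pa. All densities default to the water-like
1e-3 g/mm^3.

## Frozen tumour microenvironment

The pore space (porosity `eps`, default 0.8) is shared by tumour cells,
host cells and interstitial fluid (IF) with saturations summing to one;
the vasculature occupies a separate fraction `eps_v`, and the ECM solid
takes the remainder. The spherical generator places smoothed-step (tanh,
50 um transition) radial profiles anchored at:

* tumour radius 0.4 mm (idealised scenario), tumour-cell plateau
  St = 0.8 / Sl = 0.2 against a host of Sh = 0.6 / Sl = 0.4;
* host vascular fraction `eps_v = 0.028`, collapsing to zero in the
  avascular **core** (half the tumour radius by default) while the
  tumour rim remains perfused — the collapse region is the core, not the
  whole tumour;
* interstitial fluid pressure peaking at 4 mmHg in the centre and
  decaying linearly to zero within about one tumour radius beyond the
  rim (classic measured IFP profiles drop at the tumour margin), driving
  a weak outward Darcy flow;
* homogenised blood pressure `pv = pl + 400 Pa`: with the oncotic term
  folded to zero, the 400 Pa stands for the net Starling filtration
  pressure (~3 mmHg) of leaky tumour-adjacent capillaries;
* cell-phase pressure `pt = pl` by default (`dp_cell` configurable).

The lymphatic collapse pressure defaults to 8 mmHg — twice the peak
IFP — so drainage in the tumour core is impaired (about 50%) but not
annihilated; with a collapse pressure equal to the peak IFP the
impairment factor would cancel drainage exactly where it matters.

The elliptical (mouse-leg) generator prescribes an 8 x 4 mm tumour of
tumour cells plus IF only (St = 0.65 / Sl = 0.35, the high fluid and
necrotic fraction of glioblastoma xenografts) with inert pressures; that
scenario solves temperature only.

`clustered_np_field` redistributes a nanoparticle field into discs and
rescales so the integrated mass rho_l*eps*Sl*omega over the tumour
matches the base field to 1e-6 relative, by construction.

## Nanoparticle transport

The interstitial mass fraction `omega_l` obeys

    d/dt (rho_l eps Sl omega_l) + div(rho_l q omega_l)
      - div(rho_l eps Sl D grad omega_l) = M_inter + M_trans - M_drain

with `q = -(k/mu) grad pl` the Darcy flux. The IF mobility defaults to
1e-9 mm^3 s/g (intrinsic ECM permeability ~1e-18 m^2 over the IF
viscosity), making advection a weak effect next to diffusion
(D = 1.2955e-5 mm^2/s); much larger whole-tissue conductivity values
would flush the millimetre-scale domain within the treatment hour, which
is not what tumour nanoparticle retention looks like.

Exchange terms (homogenised form; the discrete form replaces
`eps_v * S/V` by the circumference `2 pi R` per unit vessel length and
is concentrated on the centreline):

* interendothelial (solvent drag):
  `M_inter = rho_v eps_v Lp (S/V) (pv - pl - sigma dPi) * omega_drag`.
  The dragged concentration is **upwinded**: the vessel-side `omega_v`
  during filtration (the high wall-Peclet limit of Kedem-Katchalsky
  solvent drag). The symmetric arithmetic-mean wall average is available
  as `drag_concentration='mean'`; it is not the default because it keeps
  injecting mass from an *empty* vasculature after the infusion stops
  and makes the balance exponentially unstable (source proportional to
  `omega_l` with no bound).
* transendothelial (diffusive, one-way):
  `M_trans = rho_v eps_v P_v (S/V) (omega_v - omega_l)_+`.
* lymphatic drainage:
  `M_drain = rho_l (LpS/V)_ly (pl - p_ly)_+ (1 - pt/p_coll)_+ omega_l`.

The homogenised surface-to-volume ratio defaults to the cylinder value
`S/V = 2/R` at the mean capillary radius 6.98 um (286.5 /mm), so that
`eps_v * S/V ~ 8 mm^2/mm^3`, the capillary surface density of perfused
tissue. The vascular mass fraction `omega_v` is prescribed (Dirichlet in
time) during the infusion window and zero afterwards; the initial
condition is `omega_l = 0`.

Numerics: lumped storage, consistent bilinear stiffness, and
**conservative** finite-volume upwind advection with face fluxes taken
directly from pressure differences. The conservative form matters: the
frozen pressure field has div(q) != 0 (its fluid exchange is not
modelled), and the non-conservative form silently destroys mass where
the flow decelerates. Outer (non-symmetry) edges carry a free advective
outflow; everything else is no-flux. All operators are constant over a
run, so the backward-Euler system is factorised once (sparse LU,
residual-checked at 1e-10 relative) and reused each step; the clamped
transendothelial term converges by Picard iteration inside the per-step
fixed-point sweeps (tolerance 1e-8, at most 5 sweeps; the transport-to-
heat coupling is one-way, so one sweep order is already exact for this
model). A discrete mass ledger (exchange, drainage, advective outflow)
closes against the stored mass to round-off by construction and is
asserted at 1e-6 in the tests.

## Vasculature

Homogenised mode needs no extra machinery. Discrete mode represents the
microvasculature as a tree of cylindrical segments:

* **Synthesis.** Terminals are uniform random points; a recursive
  principal-axis bisection builds a binary tree from a single feeding
  point on the boundary; radii follow Murray's law (exponent 3) upward
  from jittered terminal radii, iterated so the mean radius lands within
  10% of 6.98 um and clipped to 1.6-30 um. The plan-view length density
  is calibrated to 12 mm per mm^2 of domain, the density of measured
  planar (mesentery-type) microvascular networks. Matching instead the
  homogenised volume fraction 0.028 would require ~180 mm/mm^2 — a 3D
  volumetric density that makes no sense for a planar network and would
  make the capillary line sink as strong as the Pennes sink.
* **Collapse.** Segments whose midpoint sits where St > 0.5 are flagged
  collapsed; segments disconnected from the inlet are pruned. Collapsed
  segments carry no flow, no transport, no exchange and no heat sink.
* **Flow.** Hagen-Poiseuille conductances g = pi R^4/(8 mu L) with blood
  viscosity 3.5e-3 Pa s; inlet at 45 mmHg and terminal outlets at
  15 mmHg above the interstitium (physiological arteriolar/venular
  pressures — anchoring the venous end at the interstitial pressure
  would leave the capillary bed without transmural filtration pressure
  and hence without extravasation). Junction flow balance holds to
  1e-12 of the peak flow.
* **1D transport.** Segments are subdivided to the 2D grid spacing;
  storage rho_v pi R^2, upwinded advection by the signed flows, inlet
  Dirichlet mass fraction, and an advective discharge at every node with
  net inflow (the outlets), which keeps the scheme bounded by the inlet
  concentration. The exchange sink applied to the 1D mesh is the same
  array spread to the 2D grid, so the two ledgers match exactly.
* **Line coupling.** Each 1D element carries two Gauss points with
  bilinear shape-function weights in its host cell; spreading is the
  exact transpose of sampling, shape functions sum to one at every
  quadrature point, and an implicit line-sink matrix
  L^T diag(2 pi R beta_T w ds) L makes the discrete perfusion sink
  unconditionally stable.

## Bioheat

All phases share one temperature (local thermal equilibrium); the summed
energy balance uses `(cp rho)_eff = sum cp_g rho_g eps_g` and
`kappa_eff = sum kappa_g eps_g` (with the printed tissue values,
identical across phases, these collapse to cp*rho and kappa). The SAR
source is `Qp = (rho_v eps_v omega_v + rho_l eps Sl omega_l) SAR`
volumetrically plus `rho_v pi R^2 omega_v_hat SAR` per unit vessel
length in discrete mode, active only while the alternating magnetic
field is on. Cooling is either the lumped Pennes sink
`rho_v cp w (T - Tb)` applied uniformly (an eps_v-weighted variant
exists but is off by default) or the discrete line sink
`2 pi R beta_T (T - Tb)` with blood isothermal at Tb (no 1D energy
equation). The mass-transfer enthalpy term of the summed balance cancels
across phases and is dropped. Edges are Robin
(`-kappa dT/dn = h (T - Tb)`), no-flux (symmetry), or Dirichlet;
backward Euler with the same factorise-once strategy as transport.

## The three reference experiments

* **Idealised** (`run_idealised`): 0.5 x 0.5 mm quarter domain
  (tumour centre at the upper-left corner), 120 x 120 elements,
  homogenised vasculature, 60-min protocol (infusion 0-40 min at
  omega_v in {0.5, 1, 2}e-3; AMF 20-60 min at SAR in {1, 1.5, 2} MW/kg;
  dt = 60 s), Robin h = 2e-5 W/mm^2K on the two outer edges, no-flux on
  the symmetry edges, T(0) = 37 degC. Perfusion rates
  w in {0, 0.009, 0.018, 0.036} 1/s.
* **Discrete** (`run_discrete`): 2.7 x 3.5 mm domain, 108 x 140 grid
  (25 um spacing, one grid row at y = 1.8 mm for the profile), synthetic
  tree (defaults above), tumour of radius 0.8 mm at the domain centre
  (the reference geometry prints only the domain size), same protocol.
  The window is embedded in normothermic perfused host tissue: its edges
  carry a Robin coefficient equal to the conduction-perfusion screening
  conductance of the surroundings, h = sqrt(kappa rho cp w_host) with
  w_host = 0.036 1/s (h = 2.5e-4 W/mm^2K, screening length ~1.4 mm).
  With the bare half-space coefficient 2e-5 the lumped sink would remove
  >80% of the temperature elevation, an order of magnitude more than
  reported for this configuration, and the lumped/discrete comparison
  collapses; the published cooling fractions are mutually consistent
  only with a strongly coupled boundary.
* **Mouse leg** (`run_mouse`): 9.5 x 9.5 mm, 150 x 150 grid, 8 x 4 mm
  ellipse, prescribed interstitial nanoparticle field (homogeneous
  2e-3, or four equal-mass clusters of radius 0.6 mm), SAR =
  0.1098 MW/kg, no perfusion sink, T(0) = 29 degC, 30 x 60 s steps.
  All four edges face air (h = 0.3e-5 W/mm^2K) by default — the leg
  protrudes into air; a body-contact edge with h = 2e-5 is configurable.

## What the synthetic stand-ins do and do not show

The generators emulate *statistics and hallmarks*, not measured fields:
the real grown-state profiles, the in-vivo rat network geometry and the
MRI-segmented leg are not reproduced. Consequently the scenario outputs
are structurally faithful (saturating temperature curves peaking at the
infusion end, near-homogeneous fields in the idealised case,
vessel-localised heating and negligible capillary cooling in the
discrete case, cluster-local excess heating in the mouse) while absolute
values carry the stand-ins' uncertainty; across network seeds the
discrete-scenario peak spans roughly 39.3-40.2 degC and the capillary
cooling 0.05-0.15 degC. Passing tests therefore demonstrate correct
numerics and transfer physics under the stated synthetic conditions, not
agreement with any particular animal.

## Numerical choices and limitations

* Backward Euler + lumped storage + full upwinding: unconditionally
  stable and positivity-preserving at any Peclet number; the price is
  first-order accuracy in time and extra numerical diffusion, acceptable
  at the 25 um / 4 um grids used (halving h and dt moves the peak
  domain-average temperature by < 0.1 K).
* Direct sparse LU with factor reuse: at <= 6e4 unknowns this beats any
  iterative setup; solver residuals are verified, never assumed.
* No singularity treatment at vessel centrelines: at these resolutions
  the bilinear shape functions regularise the Dirac measure; refining to
  where the singularity matters would exceed the model's validity.
* Degenerate inputs: zero tumour radius gives a uniform host state; zero
  flow reduces 1D transport to diffusion; an all-collapsed network
  yields zero exchange and zero sink; all such paths are tested.
* Not modelled: tumour growth and mechanics, oxygen, angiogenesis, 3D
  geometry, pulsatile flow and blood rheology, cellular nanoparticle
  uptake, temperature-dependent properties, tissue damage (CEM43), and
  per-phase non-equilibrium temperatures.
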