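# Methods

## Model

The construct is a collagen cylinder (core radius R1, length L) seeded
with therapeutic cells, wrapped in an acellular annular sheath of
thickness T that is porous over a length Lp at each end (Lp = 0:
impermeable; 2 Lp = L: fully porous). Three fields are evolved on the
core: viable cell density n (cell m^-3), oxygen c and VEGF v (kg m^-3);
the porous parts of the sheath carry c and v only.

Core:

    dn/dt = beta c n (1 - n/n_max) - delta(n0) n
    dc/dt = D_cg Lap(c) - n M c / (c_half + c)
    dv/dt = D_vg Lap(v) + alpha(n0) n f(c) - K v

with the hypoxia switch f(c) = (Vm+1)/2 - ((Vm-1)/2) tanh(B (c - c_h)).
Sheath (porosity eps, tortuosity tau(eps)):

    eps dc/dt = D_cs (eps/tau) Lap(c)
    eps dv/dt = D_vs (eps/tau) Lap(v) - K eps v

Assumptions inherited from the modelling framework: no cell migration or
matrix remodelling on the 24 h timescale; glucose and neurotrophic
factors in excess; diffusivities independent of cell density; partition
coefficients equal to one, so the gel-sheath interface condition is flux
plus concentration continuity; all boundary data independent of the
azimuthal angle, so the 3D problem reduces exactly to axisymmetric
(r, z). The VEGF degradation term is kept in the acellular sheath as
written in the source model, although degradation without cells is
physically debatable.

The coefficients delta(n0) = delta0 + delta1 n0 (death),
alpha(n0) = alpha0 + alpha1 n0 + alpha2 n0^2 (baseline secretion) and
Vm(n0) = Vm0 + Vm1 n0 (hypoxic upregulation) are functions of the
*seeded* density, not the evolving one: they encode crowding at seeding
time. Under three-zone seeding they are evaluated at the zone-local
seeded density; whether the reference implementation used zone-local or
construct-average values is not documented, and zone-local is the only
reading consistent with the definition for uniform seeding. This choice
is validated a posteriori: with it, every published argmax of the
uniform-seeding sweeps is reproduced to about 1% (see "Known
discrepancies").

## Parameters and units

All computation is in SI; practical units (%O2, ng/ml, cells/ml) appear
only at configuration and reporting boundaries, with the fixed pairings
1 %O2 = 4.10e-4 kg m^-3 (an effective O2 molar mass of ~31 g/mol — used
verbatim rather than re-derived from 32 g/mol, for consistency with every
tabulated pair), 1 ng/ml = 1e-6 kg m^-3 and 1 cell/ml = 1e6 cell/m^3.

One published inconsistency is resolved deliberately: the SI value of the
density-dependent death coefficient is printed as 9.13e-23 m^3/cell/s
while its practical twin is 9.13e-14 ml/cell/s (= 9.13e-20 m^3/cell/s).
We adopt 9.13e-20: it alone reproduces the published survival-threshold
concentration (16.43 %O2 at 4e8 cells/ml) and the long-term survival
limit (~3.53e7 cells/ml at 5 %O2 tissue). Both values are recorded in the
provenance table (`nrcsim params dump`). The survival-threshold seeding
density itself is solved in practical units (beta = 220 ml/mol/s,
1 %O2 = 1.32e-8 mol/ml), matching how the published number was evidently
obtained; the SI route differs by ~1% through rounding of the unit
pairing.

Key defaults (changeable per scenario): c0 = 21 %O2, c_tissue = 5 %O2,
v0 = v_tissue = 0; sheath eps = 0.8, overlapping-spheres tortuosity
tau = 1 - ln(eps)/2, T = 0.25 mm; uniform seeding n0 = 1.78e8 cells/ml;
v_p = 100 ng/ml as the reference concentration in the VEGF secretion
timescale.

## Discretisation and integration

Cell-centred finite volumes on a structured axisymmetric mesh; face
conductances g = D_eff A / d with axisymmetric face areas, harmonic
averaging across the gel-sheath interface (which enforces discrete flux
continuity exactly), Dirichlet tissue values through half-cell boundary
faces, zero flux on the axis, at r = R1 over impermeable sheath sections
and on the internal porous-zone end faces. The sheath storage term is
scaled by eps. The scheme conserves mass discretely (verified to 1e-8
relative against an integrated boundary-flux ODE) and is second-order in
space (verified on a smooth manufactured solution, observed order > 1.9).

The three-zone seeding boundaries at L/3 and 2L/3 are snapped to the
nearest mesh face; default axial resolutions are multiples of 3 so the
snap is exact. Degenerate eps = 0 is handled by omitting the sheath block
entirely, never by evaluating eps/tau at 0; the cylinder tortuosity model
is rejected at eps <= 0.25 where it is singular.

Time integration is scipy's adaptive implicit BDF on the fully coupled
method-of-lines system with an exact Jacobian sparsity pattern; no
operator splitting. The tanh switch (B c_h ~ 850) and the
Michaelis-Menten term make the system stiff near c ~ c_h; reaction terms
evaluate max(c, 0) so that sub-tolerance negative excursions cannot
destabilise the kinetics. Default tolerances rtol = 1e-6,
atol = 1e-12 kg m^-3 for concentrations and 1 cell m^-3 for density. The
initial condition/boundary value conflict at t = 0 (construct stored at
21 %O2, tissue at 5 %O2) never materialises on a node because unknowns
live at cell centres: boundary values act for t > 0 through boundary-face
fluxes, and the t = 0 snapshot reports the initial condition.

With an impermeable sheath and r-uniform initial data the solution is
exactly z-only, so design sweeps use a single radial cell (the "1D fast
path"); agreement with the 2D solver is verified to < 1e-3.

## Problem sizes and sweeps

Defaults chosen so the ~1.3 mm oxygen penetration length is resolved by
~10 cells: nz = 99 (1D sweeps), nz = 45 with 5 core and 3 sheath radial
cells for porous 2D sweeps (halving the spacing changes 24 h mean metrics
by well under 1%). Seeding-density sweeps use 40 uniform points on
[1e7, 4e8] cells/ml (16 for the 2D porous case) followed by
golden-section refinement of each (metric, time) argmax between its
bracketing grid neighbours, to 2.5e6 cells/ml resolution; the refined
optimum never degrades the grid optimum by construction. v_SD is the
population (volume-normalised) standard deviation. Repartition-factor
sweeps default to 13 points on [0, 3]. The model is deterministic
end-to-end; re-running any scenario bit-reproduces its metrics.

## Verification strategy

Independent oracles, each exercised in the test suite: exact equilibria;
Fourier-series solutions of Dirichlet-slab diffusion (1e-3); the
well-mixed reaction ODE system, which the PDE solver must match in the
all-boundaries-closed configuration (1e-4); closed-form logistic-growth
and exponential-decay solutions of the kinetics; stationary-state
convergence on both sides of the survival threshold c_tau = delta/beta;
discrete conservation; 1D/2D equivalence; axial symmetry of symmetric
problems to 1e-9; positivity on the baseline scenarios; and the
qualitative design orderings (porosity >= 0.1 raises 24 h cell density
and collapses VEGF; partial porosity interpolates between regimes; the
porous-sheath repartition optimum sits near uniform seeding).

## Known discrepancies with the published values

- Reproduced to ~1%: argmax n-bar = 2.09e8 (12 h) and 8.74e7 (24 h)
  cells/ml, argmax v-bar = 3.40e8 (12 h) and 2.37e8 (24 h), argmax
  v_SD = 3.53e8 (12 h) and 2.67e8 (24 h), max n-bar = 2.58e7 cells/ml
  (survival fraction ~30%), porous argmax n-bar = 1.11e8 cells/ml.
- The published maximal mean VEGF concentration at 24 h (~112 ng/ml) is
  ~18% below the mesh-converged model value (132 ng/ml). No evaluation
  variant of the density-dependent coefficients closes this gap without
  breaking the argmax agreement above (evaluating alpha and Vm at the
  evolving density gives ~116 ng/ml but pushes the 12 h VEGF argmax to
  the sweep boundary), and the value is insensitive to the initial
  oxygen concentration (128-132 ng/ml over 1-21 %O2). The corresponding
  acceptance assertion is therefore expected to fail at its 5% tolerance
  and is kept as an honest record of the discrepancy.
- The published consumption and secretion times (1.95 h, 3.63 h) match
  the stated formulas at n0 = 2.0e8, not the quoted 1.78e8 cells/ml; the
  package reports formula values.
- One published radial VEGF time (5.22 h at T = 1.5 mm) is consistent
  with tau^1 weighting; the formulas here use tau^2 exactly as defined
  and that value is not matched.

## Limitations

Simulations beyond 24 h extrapolate kinetics fitted to 24 h in-vitro
data and should be read qualitatively. The model omits cell migration,
matrix remodelling, angiogenesis/endothelial invasion, neurite growth,
glucose limitation and density-dependent diffusivities. Tissue boundary
concentrations are held constant (homeostasis assumption) and are poorly
constrained experimentally; they are exposed as scenario parameters for
sensitivity studies.
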