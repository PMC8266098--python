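# nrcsim

Cell–solute simulation of cell-seeded nerve repair constructs (NRCs).

Engineered neural tissue for repairing large peripheral-nerve gaps is
built as a collagen hydrogel cylinder (length *L* = 15 mm, core radius
*R*₁ = 0.25 mm) seeded with therapeutic cells (e.g. differentiated
adipose-derived stem cells) and wrapped in an annular sheath that may be
impermeable, porous, or porous only near the nerve stumps. In the first
24 h after implantation the seeded cells proliferate, consume oxygen and —
once the construct turns hypoxic — secrete VEGF, the key pro-angiogenic
signal. `nrcsim` simulates these first 24–120 h and ranks construct
designs (seeding density and distribution, sheath porosity, material and
thickness, culture and tissue conditions) by the metrics that matter for
later regeneration: the core-averaged cell density n̄, the mean VEGF
concentration v̄ and its spatial spread v_SD.

It is intended for tissue-engineering and mathematical-biology groups who
want to shortlist NRC designs computationally before committing to
in-vivo experiments.

## Model

On the gel core (axisymmetric, no cell migration over this timescale):

    ∂t n = β c n (1 − n/n_max) − δ(n₀) n
    ∂t c = D_c,g ∇²c − n M c / (c_½ + c)
    ∂t v = D_v,g ∇²v + α(n₀) n f(c) − K v

with the hypoxia switch
`f(c) = (V_m+1)/2 − ((V_m−1)/2)·tanh(B (c − c_h))`, which interpolates
from baseline secretion (c ≫ c_h) to V_m-fold upregulated secretion
(c ≪ c_h). The death rate δ, baseline secretion α and upregulation factor
V_m are functions of the locally *seeded* density n₀(z). The acellular
sheath is a porous medium with effective diffusivity `D ε/τ(ε)`
(tortuosity τ from overlapping-spheres, cylinder or disordered-tube
models), coupled to the gel by flux and concentration continuity.
Dirichlet tissue values (default 5 %O₂, 0 ng/ml VEGF) act at the stump
ends and, where the sheath is porous, at its outer surface; the construct
starts at storage conditions (default 21 %O₂, 0 ng/ml).

The discretisation is a conservative cell-centred finite-volume scheme on
a structured (r, z) mesh, advanced by an adaptive implicit BDF integrator
(no operator splitting). For impermeable sheaths an exact 1D axial
reduction makes design sweeps fast. Closed-form diagnostics (diffusion,
consumption and secretion timescales, oxygen penetration length, the
survival threshold c_τ = δ/β and its seeding-density counterpart) are
provided alongside the PDE solver. Everything is deterministic.

## Worked example

```python
from nrcsim import (ConstructGeometry, BoundaryEnvironment, SeedingSpec,
                    simulate_axial_1d, timescales)
from nrcsim.units import HOUR, CELLS_ML_TO_M3, NG_ML_TO_KG_M3, PCT_O2_TO_KG_M3

geo = ConstructGeometry(Lp=0.0)                  # impermeable sheath
env = BoundaryEnvironment()                      # 21 %O2 start, 5 %O2 tissue
seed = SeedingSpec.uniform(1.78e8 * CELLS_ML_TO_M3)
res = simulate_axial_1d(geo, env, seed, t_end=24 * HOUR)
m = res.metrics()
for _, row in m.iterrows():
    print(f"t = {row.t/HOUR:5.1f} h   n̄ = {row.n_bar/CELLS_ML_TO_M3:.3g} "
          f"cells/ml   c̄ = {row.c_bar/PCT_O2_TO_KG_M3:5.2f} %O2   "
          f"v̄ = {row.v_bar/NG_ML_TO_KG_M3:6.1f} ng/ml")
```

prints

```
t =   0.0 h   n̄ = 1.78e+08 cells/ml   c̄ = 21.00 %O2   v̄ =    0.0 ng/ml
t =   0.5 h   n̄ = 1.78e+08 cells/ml   c̄ = 14.54 %O2   v̄ =   10.6 ng/ml
t =   1.0 h   n̄ = 1.76e+08 cells/ml   c̄ =  9.77 %O2   v̄ =   20.2 ng/ml
t =   6.0 h   n̄ = 1.12e+08 cells/ml   c̄ =  0.46 %O2   v̄ =  208.0 ng/ml
t =  12.0 h   n̄ = 6.36e+07 cells/ml   c̄ =  0.60 %O2   v̄ =  233.1 ng/ml
t =  24.0 h   n̄ = 2.15e+07 cells/ml   c̄ =  1.00 %O2   v̄ =  128.5 ng/ml
```

The construct consumes its stored oxygen within ~6 h (the consumption
time c₀/(M n₀) is far shorter than the 15 mm axial diffusion time of
~35 h), cells then decline from the centre outwards, and VEGF — strongly
upregulated below the hypoxic threshold c_h = 4.77 %O₂ — peaks near 12 h
before degradation (1/K ≈ 9.3 h) and stump losses take over.

The same machinery drives design sweeps: `run_sweep` finds, e.g., that an
impermeable construct maximises the 24 h mean cell density at a seeding
density of ≈8.7×10⁷ cells/ml — seeding more cells is counterproductive —
while a fully porous sheath (ε = 0.8, T = 0.25 mm) shifts the optimum to
≈1.1×10⁸ cells/ml but collapses VEGF accumulation.

## Command line

```bash
nrcsim presets                           # list built-in scenario presets
nrcsim run -p impermeable-baseline -o out/
nrcsim sweep -c scenario.yaml -o out/
nrcsim analyze timescales
nrcsim analyze stability --n0-cells-ml 4e8
nrcsim params dump -o params.csv
```

Scenario configs are YAML; outputs are CSV metric and field tables plus
the resolved configuration.

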