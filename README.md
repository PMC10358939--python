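# aggflow

Image-based simulation of blood flow through and around porous platelet
aggregates in a microfluidic perfusion channel.

Platelet aggregates that form on a collagen-coated channel wall are not
solid plugs: they are porous media with a dense *core* and a loose outer
*shell*, and the trickle of plasma that penetrates them controls how
agonists (ADP, Ca²⁺, coagulation factors) reach the platelets inside.
`aggflow` reconstructs an aggregate's geometry from per-slice microscopy
masks, infers its internal platelet volume fraction from fluorescence
intensity, converts that to a permeability field, solves the steady
incompressible flow with a Brinkman drag term, and reports the hemodynamic
quantities that matter for aggregation biology: intrathrombus velocity,
shear stress, elongation rate, drag (kinetic) force and per-agonist Péclet
transport classification.

## Model

Flow is an incompressible Newtonian fluid with a Darcy resistance inside
the aggregate:

    ρ (∂u/∂t + u·∇u) = −∇p + μ Δu − (μ/k) u ,   ∇·u = 0

The local permeability k comes from the Kozeny–Carman closure

    k = Φs² ε³ Dp² / (150 (1 − ε)²)

with porosity ε = 1 − φ, platelet sphericity Φs = 0.71 and platelet
diameter Dp = 2 µm.  The platelet volume fraction φ is an affine function
of fluorescence intensity, φ = a·I + b, calibrated by ordinary least
squares against manually counted samples.  Boundary conditions are those of
a perfusion chamber: a parabolic inlet profile with prescribed wall shear
rate γ̇w (peak γ̇w·H/4 at mid-height of a channel of height H = 100 µm),
constant pressure at the outlet, no-slip walls, and free-slip symmetry on
the lateral faces.

The solver is a staggered (MAC) voxel-grid projection method marched in
pseudo-time to steady state; the Darcy term is treated implicitly per cell
(it spans many orders of magnitude between shell and core) and the pressure
Poisson problem is solved exactly by FFT diagonalization, so the discrete
divergence of every returned field is at round-off level.

Derived fields follow the standard definitions: shear rate
γ̇ = √(2 D:D) with D the strain-rate tensor, shear stress σ = μγ̇,
elongation rate ε̇ = √((∂u/∂x)² + (∂v/∂y)² + (∂w/∂z)²), per-voxel Darcy
force σ_D·|u|·V_cell, and Péclet number Pe = |u|·Dp/D_diff per agonist.

Because no experimental image stacks ship with the package, a first-class
phantom generator produces wall-attached core–shell aggregates with the
same statistical structure (affine intensity–density law plus noise,
per-slice masks), so the entire pipeline is testable and reproducible from
a single seed.

## Worked example

```python
from aggflow import AggregateFlowModel, PhantomSpec

model = AggregateFlowModel.from_phantom(PhantomSpec(seed=1), nz=32,
                                        wall_shear_rate=1600.0)
results = model.fit()
print(results.summary())
```

```
Aggregate flow results
==========================================================
wall shear rate                  1600 1/s
intrathrombus speed            0.1604 +/- 0.5336 mm/s
extra-thrombus speed            28.21 +/- 13.1 mm/s
kinetic force per voxel      4.78e-10 +/- 1.577e-09 N
Peclet [Ca2+    ]             0.4832 +/- 1.607   advection-dominated 8.51%
Peclet [ADP     ]              1.248 +/- 4.153   advection-dominated 9.44%
Peclet [FactorX ]              6.417 +/- 21.35   advection-dominated 17.30%
----------------------------------------------------------
cells: 3242 intrathrombus / 62294 extra-thrombus
converged in 1190 steps (dt = 4.45e-07 s, residual 5.43e-07)
max divergence 1.92e-16, flux mismatch 0.00e+00
```

Reading the numbers: the mean speed inside the aggregate (0.16 mm/s) is two
orders of magnitude below the free-lumen mean (28.2 mm/s) — the porous
matrix screens the interior almost completely.  Ca²⁺, the most diffusive
agonist, is advection-dominated (Pe > 1) in only 8.5% of the aggregate,
while the slowly diffusing Factor X is advected faster than it diffuses in
17.3% — chemistry deep in the core sees a diffusion-controlled environment
regardless of the outside flow.

`results.save("runs/demo")` writes the occupancy/porosity/permeability and
velocity/shear/transport lattices as legacy-ASCII VTK files plus summary
and convergence CSVs.  The same pipeline is scriptable from the shell:

```bash
aggflow all --wsr 800 --wsr 1600 --wsr 4000 --out runs/wsr_study
aggflow sweep --porosity 0.5 --porosity 0.7 --porosity 0.9 --wsr 1600
```

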