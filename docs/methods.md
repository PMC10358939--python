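# Methods

This note documents the model, the numerical scheme, the synthetic-data
generator and the design decisions behind `aggflow`, at the level of detail
a user needs to judge what the package's results do and do not show.

## Physical model

Blood in the lumen is an incompressible Newtonian fluid (density
ρ = 1.025×10⁻³ g/mm³, dynamic viscosity μ = 3×10⁻³ g mm⁻¹ s⁻¹).  The
platelet aggregate is a fixed, rigid porous medium: its effect on the flow
is a volumetric Darcy drag −(μ/k)u added to the momentum equation
(a Brinkman-type model), with no aggregate deformation, contraction or
embolization.  All units are mm–g–s, so pressure is numerically in Pa and
forces in 10⁻⁶ N before the reporting conversion.

Permeability comes from the Kozeny–Carman closure for a packed bed,
k = Φs²ε³Dp²/(150(1−ε)²), with activated-platelet sphericity Φs = 0.71 and
platelet diameter Dp = 2×10⁻³ mm.  At ε = 0.5 this gives
k = 6.72×10⁻⁹ mm²; at ε = 0.9, k = 9.80×10⁻⁷ mm².  The Darcy screening
length √k is then far below the aggregate size, which is why interior
velocities drop by orders of magnitude within a few cells of the surface.

The platelet volume fraction φ = 1 − ε is inferred from fluorescence
intensity through an affine map φ = a·I + b fitted by unweighted OLS to
counted (intensity, fraction) samples.  Because an affine calibration can
leave [0, 1] (measured intercepts include negative values), φ is clamped to
[0.05, 0.95] before the permeability conversion; the clamp bounds the Darcy
coefficient between ~3×10³ and ~2×10⁸ g mm⁻³ s⁻¹ and is exposed in the
configuration.

### Boundary conditions

The simulated box is a small streamwise section of a perfusion chamber of
height H = 0.1 mm.  At the inlet (y = 0) the streamwise velocity is the
plane-Poiseuille parabola v(z) = (γ̇w/H)·z·(H−z), uniform laterally, whose
wall slope is exactly the prescribed wall shear rate γ̇w and whose peak is
γ̇w·H/4.  The outlet (y = Ly) holds a constant reference pressure with
zero-gradient velocity.  Top and bottom walls are no-slip.  The lateral
faces are free-slip symmetry planes by default (the box is a lateral
excerpt of a much wider channel); a periodic option is available.  For
fully developed porous-channel verification runs, a uniform streamwise body
force G can drive the flow and an arbitrary inlet profile v(z) can be
prescribed.

## Numerical scheme

Velocity components live on the faces of a uniform cubic voxel grid
(MAC staggering), pressure at cell centers, so discrete incompressibility
is enforced exactly.  Steady state is reached by pseudo-time marching:

1. explicit momentum update (central second-order advection and diffusion,
   current pressure gradient, optional body force);
2. division by the per-cell factor 1 + Δt·σ_D/ρ, where σ_D = μ/k is
   harmonically averaged onto faces (the harmonic mean with an empty
   neighbour is zero, so the aggregate surface acquires no spurious drag);
3. an incremental-pressure projection: the Poisson problem for the pressure
   increment is diagonalized exactly by fast cosine transforms (DCT-II
   across the Neumann wall/lateral pairs, DCT-IV along the streamwise axis
   whose inlet is Neumann and outlet Dirichlet), and the face velocities
   are corrected to machine-precision divergence-free.

The implicit per-cell Darcy treatment is essential: σ_D·Δt/ρ reaches ~10³
in the aggregate core and an explicit term would be violently unstable.
The *incremental* form of the projection is equally important here: with a
non-incremental (pressure-free) predictor the pressure-gradient correction
is not divided by the Darcy factor, and the converged state inside the core
satisfies a momentum balance with ∇p mis-scaled by 1 + Δt·σ_D/ρ — a factor
of thousands.  With the pressure gradient included in the predictor, the
fixed point of the iteration satisfies the exact discrete steady momentum
equation regardless of Δt.

The time step defaults to the Table value 10⁻⁵ s and is automatically
reduced to 0.8·ρh²/(6μ) (explicit diffusion limit) and 0.4·h/u_max
(advective CFL); at the default resolution the diffusive limit governs
(Δt ≈ 4.4×10⁻⁷ s).  The march starts from the undisturbed inlet parabola
replicated through the domain, which removes most of the start-up
transient, and stops when the relative max-norm velocity change per step
stays below 10⁻⁶ for 100 consecutive steps.  A Stokes mode drops the
advective term, making the solution exactly linear in γ̇w (used for
linearity and reproducibility checks).  Non-convergence and NaNs raise an
explicit error carrying the residual history.

Verification: the empty channel reproduces the analytic Poiseuille profile
to 0.04% (L₂, 32 cells across H) and the fully porous channel the
closed-form Brinkman cosh profile to 0.13%, with the error falling ~4–5×
when h is halved (second-order interior scheme; the wall treatment
contributes a uniform O(h²) offset).  The recovered wall shear rate is
measured by a three-point quadratic fit at the wall, which is exact for any
quadratic profile and therefore insensitive to that offset.

## Image processing

Geometry is voxelized throughout; no surface or tetrahedral meshing is
performed.  Per-slice binary outlines are converted to 2D signed-distance
fields (anisotropy-aware, with the zero level set half a pixel outside the
foreground so thresholding at 0.5 round-trips the input masks exactly),
linearly interpolated along z — which fills the gap between slices with the
geometric blend of the neighbouring outlines — and converted to a soft
occupancy in [0, 1].  Optional surface smoothing filters the 3D signed
distance with a Gaussian of physical standard deviation equal to the
configured smoothing length (default 0: the strength of the smoothing
applied to the original data is unknown, so none is claimed).  Occupancy
and intensity are then resampled onto the flow grid by trilinear
interpolation (exact for affine fields, range-preserving).  A cell is
classified intrathrombus when its occupancy is ≥ 0.5, the midpoint of the
level-set convention.

## Synthetic aggregates

The phantom generator emulates the structure the pipeline assumes, not any
individual specimen (no quantitative core/shell dimensions are available
for the real aggregates, so these are free parameters chosen once):

* a wall-attached half-ellipsoid, semi-axes (35, 45, 30) µm, centered in a
  0.1 × 0.2 × 0.1 mm channel section — a realistic footprint that leaves
  the aggregate clear of the outlet;
* core volume fraction 0.75 inside half the normalized radius, shell 0.35,
  blended by a cubic smoothstep over 8 µm (differentiable permeability,
  no solver shocks);
* intensity I = (φ − b)/a with the measured 1600 s⁻¹ calibration
  (a = 0.0014, b = 0.28) plus additive Gaussian noise (sd 5 a.u., clipped
  at 0) — noise touches intensity only, so the geometry is deterministic
  given the spec;
* 1 µm isotropic voxels, per-slice masks from the occupancy, one integer
  seed for all stochastic draws.

What the phantoms do *not* model: optics (point-spread function,
photobleaching, exposure drift), segmentation error in the masks, and any
irregularity of real aggregate shapes.  Passing tests therefore demonstrate
the correctness of the numerics and the internal consistency of the
calibration-porosity-permeability-flow chain, not fidelity to any
particular experimental aggregate.

## Derived quantities and conventions

* Shear rate γ̇ = √(2 D:D) and stress σ = μγ̇; the tensor and fully
  expanded forms agree per cell to round-off.  Diagonal velocity gradients
  are taken directly from staggered face differences (exact at centers),
  off-diagonals by centered differences of the cell-centered components,
  one-sided at boundaries.
* Elongation rate ε̇ is the magnitude of the diagonal of D; thresholds for
  VWF unfolding are 5000 s⁻¹ (shear) and 1000 s⁻¹ (elongation), both
  applied inclusively (≥).
* The kinetic (Darcy drag) force is reported per voxel, σ_D·|u|·V_cell in
  N, so magnitudes are comparable across resolutions only through the cell
  volume; the force density σ_D·|u| is the resolution-independent field.
* Péclet numbers use the superficial (computed) velocity and the free-flow
  diffusion coefficients (Ca²⁺ 6.64×10⁻⁴, ADP 2.57×10⁻⁴, Factor X
  5×10⁻⁵ mm²/s); whether the porous matrix reduces effective diffusivity
  is unknown, so no hindrance correction is applied.  Advection-dominated
  means strictly Pe > 1.
* Extra-thrombus statistics average over the entire non-occupied fluid
  domain (not a near-aggregate shell); intrathrombus statistics, force and
  Péclet statistics are over occupied cells only.

## Default problem sizes

The default flow grid is 32 × 64 × 32 cubic cells (h = H/32 ≈ 3.1 µm) over
a 0.1 × 0.2 × 0.1 mm box; one steady solve takes ~1000–1500 pseudo-time
steps (tens of seconds on one CPU).  The verification oracles use narrow
boxes (4 and 2 cells laterally) since the reference solutions are
one-dimensional.  These sizes resolve the phantom shell with 2–3 cells;
they are deliberately desk-scale and coarser than the ~0.9 µm elements a
production supercomputer study would use, which mainly inflates
surface-cell averaging in the intrathrombus statistics (a surface cell
blends damped interior and free-stream faces).  The two-orders-of-magnitude
contrast between extra- and intrathrombus mean speeds is robust to this.

## Known limitations

* Newtonian single-phase rheology: no red-blood-cell migration, cell-free
  layer, or plasma-only interior viscosity correction.
* The aggregate is rigid; forces are reported but not fed back into any
  mechanical model.
* The affine intensity-density calibration is assumed exposure-independent;
  cross-dataset slopes are not comparable and are never mixed.
* Porosity sensitivity is explored by remapping intensity onto prescribed
  porosity values/ranges (brighter = denser), which preserves geometry but
  discards the calibrated absolute scale — by design, as an uncertainty
  sweep.
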