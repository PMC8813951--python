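# Methods

This note documents the models, numerical choices and parameter defaults
behind `biofilmscape`, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Coupled flow model

The 2D domain is a rectangle of fixed height 5 mm spanning one patch
cross-section along the flow direction (width typically 4–10 mm). Cells
below the (optionally Gaussian-smoothed) elevation profile form the
porous biofilm region; the rest is free-flowing water. The momentum
balance is

- free water: steady incompressible RANS with a single constant eddy
  viscosity ν_t (no wall damping). Total kinematic viscosity ν + ν_t.
- biofilm: Brinkman — Darcy drag (ν/K)·ū plus a viscous term with
  effective viscosity ν/ε. Velocity and viscous stress are continuous
  across the interface because both regions share one face-based
  finite-volume discretization; only the cell coefficients change.

Eddy viscosity and eddy diffusivity are applied in the free region only:
at these scales turbulence cannot penetrate the porous matrix.

Boundary conditions: Dirichlet velocity profile at the inlet (a
quadratic least-squares fit of velocimetry points over the domain
height), zero static pressure at the outlet, no-slip at the bottom, slip
(zero shear, zero normal velocity) at the top. A pressure-inlet mode
(prescribed inlet static pressure, zero upstream velocity gradient)
serves the pressure-driven oracle configurations.

The inlet Dirichlet profile is imposed across the full inlet, including
porous inlet cells. This over-predicts velocities inside the biofilm
near the inlet; the excess decays within roughly 1 mm downstream.
Diagnostics that average over the biofilm therefore accept an
`x_min_m` entrance-exclusion argument (1 mm in the transport-ordering
analyses).

### Discretization and solver

Staggered (MAC) finite volumes on a rectilinear grid: u on vertical
faces, w on horizontal faces, pressure at cell centres. The vertical
grid is fine (default 25–50 µm) in a band covering the biofilm and the
fluid–biofilm interface — which also provides the bottom inflation
layer — and coarsens geometrically above (growth 1.3, cap 250–300 µm).
Horizontal spacing is uniform.

The linear Stokes–Brinkman system (momentum + continuity, a saddle-point
problem closed by the outlet-pressure condition) is solved directly with
SuperLU; discrete continuity holds to machine rounding, so the
mass-conservation residual is ~1e-16 of the inflow. Momentum advection,
when enabled, is Picard-linearized with first-order upwinding,
under-relaxation 0.7, and a relative-change stopping tolerance of 1e-6
(error with the residual history if not reached).

Wall and Dirichlet-face derivative stencils use a one-sided quadratic
fit, which is exact for parabolic profiles — the half-Poiseuille and 1D
reaction–diffusion oracles are therefore reproduced to machine precision
rather than merely to truncation order, and the Darcy slab is exact
because the solution is uniform.

### Scalar transport

Cell-centred finite volumes: first-order upwind advection with an
optional deferred-correction central pass (default one pass; the
central-minus-upwind flux difference of the previous iterate moves to
the right-hand side, leaving the boundary flux balance telescoping
exactly). Diffusivities are harmonically averaged at faces. The reaction
rate R applies uniformly over biofilm cells. Boundary conditions: inlet
Dirichlet profile (or a closed no-flux inlet for slab oracles), pure
advective outflow, zero flux top and bottom (a Dirichlet top is
available for the 1D oracle). Negative concentrations beyond 1% of the
bulk scale are flagged as "consumption exceeds supply" and reported, not
clipped.

At steady state the integral of R over the biofilm balances the net
boundary flux; with the conservative scheme the residual is at rounding
level, far inside the 1% requirement that underpins areal-flux
estimates.

### Grid sizes

The solver runs at deliberately desk-scale resolutions: recovery and
fitting domains use ~1 000–2 000 cells (nx = 32, fine dz = 50 µm),
transport-ordering runs ~2 000 cells (nx = 48). Grid-convergence tests
show the biofilm-mean concentration changes by <1% when the cell size is
halved, and the closed-form oracles hold at 64-cell columns, so these
resolutions are adequate for the quantities reported here.

## Physical defaults

| parameter | default | note |
|---|---|---|
| ρ | 999.1 kg m⁻³ | water, 15 °C |
| ν | 1.139e-6 m² s⁻¹ | water, 15 °C |
| D_aq | 1.67e-9 m² s⁻¹ | O₂ in water, 15 °C |
| domain height | 5 mm | model water column |
| ε | 0.5 | biofilm void fraction |
| K | 1e-10 m² | permeability |
| C = D_eff/D_aq | 0.7 | diffusivity reduction in biofilm |
| P_rt | 1.0 | turbulent Prandtl number |
| ν_t | 1e-5 m² s⁻¹ | constant eddy viscosity |

ν_t is initialized as 0.07·h·u\* (integral length scale ≈ 7% of the
water depth times turbulent fluctuations taken equal to the friction
velocity); D_t = ν_t/P_rt holds by construction. All defaults are
overridable per run.

## Parameter estimation

The objective is Σᵢ (c_model(xᵢ,zᵢ) − c_measᵢ)² with bilinear
interpolation of the modelled field at sensor coordinates; solver
failures return +∞ so the simplex retreats. Nelder–Mead runs in a
transformed space — a sigmoid onto the bounds, log-scaled for K and ν_t,
linear for the rest — with simplex-spread tolerance 1e-4 per variable
and, by default, three restarts (one from the given initial values, the
others from seeded unit-normal perturbations in the transformed space);
the best objective wins and all restart objectives are reported. The
flow solution depends only on (ε, K, ν_t) and is memoized across
objective evaluations; transport re-solves are cheap, which is what
makes ~10³-evaluation fits take seconds.

Default fitting bounds bracket the survey's fitted values by roughly a
factor of three: R ∈ [−5e-3, −1e-5] (dark) mol m⁻³ s⁻¹,
K ∈ [1e-11, 5e-10] m², ε ∈ [0.2, 0.95], C ∈ [0.4, 1.0].

### Identifiability

Porosity is, under this model, structurally unidentifiable from O₂
transect data. The steady transport equation contains no ε term (the
conservative advective flux uses the Darcy velocity, so interstitial
scaling cancels), leaving ε only in the Brinkman effective-viscosity
term ν/ε. Its influence on the flow is confined to a layer of thickness
√(K/ε) ≈ 10–20 µm at K ≈ 1e-10 m² — below the 50 µm sensor spacing. A
noise-free sensitivity sweep shows the objective varies by ≤ 1.6e-5
(mol m⁻³)² over the entire ε range, roughly 50× below the noise floor
n·σ² of a 200-point transect at σ = 2e-3 mol m⁻³. Consequently the
simplex drifts ε along this flat direction and any reported ε
essentially reflects the initial value and bounds, not the data. R, C
and K are identifiable (noise-free objective curvature well above the
noise floor), with typical single-transect errors of ~5–10% for R and C
and ~10–25% for K; the least-squares minimum genuinely shifts along the
correlated R–K–C ridge from one noise draw to the next, so occasional
~20% errors are statistical, not an optimizer defect.

## Imaging

- DEM extraction: per image column, the surface is the highest voxel
  above an intensity threshold (default 130) over the substrate plane
  (the brightest z-slice in the lowest quartile of the volume — the
  reflective flume bottom); a 2D median filter of size 4 denoises the
  raster. Detection error is at most one axial voxel.
- Mosaics: translation-based stitching with fractional overlap (default
  30%); overlapping pixels averaged.
- Segmentation: DDP from a red/green-ratio threshold, KDP from a
  threshold on the mean of the green channel and its local-mean filter;
  defaults are Otsu's criterion on each statistic (the parameter-free
  reproducible choice), overridable. Objects and holes below 25 px are
  removed; the KDP mask is dilated by 5 px and takes precedence over
  DDP; the remainder is CDB.
- Porosity is the void fraction (void voxels / total) of the top biofilm
  layer: for each gray threshold (120, 130) × layer thickness (0.1,
  0.2 mm), the per-column fraction of sub-surface voxels below the
  threshold (the one-voxel surface skin excluded), median across
  columns; the min–max over the four settings is the uncertainty band.
  Columns taller than 1.2 mm (the OCT imaging depth) are excluded. The
  void/total reading is the one under which the loose filamentous KDP
  gets the *higher* porosity, consistent with the survey values.
- Geometry: biovolume is the sum of DEM heights times pixel area;
  thickness statistics are the median and the 0.2–0.8 inter-quantile
  range; coverage and volume shares are relative to the labelled
  biofilm totals.

## Microprofiles

Two-point linear calibration (anoxic ascorbate → 0, air-saturated →
saturation concentration); drift correction rescales each sample by the
ratio of the reference bulk concentration to the bulk value linearly
interpolated at its timestamp (bulk readings must bracket the data).
The biofilm surface is the z of maximum |d²c/dz²| — centred second
differences after 3-point moving-average smoothing — of the mean of the
light and dark profiles within ±0.3 mm of the OCT-indicated height,
falling back to the OCT height with a warning for flat profiles or
out-of-window cases. Averaging light and dark is a choice; using either
alone changes the estimate by at most a sensor step on forward-model
data.

Transects are Delaunay-triangulated; per-triangle gradients come from
the exact plane fit (affine fields are recovered to machine precision)
and nodal gradients are area-weighted over incident triangles. The angle
convention is 0° downstream (+x) and 90° toward the substrate (−z).
Pooling collects samples strictly below each profile's aligned surface,
grouped by patch type, light and flow; the output is designed to feed
any standard distributional test rather than re-implementing them.

## Upscaling

Areal flux = volumetric rate × mean patch thickness with the thickness
carried in **mm** — the only convention under which the survey's printed
areal numbers follow from its volumetric rates and geometry (e.g.
0.98 × 591/1411 = 0.41). The printed unit label (mmol m⁻² s⁻¹) is
reproduced as-is with this caveat. Landscape volumetric rates are
biovolume-weighted means; landscape areal flux is that rate times total
volume / total area. Comparisons against printed values use half-up
rounding to the printed decimals. Spatial arrangement of patches is
deliberately ignored.

## The synthetic generator

`synth` emulates the flume survey's observable statistics, not its
biology or optics:

- Landscapes: DDP and KDP blobs are Gaussian-smoothed thresholded noise
  fields (KDP precedence) on a CDB base; coverage thresholds are set by
  quantile so realized coverages match targets exactly, and per-type
  heights are standardized over each mask so realized means and SDs hit
  the targets up to clipping at zero. Default targets are the slow-flow
  survey values (heights 0.39/0.58/1.09 ± 0.15/0.15/0.24 mm, coverages
  70/20.2/9.8%).
- OCT volumes: sub-surface voxels are biomass (gray 131–250) or void
  (gray 0–119) per the target porosity, with 4% of voxels placed in the
  120–130 band so the two-threshold uncertainty band is exercised, a
  one-voxel biomass skin at the surface (OCT always returns signal at
  the interface; this biases layer porosity low by one voxel per layer,
  ≈ 0.015 at default settings), low-intensity noise above the surface
  and a gray-255 substrate plane. No speckle statistics or attenuation
  physics.
- Macrophotographs: flat per-type coloration (DDP elevated red/green,
  KDP elevated green) plus Gaussian noise (SD 10 gray levels).
- Velocimetry: a quadratic profile vanishing at the bottom with apex
  velocity u_bulk at 5 mm, 14 points, optional noise.
- O₂ transects: the forward model itself (flow + transport at known
  parameters) sampled at 50 µm vertical steps along 5 profile positions
  spanning the central 70% of the domain, plus i.i.d. Gaussian sensor
  noise; the generating parameters are recorded in the metadata.

Because forward transects come from the same solver that fitting uses,
recovery experiments are self-consistent ("inverse crime") by design:
they measure estimator and optimizer behaviour under noise, not model
misspecification. Passing them says nothing about structural error on
real sensor data.

## Known limitations

- 2D: flow cannot divert laterally around patches, so pressure
  differences across protruding structures — and hence internal
  velocities — are somewhat overestimated; fitted permeabilities absorb
  part of this.
- The constant-eddy-viscosity closure has no wall damping; wall shear
  and the derived δ and DBL scales use the full ν + ν_t at the surface
  and should be read as model-consistent scales, not literal boundary
  layer thicknesses.
- First-order upwinding (plus one deferred-correction pass) is diffusive
  at high cell Péclet numbers; Jc/Jd magnitudes are sensitive to this
  and to near-zero-gradient cells, which is why only orderings across
  conditions — not magnitudes — are treated as meaningful.
- Porosity is not identifiable from transect data (above); its fitted
  values are prior-dominated.
- The uniform-R metabolism has no light attenuation, nutrient limitation
  or depth structure.
- No sensor response-time deconvolution; no cross-correlation
  registration of macrophotographs to DEMs (alignment is assumed given).
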