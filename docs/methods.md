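# Methods

This note documents the models, numerical choices and limitations behind
`coarct`. The package reproduces, at workstation scale, a complete
simulate-then-surrogate workflow for coarctation of the aorta (CoA): a
lattice Boltzmann blood-flow solver, extraction of the clinical metrics ΔP
(trans-stenotic pressure gradient) and TAWSS (time-averaged wall shear
stress), a small neural-network surrogate that predicts those metrics from
physiological factors, and a design-of-experiments search for the smallest
set of simulations that trains an accurate per-patient surrogate.

## Geometry

Vessels are axisymmetric tubes with a cosine-shaped constriction. The
degree of stenosis (DoS) is defined as the fractional **diameter**
reduction at the throat: a 65% DoS tube narrows from diameter D to 0.35 D.
Diameter reduction is the convention of the clinical stenosis-grading
literature; an area-based reading would give a much milder throat
(area 12.25% vs 35% of reference for "65%"), and the two must not be
mixed. The cosine profile

    r(z) = R [1 − (dos/2)(1 + cos(2π (z − z_c)/s))],   |z − z_c| ≤ s/2

is C¹-continuous at the span edges and is the standard smooth benchmark
stenosis; patient CoA shapes are irregular, so results here characterize
the method, not any particular anatomy.

Geometries are voxelized on a node-centered Cartesian grid (a node is
fluid when its center lies inside the surface). With halfway bounce-back
the no-slip wall is realized midway between the outermost fluid nodes and
the adjacent solid nodes, so the *effective* hydraulic radius of a
staircase cylinder differs from the nominal radius by O(dx/2). Analytic
pipe-flow comparisons therefore use the area-equivalent lumen diameter
`D_eff = 2 sqrt(N dx²/π)` (N = fluid nodes per cross-section); against the
nominal diameter the ΔP error would be inflated by (D_eff/D)⁴. STL
surfaces are imported with trimesh and classified by an x-ray
parity-counting test (vectorized ray-triangle plane intersections), which
requires a closed manifold. The minimum supported resolution is 6 lattice
units across the stenosis throat; desk defaults resolve the throat with 8.

## Lattice Boltzmann solver

Single-relaxation-time (BGK) D3Q19 in double precision. Each step relaxes
the 19 per-node distributions toward the second-order low-Mach equilibrium
at rate 1/τ and streams them to neighbors (fused push-scheme kernel,
numba-compiled); wall links use halfway bounce-back, which together with
BGK conserves mass to round-off (verified to 1e-12 per step in a closed
box). Lattice pressure is the ideal-gas relation P = c_s² ρ with
c_s = 1/√3.

Unit bridge: the lattice viscosity ν_lb = c_s²(τ − ½) is matched to the
physical kinematic viscosity through the time step dt = dx² ν_lb/ν_phys.
Given dx and ν_phys, τ is chosen so the peak lattice velocity sits at a
target Mach number (default Ma = 0.05, cap 0.1), clipped to
τ ∈ [0.55, 1.0]; smaller dx or smaller τ lowers Ma, which is the
resolution/stability trade-off of the weakly compressible method.
Compressibility error is accepted and monitored (no incompressible
equilibrium correction); configurations over the Mach cap are rejected
before running.

One consequence of weak compressibility worth knowing when reading desk
results: pressure signals travel at the lattice sound speed, so an
imposed inflow pulse reaches interior planes with a physical delay of a
few steps, and the *volume* flux drifts slightly (~1%) along the duct
while the *mass* flux is exactly conserved. Mass-balance checks use mass
flux for this reason.

Desk scale: default runs resolve a 2 mm tube at dx = 87.5 μm (~2,000
steps per 0.7 s cardiac cycle, ~20 s per run on one core) with peak flows
of order mm³/s, giving throat Reynolds numbers of order 1–10. The
turbulent Re > 3,000 regime of a real exercising aorta is *not*
reachable at this scale; what the desk runs validate is the solver's
analytic limits and the plumbing of the full pipeline, not transitional
flow physics. Production-scale resolutions (50 μm on a 2 cm aorta) are
config-reachable but not defaults.

## Boundary conditions

Inlet: a parabolic (Poiseuille) velocity profile scaled each step to the
instantaneous waveform flow rate, imposed by a non-equilibrium
extrapolation closure (equilibrium at the imposed velocity plus the
neighbor node's non-equilibrium part). The discrete parabola is
renormalized so the node-summed flux equals the target exactly, and a slow
feedback gain (relaxation 0.05, clipped to [0.8, 1.25]) trims the
residual ~1–2% flux bias of the staircase cap; the achieved inflow then
matches the target within 1% steady and 2% pulsatile.

Outlet: the lumped resistance rule P_i = Q_i R_i, implemented on density
as ρ_i = Q_i R_i + 1 (ρ = 1 is zero gauge pressure). Q_i is measured from
the outward normal velocities of the outlet's own nodes each step and
exponentially smoothed (α = 0.1) to damp the acoustic startup transient.
Resistances are non-dimensionalized by R_lb = R_phys dx dt/(c_s² ρ_phys).
Multi-outlet manifolds split the outlet cap into equal angular sectors
(node rows falling exactly on a sector edge are alternated to keep the
discrete split balanced).

Calibration of outlet resistances to target flow fractions uses damped
multiplicative fixed-point iteration R_i ← R_i (q_i/t_i)^0.5 — raising an
outlet's resistance raises its pressure and lowers its flow share — and
converges to a 70/30 split within 2% in a handful of iterations on the
two-outlet fixture.

## Metrics

**Pressure.** Pressure *differences* convert exactly to physical units
(ΔP_phys = c_s² Δρ · ρ_phys dx²/dt²), and ΔP is computed that way.
Absolute lattice pressure is known only up to a constant; the
least-squares map fitted between the simulated inlet P_LB(t) and a
physiological reference pressure waveform at 20 evenly spaced cycle times
(rest preset anchored at 115/65 mmHg systolic/diastolic; a 140/80 stress
preset is provided as a representative exercise response) fixes that
constant and is recorded per run. The map is *not* used for ΔP itself: at
desk scale the per-run refit against a fixed-amplitude reference would
normalize away the flow dependence of the pressure field.

**ΔP** is the cross-section-averaged pressure difference between a plane
one inlet diameter proximal to the stenosis span and one diameter distal
to it, reported at peak systole (the time of maximum inlet flow; in
well-behaved runs also the cycle maximum). The plane rule is fixed and
config-overridable; the clinically standardized plane locations it stands
in for are not published coordinates.

**WSS** is assembled from non-equilibrium second moments,
σ_αβ = −(1 − 1/(2τ)) Σ_i c_iα c_iβ (f_i − f_i^eq), projected on the
stored wall normals; the tangential traction magnitude is converted to Pa
with ρ_phys dx²/dt². On the D = 20 lattice-unit Poiseuille tube this
reproduces 4 μ ū/R within 10%.

**TAWSS** is the trapezoidal cycle average of |WSS| from snapshots stored
every cycle/140 (a time-resolution choice balancing disk and quadrature
error). The analysis slice sits half an inlet diameter beyond the
stenosis span; it is divided into four quadrant sectors, sector 1
starting at +y and numbered clockwise viewed from upstream — an arbitrary
but fixed convention. Early-cycle WSS features are the circumferential
averages at t = 0.035, 0.07 and 0.105 s; stopping a rest-cycle run at the
last of these uses 15% of the 0.7 s cycle (25% of the 0.42 s exercise
cycle), which is what makes them attractive as cheap surrogate features.

## Waveforms

Patient PC-MRI waveforms are not shipped; a parametric two-harmonic pulse
(half-sine-squared systolic peak over the first third of the cycle plus a
low diastolic tail, continuous at the seam) stands in. The five-member
rest-to-exercise family scales a rest pulse (cycle 0.7 s) and a stress
pulse (0.42 s) so the five peak flows are evenly spaced over a configured
range — 1.51e5–4.03e5 mm³/s at aortic scale, giving a 6.3e4 mm³/s spacing
— with 3 rest-derived and 2 stress-derived members. Desk solver configs
use the same family shape with peaks of order mm³/s, preserving the
2.67× rest-to-exercise peak ratio; at desk dimensions this keeps the
Mach number in the stable range.

## Synthetic response surfaces

Production pulsatile aorta simulations (the real training data for the
surrogate study) need supercomputer resources, so the surrogate and DoE
layers are exercised against analytic stand-in surfaces with the
qualitative structure such data exhibits. ΔP uses the classical stenosis
loss: a Poiseuille viscous term (128 μ L Q/(π D⁴), linear in μQ) plus a
Borda–Carnot expansion term (quadratic in Q, scaled by
(1/(1−dos)² − 1)²). The loss coefficient (9.12e-4) was calibrated once so
the default flow range quadruples ΔP at dos = 0.65 and physiological
viscosity, then frozen. TAWSS is the Poiseuille wall shear at peak flow
with an inertial steepening factor, increasing in both μ and Q; early-WSS
features are fixed fractions (0.45/0.65/0.85) of TAWSS. Gaussian noise is
available but defaults to zero. At dos = 0 the ΔP surface is exactly
Poiseuille and is cross-checked against the LBM solver within 15%.

These surfaces are smooth and noiseless where the real data are turbulent
and noisy; DoE results on them (minimal sets of 7–8 pairings) bound the
easy-surface behavior and say nothing quantitative about how many runs a
real turbulent patient dataset needs — on harder surfaces the same search
returns larger sets. All synthetic outputs carry `source = "synthetic"`.

## Surrogate

A fully connected network with one hidden layer of ten ReLU units and a
linear output, trained on mean squared error. Inputs are standardized to
mean 0, sd 1 (population convention, divide by n) with training-set
statistics; the target is standardized internally for conditioning and
predictions return on the raw scale. Pearson R, the headline metric, is
affine-invariant, so the target convention is immaterial to it.

Optimizer: full-batch Adam (β = 0.9/0.999), step size 1e-2 decayed on a
cosine schedule to 1e-5 over at most 5,000 epochs, L2 penalty 1e-3, three
seeded restarts keeping the lowest monitored loss, early stopping with
patience 250 on the validation MSE when a validation set is given and on
the training MSE otherwise. All randomness derives from one seed, so
training is bit-reproducible. The weight decay and restarts are what make
a 10-unit ReLU net recover an exactly linear target to test R ≥ 0.9999:
an unpenalized interpolant of 40 points matches the data but wiggles
between them (test R ~0.998), and single-start Adam occasionally lands in
a poor basin. A plain fixed-step Adam at 1e-3 with tight early stopping
plateaus short of that bar, which is why those conventional defaults were
not kept.

Evaluation: Pearson R between predicted and simulated metrics, mean
absolute error, Bland–Altman bias and 1.96·sd limits of agreement
(sample sd, n−1), and seeded 5-fold cross-validation. A named experiment
preset applies the 70/10/20 train/validation/test split to 100-row
datasets.

## Design-of-experiments search

From a 50-run sweep (10 viscosities spanning 2.66–6.38 cP × 5 waveforms)
on one geometry, the search starts with a seeded 40/10 train/test split
and shrinks the training set one run at a time, while the best candidate
subset still reaches test R ≥ 0.98 on its complement. Candidates per
size: the first reduction enumerates all drop-one subsets of the current
training set (40 of them); later sizes enumerate every k-subset when
there are ≤ 1,000 and otherwise draw 1,000 random subsets. Ties break in
seeded evaluation order. The floor is 4 training rows (below that
standardization and fitting degenerate).

Candidate screening trains all subset models simultaneously (a vectorized
fixed-epoch trainer with the same architecture and recipe as the
reference trainer at a 1,000-epoch budget, best of 3 restarts) — this is
what makes 1,000 fits per size take seconds. Because the screening score
is a maximum over many noisy fits, the winning candidate at each size is
*verified* with independent full-budget fits under three training seeds
before the reduction is accepted; up to five screening winners are tried.
Without this step the recorded "minimal" set can be an artifact of one
lucky initialization and fails to reproduce its R when retrained. With
it, recorded sets retrain to within 0.01 of threshold by construction.

The transfer protocol reruns the minimal pairings on a new geometry with
the same DoS (emulated synthetically by jittering the response
coefficients ±10%), trains on those records, and evaluates R on 9
seeded-random distinct pairings — |minimal| + 9 runs per new geometry.

## Orchestration

YAML-configurable pipeline with three presets: `full_dp` (ΔP surrogate,
two-geometry 100-run dataset, 70/10/20), `tawss` (TAWSS surrogate with
and without early-WSS features) and `doe` (search plus transfer to two
perturbed geometries). Sweeps write metrics rows incrementally and are
resumable; per-run failures are recorded and the sweep continues. Reports
embed the config hash and seeds; identical config and seeds reproduce
identical reports.

## Problem sizes used in validation

The test and acceptance runs use: a D = 20 lattice-unit straight tube for
the analytic limits; 12-unit tubes for boundary-condition checks; a 65%
DoS desk vessel (2 mm diameter, dx = 87.5 μm, one cardiac cycle) for the
2 × 2 end-to-end sweep; the 10 × 5 noiseless synthetic grid for surrogate
and DoE runs. These sizes were chosen as the smallest at which each
analytic tolerance is met with margin.

## Known limitations

- Rigid walls, Newtonian rheology, single uniform resolution, BGK
  collision — all deliberate scope choices matching the modeled workflow.
- Desk Reynolds numbers are laminar; turbulent patient-scale flow is out
  of desk reach, and the synthetic surfaces are easier to learn than
  turbulent data (minimal-set sizes transfer qualitatively, not
  numerically).
- The staircase wall limits pipe-flow accuracy to a few percent at
  D = 20 lattice units; curved-boundary (interpolated bounce-back)
  schemes would improve this but are out of scope.
- Absolute pressures depend on the chosen reference waveform; only
  pressure differences are reference-free.
- Oscillatory shear index, vorticity, RCR (Windkessel) outlets and
  multi-branch aortic topologies are not implemented.
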