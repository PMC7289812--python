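# coarct

Desk-scale hemodynamics of **coarctation of the aorta (CoA)**: a D3Q19
lattice Boltzmann blood-flow solver, clinical metric extraction, a small
neural-network surrogate, and a design-of-experiments search for the
minimal simulation set that trains an accurate per-patient predictor.

## The problem

CoA is a congenital narrowing of the aorta. Its severity is graded by the
trans-stenotic pressure gradient ΔP (the primary surgical decision
metric) and by the time-averaged wall shear stress (TAWSS) downstream of
the stenosis, which correlates with plaque localization. Both depend
jointly on blood viscosity and flow rate — quantities that vary with
exercise, anemia, dehydration and other co-factors — so assessing a
patient's risk across conditions means sweeping a (viscosity, flow-rate)
parameter space with 3-D simulations. Each such simulation is expensive;
the practical question is **how few simulations suffice to train a
surrogate that predicts the rest**.

This package implements that whole workflow at a scale that runs on one
CPU core:

- **Solver** (`lbm_core`, `boundaries`, `geometry`): single-relaxation-time
  (BGK) D3Q19 lattice Boltzmann with halfway bounce-back walls, pulsatile
  parabolic velocity inlets, and resistance outlets ρ = Q·R + 1. The
  evolution equation is the standard BGK update
  `f_i(x + c_i Δt, t + Δt) − f_i(x, t) = −(1/τ)(f_i − f_i^eq)`,
  with pressure P = c_s²ρ and the time step set by the viscosity match
  δt = δx² ν_LB/ν_phys. Geometries are parametric cosine-stenosis tubes
  (degree of stenosis = fractional diameter reduction) or imported STL
  surfaces, voxelized to a Cartesian grid.
- **Metrics** (`metrics`): cross-section-averaged peak-systole ΔP, the
  least-squares lattice-to-mmHg pressure map, wall shear stress from
  non-equilibrium moments, TAWSS = (1/T)∫|WSS|dt on a four-sector slice
  distal to the stenosis, and early-cycle WSS features at t = 0.035,
  0.07, 0.105 s.
- **Surrogate** (`surrogate`): a ten-unit single-hidden-layer ReLU network
  (Adam, MSE, early stopping, standardized inputs) with Pearson-R,
  MAE and Bland–Altman evaluation and 5-fold cross-validation.
- **DoE search** (`doe`): shrink a 50-run sweep (10 viscosities spanning
  2.66–6.38 cP × 5 rest-to-exercise waveforms) one run at a time, keeping
  the best of up to 1,000 candidate training subsets per size, while the
  surrogate still reaches test R ≥ 0.98; then transfer the surviving
  viscosity–flow pairings to new geometries.
- **Synthetic stand-in** (`synthetic_response`): analytic stenosis
  pressure-loss and TAWSS surfaces (viscous + Borda–Carnot terms) that
  make the surrogate and DoE layers runnable in seconds, clearly labelled
  `synthetic` — production-scale patient simulations need supercomputer
  time and are out of desk scope.

## Worked example

Find the minimal training set on the synthetic 10 × 5 sweep:

```python
from coarct import synthetic_response as sr
from coarct.doe import default_grid, minimal_set_search

grid = default_grid()                      # 10 viscosities x 5 waveforms
data = sr.generate_dataset(grid, sr.ResponseParams(), seed=0)
result = minimal_set_search(data, threshold=0.98, seed=1)
print(f"minimal set: {result.size} pairings, test R = {result.best_r:.4f}")
for v, w in result.pairings[:3]:
    print(f"  viscosity {v:.2f} cP, waveform {w}")
```

prints

```
minimal set: 8 pairings, test R = 0.9817
  viscosity 2.66 cP, waveform rest_0
  viscosity 2.66 cP, waveform stress_4
  viscosity 3.90 cP, waveform stress_4
```

i.e. of the 50 sweep runs, 8 carefully chosen viscosity–flow pairings
train a surrogate that predicts ΔP for the other 42 with correlation
0.98; `result.r_trace` records the best test R at every training-set
size on the way down. The surviving pairings concentrate on the corners
of the (viscosity, flow) grid, which is what a design-of-experiments
intuition would predict for a smooth response.

The same machinery runs against the real solver: `coarct sweep` executes
each (viscosity, waveform) pairing for one cardiac cycle on a voxelized
stenosed tube and writes a metrics CSV (ΔP in mmHg, TAWSS and sector
TAWSS in Pa, early-WSS features), which `minimal_set_search` consumes
unchanged. CLI entry points: `coarct geometry`, `coarct sweep`,
`coarct synth`, `coarct train --preset {full_dp,tawss,doe}`,
`coarct doe search|transfer`.

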