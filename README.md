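# solidstress

Mapping residual solid stress in soft tissue from slice deformation, plus
unconfined-compression viscoelastic analysis — with synthetic ground
truth for end-to-end validation.

Residual (solid) stresses are mechanical stresses stored in a tissue's
solid phase that persist without external load.  They can be revealed by
slicing: a thin slice cut from a stressed organ (brain being a prominent
example) deforms out of plane once confinement is released.  Imaged in
3D by fluorescence microscopy, the relaxed slice's surface geometry
quantifies the released stress.  This package is for experimentalists
who have such stacks (and/or Instron-style compression traces) and want
reproducible, unit-aware indices and statistics out of them.

## What it computes

From a stack, the slice surface is reconstructed as a height field
z(x, y) over the tissue footprint, then reduced to three stress indices:

- **D_n** — normalized deformation, `mean |z − z̄|` (µm),
- **R_a** — area ratio `A_s / A_p` ≥ 1 (true vs projected surface area),
- **K_m** — mean absolute Monge-patch mean curvature
  `mean |(κ1 + κ2)/2|` (mm⁻¹),

together with per-pixel deformation and curvature maps.  From a
force–displacement–time trace of a 4-step ramp-hold compression test it
fits σ = Eε + C (Young's modulus), the instantaneous/equilibrium
modulus ratio R_s = σ_max/σ_eq per step, and the bi-exponential
relaxation σ(t) = a1·e^(−t/τ_fast) + a2·e^(−t/τ_slow) + b.  A statistics
layer provides Welch/Student t-tests, one-way ANOVA, anterior–posterior
slope trends, and mean ± SEM report tables.

Every stage has a synthetic ground-truth generator (analytic surfaces
rendered into stacks; traces with known E, R_s, τ), and an independent
quadrature oracle computes the indices from closed forms so the image
pipeline can be validated without any raw study data.  See
`docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

A spherical-cap slice (sphere radius R = 1000 µm, outline radius
a = 500 µm) rendered at SNR 10 and pushed through the full pipeline,
against the analytic oracle:

```python
from solidstress import (SliceShapeSpec, StackRenderSpec, TraceSimSpec,
                         make_height_field, render_stack, compute_indices,
                         oracle_indices, simulate_trace, analyze_trace)

cap = SliceShapeSpec(shape_kind="spherical_cap", amplitude_or_radius=1000, outline_radius=500)
stack = render_stack(make_height_field(cap, resolution=10.0),
                     StackRenderSpec(noise_sd=90.0, seed=0))
idx, maps = compute_indices(stack)
oracle = oracle_indices(cap)
print(f"D_n = {idx.dn_um:.2f} um   (oracle {oracle.dn_um:.2f})")
print(f"R_a = {idx.ra:.4f}     (oracle {oracle.ra:.4f})")
print(f"K_m = {idx.km_per_mm:.4f} 1/mm (oracle {oracle.km_per_mm:.4f})")

fit = analyze_trace(simulate_trace(TraceSimSpec(E_true=5.0, Rs_true=1.8,
                                                noise_sd=0.036, seed=0)))
print(f"E = {fit.E:.3f} kPa, Rs = {fit.rs_mean:.3f}, "
      f"tau_fast = {fit.relaxation_joint.tau_fast:.2f} s, "
      f"tau_slow = {fit.relaxation_joint.tau_slow:.1f} s")
```

prints

```
D_n = 33.43 um   (oracle 33.45)
R_a = 1.0720     (oracle 1.0718)
K_m = 1.0082 1/mm (oracle 1.0000)
E = 5.032 kPa, Rs = 1.853, tau_fast = 1.92 s, tau_slow = 60.0 s
```

The cap's true values are K_m = 1/R = 1 mm⁻¹ and R_a = 2Rh/a² ≈ 1.0718:
even with noise at SNR 10 the pipeline recovers all three indices to
≈1%.  The compression fit recovers the generating parameters (5 kPa,
1.8, 2 s, 60 s) from a trace with 2%-of-peak noise.

A command-line interface wraps the same operations:

```bash
solidstress simulate --shape spherical_cap --out sim/ --seed 1
solidstress indices sim/stack.tif --out indices.csv
solidstress simulate-trace --out trace.csv
solidstress rheology trace.csv --out rheo/
solidstress compare indices_groupA.csv indices_groupB.csv --out report/
```

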