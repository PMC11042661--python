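# Methods

## Scope and model

`solidstress` quantifies residual solid stress in soft-tissue slices and
the bulk viscoelastic behaviour of the same tissues.  The measurement
principle: a thin slice (≈250 µm) cut from a stressed organ deforms out
of plane once its confinement is released; the deformed slice, fixed and
imaged as a 3D fluorescence stack, carries the stress signature in its
surface geometry.  The package reconstructs that surface as a Monge
patch z(x, y) over a tissue-footprint mask and reduces it to three
indices:

- **Normalized deformation** `D_n = (1/N) Σ_k |z_k − z̄|` (µm), with `z̄`
  the mean height over the mask — the mean absolute deviation of the
  surface from its mid-plane.
- **Area ratio** `R_a = A_s / A_p` (≥ 1), the true surface area
  `A_s = Σ √(1 + z_x² + z_y²) dx dy` over the projected footprint area
  `A_p`.
- **Mean-curvature index** `K_m = (1/N) Σ_k |(κ1 + κ2)/2|` (reported in
  mm⁻¹, computed in µm⁻¹), using the closed-form Monge-patch mean
  curvature
  `H = [(1 + z_y²) z_xx − 2 z_x z_y z_xy + (1 + z_x²) z_yy] / [2 (1 + z_x² + z_y²)^{3/2}]`.

All three depend on z only through z − z̄ and through even functions of
the derivatives, so they are exactly invariant to rigid translation and
to physically flipping the slice (z → −z with x mirrored).  The flip
invariance doubles as the buoyancy control: a measurement artifact that
depended on which face of the slice points up would break it.

### Assumptions

- **Single-valued surface.**  The slice bends but does not fold over.
  Columns of the stack whose thresholded intensity forms more than one
  bright run indicate folding; their fraction is reported in the height
  field's provenance (`multi_run_column_frac`) as a warning metric
  rather than silently averaged.
- **Thin-sheet geometry.**  The digitized surface is the intensity-
  weighted midsurface of the bright sheet (`centroid` method, default).
  `max` (brightest voxel) and `top` (upper envelope) are available; the
  midsurface is preferred because it is symmetric under flipping and
  does not bias indices by half the slice thickness where the slice
  tilts.  Which surface the maps describe is always recorded in
  provenance.

## Surface reconstruction

1. **Segmentation** — Otsu threshold on the maximum-intensity
   projection, hole filling, removal of components below
   `min_object_area` (default 10⁴ µm²), largest connected component.
2. **Height extraction** — per masked column, the chosen surface
   statistic of the above-threshold voxels; columns with no bright voxel
   are in-filled from the nearest valid neighbour and counted (more than
   10% failing is an error).
3. **Smoothing** — in-plane Gaussian of width `smoothing_scale`
   (default: 2 in-plane pixels, i.e. 20 µm at the default 10 µm grid).
   Before smoothing, z is extended beyond the mask by first-order Taylor
   extrapolation along the boundary gradient; constant extension would
   flatten the boundary slope and corrupt curvature in a band of width
   ≈3σ inside the mask.

Curvature is scale dependent, so K_m values are comparable only within a
fixed `smoothing_scale`; the scale used is part of every result.

### Derivative stencils

First derivatives for `A_s` use centred differences where both
neighbours lie in the mask and one-sided differences at the boundary.
Curvature uses centred 3×3 stencils and is averaged only over the mask
eroded by that stencil, so no partially supported pixel contributes; the
excluded count is reported (`n_curvature_pixels`).

### Area normalization

For spatial-trend analysis the dimensionless variants `D_n/√A_p` and
`K_m·√A_p` are always computed alongside the raw indices (fields
`dn_area_norm`, `km_area_norm`).  The exact normalization convention for
slice-size variation is not uniquely determined by the printed index
definitions, so both raw and normalized values are written and the mode
is flagged; no single convention is silently treated as canonical.

## Synthetic ground truth

`synthetic` renders slices with analytically known geometry (flat,
spherical cap, sinusoid, composite; disk or seeded Fourier-blob
outlines; optional rigid tilt) into stacks, and `oracle_indices`
evaluates D_n, R_a, K_m by dense quadrature on the *analytic* surface
using closed-form derivatives — no images, no finite differences — so
the oracle shares no code path with the pipeline it validates.  At its
default 2 µm quadrature resolution the oracle is converged to ≲0.1%.

Rendering defaults: 10×10×5 µm voxels, foreground 1000, background 100
(arbitrary units), additive Gaussian noise of configurable SD (SNR 10
means (fg − bg)/σ = 10), partial-volume anti-aliasing at the sheet
boundary (a straddling voxel's intensity is proportional to its overlap
with the sheet, as in real imaging; a hard binary assignment is
available with `antialias=False`).  What the generator does **not**
emulate: optical PSF blur, depth attenuation, Poisson photon statistics,
agarose autofluorescence, multi-channel bleed-through.  Passing tests
therefore certify the geometry pipeline, not robustness to every optical
artifact of a real confocal stack.

## Compression rheology

Specimens are cylinders (defaults: 6 mm punch diameter, 2 mm thickness)
compressed in `n_steps` = 4 ramp-hold steps of 5% strain each (1 s
ramps, 180 s holds).  Conversions: σ = F/(π(d/2)²) in kPa,
ε = displacement/thickness, compression positive.

- **Segmentation**: ramps found by displacement-rate thresholding (20%
  of the peak rate); each hold runs to the next ramp's start.  A wrong
  step count is an error listing the detected ramp times.
- **Young's modulus**: OLS of per-step equilibrium stress (mean of the
  final 10% of each hold, configurable) on strain, σ = Eε + C.  A
  linear law is used deliberately; it holds well within 20% strain.
- **Rate-dependent stiffening**: R_s = σ_max/σ_eq per step, σ_max taken
  as the peak over ramp + hold (`ramp_peak`, default) or the first hold
  sample (`hold_start`); at 1 s ramps the two differ negligibly.
- **Relaxation**: σ(t) = a1·e^(−t/τ_fast) + a2·e^(−t/τ_slow) + b fitted
  per hold by bounded nonlinear least squares with multistart
  (b starts at σ_eq; the excess split {0.25, 0.5, 0.75} between
  exponentials; τ starts log-spaced over [0.01, 1] × hold duration,
  crossed with τ_fast < τ_slow; best residual wins, ties to the smaller
  τ_slow).  a1, a2, b are bounded ≥ 0: negative amplitudes indicate
  mis-segmentation and must surface as failure, not as numbers.
  τ_fast < τ_slow is enforced by reordering after the fit.  Degenerate
  fits (vanishing amplitude, τ ratio < 1.2) are flagged, and an AIC
  comparison against a single-exponential fit is attached.
- **Per-specimen time constants** come from a joint fit sharing τ_fast
  and τ_slow across all holds (amplitudes and offsets free), since the
  time constants are material properties; per-step fits are also
  reported to expose strain dependence.

Each hold is fitted independently of the loading history (no Boltzmann
superposition) — a simplification that mirrors per-step reporting and is
exact for the synthetic generator.

### Generator conventions

The trace generator defines `E_true` and `Rs_true` against the same
equilibrium estimator the analysis uses (mean of the final 10% of the
hold), not the t→∞ asymptote.  With τ_slow = 60 s and a 180 s hold the
slow exponential retains ≈5% of its amplitude at the window, so an
asymptote-based definition would bias even noiseless recovery by ≈2%;
the operational definition makes noiseless recovery exact and keeps
"what the generator promises" and "what the analysis measures"
consistent.  `offset_b_frac=None` (default) chooses the self-consistent
offset; setting it forces b = offset_b_frac·σ_eq as a robustness knob.
The transient is split 50/50 between the two exponentials by default
(`amp_split_fast`); sampling is 10 Hz, which resolves the 2 s fast
constant with ≈20 samples per time constant.

## Statistics

Two-group comparisons: two-tailed t-test, Welch's unequal-variance form
by default (robust across age groups with different spread), Student's
pooled form as an option; the form used is recorded.  Groups below n = 3
are rejected.  Multi-group: one-way ANOVA.  Spatial trends: OLS of an
index on anterior–posterior position within fixed windows (defaults
0–1000, 1000–2250, 2250–4250 µm), reporting slope, SE, and the two-sided
p for zero slope; area-normalized indices are the intended input.
Summaries are mean ± SEM (SD/√n).  No multiple-testing correction by
default; `holm_correction` is available.  The unit of analysis (mouse
vs slice) is whatever the metadata grouping encodes — it is never
inferred.

Degenerate cases are explicit: ANOVA on groups with zero variance and
equal means reports F = 0, p = 1 with a flag rather than NaN.

## Numerical choices and problem sizes

Validation runs at desk scale: 10 µm in-plane grids (≈7,800 masked
pixels for the 500 µm disk outline), 20-seed noise ensembles, 100
simulated traces for noisy parameter recovery, 2,000 null simulations
for slope-test calibration, 50 random datasets for the statistical
cross-checks.  Tolerances used in validation: pipeline vs oracle within
2% noiseless and 5% median at SNR 10; sphere curvature and tilted-plane
area laws within 0.5%; flip invariance to 6 significant figures;
noiseless viscoelastic recovery within 1%, noisy medians within 5%;
statistics against independent closed forms to 1e-10 relative.

## Known limitations

- Folded (non-Monge) slices are detected and reported, not analyzed.
- K_m is comparable only at a fixed smoothing scale; no scale-free
  curvature index is attempted.
- The stress indices are geometric proxies; no inverse computation of a
  stress tensor in kPa is performed.
- The viscoelastic model is linear-elastic plus two exponentials; no
  poroelastic/biphasic or hyperelastic fitting.
- Real-image nuisances not in the generator (PSF, attenuation, Poisson
  noise) are untested by construction.
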