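"""Ground-truth generators for the whole pipeline.

Two families of synthetic data mirror the study's measurements:

* thin curved fluorescent sheets (a ~250 µm slice deformed out of plane)
  rendered into 3D stacks with additive Gaussian noise — ground truth for
  segmentation, surface reconstruction and the stress indices; and
* 4-step ramp-hold unconfined-compression traces following a linear
  elastic law with a bi-exponential relaxation transient — ground truth
  for the viscoelastic fits.

Every generator is deterministic given its seed.  ``oracle_indices``
computes D_n, R_a and K_m by dense quadrature on the *analytic* surface
(closed-form derivatives, no images, no finite differences), so it is an
independent oracle for the image-based pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageStack3D, RelaxationTrace
from .surface import HeightField


# --------------------------------------------------------------------------
# slice shapes
# --------------------------------------------------------------------------

_SHAPE_KINDS = ("flat", "spherical_cap", "sinusoid", "composite")
_OUTLINE_KINDS = ("disk", "blob")


@dataclass
class SliceShapeSpec:
    """Analytic description of a deformed-slice surface.

    ``amplitude_or_radius`` is the sinusoid amplitude (µm) or the sphere
    radius (µm) depending on ``shape_kind``; ``outline_radius`` is the
    characteristic in-plane radius of the tissue footprint.  ``tilt`` adds
    a rigid plane of slope tan(tilt) along x.  ``composite`` superposes a
    spherical cap and a sinusoidal ripple of ``ripple_amplitude``.
    """

    shape_kind: str = "spherical_cap"
    amplitude_or_radius: float = 1000.0
    wavelength: float = 800.0
    outline: str = "disk"
    outline_radius: float = 500.0
    thickness: float = 250.0
    tilt: float = 0.0
    ripple_amplitude: float = 25.0
    blob_irregularity: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_kind not in _SHAPE_KINDS:
            raise ValueError(f"shape_kind must be one of {_SHAPE_KINDS}")
        if self.outline not in _OUTLINE_KINDS:
            raise ValueError(f"outline must be one of {_OUTLINE_KINDS}")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if self.outline_radius <= 0:
            raise ValueError("outline radius must be > 0")
        if self.shape_kind in ("spherical_cap", "composite"):
            if self.amplitude_or_radius <= 0:
                raise ValueError("sphere radius must be > 0")
            if self._max_outline_radius() > self.amplitude_or_radius:
                raise ValueError(
                    "spherical cap would exceed a hemisphere: outline radius "
                    f"{self._max_outline_radius():.1f} µm > sphere radius "
                    f"{self.amplitude_or_radius:.1f} µm"
                )
        if self.shape_kind in ("sinusoid", "composite") and self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")

    # -- outline ----------------------------------------------------------
    def _blob_modes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        ks = np.arange(2, 6)
        amps = self.blob_irregularity * rng.uniform(0.3, 1.0, size=ks.size) / np.sqrt(ks)
        phases = rng.uniform(0, 2 * np.pi, size=ks.size)
        return ks, amps, phases

    def boundary_radius(self, theta: np.ndarray) -> np.ndarray:
        """Outline radius r(θ): a disk, or a seeded low-order Fourier blob."""
        if self.outline == "disk":
            return np.full_like(np.asarray(theta, dtype=float), self.outline_radius)
        ks, amps, phases = self._blob_modes()
        pert = sum(a * np.cos(k * theta + p) for k, a, p in zip(ks, amps, phases))
        return self.outline_radius * (1.0 + pert)

    def _max_outline_radius(self) -> float:
        if self.outline == "disk":
            return self.outline_radius
        _, amps, _ = self._blob_modes()
        return self.outline_radius * (1.0 + float(amps.sum()))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r = np.hypot(x, y)
        theta = np.arctan2(y, x)
        return r <= self.boundary_radius(theta)

    # -- surface and closed-form derivatives ------------------------------
    def surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        z = np.zeros(np.broadcast(x, y).shape, dtype=float)
        if self.shape_kind in ("spherical_cap", "composite"):
            r2 = self.amplitude_or_radius**2
            a = self._max_outline_radius()
            # radicand clipped so grid corners beyond the sphere's equator
            # (always outside the outline mask) stay finite
            z = z + np.sqrt(np.maximum(r2 - x**2 - y**2, 0.0)) - math.sqrt(r2 - a**2)
        if self.shape_kind == "sinusoid":
            z = z + self.amplitude_or_radius * np.sin(2 * np.pi * x / self.wavelength)
        if self.shape_kind == "composite":
            z = z + self.ripple_amplitude * np.sin(2 * np.pi * x / self.wavelength)
        if self.tilt:
            z = z + math.tan(self.tilt) * x
        return z

    def derivatives(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Analytic (z_x, z_y, z_xx, z_yy, z_xy)."""
        shape = np.broadcast(x, y).shape
        zx = np.zeros(shape)
        zy = np.zeros(shape)
        zxx = np.zeros(shape)
        zyy = np.zeros(shape)
        zxy = np.zeros(shape)
        if self.shape_kind in ("spherical_cap", "composite"):
            s = np.sqrt(self.amplitude_or_radius**2 - x**2 - y**2)
            zx = zx - x / s
            zy = zy - y / s
            zxx = zxx - 1 / s - x**2 / s**3
            zyy = zyy - 1 / s - y**2 / s**3
            zxy = zxy - x * y / s**3
        if self.shape_kind in ("sinusoid", "composite"):
            amp = self.amplitude_or_radius if self.shape_kind == "sinusoid" else self.ripple_amplitude
            k = 2 * np.pi / self.wavelength
            zx = zx + amp * k * np.cos(k * x)
            zxx = zxx - amp * k**2 * np.sin(k * x)
        if self.tilt:
            zx = zx + math.tan(self.tilt)
        return zx, zy, zxx, zyy, zxy


def _grid(spec: SliceShapeSpec, resolution: float) -> tuple[np.ndarray, np.ndarray]:
    half = 1.3 * spec._max_outline_radius()
    n = int(np.ceil(2 * half / resolution)) | 1  # odd: a pixel sits on the centre
    coords = (np.arange(n) - (n - 1) / 2) * resolution
    return np.meshgrid(coords, coords)  # x varies along axis 1


def make_height_field(spec: SliceShapeSpec, resolution: float = 10.0) -> HeightField:
    """Sample the analytic surface on a regular grid with its outline mask."""
    x, y = _grid(spec, resolution)
    mask = spec.contains(x, y)
    z = spec.surface(x, y)
    return HeightField(
        z=z,
        mask=mask,
        pixel_spacing=(resolution, resolution),
        provenance={"surface_method": "analytic", "shape_kind": spec.shape_kind, "seed": spec.seed},
    )


def oracle_indices(spec: SliceShapeSpec, resolution: float = 2.0):
    """D_n, R_a, K_m by dense quadrature on the analytic surface.

    Uses the closed-form Monge-patch mean curvature from the analytic
    partial derivatives — no image rendering, no finite differences —
    so it is an independent oracle for the image-based pipeline.
    Converges as ``resolution`` → 0.
    """
    from .indices import StressIndices, monge_mean_curvature

    x, y = _grid(spec, resolution)
    mask = spec.contains(x, y)
    xm, ym = x[mask], y[mask]
    z = spec.surface(xm, ym)
    zx, zy, zxx, zyy, zxy = spec.derivatives(xm, ym)
    dn = float(np.abs(z - z.mean()).mean())
    integrand = np.sqrt(1 + zx**2 + zy**2)
    a_p = float(mask.sum() * resolution**2)
    a_s = float(integrand.sum() * resolution**2)
    h = monge_mean_curvature(zx, zy, zxx, zyy, zxy)
    km = float(np.abs(h).mean())
    return StressIndices(
        dn_um=dn,
        ra=a_s / a_p,
        km_per_um=km,
        a_s_um2=a_s,
        a_p_um2=a_p,
        z_bar_um=float(z.mean()),
        n_pixels=int(mask.sum()),
        n_curvature_pixels=int(mask.sum()),
        dn_area_norm=dn / np.sqrt(a_p),
        km_area_norm=km * np.sqrt(a_p),
        provenance={"surface_method": "analytic_quadrature", "resolution_um": resolution},
    )


# --------------------------------------------------------------------------
# stack rendering
# --------------------------------------------------------------------------

@dataclass
class StackRenderSpec:
    """How to voxelize a height field into a fluorescence stack.

    ``voxel_spacing`` is (dx, dy, dz) µm; in-plane spacing must match the
    height field's grid.  ``n_z`` of None auto-fits the volume with a
    5-voxel margin above and below the sheet.  With ``antialias`` (the
    default) a voxel that straddles the sheet boundary gets an intensity
    proportional to its overlap with the sheet, emulating the partial-
    volume effect of a real voxel; ``antialias=False`` gives a hard
    binary assignment.
    """

    voxel_spacing: tuple[float, float, float] = (10.0, 10.0, 5.0)
    n_z: int | None = None
    foreground_intensity: float = 1000.0
    background_intensity: float = 100.0
    noise_sd: float = 0.0
    antialias: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be > 0")
        if self.foreground_intensity <= self.background_intensity:
            raise ValueError("foreground_intensity must exceed background_intensity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def render_stack(
    hf: HeightField, spec: StackRenderSpec, thickness: float = 250.0
) -> ImageStack3D:
    """Voxelize a sheet of ``thickness`` µm centred on the surface.

    A voxel is foreground when its z centre lies within thickness/2 of the
    surface over a masked column; independent Gaussian noise of
    ``noise_sd`` is added everywhere.  The surface plus margin must fit
    in the volume (≥ 3 voxels of z clearance).
    """
    dx, dy, dz = spec.voxel_spacing
    if not np.allclose((dx, dy), hf.pixel_spacing):
        raise ValueError(
            f"in-plane voxel spacing {dx, dy} must match the height field's {hf.pixel_spacing}"
        )
    z_vals = hf.z[hf.mask]
    z_lo = z_vals.min() - thickness / 2
    z_hi = z_vals.max() + thickness / 2
    margin = 3 * dz
    if spec.n_z is None:
        n_z = int(np.ceil((z_hi - z_lo + 2 * (margin + 2 * dz)) / dz))
    else:
        n_z = spec.n_z
        if (n_z - 1) * dz < (z_hi - z_lo) + 2 * margin:
            raise ValueError(
                f"surface exits volume: needs {(z_hi - z_lo) + 2 * margin:.0f} µm in z "
                f"but n_z={n_z} at dz={dz} gives {(n_z - 1) * dz:.0f} µm"
            )
    origin = (z_lo + z_hi) / 2 - (n_z - 1) / 2 * dz
    zc = origin + np.arange(n_z) * dz
    if spec.antialias:
        # fraction of the voxel's z extent covered by the sheet
        top = np.minimum(zc[:, None, None] + dz / 2, hf.z[None, :, :] + thickness / 2)
        bot = np.maximum(zc[:, None, None] - dz / 2, hf.z[None, :, :] - thickness / 2)
        frac = np.clip((top - bot) / dz, 0.0, 1.0) * hf.mask[None, :, :]
    else:
        dist = np.abs(zc[:, None, None] - hf.z[None, :, :])
        frac = ((dist <= thickness / 2) & hf.mask[None, :, :]).astype(float)
    vol = spec.background_intensity + (spec.foreground_intensity - spec.background_intensity) * frac
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    return ImageStack3D(intensities=vol, voxel_spacing=(dx, dy, dz), channel_label="synthetic")


def make_random_height_field(
    seed: int,
    outline_radius: float = 500.0,
    resolution: float = 10.0,
    amplitude: float = 60.0,
    correlation_length: float = 150.0,
) -> HeightField:
    """Smooth random surface on a blob outline, for invariance testing."""
    spec = SliceShapeSpec(
        shape_kind="flat", outline="blob", outline_radius=outline_radius, seed=seed
    )
    hf = make_height_field(spec, resolution=resolution)
    rng = np.random.default_rng(seed + 7919)
    noise = rng.normal(size=hf.z.shape)
    sigma = correlation_length / resolution
    smooth = ndimage.gaussian_filter(noise, sigma)
    smooth *= amplitude / max(smooth.std(), 1e-12)
    return HeightField(
        z=smooth, mask=hf.mask, pixel_spacing=hf.pixel_spacing,
        provenance={"surface_method": "random", "seed": seed},
    )


# --------------------------------------------------------------------------
# compression traces
# --------------------------------------------------------------------------

@dataclass
class TraceSimSpec:
    """Ramp-hold compression protocol with known mechanical parameters.

    Defaults follow the measurement protocol: four 5%-strain steps, 1 s
    ramps, 3 min holds, a 6 mm punch of 2 mm thickness.  The hold-phase
    stress follows a1·exp(−t/τ_fast) + a2·exp(−t/τ_slow) + b with the
    transient split ``amp_split_fast``/(1−``amp_split_fast``) between the
    exponentials.  E_true and Rs_true are defined against the same
    equilibrium estimator the analysis uses (mean of the final
    ``eq_window_frac`` of each hold), so noiseless recovery is exact.
    ``offset_b_frac`` of None chooses the self-consistent offset; setting
    it forces b = offset_b_frac × equilibrium stress instead.
    """

    E_true: float = 5.0            # kPa
    Rs_true: float = 1.8           # ≥ 1
    tau_fast_true: float = 2.0     # s
    tau_slow_true: float = 60.0    # s
    offset_b_frac: float | None = None
    amp_split_fast: float = 0.5
    n_steps: int = 4
    strain_per_step: float = 0.05
    ramp_duration: float = 1.0     # s
    hold_duration: float = 180.0   # s
    sample_rate: float = 10.0      # Hz
    noise_sd: float = 0.0          # kPa, on stress
    specimen_diameter: float = 6.0  # mm
    specimen_thickness: float = 2.0  # mm
    eq_window_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_fast_true >= self.tau_slow_true:
            raise ValueError("tau_fast_true must be < tau_slow_true")
        if self.Rs_true < 1:
            raise ValueError("Rs_true must be >= 1")
        if self.n_steps * self.strain_per_step >= 1:
            raise ValueError("cumulative strain must be < 1")
        if not 0 <= self.amp_split_fast <= 1:
            raise ValueError("amp_split_fast must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _window_mean_exp(tau: float, t1: float, t2: float) -> float:
    """Mean of exp(-t/tau) over [t1, t2]."""
    return tau * (math.exp(-t1 / tau) - math.exp(-t2 / tau)) / (t2 - t1)


def simulate_trace(spec: TraceSimSpec) -> RelaxationTrace:
    """Simulate a staircase compression trace with known parameters."""
    dt = 1.0 / spec.sample_rate
    step_t = spec.ramp_duration + spec.hold_duration
    total = spec.n_steps * step_t
    t = np.arange(0.0, total + dt / 2, dt)
    disp = np.zeros_like(t)
    stress = np.zeros_like(t)

    f = spec.amp_split_fast
    t1 = (1 - spec.eq_window_frac) * spec.hold_duration
    g = f * _window_mean_exp(spec.tau_fast_true, t1, spec.hold_duration) + (1 - f) * _window_mean_exp(
        spec.tau_slow_true, t1, spec.hold_duration
    )

    d_step = spec.strain_per_step * spec.specimen_thickness
    sigma_end_prev = 0.0
    for i in range(1, spec.n_steps + 1):
        eps = i * spec.strain_per_step
        sigma_eq = spec.E_true * eps
        if spec.offset_b_frac is None:
            amp = (spec.Rs_true - 1) * sigma_eq / (1 - g)
            b = sigma_eq - amp * g
        else:
            b = spec.offset_b_frac * sigma_eq
            amp = spec.Rs_true * sigma_eq - b
        if amp < 0:
            raise ValueError("offset_b_frac too large: transient amplitude would be negative")
        a1, a2 = f * amp, (1 - f) * amp
        peak = b + amp

        t0 = (i - 1) * step_t
        ramp = (t >= t0) & (t < t0 + spec.ramp_duration)
        hold = (t >= t0 + spec.ramp_duration) & (t <= t0 + step_t + dt / 4)
        frac = (t[ramp] - t0) / spec.ramp_duration
        disp[ramp] = (i - 1) * d_step + frac * d_step
        disp[hold] = i * d_step
        stress[ramp] = sigma_end_prev + frac * (peak - sigma_end_prev)
        th = t[hold] - (t0 + spec.ramp_duration)
        stress[hold] = a1 * np.exp(-th / spec.tau_fast_true) + a2 * np.exp(-th / spec.tau_slow_true) + b
        sigma_end_prev = float(stress[hold][-1]) if hold.any() else peak

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + rng.normal(0.0, spec.noise_sd, size=stress.shape)

    area_mm2 = np.pi * (spec.specimen_diameter / 2) ** 2
    force = stress * area_mm2 * 1e-3  # kPa (=1e3 Pa) × mm² (=1e-6 m²) → N
    return RelaxationTrace(
        time=t,
        displacement=disp,
        force=force,
        specimen_diameter=spec.specimen_diameter,
        specimen_thickness=spec.specimen_thickness,
    )
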