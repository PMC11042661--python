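"""Generators: closed-form shapes, the quadrature oracle, rendering, traces."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from solidstress import (
    SliceShapeSpec,
    StackRenderSpec,
    TraceSimSpec,
    make_height_field,
    oracle_indices,
    render_stack,
    simulate_trace,
    to_stress_strain,
)
from conftest import CAP_RADIUS_UM, OUTLINE_RADIUS_UM, render_shape

# sinusoid A=50 µm, λ=800 µm, disk a=500 µm: frozen from the quadrature
# oracle at its default resolution before the pipeline was built
SIN_ORACLE_DN = 30.6359730723559
SIN_ORACLE_RA = 1.0394960842414205
SIN_ORACLE_KM = 8.764539159001572e-4


class TestSliceShapes:
    def test_flat_surface_is_zero_on_mask(self):
        hf = make_height_field(SliceShapeSpec(shape_kind="flat"), resolution=10.0)
        assert np.allclose(hf.z[hf.mask], 0.0)

    def test_spherical_cap_matches_closed_form(self, cap_spec):
        hf = make_height_field(cap_spec, resolution=10.0)
        n = hf.z.shape[0]
        coords = (np.arange(n) - (n - 1) / 2) * 10.0
        x, y = np.meshgrid(coords, coords)
        R, a = CAP_RADIUS_UM, OUTLINE_RADIUS_UM
        expected = np.sqrt(R**2 - x**2 - y**2) - math.sqrt(R**2 - a**2)
        assert np.allclose(hf.z[hf.mask], expected[hf.mask])

    def test_sinusoid_matches_closed_form(self, sin_spec):
        hf = make_height_field(sin_spec, resolution=10.0)
        n = hf.z.shape[0]
        x = np.tile((np.arange(n) - (n - 1) / 2) * 10.0, (n, 1))
        expected = 50.0 * np.sin(2 * np.pi * x / 800.0)
        assert np.allclose(hf.z[hf.mask], expected[hf.mask])

    def test_cap_exceeding_hemisphere_rejected(self):
        with pytest.raises(ValueError, match="hemisphere"):
            SliceShapeSpec(
                shape_kind="spherical_cap", amplitude_or_radius=400.0, outline_radius=500.0
            )

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"thickness": 0.0}, "thickness"),
            ({"outline_radius": -5.0}, "outline radius"),
            ({"shape_kind": "sinusoid", "wavelength": 0.0}, "wavelength"),
        ],
    )
    def test_invalid_shape_parameters_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            SliceShapeSpec(**kwargs)

    def test_blob_outline_is_seeded_and_irregular(self):
        spec_a = SliceShapeSpec(shape_kind="flat", outline="blob", seed=1)
        spec_b = SliceShapeSpec(shape_kind="flat", outline="blob", seed=2)
        theta = np.linspace(0, 2 * np.pi, 64)
        ra = spec_a.boundary_radius(theta)
        assert np.allclose(ra, spec_a.boundary_radius(theta))  # deterministic
        assert not np.allclose(ra, spec_b.boundary_radius(theta))
        assert ra.std() > 0  # genuinely non-circular


class TestOracle:
    def test_flat_slice_has_no_deformation(self):
        o = oracle_indices(SliceShapeSpec(shape_kind="flat"))
        assert o.dn_um == 0.0
        assert o.ra == 1.0
        assert o.km_per_um == 0.0

    def test_cap_curvature_is_reciprocal_radius(self, cap_oracle):
        # both principal curvatures of a sphere are 1/R everywhere
        assert cap_oracle.km_per_um == pytest.approx(1.0 / CAP_RADIUS_UM, rel=1e-12)

    def test_cap_area_ratio_matches_spherical_cap_formula(self, cap_oracle):
        R, a = CAP_RADIUS_UM, OUTLINE_RADIUS_UM
        h = R - math.sqrt(R**2 - a**2)
        assert cap_oracle.ra == pytest.approx(2 * R * h / a**2, rel=1e-3)

    def test_cap_deformation_matches_radial_quadrature(self, cap_oracle):
        # independent 1D route: mean |z - z̄| over the disk in polar coords
        R, a = CAP_RADIUS_UM, OUTLINE_RADIUS_UM
        c = math.sqrt(R**2 - a**2)
        z_bar = quad(lambda r: (math.sqrt(R**2 - r**2) - c) * 2 * r / a**2, 0, a)[0]
        dn = quad(lambda r: abs(math.sqrt(R**2 - r**2) - c - z_bar) * 2 * r / a**2, 0, a)[0]
        assert cap_oracle.dn_um == pytest.approx(dn, rel=1e-3)

    def test_sinusoid_oracle_matches_frozen_values(self, sin_oracle):
        assert sin_oracle.dn_um == pytest.approx(SIN_ORACLE_DN, rel=1e-6)
        assert sin_oracle.ra == pytest.approx(SIN_ORACLE_RA, rel=1e-6)
        assert sin_oracle.km_per_um == pytest.approx(SIN_ORACLE_KM, rel=1e-6)

    @pytest.mark.parametrize("shape", ["spherical_cap", "sinusoid"])
    def test_resolution_convergence(self, shape, cap_spec, sin_spec):
        spec = cap_spec if shape == "spherical_cap" else sin_spec
        coarse = oracle_indices(spec, resolution=2.0)
        fine = oracle_indices(spec, resolution=1.0)
        for attr in ("dn_um", "ra", "km_per_um"):
            assert getattr(fine, attr) == pytest.approx(getattr(coarse, attr), rel=1e-3)


class TestRenderStack:
    def test_flat_slab_columns_are_identical_bright_runs(self):
        hf, stack = render_shape(SliceShapeSpec(shape_kind="flat"))
        vol = stack.intensities
        thr = (vol.max() + vol.min()) / 2
        bright = vol > thr
        cols = bright[:, hf.mask]
        assert np.all(cols == cols[:, :1])  # same run everywhere
        runs = np.flatnonzero(cols[:, 0])
        assert np.all(np.diff(runs) == 1)  # contiguous

    def test_cap_bright_run_center_tracks_surface(self, cap_spec):
        hf, stack = render_shape(cap_spec)
        vol = stack.intensities
        thr = (vol.max() + vol.min()) / 2
        dz = stack.voxel_spacing[2]
        zc = np.arange(vol.shape[0]) * dz
        bright = vol > thr
        w = bright[:, hf.mask].astype(float)
        centers = (w * zc[:, None]).sum(axis=0) / w.sum(axis=0)
        # each column's run centre is within dz/2 of the surface plus the
        # (arbitrary) rendering origin, so after mean alignment the
        # per-column error is bounded by dz
        centered = centers - centers.mean()
        truth = hf.z[hf.mask] - hf.z[hf.mask].mean()
        assert np.abs(centered - truth).max() <= dz + 1e-9

    def test_seeding_contract(self, cap_spec):
        hf = make_height_field(cap_spec, resolution=10.0)
        a = render_stack(hf, StackRenderSpec(noise_sd=50.0, seed=1))
        a2 = render_stack(hf, StackRenderSpec(noise_sd=50.0, seed=1))
        b = render_stack(hf, StackRenderSpec(noise_sd=50.0, seed=2))
        clean = render_stack(hf, StackRenderSpec(noise_sd=0.0))
        assert np.array_equal(a.intensities, a2.intensities)
        assert not np.array_equal(a.intensities, b.intensities)
        # the seed only affects the noise, never the structure
        clean2 = render_stack(hf, StackRenderSpec(noise_sd=0.0, seed=99))
        assert np.array_equal(clean.intensities, clean2.intensities)

    def test_surface_exiting_volume_rejected(self, cap_spec):
        hf = make_height_field(cap_spec, resolution=10.0)
        with pytest.raises(ValueError, match="exits volume"):
            render_stack(hf, StackRenderSpec(n_z=10))

    def test_invalid_render_spec_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            StackRenderSpec(foreground_intensity=10.0, background_intensity=100.0)


class TestSimulateTrace:
    def test_trace_length_and_schedule(self, noiseless_trace):
        spec = TraceSimSpec()
        expected = int(spec.n_steps * (spec.ramp_duration + spec.hold_duration)
                       * spec.sample_rate) + 1
        assert noiseless_trace.time.size == expected
        assert noiseless_trace.displacement.max() == pytest.approx(
            spec.n_steps * spec.strain_per_step * spec.specimen_thickness
        )

    def test_no_transient_when_rs_is_one(self):
        trace = simulate_trace(TraceSimSpec(Rs_true=1.0))
        stress, strain = to_stress_strain(trace)
        hold = (trace.time > 1.0) & (trace.time < 181.0)  # first hold
        assert np.ptp(stress[hold]) == pytest.approx(0.0, abs=1e-12)

    def test_equilibrium_force_matches_linear_elasticity(self):
        # E=5 kPa at ε=0.05 with a 6 mm punch: F_eq = 5000·0.05·π·(0.003 m)²
        trace = simulate_trace(TraceSimSpec(E_true=5.0, Rs_true=1.0, noise_sd=0.0))
        i_end_hold1 = np.searchsorted(trace.time, 181.0) - 1
        expected = 5000 * 0.05 * math.pi * 0.003**2
        assert trace.force[i_end_hold1] == pytest.approx(expected, rel=1e-6)

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError, match="tau_fast"):
            TraceSimSpec(tau_fast_true=60.0, tau_slow_true=2.0)

    def test_noise_is_seeded(self):
        a = simulate_trace(TraceSimSpec(noise_sd=0.05, seed=3))
        b = simulate_trace(TraceSimSpec(noise_sd=0.05, seed=3))
        c = simulate_trace(TraceSimSpec(noise_sd=0.05, seed=4))
        assert np.array_equal(a.force, b.force)
        assert not np.array_equal(a.force, c.force)
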