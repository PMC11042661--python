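"""Stress indices: closed forms, oracle equivalence, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from solidstress import (
    HeightField,
    RunConfig,
    SliceShapeSpec,
    area_ratio,
    compute_indices,
    flip_height_field,
    indices_from_height_field,
    make_height_field,
    make_random_height_field,
    mean_curvature,
    normalized_deformation,
    oracle_indices,
)
from conftest import index_rel_errors, render_shape


def square_field(z, spacing=10.0):
    return HeightField(z=z, mask=np.ones_like(z, bool), pixel_spacing=(spacing, spacing))


class TestNormalizedDeformation:
    def test_flat_field_zero(self):
        dn, dev = normalized_deformation(square_field(np.zeros((20, 20))))
        assert dn == 0.0
        assert np.nanmax(dev) == 0.0

    def test_two_level_field_gives_half_gap(self):
        # half the mask at +h, half at -h: mean |z - z̄| = h
        h = 7.5
        z = np.concatenate([np.full((10, 20), h), np.full((10, 20), -h)])
        dn, _ = normalized_deformation(square_field(z))
        assert dn == pytest.approx(h)

    def test_cap_matches_oracle(self, cap_spec, cap_oracle):
        hf = make_height_field(cap_spec, resolution=10.0)
        dn, dev = normalized_deformation(hf)
        assert dn == pytest.approx(cap_oracle.dn_um, rel=0.01)
        assert np.nanmean(dev[hf.mask]) == pytest.approx(dn)  # map mean equals D_n


class TestAreaRatio:
    def test_flat_field_is_one(self):
        ra, a_s, a_p = area_ratio(square_field(np.zeros((15, 15))))
        assert ra == pytest.approx(1.0)
        assert a_s == pytest.approx(a_p)

    @pytest.mark.parametrize("deg", [10, 20, 30])
    def test_tilted_plane_secant_law(self, deg):
        spec = SliceShapeSpec(shape_kind="flat", tilt=math.radians(deg))
        hf = make_height_field(spec, resolution=10.0)
        ra, _, _ = area_ratio(hf)
        assert ra == pytest.approx(1 / math.cos(math.radians(deg)), rel=0.005)

    def test_cap_matches_closed_form(self, cap_spec):
        hf = make_height_field(cap_spec, resolution=10.0)
        ra, _, _ = area_ratio(hf)
        R, a = 1000.0, 500.0
        h = R - math.sqrt(R**2 - a**2)
        assert ra == pytest.approx(2 * R * h / a**2, rel=0.01)


class TestMeanCurvature:
    def test_flat_field_zero(self):
        km, _, _ = mean_curvature(square_field(np.zeros((15, 15))))
        assert km == pytest.approx(0.0, abs=1e-15)

    def test_sphere_patch_every_pixel_reciprocal_radius(self):
        R = 1000.0
        x = (np.arange(81) - 40) * 10.0
        X, Y = np.meshgrid(x, x)
        hf = square_field(np.sqrt(R**2 - X**2 - Y**2))
        km, h_map, n_int = mean_curvature(hf)
        assert km == pytest.approx(1 / R, rel=0.005)
        assert np.nanmax(np.abs(h_map * R - 1)) < 0.005  # pointwise, not just on average
        assert n_int == 79 * 79

    def test_cylinder_patch_half_reciprocal_radius(self):
        # κ1 = 1/R along the bend, κ2 = 0 along the axis
        R = 1000.0
        x = (np.arange(81) - 40) * 10.0
        X, _ = np.meshgrid(x, x)
        hf = square_field(np.sqrt(R**2 - X**2))
        km, _, _ = mean_curvature(hf)
        assert km == pytest.approx(1 / (2 * R), rel=0.005)

    def test_mask_too_small_for_stencil(self):
        z = np.zeros((4, 4))
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[1, 2] = True  # no pixel has a full 3x3 neighbourhood
        hf = HeightField(z=z, mask=mask, pixel_spacing=(1, 1))
        with pytest.raises(ValueError, match="too small"):
            mean_curvature(hf)


class TestPipeline:
    def test_flat_slab_end_to_end(self):
        _, stack = render_shape(SliceShapeSpec(shape_kind="flat"))
        idx, _ = compute_indices(stack)
        assert idx.dn_um == pytest.approx(0.0, abs=1e-9)
        assert idx.ra == pytest.approx(1.0, abs=1e-9)
        assert idx.km_per_um == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("shape", ["cap", "sinusoid"])
    def test_noiseless_pipeline_matches_oracle(self, shape, cap_spec, sin_spec,
                                               cap_oracle, sin_oracle):
        spec, oracle = (cap_spec, cap_oracle) if shape == "cap" else (sin_spec, sin_oracle)
        _, stack = render_shape(spec)
        idx, _ = compute_indices(stack)
        assert max(index_rel_errors(idx, oracle)) < 0.02

    def test_z_flipped_stack_gives_same_indices(self, cap_spec):
        _, stack = render_shape(cap_spec)
        idx, _ = compute_indices(stack)
        from solidstress import ImageStack3D

        flipped = ImageStack3D(stack.intensities[::-1].copy(), stack.voxel_spacing)
        idx_f, _ = compute_indices(flipped)
        assert idx_f.dn_um == pytest.approx(idx.dn_um, rel=1e-6)
        assert idx_f.ra == pytest.approx(idx.ra, rel=1e-6)
        assert idx_f.km_per_um == pytest.approx(idx.km_per_um, rel=1e-6)

    def test_area_normalized_variants(self, cap_spec):
        _, stack = render_shape(cap_spec)
        idx, _ = compute_indices(stack, RunConfig(normalization_mode="area"))
        assert idx.normalization_mode == "area"
        assert idx.dn_area_norm == pytest.approx(idx.dn_um / math.sqrt(idx.a_p_um2))
        assert idx.km_area_norm == pytest.approx(idx.km_per_um * math.sqrt(idx.a_p_um2))

    def test_stage_errors_are_attributed(self):
        from solidstress import ImageStack3D

        stack = ImageStack3D(np.full((5, 30, 30), 3.0), (10, 10, 5))
        with pytest.raises(Exception, match="segment_tissue"):
            compute_indices(stack)


class TestInvariances:
    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=12, deadline=None, derandomize=True)
    def test_flip_invariance(self, seed):
        hf = make_random_height_field(seed)
        a, _ = indices_from_height_field(hf)
        b, _ = indices_from_height_field(flip_height_field(hf))
        assert b.dn_um == pytest.approx(a.dn_um, rel=1e-9)
        assert b.ra == pytest.approx(a.ra, rel=1e-9)
        assert b.km_per_um == pytest.approx(a.km_per_um, rel=1e-9)

    @given(seed=st.integers(min_value=0, max_value=10_000),
           offset=st.floats(min_value=-500, max_value=500))
    @settings(max_examples=12, deadline=None, derandomize=True)
    def test_translation_invariance_and_ra_floor(self, seed, offset):
        hf = make_random_height_field(seed)
        shifted = HeightField(z=hf.z + offset, mask=hf.mask, pixel_spacing=hf.pixel_spacing)
        a, _ = indices_from_height_field(hf)
        b, _ = indices_from_height_field(shifted)
        assert b.dn_um == pytest.approx(a.dn_um, rel=1e-9, abs=1e-12)
        assert b.ra == pytest.approx(a.ra, rel=1e-12)
        assert b.km_per_um == pytest.approx(a.km_per_um, rel=1e-9, abs=1e-15)
        assert a.ra >= 1.0

    def test_monotone_in_sinusoid_amplitude(self):
        amplitudes = [10.0, 30.0, 60.0]
        oracle_vals, pipeline_vals = [], []
        for amp in amplitudes:
            spec = SliceShapeSpec(shape_kind="sinusoid", amplitude_or_radius=amp,
                                  wavelength=800.0)
            o = oracle_indices(spec, resolution=4.0)
            oracle_vals.append((o.dn_um, o.ra, o.km_per_um))
            _, stack = render_shape(spec)
            idx, _ = compute_indices(stack)
            pipeline_vals.append((idx.dn_um, idx.ra, idx.km_per_um))
        for vals in (oracle_vals, pipeline_vals):
            arr = np.array(vals)
            assert np.all(np.diff(arr, axis=0) > 0)

    def test_scale_consistency_on_smooth_shape(self, cap_spec):
        fine, _ = indices_from_height_field(make_height_field(cap_spec, resolution=10.0))
        coarse, _ = indices_from_height_field(make_height_field(cap_spec, resolution=20.0))
        assert coarse.dn_um == pytest.approx(fine.dn_um, rel=0.01)
        assert coarse.ra == pytest.approx(fine.ra, rel=0.01)
        assert coarse.km_per_um == pytest.approx(fine.km_per_um, rel=0.01)

    def test_km_unit_conversion(self):
        R = 1000.0
        x = (np.arange(41) - 20) * 10.0
        X, Y = np.meshgrid(x, x)
        idx, _ = indices_from_height_field(square_field(np.sqrt(R**2 - X**2 - Y**2)))
        assert idx.km_per_mm == pytest.approx(idx.km_per_um * 1000.0)
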