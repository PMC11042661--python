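"""Residual-solid-stress indices of a relaxed tissue slice.

A slice that stored solid stress bends when the confinement is cut away.
Three scalar indices quantify that bending from the reconstructed height
field z(x, y):

* normalized deformation  D_n = mean_k |z_k - z̄|            (µm)
* area ratio              R_a = A_s / A_p                    (≥ 1)
* mean-curvature index    K_m = mean_k |(κ1 + κ2)/2|         (µm⁻¹)

with z̄ the mean height over the mask, A_s the true surface area, A_p the
projected (footprint) area, and κ1, κ2 the principal curvatures
(reciprocals of the curvature radii).  For a Monge patch the mean
curvature has the closed form

    H = [(1 + z_y²) z_xx − 2 z_x z_y z_xy + (1 + z_x²) z_yy]
        / [2 (1 + z_x² + z_y²)^{3/2}]

evaluated here with finite differences.  D_n and K_m take absolute
values, and all three indices depend on z only through z − z̄, so they
are invariant to flipping the slice (the buoyancy control) and to rigid
translation.

Derivative stencils: first derivatives use centred differences where both
neighbours are inside the mask and one-sided differences at the mask
boundary (used for A_s); curvature uses centred 3×3 stencils and is
averaged only over the mask eroded by that stencil, so no boundary pixel
contributes.  Excluded pixel counts are part of the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageStack3D, RunConfig, SliceMetadata
from .surface import (
    HeightField,
    extract_height_field,
    masked_first_derivatives,
    segment_tissue,
)


@dataclass
class StressIndices:
    """Scalar stress indices plus the bookkeeping they depend on.

    ``dn_um`` in µm; ``km_per_um`` in µm⁻¹ (reports print mm⁻¹ =
    1000 × µm⁻¹); areas in µm².  ``dn_area_norm`` = D_n/√A_p and
    ``km_area_norm`` = K_m·√A_p are the dimensionless area-normalized
    variants used for spatial-trend analysis.
    """

    dn_um: float
    ra: float
    km_per_um: float
    a_s_um2: float
    a_p_um2: float
    z_bar_um: float
    n_pixels: int
    n_curvature_pixels: int
    dn_area_norm: float
    km_area_norm: float
    normalization_mode: str = "none"
    provenance: dict | None = None

    @property
    def km_per_mm(self) -> float:
        return self.km_per_um * 1000.0


def _interior_second_derivatives(
    z: np.ndarray, dx: float, dy: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centred 3×3-stencil derivatives on the full grid (edge-padded)."""
    zp = np.pad(z, 1, mode="edge")
    c = zp[1:-1, 1:-1]
    zx = (zp[1:-1, 2:] - zp[1:-1, :-2]) / (2 * dx)
    zy = (zp[2:, 1:-1] - zp[:-2, 1:-1]) / (2 * dy)
    zxx = (zp[1:-1, 2:] - 2 * c + zp[1:-1, :-2]) / dx**2
    zyy = (zp[2:, 1:-1] - 2 * c + zp[:-2, 1:-1]) / dy**2
    zxy = (zp[2:, 2:] - zp[2:, :-2] - zp[:-2, 2:] + zp[:-2, :-2]) / (4 * dx * dy)
    return zx, zy, zxx, zyy, zxy


def monge_mean_curvature(
    zx: np.ndarray, zy: np.ndarray, zxx: np.ndarray, zyy: np.ndarray, zxy: np.ndarray
) -> np.ndarray:
    """Signed Monge-patch mean curvature H = (κ1 + κ2)/2."""
    num = (1 + zy**2) * zxx - 2 * zx * zy * zxy + (1 + zx**2) * zyy
    return num / (2 * (1 + zx**2 + zy**2) ** 1.5)


def normalized_deformation(hf: HeightField) -> tuple[float, np.ndarray]:
    """D_n and its per-pixel map |z − z̄| (NaN outside the mask)."""
    z_bar = float(hf.z[hf.mask].mean())
    dev = np.abs(hf.z - z_bar)
    dn = float(dev[hf.mask].mean())
    dev_map = np.where(hf.mask, dev, np.nan)
    return dn, dev_map


def area_ratio(hf: HeightField) -> tuple[float, float, float]:
    """(R_a, A_s, A_p): true surface area over projected area."""
    dx, dy = hf.pixel_spacing
    zx, zy = masked_first_derivatives(hf.z, hf.mask, dx, dy)
    integrand = np.sqrt(1.0 + zx**2 + zy**2)
    a_s = float(integrand[hf.mask].sum() * dx * dy)
    a_p = float(hf.mask.sum() * dx * dy)
    return a_s / a_p, a_s, a_p


def mean_curvature(
    hf: HeightField, signed: bool = False
) -> tuple[float, np.ndarray, int]:
    """K_m, the per-pixel curvature map, and the interior pixel count.

    The map holds |H| (or signed H with ``signed=True``) on the mask
    eroded by the 3×3 stencil and NaN elsewhere.
    """
    dx, dy = hf.pixel_spacing
    interior = ndimage.binary_erosion(hf.mask, structure=np.ones((3, 3), bool))
    n_int = int(interior.sum())
    if n_int == 0:
        raise ValueError("mask too small for the curvature stencil")
    # neighbours outside the mask never enter: interior pixels have a full
    # in-mask 3×3 neighbourhood, and padded edges are eroded away
    zx, zy, zxx, zyy, zxy = _interior_second_derivatives(hf.z, dx, dy)
    h = monge_mean_curvature(zx, zy, zxx, zyy, zxy)
    km = float(np.abs(h)[interior].mean())
    vals = h if signed else np.abs(h)
    h_map = np.where(interior, vals, np.nan)
    return km, h_map, n_int


def indices_from_height_field(
    hf: HeightField, normalization_mode: str = "none"
) -> tuple[StressIndices, dict[str, np.ndarray]]:
    """All three indices plus deformation and curvature maps."""
    dn, dev_map = normalized_deformation(hf)
    ra, a_s, a_p = area_ratio(hf)
    km, h_map, n_int = mean_curvature(hf)
    _, h_signed, _ = mean_curvature(hf, signed=True)
    z_bar = float(hf.z[hf.mask].mean())
    idx = StressIndices(
        dn_um=dn,
        ra=ra,
        km_per_um=km,
        a_s_um2=a_s,
        a_p_um2=a_p,
        z_bar_um=z_bar,
        n_pixels=hf.n_pixels,
        n_curvature_pixels=n_int,
        dn_area_norm=dn / np.sqrt(a_p),
        km_area_norm=km * np.sqrt(a_p),
        normalization_mode=normalization_mode,
        provenance=dict(hf.provenance),
    )
    maps = {"deformation": dev_map, "curvature_abs": h_map, "curvature_signed": h_signed}
    return idx, maps


def compute_indices(
    stack: ImageStack3D,
    config: RunConfig | None = None,
    meta: SliceMetadata | None = None,
) -> tuple[StressIndices, dict[str, np.ndarray]]:
    """Full pipeline: segment → reconstruct surface → index.

    Errors from each stage propagate with the stage named.
    """
    config = config or RunConfig()
    try:
        mask = segment_tissue(stack, min_object_area=config.min_object_area)
    except Exception as exc:
        raise type(exc)(f"segment_tissue: {exc}") from exc
    try:
        hf = extract_height_field(
            stack,
            mask,
            method=config.surface_method,
            smoothing_scale=config.smoothing_scale,
        )
    except Exception as exc:
        raise type(exc)(f"extract_height_field: {exc}") from exc
    idx, maps = indices_from_height_field(hf, normalization_mode=config.normalization_mode)
    if meta is not None and idx.provenance is not None:
        idx.provenance.update(
            {"slice_id": meta.slice_id, "group": meta.group, "position_ap": meta.position_ap}
        )
    return idx, maps
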