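"""Height-field reconstruction of a relaxed tissue slice from a 3D stack.

A slice released from confinement bends out of plane; imaged in 3D it is
a thin bright sheet.  Because deformation and curvature maps are reported
as 2D projections, the sheet is modelled as a Monge patch: a single-valued
height ``z(x, y)`` over a tissue footprint mask.  Slices that fold over
violate that assumption; columns with multiple bright runs are counted and
reported as a warning metric rather than silently averaged.

The surface digitized from the sheet is configurable (``centroid`` — the
intensity-weighted midsurface, ``max`` — brightest voxel, ``top`` — upper
envelope); the midsurface is the default because it is symmetric under
physically flipping the slice and robust to noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import ImageStack3D


class SurfaceError(ValueError):
    """Raised when a surface cannot be reconstructed from the stack."""


@dataclass
class HeightField:
    """Surface height ``z(x, y)`` (µm) over a boolean tissue mask.

    ``z`` and ``mask`` are indexed ``[y, x]``; ``pixel_spacing`` is
    ``(dx, dy)`` in µm.  ``provenance`` records how the field was made.
    """

    z: np.ndarray
    mask: np.ndarray
    pixel_spacing: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z.shape != self.mask.shape or self.z.ndim != 2:
            raise ValueError("z and mask must be 2D arrays of identical shape")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.all(np.isfinite(self.z[self.mask])):
            raise ValueError("z must be finite on the mask")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if len(self.pixel_spacing) != 2 or any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing must be two positive values (dx, dy)")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def segment_tissue(stack: ImageStack3D, min_object_area: float = 1e4) -> np.ndarray:
    """Tissue footprint from the maximum-intensity projection.

    Otsu-thresholds the projection, fills holes, removes components below
    ``min_object_area`` (µm²) and keeps the largest connected component.
    """
    mip = stack.intensities.max(axis=0)
    if np.ptp(mip) == 0:
        raise SurfaceError("no tissue detected: projection is uniform")
    thr = threshold_otsu(mip)
    fg = mip > thr
    if not fg.any():
        raise SurfaceError("no tissue detected")
    fg = ndimage.binary_fill_holes(fg)
    dx, dy, _ = stack.voxel_spacing
    min_px = max(1, int(round(min_object_area / (dx * dy))))
    labels, n = ndimage.label(fg)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_px) + 1
        fg = np.isin(labels, keep)
    if not fg.any():
        raise SurfaceError("no tissue detected: all components below min_object_area")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return fg


def _nearest_fill(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid entries by their nearest valid neighbour's value."""
    if valid.all():
        return values
    idx = ndimage.distance_transform_edt(~valid, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def masked_first_derivatives(
    z: np.ndarray, mask: np.ndarray, dx: float, dy: float
) -> tuple[np.ndarray, np.ndarray]:
    """∂z/∂x, ∂z/∂y: centred where both neighbours are masked, one-sided
    at the mask boundary, zero where no masked neighbour exists."""
    zp = np.pad(z, 1, mode="edge")
    mp = np.pad(mask, 1, mode="constant", constant_values=False)

    def deriv(axis: int, d: float) -> np.ndarray:
        if axis == 1:  # x
            z_f, z_b = zp[1:-1, 2:], zp[1:-1, :-2]
            m_f, m_b = mp[1:-1, 2:], mp[1:-1, :-2]
        else:  # y
            z_f, z_b = zp[2:, 1:-1], zp[:-2, 1:-1]
            m_f, m_b = mp[2:, 1:-1], mp[:-2, 1:-1]
        centered = (z_f - z_b) / (2 * d)
        fwd = (z_f - z) / d
        bwd = (z - z_b) / d
        out = np.where(m_f & m_b, centered, np.where(m_f, fwd, np.where(m_b, bwd, 0.0)))
        return np.where(mask, out, 0.0)

    return deriv(1, dx), deriv(0, dy)


def _linear_extend(z: np.ndarray, mask: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Extend z beyond the mask by first-order Taylor extrapolation.

    Constant (nearest-value) extension flattens the boundary slope, which
    a subsequent Gaussian smooth would smear back into the masked region
    and corrupt boundary curvature; extrapolating along the boundary
    gradient keeps the smoothing bias second order.
    """
    if mask.all():
        return z
    ind = ndimage.distance_transform_edt(~mask, return_distances=False, return_indices=True)
    ny, nx = ind[0], ind[1]
    iy, ix = np.indices(mask.shape)
    zx, zy = masked_first_derivatives(z, mask, dx, dy)
    ext = z[ny, nx] + zx[ny, nx] * (ix - nx) * dx + zy[ny, nx] * (iy - ny) * dy
    return np.where(mask, z, ext)


def _masked_gaussian(
    z: np.ndarray, mask: np.ndarray, sigma_px: tuple[float, float], dx: float, dy: float
) -> np.ndarray:
    """Gaussian smoothing of the masked field via slope-preserving extension."""
    if max(sigma_px) <= 0:
        return z
    return ndimage.gaussian_filter(_linear_extend(z, mask, dx, dy), sigma=sigma_px)


def extract_height_field(
    stack: ImageStack3D,
    mask: np.ndarray,
    method: str = "centroid",
    smoothing_scale: float | None = None,
    max_failed_frac: float = 0.10,
) -> HeightField:
    """Digitize the slice surface per masked column of the stack.

    Per column the surface height is the intensity-weighted centroid of the
    above-threshold voxels (``centroid``), the brightest voxel (``max``),
    or the upper envelope of the thresholded run (``top``).  The field is
    then smoothed in-plane by a Gaussian of ``smoothing_scale`` µm
    (default: 2 in-plane pixels).  Columns with no bright voxel are
    in-filled from neighbours; more than ``max_failed_frac`` of them is an
    error.
    """
    if method not in ("centroid", "max", "top"):
        raise ValueError(f"unknown surface method {method!r}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.intensities.shape[1:]:
        raise ValueError("mask shape must match the stack's in-plane shape")
    if not mask.any():
        raise SurfaceError("mask is empty")
    dx, dy, dz = stack.voxel_spacing
    vol = np.asarray(stack.intensities, dtype=float)
    thr = threshold_otsu(vol) if np.ptp(vol) > 0 else vol.min()
    bright = vol > thr

    nz = vol.shape[0]
    zc = np.arange(nz, dtype=float) * dz  # voxel-centre heights, arbitrary origin

    n_bright = bright.sum(axis=0)
    ok = mask & (n_bright > 0)
    failed = mask & ~ok
    failed_frac = failed.sum() / mask.sum()
    if failed_frac > max_failed_frac:
        raise SurfaceError(
            f"{int(failed.sum())} of {int(mask.sum())} masked columns have no bright voxels "
            f"({failed_frac:.1%} > {max_failed_frac:.0%})"
        )

    if method == "centroid":
        w = np.where(bright, vol - thr, 0.0)
        wsum = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.einsum("kij,k->ij", w, zc) / wsum
    elif method == "max":
        z = zc[np.argmax(vol, axis=0)]
    else:  # top
        top_idx = nz - 1 - np.argmax(bright[::-1], axis=0)
        z = zc[top_idx]
    z = np.where(ok, z, 0.0)
    z = _nearest_fill(z, ok) if ok.any() else z

    # fraction of columns whose bright voxels form >1 run: Monge-patch warning
    starts = bright & ~np.roll(bright, 1, axis=0)
    starts[0] = bright[0]
    n_runs = starts.sum(axis=0)
    multi_run_frac = float((mask & (n_runs > 1)).sum() / mask.sum())

    if smoothing_scale is None:
        smoothing_scale = 2.0 * dx
    sigma_px = (smoothing_scale / dy, smoothing_scale / dx)
    z = _masked_gaussian(z, mask, sigma_px, dx, dy)

    return HeightField(
        z=z,
        mask=mask,
        pixel_spacing=(dx, dy),
        provenance={
            "surface_method": method,
            "smoothing_scale_um": float(smoothing_scale),
            "failed_column_frac": float(failed_frac),
            "multi_run_column_frac": multi_run_frac,
        },
    )


def flip_height_field(hf: HeightField) -> HeightField:
    """Physically flip the slice: negate z and mirror the x axis.

    Used for the buoyancy control: all stress indices must be identical
    before and after the flip.
    """
    return HeightField(
        z=-hf.z[:, ::-1].copy(),
        mask=hf.mask[:, ::-1].copy(),
        pixel_spacing=hf.pixel_spacing,
        provenance={**hf.provenance, "flipped": not hf.provenance.get("flipped", False)},
    )


def write_height_field(hf: HeightField, path: str | Path) -> Path:
    """Write z and mask as float/uint8 TIFFs plus a YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, hf.z.astype(np.float32))
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    tifffile.imwrite(mask_path, hf.mask.astype(np.uint8))
    sidecar = path.with_suffix(".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {"pixel_spacing_um": list(hf.pixel_spacing), "provenance": hf.provenance},
            sort_keys=True,
        )
    )
    return path


def read_height_field(path: str | Path) -> HeightField:
    path = Path(path)
    z = tifffile.imread(path)
    mask = tifffile.imread(path.with_name(path.stem + "_mask" + path.suffix)).astype(bool)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return HeightField(
        z=z,
        mask=mask,
        pixel_spacing=tuple(meta["pixel_spacing_um"]),
        provenance=meta.get("provenance", {}),
    )
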