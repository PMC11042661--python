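"""Readers, writers and run configuration.

Image stacks travel as multi-page TIFF (or OME-TIFF) with voxel spacing
taken from the OME header when present, otherwise from a YAML sidecar
(``<stem>.yaml``) next to the file.  Spacing is never guessed: curvature
and deformation indices carry units, so a stack without spacing is an
error, not a default.

Compression traces travel as CSV with a mandatory header
``time_s,displacement_mm,force_N`` (a column mapping can be supplied for
other exports).  Readers reject malformed input rather than repairing it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml


class FormatError(ValueError):
    """Raised when an input file violates the documented contract."""


# --------------------------------------------------------------------------
# domain containers
# --------------------------------------------------------------------------

@dataclass
class ImageStack3D:
    """Single-channel fluorescence volume.

    ``intensities`` is indexed ``[z, y, x]``; ``voxel_spacing`` is
    ``(dx, dy, dz)`` in micrometres.
    """

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float]
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive values (dx, dy, dz)")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class SliceMetadata:
    """Per-slice annotations used for grouping and spatial trends."""

    slice_id: str
    group: str = ""
    position_ap: float | None = None  # µm from the anterior reference
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.position_ap is not None and self.position_ap < 0:
            raise ValueError("position_ap must be >= 0 when present")


@dataclass
class RelaxationTrace:
    """Unconfined-compression record with specimen geometry.

    Force in newtons, displacement in millimetres, time in seconds;
    the specimen is a cylindrical punch of ``specimen_diameter`` mm and
    ``specimen_thickness`` mm (protocol default: 6 mm punch, 2 mm slice).
    """

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    specimen_diameter: float = 6.0
    specimen_thickness: float = 2.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if self.displacement.size != n or self.force.size != n:
            raise ValueError("time, displacement and force must have equal length")
        if n < 2:
            raise ValueError("trace must contain at least two samples")
        if not np.all(np.diff(self.time) > 0):
            raise FormatError("time must be strictly increasing")
        if self.specimen_diameter <= 0 or self.specimen_thickness <= 0:
            raise ValueError("specimen geometry must be positive")

    @property
    def cross_section_mm2(self) -> float:
        return float(np.pi * (self.specimen_diameter / 2.0) ** 2)


@dataclass
class RunConfig:
    """Analysis configuration carried through the pipeline.

    The surface method and smoothing scale are part of every result's
    provenance because curvature is scale dependent.
    """

    smoothing_scale: float | None = None  # µm; None -> 2 in-plane pixels
    surface_method: str = "centroid"      # centroid | max | top
    normalization_mode: str = "none"      # none | area
    min_object_area: float = 1e4          # µm², small-component floor
    equilibrium_window_frac: float = 0.1  # tail fraction of each hold
    sigma_max_source: str = "ramp_peak"   # ramp_peak | hold_start
    n_steps: int = 4
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.smoothing_scale is not None and self.smoothing_scale < 0:
            raise ValueError("smoothing_scale must be >= 0")
        if self.surface_method not in ("centroid", "max", "top"):
            raise ValueError(f"unknown surface_method {self.surface_method!r}")
        if self.normalization_mode not in ("none", "area"):
            raise ValueError(f"unknown normalization_mode {self.normalization_mode!r}")
        if not 0 < self.equilibrium_window_frac <= 0.5:
            raise ValueError("equilibrium_window_frac must be in (0, 0.5]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# --------------------------------------------------------------------------
# image stacks
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _spacing_from_ome(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tif.ome_metadata
    if not meta:
        return None
    import xml.etree.ElementTree as ET

    try:
        root = ET.fromstring(meta)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            try:
                return (
                    float(el.attrib["PhysicalSizeX"]),
                    float(el.attrib["PhysicalSizeY"]),
                    float(el.attrib["PhysicalSizeZ"]),
                )
            except KeyError:
                return None
    return None


def read_stack(
    path: str | Path,
    channel: int | None = None,
    spacing: Sequence[float] | None = None,
    channel_label: str = "",
) -> ImageStack3D:
    """Read a multi-page TIFF / OME-TIFF as an :class:`ImageStack3D`.

    Spacing resolution order: explicit ``spacing`` argument, OME header,
    YAML sidecar; a stack without any of these is rejected.  A 4D file is
    treated as channel-first and requires ``channel``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome_spacing = _spacing_from_ome(tif)
    if data.ndim == 4:
        if channel is None:
            raise FormatError(
                f"{path} has {data.shape[0]} channels; select one with channel= "
                f"(available: {list(range(data.shape[0]))})"
            )
        data = data[channel]
    elif data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D (or channel-first 4D) stack, got shape {data.shape}")

    if spacing is not None:
        vs = tuple(float(s) for s in spacing)
    elif ome_spacing is not None:
        vs = ome_spacing
    else:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(
                f"{path}: no voxel spacing found (no OME header, no sidecar {sidecar.name}); "
                "indices carry physical units so spacing is required"
            )
        meta = yaml.safe_load(sidecar.read_text())
        try:
            vs = tuple(float(s) for s in meta["voxel_spacing_um"])
        except (TypeError, KeyError) as exc:
            raise FormatError(f"{sidecar}: missing voxel_spacing_um") from exc
    return ImageStack3D(intensities=data, voxel_spacing=vs, channel_label=channel_label)


def write_stack(stack: ImageStack3D, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a YAML spacing sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.intensities, dtype=np.float32))
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        yaml.safe_dump(
            {
                "voxel_spacing_um": list(stack.voxel_spacing),
                "channel_label": stack.channel_label,
            },
            sort_keys=True,
        )
    )
    return path


# --------------------------------------------------------------------------
# compression traces
# --------------------------------------------------------------------------

_TRACE_COLUMNS = ("time_s", "displacement_mm", "force_N")


def read_trace(
    path: str | Path,
    diameter_mm: float = 6.0,
    thickness_mm: float = 2.0,
    column_map: Mapping[str, str] | None = None,
) -> RelaxationTrace:
    """Read a compression trace CSV.

    The file must carry the header ``time_s,displacement_mm,force_N``;
    ``column_map`` maps those canonical names to the file's own header for
    other instrument exports.  Non-numeric cells and non-increasing time
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, skip_blank_lines=True)
    names = dict(column_map) if column_map else {c: c for c in _TRACE_COLUMNS}
    missing = [names[c] for c in _TRACE_COLUMNS if names[c] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} (have {list(df.columns)})")
    cols = {}
    for canonical in _TRACE_COLUMNS:
        raw = df[names[canonical]]
        vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise FormatError(f"{path}: non-numeric cell in column {names[canonical]!r} at row {bad[0]}")
        cols[canonical] = vals
    if not np.all(np.diff(cols["time_s"]) > 0):
        raise FormatError(f"{path}: time_s must be strictly increasing")
    return RelaxationTrace(
        time=cols["time_s"],
        displacement=cols["displacement_mm"],
        force=cols["force_N"],
        specimen_diameter=diameter_mm,
        specimen_thickness=thickness_mm,
    )


def write_trace(trace: RelaxationTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time_s": trace.time,
            "displacement_mm": trace.displacement,
            "force_N": trace.force,
        }
    ).to_csv(path, index=False)
    return path
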