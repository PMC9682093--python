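"""Core data containers and file I/O.

All artifacts of the pipeline pass through this module: multi-channel 3D
stacks (OME-TIFF with voxel metadata), integer label masks (single-channel
OME-TIFF), spot tables (CSV with a JSON comment header) and the validated run
configuration (YAML/JSON).

Conventions
-----------
* In-memory axis order is always ``(channel, z, y, x)`` for stacks and
  ``(z, y, x)`` for masks, regardless of on-disk order.
* Voxel indices are 0-based; the physical coordinate of the *center* of voxel
  ``i`` along an axis with voxel size ``s`` is ``(i + 0.5) * s`` (µm).
* Intensities are held as ``float64`` internally even when files are integer.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger("smfish3d")

#: Columns of the on-disk spot table, in order.
SPOT_COLUMNS = [
    "x_um",
    "y_um",
    "z_um",
    "amplitude",
    "background",
    "sigma_xy_nm",
    "sigma_z_nm",
    "integrated_intensity",
    "label",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """A multi-channel 3D fluorescence volume with physical voxel sizes.

    Parameters
    ----------
    voxels
        4-D float array indexed ``(channel, z, y, x)``; non-negative.
    channel_names
        One name per channel (e.g. ``["marker", "smFISH", "DAPI"]``).
    voxel_size_um
        ``(dz, dy, dx)`` in micrometres, all > 0.
    metadata
        Free-form key/value pairs carried through file round-trips.
    """

    voxels: np.ndarray
    channel_names: list[str]
    voxel_size_um: tuple[float, float, float]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4-D (c, z, y, x), got {self.voxels.ndim}-D")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.voxels.shape}")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.voxels.shape[0]} channels"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel_size_um must be 3 positive values, got {self.voxel_size_um}")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, name_or_index: int | str) -> np.ndarray:
        """Return one channel as a 3-D ``(z, y, x)`` view."""
        idx = self.channel_index(name_or_index)
        return self.voxels[idx]

    def channel_index(self, name_or_index: int | str) -> int:
        if isinstance(name_or_index, str):
            try:
                return self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"no channel {name_or_index!r}; have {self.channel_names}"
                ) from None
        idx = int(name_or_index)
        if not 0 <= idx < self.n_channels:
            raise IndexError(f"channel index {idx} out of range (n={self.n_channels})")
        return idx

    @property
    def physical_extent_um(self) -> tuple[float, float, float]:
        """Physical size ``(z, y, x)`` of the volume in µm."""
        return tuple(n * s for n, s in zip(self.shape_zyx, self.voxel_size_um))


@dataclass
class LabelMask:
    """3-D integer segmentation mask; 0 = background, k >= 1 = region k."""

    labels: np.ndarray
    compartment: str = "cell"  # {"cell", "nucleus"}
    voxel_size_um: tuple[float, float, float] = (0.2, 0.05, 0.05)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3-D (z, y, x), got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels).astype(np.int32)
            if not np.allclose(lab, self.labels):
                raise ValueError("labels must be integers")
            self.labels = lab
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.compartment not in ("cell", "nucleus"):
            raise ValueError(f"compartment must be 'cell' or 'nucleus', got {self.compartment!r}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class SpotTable:
    """Fitted single-molecule spots plus provenance.

    ``df`` has the columns in :data:`SPOT_COLUMNS`; coordinates are physical
    (µm, voxel-center convention), widths in nm, ``label`` is the mask region
    the spot was assigned to (0 = unassigned/extracellular).
    """

    df: pd.DataFrame
    source_image: str = ""
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df is None or len(self.df.columns) == 0:
            self.df = empty_spot_frame()
        missing = [c for c in SPOT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"spot table missing columns {missing}")
        self.df = self.df[SPOT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def check_bounds(self, stack: ImageStack) -> None:
        """Raise if any spot lies outside the stack's physical bounds."""
        ez, ey, ex = stack.physical_extent_um
        for col, hi in (("x_um", ex), ("y_um", ey), ("z_um", ez)):
            v = self.df[col].to_numpy()
            if len(v) and ((v < 0).any() or (v > hi).any()):
                raise ValueError(f"spot {col} outside physical bounds [0, {hi:g}]")


def empty_spot_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in SPOT_COLUMNS}).astype(
        {"label": "int64"}
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class PSFConfig(BaseModel):
    """Gaussian spot-model widths (the effective PSF), in nanometres."""

    sigma_xy_nm: float = Field(120.0, gt=0)
    sigma_z_nm: float = Field(400.0, gt=0)

    @model_validator(mode="after")
    def _warn_aspect(self) -> "PSFConfig":
        if self.sigma_z_nm < self.sigma_xy_nm:
            warnings.warn(
                "sigma_z < sigma_xy is unusual for a confocal PSF", stacklevel=2
            )
        return self


class PipelineConfig(BaseModel):
    """Validated run configuration for the whole pipeline."""

    low_percentile: float = Field(2.0, ge=0, le=100)
    high_percentile: float = Field(98.0, ge=0, le=100)
    slab_half_width_um: float = Field(0.4, gt=0)
    psf: PSFConfig = Field(default_factory=PSFConfig)
    detection_threshold: float = Field(0.0, ge=0)
    threshold_mode: str = "absolute"  # or "mad": median + T * robust sd
    alpha: float = Field(0.05, gt=0, lt=1)
    seed: int = 0
    marker_channel: str | int = "marker"
    smfish_channel: str | int = "smFISH"
    dapi_channel: Optional[str | int] = "DAPI"
    voxel_size_um: Optional[tuple[float, float, float]] = None  # fallback for raw TIFFs
    min_voxels_um3: float = Field(1.0, gt=0)
    prob_threshold: float = Field(0.5, gt=0, lt=1)
    paths: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_percentiles(self) -> "PipelineConfig":
        if not self.low_percentile < self.high_percentile:
            raise ValueError("low_percentile must be < high_percentile")
        return self

    @field_validator("threshold_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in ("absolute", "mad"):
            raise ValueError("threshold_mode must be 'absolute' or 'mad'")
        return v


def read_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    return PipelineConfig.model_validate(data)


def write_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# Coordinate helpers
# ---------------------------------------------------------------------------


def voxel_to_physical(
    index_zyx: Sequence[float], voxel_size_um: Sequence[float]
) -> tuple[float, float, float]:
    """Physical (x, y, z) µm of a (possibly fractional) voxel index (z, y, x)."""
    z, y, x = (float(i) for i in index_zyx)
    dz, dy, dx = voxel_size_um
    return ((x + 0.5) * dx, (y + 0.5) * dy, (z + 0.5) * dz)


def physical_to_voxel(
    xyz_um: Sequence[float], voxel_size_um: Sequence[float]
) -> tuple[float, float, float]:
    """Fractional voxel index (z, y, x) of a physical (x, y, z) µm position."""
    x, y, z = (float(v) for v in xyz_um)
    dz, dy, dx = voxel_size_um
    return (z / dz - 0.5, y / dy - 0.5, x / dx - 0.5)


def containing_voxel(
    xyz_um: Sequence[float], voxel_size_um: Sequence[float]
) -> tuple[int, int, int]:
    """Integer (z, y, x) voxel containing a physical point (floor convention)."""
    x, y, z = (float(v) for v in xyz_um)
    dz, dy, dx = voxel_size_um
    return (int(np.floor(z / dz)), int(np.floor(y / dy)), int(np.floor(x / dx)))


# ---------------------------------------------------------------------------
# OME-TIFF stack I/O
# ---------------------------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as a lossless float32 OME-TIFF.

    Channel names and voxel sizes are embedded in the OME-XML; free-form
    metadata is serialized into the ImageDescription via a JSON annotation.
    """
    path = Path(path)
    dz, dy, dx = stack.voxel_size_um
    meta = {
        "axes": "CZYX",
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "µm",
        "Channel": {"Name": list(stack.channel_names)},
    }
    if stack.metadata:
        meta["Description"] = json.dumps(stack.metadata, sort_keys=True)
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        ome=True,
        metadata=meta,
        photometric="minisblack",
    )
    return path


_OME_NS = {"ome": "http://www.openmicroscopy.org/Schemas/OME/2016-06"}


def _parse_ome(xml_text: str) -> tuple[Optional[tuple[float, float, float]], list[str], dict]:
    """Extract (dz, dy, dx), channel names and description from OME-XML."""
    root = ET.fromstring(xml_text)
    pixels = root.find(".//ome:Image/ome:Pixels", _OME_NS)
    voxel = None
    names: list[str] = []
    meta: dict[str, Any] = {}
    if pixels is not None:
        px = pixels.get("PhysicalSizeX")
        py = pixels.get("PhysicalSizeY")
        pz = pixels.get("PhysicalSizeZ")
        if px is not None and py is not None and pz is not None:
            voxel = (float(pz), float(py), float(px))
        for ch in pixels.findall("ome:Channel", _OME_NS):
            names.append(ch.get("Name") or f"channel_{len(names)}")
    desc = root.find(".//ome:Image/ome:Description", _OME_NS)
    if desc is not None and desc.text:
        try:
            meta = json.loads(desc.text)
        except (json.JSONDecodeError, TypeError):
            meta = {"description": desc.text}
    return voxel, names, meta


def read_stack(
    path: str | Path,
    voxel_size_override: Optional[tuple[float, float, float]] = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into the canonical ``(c, z, y, x)`` layout.

    Voxel sizes are parsed from the OME metadata; if absent, the override is
    used (with a logged warning), and if neither exists a ``ValueError`` is
    raised because downstream physical coordinates would be meaningless.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes.upper()
            ome_xml = tf.ome_metadata
    except (tifffile.TiffFileError, ValueError) as exc:
        raise IOError(f"unreadable TIFF {path}: {exc}") from exc

    voxel, names, meta = (None, [], {})
    if ome_xml:
        voxel, names, meta = _parse_ome(ome_xml)

    # Normalize axes to CZYX, adding singleton axes as needed.
    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z").replace("T", "Z")
    for ax in "CZ":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    if set(axes) != set("CZYX") or len(axes) != 4:
        raise IOError(f"unsupported TIFF axes {series.axes!r} in {path}")
    data = np.transpose(data, [axes.index(a) for a in "CZYX"])

    if voxel is None:
        if voxel_size_override is None:
            raise ValueError(
                f"{path} has no voxel-size metadata and no override was given"
            )
        logger.warning("%s: no voxel-size metadata; using override %s", path, voxel_size_override)
        voxel = tuple(float(v) for v in voxel_size_override)
    if len(names) != data.shape[0]:
        names = [f"channel_{i}" for i in range(data.shape[0])]
    return ImageStack(
        voxels=np.asarray(data, dtype=np.float64),
        channel_names=names,
        voxel_size_um=voxel,  # type: ignore[arg-type]
        metadata=meta,
    )


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask as a single-channel int32 OME-TIFF.

    The compartment is recorded as the channel name so round-trips preserve it.
    """
    path = Path(path)
    dz, dy, dx = mask.voxel_size_um
    tifffile.imwrite(
        path,
        mask.labels.astype(np.int32)[np.newaxis],
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "Channel": {"Name": [mask.compartment]},
        },
        photometric="minisblack",
    )
    return path


def read_mask(
    path: str | Path,
    voxel_size_override: Optional[tuple[float, float, float]] = None,
) -> LabelMask:
    stack = read_stack(path, voxel_size_override=voxel_size_override)
    comp = stack.channel_names[0] if stack.channel_names[0] in ("cell", "nucleus") else "cell"
    return LabelMask(
        labels=np.rint(stack.voxels[0]).astype(np.int32),
        compartment=comp,
        voxel_size_um=stack.voxel_size_um,
    )


# ---------------------------------------------------------------------------
# Spot-table CSV I/O
# ---------------------------------------------------------------------------


def write_spot_table(table: SpotTable, path: str | Path) -> Path:
    """Write spots as CSV; provenance goes into '#' comment lines up top.

    Floats are written with 17 significant digits so numeric round-trips are
    exact to well beyond the 12-digit contract.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# source_image={json.dumps(table.source_image)}\n")
    buf.write(f"# params={json.dumps(table.params, sort_keys=True)}\n")
    table.df.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue())
    return path


def read_spot_table(path: str | Path) -> SpotTable:
    path = Path(path)
    source_image = ""
    params: dict[str, Any] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, val = line.lstrip("# ").partition("=")
        if key == "source_image":
            source_image = json.loads(val)
        elif key == "params":
            params = json.loads(val)
    body = "\n".join(lines[body_start:])
    try:
        df = pd.read_csv(io.StringIO(body))
        if len(df):
            df = df.astype({c: float for c in SPOT_COLUMNS if c != "label"})
            df["label"] = df["label"].astype(np.int64)
    except (ValueError, pd.errors.ParserError) as exc:
        bad_line = _find_bad_line(lines, body_start)
        raise ValueError(f"malformed spot table {path} at line {bad_line}: {exc}") from exc
    return SpotTable(df=df, source_image=source_image, params=params)


def _find_bad_line(lines: list[str], body_start: int) -> int:
    """1-based line number of the first row that fails numeric parsing."""
    n_fields = len(lines[body_start].split(","))
    for i, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        parts = line.split(",")
        if len(parts) != n_fields:
            return i
        try:
            [float(p) for p in parts]
        except ValueError:
            return i
    return body_start + 1
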