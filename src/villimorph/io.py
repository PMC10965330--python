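"""TIFF and sidecar-JSON I/O for label volumes, sections and fields.

Labels are written as uint16 multi-page TIFF stacks (2D: single page),
intensities and concentration fields as float32. Physical pixel size and
provenance travel in a sidecar JSON next to each TIFF (``<stem>.json``),
since plain TIFF has no reliable voxel-size convention; a missing sidecar
falls back to an explicit argument, or — only when explicitly allowed — to
the 4.8 µm microCT-like default.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .datatypes import CrossSectionLabels, IntensityImage, LabelVolume
from .errors import ConfigurationError

__all__ = ["read_label_stack", "write_label_stack", "read_cross_section",
           "write_cross_section", "write_intensity", "read_intensity",
           "DEFAULT_VOXEL_SIZE_UM", "DEFAULT_PIXEL_SIZE_2D_UM"]

DEFAULT_VOXEL_SIZE_UM = 4.8  # microCT-like isotropic voxels
DEFAULT_PIXEL_SIZE_2D_UM = 0.015  # EM-like XY pixels (15 nm)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_sidecar(path: Path, **meta) -> None:
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _resolve_size(path: Path, size_key: str, explicit: float | None,
                  default: float, allow_default: bool) -> tuple[float, str]:
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if size_key in meta:
            return float(meta[size_key]), str(meta.get("provenance", ""))
    if explicit is not None:
        return float(explicit), ""
    if allow_default:
        return default, ""
    raise ConfigurationError(
        f"no {size_key} for {path}: provide a sidecar JSON, an explicit "
        "value, or pass allow_default=True")


def _check_integer_labels(data: np.ndarray, path: Path) -> np.ndarray:
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(
            f"{path} holds {data.dtype} pixels; label images must be integer "
            "(was this an intensity or concentration TIFF?)")
    if data.dtype == np.uint16:
        return data
    if data.min(initial=0) < 0 or data.max(initial=0) > np.iinfo(np.uint16).max:
        raise ConfigurationError(f"{path}: label values outside uint16 range")
    return data.astype(np.uint16)


def write_label_stack(volume: LabelVolume, path: str | Path) -> Path:
    """Write a 3D label volume as a uint16 multi-page TIFF plus sidecar."""
    path = Path(path)
    if volume.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ConfigurationError("label values exceed uint16 range")
    tifffile.imwrite(path, volume.labels.astype(np.uint16))
    _write_sidecar(path, voxel_size_um=volume.voxel_size,
                   provenance=volume.provenance, kind="labels3d")
    return path


def read_label_stack(path: str | Path, voxel_size: float | None = None,
                     allow_default: bool = False) -> LabelVolume:
    """Read a 3D label TIFF stack; voxel size from sidecar/argument/default."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    data = _check_integer_labels(np.asarray(data), path)
    size, provenance = _resolve_size(path, "voxel_size_um", voxel_size,
                                     DEFAULT_VOXEL_SIZE_UM, allow_default)
    return LabelVolume(data, voxel_size=size,
                       provenance=provenance or f"read:{path.name}")


def write_cross_section(cross: CrossSectionLabels, path: str | Path) -> Path:
    """Write a 2D label image as a uint16 TIFF plus sidecar."""
    path = Path(path)
    tifffile.imwrite(path, cross.labels.astype(np.uint16))
    _write_sidecar(path, pixel_size_um=cross.pixel_size,
                   provenance=cross.provenance, kind="labels2d")
    return path


def read_cross_section(path: str | Path, pixel_size: float | None = None,
                       allow_default: bool = False) -> CrossSectionLabels:
    """Read a 2D label TIFF; pixel size from sidecar/argument/default."""
    path = Path(path)
    data = np.asarray(tifffile.imread(path))
    if data.ndim != 2:
        raise ConfigurationError(f"{path} is not a single 2D image")
    data = _check_integer_labels(data, path)
    size, provenance = _resolve_size(path, "pixel_size_um", pixel_size,
                                     DEFAULT_PIXEL_SIZE_2D_UM, allow_default)
    return CrossSectionLabels(data, pixel_size=size,
                              provenance=provenance or f"read:{path.name}")


def write_intensity(image: IntensityImage, path: str | Path) -> Path:
    """Write an intensity (or concentration-field) image as float32 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, image.values.astype(np.float32),
                     photometric="minisblack")
    _write_sidecar(path, pixel_size_um=image.pixel_size,
                   provenance=image.provenance, kind="intensity")
    return path


def read_intensity(path: str | Path, pixel_size: float | None = None,
                   allow_default: bool = False) -> IntensityImage:
    """Read a float TIFF as an intensity image."""
    path = Path(path)
    data = np.asarray(tifffile.imread(path)).astype(np.float32)
    default = (DEFAULT_VOXEL_SIZE_UM if data.ndim == 3
               else DEFAULT_PIXEL_SIZE_2D_UM)
    size, provenance = _resolve_size(path, "pixel_size_um", pixel_size,
                                     default, allow_default)
    return IntensityImage(data, pixel_size=size,
                          provenance=provenance or f"read:{path.name}")
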