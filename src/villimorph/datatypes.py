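"""Core in-memory containers for label images and intensity renderings.

All physical sizes are in micrometres (µm). 3D volumes are indexed (z, y, x)
and assumed isotropic; 2D cross-sections are indexed (row, col).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

# Label conventions shared by phantoms, segmentation, morphometry, transport.
BACKGROUND = 0
TROPHOBLAST = 1
STROMA = 2
CAPILLARY = 3

CLASS_NAMES = {
    BACKGROUND: "background",
    TROPHOBLAST: "trophoblast",
    STROMA: "stroma",
    CAPILLARY: "capillary",
}


def _check_labels(labels: np.ndarray, ndim: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != ndim:
        raise ConfigurationError(f"expected a {ndim}D label array, got {labels.ndim}D")
    if not np.issubdtype(labels.dtype, np.integer):
        raise TypeError(f"labels must be integer-typed, got {labels.dtype}")
    if labels.size and labels.min() < 0:
        raise ConfigurationError("labels must be non-negative (background = 0)")
    return labels


@dataclass
class LabelVolume:
    """3D integer label volume with isotropic physical voxel size in µm."""

    labels: np.ndarray
    voxel_size: float
    provenance: str = ""

    def __post_init__(self):
        self.labels = _check_labels(self.labels, 3)
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be > 0")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def foreground(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class CrossSectionLabels:
    """2D labelled villus cross-section (background/trophoblast/stroma/capillary)."""

    labels: np.ndarray
    pixel_size: float
    provenance: str = ""

    def __post_init__(self):
        self.labels = _check_labels(self.labels, 2)
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def class_mask(self, *classes: int) -> np.ndarray:
        return np.isin(self.labels, classes)


@dataclass
class IntensityImage:
    """Greyscale rendering (2D or 3D) with physical pixel/voxel size in µm."""

    values: np.ndarray
    pixel_size: float
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim not in (2, 3):
            raise ConfigurationError("intensity image must be 2D or 3D")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("intensity values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape
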