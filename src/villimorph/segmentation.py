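"""Label extraction from intensity images.

Masked intensity thresholding (fixed or Otsu-within-mask), removal of small
connected components, and cubic subvolume cropping. Manual curation is out of
band: a curated label image is supplied as data, not produced here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .datatypes import CrossSectionLabels, IntensityImage, LabelVolume
from .errors import BoundsError, ConfigurationError

__all__ = ["SegmentationConfig", "threshold_segment",
           "filter_small_components", "crop_subvolume"]

logger = logging.getLogger(__name__)

# Neighbourhood names → scipy structuring-element connectivity rank.
_CONNECTIVITY_RANK = {
    (3, 6): 1, (3, 18): 2, (3, 26): 3,  # 3D face / edge / vertex
    (2, 4): 1, (2, 8): 2,  # 2D
}


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    try:
        rank = _CONNECTIVITY_RANK[(ndim, connectivity)]
    except KeyError:
        valid = sorted(c for (d, c) in _CONNECTIVITY_RANK if d == ndim)
        raise ConfigurationError(
            f"connectivity {connectivity} invalid for {ndim}D "
            f"(choose from {valid})") from None
    return ndimage.generate_binary_structure(ndim, rank)


@dataclass
class SegmentationConfig:
    """Parameters of the thresholding + component-filter stage."""

    threshold: float | str = "otsu"  # intensity value, or "otsu" within mask
    mask: np.ndarray | None = None  # binary ROI; None = whole image
    min_component_voxels: int = 1000
    connectivity: int = 26  # 6/18/26 (3D) or 4/8 (2D)
    invert: bool = False  # foreground = low intensity when True

    def __post_init__(self):
        if self.min_component_voxels < 0:
            raise ConfigurationError("min_component_voxels must be ≥ 0")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ConfigurationError(
                f"threshold must be a number or 'otsu', got {self.threshold!r}")


def threshold_segment(intensity: IntensityImage,
                      config: SegmentationConfig) -> LabelVolume | CrossSectionLabels:
    """Binary foreground by (masked) intensity thresholding.

    Foreground = pixels inside the mask with intensity ≥ threshold (≤ when
    ``config.invert``). ``threshold='otsu'`` computes Otsu's threshold from
    the within-mask intensities only. Returns a binary label image (0/1) of
    the same dimensionality with the physical pixel size carried over.
    """
    values = intensity.values
    if config.mask is not None:
        mask = np.asarray(config.mask).astype(bool)
        if mask.shape != values.shape:
            raise ConfigurationError(
                f"mask shape {mask.shape} != image shape {values.shape}")
        if not mask.any():
            raise ConfigurationError("mask is empty: no voxels to threshold")
    else:
        mask = np.ones(values.shape, dtype=bool)

    if config.threshold == "otsu":
        t = float(threshold_otsu(values[mask]))
    else:
        t = float(config.threshold)

    fg = (values <= t) if config.invert else (values >= t)
    fg &= mask
    n_fg = int(fg.sum())
    if n_fg == 0 or n_fg == int(mask.sum()):
        logger.warning("threshold %.4g produced an all-%s result within the mask",
                       t, "background" if n_fg == 0 else "foreground")
    labels = fg.astype(np.uint16)
    provenance = f"threshold_segment(t={t:.6g}, invert={config.invert})"
    if values.ndim == 3:
        return LabelVolume(labels, voxel_size=intensity.pixel_size,
                           provenance=provenance)
    return CrossSectionLabels(labels, pixel_size=intensity.pixel_size,
                              provenance=provenance)


def filter_small_components(volume: LabelVolume | CrossSectionLabels,
                            min_voxels: int = 1000,
                            connectivity: int | None = None):
    """Remove connected foreground components smaller than ``min_voxels``.

    Strict "less than" semantics: a component of exactly ``min_voxels`` voxels
    survives. Connectivity defaults to 26 (3D) / 8 (2D). Original label values
    of surviving components are preserved; removed voxels become background.
    """
    arr = volume.labels
    if connectivity is None:
        connectivity = 26 if arr.ndim == 3 else 8
    structure = _structure(arr.ndim, connectivity)
    fg = arr > 0
    comp, n_comp = ndimage.label(fg, structure=structure)
    if n_comp == 0:
        out = arr.copy()
    else:
        counts = np.bincount(comp.ravel())
        small = counts < min_voxels
        small[0] = False
        out = np.where(small[comp], 0, arr).astype(arr.dtype)
        n_removed = int(small.sum())
        logger.info("component filter: %d components, %d removed (< %d voxels)",
                    n_comp, n_removed, min_voxels)
    kwargs = dict(provenance=volume.provenance
                  + f" | filter_small_components(min={min_voxels}, conn={connectivity})")
    if arr.ndim == 3:
        return LabelVolume(out, voxel_size=volume.voxel_size, **kwargs)
    return CrossSectionLabels(out, pixel_size=volume.pixel_size, **kwargs)


def crop_subvolume(volume: LabelVolume, origin: tuple[int, int, int],
                   edge: int = 128) -> LabelVolume:
    """Crop a cubic ``edge``³ subvolume starting at voxel ``origin``.

    Objects clipped at the crop faces are retained (clipped). The physical
    voxel size is preserved. Out-of-bounds windows raise :class:`BoundsError`.
    """
    if edge <= 0:
        raise ConfigurationError("edge must be > 0")
    origin = tuple(int(o) for o in origin)
    shape = volume.labels.shape
    if len(origin) != 3:
        raise ConfigurationError("origin must be a 3-vector of voxel indices")
    for o, s in zip(origin, shape):
        if o < 0 or o + edge > s:
            raise BoundsError(
                f"crop origin {origin} + edge {edge} exceeds volume shape {shape}")
    sl = tuple(slice(o, o + edge) for o in origin)
    return LabelVolume(volume.labels[sl].copy(), voxel_size=volume.voxel_size,
                       provenance=volume.provenance
                       + f" | crop(origin={origin}, edge={edge})")
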