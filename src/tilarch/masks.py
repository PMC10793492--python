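"""Compartment probability-mask post-processing and ROI tile selection.

The upstream segmentation model emits, per slide region, a grayscale map of
per-pixel epithelium (or stroma) probabilities.  Here those maps are
thresholded into binary masks, small connected components are removed
(default: anything under 2,000 pixels), quality-control masks are
intersected in, and the image is gridded into non-overlapping tiles that
are labeled by compartment when sufficiently covered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .errors import ValidationError


@dataclass
class ProbMask:
    """Per-pixel probability raster with physical calibration (um/pixel)."""

    values: np.ndarray
    mpp: float = 0.2527

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("mask must be a 2-D raster")
        if not self.mpp > 0:
            raise ValidationError("mpp must be positive")
        if np.isnan(self.values).any() or \
                self.values.min() < 0 or self.values.max() > 1:
            raise ValidationError("probabilities must lie in [0, 1]")


@dataclass
class BinaryMask:
    """Strictly binary raster with physical calibration."""

    values: np.ndarray
    mpp: float = 0.2527

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValidationError("mask must be a 2-D raster")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, [0, 1]).all():
                raise ValidationError("binary mask must contain only 0/1")
            arr = arr.astype(bool)
        self.values = arr
        if not self.mpp > 0:
            raise ValidationError("mpp must be positive")


@dataclass(frozen=True)
class ROITile:
    """One selected tile: 0-based top-left origin, half-open extent."""

    tile_id: str
    x0: int
    y0: int
    size_px: int
    compartment: str


def binarize_and_clean(mask: ProbMask, threshold: float = 0.5,
                       min_area_px: int = 2000,
                       connectivity: int = 2) -> BinaryMask:
    """Threshold a probability mask and drop small connected components.

    A pixel survives iff its probability is >= ``threshold`` and its
    connected component (8-connectivity by default) has at least
    ``min_area_px`` pixels.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError("threshold must lie in [0, 1]")
    if min_area_px < 0:
        raise ValidationError("min_area_px must be nonnegative")
    binary = mask.values >= threshold
    if min_area_px > 0 and binary.any():
        labels = measure.label(binary, connectivity=connectivity)
        areas = np.bincount(labels.ravel())
        keep = areas >= min_area_px
        keep[0] = False
        binary = keep[labels]
    return BinaryMask(binary, mask.mpp)


def apply_qc_and_select_tiles(epi: BinaryMask, stroma: BinaryMask,
                              qc: BinaryMask, tile_size_px: int = 512,
                              min_foreground_frac: float = 0.5) -> list[ROITile]:
    """Intersect compartments with QC and emit covered grid tiles.

    The image is gridded into non-overlapping ``tile_size_px`` squares
    (partial edge tiles are not considered).  A tile is emitted for a
    compartment when that compartment covers at least
    ``min_foreground_frac`` of its pixels; a tile covered by both
    compartments is emitted twice.
    """
    shapes = {epi.values.shape, stroma.values.shape, qc.values.shape}
    if len(shapes) != 1:
        raise ValidationError(f"mask shapes differ: {shapes}")
    if not tile_size_px > 0:
        raise ValidationError("tile_size_px must be positive")
    if not 0 < min_foreground_frac <= 1:
        raise ValidationError("min_foreground_frac must lie in (0, 1]")
    h, w = qc.values.shape
    nrow, ncol = h // tile_size_px, w // tile_size_px
    tiles: list[ROITile] = []
    masks = {"epithelium": epi.values & qc.values,
             "stroma": stroma.values & qc.values}
    denom = tile_size_px ** 2
    for comp, m in masks.items():
        cropped = m[: nrow * tile_size_px, : ncol * tile_size_px]
        if nrow == 0 or ncol == 0:
            continue
        blocks = cropped.reshape(nrow, tile_size_px, ncol, tile_size_px)
        frac = blocks.sum(axis=(1, 3)) / denom
        for r, c in zip(*np.nonzero(frac >= min_foreground_frac)):
            x0, y0 = int(c * tile_size_px), int(r * tile_size_px)
            tiles.append(ROITile(
                tile_id=f"x{x0}_y{y0}", x0=x0, y0=y0,
                size_px=tile_size_px, compartment=comp))
    tiles.sort(key=lambda t: (t.y0, t.x0, t.compartment))
    return tiles


def tiles_to_frame(tiles: list[ROITile]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tile_id": t.tile_id, "x0": t.x0, "y0": t.y0,
          "size_px": t.size_px, "compartment": t.compartment} for t in tiles],
        columns=["tile_id", "x0", "y0", "size_px", "compartment"])
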