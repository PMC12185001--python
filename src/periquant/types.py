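"""Core containers shared across the imaging pipeline.

The analysis operates on multi-channel fluorescence fields (lineage-reporter
GFP, vascular marker CD109, nuclear DAPI), restricted to a region of interest
(typically the compact myocardium), and reduces each channel to a table of
labeled connected components ("objects").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


#: Column order of every per-object table produced by segmentation.
OBJECT_COLUMNS = ("object_id", "area_px", "centroid_row", "centroid_col")


@dataclass
class MultiChannelImage:
    """Named intensity channels on a shared pixel grid.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D array of non-negative finite intensities.
        All channels must share the same ``(height, width)``.
    image_id, specimen_id, genotype
        Sample-sheet linkage; empty strings when unknown.
    pixel_size_um
        Physical pixel size. Classification stays in pixels; this field only
        enables micrometre conversion in reports.
    """

    channels: dict[str, np.ndarray]
    image_id: str = ""
    specimen_id: str = ""
    genotype: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("image must contain at least one channel")
        shapes = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValidationError(f"channel {name!r} is not a 2-D grid")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(
                    f"channel {name!r} has non-finite or negative intensities"
                )
            self.channels[name] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValidationError(f"channels disagree on shape: {sorted(shapes)}")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class RoiMask:
    """Boolean region-of-interest mask with a provenance note."""

    mask: np.ndarray
    provenance: str = "full-frame"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("ROI mask must be 2-D")

    @classmethod
    def full_frame(cls, shape: tuple[int, int]) -> "RoiMask":
        return cls(np.ones(shape, dtype=bool), provenance="full-frame")

    @classmethod
    def from_polygon(
        cls, shape: tuple[int, int], vertices_rowcol: np.ndarray
    ) -> "RoiMask":
        """Rasterize a polygon given as (row, col) vertices.

        A pixel belongs to the ROI when its center lies inside the polygon.
        """
        from matplotlib.path import Path

        vertices_rowcol = np.asarray(vertices_rowcol, dtype=float)
        if vertices_rowcol.ndim != 2 or vertices_rowcol.shape[1] != 2:
            raise ValidationError("polygon vertices must be an (n, 2) array")
        if len(vertices_rowcol) < 3:
            raise ValidationError("polygon needs at least 3 vertices")
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        pts = np.column_stack([rr.ravel(), cc.ravel()])
        inside = Path(vertices_rowcol).contains_points(pts)
        return cls(
            inside.reshape(shape),
            provenance=f"polygon:{vertices_rowcol.tolist()}",
        )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SegmentedObjects:
    """Labeled connected components of one channel.

    ``labels`` is an integer grid (0 = background, k = object k with labels
    contiguous ``1..K``); ``table`` holds one row per object with the columns
    in :data:`OBJECT_COLUMNS`. Centroids are unweighted pixel-coordinate
    means, 0-based, (row, col) order.
    """

    channel: str
    labels: np.ndarray
    table: pd.DataFrame
    threshold_used: float
    image_id: str = ""

    @property
    def n_objects(self) -> int:
        return len(self.table)

    @property
    def total_area_px(self) -> int:
        return int(self.table["area_px"].sum())

    def centroids(self) -> np.ndarray:
        """(K, 2) array of (row, col) centroids in object_id order."""
        return self.table[["centroid_row", "centroid_col"]].to_numpy(float)
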