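"""Area quantification: fluorescence area fractions and scratch closure.

Per-field "fluorescence area" is the total Otsu-foreground pixel count of a
channel after size filtering. GFP area is first normalized to DAPI area
(controls for sectioned-myocardium size differences), then to the control
group (control mean set to 1.0) for cross-genotype comparison. Field pairs
(GFP area, CD109 area) feed the regression of cell invasion against
vasculature.

Scratch closure: the acellular wound region of a confluent GFP explant field
is the union of connected sub-Otsu background components intersecting the
scratch ROI; ``closure_fraction(t) = 1 - area_t / area_0``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .segmentation import (
    DEFAULT_MIN_AREA_PX,
    DegenerateHistogramError,
    label_objects,
    otsu_threshold,
)
from .types import MultiChannelImage, RoiMask, SegmentedObjects, ValidationError

logger = logging.getLogger(__name__)

FIELD_COLUMNS = (
    "image_id",
    "specimen_id",
    "genotype",
    "gfp_area_px",
    "cd109_area_px",
    "dapi_area_px",
    "gfp_over_dapi",
    "valid",
)


# ---------------------------------------------------------------------------
# Area fractions
# ---------------------------------------------------------------------------

def area_fractions(
    objects_by_channel: dict[str, SegmentedObjects],
    *,
    image_id: str = "",
    specimen_id: str = "",
    genotype: str = "",
) -> dict:
    """Per-field channel areas and the GFP/DAPI ratio.

    A field with zero DAPI area is flagged invalid (``valid=False``,
    ``gfp_over_dapi=nan``) and later excluded from group means.
    """
    areas = {
        ch: objects_by_channel[ch].total_area_px if ch in objects_by_channel else 0
        for ch in ("GFP", "CD109", "DAPI")
    }
    valid = areas["DAPI"] > 0
    if not valid:
        logger.warning("field %s: DAPI area is 0; flagged invalid", image_id)
    gfp_over_dapi = areas["GFP"] / areas["DAPI"] if valid else float("nan")
    gfp_obj = objects_by_channel.get("GFP")
    return {
        "image_id": image_id or (gfp_obj.image_id if gfp_obj is not None else ""),
        "specimen_id": specimen_id,
        "genotype": genotype,
        "gfp_area_px": int(areas["GFP"]),
        "cd109_area_px": int(areas["CD109"]),
        "dapi_area_px": int(areas["DAPI"]),
        "gfp_over_dapi": gfp_over_dapi,
        "valid": bool(valid),
    }


def fields_table(
    objects_by_image: dict[str, dict[str, SegmentedObjects]],
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Tabulate :func:`area_fractions` over a segmented cohort."""
    sheet = sample_sheet.set_index("image_id", drop=False)
    rows = []
    for image_id, chans in objects_by_image.items():
        meta = sheet.loc[image_id]
        rows.append(
            area_fractions(
                chans,
                image_id=image_id,
                specimen_id=meta["specimen_id"],
                genotype=meta["genotype"],
            )
        )
    return pd.DataFrame(rows, columns=list(FIELD_COLUMNS))


def normalize_to_control(
    fields: pd.DataFrame, control_genotype: str = "control"
) -> pd.DataFrame:
    """Scale GFP/DAPI ratios so the control-group mean equals 1.0 exactly.

    Invalid fields (zero DAPI) receive ``normalized_gfp=nan`` and do not
    enter the control mean.
    """
    valid = fields["valid"].astype(bool)
    control = fields[(fields["genotype"] == control_genotype) & valid]
    if len(control) == 0:
        raise ValidationError("no valid control fields to normalize against")
    control_mean = float(control["gfp_over_dapi"].mean())
    out = fields.copy()
    out["normalized_gfp"] = np.where(
        valid, fields["gfp_over_dapi"] / control_mean, np.nan
    )
    return out


def field_pairs_for_regression(fields: pd.DataFrame) -> pd.DataFrame:
    """(GFP area, CD109 area) pairs with genotype labels, invalid fields
    dropped."""
    keep = fields[fields["valid"].astype(bool)]
    return keep[["gfp_area_px", "cd109_area_px", "genotype"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Scratch closure
# ---------------------------------------------------------------------------

def measure_acellular_area(
    image: MultiChannelImage,
    scratch_roi: RoiMask,
    channel: str = "GFP",
) -> int:
    """Acellular area of one frame: background components touching the ROI.

    Background is everything at or below the Otsu cut of the GFP channel;
    the acellular region is the union of connected background components
    that intersect the scratch ROI. An intensity-constant frame (fully
    closed, confluent field) has no detectable background and returns 0.
    """
    arr = image.channels[channel]
    if scratch_roi.mask.shape != arr.shape:
        raise ValidationError("scratch ROI shape does not match image")
    try:
        t = otsu_threshold(arr)
    except DegenerateHistogramError:
        return 0
    background = ~(arr > t)
    objs = label_objects(background, 8)
    if objs.n_objects == 0:
        return 0
    touching = np.unique(objs.labels[scratch_roi.mask])
    touching = touching[touching > 0]
    return int(np.isin(objs.labels, touching).sum())


def scratch_closure(
    images: list[MultiChannelImage],
    timepoints_h: list[float],
    scratch_roi: RoiMask,
    *,
    explant_id: str = "",
    genotype: str = "",
    channel: str = "GFP",
) -> pd.DataFrame:
    """Acellular area and closure fraction over a scratch time series.

    Requires >= 2 timepoints including t = 0 with a detectable wound;
    area increases > 5% between consecutive timepoints are logged as
    warnings (the assay expects monotone closure) but kept.
    """
    t = np.asarray(timepoints_h, dtype=float)
    if len(images) != len(t):
        raise ValidationError("one image per timepoint required")
    if len(t) < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValidationError("need >= 2 strictly increasing timepoints with t=0 first")
    areas = [measure_acellular_area(img, scratch_roi, channel) for img in images]
    if areas[0] == 0:
        raise ValidationError("no wound detected at t = 0 (acellular area is 0)")
    for i in range(1, len(areas)):
        if areas[i] > areas[i - 1] * 1.05:
            logger.warning(
                "scratch %s: acellular area grew %d -> %d px between t=%g and t=%g h",
                explant_id, areas[i - 1], areas[i], t[i - 1], t[i],
            )
    return pd.DataFrame(
        {
            "explant_id": explant_id,
            "genotype": genotype,
            "timepoint_h": t,
            "acellular_area_px": areas,
            "closure_fraction": 1.0 - np.asarray(areas, dtype=float) / areas[0],
        }
    )
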