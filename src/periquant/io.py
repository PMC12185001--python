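"""File I/O: per-channel 16-bit TIFFs, CSV tables, YAML scene configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import SceneSpec, ScratchSeriesSpec
from .types import MultiChannelImage, RoiMask, SegmentedObjects, ValidationError

CHANNEL_SUFFIXES = ("GFP", "CD109", "DAPI")


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_image_tiffs(image: MultiChannelImage, out_dir: str | Path) -> list[Path]:
    """Write each channel as ``<image_id>_<channel>.tif`` (16-bit grayscale)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in image.channels.items():
        path = out_dir / f"{image.image_id or 'image'}_{name}.tif"
        data = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(path, data)
        paths.append(path)
    return paths


def read_image_tiffs(
    paths: dict[str, str | Path],
    *,
    image_id: str = "",
    specimen_id: str = "",
    genotype: str = "",
) -> MultiChannelImage:
    """Read per-channel grayscale TIFFs into one multi-channel image."""
    channels = {}
    for name, path in paths.items():
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise ValidationError(f"{path}: expected a 2-D grayscale TIFF")
        channels[name] = arr.astype(float)
    return MultiChannelImage(
        channels=channels, image_id=image_id,
        specimen_id=specimen_id, genotype=genotype,
    )


def read_multipage_tiff(
    path: str | Path, channel_names: list[str], **meta
) -> MultiChannelImage:
    """Read a multi-page TIFF, one named channel per page."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(channel_names):
        raise ValidationError(
            f"{path}: {stack.shape[0]} pages but {len(channel_names)} channel names"
        )
    return MultiChannelImage(
        channels={n: stack[i].astype(float) for i, n in enumerate(channel_names)},
        **meta,
    )


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def read_roi(path: str | Path, shape: tuple[int, int]) -> RoiMask:
    """Read an ROI: polygon CSV (row,col columns), polygon JSON (list of
    [row, col]), or a binary mask TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        mask = tifffile.imread(path) > 0
        if mask.shape != shape:
            raise ValidationError(f"{path}: mask shape {mask.shape} != image {shape}")
        return RoiMask(mask, provenance=f"mask:{path.name}")
    if path.suffix.lower() == ".json":
        vertices = np.asarray(json.loads(path.read_text()), dtype=float)
    else:
        df = pd.read_csv(path)
        vertices = df[["row", "col"]].to_numpy(float)
    return RoiMask.from_polygon(shape, vertices)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_object_table(objects: SegmentedObjects, path: str | Path) -> None:
    table = objects.table.copy()
    table.insert(0, "image_id", objects.image_id)
    table.insert(2, "channel", objects.channel)
    table["threshold_used"] = objects.threshold_used
    table.to_csv(path, index=False)


def write_label_map(objects: SegmentedObjects, path: str | Path) -> None:
    tifffile.imwrite(Path(path), objects.labels.astype(np.uint16))


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scene configs
# ---------------------------------------------------------------------------

def write_scene_spec(spec: SceneSpec | ScratchSeriesSpec, path: str | Path) -> None:
    data = asdict(spec)
    if isinstance(spec, ScratchSeriesSpec):
        data["timepoints_h"] = list(data["timepoints_h"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_scene_spec(path: str | Path) -> SceneSpec:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return SceneSpec(**data)


def read_scratch_spec(path: str | Path) -> ScratchSeriesSpec:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "timepoints_h" in data:
        data["timepoints_h"] = tuple(float(t) for t in data["timepoints_h"])
    return ScratchSeriesSpec(**data)
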