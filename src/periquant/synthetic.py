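"""Synthetic fluorescence scenes with ground truth.

The generator emulates the spatial structure the proximity analysis assumes
in embryonic heart sections: CD109+ vessel cross-sections scattered
uniformly in the field, GFP+ lineage-labeled cells drawn from a mixture of a
*perivascular* component spatially coupled to vessels (centroid offset
``|Normal(0, coupling_scale_px)|`` at a uniform angle from a uniformly
chosen vessel centroid) and an *interstitial* component uniform over the
field, plus uniform DAPI nuclei. A genotype effect is modeled as selective
thinning of the interstitial component: each interstitial cell is retained
with probability ``interstitial_retention`` while perivascular cells are
always kept, so the expected cell count is
``n_gfp * (p_f + (1 - p_f) * retention)``.

Objects are rendered as filled disks of ``intensity_fg`` over
``intensity_bg``; optional Poisson resampling (photon-scaled intensities)
followed by additive Gaussian noise. Ground truth records every rendered
object pre-noise. Identical specs (including seed) produce bit-identical
output.

A scratch-assay series renders a confluent GFP field with a centered
vertical acellular band whose width closes linearly in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .types import MultiChannelImage, ValidationError

MAX_PLACEMENT_ATTEMPTS = 1000

GT_COLUMNS = (
    "object_id",
    "channel",
    "centroid_row",
    "centroid_col",
    "radius_px",
    "true_class",
)


class GenerationError(RuntimeError):
    """Raised when object placement fails after the attempt budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters of one synthetic field.

    Defaults describe the study conditions of the original cohort analysis:
    512x512 fields containing ~20 vessel cross-sections and 200 lineage-
    labeled cells of which half are vessel-coupled with a 5-px half-normal
    offset scale; ``interstitial_retention=1`` is the control condition and
    values < 1 model the mutant's selective interstitial depletion.
    """

    height_px: int = 512
    width_px: int = 512
    n_vessels: int = 20
    vessel_radius_px: float = 6.0
    n_gfp: int = 200
    gfp_radius_px: float = 3.0
    perivascular_fraction: float = 0.5
    coupling_scale_px: float = 5.0
    interstitial_retention: float = 1.0
    n_nuclei: int = 300
    nucleus_radius_px: float = 4.0
    intensity_fg: float = 3000.0
    intensity_bg: float = 200.0
    noise_gaussian_sd: float = 0.0
    noise_poisson: bool = False
    min_separation: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.height_px < 8 or self.width_px < 8:
            raise ValidationError("field must be at least 8x8 pixels")
        for name in ("n_vessels", "n_gfp", "n_nuclei"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("vessel_radius_px", "gfp_radius_px", "nucleus_radius_px",
                     "coupling_scale_px", "intensity_fg"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.perivascular_fraction <= 1.0:
            raise ValidationError("perivascular_fraction must lie in [0, 1]")
        if not 0.0 < self.interstitial_retention <= 1.0:
            raise ValidationError("interstitial_retention must lie in (0, 1]")
        if self.intensity_bg < 0 or self.noise_gaussian_sd < 0:
            raise ValidationError("intensity_bg and noise sd must be >= 0")


@dataclass(frozen=True)
class ScratchSeriesSpec:
    """Parameters of a synthetic scratch-closure time series."""

    timepoints_h: tuple[float, ...] = (0.0, 8.0, 12.0, 16.0)
    initial_gap_width_px: float = 100.0
    closure_rate_px_per_h: float = 6.25
    height_px: int = 256
    width_px: int = 256
    intensity_fg: float = 3000.0
    intensity_bg: float = 200.0
    noise_gaussian_sd: float = 0.0
    noise_poisson: bool = False
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size < 1 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("timepoints must be non-negative, strictly increasing")
        if self.initial_gap_width_px <= 0:
            raise ValidationError("initial_gap_width_px must be positive")
        if self.closure_rate_px_per_h < 0:
            raise ValidationError("closure_rate_px_per_h must be >= 0")

    def gap_width_at(self, t_h: float) -> float:
        """Analytic gap width, clamped at zero."""
        return max(0.0, self.initial_gap_width_px - self.closure_rate_px_per_h * t_h)


# ---------------------------------------------------------------------------
# Placement and rendering helpers
# ---------------------------------------------------------------------------

def _uniform_in_bounds(rng: np.random.Generator, h: int, w: int, margin: float):
    r = rng.uniform(margin, h - 1 - margin)
    c = rng.uniform(margin, w - 1 - margin)
    return r, c


def _separated(r: float, c: float, placed: list[tuple[float, float]], min_d: float) -> bool:
    return all((r - pr) ** 2 + (c - pc) ** 2 >= min_d**2 for pr, pc in placed)


def _place_uniform(
    rng: np.random.Generator,
    n: int,
    h: int,
    w: int,
    radius: float,
    min_sep: float | None,
    channel: str,
) -> list[tuple[float, float]]:
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            r, c = _uniform_in_bounds(rng, h, w, radius)
            if min_sep is None or _separated(r, c, placed, min_sep):
                placed.append((r, c))
                break
        else:
            raise GenerationError(
                f"could not place object {len(placed) + 1} in channel {channel}"
            )
    return placed


def _render_disks(
    h: int,
    w: int,
    centers: list[tuple[float, float]],
    radius: float,
    fg: float,
    bg: float,
) -> np.ndarray:
    canvas = np.full((h, w), bg, dtype=float)
    rad_i = int(math.ceil(radius))
    for r0, c0 in centers:
        r_lo, r_hi = max(0, int(r0) - rad_i - 1), min(h, int(r0) + rad_i + 2)
        c_lo, c_hi = max(0, int(c0) - rad_i - 1), min(w, int(c0) + rad_i + 2)
        rows = np.arange(r_lo, r_hi, dtype=float)[:, None]
        cols = np.arange(c_lo, c_hi, dtype=float)[None, :]
        inside = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2
        patch = canvas[r_lo:r_hi, c_lo:c_hi]
        patch[inside] = fg
    return canvas


def _add_noise(
    canvas: np.ndarray, rng: np.random.Generator, poisson: bool, gaussian_sd: float
) -> np.ndarray:
    if not poisson and gaussian_sd == 0:
        return canvas
    out = canvas
    if poisson:
        out = rng.poisson(out).astype(float)
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Render one scene and its ground-truth object table.

    Returns the image (channels GFP, CD109, DAPI) and a DataFrame with
    :data:`GT_COLUMNS`; ``true_class`` is perivascular/interstitial for GFP
    objects and ``not-applicable`` otherwise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    sep = (lambda r: 2 * r + 1) if spec.min_separation else (lambda r: None)

    vessels = _place_uniform(
        rng, spec.n_vessels, h, w, spec.vessel_radius_px,
        sep(spec.vessel_radius_px), "CD109",
    )

    gfp_centers: list[tuple[float, float]] = []
    gfp_classes: list[str] = []
    min_sep_gfp = sep(spec.gfp_radius_px)
    for _ in range(spec.n_gfp):
        is_peri = bool(spec.n_vessels) and rng.uniform() < spec.perivascular_fraction
        if not is_peri and rng.uniform() >= spec.interstitial_retention:
            continue  # interstitial cell thinned out (genotype effect)
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            if is_peri:
                vr, vc = vessels[rng.integers(spec.n_vessels)]
                dist = abs(rng.normal(0.0, spec.coupling_scale_px))
                ang = rng.uniform(0.0, 2.0 * math.pi)
                r = vr + dist * math.sin(ang)
                c = vc + dist * math.cos(ang)
                if not (spec.gfp_radius_px <= r <= h - 1 - spec.gfp_radius_px
                        and spec.gfp_radius_px <= c <= w - 1 - spec.gfp_radius_px):
                    continue
            else:
                r, c = _uniform_in_bounds(rng, h, w, spec.gfp_radius_px)
            if min_sep_gfp is None or _separated(r, c, gfp_centers, min_sep_gfp):
                gfp_centers.append((r, c))
                gfp_classes.append("perivascular" if is_peri else "interstitial")
                break
        else:
            raise GenerationError(
                f"could not place object {len(gfp_centers) + 1} in channel GFP"
            )

    nuclei = _place_uniform(
        rng, spec.n_nuclei, h, w, spec.nucleus_radius_px,
        sep(spec.nucleus_radius_px), "DAPI",
    )

    channels = {
        "GFP": _render_disks(h, w, gfp_centers, spec.gfp_radius_px,
                             spec.intensity_fg, spec.intensity_bg),
        "CD109": _render_disks(h, w, vessels, spec.vessel_radius_px,
                               spec.intensity_fg, spec.intensity_bg),
        "DAPI": _render_disks(h, w, nuclei, spec.nucleus_radius_px,
                              spec.intensity_fg, spec.intensity_bg),
    }
    for name in ("GFP", "CD109", "DAPI"):
        channels[name] = _add_noise(
            channels[name], rng, spec.noise_poisson, spec.noise_gaussian_sd
        )

    rows = []
    for i, (r, c) in enumerate(vessels, start=1):
        rows.append((i, "CD109", r, c, spec.vessel_radius_px, "not-applicable"))
    for i, ((r, c), cls) in enumerate(zip(gfp_centers, gfp_classes), start=1):
        rows.append((i, "GFP", r, c, spec.gfp_radius_px, cls))
    for i, (r, c) in enumerate(nuclei, start=1):
        rows.append((i, "DAPI", r, c, spec.nucleus_radius_px, "not-applicable"))
    truth = pd.DataFrame(rows, columns=list(GT_COLUMNS))

    image = MultiChannelImage(channels=channels)
    return image, truth


def objects_from_ground_truth(
    truth: pd.DataFrame, channel: str, image_id: str = ""
) -> "SegmentedObjects":
    """Ground-truth object table as a :class:`SegmentedObjects` view.

    Lets proximity/area analyses run on the generator's exact centroids
    (bypassing rendering and segmentation) for oracle comparisons; the label
    grid is empty and areas are the analytic disk areas.
    """
    from .types import SegmentedObjects

    sub = truth[truth["channel"] == channel].reset_index(drop=True)
    table = pd.DataFrame(
        {
            "object_id": np.arange(1, len(sub) + 1),
            "area_px": np.rint(math.pi * sub["radius_px"] ** 2).astype(int),
            "centroid_row": sub["centroid_row"].to_numpy(float),
            "centroid_col": sub["centroid_col"].to_numpy(float),
        }
    )
    return SegmentedObjects(
        channel=channel,
        labels=np.zeros((1, 1), dtype=np.int32),
        table=table,
        threshold_used=float("nan"),
        image_id=image_id,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def derive_image_seed(master_seed: int, genotype_index: int,
                      specimen_index: int, image_index: int) -> int:
    """Deterministic counter-based per-image seed (< 2**31)."""
    ss = np.random.SeedSequence(
        [int(master_seed), genotype_index, specimen_index, image_index]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    control_spec: SceneSpec,
    mutant_spec: SceneSpec,
    n_specimens: int = 4,
    images_per_specimen: int = 6,
    seed: int = 0,
    genotype_names: tuple[str, str] = ("control", "mutant"),
) -> tuple[pd.DataFrame, dict[str, tuple[MultiChannelImage, pd.DataFrame]]]:
    """Generate a two-genotype cohort with a sample sheet.

    Per-image seeds are derived from ``(seed, genotype, specimen, image)``
    so any sub-cohort is reproducible in isolation. The default cohort
    geometry (4 specimens x 6 images per genotype) mirrors the original
    study design.
    """
    if n_specimens < 1 or images_per_specimen < 1:
        raise ValidationError("need >= 1 specimen and >= 1 image per specimen")
    sheet_rows = []
    scenes: dict[str, tuple[MultiChannelImage, pd.DataFrame]] = {}
    for g_idx, (genotype, spec) in enumerate(
        zip(genotype_names, (control_spec, mutant_spec))
    ):
        for s_idx in range(1, n_specimens + 1):
            specimen_id = f"{genotype}_s{s_idx}"
            for i_idx in range(1, images_per_specimen + 1):
                image_id = f"{specimen_id}_img{i_idx}"
                img_seed = derive_image_seed(seed, g_idx, s_idx, i_idx)
                image, truth = generate_scene(replace(spec, seed=img_seed))
                image.image_id = image_id
                image.specimen_id = specimen_id
                image.genotype = genotype
                scenes[image_id] = (image, truth)
                sheet_rows.append(
                    {"image_id": image_id, "specimen_id": specimen_id,
                     "genotype": genotype, "seed": img_seed}
                )
    sample_sheet = pd.DataFrame(sheet_rows)
    return sample_sheet, scenes


# ---------------------------------------------------------------------------
# Scratch series
# ---------------------------------------------------------------------------

def generate_scratch_series(
    spec: ScratchSeriesSpec,
) -> tuple[list[MultiChannelImage], pd.DataFrame]:
    """Render a scratch-closure series and its true acellular areas.

    Each timepoint is a confluent GFP field with a centered vertical
    background band of analytic width ``max(0, w0 - rate * t)``. The
    returned table holds the analytic width and the rasterized true
    acellular pixel area per timepoint.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    col_centers = np.arange(w) + 0.5
    cx = w / 2.0

    images: list[MultiChannelImage] = []
    rows = []
    for t in spec.timepoints_h:
        width = spec.gap_width_at(t)
        in_gap = np.abs(col_centers - cx) < width / 2.0
        canvas = np.full((h, w), spec.intensity_fg, dtype=float)
        canvas[:, in_gap] = spec.intensity_bg
        true_area = int(in_gap.sum()) * h
        canvas = _add_noise(canvas, rng, spec.noise_poisson, spec.noise_gaussian_sd)
        img = MultiChannelImage(channels={"GFP": canvas}, image_id=f"scratch_t{t:g}h")
        images.append(img)
        rows.append(
            {"timepoint_h": float(t), "true_gap_width_px": width,
             "true_acellular_area_px": true_area}
        )
    return images, pd.DataFrame(rows)
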