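"""End-to-end simulation studies on synthetic cohorts.

Each study runs the full pipeline — scene generation, per-channel Otsu
segmentation, nearest-neighbor proximity, classification, statistics — on
seeded synthetic cohorts with known ground truth, and reports recovery of
the generating parameters. These are the package's calibration experiments:
they quantify whether the analysis detects the spatial redistribution and
interstitial depletion that the generator encodes.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .proximity import analyze_cohort, derive_threshold, nearest_neighbor_distances
from .quantify import fields_table, normalize_to_control
from .segmentation import segment_image
from .stats import proximity_shift_report
from .synthetic import (
    SceneSpec,
    generate_cohort,
    generate_scene,
    objects_from_ground_truth,
)


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(s % (2**31)) for s in ss.generate_state(n)]


def run_cohort_pipeline(
    control_spec: SceneSpec,
    mutant_spec: SceneSpec,
    n_specimens: int,
    images_per_specimen: int,
    seed: int,
    *,
    channels: tuple[str, ...] = ("GFP", "CD109"),
    threshold: str | float = "auto",
):
    """Generate a cohort and run segmentation + proximity on it."""
    sheet, scenes = generate_cohort(
        control_spec, mutant_spec, n_specimens, images_per_specimen, seed
    )
    objects = {
        image_id: segment_image(img, channels=channels)
        for image_id, (img, _) in scenes.items()
    }
    study = analyze_cohort(objects, sheet, threshold=threshold)
    return study, sheet, objects, scenes


def redistribution_power_study(
    n_replicates: int = 50,
    retention: float = 0.5,
    seed: int = 0,
    alpha: float = 0.05,
    control_spec: SceneSpec = SceneSpec(),
    n_specimens: int = 4,
    images_per_specimen: int = 6,
) -> dict:
    """Power of the redistribution analysis under interstitial depletion.

    For each replicate: a two-genotype cohort (control vs ``retention``-
    thinned interstitial component), full pipeline, control-derived
    threshold, then (a) the chi-square test on the pooled perivascular/
    interstitial count table and (b) the direction of the mutant-vs-control
    difference in image-mean NN distance. Returns the fraction of replicates
    with a significant chi-square and with the depletion-consistent
    direction (mutant mean below control).
    """
    mutant_spec = dataclasses.replace(
        control_spec, interstitial_retention=retention
    )
    sig = 0
    direction = 0
    thresholds = []
    last_report = None
    for rep_seed in _sub_seeds(seed, n_replicates):
        study, _, _, _ = run_cohort_pipeline(
            control_spec, mutant_spec, n_specimens, images_per_specimen, rep_seed
        )
        report = proximity_shift_report(
            study.summaries, study.threshold.value_px, alpha=alpha
        )
        sig += report["chi_square"]["significant"]
        means = study.summaries.groupby("genotype")["mean_nn_distance_px"].mean()
        direction += means["mutant"] < means["control"]
        thresholds.append(study.threshold.value_px)
        last_report = report
    return {
        "n_replicates": n_replicates,
        "chi_square_significant_fraction": sig / n_replicates,
        "mutant_below_control_fraction": direction / n_replicates,
        "mean_derived_threshold_px": float(np.mean(thresholds)),
        "alpha": alpha,
        "last_report": last_report,
    }


def thinning_recovery_study(
    n_replicates: int = 6,
    perivascular_fraction: float = 0.3,
    retention: float = 0.4,
    seed: int = 0,
    control_spec: SceneSpec | None = None,
    n_specimens: int = 4,
    images_per_specimen: int = 6,
) -> dict:
    """Recovery of the analytic thinning expectation from normalized areas.

    Thinning the interstitial component to ``retention`` scales the expected
    GFP cell count — and, with non-overlapping rendered cells, the GFP
    fluorescence area — by ``p_f + (1 - p_f) * retention``. Each replicate
    runs the area pipeline (Otsu areas, DAPI normalization, control
    normalization) on a fresh cohort; reported is the across-replicate mean
    of the mutant group mean ``normalized_gfp`` with its standard error.
    """
    if control_spec is None:
        control_spec = dataclasses.replace(
            SceneSpec(),
            perivascular_fraction=perivascular_fraction,
            min_separation=True,
        )
    mutant_spec = dataclasses.replace(
        control_spec, interstitial_retention=retention
    )
    expected = perivascular_fraction + (1 - perivascular_fraction) * retention
    group_means = []
    for rep_seed in _sub_seeds(seed, n_replicates):
        sheet, scenes = generate_cohort(
            control_spec, mutant_spec, n_specimens, images_per_specimen, rep_seed
        )
        objects = {
            image_id: segment_image(img, channels=("GFP", "CD109", "DAPI"))
            for image_id, (img, _) in scenes.items()
        }
        fields = normalize_to_control(fields_table(objects, sheet))
        mutant = fields[(fields["genotype"] == "mutant") & fields["valid"]]
        group_means.append(float(mutant["normalized_gfp"].mean()))
    group_means = np.asarray(group_means)
    return {
        "expected": expected,
        "mutant_normalized_gfp_mean": float(group_means.mean()),
        "se": float(group_means.std(ddof=1) / math.sqrt(n_replicates)),
        "replicate_means": group_means.tolist(),
        "n_replicates": n_replicates,
    }


def threshold_calibration_study(
    n_images: int = 24,
    coupling_scale_px: float = 5.0,
    seed: int = 0,
    base_spec: SceneSpec | None = None,
) -> dict:
    """Derived threshold vs the generator's analytic mean coupling distance.

    Uses a purely perivascular condition (``perivascular_fraction=1``) with
    sparse vasculature (5 vessels per field) where the mean nearest-vessel
    distance has a closed form: the half-normal mean ``sigma * sqrt(2/pi)``.
    The closed form assumes (a) the coupled vessel is the nearest one —
    sparse vasculature makes the chance that an unrelated vessel lies closer
    negligible relative to the sampling error — and (b) no boundary
    truncation of the offset distribution, so vessels are kept well inside
    the frame (coupled placements near the border would otherwise be redrawn,
    skewing offsets small). Distances are taken on ground-truth centroids so
    the comparison isolates the generator's coupling and the threshold-
    derivation rule from rasterization error.
    """
    if base_spec is None:
        base_spec = SceneSpec()
    spec = dataclasses.replace(
        base_spec, perivascular_fraction=1.0, coupling_scale_px=coupling_scale_px,
        n_vessels=5, vessel_radius_px=8 * coupling_scale_px, n_nuclei=0,
    )
    records = []
    for i, img_seed in enumerate(_sub_seeds(seed, n_images)):
        _, truth = generate_scene(dataclasses.replace(spec, seed=img_seed))
        gfp = objects_from_ground_truth(truth, "GFP", image_id=f"img{i}")
        cd = objects_from_ground_truth(truth, "CD109", image_id=f"img{i}")
        records.append(nearest_neighbor_distances(gfp, cd))
    pooled = pd.concat(records, ignore_index=True)
    thr = derive_threshold(pooled)
    analytic_mean = coupling_scale_px * math.sqrt(2.0 / math.pi)
    # distances within an image share one vessel configuration, so the
    # standard error of the pooled mean is the clustered (per-image) one
    image_means = pooled.groupby("image_id")["nn_distance_px"].mean()
    se = float(image_means.std(ddof=1) / math.sqrt(len(image_means)))
    return {
        "derived_threshold_px": thr.value_px,
        "analytic_mean_px": analytic_mean,
        "se": se,
        "n_distances": len(pooled),
        "n_images": int(len(image_means)),
    }


def invasion_regression_study(
    n_specimens: int = 3,
    fields_per_specimen: int = 18,
    seed: int = 0,
    latent_weight: float = 0.5,
) -> dict:
    """Regression of cell-invasion area on vasculature area across fields.

    Emulates the field-level covariation the area regression is meant to
    detect: each field draws a latent intensity ``u`` that drives its vessel
    count, and its lineage-labeled cell count mixes the same latent with
    independent noise (``latent_weight`` each on the latent and the noise
    scale, giving an analytic field-count correlation of
    ``w / sqrt(w^2 + (1-w)^2)``, about 0.71 — a moderate-strength setting).
    Fields are rendered and pushed through the full Otsu area pipeline; the
    fit is on measured areas.
    """
    rng = np.random.default_rng(seed)
    gfp_areas = []
    cd_areas = []
    n_fields = n_specimens * fields_per_specimen
    for img_seed in _sub_seeds(seed, n_fields):
        u = rng.uniform()
        eps = rng.uniform()
        n_vessels = int(round(8 + 24 * u))
        mix = latent_weight * u + (1 - latent_weight) * eps
        n_gfp = int(round(40 + 160 * mix))
        spec = SceneSpec(n_vessels=n_vessels, n_gfp=n_gfp, n_nuclei=0,
                         seed=img_seed)
        img, _ = generate_scene(spec)
        objects = segment_image(img, channels=("GFP", "CD109"))
        gfp_areas.append(objects["GFP"].total_area_px)
        cd_areas.append(objects["CD109"].total_area_px)
    from .stats import linear_regression

    fit = linear_regression(np.asarray(cd_areas, float), np.asarray(gfp_areas, float))
    w = latent_weight
    return {
        "r_squared": fit.r_squared,
        "strength_label": fit.strength_label,
        "slope": fit.slope,
        "n_fields": n_fields,
        "analytic_correlation": w / math.sqrt(w**2 + (1 - w) ** 2),
    }


def classification_recovery_study(
    seed: int = 0,
    n_images: int = 6,
    threshold_px: float = 22.0,
) -> dict:
    """Ground-truth label recovery of the perivascular/interstitial split.

    Distance-threshold classification has an irreducible error: a uniformly
    placed "interstitial" cell can land next to a vessel, and nothing in the
    image distinguishes it from a coupled cell. Recovery is therefore
    checked in a well-separated regime — sparse vasculature (4 vessels per
    field) so interstitial cells rarely fall within the threshold of a
    vessel, tight 5-px coupling, a light per-vessel load with minimum
    separation so segmentation is lossless — under the fixed 22-px
    threshold. Reports the pipeline-classified perivascular proportion and
    the generator's ground-truth proportion with its 3-s.e. binomial band.
    """
    spec = SceneSpec(
        n_vessels=4, n_gfp=40, perivascular_fraction=0.4,
        min_separation=True, n_nuclei=0,
    )
    n_class_peri = 0
    n_class_total = 0
    n_true_peri = 0
    n_true_total = 0
    for img_seed in _sub_seeds(seed, n_images):
        img, truth = generate_scene(dataclasses.replace(spec, seed=img_seed))
        objects = segment_image(img, channels=("GFP", "CD109"))
        rec = nearest_neighbor_distances(objects["GFP"], objects["CD109"])
        n_class_peri += int((rec["nn_distance_px"] < threshold_px).sum())
        n_class_total += len(rec)
        gfp_truth = truth[truth["channel"] == "GFP"]
        n_true_peri += int((gfp_truth["true_class"] == "perivascular").sum())
        n_true_total += len(gfp_truth)
    p_true = n_true_peri / n_true_total
    return {
        "classified_perivascular_fraction": n_class_peri / n_class_total,
        "true_perivascular_fraction": p_true,
        "binomial_3se": 3.0 * math.sqrt(p_true * (1 - p_true) / n_class_total),
        "n_objects": n_class_total,
    }
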