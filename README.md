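# periquant

Proximity-based quantification of cell invasion and perivascular vs
interstitial distribution in multi-channel fluorescence microscopy.

During heart development, epicardial-derived cells (EPDCs) invade the
compact myocardium and take up positions either adjacent to the forming
coronary vasculature (perivascular) or between vessels (interstitial).
Quantifying that spatial choice — and how a genetic perturbation shifts
it — requires reducing each image to objects and distances: segment the
lineage reporter (GFP), the vascular marker (CD109) and nuclei (DAPI)
inside a tissue ROI; measure each GFP+ object's nearest-neighbor distance
to a CD109+ object; classify objects against a control-derived pixel
threshold; and compare genotypes with contingency-table and group-mean
statistics. `periquant` implements that pipeline as a tested, reusable
library and CLI, together with a synthetic-scene generator that provides
exact ground truth for every stage.

## The model

For GFP objects with centroids $g_i$ and CD109 objects $c_j$,

$$d_i = \min_j \lVert g_i - c_j \rVert \quad\text{(pixels)},$$

and the classification cut is the mean of pooled control-genotype
distances, $T = \overline{d^{\,\mathrm{ctrl}}}$ (22 px in the original
embryonic-heart dataset, shipped as the fixed-mode default). Object $i$ is
**perivascular** iff $d_i < T$ (strictly), else **interstitial**.
Segmentation is per-image, per-channel Otsu thresholding (256 bins over the
ROI intensity range, foreground strictly above the cut) followed by
8-connected components and a 5-px speckle filter. Downstream statistics:
Fisher's exact test (two-sided) for per-specimen binary outcomes;
uncorrected chi-square for class-count and K×2 frequency tables; pooled
Student t-tests at image and specimen level; OLS regression of GFP area on
CD109 area with R² strength tiers (≥ 0.75 substantial / ≥ 0.50 moderate /
≥ 0.25 weak); 95% data ellipses. GFP fluorescence area is normalized to
DAPI area, then to the control mean (≡ 1.0). Scratch-assay closure is
`1 − area_t/area_0` of the sub-Otsu acellular region.

The synthetic generator renders vessels, lineage-labeled cells and nuclei
as disks with optional Poisson–Gaussian noise; GFP cells mix a
vessel-coupled component (half-normal offset) with a uniform interstitial
component, and a genotype effect is modeled as selective interstitial
thinning with retention probability ρ, so the expected cell count scales
by $p_f + (1-p_f)\rho$. See `docs/methods.md` for assumptions, parameter
defaults and limitations.

## Worked example

A two-genotype synthetic cohort (4 specimens × 6 images each; mutant
interstitial retention 0.5) pushed through the full pipeline:

```python
import dataclasses, periquant as pq

control = pq.SceneSpec()                      # study-condition defaults
mutant = dataclasses.replace(control, interstitial_retention=0.5)
study, sheet, objects, _ = pq.run_cohort_pipeline(
    control, mutant, n_specimens=4, images_per_specimen=6, seed=1,
    channels=("GFP", "CD109", "DAPI"),
)
print(f"derived threshold: {study.threshold.value_px:.2f} px "
      f"(mean of {study.threshold.n_control_distances} control distances)")

report = pq.proximity_shift_report(study.summaries, study.threshold.value_px)
for g in report["genotypes"]:
    row = report["per_genotype"][g]
    print(f"{g:8s} perivascular {row['perivascular_count_fraction']:.3f} "
          f"of {row['n_gfp_objects']} objects, "
          f"mean NN distance {row['mean_nn_distance_px_by_image']:.1f} px")
chi = report["chi_square"]
print(f"class-count chi-square: chi2={chi['chi2']:.1f}, df={chi['df']}, p={chi['p']:.2e}")

fields = pq.normalize_to_control(pq.fields_table(objects, sheet))
print("mutant normalized GFP area:",
      round(fields.query("genotype=='mutant'")["normalized_gfp"].mean(), 3))
```

prints

```
derived threshold: 48.61 px (mean of 2961 control distances)
control  perivascular 0.538 of 2961 objects, mean NN distance 48.6 px
mutant   perivascular 0.629 of 1841 objects, mean NN distance 39.9 px
class-count chi-square: chi2=38.4, df=1, p=5.68e-10
mutant normalized GFP area: 0.709
```

Read: thinning the interstitial population to 50% removes distant cells,
so the mutant has fewer GFP objects (1841 vs 2961), a shorter mean
nearest-vessel distance (39.9 vs 48.6 px), a larger perivascular share
(0.629 vs 0.538; chi-square p ≈ 6×10⁻¹⁰), and about 71% of the control's
normalized GFP area — close to the analytic thinning expectation
0.5 + 0.5·0.5 = 0.75, minus a few percent of disk-overlap area loss.

The same steps are available from a shell:

```sh
periquant simulate cohort --out sim --seed 1
periquant segment --image sim/images/control_s1_img1_GFP.tif \
    --image sim/images/control_s1_img1_CD109.tif \
    --image sim/images/control_s1_img1_DAPI.tif --out objects
periquant proximity --objects objects --samples sim/sample_sheet.csv --out prox
periquant areas --objects objects --samples sim/sample_sheet.csv --out areas
periquant stats --proximity prox/image_summaries.csv --fields areas/fields.csv --out report
```

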