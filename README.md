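# etilscore

Automated scoring of tumor-infiltrating lymphocytes (TILs) on
hematoxylin–eosin (H&E) stained melanoma sections, with the outcome-based
threshold and survival machinery needed to use the score as a prognostic
marker.

Visual TIL grading (absent / non-brisk / brisk) is poorly reproducible
between pathologists, which has kept TILs out of routine melanoma
decision-making. This package implements a fully automated alternative: cells
are segmented and classified directly on the H&E image, and the TIL burden is
summarized as a single number,

```
eTIL% = 100 · n_TIL / (n_TIL + n_tumor)
```

the percentage of lymphocytes among the cells of the tumor/immune
compartment (stromal cells and false detections never enter the ratio).
Cases are dichotomized at a threshold (default 16.6%, strictly-greater =
"high"), and the threshold itself can be re-derived from outcome data by an
X-tile-style scan: the two-group log-rank χ² is evaluated at every
admissible division of the cohort and the maximizing cut is reported, with
Monte-Carlo cross-validation to correct the optimism of the maximal χ².

## Pipeline

1. **Stain estimation** (`etilscore.stain`) — per-slide refinement of the
   H&E stain vectors (Macenko-style: robust extreme directions of the OD
   cloud in its top-2 principal plane), then linear deconvolution of the
   optical density `OD_c = log10(I0_c / I_c)` into hematoxylin / eosin /
   residual concentrations.
2. **Watershed cell detection** (`etilscore.detection`) — on the
   hematoxylin OD channel at a 0.5 µm working pixel: background subtraction
   (8 µm opening), 1.5 µm Gaussian smoothing, threshold 0.1 OD,
   marker-controlled watershed to split touching nuclei, nucleus area filter
   [10, 400] µm², 5 µm Voronoi-constrained cell expansion.
3. **Features** (`etilscore.features`) — 64 shape/intensity features per
   cell plus spatially smoothed copies at 25 µm and 50 µm radius:
   64 × 3 = 192 classifier inputs.
4. **Classification** (`etilscore.classifier`) — an 8-hidden-layer MLP
   (≤ 100 iterations, deterministic per seed) assigning tumor / til /
   stroma / other, with a class-colored overlay writer for pathologist QC.
5. **Scoring** (`etilscore.scoring`) — eTIL% per annotated region (cells
   counted by centroid-in-polygon).
6. **Outcome statistics** (`etilscore.survival_stats`) — log-rank,
   Kaplan–Meier, multivariable Cox (HR, 95% CI, p), cutpoint scan with
   cross-validated significance, Mann–Whitney association, ICC(2,1) +
   Wilcoxon agreement.
7. **Synthetic data** (`etilscore.synthetic_data`) — H&E-like scenes
   composed by Beer–Lambert transmission with known cell polygons/labels,
   and survival cohorts whose hazard changes by a known ratio at a known
   score threshold. The generator's truth is the oracle for every test.

## Worked example

```pycon
>>> from shapely.geometry import Polygon
>>> from etilscore.pipeline import train_scene_classifier
>>> from etilscore.synthetic_data import SceneSpec, generate_scene
>>> from etilscore.scoring import score_region
>>> from etilscore.image_io import RegionAnnotation
>>> model = train_scene_classifier(n_scenes=4, seed=5)
>>> print(f"holdout accuracy: {model.training_meta['holdout_accuracy']:.3f}")
holdout accuracy: 0.979
>>> image, truth = generate_scene(SceneSpec(seed=99,
...     counts={"tumor": 70, "til": 30}, width_um=200, height_um=200))
>>> h, w = image.shape
>>> region = RegionAnnotation([Polygon([(0, 0), (w, 0), (w, h), (0, h)])])
>>> res = score_region(image, region, model)
>>> print(f"tumor={res.n_tumor} til={res.n_til}")
tumor=70 til=30
>>> print(f"eTIL% = {res.etil_pct:.1f} -> {res.group} (threshold 16.6)")
eTIL% = 30.0 -> high (threshold 16.6)
```

The scene was generated with 70 tumor cells and 30 lymphocytes, so the true
eTIL% is 30.0; the pipeline re-detects and re-classifies every cell from the
rendered pixels and recovers it.

The same flow from the shell (`etil --help` lists all subcommands):

```console
$ etil simulate scene --out scene.tif --truth truth.geojson --seed 4
wrote scene.tif (58 cells)
$ etil stains --image scene.tif --out profile.json
wrote profile.json (estimated=True)
$ etil detect --image scene.tif --stain-profile profile.json --out cells.geojson
wrote cells.geojson (57 cells)
$ etil simulate cohort --out cohort.csv --seed 3 --n 200 --hazard-ratio 0.42 --true-threshold 16.6
wrote cohort.csv (n=200, events=151)
$ etil cutpoint --survival cohort.csv --out cut.json
{"threshold": 16.929..., "chi2_max": 31.49..., "p_uncorrected": 2.0e-08, "p_crossvalidated": 0.0012, "n_candidates": 161}
```

The simulated cohort's hazard drops by the factor 0.42 above score 16.6; the
outcome-based scan recovers a threshold of 16.9 with a cross-validated
log-rank p of 0.001.

Inputs are standard formats: TIFF (resolution tags) or PNG (+ JSON sidecar)
images with µm/px calibration, GeoJSON region annotations and cell output,
CSV survival tables (`id, score, time_months, event, covariates...`).

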