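"""Convenience glue: featurize detected cells and train scene classifiers.

These helpers chain the stain → detection → features → classifier modules
for the common cases: computing the full smoothed feature table for one
image, and training a cell classifier from synthetic scenes using the
generator's ground truth as labels.
"""

from __future__ import annotations

import numpy as np

from etilscore.classifier import ClassifierModel
from etilscore.features import FeatureTable, compute_features, smooth_features
from etilscore.image_io import CalibratedImage
from etilscore.stain import StainProfile, deconvolve, default_he_profile, rgb_to_od

__all__ = ["featurize_image", "train_scene_classifier"]


def featurize_image(
    image: CalibratedImage,
    cells,
    profile: StainProfile | None = None,
    smoothing_radii_um=(25.0, 50.0),
) -> FeatureTable:
    """Base features plus smoothed variants for detected cells of one image."""
    if profile is None:
        profile = default_he_profile()
    od = rgb_to_od(image.pixels, profile.background_intensity)
    conc = deconvolve(od, profile)
    table = compute_features(cells, conc, image.pixel_size_um)
    if cells:
        centroids = np.array([c.centroid_um for c in cells])
        for radius in smoothing_radii_um:
            table = smooth_features(table, centroids, radius)
    return table


def train_scene_classifier(
    n_scenes: int = 4,
    seed: int = 0,
    smoothing_radii_um=(25.0, 50.0),
    scene_kwargs: dict | None = None,
    **train_kwargs,
) -> ClassifierModel:
    """Train a cell classifier on synthetic scenes labelled by generator truth.

    Scenes use seeds ``seed*1000 .. seed*1000+n_scenes-1``; detections are
    labelled by nearest ground-truth centroid (unmatched detections become
    "other").
    """
    from etilscore.classifier import train
    from etilscore.detection import detect_cells
    from etilscore.synthetic_data import SceneSpec, generate_scene, match_to_truth

    profile = default_he_profile()
    if scene_kwargs is None:
        # training mix oversamples the rarer stroma/other classes so every
        # class clears the classifier's 10-example floor after detection
        scene_kwargs = {"counts": {"tumor": 30, "til": 15, "stroma": 8, "other": 6}}
    tables, labels = [], []
    for i in range(n_scenes):
        spec = SceneSpec(seed=seed * 1000 + i, **scene_kwargs)
        image, truth = generate_scene(spec)
        cells = detect_cells(image, profile)
        lab, _ = match_to_truth(cells, truth)
        tables.append(featurize_image(image, cells, profile, smoothing_radii_um))
        labels.extend(lab)
    values = np.vstack([t.values for t in tables])
    table = FeatureTable(
        cell_ids=list(range(len(values))),
        feature_names=tables[0].feature_names,
        values=values,
    )
    return train(table, labels, seed=seed, **train_kwargs)
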