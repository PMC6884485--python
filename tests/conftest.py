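import numpy as np
import pytest

from etilscore.stain import default_he_profile
from etilscore.synthetic_data import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def he_profile():
    return default_he_profile()


@pytest.fixture(scope="session")
def small_scene():
    """One mixed-class scene with its ground truth (deterministic)."""
    spec = SceneSpec(seed=42)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def benchmark_model():
    """Classifier trained on the 4-class Gaussian feature benchmark."""
    from etilscore.classifier import train
    from etilscore.synthetic_data import generate_feature_benchmark

    table, labels = generate_feature_benchmark(seed=7)
    return train(table, labels, seed=7), table, labels


@pytest.fixture(scope="session")
def scene_model():
    """Classifier trained end-to-end on synthetic scenes (truth-labelled)."""
    from etilscore.pipeline import train_scene_classifier

    return train_scene_classifier(n_scenes=4, seed=5)


def detection_scene(seed: int, n: int = 50):
    """Scene of n dark ~30 µm² round nuclei with >= 3 µm gaps (the
    segmentation stress substrate: dense, lymphocyte-like)."""
    spec = SceneSpec(
        seed=seed,
        width_um=150.0,
        height_um=150.0,
        counts={"til": n},
        min_gap_um=3.0,
    )
    return generate_scene(spec)
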