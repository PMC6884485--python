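"""Synthetic H&E scenes and survival cohorts with known ground truth.

The scene generator composes calibrated RGB images by Beer–Lambert
transmission through a known stain profile: elliptical nuclei with
low-order Fourier boundary jitter are placed by rejection sampling with a
minimum gap, per-class hematoxylin densities are drawn (lymphocytes
densest, tumor nuclei large and pale, stromal nuclei spindly, "other"
debris small and faint), a mild eosin wash mimics cytoplasm, and Gaussian
sensor noise is added.  The generator's truth — polygons, labels, counts —
is the oracle every downstream module is measured against.

The cohort generator draws eTIL%-like scores from a scaled Beta
distribution and exponential event times whose hazard changes by a known
ratio above a known score threshold, with uniform administrative censoring
(disease-specific-survival semantics: event = disease death observed).

One global seed fans out to per-stage child seeds so placement, staining,
noise and survival draws are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from etilscore.detection import Cell
from etilscore.image_io import CalibratedImage
from etilscore.stain import StainProfile, compose_od, default_he_profile
from etilscore.survival_stats import SurvivalRecord

__all__ = [
    "SceneSpec",
    "CohortSpec",
    "generate_scene",
    "generate_cohort",
    "generate_feature_benchmark",
]

# per-class nucleus geometry (µm) and hematoxylin density (OD units):
# lymphocytes are small, round and dense; tumor nuclei large and pale;
# stromal nuclei elongated; "other" is faint sub-cellular debris.
CLASS_GEOMETRY = {
    "tumor": {"diameter_um": (8.0, 14.0), "elongation": (1.0, 1.3), "h_od": (0.35, 0.55)},
    "til": {"diameter_um": (5.0, 7.0), "elongation": (1.0, 1.1), "h_od": (0.95, 1.25)},
    "stroma": {"diameter_um": (4.0, 6.0), "elongation": (2.5, 3.5), "h_od": (0.50, 0.70)},
    "other": {"diameter_um": (3.6, 4.6), "elongation": (1.0, 1.6), "h_od": (0.22, 0.32)},
}

_MAX_RETRIES = 100_000


@dataclass
class SceneSpec:
    """Layout and optics of one synthetic H&E scene."""

    width_um: float = 150.0
    height_um: float = 150.0
    pixel_size_um: float = 0.5
    counts: dict = field(default_factory=lambda: {"tumor": 35, "til": 15, "stroma": 5, "other": 3})
    min_gap_um: float = 3.0
    noise_sd: float = 2.0
    eosin_wash_od: float = 0.25
    boundary_jitter: float = 0.08
    profile: StainProfile | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("scene dimensions and pixel size must be positive")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("class counts must be non-negative")
        if not 0 <= self.boundary_jitter <= 0.10:
            raise ValueError("boundary_jitter must lie in [0, 0.10]")
        if self.profile is None:
            self.profile = default_he_profile()
        # feasibility: total nucleus area must not exceed 40% of the scene
        total = sum(
            n * np.pi * (np.mean(CLASS_GEOMETRY[c]["diameter_um"]) / 2) ** 2
            for c, n in self.counts.items()
        )
        if total > 0.4 * self.width_um * self.height_um:
            raise ValueError("infeasible packing: nuclei would cover more than 40% of the scene")


def generate_scene(spec: SceneSpec) -> tuple[CalibratedImage, list[Cell]]:
    """Generate one scene; returns the image and the ground-truth cells.

    Deterministic per seed: the same spec yields identical image bytes and
    truth.  Raises after 10⁵ failed placement retries.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_place, rng_shape, rng_stain, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    px = spec.pixel_size_um
    h_px = int(round(spec.height_um / px))
    w_px = int(round(spec.width_um / px))

    order = [c for c in ("tumor", "til", "stroma", "other") for _ in range(spec.counts.get(c, 0))]
    placements = _place_nuclei(order, spec, rng_place)

    h_conc = np.zeros((h_px, w_px))
    # the eosin wash emulates cytoplasm/stroma: present only when the scene
    # holds tissue, so an empty spec yields a blank-white slide
    wash = spec.eosin_wash_od if order else 0.0
    e_conc = np.full((h_px, w_px), wash)
    truth: list[Cell] = []
    from skimage.draw import polygon as draw_polygon

    for label, (cx_um, cy_um, base_radius_um, _) in zip(order, placements):
        geom = CLASS_GEOMETRY[label]
        ring_um = _jittered_ellipse(
            cx_um, cy_um, base_radius_um, geom["elongation"], spec.boundary_jitter, rng_shape
        )
        ring_px = ring_um / px
        poly = Polygon(ring_px)
        h_draw = rng_stain.uniform(*geom["h_od"])
        e_draw = rng_stain.uniform(0.05, 0.15)
        rr, cc = draw_polygon(ring_px[:, 1], ring_px[:, 0], shape=(h_px, w_px))
        h_conc[rr, cc] = h_draw
        # chromatin displaces the cytoplasmic eosin wash inside nuclei
        e_conc[rr, cc] = e_draw
        area = poly.area * px**2
        truth.append(
            Cell(
                nucleus_polygon=poly,
                cell_polygon=poly,
                centroid_um=np.array([cx_um, cy_um]),
                nucleus_area_um2=area,
                cell_area_um2=area,
                label=label,
            )
        )

    conc = np.stack([h_conc, e_conc, np.zeros_like(h_conc)], axis=-1)
    od = compose_od(conc, spec.profile)
    rgb = spec.profile.background_intensity * 10.0 ** (-od)
    if spec.noise_sd > 0:
        rgb = rgb + rng_noise.normal(0.0, spec.noise_sd, size=rgb.shape)
    pixels = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    image = CalibratedImage(pixels=pixels, pixel_size_um=px, id=f"scene-{spec.seed}")
    return image, truth


def _place_nuclei(order, spec: SceneSpec, rng):
    """Rejection-sample (cx, cy, base_radius, collision_radius) in µm
    honouring min_gap_um (collision radius = semi-major axis incl. jitter)."""
    placed: list[tuple[float, float, float, float]] = []
    margin = 2.0
    retries = 0
    for label in order:
        geom = CLASS_GEOMETRY[label]
        diameter = rng.uniform(*geom["diameter_um"])
        base_radius = diameter / 2.0
        elong_max = geom["elongation"][1]
        collision = base_radius * np.sqrt(elong_max) * (1.0 + spec.boundary_jitter)
        while True:
            if retries > _MAX_RETRIES:
                raise RuntimeError(f"could not place nuclei after {_MAX_RETRIES} retries")
            cx = rng.uniform(margin + collision, spec.width_um - margin - collision)
            cy = rng.uniform(margin + collision, spec.height_um - margin - collision)
            ok = all(
                np.hypot(cx - px_, cy - py_) >= collision + c_ + spec.min_gap_um
                for px_, py_, _, c_ in placed
            )
            if ok:
                placed.append((cx, cy, base_radius, collision))
                break
            retries += 1
    return placed


def _jittered_ellipse(cx, cy, base_radius_um, elongation_range, jitter, rng, n_vertices=48):
    """Ellipse boundary with low-order Fourier perturbation, in µm coords."""
    elong = rng.uniform(*elongation_range)
    a = base_radius_um * np.sqrt(elong)
    b = base_radius_um / np.sqrt(elong)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    perturb = np.zeros_like(theta)
    if jitter > 0:
        amps = rng.uniform(0, jitter / 3.0, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
            perturb += amp * np.cos(k * theta + ph)
    rx = a * (1.0 + perturb)
    ry = b * (1.0 + perturb)
    rot = rng.uniform(0, np.pi)
    x = rx * np.cos(theta)
    y = ry * np.sin(theta)
    xr = x * np.cos(rot) - y * np.sin(rot) + cx
    yr = x * np.sin(rot) + y * np.cos(rot) + cy
    return np.column_stack([xr, yr])


def match_to_truth(cells, truth, max_dist_um: float = 3.0):
    """Label detected cells by nearest ground-truth centroid.

    Returns (labels, matched_mask): a detection farther than ``max_dist_um``
    from every truth centroid gets the label ``"other"`` (a false
    detection, by the generator's definition of truth).
    """
    from scipy.spatial import cKDTree

    if not truth:
        return ["other"] * len(cells), np.zeros(len(cells), dtype=bool)
    truth_xy = np.array([t.centroid_um for t in truth])
    tree = cKDTree(truth_xy)
    labels, matched = [], []
    for cell in cells:
        dist, idx = tree.query(cell.centroid_um)
        if dist <= max_dist_um:
            labels.append(truth[idx].label)
            matched.append(True)
        else:
            labels.append("other")
            matched.append(False)
    return labels, np.asarray(matched, dtype=bool)


@dataclass
class CohortSpec:
    """Survival cohort with a known hazard change at a known score threshold.

    Scores follow ``100 * Beta(score_alpha, score_beta)`` (right-skewed, like
    observed TIL fractions).  Event times are exponential with
    ``baseline_hazard`` per month below the threshold and
    ``baseline_hazard * hazard_ratio_high_vs_low`` above it; censoring is
    uniform on [0, censoring_window_months] (0 = no censoring).
    """

    n: int = 200
    score_alpha: float = 2.0
    score_beta: float = 5.0
    true_threshold: float = 16.6
    hazard_ratio_high_vs_low: float = 0.42
    baseline_hazard: float = 0.02
    censoring_window_months: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.hazard_ratio_high_vs_low <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if not 0 < self.true_threshold < 100:
            raise ValueError("true_threshold must lie in (0, 100)")


def generate_cohort(spec: CohortSpec) -> tuple[list[SurvivalRecord], dict]:
    """Generate survival records plus an echo of the true parameters."""
    ss = np.random.SeedSequence(spec.seed)
    rng_score, rng_time, rng_cens, rng_cov = (np.random.default_rng(c) for c in ss.spawn(4))
    scores = 100.0 * rng_score.beta(spec.score_alpha, spec.score_beta, size=spec.n)
    high = scores > spec.true_threshold
    rates = spec.baseline_hazard * np.where(high, spec.hazard_ratio_high_vs_low, 1.0)
    event_times = rng_time.exponential(1.0 / rates)
    if spec.censoring_window_months > 0:
        cens_times = rng_cens.uniform(0.0, spec.censoring_window_months, size=spec.n)
    else:
        cens_times = np.full(spec.n, np.inf)
    times = np.minimum(event_times, cens_times)
    events = event_times <= cens_times

    ages = np.clip(rng_cov.normal(60.0, 15.0, size=spec.n), 18, 95)
    sexes = rng_cov.choice(["male", "female"], size=spec.n, p=[0.6, 0.4])
    depths = np.round(rng_cov.lognormal(0.6, 0.8, size=spec.n), 2)
    clarke = rng_cov.integers(1, 6, size=spec.n)
    ulcer = rng_cov.integers(0, 2, size=spec.n)
    stage = rng_cov.integers(1, 5, size=spec.n)
    location = rng_cov.choice(["trunk", "extremity", "head_neck"], size=spec.n, p=[0.5, 0.4, 0.1])

    records = [
        SurvivalRecord(
            id=f"case-{i:04d}",
            score=float(scores[i]),
            time_months=float(times[i]),
            event=bool(events[i]),
            covariates={
                "age": float(ages[i]),
                "sex": str(sexes[i]),
                "tumor_depth": float(depths[i]),
                "clarke_level": int(clarke[i]),
                "ulceration": int(ulcer[i]),
                "stage": int(stage[i]),
                "location": str(location[i]),
            },
        )
        for i in range(spec.n)
    ]
    echo = {
        "true_threshold": spec.true_threshold,
        "hazard_ratio_high_vs_low": spec.hazard_ratio_high_vs_low,
        "baseline_hazard": spec.baseline_hazard,
        "n_high": int(high.sum()),
        "n_events": int(events.sum()),
    }
    return records, echo


def generate_feature_benchmark(
    n: int = 2000,
    n_features: int = 192,
    separation_sd: float = 3.0,
    n_informative_per_class: int = 4,
    seed: int = 0,
):
    """Four-class Gaussian feature benchmark; returns (FeatureTable, labels).

    Each class is shifted by ``separation_sd`` pooled standard deviations
    along each of ``n_informative_per_class`` dedicated features — the way
    real cell classes differ jointly in several correlated morphology
    features (a lymphocyte is simultaneously smaller, denser and rounder),
    not along a single axis.  The remaining features are pure noise.
    """
    from etilscore.classifier import CLASS_NAMES
    from etilscore.features import FeatureTable

    rng = np.random.default_rng(seed)
    n_classes = len(CLASS_NAMES)
    if n_features < n_classes * n_informative_per_class:
        raise ValueError("n_features too small for the informative block layout")
    labels = np.array([CLASS_NAMES[i % n_classes] for i in range(n)])
    means = np.zeros((n_classes, n_features))
    for i in range(n_classes):
        lo = i * n_informative_per_class
        means[i, lo : lo + n_informative_per_class] = separation_sd
    x = rng.normal(size=(n, n_features))
    for i, cls in enumerate(CLASS_NAMES):
        x[labels == cls] += means[i]
    table = FeatureTable(
        cell_ids=list(range(n)),
        feature_names=[f"f{j:03d}" for j in range(n_features)],
        values=x,
    )
    return table, labels.tolist()
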