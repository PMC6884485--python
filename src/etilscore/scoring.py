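"""The eTIL% statistic and region-level scoring.

eTIL% is the percentage of machine-classified tumor-infiltrating
lymphocytes among the cells relevant to the tumor/immune balance:

    eTIL% = 100 * n_til / (n_til + n_tumor)

Stromal and "other" detections never enter the ratio.  When no tumor cells
and no TILs are present the score is undefined (``None``), never 0.  Cases
are dichotomized at a threshold (default 16.6); "high" means strictly
greater than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from etilscore.detection import DetectionParams, detect_cells
from etilscore.image_io import CalibratedImage, RegionAnnotation, region_area_mm2

__all__ = ["ETILResult", "compute_etil", "dichotomize", "score_region", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 16.6


@dataclass
class ETILResult:
    """Per-region class counts, the eTIL% score, and its high/low group."""

    region_id: str
    n_tumor: int
    n_til: int
    n_stroma: int = 0
    n_other: int = 0
    etil_pct: float | None = None
    area_mm2: float = 0.0
    group: str = "undefined"

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_til", "n_stroma", "n_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.etil_pct is not None and not 0.0 <= self.etil_pct <= 100.0:
            raise ValueError("etil_pct must lie in [0, 100]")


def compute_etil(n_til: int, n_tumor: int) -> float | None:
    """eTIL% = 100 * TILs / (TILs + tumor cells); None when both are zero."""
    if n_til < 0 or n_tumor < 0:
        raise ValueError("counts must be non-negative")
    total = n_til + n_tumor
    if total == 0:
        return None
    return 100.0 * n_til / total


def dichotomize(etil_pct: float | None, threshold: float = DEFAULT_THRESHOLD) -> str:
    """'high' iff the score strictly exceeds the threshold, else 'low';
    an undefined score maps to 'undefined'."""
    if etil_pct is None:
        return "undefined"
    return "high" if etil_pct > threshold else "low"


def score_region(
    image: CalibratedImage,
    region: RegionAnnotation | None,
    model,
    profile=None,
    params: DetectionParams | None = None,
    smoothing_radii_um=(25.0, 50.0),
    threshold: float = DEFAULT_THRESHOLD,
) -> ETILResult:
    """Run the full pipeline on one annotated region and score it.

    Detection and feature smoothing run over the whole image (smoothing must
    see neighbours across tile seams); a cell belongs to the region when its
    centroid lies inside one of the region polygons (pixel coordinates).
    ``region=None`` scores the entire image.
    """
    from etilscore.classifier import predict
    from etilscore.pipeline import featurize_image
    from etilscore.stain import default_he_profile

    if profile is None:
        profile = default_he_profile()
    if params is None:
        params = DetectionParams()

    cells = detect_cells(image, profile, params)
    counts = {c: 0 for c in ("tumor", "til", "stroma", "other")}
    if cells:
        table = featurize_image(image, cells, profile, smoothing_radii_um)
        labels, _ = predict(model, table)
        px = image.pixel_size_um
        for cell, label in zip(cells, labels):
            cell.label = label
            if region is not None:
                x_px, y_px = cell.centroid_um[0] / px, cell.centroid_um[1] / px
                if not region.contains_point(x_px, y_px):
                    continue
            if label in counts:
                counts[label] += 1

    if region is not None:
        area = region_area_mm2(region, image.pixel_size_um)
    else:
        h, w = image.shape
        area = h * w * image.pixel_size_um**2 / 1e6
    etil = compute_etil(counts["til"], counts["tumor"])
    return ETILResult(
        region_id=image.id or "region",
        n_tumor=counts["tumor"],
        n_til=counts["til"],
        n_stroma=counts["stroma"],
        n_other=counts["other"],
        etil_pct=etil,
        area_mm2=area,
        group=dichotomize(etil, threshold),
    )
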