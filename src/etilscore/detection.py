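"""Watershed cell detection on the hematoxylin OD channel.

The detector mirrors the classical brightfield nucleus-segmentation recipe:
resample to a requested working pixel size, deconvolve to hematoxylin OD,
estimate and subtract a smooth background (morphological opening), Gaussian
smoothing, threshold, seed at regional maxima, split touching nuclei by
marker-controlled watershed, filter by physical nucleus area, and expand
each nucleus into a cell outline without crossing a neighbour's territory.
All size parameters are given in µm / µm² and converted internally through
the image calibration, so the same settings apply across scanner
magnifications.  The pipeline is deterministic: identical input produces
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure, morphology, segmentation, transform
from skimage.filters import gaussian, median

from etilscore.image_io import CalibratedImage
from etilscore.stain import StainProfile, deconvolve, rgb_to_od

__all__ = ["DetectionParams", "Cell", "detect_cells"]

CLASS_NAMES = ("tumor", "til", "stroma", "other")

# depth for h-maxima seed suppression (OD units); keeps noise from seeding
_SEED_H = 0.05


@dataclass
class DetectionParams:
    """Watershed detection settings (physical units).

    Defaults are the published whole-slide H&E settings: working pixel size
    0.5 µm, background radius 8 µm, no median filter, Gaussian sigma 1.5 µm,
    nucleus area within [10, 400] µm², hematoxylin-OD threshold 0.1, local
    background cap 2 OD, and 5 µm cell expansion around each nucleus.
    """

    requested_pixel_size_um: float = 0.5
    background_radius_um: float = 8.0
    median_radius_um: float = 0.0
    sigma_um: float = 1.5
    min_cell_area_um2: float = 10.0
    max_cell_area_um2: float = 400.0
    threshold_od: float = 0.1
    max_background_od: float = 2.0
    cell_expansion_um: float = 5.0

    def __post_init__(self) -> None:
        if self.requested_pixel_size_um <= 0:
            raise ValueError("requested_pixel_size_um must be positive")
        for name in ("background_radius_um", "median_radius_um", "sigma_um", "cell_expansion_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.min_cell_area_um2 < self.max_cell_area_um2:
            raise ValueError(
                f"min_cell_area_um2 ({self.min_cell_area_um2}) must be smaller than "
                f"max_cell_area_um2 ({self.max_cell_area_um2})"
            )


@dataclass
class Cell:
    """A detected cell: nucleus/cell outlines (original pixel coords), centroid
    in µm, physical areas, a feature map filled by the features module, and a
    class label."""

    nucleus_polygon: Polygon
    cell_polygon: Polygon | None
    centroid_um: np.ndarray
    nucleus_area_um2: float
    cell_area_um2: float
    features: dict = field(default_factory=dict)
    label: str = "unclassified"


def detect_cells(
    image: CalibratedImage,
    profile: StainProfile | None = None,
    params: DetectionParams | None = None,
    tile_size: int = 2048,
    tile_overlap: int = 128,
) -> list[Cell]:
    """Detect cells in a calibrated H&E image.

    Images larger than ``tile_size`` (in working pixels) are processed in
    overlapping tiles; a cell belongs to the tile containing its centroid,
    so no cell is counted twice.  Returns an empty list (not an error) when
    nothing is detected.
    """
    if profile is None:
        from etilscore.stain import default_he_profile

        profile = default_he_profile()
    if params is None:
        params = DetectionParams()

    scale = image.pixel_size_um / params.requested_pixel_size_um
    if abs(scale - 1.0) < 1e-9:
        work = image.pixels.astype(float)
        scale = 1.0
    else:
        work = transform.rescale(
            image.pixels.astype(float),
            scale,
            channel_axis=2,
            anti_aliasing=scale < 1.0,
            preserve_range=True,
            order=1,
        )
    h, w = work.shape[:2]

    cells: list[Cell] = []
    for r0, r1, c0, c1, core in _tiles(h, w, tile_size, tile_overlap):
        tile_cells = _detect_tile(work[r0:r1, c0:c1], profile, params, offset=(r0, c0))
        cells.extend(cell for cell in tile_cells if _centroid_in(cell, core))

    # map working-grid polygons back to original pixel grid and build Cells
    out: list[Cell] = []
    px = image.pixel_size_um
    for nuc_ring, cell_ring, centroid_rc in cells:
        nuc_poly = Polygon([(x / scale, y / scale) for y, x in nuc_ring])
        cell_poly = Polygon([(x / scale, y / scale) for y, x in cell_ring]) if cell_ring is not None else None
        area_nuc = nuc_poly.area * px**2
        area_cell = cell_poly.area * px**2 if cell_poly is not None else area_nuc
        centroid = np.array([centroid_rc[1] / scale * px, centroid_rc[0] / scale * px])
        out.append(
            Cell(
                nucleus_polygon=nuc_poly,
                cell_polygon=cell_poly,
                centroid_um=centroid,
                nucleus_area_um2=area_nuc,
                cell_area_um2=area_cell,
            )
        )
    # physical-area filter on the exact polygon (shoelace) areas
    out = [
        c
        for c in out
        if params.min_cell_area_um2 <= c.nucleus_area_um2 <= params.max_cell_area_um2
    ]
    out.sort(key=lambda c: (c.centroid_um[1], c.centroid_um[0]))
    return out


def _tiles(h: int, w: int, tile: int, overlap: int) -> Iterator[tuple[int, int, int, int, tuple]]:
    """Yield (r0, r1, c0, c1, core) tile windows with ownership cores."""
    if h <= tile and w <= tile:
        yield 0, h, 0, w, (0.0, float(h), 0.0, float(w))
        return
    step = tile - overlap
    for r in range(0, max(h - overlap, 1), step):
        for c in range(0, max(w - overlap, 1), step):
            r0, c0 = r, c
            r1, c1 = min(r + tile, h), min(c + tile, w)
            core_r0 = 0.0 if r0 == 0 else r0 + overlap / 2
            core_c0 = 0.0 if c0 == 0 else c0 + overlap / 2
            core_r1 = float(h) if r1 == h else r1 - overlap / 2
            core_c1 = float(w) if c1 == w else c1 - overlap / 2
            yield r0, r1, c0, c1, (core_r0, core_r1, core_c0, core_c1)


def _centroid_in(cell_tuple, core) -> bool:
    _, _, (cy, cx) = cell_tuple
    r0, r1, c0, c1 = core
    return r0 <= cy < r1 and c0 <= cx < c1


def _detect_tile(work_rgb: np.ndarray, profile: StainProfile, params: DetectionParams, offset):
    """Core single-tile detector; returns (nucleus_ring, cell_ring, centroid_rc)
    tuples in working-grid coordinates."""
    px = params.requested_pixel_size_um
    od = rgb_to_od(work_rgb, profile.background_intensity)
    h_od = deconvolve(od, profile)[..., 0]

    if params.median_radius_um > 0:
        rad = max(1, round(params.median_radius_um / px))
        h_od = median(h_od, footprint=morphology.disk(rad))

    excluded = np.zeros(h_od.shape, dtype=bool)
    if params.background_radius_um > 0:
        bg_rad = max(1, round(params.background_radius_um / px))
        background = morphology.opening(h_od, morphology.disk(bg_rad))
        excluded = background > params.max_background_od
        h_od = h_od - background

    if params.sigma_um > 0:
        smoothed = gaussian(h_od, sigma=params.sigma_um / px, preserve_range=True)
    else:
        smoothed = h_od

    foreground = (smoothed > params.threshold_od) & ~excluded
    if not foreground.any():
        return []

    # seeds: regional maxima surviving h-maxima suppression, inside foreground
    seeds = morphology.h_maxima(smoothed, _SEED_H) & foreground
    if not seeds.any():
        return []
    markers, _ = ndimage.label(seeds)  # row-major labeling: deterministic tie-break
    labels = segmentation.watershed(-smoothed, markers=markers, mask=foreground)

    # refine boundaries to the unsmoothed OD support: smoothing dilates the
    # thresholded region by ~sigma, which would inflate every nucleus mask
    support = (h_od > params.threshold_od) & ~excluded
    labels[~support] = 0
    labels = _fill_holes_per_label(labels)

    # generous pixel-count prefilter; the exact polygon-area filter runs later
    areas_px = np.bincount(labels.ravel())
    min_px = 0.5 * params.min_cell_area_um2 / px**2
    max_px = 2.0 * params.max_cell_area_um2 / px**2
    kill = (areas_px < min_px) | (areas_px > max_px)
    kill[0] = False
    if kill.any():
        labels[kill[labels]] = 0

    if labels.max() == 0:
        return []
    labels, _, _ = segmentation.relabel_sequential(labels)

    if params.cell_expansion_um > 0:
        cell_labels = segmentation.expand_labels(labels, distance=params.cell_expansion_um / px)
    else:
        cell_labels = labels

    results = []
    dr, dc = offset
    for region in measure.regionprops(labels):
        lab = region.label
        nuc_ring = _mask_ring(labels == lab)
        if nuc_ring is None:
            continue
        if cell_labels is labels:
            cell_ring = nuc_ring
        else:
            cell_ring = _mask_ring(cell_labels == lab) or nuc_ring
        cy, cx = region.centroid
        nuc_ring = [(y + dr, x + dc) for y, x in nuc_ring]
        cell_ring = [(y + dr, x + dc) for y, x in cell_ring] if cell_ring is not None else nuc_ring
        results.append((nuc_ring, cell_ring, (cy + dr, cx + dc)))
    return results


def _fill_holes_per_label(labels: np.ndarray) -> np.ndarray:
    filled = labels.copy()
    for region in measure.regionprops(labels):
        sl = region.slice
        mask = labels[sl] == region.label
        fill = ndimage.binary_fill_holes(mask)
        filled[sl][fill & (labels[sl] == 0)] = region.label
    return filled


def _mask_ring(mask: np.ndarray):
    """Outer boundary ring of a binary mask as (row, col) vertices, or None."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    best = max(contours, key=lambda c: _ring_area(c))
    ring = [(r - 1.0, c - 1.0) for r, c in best]
    if len(ring) < 4:
        return None
    return ring


def _ring_area(contour: np.ndarray) -> float:
    y, x = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
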