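"""Per-cell shape/intensity features and spatially smoothed variants.

The base set holds 64 features per cell: 19 shape descriptors computed
analytically from the nucleus and cell polygons (shoelace areas, perimeters,
circularity, rotating-caliper diameters, moment-based eccentricity/aspect,
solidity, nucleus/cell area ratio, a cytoplasm-present flag) and 45
intensity statistics (mean/std/min/max/range of the hematoxylin, eosin and
residual OD channels over the nucleus, the cytoplasm = cell minus nucleus,
and the whole cell).  With smoothed copies at two radii (default 25 µm and
50 µm) the classifier sees 64 x 3 = 192 inputs.

Smoothing averages each feature over neighbouring cells with a Gaussian
weight of scale radius/2, hard-truncated at the radius; the cell itself
contributes with weight 1, so an isolated cell keeps its raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

__all__ = [
    "FeatureTable",
    "BASE_FEATURE_NAMES",
    "compute_features",
    "smooth_features",
]

_STAINS = ("hematoxylin", "eosin", "residual")
_COMPARTMENTS = ("nucleus", "cytoplasm", "cell")
_STATS = ("mean", "std", "min", "max", "range")

_SHAPE_NAMES = (
    [f"nucleus_{n}" for n in (
        "area_um2", "perimeter_um", "circularity", "caliper_max_um",
        "caliper_min_um", "eccentricity", "solidity", "aspect_ratio",
    )]
    + [f"cell_{n}" for n in (
        "area_um2", "perimeter_um", "circularity", "caliper_max_um",
        "caliper_min_um", "eccentricity", "solidity", "aspect_ratio",
    )]
    + ["nucleus_cell_area_ratio", "nucleus_equivalent_diameter_um", "has_cytoplasm"]
)
_INTENSITY_NAMES = [
    f"{comp}_{stain}_{stat}" for stain in _STAINS for comp in _COMPARTMENTS for stat in _STATS
]
BASE_FEATURE_NAMES: tuple[str, ...] = tuple(_SHAPE_NAMES + _INTENSITY_NAMES)
assert len(BASE_FEATURE_NAMES) == 64


@dataclass
class FeatureTable:
    """Cells × features matrix with ordered names and applied smoothing radii."""

    cell_ids: list
    feature_names: list[str]
    values: np.ndarray
    smoothing_radii_um: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.cell_ids), len(self.feature_names)):
            raise ValueError("values must be (n_cells, n_features)")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains missing values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def to_csv(self, path: str | Path) -> Path:
        self.to_frame().to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        return cls(
            cell_ids=df["cell_id"].tolist(),
            feature_names=[c for c in df.columns if c != "cell_id"],
            values=df.drop(columns="cell_id").to_numpy(dtype=float),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(
            cell_ids=df["cell_id"].tolist(),
            feature_names=[c for c in df.columns if c != "cell_id"],
            values=df.drop(columns="cell_id").to_numpy(dtype=float),
        )


def compute_features(cells, od_channels, pixel_size_um: float) -> FeatureTable:
    """Compute the 64-feature base set for each cell.

    ``od_channels`` is the (H, W, 3) stain-concentration array from
    deconvolution (hematoxylin, eosin, residual), on the same pixel grid as
    the cell polygons.  Undefined compartments (no cytoplasm when cell
    expansion is 0) yield zeros with ``has_cytoplasm`` = 0 so no value is
    ever missing.
    """
    od = np.asarray(od_channels, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("od_channels must be H x W x 3 (hematoxylin, eosin, residual)")
    rows = []
    for cell in cells:
        rows.append(_cell_features(cell, od, pixel_size_um))
    values = np.array(rows, dtype=float) if rows else np.empty((0, 64))
    return FeatureTable(
        cell_ids=list(range(len(rows))),
        feature_names=list(BASE_FEATURE_NAMES),
        values=values,
    )


def _cell_features(cell, od: np.ndarray, px: float) -> list[float]:
    nuc = cell.nucleus_polygon
    cel = cell.cell_polygon if cell.cell_polygon is not None else nuc
    feats = {}
    for prefix, poly in (("nucleus", nuc), ("cell", cel)):
        feats.update(_shape_features(prefix, poly, px))
    nuc_area = feats["nucleus_area_um2"]
    cell_area = feats["cell_area_um2"]
    feats["nucleus_cell_area_ratio"] = nuc_area / cell_area if cell_area > 0 else 1.0
    feats["nucleus_equivalent_diameter_um"] = 2.0 * np.sqrt(nuc_area / np.pi)

    shape_hw = od.shape[:2]
    nuc_mask = _rasterize(nuc, shape_hw)
    cell_mask = _rasterize(cel, shape_hw) | nuc_mask
    cyto_mask = cell_mask & ~nuc_mask
    feats["has_cytoplasm"] = 1.0 if cyto_mask.any() else 0.0

    masks = {"nucleus": nuc_mask, "cytoplasm": cyto_mask, "cell": cell_mask}
    for si, stain in enumerate(_STAINS):
        channel = od[..., si]
        for comp in _COMPARTMENTS:
            mask = masks[comp]
            if mask.any():
                vals = channel[mask]
                stats = {
                    "mean": vals.mean(),
                    "std": vals.std(),
                    "min": vals.min(),
                    "max": vals.max(),
                    "range": vals.max() - vals.min(),
                }
            else:
                stats = dict.fromkeys(_STATS, 0.0)
            for stat in _STATS:
                feats[f"{comp}_{stain}_{stat}"] = float(stats[stat])
    return [feats[name] for name in BASE_FEATURE_NAMES]


def _shape_features(prefix: str, poly: Polygon, px: float) -> dict[str, float]:
    area = poly.area * px**2
    perimeter = poly.length * px
    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    hull = poly.convex_hull
    hull_pts = np.asarray(hull.exterior.coords)[:-1] * px if hull.geom_type == "Polygon" else None
    if hull_pts is not None and len(hull_pts) >= 2:
        cal_max, cal_min = _caliper(hull_pts)
        solidity = area / (hull.area * px**2) if hull.area > 0 else 1.0
    else:
        cal_max = cal_min = 0.0
        solidity = 1.0
    ecc, aspect = _moment_shape(poly)
    return {
        f"{prefix}_area_um2": area,
        f"{prefix}_perimeter_um": perimeter,
        f"{prefix}_circularity": circularity,
        f"{prefix}_caliper_max_um": cal_max,
        f"{prefix}_caliper_min_um": cal_min,
        f"{prefix}_eccentricity": ecc,
        f"{prefix}_solidity": solidity,
        f"{prefix}_aspect_ratio": aspect,
    }


def _caliper(points: np.ndarray) -> tuple[float, float]:
    """Max Feret diameter and exact rotating-calipers minimum width."""
    diffs = points[:, None, :] - points[None, :, :]
    dists = np.hypot(diffs[..., 0], diffs[..., 1])
    cal_max = float(dists.max())
    # min width over hull-edge normal directions
    edges = np.roll(points, -1, axis=0) - points
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    valid = lengths > 0
    widths = []
    for (ex, ey), ln in zip(edges[valid], lengths[valid]):
        nx, ny = -ey / ln, ex / ln
        proj = points @ np.array([nx, ny])
        widths.append(proj.max() - proj.min())
    cal_min = float(min(widths)) if widths else 0.0
    return cal_max, cal_min


def _moment_shape(poly: Polygon) -> tuple[float, float]:
    """Eccentricity and aspect ratio from the polygon's second central moments."""
    x, y = np.asarray(poly.exterior.coords).T
    x0, y0 = x[:-1], y[:-1]
    x1, y1 = x[1:], y[1:]
    cross = x0 * y1 - x1 * y0
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return 0.0, 1.0
    cx = ((x0 + x1) * cross).sum() / (6.0 * a)
    cy = ((y0 + y1) * cross).sum() / (6.0 * a)
    ixx = ((y0**2 + y0 * y1 + y1**2) * cross).sum() / 12.0
    iyy = ((x0**2 + x0 * x1 + x1**2) * cross).sum() / 12.0
    ixy = ((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross).sum() / 24.0
    # central second moments per unit area
    mxx = iyy / a - cx**2
    myy = ixx / a - cy**2
    mxy = ixy / a - cx * cy
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals = np.linalg.eigvalsh(cov)
    lmin, lmax = max(evals[0], 0.0), max(evals[1], 1e-24)
    ecc = float(np.sqrt(max(0.0, 1.0 - lmin / lmax)))
    aspect = float(np.sqrt(lmax / lmin)) if lmin > 0 else float("inf")
    if not np.isfinite(aspect):
        aspect = 1e6
    return ecc, aspect


def _rasterize(poly: Polygon, shape_hw: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape_hw, dtype=bool)
    xs, ys = np.asarray(poly.exterior.coords).T
    rr, cc = draw_polygon(ys, xs, shape=shape_hw)
    mask[rr, cc] = True
    for interior in poly.interiors:
        xs, ys = np.asarray(interior.coords).T
        rr, cc = draw_polygon(ys, xs, shape=shape_hw)
        mask[rr, cc] = False
    return mask


def smooth_features(table: FeatureTable, centroids_um: np.ndarray, radius_um: float) -> FeatureTable:
    """Append Gaussian-weighted neighbourhood means of the base features.

    For cell i and feature f the smoothed value is
    ``sum_j w_ij f_j / sum_j w_ij`` over cells j within ``radius_um`` of i,
    with ``w_ij = exp(-d_ij^2 / (2 (radius/2)^2))``; the cell itself is
    included with weight 1.  Appended columns are named
    ``<feature>_smoothed_<radius>um``.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    centroids = np.asarray(centroids_um, dtype=float)
    n = len(table.cell_ids)
    if centroids.shape != (n, 2):
        raise ValueError("centroids_um must be (n_cells, 2)")
    base_cols = [i for i, name in enumerate(table.feature_names) if "_smoothed_" not in name]
    base = table.values[:, base_cols]
    smoothed = np.empty_like(base)
    if n > 0:
        tree = cKDTree(centroids)
        sigma2 = (radius_um / 2.0) ** 2
        for i in range(n):
            idx = tree.query_ball_point(centroids[i], radius_um)
            idx = np.asarray(sorted(idx))
            d2 = ((centroids[idx] - centroids[i]) ** 2).sum(axis=1)
            w = np.exp(-d2 / (2.0 * sigma2))
            smoothed[i] = (w[:, None] * base[idx]).sum(axis=0) / w.sum()
    suffix = f"_smoothed_{radius_um:g}um"
    new_names = table.feature_names + [table.feature_names[i] + suffix for i in base_cols]
    return FeatureTable(
        cell_ids=list(table.cell_ids),
        feature_names=new_names,
        values=np.hstack([table.values, smoothed]),
        smoothing_radii_um=table.smoothing_radii_um + [radius_um],
    )
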