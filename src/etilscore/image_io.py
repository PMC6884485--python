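"""Calibrated image and annotation I/O plus geometry in physical units.

All pixel coordinates are 0-based with the pixel-center convention; the only
place physical units enter is through ``pixel_size_um`` (isotropic µm per
pixel).  TIFF calibration travels in the X/YResolution tags
(pixels-per-centimeter); PNG calibration in a JSON sidecar
``<image>.meta.json`` with key ``pixel_size_um``.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage
from shapely.geometry import Polygon, mapping, shape

__all__ = [
    "CalibratedImage",
    "RegionAnnotation",
    "read_image",
    "write_image",
    "read_annotations",
    "write_annotations",
    "region_area_mm2",
    "write_cells",
    "read_cells",
    "write_scores",
    "read_scores",
]

_UM_PER_CM = 10_000.0


@dataclass
class CalibratedImage:
    """RGB brightfield image with isotropic physical pixel size.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array of intensities in [0, 255].
    pixel_size_um : µm per pixel (isotropic); must be positive.
    id : identifier used in result tables.
    """

    pixels: np.ndarray
    pixel_size_um: float
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("pixels must be integer-valued in [0, 255]")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class RegionAnnotation:
    """Named set of polygons (slide pixel coordinates) delimiting a region.

    ``polygons`` are shapely Polygons; holes are interior rings and are
    subtracted from areas.
    """

    polygons: list[Polygon]
    label: str = "tumor"

    def __post_init__(self) -> None:
        for poly in self.polygons:
            if len(poly.exterior.coords) < 4:  # closed ring: >= 3 distinct vertices
                raise ValueError("each polygon ring needs at least 3 vertices")
            # zero-area (degenerate) rings are tolerated; they contribute no
            # area and region_area_mm2 warns about them
            if not poly.is_valid and poly.area > 0:
                raise ValueError(f"self-intersecting or invalid polygon in region '{self.label}'")

    def contains_point(self, x: float, y: float) -> bool:
        from shapely.geometry import Point

        p = Point(x, y)
        return any(poly.contains(p) for poly in self.polygons)


class CalibrationError(ValueError):
    """No physical pixel size could be determined for an image."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_image(path: str | Path, pixel_size_um: float | None = None) -> CalibratedImage:
    """Read a TIFF or PNG image with its µm/px calibration.

    Calibration is taken from TIFF resolution tags, then from a
    ``<image>.meta.json`` sidecar, then from the ``pixel_size_um`` override.
    Raises :class:`CalibrationError` when none is available, and
    ``ValueError`` on anisotropic calibration.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    calib: float | None = None
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            pixels = page.asarray()
            tags = page.tags
            if "XResolution" in tags and "YResolution" in tags:
                xres = _ratio(tags["XResolution"].value)
                yres = _ratio(tags["YResolution"].value)
                unit = tags.get("ResolutionUnit")
                unit_val = getattr(unit, "value", None) if unit is not None else None
                # 3 == centimeter (the convention this package writes)
                if xres > 0 and yres > 0 and (unit_val is None or int(unit_val) == 3):
                    sx = _UM_PER_CM / xres
                    sy = _UM_PER_CM / yres
                    if abs(sx - sy) > 1e-6 * max(sx, sy):
                        raise ValueError(
                            f"anisotropic calibration ({sx:.6g} x {sy:.6g} µm) is not supported"
                        )
                    calib = sx
    elif suffix == ".png":
        pixels = np.asarray(PILImage.open(path).convert("RGB"))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")

    if calib is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            calib = float(meta["pixel_size_um"])
    if calib is None:
        calib = pixel_size_um
    if calib is None:
        raise CalibrationError(
            f"no pixel size found for {path}; supply pixel_size_um explicitly "
            f"or provide a {_sidecar_path(path).name} sidecar"
        )
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    return CalibratedImage(pixels=pixels[..., :3], pixel_size_um=float(calib), id=path.stem)


def _ratio(value) -> float:
    if isinstance(value, tuple):
        num, den = value
        return num / den if den else 0.0
    return float(value)


def write_image(image: CalibratedImage, path: str | Path) -> Path:
    """Write TIFF (resolution tags in px/cm) or PNG (+ JSON sidecar)."""
    path = Path(path)
    px_per_cm = _UM_PER_CM / image.pixel_size_um
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            image.pixels.astype(np.uint8),
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
            photometric="rgb",
        )
    elif path.suffix.lower() == ".png":
        PILImage.fromarray(image.pixels.astype(np.uint8)).save(path)
        _sidecar_path(path).write_text(json.dumps({"pixel_size_um": image.pixel_size_um}))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    return path


def region_area_mm2(region: RegionAnnotation, pixel_size_um: float) -> float:
    """Area of a region in mm²: shoelace polygon area × (µm/px)² / 10⁶.

    Interior rings (holes) are subtracted.  A degenerate (zero-area) region
    triggers a warning and returns 0.0.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    area_px = sum(poly.area for poly in region.polygons)
    if area_px == 0:
        warnings.warn(f"region '{region.label}' has zero area", stacklevel=2)
        return 0.0
    return area_px * pixel_size_um**2 / 1e6


def read_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Read region annotations from a GeoJSON FeatureCollection."""
    data = json.loads(Path(path).read_text())
    regions: dict[str, list[Polygon]] = {}
    for feat in data.get("features", []):
        geom = shape(feat["geometry"])
        label = feat.get("properties", {}).get("label", "tumor")
        polys = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
        regions.setdefault(label, []).extend(polys)
    return [RegionAnnotation(polygons=p, label=lbl) for lbl, p in regions.items()]


def write_annotations(regions: list[RegionAnnotation], path: str | Path) -> Path:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"label": region.label},
        }
        for region in regions
        for poly in region.polygons
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return Path(path)


def write_cells(cells, path: str | Path) -> Path:
    """Write detected cells as a GeoJSON FeatureCollection.

    The feature geometry is the nucleus polygon; the cell outline, class
    label, centroid and any computed features travel in ``properties``.
    An empty cell list produces a valid empty FeatureCollection.
    """
    features = []
    for i, cell in enumerate(cells):
        props = {
            "cell_id": getattr(cell, "cell_id", i),
            "label": cell.label,
            "centroid_um": [float(cell.centroid_um[0]), float(cell.centroid_um[1])],
            "nucleus_area_um2": float(cell.nucleus_area_um2),
            "cell_area_um2": float(cell.cell_area_um2),
            "cell_polygon": mapping(cell.cell_polygon) if cell.cell_polygon is not None else None,
            "features": {k: float(v) for k, v in cell.features.items()},
        }
        features.append(
            {"type": "Feature", "geometry": mapping(cell.nucleus_polygon), "properties": props}
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return Path(path)


def read_cells(path: str | Path):
    """Read cells written by :func:`write_cells` back into Cell objects."""
    from etilscore.detection import Cell

    data = json.loads(Path(path).read_text())
    cells = []
    for feat in data.get("features", []):
        props = feat["properties"]
        cell_poly = shape(props["cell_polygon"]) if props.get("cell_polygon") else None
        cells.append(
            Cell(
                nucleus_polygon=shape(feat["geometry"]),
                cell_polygon=cell_poly,
                centroid_um=np.asarray(props["centroid_um"], dtype=float),
                nucleus_area_um2=props["nucleus_area_um2"],
                cell_area_um2=props["cell_area_um2"],
                features=dict(props.get("features", {})),
                label=props.get("label", "unclassified"),
            )
        )
    return cells


_SCORE_FIELDS = ["id", "n_tumor", "n_til", "n_stroma", "n_other", "etil_pct"]


def write_scores(results, path: str | Path) -> Path:
    """Write ETILResult rows as CSV; undefined scores are written as 'NA'."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCORE_FIELDS)
        for res in results:
            etil = "NA" if res.etil_pct is None else f"{res.etil_pct:.4f}"
            writer.writerow([res.region_id, res.n_tumor, res.n_til, res.n_stroma, res.n_other, etil])
    return Path(path)


def read_scores(path: str | Path):
    from etilscore.scoring import ETILResult

    results = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            etil = None if row["etil_pct"] == "NA" else float(row["etil_pct"])
            results.append(
                ETILResult(
                    region_id=row["id"],
                    n_tumor=int(row["n_tumor"]),
                    n_til=int(row["n_til"]),
                    n_stroma=int(row["n_stroma"]),
                    n_other=int(row["n_other"]),
                    etil_pct=etil,
                )
            )
    return results
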