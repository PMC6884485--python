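"""H&E optical density, per-slide stain-vector estimation and deconvolution.

Absorbances of mixed stains add linearly in optical density (Beer–Lambert):
``OD_c = log10(I0_c / I_c)`` per channel ``c``.  A slide's color model is a
3×3 matrix whose rows are unit OD vectors for hematoxylin, eosin, and a
residual completing the basis; deconvolution inverts this matrix per pixel
to recover stain concentrations.  Because staining varies between labs and
over time, the hematoxylin/eosin directions are re-estimated per slide by a
Macenko-style procedure: the OD cloud of stained pixels is projected onto
its top-2 principal plane and robust extreme directions are taken as the
two stains.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "StainProfile",
    "default_he_profile",
    "rgb_to_od",
    "od_to_rgb",
    "compose_od",
    "estimate_stain_vectors",
    "deconvolve",
]

# QuPath's documented default H&E vectors (unnormalized)
_DEFAULT_H = np.array([0.65, 0.70, 0.29])
_DEFAULT_E = np.array([0.07, 0.99, 0.11])


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length stain vector")
    return v / n


@dataclass
class StainProfile:
    """Unit stain vectors in OD space plus per-channel background intensity.

    ``estimated`` is True when the H/E directions were refined from a slide
    rather than taken from defaults.
    """

    h_vector: np.ndarray
    e_vector: np.ndarray
    residual_vector: np.ndarray | None = None
    background_intensity: np.ndarray = field(default_factory=lambda: np.array([255.0, 255.0, 255.0]))
    estimated: bool = False

    def __post_init__(self) -> None:
        self.h_vector = _unit(self.h_vector)
        self.e_vector = _unit(self.e_vector)
        if np.any(self.h_vector < 0) or np.any(self.e_vector < 0):
            raise ValueError("stain vectors must have non-negative components")
        angle = np.degrees(np.arccos(np.clip(self.h_vector @ self.e_vector, -1, 1)))
        if angle < 1.0:
            raise ValueError(f"h and e vectors are nearly collinear (angle {angle:.3f} deg)")
        if self.residual_vector is None:
            self.residual_vector = _unit(np.cross(self.h_vector, self.e_vector))
        else:
            self.residual_vector = _unit(self.residual_vector)
        self.background_intensity = np.asarray(self.background_intensity, dtype=float)
        if self.background_intensity.shape != (3,) or np.any(self.background_intensity <= 0) or np.any(
            self.background_intensity > 255
        ):
            raise ValueError("background_intensity must be a 3-vector in (0, 255]")

    @property
    def matrix(self) -> np.ndarray:
        """3×3 matrix with rows (h, e, residual)."""
        return np.stack([self.h_vector, self.e_vector, self.residual_vector])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "h": self.h_vector.tolist(),
                "e": self.e_vector.tolist(),
                "residual": self.residual_vector.tolist(),
                "background": self.background_intensity.tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "StainProfile":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(
            h_vector=np.asarray(data["h"]),
            e_vector=np.asarray(data["e"]),
            residual_vector=np.asarray(data["residual"]),
            background_intensity=np.asarray(data["background"]),
        )


def default_he_profile() -> StainProfile:
    """The standard H&E profile used before per-slide refinement."""
    return StainProfile(h_vector=_DEFAULT_H, e_vector=_DEFAULT_E)


def rgb_to_od(pixels: np.ndarray, background_intensity: np.ndarray | None = None) -> np.ndarray:
    """Convert RGB intensities to optical density per channel.

    ``OD_c = log10(I0_c / max(I_c, 1))``; intensities are clamped at 1 so the
    OD stays finite, and OD is non-negative wherever I <= I0.
    """
    if background_intensity is None:
        background_intensity = np.array([255.0, 255.0, 255.0])
    background_intensity = np.asarray(background_intensity, dtype=float)
    if np.any(background_intensity <= 0):
        raise ValueError("background intensities must be positive")
    intensities = np.maximum(np.asarray(pixels, dtype=float), 1.0)
    return np.log10(background_intensity / intensities)


def od_to_rgb(od: np.ndarray, background_intensity: np.ndarray | None = None) -> np.ndarray:
    """Invert :func:`rgb_to_od` (float output, not clipped to integers)."""
    if background_intensity is None:
        background_intensity = np.array([255.0, 255.0, 255.0])
    return np.asarray(background_intensity, dtype=float) * 10.0 ** (-np.asarray(od, dtype=float))


def compose_od(concentrations: np.ndarray, profile: StainProfile) -> np.ndarray:
    """Mix per-pixel stain concentrations into an OD image (Beer–Lambert)."""
    conc = np.asarray(concentrations, dtype=float)
    return conc @ profile.matrix


def deconvolve(od: np.ndarray, profile: StainProfile) -> np.ndarray:
    """Recover per-pixel (h, e, residual) concentrations from an OD image.

    Solves the 3×3 linear stain mixture exactly per pixel.  Raises on a
    singular stain matrix, naming the offending vectors.
    """
    mat = profile.matrix
    if abs(np.linalg.det(mat)) < 1e-12:
        raise ValueError(
            f"singular stain matrix: h={profile.h_vector}, e={profile.e_vector}, "
            f"residual={profile.residual_vector} are linearly dependent"
        )
    inv = np.linalg.inv(mat)
    return np.asarray(od, dtype=float) @ inv


def estimate_stain_vectors(
    image,
    defaults: StainProfile | None = None,
    min_od: float = 0.15,
    percentile: float = 1.0,
) -> StainProfile:
    """Refine H&E stain vectors for one slide (Macenko-style).

    Pixels with total OD >= ``min_od`` are projected onto the plane of the
    top-2 principal components of the OD cloud; the directions at the
    ``percentile``-th and (100-percentile)-th percentile of the planar angle
    are taken as the two stains.  Hematoxylin is the direction whose green
    fraction is smaller (eosin absorbance is dominated by the green channel).

    With fewer than 100 qualifying pixels the defaults are returned
    unchanged (``estimated`` stays False) with a warning.
    """
    if defaults is None:
        defaults = default_he_profile()
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    od = rgb_to_od(pixels, defaults.background_intensity).reshape(-1, 3)
    stained = od[od.sum(axis=1) >= min_od]
    if stained.shape[0] < 100:
        warnings.warn("too few stained pixels; returning default stain vectors", stacklevel=2)
        return replace(defaults, estimated=False)

    # principal plane of the (uncentered) OD cloud
    _, _, vt = np.linalg.svd(stained, full_matrices=False)
    basis = vt[:2]
    # orient the basis so projections are mostly positive
    if (stained @ basis[0]).sum() < 0:
        basis[0] = -basis[0]
    proj = stained @ basis.T
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [percentile, 100.0 - percentile])
    v1 = np.cos(lo) * basis[0] + np.sin(lo) * basis[1]
    v2 = np.cos(hi) * basis[0] + np.sin(hi) * basis[1]
    v1 = _unit(np.clip(v1, 0, None))
    v2 = _unit(np.clip(v2, 0, None))
    # eosin absorbs green most strongly; hematoxylin is the other extreme
    g1, g2 = v1[1], v2[1]
    h_vec, e_vec = (v1, v2) if g1 <= g2 else (v2, v1)
    angle = np.degrees(np.arccos(np.clip(h_vec @ e_vec, -1, 1)))
    if angle < 1.0:
        warnings.warn("estimated stain vectors collapsed; returning defaults", stacklevel=2)
        return replace(defaults, estimated=False)
    return StainProfile(
        h_vector=h_vec,
        e_vector=e_vec,
        background_intensity=defaults.background_intensity.copy(),
        estimated=True,
    )
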