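"""Measurements of a segmented nodule: size, voxel count, roundness, type.

Size is reported as an equivalent diameter — the diameter of the disc (2D)
or sphere (3D) with the same area/volume as the mask, with physical voxel
spacing applied.  For TNM staging of 3D masks the *maximal in-plane*
equivalent diameter is used by default, matching the longest-dimension
convention of clinical size categories; the 3D volume-equivalent diameter is
available via ``mode="volume"``.

Roundness is the compactness 4·pi·Area / Perimeter², which is 1 for a perfect
disc and < 1 for anything else.  The perimeter uses a Crofton-style
multi-directional estimator, which is unbiased enough that rasterized discs
score ≈ 1 (a naive edge count would not).

Nodule type (solid / semisolid / nonsolid) is decided from the mean interior
contrast relative to a full-contrast reference: >= 75% solid, 40–75%
semisolid, < 40% nonsolid, with a value exactly on a threshold assigned to
the upper class.  When no reference contrast is supplied it is estimated as
the 95th percentile of the interior contrast — adequate for solid and
semisolid nodules, but a uniformly faint (nonsolid) nodule then looks solid,
so pass a dataset-level reference when nonsolid detection matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "NoduleMeasurements",
    "voxel_count",
    "equivalent_diameter",
    "roundness",
    "classify_nodule_type",
    "measure_nodule",
    "measurements_table",
]

SOLID_THRESHOLD = 0.75
NONSOLID_THRESHOLD = 0.40


@dataclass
class NoduleMeasurements:
    equivalent_diameter_mm: float
    voxel_count: int
    roundness: float
    nodule_type: str
    bounding_box_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.voxel_count <= 0:
            raise ValueError("voxel_count must be > 0")
        if self.equivalent_diameter_mm <= 0:
            raise ValueError("equivalent_diameter_mm must be > 0")
        if self.roundness <= 0:
            raise ValueError("roundness must be > 0")


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        if not np.isin(np.unique(mask), (0, 1)).all():
            raise ValueError("mask must be boolean or 0/1 valued")
        mask = mask.astype(bool)
    return mask


def voxel_count(mask: np.ndarray) -> int:
    """Exact foreground voxel count."""
    return int(_as_bool_mask(mask).sum())


def equivalent_diameter(mask: np.ndarray, spacing_mm: Sequence[float],
                        mode: str = "auto") -> float:
    """Equivalent diameter of the mask in mm.

    mode:
      * ``"auto"`` — area-equivalent disc diameter for 2D masks, maximal
        in-plane equivalent diameter for 3D masks (the staging convention);
      * ``"volume"`` — volume-equivalent sphere diameter (3D);
      * ``"max_inplane"`` — maximal per-slice disc-equivalent diameter (3D).
    """
    mask = _as_bool_mask(mask)
    spacing = tuple(float(s) for s in spacing_mm)
    n = mask.sum()
    if n == 0:
        raise ValueError("empty mask has no diameter")
    if mask.ndim == 2:
        area = n * spacing[0] * spacing[1]
        return float(2.0 * np.sqrt(area / np.pi))
    if mask.ndim != 3:
        raise ValueError("mask must be 2D or 3D")
    if mode == "volume":
        volume = n * spacing[0] * spacing[1] * spacing[2]
        return float((6.0 * volume / np.pi) ** (1.0 / 3.0))
    if mode in ("auto", "max_inplane"):
        px_area = spacing[0] * spacing[1]
        counts = mask.sum(axis=(0, 1))
        best = int(counts.max())
        return float(2.0 * np.sqrt(best * px_area / np.pi))
    raise ValueError(f"unknown diameter mode {mode!r}")


def _max_area_slice(mask: np.ndarray) -> np.ndarray:
    counts = mask.sum(axis=(0, 1))
    return mask[..., int(np.argmax(counts))]


def roundness(mask: np.ndarray) -> float:
    """Compactness 4·pi·A / P² of a single-component mask.

    For 3D masks the slice of maximal area is scored.  Multiple connected
    components are rejected — call per component.
    """
    mask = _as_bool_mask(mask)
    if not mask.any():
        raise ValueError("empty mask has no roundness")
    _, n_comp = ndimage.label(mask)
    if n_comp > 1:
        raise ValueError(
            f"mask has {n_comp} connected components; measure roundness per component"
        )
    plane = mask if mask.ndim == 2 else _max_area_slice(mask)
    area = float(plane.sum())
    perim = _perimeter(plane)
    if perim == 0:  # single pixel / degenerate: treat as a tiny disc
        return 1.0
    return float(4.0 * np.pi * area / perim ** 2)


def _perimeter(plane: np.ndarray, sigma: float = 1.5) -> float:
    """Sub-pixel perimeter: marching-squares polyline, Gaussian-smoothed.

    The raw marching-squares polyline staircases along smooth boundaries and
    overestimates length by ~7%, which would push disc roundness down to
    ~0.88; smoothing the contour coordinates (sigma in polyline points,
    scaled down for short contours so small objects are not over-shrunk)
    removes the staircase while barely rounding true corners, so discs score
    ~1 and squares stay near pi/4.
    """
    from scipy.ndimage import gaussian_filter1d
    from skimage import measure

    total = 0.0
    for poly in measure.find_contours(plane.astype(float), 0.5):
        closed = bool(np.allclose(poly[0], poly[-1]))
        pts = poly[:-1] if closed else poly
        if len(pts) < 3:
            continue
        mode = "wrap" if closed else "nearest"
        s = min(sigma, 0.03 * len(pts))
        sm = np.column_stack([gaussian_filter1d(pts[:, 0], s, mode=mode),
                              gaussian_filter1d(pts[:, 1], s, mode=mode)])
        length = float(np.linalg.norm(np.diff(sm, axis=0), axis=1).sum())
        if closed:
            length += float(np.linalg.norm(sm[0] - sm[-1]))
        total += length
    return total


def classify_nodule_type(mask: np.ndarray, image: np.ndarray,
                         background_estimate: float,
                         reference_contrast: float | None = None,
                         solid_threshold: float = SOLID_THRESHOLD,
                         nonsolid_threshold: float = NONSOLID_THRESHOLD) -> str:
    """Type a nodule from its mean interior contrast.

    ``background_estimate`` is the parenchyma intensity (must be nonzero —
    contrast is measured relative to it).  ``reference_contrast`` is the
    full-contrast scale; when None it is estimated from the interior itself
    (95th percentile), which cannot flag uniformly faint nodules.
    """
    mask = _as_bool_mask(mask)
    if not mask.any():
        raise ValueError("empty mask cannot be typed")
    if background_estimate == 0:
        raise ValueError("background estimate must be nonzero")
    contrast = np.asarray(image, dtype=np.float64)[mask] - background_estimate
    mean_contrast = float(contrast.mean())
    if reference_contrast is None:
        reference_contrast = float(np.percentile(contrast, 95))
    if reference_contrast <= 0:
        raise ValueError("reference contrast must be > 0 (nodule darker than background?)")
    ratio = mean_contrast / reference_contrast
    if ratio >= solid_threshold:
        return "solid"
    if ratio >= nonsolid_threshold:
        return "semisolid"
    return "nonsolid"


def measure_nodule(mask: np.ndarray, spacing_mm: Sequence[float],
                   image: np.ndarray | None = None,
                   background_estimate: float | None = None,
                   reference_contrast: float | None = None,
                   diameter_mode: str = "auto") -> NoduleMeasurements:
    """Full measurement bundle for one segmented nodule.

    When an image is supplied, the nodule type is computed (background
    defaults to the median intensity outside the mask); without an image the
    type defaults to "solid".
    """
    mask = _as_bool_mask(mask)
    spacing = tuple(float(s) for s in spacing_mm)
    if mask.sum() == 0:
        raise ValueError("empty mask: nothing to measure")

    if image is not None:
        if background_estimate is None:
            background_estimate = float(np.median(np.asarray(image)[~mask]))
        nodule_type = classify_nodule_type(mask, image, background_estimate,
                                           reference_contrast=reference_contrast)
    else:
        nodule_type = "solid"

    idx = np.nonzero(mask)
    bbox = tuple(float((idx[a].max() - idx[a].min() + 1) * spacing[a])
                 for a in range(mask.ndim))

    return NoduleMeasurements(
        equivalent_diameter_mm=equivalent_diameter(mask, spacing, mode=diameter_mode),
        voxel_count=voxel_count(mask),
        roundness=roundness(mask),
        nodule_type=nodule_type,
        bounding_box_mm=bbox,
    )


def measurements_table(measurements: Sequence[NoduleMeasurements],
                       ids: Sequence[str] | None = None):
    """One CSV-ready row per nodule: id, diameter_mm, voxels, roundness, type."""
    import pandas as pd

    ids = ids if ids is not None else [f"nodule_{i}" for i in range(len(measurements))]
    return pd.DataFrame({
        "id": list(ids),
        "diameter_mm": [m.equivalent_diameter_mm for m in measurements],
        "voxels": [m.voxel_count for m in measurements],
        "roundness": [m.roundness for m in measurements],
        "type": [m.nodule_type for m in measurements],
    })
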