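"""Synthetic lung-slab phantoms with ground-truth masks and stage labels.

A phantom is a constant-intensity parenchyma slab with one embedded nodule
(disc in 2D, sphere/ellipsoid in 3D) of known diameter and contrast, plus
additive Gaussian noise.  Diameter and contrast defaults follow the measured
characteristics of real and simulated screening nodules: diameters 4–20 mm,
contrasts 20–65 intensity units above parenchyma.  Intensity units are
arbitrary (recorded as such in the volume metadata); no Hounsfield calibration
is implied.

Nodule texture classes:

* ``solid`` — uniform full contrast;
* ``semisolid`` — full-contrast core plus a half-contrast rim over the outer
  30% of the radius;
* ``nonsolid`` — uniform sub-threshold contrast (35% of nominal).

The ground-truth mask is always the noise-free geometric indicator, and every
generated item carries a TNM descriptor whose stage group is recomputed from
the descriptor, so label consistency is guaranteed by construction.

A nodule whose through-plane extent would exceed the slab depth is flattened
into an oblate ellipsoid that fits (the in-plane diameter — the quantity TNM
staging uses — is preserved); disable with ``cap_through_plane=False`` to get
a rejection error instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from pulmostage.io import ImageVolume
from pulmostage.tnm_staging import TNMDescriptor, stage_group, tu_category

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "ClassDef",
    "PhantomDataset",
    "generate_phantom",
    "sample_spec",
    "generate_dataset",
    "benchmark_class_map",
    "dataset_to_arrays",
    "DIAMETER_RANGE_MM",
    "CONTRAST_RANGE",
]

#: Overall nodule characteristics (real + simulated rows pooled).
DIAMETER_RANGE_MM = (4.0, 20.0)
CONTRAST_RANGE = (20.0, 65.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity description of one synthetic slab."""

    nodule_diameter_mm: float = 10.0
    contrast: float = 40.0
    background_intensity: float = 100.0
    noise_sigma: float = 5.0
    slab_shape: tuple[int, ...] = (64, 64, 8)
    voxel_spacing_mm: tuple[float, ...] = (2.0, 2.0, 2.5)
    nodule_center: tuple[float, ...] | None = None  # grid coords; None = slab center
    nodule_class: str = "solid"
    axis_ratio: float = 1.0  # in-plane col/row semi-axis ratio (ellipsoid option)
    semisolid_rim_fraction: float = 0.30
    semisolid_rim_contrast_fraction: float = 0.50
    nonsolid_contrast_fraction: float = 0.35
    cap_through_plane: bool = True

    def __post_init__(self) -> None:
        if self.nodule_diameter_mm <= 0:
            raise ValueError("nodule_diameter_mm must be > 0")
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if len(self.slab_shape) not in (2, 3):
            raise ValueError("slab_shape must be 2D or 3D")
        if len(self.voxel_spacing_mm) != len(self.slab_shape):
            raise ValueError("voxel_spacing_mm must match slab_shape dimensionality")
        if self.nodule_class not in ("solid", "semisolid", "nonsolid"):
            raise ValueError(f"unknown nodule_class {self.nodule_class!r}")
        if self.axis_ratio <= 0:
            raise ValueError("axis_ratio must be > 0")
        # in-plane extent must fit the slab
        for axis in range(2):
            extent_vox = self.nodule_diameter_mm / self.voxel_spacing_mm[axis]
            if extent_vox > self.slab_shape[axis]:
                raise ValueError(
                    f"nodule extent {extent_vox:.1f} voxels exceeds slab axis "
                    f"{axis} ({self.slab_shape[axis]} voxels)"
                )
        if len(self.slab_shape) == 3 and not self.cap_through_plane:
            extent_vox = self.nodule_diameter_mm / self.voxel_spacing_mm[2]
            if extent_vox > self.slab_shape[2]:
                raise ValueError(
                    f"nodule through-plane extent {extent_vox:.1f} slices exceeds "
                    f"slab depth {self.slab_shape[2]}"
                )


@dataclass
class GroundTruth:
    """Noise-free nodule indicator plus the true size and stage labels."""

    mask: np.ndarray
    true_diameter_mm: float
    tnm: TNMDescriptor
    stage: str

    def __post_init__(self) -> None:
        if stage_group(self.tnm) != self.stage:
            raise ValueError(
                f"stage {self.stage!r} inconsistent with descriptor {self.tnm}"
            )
        if self.true_diameter_mm > 0 and not self.mask.any():
            raise ValueError("nonzero nodule diameter but empty ground-truth mask")


def _radial_field(spec: PhantomSpec) -> np.ndarray:
    """Normalized elliptical radius rho on the grid; the nodule is rho <= 1."""
    shape = spec.slab_shape
    spacing = spec.voxel_spacing_mm
    center = spec.nodule_center or tuple((s - 1) / 2.0 for s in shape)
    a_row = spec.nodule_diameter_mm / 2.0
    a_col = a_row * spec.axis_ratio

    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    rho_sq = (((coords[0] - center[0]) * spacing[0]) / a_row) ** 2
    rho_sq = rho_sq + (((coords[1] - center[1]) * spacing[1]) / a_col) ** 2
    if len(shape) == 3:
        a_z = a_row
        if spec.cap_through_plane:
            # largest through-plane semi-axis that keeps the nodule inside the slab
            half_depth_mm = (shape[2] / 2.0 - 0.5) * spacing[2]
            a_z = min(a_row, max(half_depth_mm, spacing[2] / 2.0))
        rho_sq = rho_sq + (((coords[2] - center[2]) * spacing[2]) / a_z) ** 2
    return np.sqrt(rho_sq)


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[ImageVolume, GroundTruth]:
    """Render one phantom slab: background + contrast·indicator + noise.

    Bit-identical for a fixed (spec, seed).  The ground-truth mask is the
    noise-free indicator; the TNM descriptor is TU from the true diameter with
    LN0/DM0 (pass other codes through :func:`generate_dataset` for labelled
    collections).
    """
    rng = np.random.default_rng(seed)
    rho = _radial_field(spec)
    mask = rho <= 1.0

    contrast_field = np.zeros(spec.slab_shape, dtype=np.float64)
    if spec.nodule_class == "solid":
        contrast_field[mask] = spec.contrast
    elif spec.nodule_class == "semisolid":
        core = rho <= (1.0 - spec.semisolid_rim_fraction)
        rim = mask & ~core
        contrast_field[core] = spec.contrast
        contrast_field[rim] = spec.contrast * spec.semisolid_rim_contrast_fraction
    else:  # nonsolid
        contrast_field[mask] = spec.contrast * spec.nonsolid_contrast_fraction

    image = spec.background_intensity + contrast_field
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.slab_shape)

    volume = ImageVolume(image, spec.voxel_spacing_mm, modality="synthetic",
                         origin={"intensity_units": "arbitrary",
                                 "nodule_class": spec.nodule_class,
                                 "seed": int(seed)})
    tnm = TNMDescriptor(tu=tu_category(spec.nodule_diameter_mm / 10.0), ln="LN0", dm="DM0")
    truth = GroundTruth(mask=mask, true_diameter_mm=spec.nodule_diameter_mm,
                        tnm=tnm, stage=stage_group(tnm))
    return volume, truth


def sample_spec(rng_seed: int,
                diameter_range_mm: tuple[float, float] = DIAMETER_RANGE_MM,
                contrast_range: tuple[float, float] = CONTRAST_RANGE,
                **overrides) -> PhantomSpec:
    """Draw a PhantomSpec with diameter and contrast uniform in the ranges."""
    d_lo, d_hi = diameter_range_mm
    c_lo, c_hi = contrast_range
    if d_lo > d_hi:
        raise ValueError(f"inverted diameter interval {diameter_range_mm}")
    if c_lo > c_hi:
        raise ValueError(f"inverted contrast interval {contrast_range}")
    rng = np.random.default_rng(rng_seed)
    diameter = float(rng.uniform(d_lo, d_hi)) if d_hi > d_lo else float(d_lo)
    contrast = float(rng.uniform(c_lo, c_hi)) if c_hi > c_lo else float(c_lo)
    return PhantomSpec(nodule_diameter_mm=diameter, contrast=contrast, **overrides)


# ---------------------------------------------------------------------------
# Labelled datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassDef:
    """One dataset class: a diameter interval (cm, half-open (lo, hi]) plus
    the LN/DM codes attached to every item of the class."""

    diameter_interval_cm: tuple[float, float]
    ln: str = "LN0"
    dm: str = "DM0"
    allow_tu_straddle: bool = False


@dataclass
class PhantomDataset:
    """A labelled collection of phantom slabs."""

    volumes: list[ImageVolume]
    truths: list[GroundTruth]
    class_names: list[str]         # per item
    classes: tuple[str, ...]       # distinct, in class_map order

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def labels(self) -> np.ndarray:
        """Integer class index per item (index into ``classes``)."""
        lookup = {name: i for i, name in enumerate(self.classes)}
        return np.array([lookup[name] for name in self.class_names], dtype=np.int64)


def benchmark_class_map() -> dict[str, ClassDef]:
    """The default 9-class size-binned benchmark.

    LN/DM codes are invisible in the images, so each of the nine stage labels
    gets its own disjoint diameter bin; LN codes are used only where needed to
    reach a distinct label (the TU4 bins).  With the default 2 mm in-plane
    spacing a 10 cm nodule still fits a 64×64 slab.
    """
    return {
        "1A1": ClassDef((0.4, 1.0)),
        "1A2": ClassDef((1.0, 2.0)),
        "1A3": ClassDef((2.0, 3.0)),
        "1B": ClassDef((3.0, 4.0)),
        "2A": ClassDef((4.0, 5.0)),
        "2B": ClassDef((5.0, 7.0)),
        "3A": ClassDef((7.0, 8.0)),
        "3B": ClassDef((8.0, 9.0), ln="LN2"),
        "3C": ClassDef((9.0, 10.0), ln="LN3"),
    }


def _check_no_straddle(name: str, cdef: ClassDef) -> None:
    lo, hi = cdef.diameter_interval_cm
    if lo >= hi:
        raise ValueError(f"class {name!r}: inverted diameter interval ({lo}, {hi}]")
    # the interval is (lo, hi]; TU boundaries are upper-inclusive, so the
    # interval stays within one TU category iff tu(lo+) == tu(hi)
    if tu_category(np.nextafter(lo, np.inf)) != tu_category(hi):
        if not cdef.allow_tu_straddle:
            raise ValueError(
                f"class {name!r} interval ({lo}, {hi}] cm straddles a TU size "
                "boundary; set allow_tu_straddle=True to override"
            )


def generate_dataset(n_per_class: int,
                     class_map: Mapping[str, ClassDef] | None = None,
                     seed: int = 0,
                     spec_template: PhantomSpec | None = None,
                     contrast_range: tuple[float, float] = CONTRAST_RANGE) -> PhantomDataset:
    """Generate exactly ``n_per_class`` phantoms per class, reproducibly.

    Diameters are drawn uniformly inside each class interval; contrasts
    uniformly in ``contrast_range``.  The per-item stage label is recomputed
    from the sampled diameter via the TU categorizer plus the class's LN/DM
    codes, and must agree across the class (guaranteed when the interval does
    not straddle a TU boundary).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    class_map = dict(class_map) if class_map is not None else benchmark_class_map()
    template = spec_template or PhantomSpec()
    for name, cdef in class_map.items():
        _check_no_straddle(name, cdef)

    root = np.random.SeedSequence(seed)
    volumes, truths, names = [], [], []
    for (name, cdef), class_seq in zip(class_map.items(), root.spawn(len(class_map))):
        lo_mm, hi_mm = (10.0 * v for v in cdef.diameter_interval_cm)
        sampler = np.random.default_rng(class_seq)
        item_seeds = class_seq.spawn(n_per_class)
        for k in range(n_per_class):
            # open at lo: shift the draw off the boundary so tu is constant
            d = float(sampler.uniform(np.nextafter(lo_mm, np.inf), hi_mm))
            c = float(sampler.uniform(*contrast_range))
            spec = replace(template, nodule_diameter_mm=d, contrast=c)
            noise_seed = int(item_seeds[k].generate_state(1, np.uint32)[0])
            volume, truth = generate_phantom(spec, seed=noise_seed)
            tnm = TNMDescriptor(tu=tu_category(d / 10.0), ln=cdef.ln, dm=cdef.dm)
            truth = GroundTruth(mask=truth.mask, true_diameter_mm=d,
                                tnm=tnm, stage=stage_group(tnm))
            volumes.append(volume)
            truths.append(truth)
            names.append(name)
    return PhantomDataset(volumes=volumes, truths=truths, class_names=names,
                          classes=tuple(class_map))


def dataset_to_arrays(dataset: PhantomDataset,
                      masks: Sequence[np.ndarray] | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset into classifier arrays.

    Returns ``(X, y)`` with ``X`` of shape (n, depth, rows, cols) — slab
    slices become input channels — and integer labels ``y``.  When ``masks``
    is given (e.g. segmentation output), each image is multiplied by its mask
    first ("segmentation-fed" inputs).
    """
    xs = []
    for i, vol in enumerate(dataset.volumes):
        img = vol.intensities
        if masks is not None:
            img = img * masks[i].astype(img.dtype)
        if img.ndim == 2:
            img = img[..., None]
        xs.append(np.moveaxis(img, -1, 0))  # (depth, rows, cols)
    X = np.stack(xs).astype(np.float32)
    return X, dataset.labels
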