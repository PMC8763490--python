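"""Image and record I/O plus the end-to-end pipeline runner.

Coordinate convention (used everywhere in the package): arrays are indexed
0-based as ``(row, column)`` for 2D images and ``(row, column, slice)`` for
volumes; physical position = index × spacing, with ``spacing_mm`` ordered the
same way.  CT intensities are used as read (rescale slope/intercept applied);
no window/level is applied by default.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger("pulmostage")

RECORD_SCHEMA_VERSION = 1

__all__ = [
    "ImageVolume",
    "CaseRecord",
    "read_dicom_series",
    "write_dicom_series",
    "read_raster",
    "write_outputs",
    "write_mask_png",
    "read_mask_png",
    "run_pipeline",
]


@dataclass
class ImageVolume:
    """A 2D/3D scalar intensity grid with physical voxel spacing in mm."""

    intensities: np.ndarray
    spacing_mm: tuple[float, ...]
    modality: str = "synthetic"
    origin: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim not in (2, 3):
            raise ValueError(f"image must be 2D or 3D, got ndim={self.intensities.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != self.intensities.ndim:
            raise ValueError("spacing_mm must have one entry per image axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    @property
    def ndim(self) -> int:
        return self.intensities.ndim


@dataclass
class CaseRecord:
    """One processed case: measurements, TNM descriptor, stage, probabilities.

    The stage label is validated against the descriptor via
    :func:`pulmostage.tnm_staging.stage_group` both at construction and at
    write time, so an inconsistent record can neither be built nor persisted.
    """

    case_id: str
    measurements: dict
    tnm: dict
    stage: str
    classifier_probabilities: dict | None = None
    provenance: dict = field(default_factory=dict)
    schema_version: int = RECORD_SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        from pulmostage.tnm_staging import TNMDescriptor, stage_group

        descriptor = TNMDescriptor(**self.tnm)
        expected = stage_group(descriptor)
        if expected != self.stage:
            raise ValueError(
                f"stage {self.stage!r} inconsistent with descriptor {self.tnm} "
                f"(expected {expected!r})"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CaseRecord":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_series(directory: str | Path) -> ImageVolume:
    """Read a single DICOM series from a directory into an ImageVolume.

    Slices are sorted by their position along the slice axis (falling back to
    instance number), pixel spacing and slice spacing are taken from the tags,
    and the rescale slope/intercept are applied.  File order on disk is
    irrelevant.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    datasets = [pydicom.dcmread(str(p)) for p in files]

    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series_uids) != 1:
        raise ValueError(f"directory {directory} mixes {len(series_uids)} DICOM series")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)

    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("DICOM series lacks PixelSpacing; cannot build ImageVolume")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)

    if len(datasets) > 1 and all(hasattr(d, "ImagePositionPatient") for d in datasets):
        zs = [float(d.ImagePositionPatient[2]) for d in datasets]
        slice_mm = float(np.median(np.diff(zs)))
    else:
        slice_mm = float(getattr(first, "SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    volume = np.stack(slices, axis=-1)
    if volume.shape[-1] == 1:
        return ImageVolume(volume[..., 0], (row_mm, col_mm),
                           modality=str(getattr(first, "Modality", "CT")))
    return ImageVolume(volume, (row_mm, col_mm, abs(slice_mm)),
                       modality=str(getattr(first, "Modality", "CT")))


def write_dicom_series(volume: ImageVolume, directory: str | Path,
                       series_description: str = "pulmostage phantom") -> list[Path]:
    """Write an ImageVolume as one secondary-capture DICOM file per slice.

    Intensities are stored as int16 with a rescale intercept so that
    ``read_dicom_series(write_dicom_series(v)) == v`` whenever the intensities
    are integral (phantom defaults are).
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    data = volume.intensities
    if data.ndim == 2:
        data = data[..., None]
        spacing = (*volume.spacing_mm, 1.0)
    else:
        spacing = volume.spacing_mm

    intercept = float(np.floor(data.min()))
    scaled = np.round(data - intercept)
    if scaled.max() > np.iinfo(np.uint16).max:
        raise ValueError("intensity range too wide for 16-bit DICOM storage")
    scaled = scaled.astype(np.uint16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for k in range(data.shape[-1]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = volume.modality if volume.modality in ("CT", "PET") else "OT"
        ds.SeriesDescription = series_description
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * spacing[2]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [spacing[0], spacing[1]]
        ds.SliceThickness = spacing[2]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.Rows, ds.Columns = scaled.shape[:2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = scaled[..., k].tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Raster formats
# ---------------------------------------------------------------------------

_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


def read_raster(path: str | Path, spacing_mm: Sequence[float] | None = None) -> ImageVolume:
    """Read a PNG or (multi-page) TIFF into an ImageVolume.

    Raster formats carry no physical spacing; pass ``spacing_mm`` or accept
    the 1 mm default.
    """
    path = Path(path)
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise ValueError(
            f"unsupported raster format {path.suffix!r}; supported: {sorted(_RASTER_SUFFIXES)}"
        )
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=np.float64)
    else:
        import tifffile

        arr = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
        if arr.ndim == 3:  # tifffile stacks pages first; slice axis goes last
            arr = np.moveaxis(arr, 0, -1)
    if spacing_mm is None:
        spacing_mm = (1.0,) * arr.ndim
    return ImageVolume(arr, tuple(spacing_mm))


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a 2D binary mask as an 8-bit PNG with foreground 255."""
    import imageio.v3 as iio

    path = Path(path)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("write_mask_png expects a 2D mask; write slices separately")
    iio.imwrite(path, (mask.astype(bool).astype(np.uint8) * 255))
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(Path(path))) > 127


def write_outputs(record: CaseRecord, masks: np.ndarray | None,
                  directory: str | Path) -> dict[str, Path]:
    """Persist a CaseRecord (JSON), its measurement row (CSV) and masks (PNG).

    The record is re-validated before anything touches disk, so a stage label
    inconsistent with the descriptor is refused at write time.
    """
    import pandas as pd

    record.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    record_path = directory / f"{record.case_id}_record.json"
    record_path.write_text(record.to_json())
    written["record"] = record_path

    row = {"id": record.case_id, **record.measurements,
           **record.tnm, "stage": record.stage}
    csv_path = directory / f"{record.case_id}_measurements.csv"
    pd.DataFrame([row]).to_csv(csv_path, index=False)
    written["measurements"] = csv_path

    if masks is not None:
        masks = np.asarray(masks)
        if masks.ndim == 2:
            masks = masks[..., None]
        for k in range(masks.shape[-1]):
            p = write_mask_png(masks[..., k], directory / f"{record.case_id}_mask_{k:03d}.png")
            written[f"mask_{k:03d}"] = p
    return written


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(volume: ImageVolume, *, case_id: str = "case",
                 ln_code: str = "LN0", dm_code: str = "DM0",
                 segmentation_params: dict | None = None,
                 classifier=None, seed: int = 0,
                 cache_dir: str | Path | None = None) -> tuple[CaseRecord, np.ndarray]:
    """Segment → measure → stage → (optionally) classify one volume.

    Returns the CaseRecord and the binary segmentation mask.  Deterministic
    for a fixed seed and configuration.  ``classifier`` is an optional trained
    :class:`~pulmostage.mcnn.MCNN`; when absent the record carries staging only.

    ``cache_dir`` enables an availability-match cache: cases whose image
    content, parameters and codes hash to an already-processed entry are
    returned from disk instead of being reprocessed.
    """
    from pulmostage.acm import LevelSetParams, segment_volume
    from pulmostage.nodule_metrics import measure_nodule
    from pulmostage.tnm_staging import stage_from_measurement

    t0 = time.time()
    params = LevelSetParams(**(segmentation_params or {}))

    cache_key = None
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        h = hashlib.sha256()
        h.update(volume.intensities.tobytes())
        h.update(json.dumps([volume.spacing_mm, ln_code, dm_code, seed,
                             sorted(params.__dict__.items())],
                            default=str).encode())
        cache_key = h.hexdigest()[:24]
        record_path = cache_dir / f"{cache_key}.json"
        mask_path = cache_dir / f"{cache_key}_mask.npy"
        if record_path.exists() and mask_path.exists():
            logger.info("cache hit %s for case %s", cache_key, case_id)
            return CaseRecord.from_json(record_path.read_text()), np.load(mask_path)
    result = segment_volume(volume, params)
    logger.info("segmentation: %d iterations, converged=%s (%.2fs)",
                result.iterations, result.converged, time.time() - t0)
    if not result.mask.any():
        raise RuntimeError("segmentation produced an empty mask; no nodule found")

    measurements = measure_nodule(result.mask, volume.spacing_mm, image=volume.intensities)
    tnm, stage = stage_from_measurement(measurements, ln_code, dm_code)
    logger.info("measured d=%.2f mm -> %s/%s/%s -> stage %s",
                measurements.equivalent_diameter_mm, tnm.tu, tnm.ln, tnm.dm, stage)

    probabilities = None
    if classifier is not None:
        from pulmostage.mcnn import predict

        probs, label = predict(classifier, volume.intensities * result.mask)
        probabilities = {name: float(p) for name, p in zip(classifier.class_names, probs)}
        logger.info("classifier: argmax %s", label)

    record = CaseRecord(
        case_id=case_id,
        measurements={
            "diameter_mm": measurements.equivalent_diameter_mm,
            "voxels": measurements.voxel_count,
            "roundness": measurements.roundness,
            "type": measurements.nodule_type,
        },
        tnm={"tu": tnm.tu, "ln": tnm.ln, "dm": tnm.dm},
        stage=stage,
        classifier_probabilities=probabilities,
        provenance={
            "seed": seed,
            "config_hash": _config_hash(params.__dict__),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    if cache_key is not None:
        (cache_dir / f"{cache_key}.json").write_text(record.to_json())
        np.save(cache_dir / f"{cache_key}_mask.npy", result.mask)
    return record, result.mask
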