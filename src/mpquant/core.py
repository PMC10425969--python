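"""Domain types, image/table I/O and physical-scale calibration.

The pipeline works on 8-bit RGB micrographs of filter membranes bearing
fluorescently labelled plastic particles.  Pixel measurements are converted
to physical units through a :class:`ScaleCalibration` (microns per pixel),
obtained either directly or from a scale-bar measurement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "CalibrationError",
    "MissingScaleError",
    "ThresholdFailedError",
    "ScaleCalibration",
    "ImageMeta",
    "RGBMicrograph",
    "ParticleRecord",
    "ImageQC",
    "ParticleTable",
    "calibrate_scale",
    "px_area_to_um2",
    "read_micrograph",
    "write_particle_table",
    "read_particle_table",
    "PARTICLE_TABLE_COLUMNS",
]

GUT_REGIONS = ("foregut", "midgut", "hindgut")
SOURCE_CLASSES = GUT_REGIONS + ("frass",)

EXCLUSION_REASONS = ("none", "below_min_px", "above_max_area", "outside_circularity")

PARTICLE_TABLE_COLUMNS = [
    "image_id",
    "label",
    "area_px",
    "area_um2",
    "perimeter_um",
    "circularity",
    "centroid_row",
    "centroid_col",
    "excluded",
    "exclusion_reason",
]


class CalibrationError(ValueError):
    """Raised for invalid scale-calibration inputs."""


class MissingScaleError(ValueError):
    """Raised when a physical-unit quantity is requested without a calibration."""


class ThresholdFailedError(RuntimeError):
    """Raised when an automatic threshold cannot be determined for an image."""


@dataclass(frozen=True)
class ScaleCalibration:
    """Conversion factor from pixels to microns.

    Attributes
    ----------
    microns_per_pixel : float
        Physical edge length of one pixel, strictly positive.  Areas convert
        with the square of this factor.
    """

    microns_per_pixel: float

    def __post_init__(self) -> None:
        v = self.microns_per_pixel
        if not (np.isfinite(v) and v > 0):
            raise CalibrationError(
                f"microns_per_pixel must be finite and > 0, got {v!r}"
            )

    @property
    def um2_per_px(self) -> float:
        return self.microns_per_pixel**2


def calibrate_scale(scale_bar_length_px: float, known_length_um: float) -> ScaleCalibration:
    """Derive a calibration from a measured scale bar.

    Parameters
    ----------
    scale_bar_length_px : float
        Length of the scale bar in pixels (e.g. measured with a straight-line
        tool on the micrograph).
    known_length_um : float
        The physical length the bar represents, in microns.
    """
    for name, v in (("scale_bar_length_px", scale_bar_length_px),
                    ("known_length_um", known_length_um)):
        if not (np.isfinite(v) and v > 0):
            raise CalibrationError(f"{name} must be finite and > 0, got {v!r}")
    return ScaleCalibration(known_length_um / scale_bar_length_px)


def px_area_to_um2(area_px: int, scale: ScaleCalibration | None) -> float:
    """Convert a pixel-count area to square microns."""
    if scale is None:
        raise MissingScaleError(
            "no scale calibration: supply microns-per-pixel directly or via "
            "calibrate_scale(scale_bar_length_px, known_length_um)"
        )
    if area_px < 0:
        raise ValueError(f"area_px must be >= 0, got {area_px}")
    return float(area_px) * scale.um2_per_px


@dataclass(frozen=True)
class ImageMeta:
    """Per-image sample metadata.

    ``source`` is a gut region (foregut/midgut/hindgut) or ``frass``; ``week``
    is the frass collection week (1-based) where applicable.
    """

    sample_id: str = ""
    source: str | None = None
    week: int | None = None

    def __post_init__(self) -> None:
        if self.source is not None and self.source not in SOURCE_CLASSES:
            raise ValueError(
                f"source must be one of {SOURCE_CLASSES} or None, got {self.source!r}"
            )
        if self.week is not None and self.week < 1:
            raise ValueError(f"week must be >= 1, got {self.week}")


@dataclass
class RGBMicrograph:
    """An 8-bit, 3-channel micrograph with metadata and optional calibration."""

    pixels: np.ndarray
    meta: ImageMeta = field(default_factory=ImageMeta)
    scale: ScaleCalibration | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ValueError("pixel intensities must be integers in [0, 255]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def with_scale(self, scale: ScaleCalibration) -> "RGBMicrograph":
        return replace(self, scale=scale)


@dataclass(frozen=True)
class ParticleRecord:
    """One detected particle and its morphometry.

    ``area_um2`` and ``perimeter_um`` are NaN when the image is uncalibrated.
    ``excluded`` is True exactly when ``exclusion_reason != "none"``.
    """

    label: int
    area_px: int
    area_um2: float
    perimeter_um: float
    circularity: float
    centroid: tuple[float, float]
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.label < 1:
            raise ValueError("label must be a positive integer")
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")
        if not (0.0 <= self.circularity <= 1.0):
            raise ValueError("circularity must lie in [0, 1]")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion_reason {self.exclusion_reason!r}")
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError("excluded flag inconsistent with exclusion_reason")


@dataclass
class ImageQC:
    """Per-image quality control outcome.

    ``processable`` is False iff any flag (``saturated``, ``threshold_failed``)
    is raised.
    """

    processable: bool = True
    foreground_fraction: float = 0.0
    threshold_method: str | None = None
    threshold_value: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for fl in self.flags:
            if fl not in ("saturated", "threshold_failed"):
                raise ValueError(f"unknown QC flag {fl!r}")
        if self.processable != (len(self.flags) == 0):
            raise ValueError("processable must be False iff flags are present")


@dataclass
class ParticleTable:
    """All particles measured in one image, plus the image's QC record."""

    image_id: str
    records: list[ParticleRecord] = field(default_factory=list)
    qc: ImageQC = field(default_factory=ImageQC)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.records]
        if len(labels) != len(set(labels)):
            raise ValueError("particle labels must be unique within an image")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def retained(self) -> list[ParticleRecord]:
        return [r for r in self.records if not r.excluded]

    @property
    def retained_count(self) -> int:
        return len(self.retained)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "image_id": self.image_id,
                "label": r.label,
                "area_px": r.area_px,
                "area_um2": r.area_um2,
                "perimeter_um": r.perimeter_um,
                "circularity": r.circularity,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=PARTICLE_TABLE_COLUMNS)


def _records_from_frame(df: pd.DataFrame) -> list[ParticleRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            ParticleRecord(
                label=int(row.label),
                area_px=int(row.area_px),
                area_um2=float(row.area_um2),
                perimeter_um=float(row.perimeter_um),
                circularity=float(row.circularity),
                centroid=(float(row.centroid_row), float(row.centroid_col)),
                excluded=bool(row.excluded),
                exclusion_reason=str(row.exclusion_reason),
            )
        )
    return recs


def write_particle_table(table: ParticleTable, path) -> None:
    """Write a particle table as CSV (one row per particle)."""
    table.to_dataframe().to_csv(path, index=False)


def read_particle_table(path) -> ParticleTable:
    """Read a particle-table CSV written by :func:`write_particle_table`."""
    df = pd.read_csv(path)
    missing = set(PARTICLE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"particle table {path} is missing columns: {sorted(missing)}")
    if df.empty:
        return ParticleTable(image_id="", records=[])
    ids = df["image_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"particle table {path} mixes image ids: {list(ids)}")
    return ParticleTable(image_id=str(ids[0]), records=_records_from_frame(df))


def read_micrograph(path, meta: ImageMeta | None = None,
                    scale: ScaleCalibration | None = None) -> RGBMicrograph:
    """Read an 8-bit RGB TIFF/PNG micrograph.

    RGBA images have the alpha channel dropped; 16-bit images are linearly
    rescaled to [0, 255] with a warning; grayscale images are rejected.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise OSError(f"could not read image {path!r}: {exc}") from exc
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise ValueError(
            f"{path!r} is single-channel; an RGB (3-channel) micrograph is required"
        )
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"{path!r} has unsupported shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        warnings.warn(
            f"{path!r} is 16-bit; rescaling intensities linearly to [0, 255]",
            stacklevel=2,
        )
        arr = np.round(arr.astype(np.float64) / 257.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path!r} has unsupported dtype {arr.dtype}")
    return RGBMicrograph(pixels=arr, meta=meta or ImageMeta(), scale=scale)


def write_micrograph(img: RGBMicrograph, path) -> None:
    """Write a micrograph as 8-bit RGB TIFF or PNG (by file extension)."""
    iio.imwrite(path, img.pixels)


def circularity_from(area_px: float, perimeter_px: float) -> float:
    """Circularity 4*pi*A/P^2 clamped to [0, 1]; a zero perimeter maps to 1."""
    if perimeter_px <= 0:
        return 1.0
    return min(1.0, 4.0 * math.pi * area_px / perimeter_px**2)
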