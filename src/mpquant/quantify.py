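"""Particle morphometry and exclusion rules.

Measures every labelled region (area, perimeter, circularity, centroid) and
applies the counting rules used for fluorescent plastic on filter images:
drop detections below a minimum pixel size (default 5 px, which removes
thresholding/watershed artifacts), drop implausibly large regions (default
> 20 000 um^2, roughly double the largest bead in the feed stock — such
regions are fused clumps, not single particles), and optionally restrict
circularity (default range [0, 1], i.e. keep any shape).

Perimeter uses an 8-connected boundary chain with diagonal steps weighted
sqrt(2); circularity 4*pi*A/P^2 is clamped to [0, 1].  Excluded particles
are flagged with a reason, never deleted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi

from .core import (
    ImageQC,
    ParticleRecord,
    ParticleTable,
    ScaleCalibration,
    circularity_from,
)

__all__ = [
    "FilterSettings",
    "ImageSummary",
    "measure_particles",
    "apply_filters",
    "qc_image",
    "summarize_image",
    "exclusion_percentage",
    "chain_perimeter",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

# clockwise Moore neighbourhood starting due north
_NB = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class FilterSettings:
    """Particle exclusion rules and the image-saturation QC cutoff.

    ``min_size_px`` and ``max_area_um2`` are strict bounds: a particle of
    exactly ``min_size_px`` pixels or exactly ``max_area_um2`` um^2 is kept.
    ``min_size_um2``, when set, replaces the pixel-based minimum size.
    ``saturation_cutoff`` is the foreground fraction above which an image is
    flagged as carrying too much plastic to quantify.
    """

    min_size_px: int = 5
    circularity_range: tuple[float, float] = (0.0, 1.0)
    max_area_um2: float = 20_000.0
    saturation_cutoff: float = 0.30
    min_size_um2: float | None = None
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if self.min_size_px < 1:
            raise ValueError("min_size_px must be >= 1")
        lo, hi = self.circularity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("circularity_range must satisfy 0 <= lo <= hi <= 1")
        if self.max_area_um2 <= 0:
            raise ValueError("max_area_um2 must be > 0")
        if not (0.0 < self.saturation_cutoff <= 1.0):
            raise ValueError("saturation_cutoff must lie in (0, 1]")
        if self.min_size_um2 is not None and self.min_size_um2 <= 0:
            raise ValueError("min_size_um2 must be > 0 when set")


@dataclass(frozen=True)
class ImageSummary:
    """Retained count, total retained area and exclusion tallies for one image."""

    image_id: str
    retained_count: int
    total_area_um2: float
    n_below_min_px: int
    n_above_max_area: int
    n_outside_circ: int
    n_total: int
    processable: bool = True


def chain_perimeter(mask: np.ndarray) -> float:
    """Outer-boundary chain length of a single 8-connected region.

    Moore-neighbour tracing; axis steps count 1, diagonal steps sqrt(2).
    A single-pixel region has chain length 0 (its circularity is clamped
    to 1 downstream).  Interior holes do not contribute.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() <= 1:
        return 0.0
    m = np.pad(mask, 1)
    rows, cols = np.nonzero(m)
    start = (int(rows[0]), int(cols[0]))  # first in raster order

    def scan(cur, back):
        i = _NB.index((back[0] - cur[0], back[1] - cur[1]))
        for k in range(1, 9):
            d = _NB[(i + k) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if m[cand]:
                dprev = _NB[(i + k - 1) % 8]
                return cand, (cur[0] + dprev[0], cur[1] + dprev[1])
        return None, None

    def step_len(a, b):
        return _SQRT2 if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 2 else 1.0

    back0 = (start[0], start[1] - 1)  # west of start is background
    nxt, back = scan(start, back0)
    if nxt is None:
        return 0.0
    first_move = (start, nxt)
    perim = step_len(start, nxt)
    cur = nxt
    while True:
        nxt, back = scan(cur, back)
        if (cur, nxt) == first_move:
            break
        perim += step_len(cur, nxt)
        cur = nxt
    return perim


def measure_particles(labels: np.ndarray, scale: ScaleCalibration | None,
                      image_id: str = "",
                      exclude_border: bool = False) -> ParticleTable:
    """Measure every labelled region into a :class:`ParticleTable`.

    ``labels`` is an integer mask (0 = background) as produced by
    ``watershed_split``.  With no calibration the physical-unit columns are
    NaN.  Border-touching particles are measured and retained unless
    ``exclude_border`` is set.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be a 2-D integer mask")
    present = np.unique(labels)
    present = present[present > 0]
    if exclude_border and len(present):
        edge = np.unique(np.concatenate([
            labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
        ]))
        present = present[~np.isin(present, edge)]
    if len(present) == 0:
        return ParticleTable(image_id=image_id, records=[])

    slices = ndi.find_objects(labels)
    um = scale.microns_per_pixel if scale is not None else float("nan")
    records = []
    for new_label, lab in enumerate(present, start=1):
        sl = slices[int(lab) - 1]
        sub = labels[sl] == lab
        area_px = int(sub.sum())
        rr, cc = np.nonzero(sub)
        centroid = (float(rr.mean()) + sl[0].start, float(cc.mean()) + sl[1].start)
        perim_px = chain_perimeter(sub)
        records.append(ParticleRecord(
            label=new_label,
            area_px=area_px,
            area_um2=area_px * um * um,
            perimeter_um=perim_px * um,
            circularity=circularity_from(area_px, perim_px),
            centroid=centroid,
        ))
    return ParticleTable(image_id=image_id, records=records)


def apply_filters(table: ParticleTable, settings: FilterSettings | None = None) -> ParticleTable:
    """Flag excluded particles; nothing is deleted.

    Exclusion reasons, checked in order: ``below_min_px`` (area below the
    minimum size, strict), ``above_max_area`` (area strictly above the
    maximum, in um^2), ``outside_circularity``.  The maximum-area rule needs
    a calibrated image; without one it is skipped with a warning.
    """
    f = settings or FilterSettings()
    lo, hi = f.circularity_range
    warned = False
    out = []
    for r in table.records:
        reason = "none"
        if f.min_size_um2 is not None and not math.isnan(r.area_um2):
            too_small = r.area_um2 < f.min_size_um2
        else:
            too_small = r.area_px < f.min_size_px
        if too_small:
            reason = "below_min_px"
        elif math.isnan(r.area_um2):
            if not warned:
                warnings.warn(
                    "image is uncalibrated: the maximum-area rule (um^2) "
                    "cannot be applied and is skipped",
                    stacklevel=2,
                )
                warned = True
            if not (lo <= r.circularity <= hi):
                reason = "outside_circularity"
        elif r.area_um2 > f.max_area_um2:
            reason = "above_max_area"
        elif not (lo <= r.circularity <= hi):
            reason = "outside_circularity"
        out.append(replace(r, excluded=reason != "none", exclusion_reason=reason))
    return ParticleTable(image_id=table.image_id, records=out, qc=table.qc)


def qc_image(mask: np.ndarray, settings: FilterSettings | None = None,
             threshold_method: str | None = None,
             threshold_value: int | None = None) -> ImageQC:
    """Flag an image whose mask is mostly foreground as saturated.

    A filter image covered in plastic beyond ``saturation_cutoff`` cannot be
    quantified particle-by-particle and is marked unprocessable.
    """
    f = settings or FilterSettings()
    mask = np.asarray(mask, dtype=bool)
    frac = float(mask.mean()) if mask.size else 0.0
    flags = ["saturated"] if frac > f.saturation_cutoff else []
    return ImageQC(
        processable=not flags,
        foreground_fraction=frac,
        threshold_method=threshold_method,
        threshold_value=threshold_value,
        flags=flags,
    )


def summarize_image(table: ParticleTable) -> ImageSummary:
    """Retained count, total retained area, and exclusion tallies."""
    retained = table.retained
    total_area = float(sum(r.area_um2 for r in retained)) if retained else 0.0
    reasons = [r.exclusion_reason for r in table.records]
    return ImageSummary(
        image_id=table.image_id,
        retained_count=len(retained),
        total_area_um2=total_area,
        n_below_min_px=reasons.count("below_min_px"),
        n_above_max_area=reasons.count("above_max_area"),
        n_outside_circ=reasons.count("outside_circularity"),
        n_total=len(table.records),
        processable=table.qc.processable,
    )


def exclusion_percentage(summary: ImageSummary, reason: str | None = None) -> float:
    """Percentage of records excluded (optionally for one reason only)."""
    if summary.n_total == 0:
        return 0.0
    if reason is None:
        n = summary.n_below_min_px + summary.n_above_max_area + summary.n_outside_circ
    elif reason == "below_min_px":
        n = summary.n_below_min_px
    elif reason == "above_max_area":
        n = summary.n_above_max_area
    elif reason == "outside_circularity":
        n = summary.n_outside_circ
    else:
        raise ValueError(f"unknown exclusion reason {reason!r}")
    return 100.0 * n / summary.n_total
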