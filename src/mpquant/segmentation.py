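"""RGB micrograph -> binary particle mask.

Three stages: (1) drop the red channel and average the green and blue
channels into a single composite; (2) pick a global threshold from the
composite's 256-bin histogram, with either the iterative-smoothing
Intermodes rule or a Renyi-entropy maximization; (3) split touching
particles with a distance-transform watershed.

Fluorescent particles are bright on a dark background in the composite, so
mask foreground (True) is the bright side of the threshold.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .core import RGBMicrograph, ThresholdFailedError

__all__ = [
    "combine_channels",
    "histogram256",
    "threshold_intermodes",
    "threshold_renyi",
    "select_threshold_method",
    "binarize",
    "watershed_split",
]

INTERMODES_MAX_ITER = 10_000

_STRUCT8 = np.ones((3, 3), dtype=bool)


def combine_channels(img: RGBMicrograph | np.ndarray) -> np.ndarray:
    """Average the green and blue channels; the red channel is discarded.

    Returns a uint8 image with half-up rounding: out = round((G + B) / 2).
    """
    px = img.pixels if isinstance(img, RGBMicrograph) else np.asarray(img)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {px.shape}")
    g = px[:, :, 1].astype(np.uint16)
    b = px[:, :, 2].astype(np.uint16)
    return ((g + b + 1) // 2).astype(np.uint8)


def histogram256(intensity: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of a uint8 image."""
    intensity = np.asarray(intensity)
    if intensity.dtype != np.uint8:
        raise ValueError("histogram256 expects a uint8 intensity image")
    return np.bincount(intensity.ravel(), minlength=256).astype(np.int64)


def threshold_intermodes(hist: np.ndarray,
                         max_iter: int = INTERMODES_MAX_ITER) -> int:
    """Intermodes threshold: smooth the histogram with a 3-bin moving mean
    until exactly two local maxima remain, then return the floor of their
    midpoint.

    Raises :class:`ThresholdFailedError` if the histogram collapses to fewer
    than two modes (effectively unimodal) or does not become bimodal within
    the iteration cap.
    """
    arr = np.asarray(hist)
    if arr.shape != (256,) or np.any(arr < 0):
        raise ValueError("hist must be 256 non-negative counts")
    if arr.sum() < 1:
        raise ValueError("histogram is empty")
    # Smoothing is run on unnormalized integer sums (kernel [1,1,1] without
    # the /3): only comparisons matter, and exact arithmetic keeps the mode
    # structure reflection-symmetric where floats would not be.
    h = [int(v) for v in arr]
    for _ in range(max_iter):
        peaks = [i for i in range(1, 255) if h[i - 1] < h[i] > h[i + 1]]
        if len(peaks) == 2:
            return (peaks[0] + peaks[1]) // 2
        if len(peaks) < 2:
            raise ThresholdFailedError(
                "histogram is unimodal; Intermodes needs a bimodal histogram"
            )
        h = [(h[i - 1] if i > 0 else 0) + h[i] + (h[i + 1] if i < 255 else 0)
             for i in range(256)]
    raise ThresholdFailedError(
        f"histogram not bimodal after {max_iter} smoothing passes"
    )


def _renyi_objective(hist: np.ndarray, alpha: float) -> np.ndarray:
    """Background + foreground Renyi entropy for every candidate threshold t.

    Entries where the split is degenerate (all mass on one side) are -inf.
    At alpha = 1 the Shannon-entropy (maximum-entropy) limit is used.
    """
    n = int(hist.sum())
    p = hist.astype(np.float64) / n
    cb = np.cumsum(hist)  # integer mass at or below t: exact validity test
    valid = (cb > 0) & (cb < n)
    Pb = cb / n
    Pf = (n - cb) / n  # exact complement via integer counts
    obj = np.full(256, -np.inf)
    if alpha == 1.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        A = np.cumsum(plogp)
        # right-side sums accumulated from the right to avoid cancellation
        Ar = np.concatenate([np.cumsum(plogp[::-1])[::-1][1:], [0.0]])
        hb = np.log(Pb[valid]) - A[valid] / Pb[valid]
        hf = np.log(Pf[valid]) - Ar[valid] / Pf[valid]
    else:
        pa = np.where(p > 0, p, 0.0) ** alpha
        S = np.cumsum(pa)
        Sr = np.concatenate([np.cumsum(pa[::-1])[::-1][1:], [0.0]])
        hb = (np.log(S[valid]) - alpha * np.log(Pb[valid])) / (1.0 - alpha)
        hf = (np.log(Sr[valid]) - alpha * np.log(Pf[valid])) / (1.0 - alpha)
    obj[valid] = hb + hf
    return obj


def threshold_renyi(hist: np.ndarray, alpha: float = 2.0) -> int:
    """Renyi-entropy threshold of order ``alpha``.

    Background pixels are those with intensity <= t.  The returned t is the
    smallest maximizer of the summed background and foreground Renyi
    entropies of the normalized histogram.  ``alpha = 1`` selects the Shannon
    (maximum-entropy) limit.
    """
    h = np.asarray(hist, dtype=np.int64)
    if h.shape != (256,) or np.any(h < 0):
        raise ValueError("hist must be 256 non-negative counts")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if int((h > 0).sum()) < 2:
        raise ThresholdFailedError(
            "histogram has fewer than two occupied bins; no split exists"
        )
    obj = _renyi_objective(h, alpha)
    if not np.isfinite(obj).any():
        raise ThresholdFailedError("no valid threshold candidate")
    return int(np.argmax(obj))  # argmax returns the first (smallest) maximizer


def select_threshold_method(intensity: np.ndarray, policy: str = "auto",
                            dense_cutoff: float = 0.05) -> str:
    """Choose between Intermodes and Renyi thresholding.

    Dense, plastic-heavy images threshold better with Intermodes; sparse
    fields of small particles with Renyi entropy.  Under ``policy='auto'``
    an Otsu split of the composite estimates the foreground fraction and
    ``dense_cutoff`` decides; explicit policies pass straight through.
    """
    if policy in ("intermodes", "renyi"):
        return policy
    if policy != "auto":
        raise ValueError(f"unknown threshold policy {policy!r}")
    intensity = np.asarray(intensity)
    if intensity.min() == intensity.max():
        return "renyi"  # flat image: no provisional split possible
    t = threshold_otsu(intensity)
    frac = float(np.mean(intensity > t))
    return "intermodes" if frac >= dense_cutoff else "renyi"


def binarize(intensity: np.ndarray, t: int) -> np.ndarray:
    """Foreground = pixels strictly brighter than t."""
    if not (0 <= t <= 255):
        raise ValueError(f"threshold must lie in [0, 255], got {t}")
    return np.asarray(intensity) > t


def watershed_split(mask: np.ndarray, peak_tolerance: float = 1.0) -> np.ndarray:
    """Split touching particles in a binary mask.

    Markers are regional maxima of the Euclidean distance transform, with
    maxima shallower than ``peak_tolerance`` (in pixels of distance)
    suppressed so a single plateaued disc is never split.  A marker-driven
    watershed constrained to the foreground then assigns labels; one-pixel
    background cuts separate adjacent regions.  Regions are 8-connected.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    edt = ndi.distance_transform_edt(mask)
    peaks = h_maxima(edt, peak_tolerance)
    markers, n = ndi.label(peaks, structure=_STRUCT8)
    if n == 0:  # degenerate; fall back to connected components
        labels, _ = ndi.label(mask, structure=_STRUCT8)
        return labels.astype(np.int32)
    labels = watershed(-edt, markers, mask=mask, connectivity=2,
                       watershed_line=True)
    return labels.astype(np.int32)
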