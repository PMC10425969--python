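"""Automated-vs-reference count agreement.

Replays the automated analysis at every minimum-size threshold in a sweep
(default 1-5 px) and compares the resulting per-image counts with reference
counts — typically blinded manual counts from several raters, or ground
truth from synthetic scenes.  Agreement per threshold is summarized by the
slope of automated against mean-reference counts through the origin
(b = sum(auto*ref)/sum(ref^2); b = 1 means parity with the raters), the
root-mean-square deviation, and, for transparency, an ordinary
least-squares fit with intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ParticleTable
from .quantify import FilterSettings

__all__ = [
    "CountComparison",
    "AgreementResult",
    "sweep_min_size",
    "compare_to_reference",
    "read_reference_counts",
    "plot_agreement",
    "DEFAULT_SWEEP",
]

DEFAULT_SWEEP = (1, 2, 3, 4, 5)


def sweep_min_size(tables: list[ParticleTable],
                   sweep: tuple[int, ...] = DEFAULT_SWEEP,
                   settings: FilterSettings | None = None) -> pd.DataFrame:
    """Per-image retained count at each minimum-size threshold.

    ``tables`` must be measured but not yet size-filtered.  A particle counts
    at threshold k if its pixel area is >= k and it survives every other
    exclusion rule (maximum area, circularity).  Counts are non-increasing
    in k by construction.
    """
    sweep = tuple(sweep)
    if not sweep:
        raise ValueError("sweep set must be non-empty")
    if any(k < 1 for k in sweep):
        raise ValueError("minimum-size thresholds must be >= 1 px")
    f = settings or FilterSettings()
    lo, hi = f.circularity_range
    rows = {}
    for t in tables:
        areas = []
        for r in t.records:
            if not np.isnan(r.area_um2) and r.area_um2 > f.max_area_um2:
                continue
            if not (lo <= r.circularity <= hi):
                continue
            areas.append(r.area_px)
        areas = np.asarray(areas)
        rows[t.image_id] = {k: int((areas >= k).sum()) if len(areas) else 0
                            for k in sweep}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(sweep))
    out.index.name = "image_id"
    out.columns.name = "min_size_px"
    return out


@dataclass
class CountComparison:
    """Reference counts (>= 1 rater per image) and automated counts per
    minimum-size threshold, aligned on image id.

    ``reference``: DataFrame with columns ``image_id, rater_id, count``.
    ``automated``: DataFrame indexed by image_id, one column per threshold
    (the output of :func:`sweep_min_size`).
    """

    reference: pd.DataFrame
    automated: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"image_id", "rater_id", "count"}
        if not need.issubset(self.reference.columns):
            raise ValueError(f"reference counts need columns {sorted(need)}")
        if (self.reference["count"] < 0).any():
            raise ValueError("reference counts must be >= 0")
        if self.automated.empty or self.automated.shape[1] == 0:
            raise ValueError("automated counts are empty")

    @property
    def reference_mean(self) -> pd.Series:
        return self.reference.groupby("image_id")["count"].mean()

    @property
    def inter_rater_sd(self) -> pd.Series | None:
        g = self.reference.groupby("image_id")["count"]
        if g.size().max() < 2:
            return None
        return g.std(ddof=1)


@dataclass
class AgreementResult:
    """Agreement statistics per minimum-size threshold.

    ``per_threshold`` has one row per threshold with columns
    ``slope_origin, rmsd, ols_slope, ols_intercept, n_images``.
    """

    per_threshold: pd.DataFrame
    inter_rater_sd: pd.Series | None = None


def compare_to_reference(cmp: CountComparison) -> AgreementResult:
    """Slope through the origin and RMSD of automated vs. mean reference
    counts, for each threshold in the sweep."""
    ref = cmp.reference_mean
    common = ref.index.intersection(cmp.automated.index)
    if len(common) < 2:
        raise ValueError("need at least two images present in both tables")
    ref = ref.loc[common].to_numpy(dtype=float)
    if not (ref > 0).any():
        raise ValueError("all reference means are zero; slope is undefined")
    rows = []
    for k in cmp.automated.columns:
        auto = cmp.automated.loc[common, k].to_numpy(dtype=float)
        slope = float(np.sum(auto * ref) / np.sum(ref * ref))
        rmsd = float(np.sqrt(np.mean((auto - ref) ** 2)))
        ols_slope, ols_intercept = np.polyfit(ref, auto, 1)
        rows.append({
            "min_size_px": k,
            "slope_origin": slope,
            "rmsd": rmsd,
            "ols_slope": float(ols_slope),
            "ols_intercept": float(ols_intercept),
            "n_images": len(common),
        })
    per = pd.DataFrame(rows).set_index("min_size_px")
    sd = cmp.inter_rater_sd
    return AgreementResult(per_threshold=per,
                           inter_rater_sd=None if sd is None else sd.loc[common])


def read_reference_counts(path) -> pd.DataFrame:
    """Read a reference-count CSV with columns image_id, rater_id, count."""
    df = pd.read_csv(path)
    need = {"image_id", "rater_id", "count"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"reference counts {path} missing columns {sorted(missing)}")
    return df


def plot_agreement(cmp: CountComparison, path, thresholds=None) -> None:
    """Scatter automated vs. mean reference counts with a 1:1 line (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = cmp.reference_mean
    common = ref.index.intersection(cmp.automated.index)
    cols = list(thresholds) if thresholds is not None else list(cmp.automated.columns)
    fig, ax = plt.subplots(figsize=(5, 5))
    for k in cols:
        ax.scatter(ref.loc[common], cmp.automated.loc[common, k],
                   label=f"min size {k} px", alpha=0.7)
    lim = max(float(ref.loc[common].max()), float(cmp.automated.loc[common, cols].to_numpy().max()), 1.0)
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="1:1")
    ax.set_xlabel("mean reference count")
    ax.set_ylabel("automated count")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
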