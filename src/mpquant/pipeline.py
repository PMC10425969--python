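"""End-to-end run orchestration: images -> masks -> tables -> summaries.

Each image goes through composite -> threshold selection -> binarize -> QC
-> watershed -> measure -> filter -> summarize.  Unprocessable images
(saturated, or no bimodal histogram) are reported with their QC flags, not
silently dropped, and one corrupt image never aborts the run.  A JSON
manifest records every setting and per-image threshold so runs are
auditable and exactly repeatable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    ImageMeta,
    ImageQC,
    ParticleTable,
    RGBMicrograph,
    ScaleCalibration,
    ThresholdFailedError,
    calibrate_scale,
    read_micrograph,
    write_particle_table,
)
from .quantify import (
    FilterSettings,
    ImageSummary,
    apply_filters,
    measure_particles,
    qc_image,
    summarize_image,
)
from .segmentation import (
    binarize,
    combine_channels,
    histogram256,
    select_threshold_method,
    threshold_intermodes,
    threshold_renyi,
    watershed_split,
)

__all__ = ["RunConfig", "RunReport", "load_config", "process_image", "run_pipeline"]

log = logging.getLogger("mpquant")

IMAGE_SUFFIXES = (".tif", ".tiff", ".png")

SUMMARY_COLUMNS = [
    "image_id", "retained_count", "total_area_um2",
    "n_below_min_px", "n_above_max_area", "n_outside_circ", "processable",
]


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    Defaults follow the standard counting protocol: minimum size 5 px,
    circularity 0-1, maximum area 20 000 um^2, size sweep 1-5 px.  Scale may
    be given directly (um/px) or as a scale-bar measurement; a direct value
    wins if both are present.
    """

    inputs: list[Path] = field(default_factory=list)
    microns_per_pixel: float | None = None
    scale_bar_px: float | None = None
    scale_bar_um: float | None = None
    threshold_method: str = "auto"
    alpha: float = 2.0
    dense_cutoff: float = 0.05
    filters: FilterSettings = field(default_factory=FilterSettings)
    sweep: tuple[int, ...] = (1, 2, 3, 4, 5)
    out_dir: Path = Path("mpquant-out")
    seed: int = 0

    def resolve_scale(self) -> ScaleCalibration | None:
        if self.microns_per_pixel is not None:
            return ScaleCalibration(self.microns_per_pixel)
        if self.scale_bar_px is not None and self.scale_bar_um is not None:
            return calibrate_scale(self.scale_bar_px, self.scale_bar_um)
        return None


@dataclass
class RunReport:
    """Outcome of a pipeline run."""

    tables: list[ParticleTable]
    summaries: list[ImageSummary]
    failures: dict[str, str]
    manifest: dict

    @property
    def n_processed(self) -> int:
        return sum(1 for s in self.summaries if s.processable)


def load_config(path) -> RunConfig:
    """Read a TOML run configuration ([scale], [threshold], [filters], [qc])."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    scale = raw.get("scale", {})
    thr = raw.get("threshold", {})
    filt = raw.get("filters", {})
    qc = raw.get("qc", {})
    fs_kwargs = {}
    if "min_size_px" in filt:
        fs_kwargs["min_size_px"] = int(filt["min_size_px"])
    if "circularity_range" in filt:
        fs_kwargs["circularity_range"] = tuple(filt["circularity_range"])
    if "max_area_um2" in filt:
        fs_kwargs["max_area_um2"] = float(filt["max_area_um2"])
    if "min_size_um2" in filt:
        fs_kwargs["min_size_um2"] = float(filt["min_size_um2"])
    if "exclude_border" in filt:
        fs_kwargs["exclude_border"] = bool(filt["exclude_border"])
    if "saturation_cutoff" in qc:
        fs_kwargs["saturation_cutoff"] = float(qc["saturation_cutoff"])
    return RunConfig(
        microns_per_pixel=scale.get("microns_per_pixel"),
        scale_bar_px=scale.get("scale_bar_px"),
        scale_bar_um=scale.get("scale_bar_um"),
        threshold_method=thr.get("method", "auto"),
        alpha=float(thr.get("alpha", 2.0)),
        dense_cutoff=float(thr.get("dense_cutoff", 0.05)),
        filters=FilterSettings(**fs_kwargs),
        sweep=tuple(raw.get("sweep", {}).get("min_size_px", (1, 2, 3, 4, 5))),
        seed=int(raw.get("seed", 0)),
    )


def process_image(img: RGBMicrograph, image_id: str,
                  settings: FilterSettings | None = None,
                  threshold_method: str = "auto", alpha: float = 2.0,
                  dense_cutoff: float = 0.05) -> ParticleTable:
    """Run the per-image stages and return the filtered particle table.

    The table's QC record carries the chosen threshold method and value;
    saturated or threshold-failed images come back empty with
    ``qc.processable`` False.
    """
    f = settings or FilterSettings()
    comp = combine_channels(img)
    method = select_threshold_method(comp, threshold_method, dense_cutoff)
    hist = histogram256(comp)
    try:
        if method == "intermodes":
            t = threshold_intermodes(hist)
        else:
            t = threshold_renyi(hist, alpha)
    except ThresholdFailedError:
        log.warning("%s: automatic threshold (%s) failed", image_id, method)
        qc = ImageQC(processable=False, foreground_fraction=0.0,
                     threshold_method=method, threshold_value=None,
                     flags=["threshold_failed"])
        return ParticleTable(image_id=image_id, records=[], qc=qc)
    mask = binarize(comp, t)
    qc = qc_image(mask, f, threshold_method=method, threshold_value=t)
    log.info("%s: method=%s t=%d foreground=%.4f", image_id, method, t,
             qc.foreground_fraction)
    if not qc.processable:
        return ParticleTable(image_id=image_id, records=[], qc=qc)
    labels = watershed_split(mask)
    table = measure_particles(labels, img.scale, image_id,
                              exclude_border=f.exclude_border)
    table.qc = qc
    table = apply_filters(table, f)
    log.info("%s: %d particles measured, %d retained", image_id,
             len(table), table.retained_count)
    return table


def _discover_images(inputs: list[Path]) -> list[Path]:
    paths: list[Path] = []
    for p in inputs:
        p = Path(p)
        if p.is_dir():
            paths.extend(sorted(q for q in p.iterdir()
                                if q.suffix.lower() in IMAGE_SUFFIXES))
        else:
            paths.append(p)
    return paths


def run_pipeline(cfg: RunConfig,
                 metadata: dict[str, ImageMeta] | None = None) -> RunReport:
    """Process every configured image and write tables, summary and manifest."""
    paths = _discover_images(cfg.inputs)
    if not paths:
        raise FileNotFoundError("no readable images found in the configured inputs")
    scale = cfg.resolve_scale()
    out = Path(cfg.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)

    tables: list[ParticleTable] = []
    summaries: list[ImageSummary] = []
    failures: dict[str, str] = {}
    qc_entries = {}
    for path in paths:
        image_id = path.stem
        try:
            meta = (metadata or {}).get(image_id, ImageMeta(sample_id=image_id))
            img = read_micrograph(path, meta=meta, scale=scale)
            table = process_image(
                img, image_id, cfg.filters,
                threshold_method=cfg.threshold_method,
                alpha=cfg.alpha, dense_cutoff=cfg.dense_cutoff,
            )
        except Exception as exc:  # noqa: BLE001 - fail-soft per image
            log.error("%s: failed (%s)", image_id, exc)
            failures[image_id] = str(exc)
            continue
        tables.append(table)
        summaries.append(summarize_image(table))
        qc_entries[image_id] = {
            "processable": table.qc.processable,
            "foreground_fraction": table.qc.foreground_fraction,
            "threshold_method": table.qc.threshold_method,
            "threshold_value": table.qc.threshold_value,
            "flags": list(table.qc.flags),
        }
        write_particle_table(table, out / "tables" / f"{image_id}.csv")

    pd.DataFrame(
        [
            {
                "image_id": s.image_id,
                "retained_count": s.retained_count,
                "total_area_um2": s.total_area_um2,
                "n_below_min_px": s.n_below_min_px,
                "n_above_max_area": s.n_above_max_area,
                "n_outside_circ": s.n_outside_circ,
                "processable": s.processable,
            }
            for s in summaries
        ],
        columns=SUMMARY_COLUMNS,
    ).to_csv(out / "summary.csv", index=False)

    manifest = {
        "mpquant_version": __version__,
        "settings": {
            "microns_per_pixel": None if scale is None else scale.microns_per_pixel,
            "threshold_method": cfg.threshold_method,
            "alpha": cfg.alpha,
            "dense_cutoff": cfg.dense_cutoff,
            "filters": dataclasses.asdict(cfg.filters),
            "sweep": list(cfg.sweep),
            "seed": cfg.seed,
        },
        "images": qc_entries,
        "failures": failures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunReport(tables=tables, summaries=summaries, failures=failures,
                     manifest=manifest)
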