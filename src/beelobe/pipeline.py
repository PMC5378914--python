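"""End-to-end pipeline: synth → (movies → preproc → segment) → metrics/ephys → report.

Stage boundaries are the documented CSV/TIFF/JSON formats, so real data can
enter at any boundary (user-traced ROIs skip segmentation; pre-extracted
trace tables skip imaging entirely).  Two data paths exist:

* the default *trace path* simulates glomerular traces directly — the
  response metrics operate at trace level, so this is the fast way to run
  cohort-scale analyses;
* the optional *raw path* (``stages: movies``) renders dual-wavelength
  pixel movies, registers them, computes ratio movies, detects glomeruli
  and re-extracts the traces, exercising the full imaging chain.

Every run writes a manifest with the seed, a parameter hash, per-stage
timings and artifact checksums.  The report JSON contains no timestamps,
so identical config + seed reproduce it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .containers import STIMULI
from .ephys import memory_scores
from .metrics import DEFAULT_PEAK_WINDOW_MS, bee_metrics
from .preproc import compute_ratio, register, register_between
from .report import default_manifest, report_to_markdown, run_report
from .segment import detect_glomeruli, extract_traces
from .synth import (
    SynthConfig,
    cohort_spikes_frame,
    cohort_traces_frame,
    iter_cohort,
    render_movie,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("synth", "movies", "metrics", "ephys", "report")


@dataclass
class PipelineConfig:
    """Pipeline-wide configuration (YAML-loadable)."""

    seed: int = 0
    outdir: Path = Path("beelobe_run")
    stages: Dict[str, bool] = field(default_factory=lambda: {
        "synth": True, "movies": False, "metrics": True,
        "ephys": True, "report": True,
    })
    synth: Dict = field(default_factory=dict)      # SynthConfig overrides
    register_mode: str = "int"                     # none | int | subpixel
    n_baseline_frames: int = 40
    normalize_distance: bool = False
    peak_window_ms: Sequence[float] = DEFAULT_PEAK_WINDOW_MS
    segment_params: Dict = field(default_factory=dict)
    render_params: Dict = field(default_factory=dict)
    manifest: Optional[List[dict]] = None          # None = study defaults
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.register_mode not in ("none", "int", "subpixel"):
            raise ValueError(f"unknown register mode {self.register_mode!r}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def synth_config(self) -> SynthConfig:
        return SynthConfig(**{**self.synth, "seed": self.seed})

    def param_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "stages": self.stages,
            "synth": self.synth,
            "register_mode": self.register_mode,
            "n_baseline_frames": self.n_baseline_frames,
            "normalize_distance": self.normalize_distance,
            "peak_window_ms": list(self.peak_window_ms),
            "segment_params": self.segment_params,
            "render_params": self.render_params,
            "manifest": self.manifest,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _timing_payload(cfg: SynthConfig) -> dict:
    return {
        "frame_period": cfg.frame_period,
        "odor_onset_frame": cfg.odor_onset_frame,
        "odor_duration_frames": cfg.odor_duration_frames,
        "seed": cfg.seed,
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_synth(config: PipelineConfig) -> List[Path]:
    cfg = config.synth_config()
    out = config.outdir
    traces = cohort_traces_frame(cfg)
    timing = _timing_payload(cfg)
    timing["stimulus_label"] = "panel"
    bio.write_traces(out / "traces.csv", traces, timing=timing)
    spikes = cohort_spikes_frame(cfg)
    bio.write_spikes(out / "spikes.csv", spikes, windows={
        "baseline_window": [0.0, 5.0],
        "odor_window": [5.0, 5.0 + cfg.odor_duration],
        "seed": cfg.seed,
    })
    return [out / "traces.csv", out / "spikes.csv"]


def _stage_movies(config: PipelineConfig) -> List[Path]:
    """Raw path: render, register, ratio, segment, re-extract the traces."""
    cfg = config.synth_config()
    out = config.outdir
    maps_dir = out / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    render = dict(config.render_params)
    seg = dict(config.segment_params)
    for uid, group, treatment, bee_id, traces, truth in iter_cohort(cfg):
        rng = np.random.default_rng([cfg.seed, 42, bee_id])
        ratio_movies = []
        movies = []
        for stim in STIMULI:
            movie = render_movie(traces[stim], truth, cfg, rng=rng, **render)
            movies.append(movie)
        if config.register_mode != "none":
            subpixel = config.register_mode == "subpixel"
            movies = [register(m, subpixel=subpixel)[0] for m in movies]
            movies, _ = register_between(movies, subpixel=subpixel)
        for movie in movies:
            ratio_movies.append(
                compute_ratio(movie, config.n_baseline_frames))
        glomap = detect_glomeruli(ratio_movies, **seg)
        if glomap.n_glomeruli == 0:
            logger.warning("bee %s: no glomeruli detected, skipped", uid)
            continue
        bio.write_labels(maps_dir / f"{uid}_labels.tif", glomap)
        for rm in ratio_movies:
            tr = extract_traces(glomap, rm)
            n_g, n_f = tr.values.shape
            rows.append(pd.DataFrame({
                "bee": uid, "group": group, "treatment": treatment,
                "stimulus": rm.stimulus_label,
                "glomerulus": np.repeat(np.arange(1, n_g + 1), n_f),
                "frame": np.tile(np.arange(n_f), n_g),
                "value": tr.values.ravel(),
            }))
    frame = pd.concat(rows, ignore_index=True)
    timing = _timing_payload(cfg)
    timing["stimulus_label"] = "panel"
    bio.write_traces(config.outdir / "traces.csv", frame, timing=timing)
    return [config.outdir / "traces.csv"]


def _stage_metrics(config: PipelineConfig) -> List[Path]:
    frame, timing = bio.read_traces(config.outdir / "traces.csv")
    if timing is None:
        raise ValueError("traces.csv lacks its timing sidecar")
    bees = bio.traces_from_frame(frame, timing)
    meta = (frame[["bee", "group", "treatment"]]
            .drop_duplicates().set_index("bee"))
    rows = []
    for bee in sorted(bees):
        for row in bee_metrics(
                bees[bee],
                normalize_distance=config.normalize_distance,
                peak_window_ms=tuple(config.peak_window_ms)):
            rows.append({
                "bee": bee,
                "group": meta.loc[bee, "group"],
                "treatment": meta.loc[bee, "treatment"],
                **row,
            })
    table = pd.DataFrame(
        rows, columns=["bee", "group", "treatment", "metric", "stimulus",
                       "value"])
    path = config.outdir / "metrics.csv"
    table.to_csv(path, index=False, float_format="%.9g")
    return [path]


def _stage_ephys(config: PipelineConfig) -> List[Path]:
    frame, windows = bio.read_spikes(config.outdir / "spikes.csv")
    if windows is None:
        raise ValueError("spikes.csv lacks its window sidecar")
    records = bio.records_from_spikes(frame, windows)
    summary, per_bee = memory_scores(records)
    p1 = config.outdir / "ephys_per_bee.csv"
    p2 = config.outdir / "ephys_summary.csv"
    per_bee.to_csv(p1, index=False, float_format="%.9g")
    summary.to_csv(p2, index=False, float_format="%.9g")
    return [p1, p2]


def _stage_report(config: PipelineConfig) -> List[Path]:
    metrics_path = config.outdir / "metrics.csv"
    ephys_path = config.outdir / "ephys_per_bee.csv"
    metrics = pd.read_csv(metrics_path) if metrics_path.exists() else None
    ephys = pd.read_csv(ephys_path) if ephys_path.exists() else None
    manifest = config.manifest if config.manifest is not None \
        else default_manifest()
    report = run_report(metrics, ephys, manifest)
    out_json = config.outdir / "report.json"
    out_md = config.outdir / "report.md"
    bio.write_json(out_json, report)
    out_md.write_text(report_to_markdown(report))
    return [out_json, out_md]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "movies": _stage_movies,
    "metrics": _stage_metrics,
    "ephys": _stage_ephys,
    "report": _stage_report,
}


def run_pipeline(config: PipelineConfig,
                 from_stage: Optional[str] = None) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    ``from_stage`` resumes at a later boundary using the cached artifacts
    of a previous run in the same output directory.  A stage failure
    aborts with the failing stage named and leaves a ``FAILED`` marker
    beside any partial outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    if from_stage is not None and from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    started = from_stage is None
    artifacts: List[Path] = []
    timings: Dict[str, float] = {}
    for stage in STAGES:
        if stage == from_stage:
            started = True
        if not started or not config.stages.get(stage, False):
            continue
        logger.info("stage %s ...", stage)
        t0 = time.perf_counter()
        try:
            artifacts += _STAGE_FUNCS[stage](config)
        except Exception as err:
            (config.outdir / "FAILED").write_text(
                f"stage {stage} failed: {err}\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed") from err
        timings[stage] = time.perf_counter() - t0
    failed = config.outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    from . import __version__
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.param_hash(),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": {str(p.relative_to(config.outdir)): _checksum(p)
                      for p in artifacts},
    }
    bio.write_json(config.outdir / "manifest.json", manifest)
    return manifest
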