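"""Reading and writing the pipeline's on-disk formats.

Stage boundaries are plain formats so that real data can enter anywhere:

* movies — multi-page TIFF per wavelength per stimulus
  (``<bee>_<stim>_<wavelength>.tif``) with a JSON sidecar carrying
  frame timing and stimulus labels;
* ratio movies — 32-bit float TIFF + sidecar;
* label images — uint16 TIFF;
* glomerular traces — long CSV (bee, group, treatment, stimulus,
  glomerulus, frame, value) + timing sidecar;
* spikes — CSV (bee, group, treatment, stimulus, spike_time_s) + window
  sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .containers import (
    DualWavelengthMovie,
    GlomerularTraces,
    GlomerulusMap,
    M17Record,
    RatioMovie,
)

__all__ = [
    "write_movie", "read_movie",
    "write_ratio_movie", "read_ratio_movie",
    "write_labels", "read_labels",
    "write_traces", "read_traces", "traces_from_frame",
    "write_spikes", "read_spikes", "records_from_spikes",
    "write_json", "read_json",
]

TRACE_COLUMNS = ["bee", "group", "treatment", "stimulus", "glomerulus",
                 "frame", "value"]
SPIKE_COLUMNS = ["bee", "group", "treatment", "stimulus", "spike_time_s"]


def write_json(path: Path, payload: dict) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: Path) -> dict:
    return json.loads(Path(path).read_text())


def _timing_sidecar(frame_period: float, odor_onset_frame: int,
                    odor_duration_frames: int, stimulus_label: str) -> dict:
    return {
        "frame_period": frame_period,
        "odor_onset_frame": odor_onset_frame,
        "odor_duration_frames": odor_duration_frames,
        "stimulus_label": stimulus_label,
    }


def write_movie(directory: Path, bee: str, movie: DualWavelengthMovie) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{bee}_{movie.stimulus_label}"
    tifffile.imwrite(directory / f"{stem}_340.tif",
                     movie.f340.astype(np.float32))
    tifffile.imwrite(directory / f"{stem}_380.tif",
                     movie.f380.astype(np.float32))
    write_json(directory / f"{stem}.json",
               _timing_sidecar(movie.frame_period, movie.odor_onset_frame,
                               movie.odor_duration_frames,
                               movie.stimulus_label))


def read_movie(directory: Path, bee: str, stimulus: str,
               ) -> DualWavelengthMovie:
    directory = Path(directory)
    stem = f"{bee}_{stimulus}"
    meta = read_json(directory / f"{stem}.json")
    return DualWavelengthMovie(
        f340=tifffile.imread(directory / f"{stem}_340.tif"),
        f380=tifffile.imread(directory / f"{stem}_380.tif"),
        **meta,
    )


def write_ratio_movie(directory: Path, bee: str, movie: RatioMovie) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{bee}_{movie.stimulus_label}_ratio"
    tifffile.imwrite(directory / f"{stem}.tif",
                     movie.delta_r.astype(np.float32))
    meta = _timing_sidecar(movie.frame_period, movie.odor_onset_frame,
                           movie.odor_duration_frames, movie.stimulus_label)
    meta["baseline_frames"] = list(movie.baseline_frames)
    write_json(directory / f"{stem}.json", meta)


def read_ratio_movie(directory: Path, bee: str, stimulus: str) -> RatioMovie:
    directory = Path(directory)
    stem = f"{bee}_{stimulus}_ratio"
    meta = read_json(directory / f"{stem}.json")
    meta["baseline_frames"] = tuple(meta["baseline_frames"])
    return RatioMovie(delta_r=tifffile.imread(directory / f"{stem}.tif"),
                      **meta)


def write_labels(path: Path, glomap: GlomerulusMap) -> None:
    tifffile.imwrite(Path(path), glomap.labels.astype(np.uint16))


def read_labels(path: Path, min_size: int = 0) -> GlomerulusMap:
    return GlomerulusMap(labels=tifffile.imread(Path(path)),
                         min_size=min_size)


def write_traces(path: Path, frame: pd.DataFrame,
                 timing: Optional[dict] = None) -> None:
    missing = set(TRACE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trace table lacks columns {sorted(missing)}")
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.9g")
    if timing is not None:
        write_json(path.with_suffix(".json"), timing)


def read_traces(path: Path) -> Tuple[pd.DataFrame, Optional[dict]]:
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    timing = read_json(sidecar) if sidecar.exists() else None
    return frame, timing


def traces_from_frame(frame: pd.DataFrame, timing: dict,
                      ) -> Dict[str, Dict[str, GlomerularTraces]]:
    """Rebuild per-bee trace objects from the long CSV table.

    Returns ``{bee: {stimulus: GlomerularTraces}}``; the timing sidecar
    supplies frame period and odor window.
    """
    out: Dict[str, Dict[str, GlomerularTraces]] = {}
    for (bee, stim), sub in frame.groupby(["bee", "stimulus"], sort=True):
        pivot = sub.pivot_table(index="glomerulus", columns="frame",
                                values="value", aggfunc="first").sort_index()
        out.setdefault(str(bee), {})[str(stim)] = GlomerularTraces(
            values=pivot.to_numpy(float),
            stimulus_label=str(stim),
            frame_period=float(timing["frame_period"]),
            odor_onset_frame=int(timing["odor_onset_frame"]),
            odor_duration_frames=int(timing["odor_duration_frames"]),
        )
    return out


def write_spikes(path: Path, frame: pd.DataFrame,
                 windows: Optional[dict] = None) -> None:
    missing = set(SPIKE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"spike table lacks columns {sorted(missing)}")
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.9g")
    if windows is not None:
        write_json(path.with_suffix(".json"), windows)


def read_spikes(path: Path) -> Tuple[pd.DataFrame, Optional[dict]]:
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    windows = read_json(sidecar) if sidecar.exists() else None
    return frame, windows


def records_from_spikes(frame: pd.DataFrame, windows: dict) -> list:
    """Rebuild :class:`M17Record` objects from the spike CSV + sidecar."""
    baseline = tuple(windows["baseline_window"])
    odor = tuple(windows["odor_window"])
    records = []
    grouped = frame.groupby(["bee", "group", "treatment", "stimulus"],
                            sort=True)
    for (bee, group, treatment, stim), sub in grouped:
        bee_id = int(str(bee).rsplit("_", 1)[-1]) if "_" in str(bee) else 0
        records.append(M17Record(
            spike_times=np.sort(sub["spike_time_s"].to_numpy(float)),
            baseline_window=baseline,
            odor_window=odor,
            stimulus_label=str(stim),
            group=str(group),
            treatment=str(treatment),
            bee_id=bee_id,
        ))
    return records
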