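"""Per-bee response metrics: pattern separation, responders, dominant glomeruli.

The odor representation of one bee at frame t is the vector of glomerular
ΔR values.  Pattern separation between two stimuli is the per-frame
Euclidean distance between their vectors; the analysis quantifies

* the *early* separation in the 81–160 ms window after odor onset (one
  80 ms frame), where antennal-lobe output reaches maximal discriminability,
* whether a bee forms *distinct* patterns at all (distance exceeding
  baseline mean + 3 SD within the first 160 ms),
* the percentage of *responsive* glomeruli (trace above its own pre-odor
  mean + 3 SD for consecutive frames during the odor),
* the pooled response of the two *dominant* glomeruli of a reference
  stimulus, and
* response *stability* across extinction trials (distance of each trial's
  pattern to the first trial; 0 = perfectly stable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .containers import GlomerularTraces
from .preproc import window_frames

__all__ = [
    "DistanceTrace",
    "ResponderSummary",
    "DominantResponse",
    "distance_trace",
    "early_separation",
    "odor_period_separation",
    "is_distinct",
    "responsive_glomeruli",
    "dominant_glomeruli",
    "extinction_stability",
    "bee_metrics",
    "DEFAULT_PEAK_WINDOW_MS",
]

logger = logging.getLogger(__name__)

#: "Peak response" window, ms after odor onset (240–800 ms = post-onset
#: frames 3..10 at the 80 ms frame rate).
DEFAULT_PEAK_WINDOW_MS: Tuple[float, float] = (240.0, 800.0)


@dataclass
class DistanceTrace:
    """Per-frame Euclidean distance between two stimuli's glomerular patterns."""

    d: np.ndarray
    baseline_mean: float
    baseline_sd: float
    stimuli: Tuple[str, str]
    normalized: bool
    frame_period: float
    odor_onset_frame: int
    odor_duration_frames: int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.d.size


@dataclass
class ResponderSummary:
    """Count and percentage of glomeruli responding to one stimulus."""

    stimulus: str
    n_responsive: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_responsive <= self.n_total:
            raise ValueError("responder count outside [0, n_total]")

    @property
    def pct(self) -> float:
        return 100.0 * self.n_responsive / self.n_total


@dataclass
class DominantResponse:
    """Pooled response of the two most active glomeruli of a reference stimulus."""

    reference_stimulus: str
    glomerulus_ids: Tuple[int, int]      # 1-based
    pooled_trace: np.ndarray
    peak_value: float
    peak_window_frames: np.ndarray       # absolute frame indices


def distance_trace(
    a: GlomerularTraces,
    b: GlomerularTraces,
    normalize: bool = False,
) -> DistanceTrace:
    """Euclidean distance ``||a(.,t) - b(.,t)||`` per frame.

    ``normalize=True`` divides by sqrt(n_glomeruli) so bees with different
    glomerulus counts become comparable.  Baseline mean/SD of the distance
    are computed over all pre-onset frames and stored for the distinctness
    criterion.
    """
    if not a.compatible_with(b):
        raise ValueError(
            "traces are not comparable: glomerulus/frame grids or odor "
            "timing differ"
        )
    diff = a.values - b.values
    d = np.sqrt(np.sum(diff * diff, axis=0))
    if normalize:
        d = d / np.sqrt(a.n_glomeruli)
    onset = a.odor_onset_frame
    if onset < 1:
        raise ValueError("no pre-onset frames to calibrate baseline noise")
    base = d[:onset]
    return DistanceTrace(
        d=d,
        baseline_mean=float(base.mean()),
        baseline_sd=float(base.std(ddof=0)),
        stimuli=(a.stimulus_label, b.stimulus_label),
        normalized=normalize,
        frame_period=a.frame_period,
        odor_onset_frame=onset,
        odor_duration_frames=a.odor_duration_frames,
    )


def _post_onset_values(dt: DistanceTrace, start_ms: float,
                       end_ms: float) -> np.ndarray:
    rel = window_frames(start_ms, end_ms, dt.frame_period)
    frames = dt.odor_onset_frame + rel
    if frames[-1] >= dt.n_frames:
        raise ValueError("analysis window extends beyond the recording")
    return dt.d[frames]


def early_separation(dt: DistanceTrace) -> float:
    """Separation in the 81–160 ms post-onset window (mean over its frames).

    At the standard 80 ms double-frame period this is exactly the second
    post-onset frame; for other frame periods the mean over all frames
    covering (80, 160] ms is returned.
    """
    return float(_post_onset_values(dt, 80.0, 160.0).mean())


def odor_period_separation(dt: DistanceTrace) -> float:
    """Mean separation over the whole odor stimulation period."""
    frames = np.arange(
        dt.odor_onset_frame,
        min(dt.odor_onset_frame + dt.odor_duration_frames, dt.n_frames),
    )
    if frames.size == 0:
        raise ValueError("odor window is empty")
    return float(dt.d[frames].mean())


def is_distinct(dt: DistanceTrace, horizon_ms: float = 160.0) -> bool:
    """Did the bee form distinct patterns within ``horizon_ms`` of onset?

    True iff the distance exceeds baseline mean + 3 x baseline SD in some
    frame of the first ``horizon_ms``.  In the degenerate noise-free case
    (zero baseline mean and SD) any positive distance counts, and the event
    is logged.
    """
    vals = _post_onset_values(dt, 0.0, horizon_ms)
    threshold = dt.baseline_mean + 3.0 * dt.baseline_sd
    if dt.baseline_sd == 0.0 and dt.baseline_mean == 0.0:
        logger.info(
            "noise-free baseline: distinctness degenerates to d > 0 "
            "(stimuli %s)", dt.stimuli,
        )
        return bool(np.max(vals) > 0.0)
    return bool(np.max(vals) > threshold)


def responsive_glomeruli(
    traces: GlomerularTraces,
    k_consecutive: int = 2,
) -> ResponderSummary:
    """Count glomeruli exceeding 3 SD of their pre-odor baseline.

    A glomerulus is responsive iff its trace exceeds its own pre-onset
    mean + 3 SD in at least ``k_consecutive`` consecutive frames of the
    odor window (two frames by default, suppressing single-frame noise
    spikes).
    """
    onset = traces.odor_onset_frame
    if onset < 5:
        raise ValueError("need at least 5 pre-onset frames for the baseline")
    odor = traces.odor_frames
    if odor.size == 0:
        raise ValueError("odor window is empty")
    if k_consecutive < 1:
        raise ValueError("k_consecutive must be >= 1")
    base = traces.values[:, :onset]
    thr = base.mean(axis=1) + 3.0 * base.std(axis=1, ddof=0)
    above = traces.values[:, odor] > thr[:, None]
    n_resp = 0
    for row in above:
        run = best = 0
        for flag in row:
            run = run + 1 if flag else 0
            best = max(best, run)
        if best >= k_consecutive:
            n_resp += 1
    return ResponderSummary(
        stimulus=traces.stimulus_label,
        n_responsive=n_resp,
        n_total=traces.n_glomeruli,
    )


def dominant_glomeruli(
    traces: GlomerularTraces,
    reference: GlomerularTraces,
    peak_window_ms: Tuple[float, float] = DEFAULT_PEAK_WINDOW_MS,
) -> DominantResponse:
    """Pool the two glomeruli most active in the reference stimulus' peak.

    Glomeruli are ranked by their mean ΔR in the reference stimulus over
    the peak window (default 240–800 ms post-onset); rank ties break toward
    the lower glomerulus index.  The pooled trace is the mean of the two
    selected glomeruli's traces in the *evaluated* stimulus, and
    ``peak_value`` its mean over the same window.
    """
    if reference.n_glomeruli < 2:
        raise ValueError("need at least 2 glomeruli to select dominants")
    if traces.n_glomeruli != reference.n_glomeruli:
        raise ValueError("traces and reference must share the glomerulus set")
    rel = window_frames(peak_window_ms[0], peak_window_ms[1],
                        reference.frame_period)
    frames = reference.odor_onset_frame + rel
    if frames[-1] >= reference.n_frames:
        raise ValueError("peak window extends beyond the recording")
    ref_means = reference.values[:, frames].mean(axis=1)
    order = np.argsort(-ref_means, kind="stable")  # stable: ties to low index
    top = tuple(int(i) + 1 for i in order[:2])
    pooled = traces.values[[top[0] - 1, top[1] - 1], :].mean(axis=0)
    return DominantResponse(
        reference_stimulus=reference.stimulus_label,
        glomerulus_ids=top,  # type: ignore[arg-type]
        pooled_trace=pooled,
        peak_value=float(pooled[frames].mean()),
        peak_window_frames=frames,
    )


def bee_metrics(
    traces: dict,
    normalize_distance: bool = False,
    peak_window_ms: Tuple[float, float] = DEFAULT_PEAK_WINDOW_MS,
) -> List[dict]:
    """All per-bee metric rows for one bee's stimulus panel.

    ``traces`` maps stimulus label -> :class:`GlomerularTraces`.  Metrics
    whose input stimuli are missing are skipped (a bee excluded from the
    extinction part of the session still contributes test metrics).
    Returns rows of ``{"metric", "stimulus", "value"}``.
    """
    rows: List[dict] = []

    def add(metric: str, stimulus: str, value: float) -> None:
        rows.append({"metric": metric, "stimulus": stimulus,
                     "value": float(value)})

    if "cs_plus" in traces and "new" in traces:
        dt = distance_trace(traces["cs_plus"], traces["new"],
                            normalize=normalize_distance)
        add("early_separation", "cs_vs_new", early_separation(dt))
        add("odor_period_separation", "cs_vs_new", odor_period_separation(dt))
        add("distinct_pattern", "cs_vs_new", float(is_distinct(dt)))
    for stim, tr in traces.items():
        add("pct_responders", stim, responsive_glomeruli(tr).pct)
    if "cs_plus" in traces:
        ref = traces["cs_plus"]
        for stim in ("cs_plus", "new", "mixture"):
            if stim in traces:
                dom = dominant_glomeruli(traces[stim], ref,
                                         peak_window_ms=peak_window_ms)
                add("dominant_peak_cs_ref", stim, dom.peak_value)
    if "new" in traces:
        dom = dominant_glomeruli(traces["new"], traces["new"],
                                 peak_window_ms=peak_window_ms)
        add("dominant_peak_new_ref", "new", dom.peak_value)
    ext = [s for s in (f"ext{j}" for j in range(1, 7)) if s in traces]
    if len(ext) >= 2:
        trials = [traces[s] for s in ext]
        for stim, dt in zip(ext[1:],
                            extinction_stability(trials,
                                                 normalize=normalize_distance)):
            add("extinction_distance", stim, odor_period_separation(dt))
        ref = trials[0]
        for stim in ext:
            dom = dominant_glomeruli(traces[stim], ref,
                                     peak_window_ms=peak_window_ms)
            add("extinction_dominant_peak", stim, dom.peak_value)
    return rows


def extinction_stability(
    trials: Sequence[GlomerularTraces],
    normalize: bool = False,
) -> List[DistanceTrace]:
    """Distance of each extinction trial's pattern to the first trial.

    Returns one :class:`DistanceTrace` per trial j >= 2; a perfectly
    repeated response gives d = 0 up to noise.
    """
    if len(trials) < 2:
        raise ValueError("need at least two extinction trials")
    first = trials[0]
    out = []
    for trial in trials[1:]:
        if not first.compatible_with(trial):
            raise ValueError("extinction trials must share the glomerulus "
                             "set and frame grid")
        out.append(distance_trace(trial, first, normalize=normalize))
    return out
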