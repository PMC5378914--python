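"""Synthetic cohorts with the recording structure of the learning study.

The generator emulates the structure of the real experiment so that every
downstream stage is testable with known ground truth:

* 200 double frames at 12.5 Hz (80 ms/frame), odor onset 4 s into the
  recording, 4 s odor duration, ~15 glomeruli per bee, 130x172 px images;
* a 2 x 2 cohort design — group (paired/unpaired training) x treatment
  (Dnmt inhibitor/solvent) — with cell sizes defaulting to those of the
  imaging dataset;
* a stimulus panel of CS+, new odor, mineral oil, binary mixture and six
  extinction trials;
* treatment effects confined to (i) early-window pattern separation
  (paired+inhibitor bees separate the new odor from the CS+ more slowly),
  (ii) new-odor responder counts, (iii) new-odor dominant-glomeruli
  amplitude, and (iv) extinction-trial drift in unpaired+inhibitor bees.

Each glomerulus trace is amplitude x temporal kernel (linear 3-frame rise,
plateau, exponential decay after odor offset) plus i.i.d. Gaussian noise.
The new odor's pattern diverges from the CS+ pattern along a per-frame ramp
``w(t)``; slowing that ramp is how the separation deficit is planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .containers import (
    GROUPS,
    STIMULI,
    TREATMENTS,
    DualWavelengthMovie,
    GlomerularTraces,
    M17Record,
    validate_group,
    validate_stimulus,
    validate_treatment,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_traces",
    "render_movie",
    "invert_ratio_movie",
    "generate_spikes",
    "iter_cohort",
    "cohort_traces_frame",
    "cohort_spikes_frame",
    "plant_early_separation_effect",
    "DEFAULT_CELL_SIZES",
    "DEFAULT_M17_ODOR_RATES",
    "M17_BASELINE_RATE",
]

Cell = Tuple[str, str]

#: Bees per (group, treatment) cell in the imaging analysis (DMF = solvent,
#: RG108 = inhibitor).
DEFAULT_CELL_SIZES: Dict[Cell, int] = {
    ("paired", "solvent"): 7,
    ("paired", "inhibitor"): 10,
    ("unpaired", "solvent"): 6,
    ("unpaired", "inhibitor"): 10,
}

#: Fraction of glomeruli responsive to the new odor, per cell.  The paired
#: solvent cell recruits more glomeruli into the new-odor response than the
#: CS+ response; inhibitor treatment during memory formation suppresses that
#: recruitment in the paired group only.
DEFAULT_NEW_RESPONDER_FRACTION: Dict[Cell, float] = {
    ("paired", "solvent"): 0.6,
    ("paired", "inhibitor"): 0.27,
    ("unpaired", "solvent"): 0.5,
    ("unpaired", "inhibitor"): 0.5,
}

#: M17 spike rates (Hz).  Baseline activity of the proboscis muscle is near
#: silent; the CS+ odor rate of trained solvent bees is anchored at the
#: printed 7 Hz mean, mineral oil near 1 Hz after baseline normalization.
M17_BASELINE_RATE = 0.2


def _extinction_rates(peak: float, tau_trials: float) -> Dict[str, float]:
    return {
        f"ext{j}": M17_BASELINE_RATE
        + peak * math.exp(-(j - 1) / tau_trials)
        for j in range(1, 7)
    }


DEFAULT_M17_ODOR_RATES: Dict[Cell, Dict[str, float]] = {
    ("paired", "solvent"): {
        "cs_plus": 7.0, "new": 2.0, "mineral_oil": 1.2, "mixture": 5.0,
        **_extinction_rates(6.8, 2.0),
    },
    ("paired", "inhibitor"): {
        # inhibitor-treated bees generalize more to the new odor and
        # extinguish more slowly
        "cs_plus": 7.0, "new": 3.5, "mineral_oil": 1.2, "mixture": 5.0,
        **_extinction_rates(6.8, 5.0),
    },
    ("unpaired", "solvent"): {
        "cs_plus": 1.2, "new": 1.2, "mineral_oil": 1.0, "mixture": 1.2,
        **_extinction_rates(1.0, 1e9),
    },
    ("unpaired", "inhibitor"): {
        "cs_plus": 1.2, "new": 1.2, "mineral_oil": 1.0, "mixture": 1.2,
        **_extinction_rates(1.0, 1e9),
    },
}


def _as_cell_map(value: Union[float, int, Mapping[Cell, float]],
                 ) -> Dict[Cell, float]:
    if isinstance(value, Mapping):
        out = {}
        for g in GROUPS:
            for t in TREATMENTS:
                if (g, t) not in value:
                    raise ValueError(f"missing cell ({g}, {t}) in mapping")
                out[(g, t)] = value[(g, t)]
        return out
    return {(g, t): float(value) for g in GROUPS for t in TREATMENTS}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the study's recording conditions."""

    n_bees_per_cell: Union[int, Mapping[Cell, int]] = field(
        default_factory=lambda: dict(DEFAULT_CELL_SIZES))
    n_glomeruli: int = 15
    frame_period: float = 0.08          # s per double frame (12.5 Hz)
    n_frames: int = 200                 # 16 s recording
    odor_onset: float = 4.0             # s
    odor_duration: float = 4.0          # s
    image_shape: Tuple[int, int] = (130, 172)
    response_amplitude: float = 0.06    # ΔR units
    noise_sd: float = 0.01              # ΔR units per frame
    separation_lag: float = 1.25        # ramp slowdown, paired+inhibitor
    responder_fraction_new: Union[float, Mapping[Cell, float]] = field(
        default_factory=lambda: dict(DEFAULT_NEW_RESPONDER_FRACTION))
    dominant_gain_new: float = 0.8      # new-odor dominant gain, paired+inhib
    extinction_drift: float = 0.006     # ΔR per trial, unpaired+inhibitor
    extinction_drift_cv: float = 0.6    # between-bee SD of the drift scale
    cs_responder_fraction: float = 0.4
    bee_gain_sd: float = 0.15           # per-bee staining/response gain SD
    responder_jitter_sd: float = 2.2    # per-bee SD of responder counts
    ramp_frames: int = 2                # frames for w(t) to reach 1 (lag 1)
    rise_frames: int = 3                # kernel linear rise
    decay_tau: float = 1.0              # s, kernel decay after odor offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glomeruli < 1 or self.n_frames < 1:
            raise ValueError("counts must be >= 1")
        if isinstance(self.n_bees_per_cell, Mapping):
            if any(v < 1 for v in self.n_bees_per_cell.values()):
                raise ValueError("cell sizes must be >= 1")
        elif self.n_bees_per_cell < 1:
            raise ValueError("cell sizes must be >= 1")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if self.odor_onset + self.odor_duration > \
                self.n_frames * self.frame_period + 1e-9:
            raise ValueError("odor window extends past the recording")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for frac in _as_cell_map(self.responder_fraction_new).values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("responder_fraction_new must be in [0, 1]")
        if not 0.0 <= self.cs_responder_fraction <= 1.0:
            raise ValueError("cs_responder_fraction must be in [0, 1]")
        if self.ramp_frames < 1 or self.rise_frames < 1:
            raise ValueError("ramp/rise frame counts must be >= 1")
        if self.separation_lag < 1.0:
            raise ValueError("separation_lag must be >= 1 (1 = no slowdown)")

    # -- derived frame geometry ---------------------------------------
    @property
    def odor_onset_frame(self) -> int:
        return int(round(self.odor_onset / self.frame_period))

    @property
    def odor_duration_frames(self) -> int:
        return int(round(self.odor_duration / self.frame_period))

    def cell_size(self, group: str, treatment: str) -> int:
        if isinstance(self.n_bees_per_cell, Mapping):
            return int(self.n_bees_per_cell[(group, treatment)])
        return int(self.n_bees_per_cell)


@dataclass
class GroundTruth:
    """Planted quantities behind one synthetic bee (for recovery tests)."""

    roi_labels: np.ndarray          # (H, W) label image, 0 = background
    pattern_a: np.ndarray           # CS+ per-glomerulus amplitudes
    pattern_b: np.ndarray           # new-odor amplitudes (gain applied)
    mixing_ramp: np.ndarray         # w(t) per frame, non-decreasing in [0,1]
    kernel: np.ndarray              # temporal kernel per frame
    spike_rates: Dict[str, float]   # odor rate per stimulus + "baseline"
    dominant_cs: np.ndarray         # indices of the 2 strongest CS+ glomeruli


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

_STREAM_STRUCTURE = 1000
_STREAM_SPIKES = 500


def _cell_index(group: str, treatment: str) -> Tuple[int, int]:
    validate_group(group)
    validate_treatment(treatment)
    return GROUPS.index(group), TREATMENTS.index(treatment)


def _rng(config: SynthConfig, group: str, treatment: str, bee_id: int,
         stream: int) -> np.random.Generator:
    gi, ti = _cell_index(group, treatment)
    if bee_id < 0:
        raise ValueError("bee_id must be non-negative")
    return np.random.default_rng([config.seed, gi, ti, bee_id, stream])


def _make_labels(config: SynthConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Round glomeruli (radius 4 px, >= 20 px) on a jittered grid."""
    h, w = config.image_shape
    n = config.n_glomeruli
    radius = 4
    ncols = int(np.ceil(np.sqrt(n * w / h)))
    nrows = int(np.ceil(n / ncols))
    labels = np.zeros((h, w), dtype=np.uint16)
    ys = np.linspace(radius + 3, h - radius - 4, nrows)
    xs = np.linspace(radius + 3, w - radius - 4, ncols)
    yy, xx = np.mgrid[0:h, 0:w]
    k = 0
    for y0 in ys:
        for x0 in xs:
            if k >= n:
                break
            cy = y0 + rng.uniform(-2, 2)
            cx = x0 + rng.uniform(-2, 2)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
            labels[mask] = k + 1
            k += 1
    return labels


def _amplitude_multiset(amp: float, m: int) -> np.ndarray:
    # graded amplitudes around `amp`: breaks rank ties, keeps the pattern
    # norm nearly constant across bees
    if m == 1:
        return np.array([amp])
    return amp * np.linspace(1.25, 0.75, m)


def _patterns(config: SynthConfig, group: str, treatment: str,
              rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    n = config.n_glomeruli
    frac_new = _as_cell_map(config.responder_fraction_new)[(group, treatment)]
    # between-bee heterogeneity: responder counts jitter around the cell
    # mean, and an overall response gain emulates variable staining quality
    jit = (rng.normal(0.0, config.responder_jitter_sd, size=2)
           if config.responder_jitter_sd > 0 else np.zeros(2))
    gain = (max(0.3, 1.0 + rng.normal(0.0, config.bee_gain_sd))
            if config.bee_gain_sd > 0 else 1.0)
    n_cs = int(np.clip(round(config.cs_responder_fraction * n + jit[0]),
                       1, n))
    n_new = int(np.clip(round(frac_new * n + jit[1]), 1, n))
    n_shared = min(n_cs, n_new) // 2
    n_new_only = min(n_new - n_shared, n - n_cs)
    perm = rng.permutation(n)
    shared = perm[:n_shared]
    cs_only = perm[n_shared:n_cs]
    new_only = perm[n_cs:n_cs + n_new_only]
    a = np.zeros(n)
    b = np.zeros(n)
    members_a = np.concatenate([shared, cs_only]).astype(int)
    a[members_a] = gain * _amplitude_multiset(config.response_amplitude,
                                              len(members_a))
    members_b = np.concatenate([shared, new_only]).astype(int)
    b[members_b] = gain * _amplitude_multiset(config.response_amplitude,
                                              len(members_b))
    if group == "paired" and treatment == "inhibitor":
        # uniform attenuation of the whole new-odor pattern: preserves the
        # within-pattern ranking, so the measured dominant-glomeruli
        # amplitude scales by exactly this factor
        b *= config.dominant_gain_new
    return a, b


def _temporal_kernel(config: SynthConfig) -> np.ndarray:
    onset = config.odor_onset_frame
    offset = onset + config.odor_duration_frames
    t = np.arange(config.n_frames)
    kernel = np.zeros(config.n_frames)
    during = (t >= onset) & (t < offset)
    kernel[during] = np.minimum(1.0, (t[during] - onset + 1)
                                / config.rise_frames)
    after = t >= offset
    kernel[after] = np.exp(-(t[after] - offset) * config.frame_period
                           / config.decay_tau)
    return kernel


def _mixing_ramp(config: SynthConfig, group: str,
                 treatment: str) -> np.ndarray:
    lag = (config.separation_lag
           if (group, treatment) == ("paired", "inhibitor") else 1.0)
    onset = config.odor_onset_frame
    t = np.arange(config.n_frames)
    w = np.clip((t - onset + 1) / (config.ramp_frames * lag), 0.0, 1.0)
    w[t < onset] = 0.0
    return w


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def generate_traces(
    config: SynthConfig,
    bee_id: int,
    group: str,
    treatment: str,
    stimuli: Optional[Sequence[str]] = None,
) -> Tuple[Dict[str, GlomerularTraces], GroundTruth]:
    """Simulate one bee's per-glomerulus ΔR traces for the stimulus panel.

    Returns a dict keyed by stimulus label plus the :class:`GroundTruth`
    describing the planted patterns.  Each stimulus draws its noise from an
    independent substream seeded from (master seed, cell, bee, stimulus), so
    requesting a subset of stimuli reproduces exactly the traces a full run
    would have produced.
    """
    _cell_index(group, treatment)
    if stimuli is None:
        stimuli = STIMULI
    for s in stimuli:
        validate_stimulus(s)

    srng = _rng(config, group, treatment, bee_id, _STREAM_STRUCTURE)
    labels = _make_labels(config, srng)
    pattern_a, pattern_b = _patterns(config, group, treatment, srng)
    kernel = _temporal_kernel(config)
    ramp = _mixing_ramp(config, group, treatment)
    dominant_cs = np.argsort(-pattern_a, kind="stable")[:2]
    gi, ti = _cell_index(group, treatment)
    truth = GroundTruth(
        roi_labels=labels,
        pattern_a=pattern_a,
        pattern_b=pattern_b,
        mixing_ramp=ramp,
        kernel=kernel,
        spike_rates={"baseline": M17_BASELINE_RATE,
                     **DEFAULT_M17_ODOR_RATES[(group, treatment)]},
        dominant_cs=dominant_cs,
    )

    drift_here = (group, treatment) == ("unpaired", "inhibitor")
    drift = 0.0
    if drift_here and config.extinction_drift > 0:
        # per-bee drift magnitude: the instability is a population trend
        # with wide between-animal scatter
        scale = max(0.1, 1.0 + srng.normal(0.0, config.extinction_drift_cv))
        drift = config.extinction_drift * scale
    out: Dict[str, GlomerularTraces] = {}
    for stim in STIMULI:          # canonical order keeps streams stable
        if stim not in stimuli:
            continue
        if stim == "cs_plus":
            clean = np.outer(pattern_a, kernel)
        elif stim == "mineral_oil":
            clean = np.zeros((config.n_glomeruli, config.n_frames))
        elif stim == "mixture":
            clean = np.outer(np.maximum(pattern_a, pattern_b), kernel)
        elif stim == "new":
            mix = ((1.0 - ramp)[None, :] * pattern_a[:, None]
                   + ramp[None, :] * pattern_b[:, None])
            clean = mix * kernel[None, :]
        else:                      # extinction trials repeat the CS+
            j = int(stim[3:])
            amp = pattern_a.copy()
            if drift_here:
                amp[dominant_cs] += drift * (j - 1)
            clean = np.outer(amp, kernel)
        values = clean
        if config.noise_sd > 0:
            nrng = _rng(config, group, treatment, bee_id, STIMULI.index(stim))
            values = clean + nrng.normal(0.0, config.noise_sd, clean.shape)
        out[stim] = GlomerularTraces(
            values=values,
            stimulus_label=stim,
            frame_period=config.frame_period,
            odor_onset_frame=config.odor_onset_frame,
            odor_duration_frames=config.odor_duration_frames,
        )
    return out, truth


def render_movie(
    traces: GlomerularTraces,
    truth: GroundTruth,
    config: SynthConfig,
    b340: float = 1000.0,
    b380: float = 1000.0,
    alpha: float = 1.0,
    beta: float = 1.0,
    read_noise_sd: float = 0.0,
    drift: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    anatomy: Optional[np.ndarray] = None,
) -> DualWavelengthMovie:
    """Render glomerular traces into a dual-wavelength pixel movie.

    Within glomerulus k: ``F340 = b340 * (1 + alpha * ΔR_k(t))`` and
    ``F380 = b380 * (1 - beta * ΔR_k(t))`` — calcium raises the 340 nm and
    lowers the 380 nm signal, the FURA signature.  Background pixels carry
    the baselines only.  Both channels are additionally scaled by a static
    ``anatomy`` image (default: dye-loaded glomerular tissue 30% brighter
    than background), mimicking the spatial structure of real resting
    fluorescence; the factor is common to both channels, so it cancels in
    the 340/380 ratio.  Optional per-frame integer drift (periodic
    translation) supports registration testing; optional Gaussian read
    noise is added per pixel after the drift.
    """
    n_rois = int(truth.roi_labels.max(initial=0))
    if n_rois != traces.n_glomeruli:
        raise ValueError(
            f"label image has {n_rois} glomeruli but traces have "
            f"{traces.n_glomeruli}"
        )
    if b340 <= 0 or b380 <= 0:
        raise ValueError("channel baselines must be positive")
    max_dr = float(np.max(traces.values, initial=0.0))
    if beta * max_dr >= 1.0:
        raise ValueError(
            f"beta * max ΔR = {beta * max_dr:.3f} >= 1 would drive "
            "F380 non-positive"
        )
    t_frames, (h, w) = traces.n_frames, truth.roi_labels.shape
    if anatomy is None:
        anatomy = 1.0 + 0.3 * (truth.roi_labels > 0)
    else:
        anatomy = np.asarray(anatomy, dtype=float)
        if anatomy.shape != (h, w) or np.min(anatomy) <= 0:
            raise ValueError("anatomy must be a positive (H, W) image")
    dr = np.zeros((t_frames, h, w))
    for k in range(1, n_rois + 1):
        dr[:, truth.roi_labels == k] = traces.values[k - 1][:, None]
    f340 = anatomy[None] * b340 * (1.0 + alpha * dr)
    f380 = anatomy[None] * b380 * (1.0 - beta * dr)
    if drift is not None:
        drift = np.asarray(drift, dtype=int)
        if drift.shape != (t_frames, 2):
            raise ValueError("drift must be an (n_frames, 2) integer table")
        for t in range(t_frames):
            dy, dx = int(drift[t, 0]), int(drift[t, 1])
            if dy or dx:
                f340[t] = np.roll(f340[t], (dy, dx), axis=(0, 1))
                f380[t] = np.roll(f380[t], (dy, dx), axis=(0, 1))
    if read_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        f340 = f340 + rng.normal(0.0, read_noise_sd, f340.shape)
        f380 = f380 + rng.normal(0.0, read_noise_sd, f380.shape)
        if np.min(f380) <= 0:
            raise ValueError("read noise drove F380 non-positive")
    return DualWavelengthMovie(
        f340=f340,
        f380=f380,
        frame_period=traces.frame_period,
        odor_onset_frame=traces.odor_onset_frame,
        odor_duration_frames=traces.odor_duration_frames,
        stimulus_label=traces.stimulus_label,
    )


def invert_ratio_movie(
    rm,
    b340: float = 1000.0,
    b380: float = 1000.0,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> np.ndarray:
    """Exact inverse of the rendering model on a baseline-normalized ratio movie.

    With ``q = F340/F380 * b380/b340 = (1 + alpha ΔR)/(1 - beta ΔR)`` the
    planted signal is ``ΔR = (q - 1)/(alpha + beta q)``.  The ratio movie
    stores ``F340/F380`` minus its pre-odor baseline (``b340/b380`` on
    noise-free data), which is added back before inverting.  Used by
    recovery tests to check the preprocessing chain to floating-point
    accuracy.
    """
    raw_ratio = rm.delta_r + b340 / b380
    q = raw_ratio * (b380 / b340)
    return (q - 1.0) / (alpha + beta * q)


def generate_spikes(
    config: SynthConfig,
    group: str,
    treatment: str,
    stimulus: str,
    bee_id: int = 0,
    odor_rate: Optional[float] = None,
    baseline_rate: Optional[float] = None,
) -> M17Record:
    """Homogeneous-Poisson M17 spikes: 5 s baseline, then the odor window.

    Default rates reproduce the study's readout: trained solvent bees fire
    near 7 Hz to the CS+ and near 1 Hz to mineral oil; the inhibitor arm
    generalizes more to the new odor and extinguishes more slowly.
    """
    validate_stimulus(stimulus)
    _cell_index(group, treatment)
    if odor_rate is None:
        odor_rate = DEFAULT_M17_ODOR_RATES[(group, treatment)][stimulus]
    if baseline_rate is None:
        baseline_rate = M17_BASELINE_RATE
    if odor_rate < 0 or baseline_rate < 0:
        raise ValueError("spike rates must be non-negative")
    rng = _rng(config, group, treatment, bee_id,
               _STREAM_SPIKES + STIMULI.index(stimulus))
    baseline_window = (0.0, 5.0)
    odor_window = (5.0, 5.0 + config.odor_duration)
    times = []
    for (t0, t1), rate in ((baseline_window, baseline_rate),
                           (odor_window, odor_rate)):
        n = rng.poisson(rate * (t1 - t0))
        times.append(np.sort(rng.uniform(t0, t1, n)))
    return M17Record(
        spike_times=np.concatenate(times),
        baseline_window=baseline_window,
        odor_window=odor_window,
        stimulus_label=stimulus,
        group=group,
        treatment=treatment,
        bee_id=bee_id,
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def iter_cohort(
    config: SynthConfig,
    stimuli: Optional[Sequence[str]] = None,
) -> Iterator[Tuple[str, str, str, int, Dict[str, GlomerularTraces],
                    GroundTruth]]:
    """Yield ``(bee_uid, group, treatment, bee_id, traces, truth)`` per bee."""
    for group in GROUPS:
        for treatment in TREATMENTS:
            for i in range(config.cell_size(group, treatment)):
                traces, truth = generate_traces(config, i, group, treatment,
                                                stimuli=stimuli)
                uid = f"{group}_{treatment}_{i:02d}"
                yield uid, group, treatment, i, traces, truth


def cohort_traces_frame(
    config: SynthConfig,
    stimuli: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Long-format trace table: bee, group, treatment, stimulus, glomerulus, frame, value."""
    chunks = []
    for uid, group, treatment, _i, traces, _truth in iter_cohort(
            config, stimuli):
        for stim, tr in traces.items():
            n_g, n_f = tr.values.shape
            chunks.append(pd.DataFrame({
                "bee": uid,
                "group": group,
                "treatment": treatment,
                "stimulus": stim,
                "glomerulus": np.repeat(np.arange(1, n_g + 1), n_f),
                "frame": np.tile(np.arange(n_f), n_g),
                "value": tr.values.ravel(),
            }))
    return pd.concat(chunks, ignore_index=True)


def cohort_spikes_frame(config: SynthConfig) -> pd.DataFrame:
    """Long-format spike table: bee, group, treatment, stimulus, spike_time_s."""
    rows = []
    for group in GROUPS:
        for treatment in TREATMENTS:
            for i in range(config.cell_size(group, treatment)):
                uid = f"{group}_{treatment}_{i:02d}"
                for stim in STIMULI:
                    rec = generate_spikes(config, group, treatment, stim,
                                          bee_id=i)
                    for t in rec.spike_times:
                        rows.append((uid, group, treatment, stim, float(t)))
    return pd.DataFrame(
        rows, columns=["bee", "group", "treatment", "stimulus",
                       "spike_time_s"])


# ---------------------------------------------------------------------------
# effect planting
# ---------------------------------------------------------------------------


def _early_separation_sample(config: SynthConfig, group: str, treatment: str,
                             n_bees: int, id_offset: int) -> np.ndarray:
    from .metrics import distance_trace, early_separation

    vals = np.empty(n_bees)
    for i in range(n_bees):
        traces, _ = generate_traces(config, id_offset + i, group, treatment,
                                    stimuli=("cs_plus", "new"))
        dt = distance_trace(traces["cs_plus"], traces["new"])
        vals[i] = early_separation(dt)
    return vals


def plant_early_separation_effect(
    config: SynthConfig,
    target_d: float = 1.408,
    n_solvent: int = 6000,
    n_refine: int = 3000,
    id_offset: int = 100_000,
    arm_weights: Tuple[int, int] = (7, 10),
) -> float:
    """Return the ``separation_lag`` that plants a given effect size.

    The treatment effect on early-window pattern separation is the
    difference in mean ``early_separation`` between the solvent and
    inhibitor arms of the paired group, expressed as Cohen's d against the
    pooled between-bee SD (pooled with the study's arm sizes via
    ``arm_weights``).  Because the metric depends on the temporal kernel,
    ramp, noise and between-bee heterogeneity jointly, the mapping
    lag → d is inverted by Monte Carlo: with the knob
    ``u = 1 − 1/lag`` (u = 0 is exactly no effect), d(u) is close to
    proportional, so two proportional fixed-point corrections with fresh
    simulation samples land within sampling error of the target.  The
    returned lag is then used via ``replace(config, separation_lag=lag)``.
    """
    if target_d <= 0:
        raise ValueError("target_d must be positive")
    solvent = _early_separation_sample(config, "paired", "solvent",
                                       n_solvent, id_offset)
    mu_s, var_s = solvent.mean(), solvent.var(ddof=1)
    w1, w2 = (arm_weights[0] - 1.0), (arm_weights[1] - 1.0)

    def d_of(u: float, offset: int) -> float:
        cfg = replace(config, separation_lag=1.0 / (1.0 - u))
        inhib = _early_separation_sample(cfg, "paired", "inhibitor",
                                         n_refine, offset)
        pooled = math.sqrt((w1 * var_s + w2 * inhib.var(ddof=1))
                           / (w1 + w2))
        return (mu_s - inhib.mean()) / pooled

    u = 0.15
    for step in range(1, 4):
        d_hat = d_of(u, id_offset + step * n_solvent)
        if d_hat <= 0:
            raise ValueError("planted effect not positive; noise dominates")
        u = u * target_d / d_hat
        if u >= 0.95:
            raise ValueError("target effect size unreachable at lag <= 20")
    return 1.0 / (1.0 - u)
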