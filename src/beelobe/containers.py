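"""Shared data containers for the antennal-lobe imaging/ephys pipeline.

Every stage of the pipeline exchanges one of the small dataclasses below:
raw dual-wavelength FURA movies, baseline-normalized ratio movies, glomerular
ROI maps, per-glomerulus time courses, and M17 spike records.  They are thin
wrappers around numpy arrays that validate the invariants the analysis relies
on (shape consistency, timing sanity, sortedness) at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

#: Experimental groups: CS-US overlap (associative learning) vs 5-minute gap
#: (stimulation control).
GROUPS = ("paired", "unpaired")

#: Pharmacological arms: Dnmt inhibitor (RG108) vs solvent (DMF).
TREATMENTS = ("inhibitor", "solvent")

#: Stimulus panel of the memory test followed by six extinction trials.
EXTINCTION_STIMULI = tuple(f"ext{j}" for j in range(1, 7))
STIMULI = ("cs_plus", "new", "mineral_oil", "mixture") + EXTINCTION_STIMULI


def validate_group(group: str) -> None:
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")


def validate_treatment(treatment: str) -> None:
    if treatment not in TREATMENTS:
        raise ValueError(
            f"unknown treatment {treatment!r}; expected one of {TREATMENTS}"
        )


def validate_stimulus(stimulus: str) -> None:
    if stimulus not in STIMULI:
        raise ValueError(
            f"unknown stimulus {stimulus!r}; expected one of {STIMULI}"
        )


@dataclass
class DualWavelengthMovie:
    """Raw two-channel FURA recording of one stimulus presentation.

    ``f340``/``f380`` are ``(n_frames, H, W)`` stacks recorded at 340 nm and
    380 nm excitation; one double frame covers ``frame_period`` seconds.
    ``valid_mask`` marks pixels whose time series is trustworthy in every
    frame (registration marks wrap-around edges invalid).
    """

    f340: np.ndarray
    f380: np.ndarray
    frame_period: float
    odor_onset_frame: int
    odor_duration_frames: int
    stimulus_label: str
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        if self.f340.ndim != 3:
            raise ValueError("f340/f380 must be (n_frames, H, W) stacks")
        if self.f340.shape != self.f380.shape:
            raise ValueError(
                f"wavelength stacks differ in shape: {self.f340.shape} vs "
                f"{self.f380.shape}"
            )
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if not 0 <= self.odor_onset_frame < self.n_frames:
            raise ValueError(
                f"odor_onset_frame {self.odor_onset_frame} outside "
                f"[0, {self.n_frames})"
            )
        if self.odor_duration_frames < 0:
            raise ValueError("odor_duration_frames must be >= 0")
        validate_stimulus(self.stimulus_label)
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.image_shape:
                raise ValueError("valid_mask must match the image shape")

    @property
    def n_frames(self) -> int:
        return self.f340.shape[0]

    @property
    def image_shape(self) -> Tuple[int, int]:
        return self.f340.shape[1:]


@dataclass
class RatioMovie:
    """Baseline-subtracted 340/380 ratio movie (dimensionless ΔR).

    ``delta_r[t, y, x]`` is the ratio at frame ``t`` minus the pixel's mean
    ratio over ``baseline_frames`` (the pre-odor frames used for
    normalization), so the per-pixel baseline average is ~0 by construction.
    """

    delta_r: np.ndarray
    baseline_frames: Tuple[int, int]
    frame_period: float
    odor_onset_frame: int
    odor_duration_frames: int
    stimulus_label: str
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.delta_r = np.asarray(self.delta_r, dtype=float)
        if self.delta_r.ndim != 3:
            raise ValueError("delta_r must be (n_frames, H, W)")
        b0, b1 = self.baseline_frames
        if not (0 <= b0 < b1 <= self.n_frames):
            raise ValueError(f"invalid baseline_frames {self.baseline_frames}")
        validate_stimulus(self.stimulus_label)

    @property
    def n_frames(self) -> int:
        return self.delta_r.shape[0]

    @property
    def image_shape(self) -> Tuple[int, int]:
        return self.delta_r.shape[1:]


@dataclass
class GlomerulusMap:
    """Labeled ROI image: 0 = background, k >= 1 = glomerulus k."""

    labels: np.ndarray
    min_size: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        present = np.unique(self.labels)
        present = present[present > 0]
        expected = np.arange(1, len(present) + 1)
        if not np.array_equal(present, expected):
            raise ValueError(
                "glomerulus labels must be contiguous 1..n; got "
                f"{present.tolist()}"
            )

    @property
    def n_glomeruli(self) -> int:
        return int(self.labels.max(initial=0))

    def pixels(self, k: int) -> np.ndarray:
        """Boolean mask of glomerulus ``k``."""
        if not 1 <= k <= self.n_glomeruli:
            raise ValueError(f"no glomerulus {k}")
        return self.labels == k


@dataclass
class GlomerularTraces:
    """Per-glomerulus ΔR time courses for one stimulus presentation.

    ``values`` is ``(n_glomeruli, n_frames)``; row k is the pixel-averaged
    baseline-normalized ratio of glomerulus k.
    """

    values: np.ndarray
    stimulus_label: str
    frame_period: float
    odor_onset_frame: int
    odor_duration_frames: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_glomeruli, n_frames)")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one glomerulus")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("traces contain missing/non-finite frames")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if not 0 <= self.odor_onset_frame < self.n_frames:
            raise ValueError("odor onset outside the recording")
        validate_stimulus(self.stimulus_label)

    @property
    def n_glomeruli(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def odor_frames(self) -> np.ndarray:
        """Absolute frame indices of the odor window."""
        stop = min(self.odor_onset_frame + self.odor_duration_frames,
                   self.n_frames)
        return np.arange(self.odor_onset_frame, stop)

    def compatible_with(self, other: "GlomerularTraces") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.frame_period == other.frame_period
            and self.odor_onset_frame == other.odor_onset_frame
        )


@dataclass
class M17Record:
    """Spike times of the proboscis muscle M17 for one odor presentation.

    Windows follow the recording protocol: spike rate is measured for 5 s
    before the stimulus (baseline) and during the 4 s odor presentation.
    """

    spike_times: np.ndarray
    baseline_window: Tuple[float, float]
    odor_window: Tuple[float, float]
    stimulus_label: str
    group: str
    treatment: str
    bee_id: int = 0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be sorted")
        b0, b1 = self.baseline_window
        o0, o1 = self.odor_window
        if not (b0 < b1 and o0 < o1):
            raise ValueError("windows must have positive duration")
        if max(b0, o0) < min(b1, o1):
            raise ValueError("baseline and odor windows overlap")
        lo = min(b0, o0)
        hi = max(b1, o1)
        if self.spike_times.size and (
            self.spike_times[0] < lo or self.spike_times[-1] > hi
        ):
            raise ValueError("spikes outside the trial bounds")
        validate_stimulus(self.stimulus_label)
        validate_group(self.group)
        validate_treatment(self.treatment)

    def count_in(self, window: Tuple[float, float]) -> int:
        t0, t1 = window
        return int(np.sum((self.spike_times >= t0) & (self.spike_times < t1)))
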