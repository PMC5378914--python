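"""Raw-movie preprocessing: movement correction, ratio and baseline.

FURA-2 is a ratiometric calcium indicator: a calcium rise increases the
fluorescence excited at 340 nm and decreases that excited at 380 nm, so the
340/380 ratio tracks intracellular calcium independent of dye concentration.
The preprocessing chain is register → ratio → baseline-subtract:

1. rigid movement correction of each frame against a reference frame
   (FFT phase cross-correlation), applied identically to both channels;
2. per-pixel ratio F340/F380;
3. subtraction of the per-pixel mean ratio over the first ``n_baseline``
   pre-odor frames (default 40, i.e. the 3.2 s before a 4 s odor onset at
   12.5 Hz double-frame rate).
"""

from __future__ import annotations

import warnings
from typing import List, Sequence, Tuple

import numpy as np
from skimage.registration import phase_cross_correlation
from scipy import ndimage

from .containers import DualWavelengthMovie, RatioMovie

__all__ = [
    "frame_of_time",
    "time_of_frame",
    "window_frames",
    "register",
    "register_between",
    "compute_ratio",
]


# ---------------------------------------------------------------------------
# Frame/time coordinate model
# ---------------------------------------------------------------------------
#
# Frame i covers the half-open interval [i*dt, (i+1)*dt).  With the standard
# 80 ms double frame, odor onset at 4 s is frame 50, and the early analysis
# window "81-160 ms after onset" is exactly post-onset frame 1 (covering
# (80, 160] ms).

_EPS = 1e-9


def frame_of_time(t: float, frame_period: float, n_frames: int) -> int:
    """Frame index whose interval contains time ``t`` (seconds).

    ``t == n_frames * frame_period`` (the recording end) maps to the last
    frame.
    """
    total = n_frames * frame_period
    if t < -_EPS or t > total + _EPS:
        raise ValueError(f"time {t} s outside recording [0, {total}] s")
    i = int(np.floor((t + _EPS) / frame_period))
    return min(max(i, 0), n_frames - 1)


def time_of_frame(i: int, frame_period: float, n_frames: int) -> float:
    """Start time (seconds) of frame ``i``."""
    if not 0 <= i < n_frames:
        raise ValueError(f"frame {i} outside [0, {n_frames})")
    return i * frame_period


def window_frames(start_ms: float, end_ms: float,
                  frame_period: float) -> np.ndarray:
    """Post-onset frame offsets fully covering the interval ``(start, end]`` ms.

    A frame offset j (0 = the frame in which the odor arrives) covers
    ``(j*dt, (j+1)*dt]`` ms after onset; the window keeps the frames whose
    interval lies inside ``(start_ms, end_ms]``.  At 80 ms frames the
    81-160 ms window is offset {1}; at 40 ms frames it is {2, 3}.
    """
    if end_ms <= start_ms:
        raise ValueError("window end must exceed start")
    dt_ms = frame_period * 1000.0
    j0 = int(np.ceil(start_ms / dt_ms - _EPS))
    j1 = int(np.floor(end_ms / dt_ms + _EPS)) - 1
    if j1 < j0:
        raise ValueError(
            f"window ({start_ms}, {end_ms}] ms contains no whole "
            f"{dt_ms:g} ms frame"
        )
    return np.arange(j0, j1 + 1)


# ---------------------------------------------------------------------------
# Movement correction
# ---------------------------------------------------------------------------


def _reference_image(movie: DualWavelengthMovie,
                     reference_frame: int | None) -> np.ndarray:
    both = movie.f340 + movie.f380
    if reference_frame is not None:
        if not 0 <= reference_frame < movie.n_frames:
            raise ValueError("reference_frame outside the movie")
        return both[reference_frame]
    # median image over the pre-odor baseline: robust to transient signal
    stop = max(movie.odor_onset_frame, 1)
    return np.median(both[:stop], axis=0)


def _shift_frame(img: np.ndarray, shift: Tuple[float, float],
                 subpixel: bool) -> np.ndarray:
    if not subpixel:
        return np.roll(img, (int(shift[0]), int(shift[1])), axis=(0, 1))
    return ndimage.shift(img, shift, order=1, mode="grid-wrap")


def register(
    movie: DualWavelengthMovie,
    reference_frame: int | None = None,
    subpixel: bool = False,
) -> Tuple[DualWavelengthMovie, List[Tuple[float, float]]]:
    """Rigidly align every frame to a reference frame.

    The shift of each frame is estimated by FFT phase cross-correlation on
    the summed channels and the same translation is applied to both
    wavelength stacks (the two channels are acquired quasi-simultaneously
    and share the motion).  Translation is periodic (wrap-around); pixels
    that wrapped in any frame are flagged invalid in ``valid_mask``.

    Returns the registered movie and the per-frame applied shifts
    ``(dy, dx)`` — a movie drifting by (+2, 0) px yields shifts (-2, 0).
    """
    ref = _reference_image(movie, reference_frame)
    upsample = 10 if subpixel else 1
    n = movie.n_frames
    f340 = np.empty_like(movie.f340)
    f380 = np.empty_like(movie.f380)
    shifts: List[Tuple[float, float]] = []
    h, w = movie.image_shape
    valid = np.ones((h, w), dtype=bool)
    if movie.valid_mask is not None:
        valid &= movie.valid_mask
    for t in range(n):
        frame = movie.f340[t] + movie.f380[t]
        if not np.any(frame) or not np.any(ref):
            warnings.warn(
                f"all-zero frame {t}: correlation undefined, shift set to 0",
                stacklevel=2,
            )
            sh = (0.0, 0.0)
        else:
            est = phase_cross_correlation(
                ref, frame, upsample_factor=upsample, normalization=None
            )[0]
            sh = (float(est[0]), float(est[1]))
            if not subpixel:
                sh = (float(np.round(sh[0])), float(np.round(sh[1])))
        f340[t] = _shift_frame(movie.f340[t], sh, subpixel)
        f380[t] = _shift_frame(movie.f380[t], sh, subpixel)
        shifts.append(sh)
        dy, dx = int(np.ceil(abs(sh[0]))), int(np.ceil(abs(sh[1])))
        if dy:
            rows = np.arange(dy) if sh[0] > 0 else np.arange(h - dy, h)
            valid[rows, :] = False
        if dx:
            cols = np.arange(dx) if sh[1] > 0 else np.arange(w - dx, w)
            valid[:, cols] = False
    out = DualWavelengthMovie(
        f340=f340,
        f380=f380,
        frame_period=movie.frame_period,
        odor_onset_frame=movie.odor_onset_frame,
        odor_duration_frames=movie.odor_duration_frames,
        stimulus_label=movie.stimulus_label,
        valid_mask=valid,
    )
    return out, shifts


def register_between(
    movies: Sequence[DualWavelengthMovie],
    subpixel: bool = False,
) -> Tuple[List[DualWavelengthMovie], List[Tuple[float, float]]]:
    """Align each stimulus movie to the first one (between-video correction).

    Within-video registration aligns frames of one presentation; this pass
    removes the slower drift between presentations by aligning each movie's
    baseline reference image to that of the first movie, shifting all frames
    of the movie by one common translation.
    """
    if not movies:
        raise ValueError("need at least one movie")
    ref = _reference_image(movies[0], None)
    out: List[DualWavelengthMovie] = []
    shifts: List[Tuple[float, float]] = []
    upsample = 10 if subpixel else 1
    for m in movies:
        img = _reference_image(m, None)
        if not np.any(img) or not np.any(ref):
            sh = (0.0, 0.0)
        else:
            est = phase_cross_correlation(
                ref, img, upsample_factor=upsample, normalization=None
            )[0]
            sh = (float(est[0]), float(est[1]))
            if not subpixel:
                sh = (float(np.round(sh[0])), float(np.round(sh[1])))
        f340 = np.stack([_shift_frame(f, sh, subpixel) for f in m.f340])
        f380 = np.stack([_shift_frame(f, sh, subpixel) for f in m.f380])
        out.append(
            DualWavelengthMovie(
                f340=f340,
                f380=f380,
                frame_period=m.frame_period,
                odor_onset_frame=m.odor_onset_frame,
                odor_duration_frames=m.odor_duration_frames,
                stimulus_label=m.stimulus_label,
                valid_mask=m.valid_mask,
            )
        )
        shifts.append(sh)
    return out, shifts


# ---------------------------------------------------------------------------
# Ratio and baseline normalization
# ---------------------------------------------------------------------------


def compute_ratio(
    movie: DualWavelengthMovie, n_baseline_frames: int = 40
) -> RatioMovie:
    """F340/F380 ratio, normalized by the mean ratio of the first pre-odor frames.

    ``delta_r(t, p) = f340(t, p)/f380(t, p) - mean_{t' < n_baseline}
    f340(t', p)/f380(t', p)``.  The baseline window must end before odor
    onset, and the 380 nm channel must be strictly positive everywhere a
    ratio is formed — a zero there indicates data outside the tissue, which
    is a hard error rather than something to clip silently.
    """
    if n_baseline_frames < 1:
        raise ValueError("need at least one baseline frame")
    if n_baseline_frames > movie.odor_onset_frame:
        raise ValueError(
            f"baseline of {n_baseline_frames} frames extends past odor onset "
            f"(frame {movie.odor_onset_frame}); baseline must precede odor"
        )
    bad = movie.f380 <= 0
    if movie.valid_mask is not None:
        bad &= movie.valid_mask[None, :, :]
    if np.any(bad):
        t, y, x = (int(v[0]) for v in np.nonzero(bad))
        raise ValueError(
            "f380 is non-positive where a ratio is required, e.g. frame "
            f"{t}, pixel ({y}, {x})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = movie.f340 / movie.f380
    if movie.valid_mask is not None:
        ratio[:, ~movie.valid_mask] = 0.0
    baseline = ratio[:n_baseline_frames].mean(axis=0)
    return RatioMovie(
        delta_r=ratio - baseline[None, :, :],
        baseline_frames=(0, n_baseline_frames),
        frame_period=movie.frame_period,
        odor_onset_frame=movie.odor_onset_frame,
        odor_duration_frames=movie.odor_duration_frames,
        stimulus_label=movie.stimulus_label,
        valid_mask=movie.valid_mask,
    )
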