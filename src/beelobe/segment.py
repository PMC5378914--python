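"""Glomerular ROI detection and trace extraction.

Glomeruli are found from the processed ratio movies of all stimulus
presentations jointly: each pixel's concatenated time series is Z-scored,
frames are spatially smoothed, the pixels x time matrix is reduced by PCA,
and a convex-cone factorization is run in PCA space.  The cone step
exploits the fact that each glomerulus imposes one characteristic time
course on its pixels: "pure" pixels of different glomeruli sit at extreme
rays of the cone spanned by all pixel loadings.  Generators (extreme
pixels) are selected greedily by maximal residual norm after projecting
out the span of those already chosen; every pixel is then assigned to the
generator carrying its largest non-negative least-squares coefficient,
provided that coefficient is a substantial fraction of the generator's
self-coefficient.  Connected components smaller than ``min_size`` are
discarded and the survivors relabeled 1..n.

A user-supplied label image can bypass detection entirely (manual ROIs on
real data), in which case only :func:`extract_traces` is needed.
"""

from __future__ import annotations

import warnings
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize
from skimage import measure
from sklearn.decomposition import PCA

from .containers import GlomerularTraces, GlomerulusMap, RatioMovie

__all__ = ["detect_glomeruli", "extract_traces", "match_maps"]


def _zscore_pixels(data: np.ndarray) -> np.ndarray:
    """Per-pixel Z-score across time; constant pixels map to zero."""
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    out = data - mean[None]
    nz = sd > 1e-12
    out[:, nz] = out[:, nz] / sd[None, nz]
    out[:, ~nz] = 0.0
    return out


def _select_generators(
    loadings: np.ndarray,
    max_generators: int,
    stop_frac: float,
) -> List[int]:
    """Greedy extreme-ray selection by maximal residual norm.

    After each pick, the span of the chosen loading vectors is projected
    out (Gram-Schmidt); selection stops when the largest residual norm
    falls below ``stop_frac`` times the initial maximum.
    """
    residual = loadings.copy()
    norms = np.linalg.norm(residual, axis=1)
    initial = norms.max()
    if initial <= 0:
        return []
    basis: List[np.ndarray] = []
    chosen: List[int] = []
    for _ in range(max_generators):
        norms = np.linalg.norm(residual, axis=1)
        i = int(np.argmax(norms))
        if norms[i] < stop_frac * initial:
            break
        chosen.append(i)
        v = residual[i].copy()
        v /= np.linalg.norm(v)
        basis.append(v)
        residual = residual - np.outer(residual @ v, v)
    return chosen


def detect_glomeruli(
    movies: Sequence[RatioMovie],
    k_components: int = 30,
    sigma: float = 2.0,
    min_size: int = 20,
    max_generators: int = 40,
    assign_threshold: float = 0.5,
    stop_frac: float = 0.2,
    min_coherence: float = 0.3,
) -> GlomerulusMap:
    """Identify glomerular ROIs from co-registered ratio movies.

    Parameters
    ----------
    movies
        Co-registered, same-shape ratio movies; their time axes are
        concatenated so one map serves every stimulus.
    k_components
        PCA components retained (must not exceed the data rank bound
        ``min(n_pixels, total frames)``).
    sigma
        Spatial Gaussian smoothing in pixels; 0 disables smoothing (useful
        on noise-free data, where smoothing only blurs ROI borders).
    min_size
        Minimum ROI size in pixels after connected-component cleanup.
    assign_threshold
        Pixel joins a generator's ROI only if its coefficient reaches this
        fraction of the generator's self-coefficient.
    min_coherence
        Candidate pixels must retain at least this time-series SD after
        smoothing.  Z-scoring gives every pixel unit variance, but spatial
        smoothing collapses incoherent (noise-only) pixels to SD
        ~1/(2 sigma sqrt(pi)) while spatially coherent glomerular pixels
        keep SD near 1 — so 0.3 separates tissue from background without
        any free scale.
    """
    if not movies:
        raise ValueError("need at least one movie")
    shape = movies[0].image_shape
    for m in movies:
        if m.image_shape != shape:
            raise ValueError("movies must share a spatial shape")
    data = np.concatenate([m.delta_r for m in movies], axis=0)
    n_t = data.shape[0]
    n_pix = shape[0] * shape[1]
    if k_components > min(n_pix, n_t):
        raise ValueError(
            f"k_components={k_components} exceeds the data rank bound "
            f"{min(n_pix, n_t)}"
        )
    valid = np.ones(shape, dtype=bool)
    for m in movies:
        if m.valid_mask is not None:
            valid &= m.valid_mask
    data = data.reshape(n_t, n_pix)
    data = _zscore_pixels(data)
    if sigma > 0:
        data = data.reshape(n_t, *shape)
        for t in range(n_t):
            data[t] = ndimage.gaussian_filter(data[t], sigma)
        data = data.reshape(n_t, n_pix)
    data[:, ~valid.ravel()] = 0.0
    coherent = data.std(axis=0) >= min_coherence
    if not np.any(coherent):
        warnings.warn("no coherent pixels above the noise floor; "
                      "returning an empty map", stacklevel=2)
        return GlomerulusMap(labels=np.zeros(shape, dtype=np.uint16),
                             min_size=min_size)
    data[:, ~coherent] = 0.0

    pca = PCA(n_components=k_components, svd_solver="randomized",
              random_state=0)
    loadings = pca.fit_transform(data.T)       # (n_pixels, k)

    chosen = _select_generators(loadings, max_generators, stop_frac)
    if not chosen:
        warnings.warn("no cone generators found; returning an empty map",
                      stacklevel=2)
        return GlomerulusMap(labels=np.zeros(shape, dtype=np.uint16),
                             min_size=min_size)
    gen = loadings[chosen].T                   # (k, m)
    m = gen.shape[1]
    self_coef = np.empty(m)
    for g in range(m):
        self_coef[g] = optimize.nnls(gen, gen[:, g])[0][g]
    self_coef[self_coef <= 0] = 1.0

    norms = np.linalg.norm(loadings, axis=1)
    floor = 0.05 * np.linalg.norm(gen, axis=0).min()
    assign = np.zeros(n_pix, dtype=np.int32)   # 0 = background
    candidates = np.nonzero((norms >= floor) & valid.ravel() & coherent)[0]
    for p in candidates:
        coef, _ = optimize.nnls(gen, loadings[p])
        g = int(np.argmax(coef))
        if coef[g] >= assign_threshold * self_coef[g]:
            assign[p] = g + 1
    assign = assign.reshape(shape)

    labels = np.zeros(shape, dtype=np.uint16)
    next_label = 1
    for g in range(1, m + 1):
        comp = measure.label(assign == g, connectivity=1)
        for region in measure.regionprops(comp):
            if region.area >= min_size:
                labels[comp == region.label] = next_label
                next_label += 1
    if next_label == 1:
        warnings.warn("no component survived the size threshold",
                      stacklevel=2)
    return GlomerulusMap(labels=labels, min_size=min_size)


def extract_traces(glomap: GlomerulusMap, movie: RatioMovie,
                   ) -> GlomerularTraces:
    """Per-glomerulus time course: unweighted pixel mean within each ROI."""
    if glomap.labels.shape != movie.image_shape:
        raise ValueError(
            f"map shape {glomap.labels.shape} does not match movie "
            f"{movie.image_shape}"
        )
    n = glomap.n_glomeruli
    if n < 1:
        raise ValueError("empty glomerulus map")
    flat = movie.delta_r.reshape(movie.n_frames, -1)
    labels = glomap.labels.ravel()
    values = np.empty((n, movie.n_frames))
    for k in range(1, n + 1):
        idx = np.nonzero(labels == k)[0]
        if idx.size == 0:
            raise ValueError(f"glomerulus {k} has no pixels")
        values[k - 1] = flat[:, idx].mean(axis=1)
    return GlomerularTraces(
        values=values,
        stimulus_label=movie.stimulus_label,
        frame_period=movie.frame_period,
        odor_onset_frame=movie.odor_onset_frame,
        odor_duration_frames=movie.odor_duration_frames,
    )


def match_maps(detected: np.ndarray, truth: np.ndarray,
               ) -> Tuple[np.ndarray, dict]:
    """Match detected ROIs to ground-truth ROIs by maximal Jaccard overlap.

    Returns the per-truth-ROI Jaccard scores (0 for unmatched) and the
    mapping ``{truth_label: detected_label}``.  Matching is one-to-one via
    the Hungarian algorithm on the pairwise Jaccard matrix.
    """
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.shape != truth.shape:
        raise ValueError("label images must share a shape")
    n_d = int(detected.max(initial=0))
    n_t = int(truth.max(initial=0))
    scores = np.zeros(n_t)
    if n_d == 0 or n_t == 0:
        return scores, {}
    jac = np.zeros((n_t, n_d))
    for i in range(1, n_t + 1):
        ti = truth == i
        for j in range(1, n_d + 1):
            dj = detected == j
            inter = np.logical_and(ti, dj).sum()
            if inter:
                union = np.logical_or(ti, dj).sum()
                jac[i - 1, j - 1] = inter / union
    rows, cols = optimize.linear_sum_assignment(-jac)
    mapping = {}
    for r, c in zip(rows, cols):
        if jac[r, c] > 0:
            scores[r] = jac[r, c]
            mapping[r + 1] = c + 1
    return scores, mapping
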