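"""Segmentation: cone-factorization recovery, trace extraction."""

import numpy as np
import pytest
from dataclasses import replace

from beelobe.containers import GlomerulusMap
from beelobe.preproc import compute_ratio
from beelobe.segment import detect_glomeruli, extract_traces, match_maps
from beelobe.synth import SynthConfig, generate_traces, render_movie

from conftest import make_ratio_movie


def bee_ratio_movies(cfg, stimuli=("cs_plus", "new", "mixture"),
                     read_noise_sd=0.0, seed=1):
    traces, truth = generate_traces(cfg, 0, "paired", "solvent",
                                    stimuli=stimuli)
    rng = np.random.default_rng(seed)
    movies = [
        compute_ratio(render_movie(traces[s], truth, cfg,
                                   read_noise_sd=read_noise_sd, rng=rng),
                      n_baseline_frames=40)
        for s in stimuli
    ]
    return traces, truth, movies


@pytest.fixture
def three_glom_config():
    return SynthConfig(seed=9, noise_sd=0.0, bee_gain_sd=0.0,
                       n_glomeruli=3, image_shape=(60, 80), n_frames=120,
                       odor_onset=3.2, odor_duration=2.4,
                       cs_responder_fraction=1.0, responder_jitter_sd=0.0)


def test_noisefree_recovery_is_exact(three_glom_config):
    """Three well-separated planted glomeruli are recovered pixel-perfect."""
    traces, truth, movies = bee_ratio_movies(three_glom_config)
    glomap = detect_glomeruli(movies, k_components=6, sigma=0.0, min_size=20)
    scores, mapping = match_maps(glomap.labels, truth.roi_labels)
    assert glomap.n_glomeruli == 3
    assert np.all(scores == 1.0)


def test_pure_noise_movie_yields_no_glomeruli():
    rng = np.random.default_rng(4)
    movie = make_ratio_movie(rng.normal(0, 1, (120, 40, 40)))
    with pytest.warns(UserWarning, match="empty map"):
        glomap = detect_glomeruli([movie], k_components=10, sigma=2.0,
                                  min_size=20)
    assert glomap.n_glomeruli == 0


def test_k_components_beyond_rank_rejected():
    rng = np.random.default_rng(4)
    movie = make_ratio_movie(rng.normal(0, 1, (30, 10, 10)), onset=10,
                             duration=10, baseline=(0, 10))
    with pytest.raises(ValueError, match="rank"):
        detect_glomeruli([movie], k_components=31)


def test_mismatched_shapes_rejected():
    rng = np.random.default_rng(4)
    a = make_ratio_movie(rng.normal(0, 1, (30, 10, 10)), onset=10,
                         duration=10, baseline=(0, 10))
    b = make_ratio_movie(rng.normal(0, 1, (30, 12, 10)), onset=10,
                         duration=10, baseline=(0, 10))
    with pytest.raises(ValueError, match="spatial shape"):
        detect_glomeruli([a, b], k_components=5)


def test_permuting_movie_order_keeps_partition(three_glom_config):
    _, truth, movies = bee_ratio_movies(three_glom_config)
    m1 = detect_glomeruli(movies, k_components=6, sigma=0.0, min_size=20)
    m2 = detect_glomeruli(movies[::-1], k_components=6, sigma=0.0,
                          min_size=20)
    parts1 = {frozenset(zip(*np.nonzero(m1.labels == k)))
              for k in range(1, m1.n_glomeruli + 1)}
    parts2 = {frozenset(zip(*np.nonzero(m2.labels == k)))
              for k in range(1, m2.n_glomeruli + 1)}
    assert parts1 == parts2


def test_recovery_degrades_monotonically_with_noise(three_glom_config):
    means = []
    for noise_sd in (0.0, 0.01, 0.02, 0.05):
        cfg = replace(three_glom_config, noise_sd=noise_sd)
        _, truth, movies = bee_ratio_movies(cfg, read_noise_sd=4.0, seed=2)
        glomap = detect_glomeruli(movies, k_components=10, sigma=1.0,
                                  min_size=20)
        scores, _ = match_maps(glomap.labels, truth.roi_labels)
        means.append(float(np.mean(scores)))
    assert all(a >= b - 0.02 for a, b in zip(means, means[1:]))


class TestExtractTraces:
    def test_mean_of_constant_pixels(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[:2, :2] = 1
        dr = np.zeros((50, 6, 6))
        dr[10, :2, :2] = 0.1
        movie = make_ratio_movie(dr, onset=20, duration=10,
                                 baseline=(0, 20))
        tr = extract_traces(GlomerulusMap(labels=labels), movie)
        assert tr.values[0, 10] == pytest.approx(0.1)
        assert tr.values[0, 11] == 0.0

    def test_noisefree_recovery(self, three_glom_config):
        traces, truth, movies = bee_ratio_movies(three_glom_config)
        tr = extract_traces(GlomerulusMap(labels=truth.roi_labels),
                            movies[0])
        # the FURA ratio is a monotone but nonlinear map of ΔR, so compare
        # through the exact inversion
        from beelobe.synth import invert_ratio_movie
        recovered = invert_ratio_movie(movies[0])
        for k in range(3):
            est = recovered[:, truth.roi_labels == k + 1].mean(axis=1)
            assert np.max(np.abs(est - traces["cs_plus"].values[k])) < 1e-9

    def test_shape_mismatch_rejected(self):
        labels = np.ones((5, 5), dtype=int)
        movie = make_ratio_movie(np.zeros((50, 6, 6)))
        with pytest.raises(ValueError, match="match"):
            extract_traces(GlomerulusMap(labels=labels), movie)

    def test_variance_shrinks_with_pixel_count(self):
        """Averaging n noise pixels divides the variance by n."""
        rng = np.random.default_rng(12)
        n_pix, sd = 25, 0.05
        labels = np.zeros((5, 5), dtype=int)
        labels[:, :] = 1
        dr = rng.normal(0, sd, (10_000, 5, 5))
        movie = make_ratio_movie(dr, onset=5000, duration=100,
                                 baseline=(0, 5000))
        tr = extract_traces(GlomerulusMap(labels=labels), movie)
        var = tr.values[0].var()
        assert var == pytest.approx(sd ** 2 / n_pix, rel=0.2)
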