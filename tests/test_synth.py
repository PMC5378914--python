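"""Generator: planted structure, determinism, rendering, Poisson spikes."""

import numpy as np
import pytest
from dataclasses import replace

from beelobe.metrics import distance_trace
from beelobe.synth import (
    SynthConfig,
    generate_spikes,
    generate_traces,
    invert_ratio_movie,
    render_movie,
)
from beelobe.preproc import compute_ratio

from conftest import SMALL


def test_mineral_oil_noisefree_is_silent(small_noisefree_config):
    traces, _ = generate_traces(small_noisefree_config, 0, "paired",
                                "solvent", stimuli=("mineral_oil",))
    assert np.all(traces["mineral_oil"].values == 0.0)


def test_planted_pattern_distance_is_exact():
    """Once the mixing ramp saturates and the kernel plateaus, the CS+/new
    distance equals the planted pattern difference norm exactly."""
    cfg = SynthConfig(seed=3, noise_sd=0.0, bee_gain_sd=0.0,
                      ramp_frames=6, **SMALL)
    traces, truth = generate_traces(cfg, 0, "paired", "solvent",
                                    stimuli=("cs_plus", "new"))
    onset = cfg.odor_onset_frame
    d = distance_trace(traces["cs_plus"], traces["new"]).d
    want = np.linalg.norm(truth.pattern_a - truth.pattern_b)
    assert d[onset + 5] == pytest.approx(want, abs=1e-12)


def test_same_seed_bitwise_identical(small_config):
    a, _ = generate_traces(small_config, 2, "unpaired", "inhibitor")
    b, _ = generate_traces(small_config, 2, "unpaired", "inhibitor")
    for stim in a:
        assert np.array_equal(a[stim].values, b[stim].values)


def test_stimulus_subset_reproduces_full_run(small_config):
    full, _ = generate_traces(small_config, 1, "paired", "solvent")
    sub, _ = generate_traces(small_config, 1, "paired", "solvent",
                             stimuli=("new", "ext3"))
    for stim in ("new", "ext3"):
        assert np.array_equal(full[stim].values, sub[stim].values)


def test_separation_lag_slows_early_distance(small_noisefree_config):
    """More ramp slowdown means strictly smaller noise-free distance at the
    second post-onset frame (the planted treatment effect)."""
    onset = small_noisefree_config.odor_onset_frame
    values = []
    for lag in (1.0, 1.5, 2.0, 4.0):
        cfg = replace(small_noisefree_config, separation_lag=lag)
        traces, _ = generate_traces(cfg, 0, "paired", "inhibitor",
                                    stimuli=("cs_plus", "new"))
        d = distance_trace(traces["cs_plus"], traces["new"]).d
        values.append(d[onset + 1])
    assert np.all(np.diff(values) < 0)


def test_mixing_ramp_and_patterns_wellformed(small_config):
    _, truth = generate_traces(small_config, 0, "paired", "inhibitor",
                               stimuli=("cs_plus",))
    assert np.all(np.diff(truth.mixing_ramp) >= 0)
    assert truth.mixing_ramp.min() == 0.0 and truth.mixing_ramp.max() == 1.0
    assert np.all(truth.pattern_a >= 0) and np.all(truth.pattern_b >= 0)
    for k in range(1, small_config.n_glomeruli + 1):
        assert np.sum(truth.roi_labels == k) >= 20


def test_unknown_labels_rejected(small_config):
    with pytest.raises(ValueError, match="unknown group"):
        generate_traces(small_config, 0, "grouped", "solvent")
    with pytest.raises(ValueError, match="unknown treatment"):
        generate_traces(small_config, 0, "paired", "rg108")


class TestRenderMovie:
    def test_zero_signal_constant_ratio(self, small_noisefree_config):
        cfg = small_noisefree_config
        traces, truth = generate_traces(cfg, 0, "paired", "solvent",
                                        stimuli=("mineral_oil",))
        movie = render_movie(traces["mineral_oil"], truth, cfg,
                             b340=1200.0, b380=800.0)
        ratio = movie.f340 / movie.f380
        assert np.allclose(ratio, 1.5, atol=1e-12)

    def test_planted_delta_r_pixel_ratio(self, small_noisefree_config):
        """ΔR = 0.1 with unit gains gives the FURA ratio 1.1/0.9."""
        cfg = small_noisefree_config
        traces, truth = generate_traces(cfg, 0, "paired", "solvent",
                                        stimuli=("cs_plus",))
        values = np.zeros_like(traces["cs_plus"].values)
        values[0, :] = 0.1
        tr = replace(traces["cs_plus"], values=values)
        movie = render_movie(tr, truth, cfg)
        in_roi = truth.roi_labels == 1
        ratio = movie.f340[0][in_roi] / movie.f380[0][in_roi]
        assert np.allclose(ratio, 1.1 / 0.9, atol=1e-12)

    def test_drift_translates_frames(self, small_noisefree_config):
        cfg = small_noisefree_config
        traces, truth = generate_traces(cfg, 0, "paired", "solvent",
                                        stimuli=("cs_plus",))
        drift = np.zeros((cfg.n_frames, 2), dtype=int)
        drift[50:] = (2, 0)
        movie = render_movie(traces["cs_plus"], truth, cfg, drift=drift)
        # frames 49/50 sit on the kernel plateau, so they differ only by
        # the planted translation
        assert np.array_equal(
            movie.f340[50], np.roll(movie.f340[49], (2, 0), axis=(0, 1)))

    def test_rejects_f380_collapse(self, small_noisefree_config):
        cfg = small_noisefree_config
        traces, truth = generate_traces(cfg, 0, "paired", "solvent",
                                        stimuli=("cs_plus",))
        values = np.full_like(traces["cs_plus"].values, 0.3)
        tr = replace(traces["cs_plus"], values=values)
        with pytest.raises(ValueError, match="F380"):
            render_movie(tr, truth, cfg, beta=4.0)

    def test_roundtrip_recovers_planted_traces(self, small_noisefree_config):
        """Render -> ratio -> invert recovers the planted ΔR to 1e-9."""
        cfg = small_noisefree_config
        traces, truth = generate_traces(cfg, 0, "paired", "solvent",
                                        stimuli=("cs_plus",))
        movie = render_movie(traces["cs_plus"], truth, cfg)
        rm = compute_ratio(movie, n_baseline_frames=40)
        recovered = invert_ratio_movie(rm)
        for k in range(cfg.n_glomeruli):
            est = recovered[:, truth.roi_labels == k + 1].mean(axis=1)
            assert np.max(np.abs(est - traces["cs_plus"].values[k])) < 1e-9


class TestSpikes:
    def test_zero_rate_zero_spikes(self, small_config):
        rec = generate_spikes(small_config, "paired", "solvent", "cs_plus",
                              odor_rate=0.0, baseline_rate=0.0)
        assert rec.spike_times.size == 0

    def test_negative_rate_rejected(self, small_config):
        with pytest.raises(ValueError, match="non-negative"):
            generate_spikes(small_config, "paired", "solvent", "cs_plus",
                            odor_rate=-1.0)

    def test_fixed_seed_reproducible(self, small_config):
        a = generate_spikes(small_config, "paired", "solvent", "new",
                            bee_id=3)
        b = generate_spikes(small_config, "paired", "solvent", "new",
                            bee_id=3)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_cs_plus_rate_matches_poisson_mean(self):
        """Trained solvent bees fire at 7 Hz during the 4 s odor: expected
        odor-window count 28, empirical mean within 3 SE over 10^4 draws."""
        cfg = SynthConfig(seed=5)
        counts = np.empty(10_000)
        for i in range(counts.size):
            rec = generate_spikes(cfg, "paired", "solvent", "cs_plus",
                                  bee_id=i)
            counts[i] = rec.count_in(rec.odor_window)
        se = np.sqrt(28.0 / counts.size)
        assert abs(counts.mean() - 28.0) < 3 * se

    def test_empirical_rate_calibration(self):
        """Poisson count distribution matches the configured rate
        (chi-square GOF at alpha = 0.01 over 10^4 draws)."""
        from scipy import stats as sps

        cfg = SynthConfig(seed=11)
        counts = np.array([
            generate_spikes(cfg, "unpaired", "solvent", "mineral_oil",
                            bee_id=i).count_in((5.0, 9.0))
            for i in range(10_000)
        ])
        lam = 1.0 * 4.0
        kmax = int(counts.max())
        observed = np.bincount(counts, minlength=kmax + 1).astype(float)
        expected = sps.poisson.pmf(np.arange(kmax + 1), lam) * counts.size
        expected[-1] += counts.size - expected.sum()  # fold the tail in
        keep = expected > 5
        chi2 = np.sum((observed[keep] - expected[keep]) ** 2
                      / expected[keep])
        p = sps.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01
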