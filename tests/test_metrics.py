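"""Response metrics: distances, distinctness, responders, dominants."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from beelobe.metrics import (
    DistanceTrace,
    bee_metrics,
    distance_trace,
    dominant_glomeruli,
    early_separation,
    extinction_stability,
    is_distinct,
    odor_period_separation,
    responsive_glomeruli,
)
from beelobe.synth import generate_traces

from conftest import make_traces


def const_distance(c, n=120, onset=40, sd=0.0, mean=None):
    return DistanceTrace(
        d=np.full(n, c), baseline_mean=c if mean is None else mean,
        baseline_sd=sd, stimuli=("cs_plus", "new"), normalized=False,
        frame_period=0.08, odor_onset_frame=onset, odor_duration_frames=30,
    )


class TestDistanceTrace:
    def test_identical_traces_zero(self):
        a = make_traces(np.random.default_rng(0).normal(0, 1, (4, 120)))
        b = replace(a, stimulus_label="new")
        assert np.all(distance_trace(a, b).d == 0.0)

    def test_pythagorean_example(self):
        a = make_traces(np.zeros((2, 120)))
        vals = np.zeros((2, 120))
        vals[0, 60], vals[1, 60] = 0.06, 0.08
        b = make_traces(vals, stimulus="new")
        dt = distance_trace(a, b)
        assert dt.d[60] == pytest.approx(0.1, abs=1e-15)
        assert dt.normalized is False

    def test_glomerulus_permutation_invariant(self):
        rng = np.random.default_rng(3)
        va = rng.normal(0, 1, (6, 120))
        vb = rng.normal(0, 1, (6, 120))
        perm = rng.permutation(6)
        d1 = distance_trace(make_traces(va),
                            make_traces(vb, stimulus="new")).d
        d2 = distance_trace(make_traces(va[perm]),
                            make_traces(vb[perm], stimulus="new")).d
        assert np.allclose(d1, d2, atol=1e-12)

    def test_normalized_divides_by_sqrt_n(self):
        rng = np.random.default_rng(3)
        a = make_traces(rng.normal(0, 1, (9, 120)))
        b = make_traces(rng.normal(0, 1, (9, 120)), stimulus="new")
        assert np.allclose(distance_trace(a, b, normalize=True).d * 3.0,
                           distance_trace(a, b).d)

    def test_mismatched_grids_rejected(self):
        a = make_traces(np.zeros((3, 120)))
        b = make_traces(np.zeros((4, 120)), stimulus="new")
        with pytest.raises(ValueError, match="not comparable"):
            distance_trace(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 10.0))
    def test_scale_covariance(self, seed, c):
        rng = np.random.default_rng(seed)
        va = rng.normal(0, 1, (5, 60))
        vb = rng.normal(0, 1, (5, 60))
        kwargs = dict(onset=20, duration=20)
        base = distance_trace(make_traces(va, **kwargs),
                              make_traces(vb, stimulus="new", **kwargs)).d
        scaled = distance_trace(
            make_traces(c * va, **kwargs),
            make_traces(c * vb, stimulus="new", **kwargs)).d
        assert np.allclose(scaled, c * base, rtol=1e-10)


class TestEarlySeparation:
    def test_constant_trace_returns_constant(self):
        assert early_separation(const_distance(0.07)) == pytest.approx(0.07)

    def test_40ms_frames_average_two(self):
        d = np.zeros(240)
        d[82], d[83] = 0.2, 0.4     # onset at frame 80, 40 ms frames
        dt = DistanceTrace(d=d, baseline_mean=0.0, baseline_sd=0.0,
                           stimuli=("cs_plus", "new"), normalized=False,
                           frame_period=0.04, odor_onset_frame=80,
                           odor_duration_frames=100)
        assert early_separation(dt) == pytest.approx(0.3)

    def test_lagged_ramp_reduces_early_separation(
            self, small_noisefree_config):
        def early(group, treatment, lag):
            cfg = replace(small_noisefree_config, separation_lag=lag)
            traces, _ = generate_traces(cfg, 0, group, treatment,
                                        stimuli=("cs_plus", "new"))
            return early_separation(
                distance_trace(traces["cs_plus"], traces["new"]))

        assert early("paired", "solvent", 2.0) > early("paired",
                                                       "inhibitor", 2.0)

    def test_window_beyond_recording_rejected(self):
        dt = const_distance(0.1, n=41, onset=40)
        with pytest.raises(ValueError, match="beyond"):
            early_separation(dt)


class TestIsDistinct:
    def test_noisefree_positive_distance_distinct(
            self, small_noisefree_config):
        traces, _ = generate_traces(small_noisefree_config, 0, "paired",
                                    "solvent", stimuli=("cs_plus", "new"))
        dt = distance_trace(traces["cs_plus"], traces["new"])
        assert dt.baseline_sd == 0.0
        assert is_distinct(dt)

    def test_subthreshold_not_distinct(self):
        d = np.full(120, 1.0)
        d[40:] = 1.0 + 2.9 * 0.1    # 2.9 SD above baseline everywhere
        dt = DistanceTrace(d=d, baseline_mean=1.0, baseline_sd=0.1,
                           stimuli=("cs_plus", "new"), normalized=False,
                           frame_period=0.08, odor_onset_frame=40,
                           odor_duration_frames=30)
        assert not is_distinct(dt)

    def test_planted_proportion(self):
        """7 of 10 noise-free bees with separable patterns -> 70%."""
        rng = np.random.default_rng(5)
        flags = []
        for i in range(10):
            va = np.zeros((4, 120))
            va[:, 40:70] = rng.uniform(0.05, 0.1, (4, 1))
            vb = va.copy()
            if i < 7:
                vb[0, 40:70] += 0.05
            flags.append(is_distinct(distance_trace(
                make_traces(va), make_traces(vb, stimulus="new"))))
        assert np.mean(flags) == pytest.approx(0.7)


class TestResponders:
    def test_strong_plateau_is_responsive(self):
        rng = np.random.default_rng(8)
        sd = 0.01
        vals = rng.normal(0, sd, (1, 120))
        vals[0, 40:90] += 6 * sd
        summary = responsive_glomeruli(make_traces(vals))
        assert summary.n_responsive == 1
        assert summary.pct == 100.0

    def test_silent_noisefree_not_responsive(self):
        summary = responsive_glomeruli(make_traces(np.zeros((5, 120))))
        assert summary.n_responsive == 0

    def test_counts_match_planted_fraction(self, small_config):
        small_config = replace(small_config, bee_gain_sd=0.0)
        traces, _ = generate_traces(small_config, 0, "paired", "solvent",
                                    stimuli=("cs_plus", "mineral_oil"))
        assert responsive_glomeruli(traces["cs_plus"]).pct == 100.0
        assert responsive_glomeruli(traces["mineral_oil"]).pct == 0.0

    def test_needs_enough_baseline(self):
        with pytest.raises(ValueError, match="pre-onset"):
            responsive_glomeruli(make_traces(np.zeros((2, 20)), onset=3,
                                             duration=10))


class TestDominantGlomeruli:
    def test_selects_two_strongest(self):
        vals = np.zeros((4, 120))
        vals[0, 40:70] = 0.3
        vals[1, 40:70] = 0.2
        vals[2, 40:70] = 0.05
        ref = make_traces(vals)
        dom = dominant_glomeruli(ref, ref)
        assert dom.glomerulus_ids == (1, 2)
        assert dom.peak_value == pytest.approx(0.25)

    def test_rank_tie_prefers_lower_index(self):
        vals = np.zeros((4, 120))
        vals[1, 40:70] = 0.3
        vals[2, 40:70] = 0.2
        vals[3, 40:70] = 0.2    # tie with glomerulus 3 at rank 2
        ref = make_traces(vals)
        assert dominant_glomeruli(ref, ref).glomerulus_ids == (2, 3)

    def test_planted_gain_halves_peak(self, small_noisefree_config):
        cfg = replace(small_noisefree_config, dominant_gain_new=0.5,
                      bee_gain_sd=0.0, responder_fraction_new=0.6)
        sol, _ = generate_traces(cfg, 0, "paired", "solvent",
                                 stimuli=("new",))
        inh, _ = generate_traces(cfg, 0, "paired", "inhibitor",
                                 stimuli=("new",))
        peak_s = dominant_glomeruli(sol["new"], sol["new"]).peak_value
        peak_i = dominant_glomeruli(inh["new"], inh["new"]).peak_value
        assert peak_i == pytest.approx(0.5 * peak_s, rel=1e-9)

    def test_requires_two_glomeruli(self):
        one = make_traces(np.zeros((1, 120)))
        with pytest.raises(ValueError, match="at least 2"):
            dominant_glomeruli(one, one)


class TestExtinction:
    def test_identical_trials_perfectly_stable(self):
        vals = np.zeros((3, 120))
        vals[:, 40:70] = 0.1
        trials = [make_traces(vals, stimulus=f"ext{j}")
                  for j in range(1, 7)]
        for dt in extinction_stability(trials):
            assert np.all(dt.d == 0.0)

    def test_linear_drift_closed_form(self):
        """+delta per trial on 2 glomeruli makes the peak distance grow as
        sqrt(2) * (j - 1) * delta."""
        delta = 0.01
        trials = []
        for j in range(1, 7):
            vals = np.zeros((4, 120))
            vals[:2, 40:70] = 0.1 + delta * (j - 1)
            trials.append(make_traces(vals, stimulus=f"ext{j}"))
        for j, dt in enumerate(extinction_stability(trials), start=2):
            want = np.sqrt(2.0) * (j - 1) * delta
            assert np.max(dt.d) == pytest.approx(want, abs=1e-12)

    def test_planted_drift_increases_dominant_peaks(
            self, small_noisefree_config):
        cfg = replace(small_noisefree_config, extinction_drift=0.01)
        traces, _ = generate_traces(
            cfg, 0, "unpaired", "inhibitor",
            stimuli=tuple(f"ext{j}" for j in range(1, 7)))
        ref = traces["ext1"]
        peaks = [dominant_glomeruli(traces[f"ext{j}"], ref).peak_value
                 for j in range(2, 7)]
        assert np.all(np.diff(peaks) > 0)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError, match="two"):
            extinction_stability([make_traces(np.zeros((2, 120)))])


def test_bee_metrics_covers_full_panel(small_config):
    traces, _ = generate_traces(small_config, 0, "paired", "solvent")
    rows = bee_metrics(traces)
    metrics = {r["metric"] for r in rows}
    assert metrics == {
        "early_separation", "odor_period_separation", "distinct_pattern",
        "pct_responders", "dominant_peak_cs_ref", "dominant_peak_new_ref",
        "extinction_distance", "extinction_dominant_peak",
    }
    per_stim = [r for r in rows if r["metric"] == "pct_responders"]
    assert len(per_stim) == 10
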