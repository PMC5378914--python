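import numpy as np
import pytest

from beelobe.containers import GlomerularTraces, RatioMovie
from beelobe.synth import SynthConfig

# Reduced recording geometry for fast unit tests: 60x80 px, 120 frames at
# 80 ms, odor onset at frame 40 for 30 frames, 5 glomeruli, all responsive
# to the CS+ and with deterministic responder counts.
SMALL = dict(
    n_glomeruli=5,
    image_shape=(60, 80),
    n_frames=120,
    odor_onset=3.2,
    odor_duration=2.4,
    cs_responder_fraction=1.0,
    responder_jitter_sd=0.0,
)


@pytest.fixture
def small_config():
    return SynthConfig(seed=7, **SMALL)


@pytest.fixture
def small_noisefree_config():
    return SynthConfig(seed=7, noise_sd=0.0, bee_gain_sd=0.0, **SMALL)


def make_traces(values, stimulus="cs_plus", frame_period=0.08,
                onset=40, duration=30):
    return GlomerularTraces(
        values=np.asarray(values, dtype=float),
        stimulus_label=stimulus,
        frame_period=frame_period,
        odor_onset_frame=onset,
        odor_duration_frames=duration,
    )


def make_ratio_movie(delta_r, stimulus="cs_plus", frame_period=0.08,
                     onset=40, duration=30, baseline=(0, 40)):
    return RatioMovie(
        delta_r=np.asarray(delta_r, dtype=float),
        baseline_frames=baseline,
        frame_period=frame_period,
        odor_onset_frame=onset,
        odor_duration_frames=duration,
        stimulus_label=stimulus,
    )
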