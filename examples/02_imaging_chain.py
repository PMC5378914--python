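"""Raw imaging chain: render movies, register, ratio, segment, extract.

A noise-free bee is rendered into dual-wavelength FURA movies with a
planted rigid drift; the chain then undoes everything: registration
recovers the drift, the 340/380 ratio with 40-frame baseline recovers the
planted ΔR, and the cone factorization recovers the planted ROIs.
Reduced geometry (60x80 px, 5 glomeruli) keeps this instant.
"""

import numpy as np

from beelobe import SynthConfig, generate_traces, render_movie
from beelobe.preproc import compute_ratio, register
from beelobe.segment import detect_glomeruli, extract_traces, match_maps

config = SynthConfig(seed=4, noise_sd=0.0, bee_gain_sd=0.0,
                     n_glomeruli=5, image_shape=(60, 80), n_frames=120,
                     odor_onset=3.2, odor_duration=2.4,
                     cs_responder_fraction=1.0, responder_jitter_sd=0.0)
traces, truth = generate_traces(config, 0, "paired", "solvent",
                                stimuli=("cs_plus", "new", "mixture"))

drift = np.zeros((config.n_frames, 2), dtype=int)
drift[60:] = (3, -1)                      # the bee moves at frame 60

ratio_movies = []
for stim in ("cs_plus", "new", "mixture"):
    movie = render_movie(traces[stim], truth, config,
                         drift=drift if stim == "cs_plus" else None)
    movie, shifts = register(movie)
    if stim == "cs_plus":
        print(f"registration: frame 60 shift estimated as {shifts[60]} "
              "(planted drift was (3, -1))")
    ratio_movies.append(compute_ratio(movie, n_baseline_frames=40))

glomap = detect_glomeruli(ratio_movies, k_components=8, sigma=0.0,
                          min_size=20)
scores, mapping = match_maps(glomap.labels, truth.roi_labels)
print(f"segmentation: {glomap.n_glomeruli}/5 glomeruli, "
      f"mean Jaccard vs planted ROIs = {np.mean(scores):.3f}")

extracted = extract_traces(glomap, ratio_movies[0])
k = mapping[1] - 1
r = np.corrcoef(extracted.values[k], traces["cs_plus"].values[0])[0, 1]
print(f"extracted trace of glomerulus 1 correlates r = {r:.4f} with the "
      "planted ΔR time course")
# Jaccard 1.0 and r ~ 1 mean the imaging chain is information-preserving
# on clean data; every loss seen on noisy data is attributable to noise.
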