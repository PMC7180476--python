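"""Align two time-warped copies of the idealised step with banded DTW.

The DTW distance uses a z-normalised pointwise distance, so amplitude
scale and offset do not matter; the band (maxsamp) limits how far the
alignment may stray from the diagonal.
"""

import numpy as np

from gaitdtw import SynthParams, dtw, strategy_piecewise, synth_step

proto = strategy_piecewise()
params = SynthParams(noise_sd=0.0)
rng = np.random.default_rng(3)

wave_a, len_a = synth_step(proto, params, rng)
wave_b, len_b = synth_step(proto, params, rng)

res = dtw(wave_a, wave_b, maxsamp=20)
print(f"step A: {len_a} samples, step B: {len_b} samples")
print(f"DTW distance {res.distance:.4f} over a path of {len(res.path)} index pairs")
print(f"identical inputs give distance {dtw(wave_a, wave_a, 20).distance:.1f}")
print(f"affine rescaling is free: {dtw(3 * wave_a + 7, wave_a, 20).distance:.2e}")
# A small distance between two independently warped, rescaled draws of the
# same prototype is exactly what makes a single template usable for detection.
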