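"""Generate the model's inputs: surrogate landscapes, saccade clips, probes.

Builds a 1/f-spectrum surrogate landscape, cuts a saccade-style clip series
from it, and constructs the eight oriented-bar probe stimuli used for
characterization.
"""

import numpy as np

import wirevo as wv

landscape = wv.generate_surrogate_landscape(seed=1, height=128, width=128)
print(f"surrogate landscape: {landscape.height}x{landscape.width}, "
      f"pixel range [{landscape.pixels.min():.2f}, {landscape.pixels.max():.2f}]")

series = wv.make_saccade_series([landscape], n_scenes=50, n_clips=40, seed=2)
print(f"saccade series: {len(series)} timesteps of "
      f"{series.vectors.shape[1]}-element clip vectors "
      f"(one {series.clip_size}x{series.clip_size} clip per step)")
print(f"  per-element mean {series.vectors.mean():.3f}, "
      f"std {series.vectors.std():.3f}")

probe = wv.make_probe_series(n_hold=20, noise_high=0.1, seed=3)
labels = np.asarray(probe.labels)
stim_names = sorted(set(labels) - {"blank"})
print(f"probe series: {len(probe)} steps, {len(stim_names)} oriented stimuli "
      f"held 20 steps each with uniform [0, 0.1] noise, blanks in between")
print("  stimuli:", ", ".join(stim_names))
# Each stimulus occupies exactly as many steps as the blank intervals, so the
# characterization sees a balanced label distribution.
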