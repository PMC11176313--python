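"""Model inputs: surrogate natural images, saccade clip series, probe stimuli.

The training signal emulates time series cut from grayscale natural
landscape photographs: surrogate images with 1/f spatial power spectra stand
in for real photographs, scene windows are extracted from each image, and a
small square clip window is shifted randomly inside each scene ("saccades").
Each clip is linearized row-major into a vector in [0, 1]^(clip_size^2) and
presented for exactly one timestep.

For characterizing evolved circuits, a probe series of eight oriented 4x4
bar patterns (two horizontal, two vertical, two diagonal-down, two
diagonal-up placements) is generated, each held for ``n_hold`` steps with
fresh per-step uniform noise, separated by equally long blank intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BLANK_LABEL = "blank"
TRAINING_LABEL = "training"


@dataclass(frozen=True)
class SurrogateImage:
    """A grayscale surrogate landscape with pixel values in [0, 1]."""

    pixels: np.ndarray
    seed: int

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def to_text(self, path) -> None:
        """Write the pixel matrix as whitespace-separated plain text."""
        np.savetxt(path, self.pixels, fmt="%.8f")

    @classmethod
    def from_text(cls, path, seed: int = -1) -> "SurrogateImage":
        return cls(pixels=np.loadtxt(path, ndmin=2), seed=seed)


@dataclass(frozen=True)
class StimulusSeries:
    """A labelled, time-ordered sequence of input vectors.

    vectors : (T, clip_size**2) array with entries in [0, 1].
    labels : (T,) array of per-timestep stimulus identities.
    clip_size : side length of the square clip each vector linearizes.
    """

    vectors: np.ndarray
    labels: np.ndarray
    clip_size: int

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a (T, d) array")
        if self.vectors.shape[1] != self.clip_size**2:
            raise ValueError("vector length must equal clip_size**2")
        if len(self.labels) != len(self.vectors):
            raise ValueError("labels and vectors must have equal length")
        if self.vectors.size and (
            self.vectors.min() < 0 or self.vectors.max() > 1
        ):
            raise ValueError("vector elements must lie in [0, 1]")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """One row per timestep: label column plus one column per element."""
        df = pd.DataFrame(
            self.vectors, columns=[f"v{i}" for i in range(self.vectors.shape[1])]
        )
        df.insert(0, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, clip_size: int) -> "StimulusSeries":
        df = pd.read_csv(path)
        return cls(
            vectors=df.drop(columns="label").to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=object),
            clip_size=clip_size,
        )


def generate_surrogate_landscape(
    seed: int,
    height: int = 128,
    width: int = 128,
    spectral_exponent: float = 1.0,
) -> SurrogateImage:
    """Spectrally shaped Gaussian noise with an approximately 1/f amplitude
    spectrum — the canonical second-order statistic of natural images —
    min-max rescaled to [0, 1].  Deterministic in ``seed``."""
    if height < 16 or width < 16:
        raise ValueError("image dimensions must be at least 16 pixels")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((height, width))
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    freq = np.hypot(fy, fx)
    amplitude = np.zeros_like(freq)
    nonzero = freq > 0
    amplitude[nonzero] = freq[nonzero] ** (-spectral_exponent)
    img = np.fft.ifft2(np.fft.fft2(white) * amplitude).real
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo)
    return SurrogateImage(pixels=img, seed=seed)


def make_saccade_series(
    landscapes: list[SurrogateImage],
    n_scenes: int = 100,
    n_clips: int = 40,
    scene_size: int = 16,
    clip_size: int = 4,
    seed: int = 0,
) -> StimulusSeries:
    """Build the saccade-emulating training/validation series.

    For every landscape, ``n_scenes`` square scene windows are extracted at
    random positions; within each scene the clip window starts centered and
    is shifted per clip by uniform integer offsets in
    ``[-scene_size // 4, +scene_size // 4]`` per axis (clamped to stay inside
    the scene).  Total length is ``len(landscapes) * n_scenes * n_clips`` and
    every clip occupies one timestep.
    """
    if not landscapes:
        raise ValueError("at least one landscape is required")
    if clip_size > scene_size:
        raise ValueError("clip_size must not exceed scene_size")
    min_dim = min(min(lm.height, lm.width) for lm in landscapes)
    if scene_size > min_dim:
        raise ValueError("scene_size exceeds the smallest landscape dimension")
    rng = np.random.default_rng(seed)
    shift_max = scene_size // 4
    slack = scene_size - clip_size
    center = slack // 2
    vectors = np.empty((len(landscapes) * n_scenes * n_clips, clip_size**2))
    t = 0
    for lm in landscapes:
        for _ in range(n_scenes):
            top = rng.integers(0, lm.height - scene_size + 1)
            left = rng.integers(0, lm.width - scene_size + 1)
            scene = lm.pixels[top : top + scene_size, left : left + scene_size]
            for _ in range(n_clips):
                dy, dx = rng.integers(-shift_max, shift_max + 1, size=2)
                y = int(np.clip(center + dy, 0, slack))
                x = int(np.clip(center + dx, 0, slack))
                vectors[t] = scene[y : y + clip_size, x : x + clip_size].ravel()
                t += 1
    labels = np.full(t, TRAINING_LABEL, dtype=object)
    return StimulusSeries(vectors=vectors, labels=labels, clip_size=clip_size)


def probe_patterns(clip_size: int = 4) -> dict[str, np.ndarray]:
    """The eight oriented bar stimuli, as named ``clip_size x clip_size``
    binary patterns: two placements each of horizontal, vertical,
    diagonal-down and diagonal-up bars."""
    n = clip_size
    eye = np.eye(n)
    patterns = {
        "horizontal_a": np.zeros((n, n)),
        "horizontal_b": np.zeros((n, n)),
        "vertical_a": np.zeros((n, n)),
        "vertical_b": np.zeros((n, n)),
        "diag_down_a": eye.copy(),
        "diag_down_b": np.eye(n, k=-1) + np.eye(n, k=n - 1),
        "diag_up_a": np.fliplr(eye),
        "diag_up_b": np.fliplr(np.eye(n, k=-1) + np.eye(n, k=n - 1)),
    }
    patterns["horizontal_a"][n // 2 - 1, :] = 1.0
    patterns["horizontal_b"][n // 2, :] = 1.0
    patterns["vertical_a"][:, n // 2 - 1] = 1.0
    patterns["vertical_b"][:, n // 2] = 1.0
    return patterns


def make_probe_series(
    n_hold: int = 20,
    noise_high: float = 0.1,
    seed: int = 0,
    clip_size: int = 4,
) -> StimulusSeries:
    """Probe series for the characterization experiments.

    Each of the eight oriented stimuli is presented for ``n_hold`` steps with
    fresh per-step uniform [0, noise_high] noise added (clamped to [0, 1]),
    followed by ``n_hold`` all-zero blank steps.  Total length is
    ``16 * n_hold``; labels carry the stimulus name or "blank".
    """
    if n_hold < 1:
        raise ValueError("n_hold must be at least 1")
    if not 0 <= noise_high < 1:
        raise ValueError("noise_high must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    d = clip_size**2
    vectors, labels = [], []
    for name, pattern in probe_patterns(clip_size).items():
        base = pattern.ravel()
        for _ in range(n_hold):
            noisy = base + rng.uniform(0, noise_high, d) if noise_high > 0 else base
            vectors.append(np.clip(noisy, 0.0, 1.0))
            labels.append(name)
        for _ in range(n_hold):
            vectors.append(np.zeros(d))
            labels.append(BLANK_LABEL)
    return StimulusSeries(
        vectors=np.array(vectors),
        labels=np.array(labels, dtype=object),
        clip_size=clip_size,
    )
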