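from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from accelmort.signal_preprocess import RawRecording

T0 = datetime(2015, 6, 1, 0, 0, 0)


def make_recording(samples: np.ndarray, rate_hz: float = 50.0,
                   pid: str = "P0000", start: datetime = T0,
                   dynamic_range_g: float = 8.0) -> RawRecording:
    return RawRecording(pid, start, rate_hz, samples, dynamic_range_g)


def gravity_samples(n: int, noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    s = np.tile([0.0, 0.0, 1.0], (n, 1))
    if noise_sd > 0:
        s = s + rng.normal(0, noise_sd, size=(n, 3))
    return s


def sinusoid_samples(duration_s: float, rate_hz: float, amplitude_g: float,
                     freq_hz: float = 1.0, axis: int = 0,
                     gravity: bool = True) -> np.ndarray:
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    s = np.zeros((t.size, 3))
    s[:, axis] = amplitude_g * np.sin(2 * np.pi * freq_hz * t)
    if gravity:
        s[:, 2] += 1.0
    return s


def still_orientations(n_orient: int = 24, window_s: float = 10.0,
                       rate_hz: float = 50.0, noise_sd: float = 0.002,
                       seed: int = 11) -> np.ndarray:
    """Still windows resting in diverse orientations on the unit sphere."""
    rng = np.random.default_rng(seed)
    w = int(round(window_s * rate_hz))
    dirs = rng.normal(size=(n_orient, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    blocks = [np.tile(d, (w, 1)) + rng.normal(0, noise_sd, size=(w, 3))
              for d in dirs]
    return np.vstack(blocks)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
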