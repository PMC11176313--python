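import numpy as np
import pytest

import wirevo as wv


@pytest.fixture(scope="session")
def params() -> wv.ReservoirParams:
    return wv.ReservoirParams()


@pytest.fixture(scope="session")
def layout() -> wv.GridLayout:
    return wv.build_layout()


@pytest.fixture(scope="session")
def pattern(params, layout) -> wv.WiringPattern:
    return wv.init_pattern(params, seed=1, layout=layout)


@pytest.fixture(scope="session")
def tiny_series() -> wv.StimulusSeries:
    """A short saccade series for fast driven-run tests."""
    imgs = [wv.generate_surrogate_landscape(7, 32, 32)]
    return wv.make_saccade_series(imgs, n_scenes=10, n_clips=10, seed=3)


@pytest.fixture(scope="session")
def long_series() -> wv.StimulusSeries:
    """A 2,000-step saccade series; long enough that the plug-in TE bias of
    the 8-bin estimator stays well below 0.1 bits per pair."""
    imgs = [wv.generate_surrogate_landscape(8)]
    return wv.make_saccade_series(imgs, n_scenes=50, n_clips=40, seed=5)


@pytest.fixture(scope="session")
def probe_series() -> wv.StimulusSeries:
    return wv.make_probe_series(n_hold=20, seed=11)


def zero_pattern(pattern: wv.WiringPattern) -> wv.WiringPattern:
    return pattern.with_weights(np.zeros_like(pattern.W), new_id="zero")
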