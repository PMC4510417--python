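import numpy as np
import pytest

from gaitmmse.entropy import EmbeddingParams, msampen
from gaitmmse.signal import MultichannelSignal


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the match-counting kernel once so timings below are honest."""
    rng = np.random.default_rng(0)
    msampen(rng.standard_normal((30, 2)), EmbeddingParams(M=[2, 2], tau=[1, 1], r=0.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tone_pair_signal():
    """2-channel mixture of a 4 Hz and a 0.5 Hz tone at 100 Hz for 30 s."""
    fs = 100.0
    t = np.arange(int(30 * fs)) / fs
    fast = np.sin(2 * np.pi * 4.0 * t)
    slow = np.sin(2 * np.pi * 0.5 * t)
    values = np.column_stack([
        fast + 0.8 * slow,
        0.7 * np.cos(2 * np.pi * 4.0 * t) + np.sin(2 * np.pi * 0.5 * t + 0.3),
    ])
    return MultichannelSignal(values, fs, ["a", "b"]), fast, slow


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """Two control subjects with 2 gait cycles each, on disk."""
    from gaitmmse.simulate import make_cohort

    out = tmp_path_factory.mktemp("cohort") / "tiny"
    make_cohort({"control": 2}, out, master_seed=11, n_cycles=2)
    return out
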