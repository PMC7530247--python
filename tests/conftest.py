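import numpy as np
import pytest

from mmnstrat.montage import FRONTOCENTRAL_24
from mmnstrat.preprocess import EpochSet
from mmnstrat.simulate import ParadigmSpec


@pytest.fixture
def small_paradigm() -> ParadigmSpec:
    """Reduced oddball paradigm keeping the 85/15 ratio."""
    return ParadigmSpec(n_trials=40, p_deviant=0.25)


def make_epochset(
    epochs: np.ndarray,
    condition=None,
    fs_hz: float = 512.0,
    window_ms=(-100.0, 400.0),
    channel_names=None,
    **kw,
) -> EpochSet:
    """Hand-built EpochSet with sensible defaults for unit tests."""
    epochs = np.asarray(epochs, dtype=float)
    n_tr, n_ch, _ = epochs.shape
    if condition is None:
        condition = np.array(["S1"] * (n_tr // 2) + ["S2"] * (n_tr - n_tr // 2))
    if channel_names is None:
        channel_names = list(FRONTOCENTRAL_24[:n_ch]) if n_ch <= 24 else [
            f"ch{i}" for i in range(n_ch)]
    return EpochSet(epochs=epochs, condition=np.asarray(condition),
                    window_ms=window_ms, fs_hz=fs_hz,
                    channel_names=channel_names, **kw)
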