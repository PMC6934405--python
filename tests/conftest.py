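import numpy as np
import pytest

from tevoc import ObserverModel, StaircaseConfig, load_feature_map


@pytest.fixture(scope="session")
def fmap():
    return load_feature_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def amd_observer():
    """An AMD observer with its 79.4 %-correct point at depth m = 0.1."""
    return ObserverModel.with_threshold(0.1, beta=8.0, lapse=0.02)


@pytest.fixture(scope="session")
def amd_config():
    return StaircaseConfig.for_task("AMD", n_trials=60)


class PerfectObserver:
    """Always answers correctly, at any level."""

    def p_correct(self, level):
        return 1.0


class GuessingObserver:
    """Ignores the stimulus entirely; chance performance on 3AFC."""

    def p_correct(self, level):
        return 1.0 / 3.0


@pytest.fixture()
def perfect_observer():
    return PerfectObserver()


@pytest.fixture()
def guessing_observer():
    return GuessingObserver()
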