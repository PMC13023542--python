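import numpy as np
import pytest

from apneaseg import sim
from apneaseg.events import EventInterval
from apneaseg.postproc import PostprocConfig
from apneaseg.segnet import ModelConfig, build_model
from apneaseg.train import LossConfig, TrainConfig, fit, prepare_night


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def micro_cfg():
    """Smallest config that still exercises every architectural block."""
    return ModelConfig(input_len=64, base_filters=4, depth=2,
                       n_transformer_blocks=1, n_heads=2,
                       smooth_kernel=7, dropout=0.0)


def random_disjoint_intervals(rng, n, span, min_len=5, max_len=40,
                              min_gap=1):
    """n sorted disjoint intervals inside [0, span)."""
    events = []
    t = 0
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        gap = int(rng.integers(min_gap, 30))
        if t + gap + length >= span:
            break
        start = t + gap
        events.append(EventInterval(start, start + length))
        t = start + length
    return events


@pytest.fixture(scope="session")
def easy_cohort():
    """Eight easy half-hour synthetic nights with known ground truth."""
    base = sim.SimParams(duration_s=1800.0)
    return sim.simulate_cohort(8, seed=42, base=base)


@pytest.fixture(scope="session")
def trained_tiny(tiny_cfg, easy_cohort):
    """A tiny model trained briefly on the easy cohort (shared across tests)."""
    nights = [prepare_night(n, tiny_cfg) for n in easy_cohort]
    model = build_model(tiny_cfg, seed=7)
    log = fit(model, nights[:6], nights[6:], LossConfig(),
              TrainConfig.tiny_pretrain(max_epochs=5, seed=7),
              PostprocConfig())
    return {"model": model, "log": log, "train": nights[:6],
            "val": nights[6:], "cfg": tiny_cfg}
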