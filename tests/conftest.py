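import numpy as np
import pandas as pd
import pytest

from allema.design import DesignConfig
from allema.simulate import synthetic_frame


@pytest.fixture(scope="session")
def config():
    return DesignConfig()


@pytest.fixture(scope="session")
def frame455():
    """The standard synthetic national frame: 455 squares, 2x5 strata."""
    return synthetic_frame(455, seed=11)


@pytest.fixture(scope="session")
def het20():
    """20-unit fixture with heterogeneous inclusion probabilities and
    scattered planar coordinates (expected sample size 6)."""
    rng = np.random.default_rng(7)
    pi = rng.uniform(0.1, 0.8, 20)
    pi *= 6.0 / pi.sum()
    pi = np.clip(pi, 0.02, 0.95)
    coords = rng.uniform(0.0, 1000.0, (20, 2))
    return pi, coords


def mc_frequencies(draw_fn, n_units, replicates, seed=123):
    """Empirical selection frequencies of a sampler over seeded replicates."""
    rng = np.random.default_rng(seed)
    acc = np.zeros(n_units)
    for _ in range(replicates):
        acc += draw_fn(rng).indicator
    return acc / replicates


def assert_pi_recovered(freq, pi, replicates, min_fraction=0.95):
    """At least ``min_fraction`` of units within 4 binomial SE of pi."""
    se = np.sqrt(pi * (1 - pi) / replicates)
    ok = np.abs(freq - pi) <= 4 * np.maximum(se, 1e-12)
    assert ok.mean() >= min_fraction, (
        f"only {ok.sum()}/{ok.size} units within 4 SE; "
        f"max dev/SE = {np.max(np.abs(freq - pi) / np.maximum(se, 1e-12)):.2f}")


@pytest.fixture(scope="session")
def toy_square():
    return {"square_id": "sq_toy", "x": 0.0, "y": 0.0, "elev": 900.0}


@pytest.fixture(scope="session")
def small_frame():
    """60-square frame with a small design (m=20, r=5) for fast MC."""
    frame = synthetic_frame(60, seed=4)
    cfg = DesignConfig(m=20, r=5)
    return frame, cfg
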