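import numpy as np
import pandas as pd
import pytest

from calgate import SyntheticConfig, TraceEnsemble, generate_ensemble


@pytest.fixture
def small_ensemble():
    """4 well-behaved traces with a step response in two of them."""
    rng = np.random.default_rng(7)
    traces = 100.0 + rng.normal(0, 1.0, (4, 300))
    traces[0, 130:200] += 80.0
    traces[2, 150:200] += 80.0
    meta = pd.DataFrame(
        {
            "neuron": ["AWA"] * 4,
            "condition": ["wt"] * 4,
            "animal": [0, 0, 1, 1],
            "pulse": [1, 2, 1, 2],
            "block": [0, 0, 0, 0],
        }
    )
    return TraceEnsemble(
        traces=traces, frame_rate=10.0, stim_onset=100, stim_offset=200, meta=meta
    )


@pytest.fixture(scope="session")
def default_synthetic():
    """Default activation ensemble with ground truth (session-cached)."""
    cfg = SyntheticConfig(n_traces=80, seed=42)
    return generate_ensemble(cfg)
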