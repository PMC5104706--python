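import numpy as np
import pytest

from sedlm import (
    Envelope,
    MLTPrior,
    SynthConfig,
    clean_series,
    fit_baseline,
    generate_daily_series,
    run_campaign,
)
from sedlm.dlm import DLMSpec


@pytest.fixture(scope="session")
def synth_series():
    """Three-year synthetic series, cleaned, shared across unit tests."""
    return clean_series(generate_daily_series(SynthConfig(n_years=3, seed=42)))


@pytest.fixture(scope="session")
def baseline_model(synth_series):
    return fit_baseline(synth_series)


@pytest.fixture(scope="session")
def tiny_campaign(synth_series, baseline_model):
    """Small but non-degenerate campaign: 6x6 cells, 8 triplets/cell, L=5."""
    env = Envelope(n_cells_x=6, n_cells_y=6)
    spec = DLMSpec(5, ("bspline", 5))
    return run_campaign(
        env,
        baseline_model,
        synth_series,
        spec,
        per_cell=8,
        prior=MLTPrior("uniform", lo=1.0, hi=10.0),
        seed=7,
        n_folds=4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
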