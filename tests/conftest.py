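import numpy as np
import pytest

from wheatnr import RichardsParams, TrialDesign, generate_trial
from wheatnr.richards import _inflection_u


def random_valid_params(rng: np.random.Generator, n: int) -> list[RichardsParams]:
    """Log-uniform draws over the documented box, filtered by the phase
    ordering condition (100/99)^N - 1 < u2 so that T3 > T2."""
    out = []
    while len(out) < n:
        a = np.exp(rng.uniform(np.log(20), np.log(60)))
        b = np.exp(rng.uniform(np.log(1), np.log(50)))
        k = np.exp(rng.uniform(np.log(0.05), np.log(0.5)))
        nn = np.exp(rng.uniform(np.log(0.2), np.log(5)))
        _, u2 = _inflection_u(nn)
        if (100.0 / 99.0) ** nn - 1.0 < u2:
            out.append(RichardsParams(a, b, k, nn))
    return out


@pytest.fixture(scope="session")
def param_draws():
    return random_valid_params(np.random.default_rng(20240901), 200)


@pytest.fixture(scope="session")
def default_trial():
    return generate_trial(design=TrialDesign(seed=42))


@pytest.fixture(scope="session")
def noiseless_trial():
    return generate_trial(design=TrialDesign(
        grain_sigma=0.0, spad_sigma=0.0, yield_sigma=0.0, npool_cv=0.0, seed=7))


def as_tables(ds):
    return {"grain_series": ds.grain_series, "spad_series": ds.spad_series,
            "organ_n": ds.organ_n, "yields": ds.yields}
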