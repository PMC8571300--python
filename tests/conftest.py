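import warnings

import numpy as np
import pytest

from xrfret import synth
from xrfret.models import FoldingKinetics

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

#: benchmark generating rates used throughout (1/s)
BENCH = synth.GeneratorRates(k_li=2.0, k_lh=0.05, k_il=1.0, k_ih=0.8, k_hl=0.1, k_hi=0.4)


@pytest.fixture(scope="session")
def bench_rates():
    return BENCH


@pytest.fixture(scope="session")
def small_condition():
    """40 traces x 30 s at the benchmark rates, default emission/noise."""
    ds = synth.simulate_titration(BENCH, [1.0], n_traces=40, duration=30.0, seed=2024)
    return ds.conditions[0]


@pytest.fixture(scope="session")
def small_fit(small_condition):
    """Shared full-model fit of the small benchmark condition."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return FoldingKinetics(small_condition.traces).fit(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
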