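import numpy as np
import pytest
from dataclasses import replace

from mrwrap import PhantomSpec, generate_phantom
from mrwrap.benchmark import run_benchmark


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def phantom64():
    """One 64x64 phantom with the default generator settings."""
    return generate_phantom(PhantomSpec(height=64, width=64, seed=11))


@pytest.fixture()
def phantom_batch():
    """Twenty 64x64 phantoms with derived seeds."""
    spec = PhantomSpec(height=64, width=64)
    return [generate_phantom(replace(spec, seed=s)) for s in range(100, 120)]


@pytest.fixture(scope="session")
def trained_benchmark():
    """The scaled-down end-to-end DUARN benchmark, trained once per session.

    Trains both U-nets on 200 synthetic samples (40 sources x 5 levels,
    64x64, widths 8/16/32/64) and evaluates on the held-out 20% of
    sources. Several training and restoration tests share this run.
    """
    return run_benchmark(seed=0)
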