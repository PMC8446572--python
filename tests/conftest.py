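import numpy as np
import pytest

import oncocea as oc


@pytest.fixture(scope="session")
def table1():
    return oc.load_table1()


@pytest.fixture(scope="session")
def base_runs(table1):
    """Base-case traces and outcomes for all four strategies (computed once)."""
    return oc.run_all(table1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
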