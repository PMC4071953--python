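import numpy as np
import pytest

from mdximmune import SimulationSettings, mdx_parameters


@pytest.fixture(scope="session")
def mdx():
    return mdx_parameters()


@pytest.fixture(scope="session")
def fast_cfg():
    """Loosened-tolerance settings for tests where speed matters more than
    the last digits."""
    return SimulationSettings(t_end=12.0, output_step=0.1,
                              rel_tol=1e-6, abs_tol=1e-8)


@pytest.fixture(scope="session")
def reference_12wk(mdx):
    """The calibrated 12-week run at default (tight) tolerances, shared
    across tests."""
    from mdximmune import integrate

    return integrate(mdx)
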