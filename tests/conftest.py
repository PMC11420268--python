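import numpy as np
import pytest

from laaoflow import anatomy as an


@pytest.fixture(scope="session")
def default_anatomy():
    return an.build_anatomy()


@pytest.fixture(scope="session")
def coarse_grid(default_anatomy):
    """Shared read-only voxelization of the default anatomy."""
    return an.discretize(default_anatomy, 2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def suite_results():
    """The nine-scenario study at the scaled-down test tier (shared run)."""
    from laaoflow import pipeline as pl

    report, results = pl.run_study(tier="test")
    return report, results
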