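import numpy as np
import pytest

from h2o2bcr import cytometry, model, synth


@pytest.fixture(scope="session")
def params():
    return model.ModelParameters()


@pytest.fixture(scope="session")
def small_static_experiment(params):
    """A small static step-dose experiment with ground truth (shared)."""
    ev, gt = synth.generate_static_experiment(
        params,
        doses=[0, 0.25, 1, 2.5, 5, 10, 20],
        times=[10],
        n_events=2000,
        seed=11,
        n_cells=300,
        replicates=1,
    )
    return ev, gt


@pytest.fixture(scope="session")
def small_gated(small_static_experiment):
    ev, gt = small_static_experiment
    gated, report = cytometry.apply_gates(ev, cytometry.GatingConfig.default())
    return gated, report, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
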