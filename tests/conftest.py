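import warnings

import numpy as np
import pytest

import fnirsflow as ff

# statsmodels RLM emits convergence chatter on some tiny inputs; the fits
# themselves are asserted on directly.
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def paper_schedule():
    """The 12-trial study session with balanced, duration-crossed labels."""
    session = ff.paper_session()
    n_trials = sum(len(s.trials) for s in session.sections)
    from fnirsflow.synthetic_data import default_labels

    labels = default_labels(n_trials)
    return ff.build_schedule(session, labels=labels), labels


@pytest.fixture(scope="session")
def small_hemo():
    """A short random HemoSeries for I/O and epoching tests."""
    rng = np.random.default_rng(7)
    return ff.HemoSeries(rng.normal(size=(400, 12)), rng.normal(size=(400, 12)),
                         fs=15.625)


def make_separable_tensors(n_per_class=8, m=16, classes=("dislike", "like"),
                           noise=0.01, seed=0):
    """Trivially separable toy tensors: class-dependent constant offset."""
    rng = np.random.default_rng(seed)
    tensors = []
    idx = 0
    for ci, lab in enumerate(classes):
        for _ in range(n_per_class):
            mat = ci * 1.0 + noise * rng.normal(size=(m, 24))
            tensors.append(ff.TrialTensor(mat, lab, idx))
            idx += 1
    return tensors


@pytest.fixture
def separable_tensors():
    return make_separable_tensors()
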