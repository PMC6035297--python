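import numpy as np
import pytest

from dynallo import synthetic


@pytest.fixture(scope="session")
def truth():
    """Small planted study shared by read-only tests."""
    return synthetic.default_truth(seed=7, n_residues=30)


@pytest.fixture(scope="session")
def peak_lists(truth):
    return synthetic.gen_peak_lists(
        truth,
        ["open-ref", "closed-ref", "tandem", "tandem-2state", "csh2-3state", "mutant"],
    )


@pytest.fixture(scope="session")
def refs(peak_lists):
    from dynallo import projection

    return projection.build_reference(peak_lists["open-ref"], peak_lists["closed-ref"])


@pytest.fixture(scope="session")
def toy_ensembles(truth):
    return synthetic.gen_toy_trajectories(
        truth, n_replicas_per_condition=3, n_frames=800, dt_ns=0.1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
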