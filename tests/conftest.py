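import numpy as np
import pytest

from corescaffold import Connectome, Cohort, CohortSpec, generate_cohort
from corescaffold.parcellation_io import index_parcellation


def make_connectome(weights, subject_id="toy", **kw) -> Connectome:
    weights = np.asarray(weights, dtype=float)
    return Connectome(subject_id=subject_id, weights=weights, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def relay_triangle():
    """3-node graph where the 2-hop relay beats the direct edge.

    Weights A-B = 2, B-C = 2, A-C = 0.25 -> lengths 0.5, 0.5, 4;
    d(A, C) = 1.0 via B.
    """
    return make_connectome([[0, 2, 0.25],
                            [2, 0, 2],
                            [0.25, 2, 0]])


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 12-node, 6-subject synthetic cohort."""
    spec = CohortSpec(G=12, n_subjects=6, n_modules=2, seed=99)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_spec():
    from corescaffold import default_bridges
    return CohortSpec(G=20, n_subjects=12, n_modules=4,
                      planted_edges=default_bridges(20, 4, 4, seed=3), seed=3)


def identical_cohort(weights, n_subjects=4) -> Cohort:
    """Cohort whose subjects all share one weight matrix."""
    W = np.asarray(weights, dtype=float)
    parcellation = index_parcellation(W.shape[0])
    subs = tuple(
        Connectome(subject_id=f"s{i}", weights=W, parcellation=parcellation)
        for i in range(n_subjects))
    return Cohort(subjects=subs, parcellation=parcellation)
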