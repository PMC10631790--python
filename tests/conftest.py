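import numpy as np
import pandas as pd
import pytest

from connstats.connectome import Cohort, ConnectomeMatrix, group_threshold


def random_symmetric(n, rng, density=0.5, scale=10.0):
    """A random valid connectome weight matrix."""
    w = np.triu((rng.random((n, n)) < density) * rng.lognormal(np.log(scale), 1.0, (n, n)), 1)
    return w + w.T


def make_cohort(matrices, groups, behavior=None, threshold=0.0):
    """Build a cohort from raw weight matrices, mask at `threshold`."""
    n_subj = len(matrices)
    ids = [f"s{i:02d}" for i in range(n_subj)]
    if behavior is None:
        behavior = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
    else:
        behavior = pd.DataFrame(behavior, index=pd.Index(ids, name="subject_id"))
    cohort = Cohort(
        subject_ids=ids,
        groups=list(groups),
        connectomes=[ConnectomeMatrix(m) for m in matrices],
        behavior=behavior,
    )
    return group_threshold(cohort, threshold)


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def toy_cohort(rng):
    """6 subjects (3+3), 8 nodes, one strongly separated edge."""
    mats = []
    base = random_symmetric(8, rng, density=0.8, scale=20.0)
    for s in range(6):
        m = base * np.exp(rng.normal(0, 0.05, base.shape))
        m = np.triu(m, 1)
        m = m + m.T
        if s >= 3:  # second group: edge (1, 2) much stronger
            m[1, 2] = m[2, 1] = m[1, 2] * 3.0
        mats.append(m)
    return make_cohort(mats, ["A"] * 3 + ["B"] * 3)
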