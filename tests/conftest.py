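import numpy as np
import pytest

from mstates import grid_layout, make_topographies


@pytest.fixture(scope="session")
def layout64():
    return grid_layout(64)


@pytest.fixture(scope="session")
def maps4(layout64):
    """Four planted topographies on the 64-channel grid."""
    return make_topographies(layout64, 4, seed=42)


@pytest.fixture(scope="session")
def sticky4():
    """Sticky symmetric 4-state transition matrix (mean run 20 samples)."""
    P = np.full((4, 4), 0.05 / 3)
    np.fill_diagonal(P, 0.95)
    return P


def abs_corr(u, v):
    """|Pearson correlation| between two topographies (test-side oracle)."""
    u = np.asarray(u, float) - np.mean(u)
    v = np.asarray(v, float) - np.mean(v)
    return abs(float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def match_maps(recovered, truth):
    """Mean best-assignment |corr| between two map stacks (brute force)."""
    from itertools import permutations

    k = len(truth)
    best = -1.0
    for perm in permutations(range(k)):
        score = np.mean([abs_corr(recovered[i], truth[p])
                         for i, p in enumerate(perm)])
        best = max(best, score)
    return best
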