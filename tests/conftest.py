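import numpy as np
import pytest

import triadkit as tk
from triadkit.stimulus_space import DESIGN_TRIADS


@pytest.fixture(scope="session")
def space():
    return tk.default_space()


@pytest.fixture(scope="session")
def triads(space):
    return tk.design_triads(space)


@pytest.fixture(scope="session")
def instances(triads):
    return tk.enumerate_instances(triads)


@pytest.fixture(scope="session")
def table(space, instances):
    return tk.build_prediction_table(space, instances)


@pytest.fixture(scope="session")
def similarity():
    return tk.default_similarity_matrix()


def brute_force_min_pair(instance, space, metric):
    """Independent odd-position oracle: enumerate all three pairwise
    distances directly from coordinates (no shared code path)."""
    l, m, r = instance
    pairs = {(l, m): 3, (l, r): 2, (m, r): 1}
    dists = {}
    for (a, b), odd in pairs.items():
        ca, ba = space.coords[a]
        cb, bb = space.coords[b]
        if metric == "chroma":
            d = abs(ca - cb)
        elif metric == "brightness":
            d = abs(ba - bb)
        else:
            d = np.hypot(space.chroma_weight * (ca - cb), ba - bb)
        dists[odd] = d
    best = min(dists.values())
    winners = [o for o, d in dists.items() if d == best]
    return winners[0] if len(winners) == 1 else None
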