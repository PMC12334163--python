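import numpy as np
import pytest

import regentrack as rt


@pytest.fixture(scope="session")
def mini_sim():
    """Small synthetic recording shared across tests (movie, forest, events, clean)."""
    return rt.simulate_recording(rt.li_synth_mini(), return_clean=True)


@pytest.fixture(scope="session")
def mini_flow(mini_sim):
    movie, forest, _, _ = mini_sim
    return rt.ground_truth_flow_field(forest, movie.grid)


@pytest.fixture(scope="session")
def benchmark_sim():
    """The packaged benchmark recording (li-synth), simulated once per session."""
    return rt.simulate_recording(rt.li_synth(), return_clean=True)


@pytest.fixture(scope="session")
def benchmark_flow(benchmark_sim):
    movie, forest, _, _ = benchmark_sim
    return rt.ground_truth_flow_field(forest, movie.grid)


def make_chain(forest, start_id, t0, n, pos=(0.0, 0.0, 0.0), step=(0.0, 0.0, 0.0), radius=2.0):
    """Append an unbranched track of n spots to a forest; returns spot ids."""
    ids = []
    for k in range(n):
        p = tuple(c + k * s for c, s in zip(pos, step))
        forest.add_spot(rt.Spot(start_id + k, t0 + k, p, radius=radius))
        if ids:
            forest.add_link(ids[-1], start_id + k)
        ids.append(start_id + k)
    return ids
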