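"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from cophylo import (
    Alignment,
    jc,
    parse_newick,
)
from cophylo.model import build_rate_matrix, transition_probabilities
from cophylo.simulate import (
    COSPECIATION_8TAXA,
    SWITCH3_8TAXA,
    make_bundle,
)


def simulate_jc_quartet(seed: int, L: int = 2000, internal: float = 0.3,
                        tip: float = 0.1) -> Alignment:
    """JC data on the quartet ((A,B),(C,D)) with a controllable inner branch.

    Kept independent of the package's own sequence simulator so that search
    and bootstrap tests do not share code with the machinery they check.
    """
    rng = np.random.default_rng(seed)
    Q = build_rate_matrix(jc())

    def evolve(states: np.ndarray, t: float) -> np.ndarray:
        if t == 0:
            return states.copy()
        P = transition_probabilities(Q, t)
        cum = np.cumsum(P, axis=1)
        u = rng.random(len(states))
        return (u[:, None] > cum[states]).sum(axis=1)

    u = rng.integers(0, 4, L)  # root placed at the (A,B) junction
    v = evolve(u, internal)
    chars = np.array(list("ACGT"))
    seqs = {
        "A": evolve(u, tip), "B": evolve(u, tip),
        "C": evolve(v, tip), "D": evolve(v, tip),
    }
    return Alignment([(n, "".join(chars[s])) for n, s in sorted(seqs.items())])


TRUE_QUARTET = "((A,B),(C,D));"


@pytest.fixture(scope="session")
def cospec_bundle():
    return make_bundle(COSPECIATION_8TAXA)


@pytest.fixture(scope="session")
def switch3_bundle():
    return make_bundle(SWITCH3_8TAXA)


@pytest.fixture()
def quartet_tree():
    return parse_newick(TRUE_QUARTET)
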