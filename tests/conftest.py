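"""Shared fixtures and independent oracles.

The direct-LP oracle below recomputes blocked sets with raw
``scipy.optimize.linprog`` calls, bypassing the package's solver wrapper
and consistency module entirely, so that agreement tests are genuinely
two-route.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy.optimize import linprog

from metnet import (
    GeneratorParams,
    MetNet,
    build_network,
    figure1_consistent_part,
    figure1_network,
    random_consistent_network,
    random_network,
)

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")

EPS = 1e-4


@pytest.fixture
def fig1() -> MetNet:
    return figure1_network()


@pytest.fixture
def fig1_consistent() -> MetNet:
    return figure1_consistent_part()


@pytest.fixture
def chain3() -> MetNet:
    """Single irreversible pathway: ∅→A, A→B, B→∅."""
    return build_network(
        ["A", "B"],
        [("in_A", {"A": 1.0}, 0.0, 10.0),
         ("A_B", {"A": -1.0, "B": 1.0}, 0.0, 10.0),
         ("out_B", {"B": -1.0}, 0.0, 10.0)],
    )


@pytest.fixture
def dead_end() -> MetNet:
    """Single producer with no consumer: the only reaction is blocked."""
    return build_network(["A"], [("in_A", {"A": 1.0}, 0.0, 10.0)])


def small_consistent_net(seed: int, m: int = 6, n: int = 12) -> MetNet:
    return random_consistent_network(GeneratorParams(m=m, n=n, seed=seed))


def raw_net(seed: int, m: int = 12, n: int = 30) -> MetNet:
    return random_network(GeneratorParams(m=m, n=n, seed=seed))


def blocked_by_direct_lp(net: MetNet, eps: float = EPS) -> frozenset[int]:
    """Blocked set via per-reaction flux variability with raw linprog."""
    S = net.dense_S()
    bounds = list(zip(net.lb.tolist(), net.ub.tolist()))
    blocked = set()
    for i in range(net.n_reactions):
        c = np.zeros(net.n_reactions)
        c[i] = 1.0
        hi = -linprog(-c, A_eq=S, b_eq=np.zeros(net.n_metabolites),
                      bounds=bounds, method="highs").fun
        lo = linprog(c, A_eq=S, b_eq=np.zeros(net.n_metabolites),
                     bounds=bounds, method="highs").fun
        if max(abs(hi), abs(lo)) < 0.99 * eps:
            blocked.add(i)
    return frozenset(blocked)


def to_cobra(net: MetNet):
    """Convert to a cobrapy model (independent solver stack: GLPK)."""
    import cobra

    model = cobra.Model("m")
    mets = {mid: cobra.Metabolite(mid, compartment="c")
            for mid in net.metabolite_ids}
    rxns = []
    for j, rid in enumerate(net.reaction_ids):
        r = cobra.Reaction(rid, lower_bound=float(net.lb[j]),
                           upper_bound=float(net.ub[j]))
        col = net.S[:, [j]].toarray().ravel()
        r.add_metabolites({mets[net.metabolite_ids[i]]: float(col[i])
                           for i in range(net.n_metabolites) if col[i]})
        rxns.append(r)
    model.add_reactions(rxns)
    return model
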