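"""Context-specific network extraction: the greedy sparse-mode algorithm.

Given a flux-consistent global network and a *core* set ``C`` of reactions
required to be active in the context of interest, the goal is the smallest
reaction set ``A`` with ``C ⊆ A`` whose induced subnetwork is consistent
(an NP-hard problem; see :mod:`metnet.exact_baseline` for the exact
small-scale solver).  The greedy algorithm builds ``A`` as a union of
supports of *sparse modes*: each iteration computes a mode that is dense
inside the uncovered core (cardinality surrogate LP) and sparse outside it
(L1-norm penalty LP), and adds its support to ``A``.

Numerical guard: the L1 step constrains core fluxes to ``scale*eps`` (with
all bounds scaled by the same factor, default 1e5) rather than ``eps``.
Without the scaling, a supporting flux that is structurally a fraction of a
core flux (e.g. forced down by a stoichiometric coefficient > 1) can land
below ``eps`` and be dropped from the support, silently disconnecting the
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .consistency import DEFAULT_EPS, READBACK, _lp7, _steady_state_eq, _Working
from .lp import LPSolution, SolverError, solve_lp
from .model import MetNet, induced_submodel

__all__ = [
    "DEFAULT_SCALE",
    "SparseModeQuery",
    "ReconstructionResult",
    "InconsistentCoreError",
    "lp10_min_l1_penalty",
    "find_sparse_mode",
    "fastcore",
]

#: Factor applied to the minimum-flux constraint and all bounds in the L1 LP.
DEFAULT_SCALE = 1e5


class InconsistentCoreError(RuntimeError):
    """A core reaction cannot carry flux; the input network is inconsistent
    (or the core contains blocked reactions)."""


@dataclass(frozen=True)
class SparseModeQuery:
    """Inputs of one sparse-mode search.

    ``J``: uncovered core reactions under test; ``P``: penalty set (non-core
    reactions not yet included); ``singleton``: test only the first (lowest
    index) element of ``J``.
    """

    J: frozenset[int]
    P: frozenset[int]
    singleton: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "J", frozenset(self.J))
        object.__setattr__(self, "P", frozenset(self.P))
        if self.J & self.P:
            raise ValueError("J and P must be disjoint")


@dataclass(frozen=True)
class ReconstructionResult:
    """Active set ``A`` with its induced submodel and LP accounting."""

    A: frozenset[int]
    lp_calls: int
    submodel: MetNet
    added_noncore: frozenset[int]


# ---------------------------------------------------------------------------
# LP-10: minimum L1 penalty subject to minimum core flux
# ---------------------------------------------------------------------------

def _lp10(S, lb, ub, K, P, eps, scale) -> LPSolution:
    m, n = S.shape
    P = list(P)
    k = len(P)
    A_eq, b_eq = _steady_state_eq(S, k)
    # epigraph: v_p - t_j <= 0 and -v_p - t_j <= 0
    if k:
        rows = np.repeat(np.arange(2 * k), 2)
        cols = np.empty(4 * k, dtype=int)
        vals = np.empty(4 * k)
        cols[0::4] = P
        vals[0::4] = 1.0
        cols[1::4] = n + np.arange(k)
        vals[1::4] = -1.0
        cols[2::4] = P
        vals[2::4] = -1.0
        cols[3::4] = n + np.arange(k)
        vals[3::4] = -1.0
        A_ub = sp.csc_array((vals, (rows, cols)), shape=(2 * k, n + k))
        b_ub = np.zeros(2 * k)
    else:
        A_ub = b_ub = None
    c = np.concatenate([np.zeros(n), np.ones(k)])
    bounds = [(float(l) * scale, float(u) * scale) for l, u in zip(lb, ub)]
    for i in K:
        l, u = bounds[i]
        bounds[i] = (max(l, scale * eps), u)
    bounds += [(0.0, None)] * k
    return solve_lp(c, A_eq, b_eq, A_ub, b_ub, bounds, n_keep=n)


def lp10_min_l1_penalty(
    net: MetNet,
    K: Iterable[int],
    P: Iterable[int],
    eps: float = DEFAULT_EPS,
    scale: float = DEFAULT_SCALE,
) -> LPSolution:
    """Minimize the L1 norm of the penalty fluxes subject to active core.

    Solves ``min sum_{i in P} |v_i|`` subject to ``S v = 0``,
    ``v_i >= scale*eps`` for ``i in K``, with all bounds multiplied by
    ``scale``.  The returned flux vector lives on the *scaled* problem;
    support read-back at a threshold of order ``eps`` is what makes the
    scaling guard effective.  Infeasibility (``K`` not jointly activatable
    in this orientation) is reported via the status, not raised.
    """
    K = sorted(set(K))
    P = sorted(set(P))
    if not K:
        raise ValueError("K must be nonempty")
    if set(K) & set(P):
        raise ValueError("K and P must be disjoint")
    if not scale > 0:
        raise ValueError("scale must be positive")
    return _lp10(net.S, net.lb, net.ub, K, P, eps, scale)


# ---------------------------------------------------------------------------
# FindSparseMode
# ---------------------------------------------------------------------------

def _find_sparse_mode(S, lb, ub, J, P, singleton, eps, scale):
    """Return (support, lp_count) of a mode dense in J and sparse in P."""
    J = sorted(J)
    if not J:
        return set(), 0
    target = [J[0]] if singleton else J
    sol = _lp7(S, lb, ub, target, eps)
    if not sol.optimal:
        raise SolverError(f"dense-mode LP returned {sol.status}")
    K = [i for i in J if sol.v[i] >= READBACK * eps]
    if not K:
        return set(), 1
    sol10 = _lp10(S, lb, ub, K, sorted(P), eps, scale)
    if not sol10.optimal:
        # K not jointly activatable at the scaled flux level; treat as no
        # progress and let the caller escalate.
        return set(), 2
    return set(np.nonzero(np.abs(sol10.v) >= READBACK * eps)[0].tolist()), 2


def find_sparse_mode(
    net: MetNet,
    query: SparseModeQuery,
    eps: float = DEFAULT_EPS,
    scale: float = DEFAULT_SCALE,
) -> frozenset[int]:
    """Support of a mode dense in ``query.J`` and sparse in ``query.P``.

    Reversible members of ``J`` are tested in their current (forward)
    orientation; the caller is responsible for sign flips.
    """
    supp, _ = _find_sparse_mode(net.S, net.lb, net.ub, query.J, query.P,
                                query.singleton, eps, scale)
    return frozenset(supp)


# ---------------------------------------------------------------------------
# The greedy reconstruction
# ---------------------------------------------------------------------------

def fastcore(
    net: MetNet,
    C: Iterable[int],
    eps: float = DEFAULT_EPS,
    scale: float = DEFAULT_SCALE,
    check_input: bool = False,
) -> ReconstructionResult:
    """Greedy minimal-cardinality consistent superset of the core set.

    Precondition: ``net`` is flux consistent (run :func:`metnet.fastcc`
    first; ``check_input=True`` does this and restricts the search to the
    consistent part, raising :class:`InconsistentCoreError` when a core
    reaction is blocked).

    The loop alternates a dense-mode LP over the uncovered core with an
    L1-sparse mode over the remaining non-core reactions; when no core
    reaction is covered by the new mode, it escalates — first flipping the
    reversible members of the uncovered core, then testing reactions one by
    one (*singleton* mode) in both orientations.  An empty core returns an
    empty reconstruction without solving any LP.
    """
    n = net.n_reactions
    C = sorted(set(int(i) for i in C))
    if C and (C[0] < 0 or C[-1] >= n):
        raise IndexError(f"core index out of range for n={n}")
    if not C:
        return ReconstructionResult(frozenset(), 0,
                                    induced_submodel(net, []), frozenset())

    if check_input:
        from .consistency import fastcc

        chk = fastcc(net, eps)
        if set(C) & chk.blocked:
            bad = sorted(set(C) & chk.blocked)
            raise InconsistentCoreError(
                f"core reactions blocked in the input network: "
                f"{[net.reaction_ids[i] for i in bad]}")
        if chk.blocked:
            keep = sorted(chk.consistent)
            back = np.asarray(keep)
            sub = induced_submodel(net, keep)
            pos = {orig: j for j, orig in enumerate(keep)}
            inner = fastcore(sub, [pos[i] for i in C], eps, scale,
                             check_input=False)
            A = frozenset(int(back[j]) for j in inner.A)
            return ReconstructionResult(
                A, inner.lp_calls + chk.lp_calls,
                induced_submodel(net, A), frozenset(A - set(C)))

    rev_set = set(net.reversible.tolist())
    irr_set = set(net.irreversible.tolist())
    work = _Working(net)
    lp_calls = 0

    J = sorted(set(C) & irr_set)
    P = set(range(n)) - set(C)
    supp, k = _find_sparse_mode(work.S, work.lb, work.ub, J, P,
                                False, eps, scale)
    lp_calls += k
    A = set(supp)
    if set(J) - A:
        bad = sorted(set(J) - A)
        raise InconsistentCoreError(
            f"irreversible core reactions cannot be activated: "
            f"{[net.reaction_ids[i] for i in bad]}")

    J = set(C) - A
    flipped = False
    singleton = False
    while J:
        P -= A
        supp, k = _find_sparse_mode(work.S, work.lb, work.ub, sorted(J), P,
                                    singleton, eps, scale)
        lp_calls += k
        A |= supp
        if A & J:
            J -= A
            flipped = False
        else:
            target = [min(J)] if singleton else sorted(J)
            target_rev = [i for i in target if i in rev_set]
            if flipped or not target_rev:
                if singleton:
                    rid = net.reaction_ids[min(J)]
                    raise InconsistentCoreError(
                        f"core reaction {rid!r} cannot be activated in "
                        f"either orientation; input network inconsistent")
                flipped = False
                singleton = True
            else:
                work.flip(target_rev)
                flipped = True

    A_frozen = frozenset(A)
    return ReconstructionResult(A_frozen, lp_calls,
                                induced_submodel(net, A),
                                frozenset(A - set(C)))
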