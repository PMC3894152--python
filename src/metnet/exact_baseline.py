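"""Exact small-scale machinery: elementary modes, MILP reconstruction,
and the consistency-by-union-of-modes check.

Any union of supports of modes of a network induces a consistent
subnetwork (each truncated mode remains a mode of the induced model and
witnesses every reaction of the union).  The minimal consistent superset of
a core set can therefore be found by searching over sets of *elementary*
modes, whose supports cover every unblocked reaction; with the full
elementary-mode list the search is a mixed-integer set-cover program solved
exactly here.  None of this scales beyond toy networks — elementary-mode
counts explode combinatorially — which is precisely why the greedy
:func:`metnet.fastcore` exists; this module is the ground truth it is
measured against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import null_space
from scipy.optimize import LinearConstraint, milp

from .consistency import DEFAULT_EPS, READBACK, fastcc, fva_check
from .lp import SolverError
from .model import MetNet, induced_submodel, support
from .reconstruction import InconsistentCoreError

__all__ = [
    "EMSet",
    "ExactReconstruction",
    "enumerate_elementary_modes",
    "milp9_reconstruct",
    "theorem1_check",
    "minimal_consistent_superset_bruteforce",
]

#: Relative tolerance for "zero" entries of a kernel vector.
_KERNEL_TOL = 1e-9


@dataclass(frozen=True)
class EMSet:
    """Supports of all elementary modes of a network.

    ``incidence`` is an ``r x n`` boolean matrix (one row per mode);
    ``witnesses`` holds one feasible flux vector per mode with exactly that
    support.
    """

    incidence: np.ndarray = field(repr=False)
    witnesses: tuple[np.ndarray, ...] = field(repr=False)

    @property
    def r(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.incidence.shape[1]

    @property
    def supports(self) -> tuple[frozenset[int], ...]:
        return tuple(frozenset(np.nonzero(row)[0].tolist())
                     for row in self.incidence)

    def union_of_supports(self) -> frozenset[int]:
        if self.r == 0:
            return frozenset()
        return frozenset(np.nonzero(self.incidence.any(axis=0))[0].tolist())


@dataclass(frozen=True)
class ExactReconstruction:
    """Optimal solution of the set-cover MILP.

    ``y`` is the binary reaction-selection vector, ``z`` the (continuous,
    selected-by-positivity) mode-selection vector; ``A = supp(y)`` and
    ``objective = |A|`` is provably minimal.
    """

    y: np.ndarray = field(repr=False)
    z: np.ndarray = field(repr=False)
    A: frozenset[int]
    objective: int


def enumerate_elementary_modes(net: MetNet, max_n: int = 20) -> EMSet:
    """Complete elementary-mode support enumeration (toy scale only).

    A support ``T`` belongs to an elementary mode iff the kernel of
    ``S[:, T]`` is one-dimensional, its generating vector has full support
    over ``T``, and one of its two orientations respects every
    irreversibility constraint in ``T``.  Supports are searched in order of
    increasing size with superset pruning, which enforces support
    minimality directly.  Refuses models with more than ``max_n`` reactions.
    """
    n = net.n_reactions
    if n > max_n:
        raise ValueError(
            f"model has {n} reactions; elementary-mode enumeration is "
            f"capped at max_n={max_n}")
    S = net.dense_S()
    irrev_mask = net.lb >= 0
    accepted: list[frozenset[int]] = []
    witnesses: list[np.ndarray] = []

    for size in range(1, n + 1):
        for T in combinations(range(n), size):
            Tset = frozenset(T)
            if any(a <= Tset for a in accepted):
                continue
            ker = null_space(S[:, T])
            if ker.shape[1] != 1:
                continue
            w = ker[:, 0]
            amax = np.abs(w).max()
            if amax == 0 or np.abs(w).min() < _KERNEL_TOL * amax:
                continue                     # kernel vector not full-support
            irr = irrev_mask[list(T)]
            if irr.any():
                if (w[irr] > 0).all():
                    pass
                elif (w[irr] < 0).all():
                    w = -w
                else:
                    continue                 # no orientation respects I
            elif w[0] < 0:
                w = -w                       # canonical sign for dedup
            witness = _bounded_witness(net, T, w)
            if witness is None:
                continue                     # direction shut off by bounds
            accepted.append(Tset)
            witnesses.append(witness)

    incidence = np.zeros((len(accepted), n), dtype=bool)
    for j, Tset in enumerate(accepted):
        incidence[j, sorted(Tset)] = True
    return EMSet(incidence, tuple(witnesses))


def _bounded_witness(net: MetNet, T: Sequence[int], w: np.ndarray,
                     eps: float = DEFAULT_EPS) -> np.ndarray | None:
    """Embed the kernel direction as a within-bounds mode, aiming for all
    support fluxes >= eps.  Returns None when the bounds forbid the
    direction entirely."""
    idx = np.asarray(T, dtype=int)
    lo, hi = net.lb[idx], net.ub[idx]
    with np.errstate(divide="ignore"):
        pos, neg = w > 0, w < 0
        caps = np.concatenate([hi[pos] / w[pos], lo[neg] / w[neg]])
    c_max = caps.min() if caps.size else np.inf
    if not c_max > 0:
        return None
    c = min(eps / np.abs(w).min(), c_max)
    v = np.zeros(net.n_reactions)
    v[idx] = c * w
    return v


def milp9_reconstruct(ems: EMSet, C: Iterable[int]) -> ExactReconstruction:
    """Exact minimal consistent superset of the core via set-cover MILP.

    Decision variables: binary ``y`` (length n, reaction selected) and
    continuous ``z`` in [0,1] (length r, mode selected by positivity).
    Constraints: ``y >= (1/r) * M z`` elementwise (any covered reaction is
    selected) and ``M z >= c`` elementwise (each core reaction is covered
    by at least one selected mode); objective ``min sum(y)``.  Requires an
    optimality gap of zero — this is the ground truth.
    """
    n, r = ems.n_reactions, ems.r
    C = sorted(set(int(i) for i in C))
    if C and (C[0] < 0 or C[-1] >= n):
        raise IndexError(f"core index out of range for n={n}")
    if not C:
        return ExactReconstruction(np.zeros(n), np.zeros(r), frozenset(), 0)
    covered = ems.union_of_supports()
    orphans = sorted(set(C) - covered)
    if orphans:
        raise InconsistentCoreError(
            f"core reactions {orphans} appear in no elementary mode "
            f"(blocked)")

    M = ems.incidence.astype(float).T       # n x r
    cost = np.concatenate([np.ones(n), np.zeros(r)])
    # (1/r) M z - y <= 0
    A1 = np.hstack([-np.eye(n), M / r])
    con1 = LinearConstraint(A1, -np.inf, 0.0)
    # core coverage: M[C,:] z >= 1
    A2 = np.hstack([np.zeros((len(C), n)), M[C, :]])
    con2 = LinearConstraint(A2, 1.0, np.inf)
    integrality = np.concatenate([np.ones(n), np.zeros(r)])
    from scipy.optimize import Bounds

    res = milp(cost, constraints=[con1, con2], integrality=integrality,
               bounds=Bounds(0.0, 1.0),
               options={"mip_rel_gap": 0.0})
    if res.status != 0:
        raise SolverError(f"MILP did not reach proven optimality: "
                          f"status={res.status} ({res.message})")
    y = np.round(res.x[:n])
    z = res.x[n:]
    A = frozenset(np.nonzero(y > 0.5)[0].tolist())
    return ExactReconstruction(y, z, A, int(round(res.fun)))


def theorem1_check(net: MetNet, modes: Sequence[np.ndarray],
                   eps: float = DEFAULT_EPS) -> bool:
    """Induced subnetwork on a union of mode supports must be consistent.

    Validates each input vector (steady state and bounds within tolerance),
    takes the union of eps-supports, induces the submodel and runs
    :func:`fastcc`.  A False return signals an implementation bug, never a
    property of valid inputs.
    """
    union: set[int] = set()
    for v in modes:
        v = np.asarray(v, float)
        resid = np.abs(net.S @ v).max() if v.size else 0.0
        vmax = max(1.0, float(np.abs(v).max())) if v.size else 1.0
        if resid > 1e-6 * vmax:
            raise ValueError(f"input vector violates steady state "
                             f"(residual {resid:.3g})")
        if ((v < net.lb - 1e-6 * vmax) | (v > net.ub + 1e-6 * vmax)).any():
            raise ValueError("input vector violates flux bounds")
        union.update(support(v, READBACK * eps).tolist())
    if not union:
        return True
    sub = induced_submodel(net, sorted(union))
    return len(fastcc(sub, eps).blocked) == 0


def minimal_consistent_superset_bruteforce(
    net: MetNet,
    C: Iterable[int],
    eps: float = DEFAULT_EPS,
    max_n: int = 12,
) -> frozenset[int]:
    """Exhaustive minimal consistent superset of ``C`` (oracle, n <= max_n).

    Enumerates reaction subsets containing ``C`` in order of increasing
    size and returns the first whose induced submodel has an empty blocked
    set under FVA.
    """
    n = net.n_reactions
    if n > max_n:
        raise ValueError(f"brute force capped at n={max_n}, got {n}")
    C = sorted(set(int(i) for i in C))
    if not C:
        return frozenset()
    rest = [i for i in range(n) if i not in set(C)]
    for extra in range(len(rest) + 1):
        for combo in combinations(rest, extra):
            T = sorted(set(C) | set(combo))
            sub = induced_submodel(net, T)
            if len(fva_check(sub, eps).blocked) == 0:
                return frozenset(T)
    raise InconsistentCoreError(
        "no consistent superset exists; core contains blocked reactions")
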