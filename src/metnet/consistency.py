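"""Flux-consistency checkers.

A reaction is *blocked* when no steady-state flux vector within bounds gives
it a rate of magnitude at least ``eps``; a network with no blocked reactions
is *flux consistent*.  This module implements four checkers:

``lp2_feasibility_check``
    The single-LP test on the reversible-split network.  Documented unsound:
    the two irreversible copies of a blocked reversible reaction can carry
    equal flux and cancel, producing a false positive.
``cmc_check``
    Iterative certification built on a bounded sum-of-fluxes LP (the
    objective caps each tested flux at ``eps`` so the sum is finite).
    Complete, but the sum objective concentrates rather than spreads flux,
    so it can need more iterations than necessary.
``fastcc``
    Iterative certification built on the concave cardinality surrogate
    (one auxiliary variable ``z_i = min(v_i, eps)`` per tested reaction,
    maximizing their sum).  Complete, and typically certifies the whole
    consistent part of the irreversible reactions in a single LP.
``fva_check``
    Exhaustive per-reaction flux-variability analysis (<= 2 LPs per
    reaction).  Slowest, but the natural ground-truth oracle.

All checkers return a :class:`ConsistencyResult` carrying the partition, the
LP-call count, a certification trace and one witness mode per consistent
reaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .lp import LPSolution, SolverError, solve_lp
from .model import MetNet

__all__ = [
    "ConsistencyResult",
    "DEFAULT_EPS",
    "lp2_feasibility_check",
    "lp3_max_flux_sum",
    "lp7_maximize_active",
    "cmc_check",
    "fastcc",
    "fva_check",
]

logger = logging.getLogger(__name__)

#: Flux threshold below which a rate counts as zero.
DEFAULT_EPS = 1e-4

#: Fraction of eps used when reading solver fluxes back, absorbing the
#: floating-point slack of solutions that sit exactly on the eps constraint.
READBACK = 0.99

#: Noise floor for scaled-witness certification: fluxes below this fraction
#: of eps are treated as solver noise and never certified by scaling.
_SCALE_FLOOR = 1e-2


@dataclass(frozen=True)
class ConsistencyResult:
    """Partition of the reaction set into consistent and blocked.

    ``trace`` lists ``(lp_index, newly_certified)`` pairs in solve order
    (1-based LP index); ``witnesses`` maps each consistent reaction to a
    stored mode with that coordinate of magnitude >= READBACK*eps, expressed
    in the original orientation of the input model.
    """

    consistent: frozenset[int]
    blocked: frozenset[int]
    lp_calls: int
    trace: tuple[tuple[int, frozenset[int]], ...] = ()
    witnesses: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.consistent & self.blocked:
            raise ValueError("consistent and blocked sets overlap")

    @property
    def n_reactions(self) -> int:
        return len(self.consistent) + len(self.blocked)


# ---------------------------------------------------------------------------
# LP building blocks
# ---------------------------------------------------------------------------

def _steady_state_eq(S: sp.sparray, n_aux: int):
    m, n = S.shape
    if n_aux:
        A = sp.hstack([sp.csc_array(S), sp.csc_array((m, n_aux))])
    else:
        A = sp.csc_array(S)
    return A, np.zeros(m)


def _lp7(S, lb, ub, J, eps) -> LPSolution:
    """max sum_{i in J} z_i  s.t.  S v = 0, lb<=v<=ub, 0<=z<=eps, z_i<=v_i."""
    m, n = S.shape
    J = list(J)
    k = len(J)
    A_eq, b_eq = _steady_state_eq(S, k)
    # z_j - v_{J[j]} <= 0
    rows = np.repeat(np.arange(k), 2)
    cols = np.empty(2 * k, dtype=int)
    vals = np.empty(2 * k)
    cols[0::2], vals[0::2] = np.add(J, 0), -1.0
    cols[1::2], vals[1::2] = n + np.arange(k), 1.0
    A_ub = sp.csc_array((vals, (rows, cols)), shape=(k, n + k))
    c = np.concatenate([np.zeros(n), np.ones(k)])
    bounds = [(float(l), float(u)) for l, u in zip(lb, ub)]
    bounds += [(0.0, float(eps))] * k
    sol = solve_lp(c, A_eq, b_eq, A_ub, np.zeros(k), bounds,
                   n_keep=n, maximize=True)
    if sol.status == "infeasible":
        raise SolverError(
            "steady-state system infeasible: malformed model bounds")
    return sol


def _lp3(S, lb, ub, J, eps) -> LPSolution:
    """max sum_{i in J} v_i with v_i (i in J) capped at eps for boundedness."""
    m, n = S.shape
    A_eq, b_eq = _steady_state_eq(S, 0)
    c = np.zeros(n)
    c[list(J)] = 1.0
    bounds = [(float(l), float(u)) for l, u in zip(lb, ub)]
    for i in J:
        l, u = bounds[i]
        bounds[i] = (l, min(u, max(eps, l)))
    return solve_lp(c, A_eq, b_eq, bounds=bounds, n_keep=n, maximize=True)


def lp7_maximize_active(net: MetNet, J, eps: float = DEFAULT_EPS) -> LPSolution:
    """Cardinality-surrogate LP: push as many fluxes in ``J`` to >= eps.

    Reactions in ``J`` are tested for *positive* flux; reversible members
    must have been flipped by the caller into the orientation under test.
    """
    J = sorted(set(J))
    if not J:
        raise ValueError("J must be nonempty")
    return _lp7(net.S, net.lb, net.ub, J, eps)


def lp3_max_flux_sum(net: MetNet, J, eps: float = DEFAULT_EPS) -> LPSolution:
    """Bounded sum-of-fluxes LP over ``J`` (each tested flux capped at eps)."""
    J = sorted(set(J))
    if not J:
        raise ValueError("J must be nonempty")
    sol = _lp3(net.S, net.lb, net.ub, J, eps)
    if sol.status == "unbounded":
        raise SolverError("LP-3 unbounded: flux caps missing")
    return sol


def lp2_feasibility_check(net: MetNet, eps: float = DEFAULT_EPS) -> bool:
    """Single-LP consistency test on the reversible-split network.

    Each reversible reaction becomes two irreversible copies (net flux =
    forward minus backward); the test asks whether a steady state exists
    with *every* split-network flux >= eps.  Unsound: both copies of a
    blocked reversible reaction can carry equal flux and cancel.
    """
    cols = [sp.csc_array(net.S)]
    lo = np.maximum(net.lb, eps)
    hi = net.ub.copy()
    rev = net.reversible
    if rev.size:
        cols.append(sp.csc_array(-net.S[:, rev]))
        lo[rev] = eps
        lo = np.concatenate([lo, np.full(rev.size, eps)])
        hi = np.concatenate([hi, -net.lb[rev]])
    S_split = sp.hstack(cols) if len(cols) > 1 else cols[0]
    n_split = S_split.shape[1]
    A_eq, b_eq = _steady_state_eq(S_split, 0)
    sol = solve_lp(np.zeros(n_split), A_eq, b_eq,
                   bounds=list(zip(lo.tolist(), hi.tolist())))
    return sol.status == "optimal"


# ---------------------------------------------------------------------------
# Certification helpers
# ---------------------------------------------------------------------------

def _max_uniform_scale(v, lb, ub) -> float:
    """Largest c >= 1 with c*v still within bounds (c*v is again a mode)."""
    with np.errstate(divide="ignore"):
        pos = v > 1e-12
        neg = v < -1e-12
        ratios = np.concatenate([ub[pos] / v[pos], lb[neg] / v[neg]])
    if ratios.size == 0:
        return 1.0
    return max(1.0, float(ratios.min()))


def _certified_plain(v, eps) -> np.ndarray:
    return np.abs(v) >= READBACK * eps


def _certified_scaled(v, lb, ub, eps) -> np.ndarray:
    """Certify via the best uniformly scaled witness.

    Steady state is homogeneous, so ``c*v`` is a mode for any ``c`` that
    respects the bounds; a flux below eps in ``v`` may still witness
    consistency once scaled up.  Fluxes under the noise floor are ignored.
    """
    a = np.abs(v)
    c = _max_uniform_scale(v, lb, ub)
    return (a >= READBACK * eps) | (
        (a >= _SCALE_FLOOR * eps) & (c * a >= READBACK * eps))


class _Working:
    """Mutable oriented copy of a model for the iterative checkers."""

    def __init__(self, net: MetNet):
        self.S = sp.csc_array(net.S, copy=True)
        self.lb = net.lb.copy()
        self.ub = net.ub.copy()
        self.orient = np.ones(net.n_reactions)

    def flip(self, idx) -> None:
        idx = list(idx)
        sign = np.ones(self.S.shape[1])
        sign[idx] = -1.0
        self.S = sp.csc_array(self.S @ sp.diags_array(sign))
        lo, hi = self.lb[idx].copy(), self.ub[idx].copy()
        self.lb[idx], self.ub[idx] = -hi, -lo
        self.orient[idx] *= -1.0

    def to_original(self, v: np.ndarray) -> np.ndarray:
        return self.orient * v


# ---------------------------------------------------------------------------
# Iterative checkers
# ---------------------------------------------------------------------------

def _iterative_check(net: MetNet, eps: float, use_lp7: bool,
                     irreversibles_first: bool) -> ConsistencyResult:
    n = net.n_reactions
    locked = set(net.zero_locked.tolist())        # lb = ub = 0: no LP needed
    N = set(range(n)) - locked
    rev_set = set(net.reversible.tolist())
    work = _Working(net)

    lp_idx = 0
    A: set[int] = set()
    blocked: set[int] = set(locked)
    trace: list[tuple[int, frozenset[int]]] = []
    witnesses: dict[int, np.ndarray] = {}

    def run(J_sorted) -> np.ndarray:
        nonlocal lp_idx
        sol = (_lp7 if use_lp7 else _lp3)(work.S, work.lb, work.ub,
                                          J_sorted, eps)
        lp_idx += 1
        if not sol.optimal:
            raise SolverError(f"consistency LP #{lp_idx} not optimal: "
                              f"{sol.status}")
        return sol.v

    def certify(v: np.ndarray) -> int:
        if use_lp7:
            mask = _certified_plain(v, eps)
        else:
            mask = _certified_scaled(v, work.lb, work.ub, eps)
        newly = {i for i in N - A if mask[i]}
        orig = work.to_original(v)
        for i in newly:
            witnesses[i] = orig
        A.update(newly)
        trace.append((lp_idx, frozenset(newly)))
        logger.info("LP #%d certified %d reaction(s); %d of %d done",
                    lp_idx, len(newly), len(A), len(N))
        return len(newly)

    if irreversibles_first:
        J0 = sorted(set(net.irreversible.tolist()) & N)
        if J0:
            certify(run(J0))
        J = set(N) - A
    else:
        J = set(N)

    flipped = False
    singleton = False
    while J:
        Ji = [min(J)] if singleton else sorted(J)
        progress = certify(run(Ji)) > 0
        if progress:
            J -= A
            flipped = False
        else:
            Ji_rev = [i for i in Ji if i in rev_set]
            if flipped or not Ji_rev:
                flipped = False
                if singleton:
                    i0 = Ji[0]
                    blocked.add(i0)
                    J.discard(i0)
                else:
                    singleton = True
            else:
                work.flip(Ji_rev)
                flipped = True

    return ConsistencyResult(frozenset(A), frozenset(blocked), lp_idx,
                             tuple(trace), witnesses)


def fastcc(net: MetNet, eps: float = DEFAULT_EPS) -> ConsistencyResult:
    """Detect the consistent part of ``net`` with the LP-7 surrogate.

    The first LP tests all irreversible reactions at once (a single LP
    typically certifies every unblocked one); remaining reactions are then
    retested with en-bloc sign flips of the uncertified reversibles, and
    stubborn reactions fall back to one-by-one testing in both orientations.
    Complete: the blocked set equals the FVA oracle's.
    """
    return _iterative_check(net, eps, use_lp7=True, irreversibles_first=True)


def cmc_check(net: MetNet, eps: float = DEFAULT_EPS) -> ConsistencyResult:
    """Iterative consistency check driven by the capped sum-of-fluxes LP.

    Complete like :func:`fastcc`, but the sum objective routes flux through
    few high-throughput pathways, so parallel routes may need extra
    iterations to certify.  Certification reads fluxes back through the
    best within-bounds uniform scaling of the solution, so a genuinely
    nonzero flux below eps (e.g. forced down by a stoichiometric
    coefficient > 1) still certifies.
    """
    return _iterative_check(net, eps, use_lp7=False, irreversibles_first=False)


def fva_check(net: MetNet, eps: float = DEFAULT_EPS) -> ConsistencyResult:
    """Exhaustive flux-variability consistency oracle (<= 2 LPs/reaction)."""
    n = net.n_reactions
    locked = set(net.zero_locked.tolist())
    A_eq, b_eq = _steady_state_eq(net.S, 0)
    bounds = [(float(l), float(u)) for l, u in zip(net.lb, net.ub)]
    lp_idx = 0
    consistent: set[int] = set()
    blocked: set[int] = set(locked)
    trace: list[tuple[int, frozenset[int]]] = []
    witnesses: dict[int, np.ndarray] = {}

    for i in range(n):
        if i in locked:
            continue
        c = np.zeros(n)
        c[i] = 1.0
        found = False
        for maximize in (True, False):
            if not maximize and net.lb[i] >= 0:
                break                      # irreversible: min flux is >= 0
            sol = solve_lp(c, A_eq, b_eq, bounds=bounds, maximize=maximize)
            lp_idx += 1
            if not sol.optimal:
                raise SolverError(f"FVA LP for reaction {i} returned "
                                  f"{sol.status}")
            if abs(sol.objective) >= READBACK * eps:
                consistent.add(i)
                witnesses[i] = sol.v
                trace.append((lp_idx, frozenset({i})))
                found = True
                break
        if not found:
            blocked.add(i)
    return ConsistencyResult(frozenset(consistent), frozenset(blocked),
                             lp_idx, tuple(trace), witnesses)
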