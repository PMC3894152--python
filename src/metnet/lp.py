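"""Thin wrapper around scipy's HiGHS LP interface.

Every optimization problem in this package is funnelled through
:func:`solve_lp` so that status handling, tolerances and call accounting are
uniform.  Any solver status other than optimal/infeasible/unbounded raises
:class:`SolverError`: silent near-feasibility would corrupt blocked sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = ["LPSolution", "SolverError", "solve_lp"]

# Requested solver tolerances; tighter than the certification threshold
# (0.99*eps with eps=1e-4) by several orders of magnitude.
FEASIBILITY_TOL = 1e-9

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


class SolverError(RuntimeError):
    """The LP/MILP solver returned an unusable status."""


@dataclass(frozen=True)
class LPSolution:
    """Outcome of one linear program.

    ``v`` holds the flux-variable block of the solution (auxiliary epigraph
    variables are stripped by the callers); ``objective`` is reported for the
    original maximization/minimization sense of the calling routine.
    """

    status: str
    v: np.ndarray | None
    objective: float

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve_lp(
    c: np.ndarray,
    A_eq: sp.sparray | None = None,
    b_eq: np.ndarray | None = None,
    A_ub: sp.sparray | None = None,
    b_ub: np.ndarray | None = None,
    bounds: list[tuple[float, float]] | None = None,
    n_keep: int | None = None,
    maximize: bool = False,
) -> LPSolution:
    """Solve ``min c@x`` (or max) subject to equality/inequality constraints.

    ``n_keep`` truncates the returned variable vector to its first entries
    (the flux block) when auxiliary variables were appended.
    """
    c = np.asarray(c, float)
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * c,
        A_eq=A_eq, b_eq=b_eq,
        A_ub=A_ub, b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )
    status = _STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failed: status={res.status} "
                          f"({res.message})")
    if status != "optimal":
        return LPSolution(status, None, float("nan"))
    x = np.asarray(res.x, float)
    if n_keep is not None:
        x = x[:n_keep]
    return LPSolution("optimal", x, float(sign * res.fun))
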