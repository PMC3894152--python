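"""Stoichiometric network container and structural operations.

A metabolic network is represented by an ``m x n`` stoichiometric matrix
``S`` (metabolites x reactions), per-reaction flux bounds ``lb <= v <= ub``
and the derived irreversibility classification.  A steady-state flux vector
(*mode*) satisfies ``S @ v = 0`` within the bounds.  All algorithms in this
package operate on :class:`MetNet` instances; reactions and metabolites are
addressed by 0-based column/row index internally and by id string at every
file interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MetNet",
    "ModelError",
    "DuplicateIdentifierError",
    "MissingBoundsError",
    "build_network",
    "induced_submodel",
    "flip_reactions",
    "scale_bounds",
    "support",
]


class ModelError(ValueError):
    """Malformed network model (parse failure or invariant violation)."""


class DuplicateIdentifierError(ModelError):
    """A reaction or metabolite id occurs more than once."""


class MissingBoundsError(ModelError):
    """A reaction carries no flux bounds."""


@dataclass(frozen=True)
class MetNet:
    """Immutable stoichiometric network.

    Attributes
    ----------
    metabolite_ids, reaction_ids
        Unique id strings; row/column order of ``S``.
    S
        ``m x n`` sparse stoichiometric matrix (CSC).
    lb, ub
        Length-``n`` finite flux bounds, ``lb <= ub`` elementwise.

    A reaction is *reversible* iff ``lb < 0``; the irreversible index set is
    ``I = {i : lb_i >= 0}``.  Any "reversible" flag in an input file is
    ignored when it contradicts the bounds.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: sp.csc_array = field(repr=False)
    lb: np.ndarray = field(repr=False)
    ub: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m, n = self.S.shape
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != n:
            raise ModelError(
                f"shape mismatch: S is {m}x{n} but "
                f"{len(self.metabolite_ids)} metabolites / "
                f"{len(self.reaction_ids)} reactions declared"
            )
        for kind, ids in (("metabolite", self.metabolite_ids),
                          ("reaction", self.reaction_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if list(ids).count(x) > 1})
                raise DuplicateIdentifierError(f"duplicate {kind} ids: {dup}")
        lb, ub = np.asarray(self.lb, float), np.asarray(self.ub, float)
        if lb.shape != (n,) or ub.shape != (n,):
            raise ModelError("bounds must be length-n vectors")
        if not (np.isfinite(lb).all() and np.isfinite(ub).all()):
            raise MissingBoundsError("non-finite flux bound")
        if (lb > ub).any():
            bad = [self.reaction_ids[i] for i in np.nonzero(lb > ub)[0]]
            raise ModelError(f"lb > ub for reactions {bad}")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)
        object.__setattr__(self, "S", sp.csc_array(self.S, dtype=float))

    # -- basic views -------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def reversible_mask(self) -> np.ndarray:
        """Boolean mask of reversible reactions (``lb < 0``)."""
        return self.lb < 0

    @property
    def irreversible(self) -> np.ndarray:
        """Sorted indices of irreversible reactions (``lb >= 0``)."""
        return np.nonzero(self.lb >= 0)[0]

    @property
    def reversible(self) -> np.ndarray:
        """Sorted indices of reversible reactions (``lb < 0``)."""
        return np.nonzero(self.lb < 0)[0]

    @property
    def zero_locked(self) -> np.ndarray:
        """Indices with ``lb == ub == 0``: analytically blocked, no LP needed."""
        return np.nonzero((self.lb == 0) & (self.ub == 0))[0]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def reaction_indices(self, rids: Iterable[str]) -> list[int]:
        return [self.reaction_index(r) for r in rids]

    def dense_S(self) -> np.ndarray:
        return self.S.toarray()


def build_network(
    metabolite_ids: Sequence[str],
    reactions: Sequence[tuple[str, dict[str, float], float, float]],
) -> MetNet:
    """Assemble a :class:`MetNet` from (id, stoichiometry, lb, ub) tuples.

    ``stoichiometry`` maps metabolite id to coefficient (negative =
    consumed).  Metabolites referenced by a reaction must appear in
    ``metabolite_ids``.
    """
    met_ids = tuple(metabolite_ids)
    row = {mid: i for i, mid in enumerate(met_ids)}
    if len(row) != len(met_ids):
        raise DuplicateIdentifierError("duplicate metabolite ids")
    rows, cols, vals = [], [], []
    rids, lbs, ubs = [], [], []
    for j, (rid, stoich, lb, ub) in enumerate(reactions):
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        for mid, coef in stoich.items():
            if mid not in row:
                raise ModelError(
                    f"reaction {rid!r} references unknown metabolite {mid!r}")
            if coef != 0:
                rows.append(row[mid])
                cols.append(j)
                vals.append(float(coef))
    S = sp.csc_array(
        (vals, (rows, cols)), shape=(len(met_ids), len(reactions)))
    return MetNet(met_ids, tuple(rids), S,
                  np.asarray(lbs, float), np.asarray(ubs, float))


def induced_submodel(net: MetNet, A: Iterable[int]) -> MetNet:
    """Submodel keeping exactly the reaction columns in ``A``.

    Column order of the input is preserved; metabolites that participate in
    no kept reaction (all-zero rows) are dropped.  Theorem-style arguments
    about induced subnetworks concern columns only, so empty rows are inert
    constraints and safe to prune.
    """
    idx = np.asarray(sorted(set(A)), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= net.n_reactions):
        raise IndexError(f"reaction index out of range for n={net.n_reactions}")
    S = net.S[:, idx] if idx.size else sp.csc_array((net.n_metabolites, 0))
    keep_rows = np.nonzero(abs(S).sum(axis=1) > 0)[0]
    S = S[keep_rows, :]
    return MetNet(
        tuple(net.metabolite_ids[i] for i in keep_rows),
        tuple(net.reaction_ids[i] for i in idx),
        sp.csc_array(S),
        net.lb[idx].copy(),
        net.ub[idx].copy(),
    )


def flip_reactions(net: MetNet, F: Iterable[int]) -> MetNet:
    """Reorient the reversible reactions in ``F``.

    For each ``i`` in ``F`` the i-th column of ``S`` is negated and the
    bounds become ``(-ub_i, -lb_i)``.  Flipping is an involution.  Only
    reversible reactions may be flipped.
    """
    idx = np.asarray(sorted(set(F)), dtype=int)
    if idx.size == 0:
        return net
    if idx.min() < 0 or idx.max() >= net.n_reactions:
        raise IndexError(f"reaction index out of range for n={net.n_reactions}")
    irrev = idx[net.lb[idx] >= 0]
    if irrev.size:
        bad = [net.reaction_ids[i] for i in irrev]
        raise ModelError(f"cannot flip irreversible reactions {bad}")
    sign = np.ones(net.n_reactions)
    sign[idx] = -1.0
    S = sp.csc_array(net.S @ sp.diags_array(sign))
    lb, ub = net.lb.copy(), net.ub.copy()
    lb[idx], ub[idx] = -net.ub[idx], -net.lb[idx]
    return MetNet(net.metabolite_ids, net.reaction_ids, S, lb, ub)


def scale_bounds(net: MetNet, factor: float) -> MetNet:
    """Multiply all flux bounds by ``factor`` (> 0); ``S`` is unchanged.

    The blocked/consistent partition is invariant under any positive factor
    (steady-state constraints are homogeneous).
    """
    if not factor > 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    return MetNet(net.metabolite_ids, net.reaction_ids, net.S,
                  net.lb * factor, net.ub * factor)


def support(v: np.ndarray, tol: float) -> np.ndarray:
    """Indices ``{i : |v_i| >= tol}`` of the flux vector ``v``."""
    if not tol > 0:
        raise ValueError(f"support threshold must be positive, got {tol}")
    v = np.asarray(v, float)
    if not np.isfinite(v).all():
        raise ValueError("flux vector has non-finite entries")
    return np.nonzero(np.abs(v) >= tol)[0]


def warn_reversible_flag_mismatch(rid: str, flag: bool, lb: float) -> None:
    """Reversibility is defined by ``lb < 0``; warn when a file flag disagrees."""
    if flag != (lb < 0):
        warnings.warn(
            f"reaction {rid!r}: 'reversible' flag {flag} contradicts "
            f"lower bound {lb}; bounds take precedence",
            stacklevel=3,
        )
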