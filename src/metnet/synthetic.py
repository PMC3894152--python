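"""Deterministic test inputs and the sub-sampling validation protocol.

Provides the six-reaction toy network used throughout the documentation
(one blocked reversible dead-end, one stoichiometric coefficient of 2 on
the boundary inflow), a seeded random generator of flux-consistent
networks, core-set samplers, a planted-module network for enrichment
studies, and the repeated random sub-sampling validation with its exact
hypergeometric enrichment test.

The random generator emulates the gross structure of genome-scale models —
sparse internal conversions with small integer stoichiometry, a minority of
reversible reactions, boundary exchanges on a subset of metabolites — and
enforces flux consistency post hoc by restriction to the FVA-consistent
part.  It does not emulate gene rules, compartments, or realistic degree
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

import numpy as np

from .consistency import DEFAULT_EPS, fva_check
from .model import MetNet, build_network, induced_submodel
from .reconstruction import DEFAULT_SCALE, fastcore

__all__ = [
    "FIG1_REACTIONS",
    "FIG1_BLOCKED",
    "GeneratorParams",
    "ValidationReport",
    "figure1_network",
    "figure1_consistent_part",
    "random_consistent_network",
    "planted_module_network",
    "sample_core",
    "hypergeometric_enrichment_p",
    "subsampling_validation",
]

#: Reaction ids of the toy network, in column order.
FIG1_REACTIONS = ("r1_src_2A", "r2_A_B", "r3_A_C",
                  "r4_C_D", "r5_A_D", "r6_D_snk")

#: The single blocked reaction of the toy network (reversible dead end).
FIG1_BLOCKED = "r2_A_B"


def figure1_network() -> MetNet:
    """Four-metabolite, six-reaction toy network with one blocked reaction.

    Reactions (all coefficients 1 except the 2 on the inflow):

    ========== =====================  ==========
    id         reaction               bounds
    ========== =====================  ==========
    r1_src_2A  ∅ → 2 A                [0, 10]
    r2_A_B     A ↔ B  (dead end)      [-10, 10]
    r3_A_C     A → C                  [0, 10]
    r4_C_D     C → D                  [0, 10]
    r5_A_D     A → D                  [0, 10]
    r6_D_snk   D → ∅                  [0, 10]
    ========== =====================  ==========

    ``A ↔ B`` is the only reversible reaction and, having no other
    consumer/producer of B, the only blocked one.  The bound values are a
    fixture choice; every qualitative behaviour of the network (including
    the sum-of-fluxes LP preferring the A→C→D route, 3.5x vs 2.5x the
    per-reaction cap) depends only on boundedness and the coefficient 2.
    """
    return build_network(
        ["A", "B", "C", "D"],
        [
            ("r1_src_2A", {"A": 2.0}, 0.0, 10.0),
            ("r2_A_B", {"A": -1.0, "B": 1.0}, -10.0, 10.0),
            ("r3_A_C", {"A": -1.0, "C": 1.0}, 0.0, 10.0),
            ("r4_C_D", {"C": -1.0, "D": 1.0}, 0.0, 10.0),
            ("r5_A_D", {"A": -1.0, "D": 1.0}, 0.0, 10.0),
            ("r6_D_snk", {"D": -1.0}, 0.0, 10.0),
        ],
    )


def figure1_consistent_part() -> MetNet:
    """The toy network minus its blocked reaction (5 reactions, B dropped)."""
    net = figure1_network()
    keep = [i for i, rid in enumerate(net.reaction_ids)
            if rid != FIG1_BLOCKED]
    return induced_submodel(net, keep)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the random consistent-network generator.

    ``n`` counts all reactions; about a quarter are reversible boundary
    exchanges so that mass balance is satisfiable, the rest internal
    conversions touching on average ``density`` metabolites each (never
    fewer than 2) with integer coefficients in {1, 2}.
    ``reversible_fraction`` applies to the internal reactions.  Bounds are
    ``[0, bound_magnitude]`` or ``[-bound_magnitude, bound_magnitude]``.
    """

    m: int = 12
    n: int = 24
    reversible_fraction: float = 0.3
    density: float = 3.0
    bound_magnitude: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.density < 2:
            raise ValueError("density must be >= 2")
        if not 0 <= self.reversible_fraction <= 1:
            raise ValueError("reversible_fraction must lie in [0, 1]")
        if not self.bound_magnitude > 0:
            raise ValueError("bound_magnitude must be positive")


def random_network(params: GeneratorParams,
                   rng: np.random.Generator | None = None) -> MetNet:
    """One raw seeded random draw; may contain blocked reactions.

    Sparse internal conversions plus reversible boundary exchanges on a
    random metabolite subset.  This is the unrestricted draw; use
    :func:`random_consistent_network` for a guaranteed consistent model.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    M = params.bound_magnitude
    n_exch = min(params.m, max(2, round(0.25 * params.n)))
    n_int = max(0, params.n - n_exch)
    mets = [f"M{i}" for i in range(params.m)]
    reactions = []
    for j in range(n_int):
        k = int(min(max(2, rng.poisson(params.density)),
                    min(params.m, 5)))
        chosen = rng.choice(params.m, size=k, replace=False)
        n_sub = int(rng.integers(1, k))
        stoich = {}
        for mi in chosen[:n_sub]:
            stoich[mets[mi]] = -float(rng.integers(1, 3))
        for mi in chosen[n_sub:]:
            stoich[mets[mi]] = float(rng.integers(1, 3))
        lb = -M if rng.random() < params.reversible_fraction else 0.0
        reactions.append((f"R{j}", stoich, lb, M))
    ex_mets = rng.choice(params.m, size=n_exch, replace=False)
    for e, mi in enumerate(sorted(ex_mets.tolist())):
        reactions.append((f"EX{e}_{mets[mi]}", {mets[mi]: -1.0}, -M, M))
    return build_network(mets, reactions)


def random_consistent_network(params: GeneratorParams,
                              eps: float = DEFAULT_EPS) -> MetNet:
    """Seeded random network, restricted to its flux-consistent part.

    Draws a sparse random stoichiometry plus boundary exchanges, runs the
    FVA oracle and returns the induced submodel on the consistent
    reactions.  Degenerate draws (fewer than 3 consistent reactions) are
    retried with fresh randomness from the same stream, up to a bounded
    number of attempts.  Identical params give identical output.
    """
    rng = np.random.default_rng(params.seed)
    for _attempt in range(30):
        net = random_network(params, rng)
        res = fva_check(net, eps)
        if len(res.consistent) >= 3:
            return induced_submodel(net, sorted(res.consistent))
    raise RuntimeError(
        "random network generation degenerated repeatedly; "
        "loosen the generator parameters")


def planted_module_network(
    n_chain: int = 10,
    n_decoys: int = 10,
    seed: int = 0,
    bound_magnitude: float = 100.0,
) -> tuple[MetNet, frozenset[int]]:
    """Consistent network with a planted linear pathway as core module.

    The module is an irreversible chain ``∅ → X_1 → ... → X_k → ∅`` whose
    interior steps form the core; ``n_decoys`` independent two-reaction
    import/export pairs provide non-core background.  Each interior chain
    step is the unique route between its neighbours, so a reconstruction
    from any sub-core of the chain must recover the left-out steps —
    the planted structure that the enrichment test is meant to detect.
    Reaction columns are shuffled by ``seed``.
    """
    if n_chain < 3:
        raise ValueError("n_chain must be >= 3")
    M = bound_magnitude
    mets = [f"X{i}" for i in range(1, n_chain + 1)]
    mets += [f"Y{d}" for d in range(n_decoys)]
    reactions = [("chain_in", {"X1": 1.0}, 0.0, M)]
    core_ids = []
    for i in range(1, n_chain):
        rid = f"chain_{i}_{i + 1}"
        reactions.append((rid, {f"X{i}": -1.0, f"X{i + 1}": 1.0}, 0.0, M))
        core_ids.append(rid)
    reactions.append(("chain_out", {f"X{n_chain}": -1.0}, 0.0, M))
    for d in range(n_decoys):
        reactions.append((f"decoy_in_{d}", {f"Y{d}": 1.0}, 0.0, M))
        reactions.append((f"decoy_out_{d}", {f"Y{d}": -1.0}, 0.0, M))
    order = np.random.default_rng(seed).permutation(len(reactions))
    reactions = [reactions[i] for i in order]
    net = build_network(mets, reactions)
    core = frozenset(net.reaction_index(rid) for rid in core_ids)
    return net, core


def sample_core(
    net: MetNet,
    fraction: float,
    seed: int,
    candidates: Iterable[int] | None = None,
) -> frozenset[int]:
    """Uniform sample without replacement of ``ceil(fraction * n_cand)``
    reactions from the candidate set (default: all reactions)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    cand = sorted(set(range(net.n_reactions) if candidates is None
                      else (int(i) for i in candidates)))
    if not cand:
        raise ValueError("empty candidate set")
    k = math.ceil(fraction * len(cand))
    rng = np.random.default_rng(seed)
    return frozenset(rng.choice(cand, size=k, replace=False).tolist())


def hypergeometric_enrichment_p(
    population: int,
    draws: int,
    successes_in_population: int,
    successes_observed: int,
) -> float:
    """Upper-tail hypergeometric probability ``P[X >= observed]``.

    Computed by exact big-integer summation of the probability mass
    function (no floating-point cancellation), then returned as a float.
    """
    Mpop, N, K, k = (int(population), int(draws),
                     int(successes_in_population), int(successes_observed))
    if min(Mpop, N, K, k) < 0 or K > Mpop or N > Mpop or k > min(N, K):
        raise ValueError(
            f"inconsistent counts: population={Mpop}, draws={N}, "
            f"successes={K}, observed={k}")
    denom = math.comb(Mpop, N)
    num = sum(math.comb(K, j) * math.comb(Mpop - K, N - j)
              for j in range(k, min(N, K) + 1))
    return float(Fraction(num, denom))


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the repeated random sub-sampling validation."""

    pvalues: tuple[float, ...]
    median_p: float
    reps: int
    subcore_fraction: float

    def __post_init__(self) -> None:
        if len(self.pvalues) != self.reps:
            raise ValueError("one p-value per repetition required")


def subsampling_validation(
    net: MetNet,
    C: Iterable[int],
    fraction: float = 0.8,
    reps: int = 50,
    eps: float = DEFAULT_EPS,
    seed: int = 0,
    scale: float = DEFAULT_SCALE,
) -> ValidationReport:
    """Repeated random sub-sampling validation of the reconstruction.

    Each repetition reconstructs from a random sub-core (``fraction`` of
    ``C``), then tests enrichment of the left-out core reactions among the
    non-sub-core reactions pulled into the reconstruction: population = all
    non-sub-core reactions of the network, draws = non-sub-core reactions
    in the reconstruction, successes = left-out core reactions, and the
    p-value is the exact upper-tail probability of observing at least the
    seen number of recovered left-out reactions.  All randomness flows
    from ``seed``.
    """
    C = sorted(set(int(i) for i in C))
    if not C:
        raise ValueError("core set must be nonempty")
    rng = np.random.default_rng(seed)
    n = net.n_reactions
    k = math.ceil(fraction * len(C))
    pvals = []
    for _rep in range(reps):
        sub = set(rng.choice(C, size=k, replace=False).tolist())
        rec = fastcore(net, sub, eps, scale)
        left_out = set(C) - sub
        population = n - len(sub)
        draws = len(rec.A - sub)
        observed = len(left_out & rec.A)
        if draws == 0:
            pvals.append(1.0)
        else:
            pvals.append(hypergeometric_enrichment_p(
                population, draws, len(left_out), observed))
    return ValidationReport(tuple(pvals), float(np.median(pvals)),
                            reps, fraction)
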