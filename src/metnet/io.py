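"""File formats: JSON network dialect, SBML L3/FBC read, id lists, flux TSV.

The JSON dialect is self-contained and round-trips exactly::

    {
      "metabolites": [{"id": "A"}, ...],
      "reactions": [
        {"id": "r1", "stoichiometry": {"A": 2.0}, "lb": 0.0, "ub": 10.0},
        ...
      ]
    }

SBML reading requires Level 3 with the ``fbc`` package supplying per-reaction
flux bound parameters.  SBML writing, gene rules and compartment semantics
are out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np

from .model import (
    DuplicateIdentifierError,
    MetNet,
    MissingBoundsError,
    ModelError,
    build_network,
    warn_reversible_flag_mismatch,
)

__all__ = [
    "load_model",
    "load_json_model",
    "load_sbml_model",
    "write_json_model",
    "read_reaction_set",
    "write_reaction_set",
    "write_flux_tsv",
]


def load_model(path: str | Path, format: str | None = None) -> MetNet:
    """Load a network from ``path``; ``format`` in {"json", "sbml"}.

    When ``format`` is None it is inferred from the file suffix
    (``.json`` -> JSON, ``.xml``/``.sbml`` -> SBML).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"json": "json", ".json": "json",
                  ".xml": "sbml", ".sbml": "sbml"}.get(suffix)
        if format is None:
            raise ModelError(f"cannot infer model format from {path.name!r}")
    if format == "json":
        return load_json_model(path)
    if format == "sbml":
        return load_sbml_model(path)
    raise ModelError(f"unknown model format {format!r}")


def load_json_model(path: str | Path) -> MetNet:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelError(f"invalid JSON in {path}: {exc}") from exc
    try:
        met_ids = [m["id"] for m in doc["metabolites"]]
        reactions = []
        for r in doc["reactions"]:
            if "lb" not in r or "ub" not in r:
                raise MissingBoundsError(
                    f"reaction {r.get('id')!r} lacks flux bounds")
            reactions.append((r["id"], dict(r["stoichiometry"]),
                              float(r["lb"]), float(r["ub"])))
    except (KeyError, TypeError) as exc:
        raise ModelError(f"malformed model document in {path}: {exc}") from exc
    return build_network(met_ids, reactions)


def write_json_model(net: MetNet, path: str | Path) -> None:
    Sc = net.S.tocoo()
    stoich: list[dict[str, float]] = [dict() for _ in net.reaction_ids]
    for i, j, x in zip(Sc.coords[0], Sc.coords[1], Sc.data):
        stoich[j][net.metabolite_ids[i]] = float(x)
    doc = {
        "metabolites": [{"id": m} for m in net.metabolite_ids],
        "reactions": [
            {"id": rid, "stoichiometry": stoich[j],
             "lb": float(net.lb[j]), "ub": float(net.ub[j])}
            for j, rid in enumerate(net.reaction_ids)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_sbml_model(path: str | Path) -> MetNet:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(k).getMessage()
                for k in range(doc.getNumErrors())]
        raise ModelError(f"SBML parse failure in {path}: {msgs[:3]}")
    model = doc.getModel()
    if model is None:
        raise ModelError(f"no model element in {path}")
    met_ids = [model.getSpecies(i).getId()
               for i in range(model.getNumSpecies())
               if not model.getSpecies(i).getBoundaryCondition()]
    met_set = set(met_ids)
    reactions = []
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        fbc = r.getPlugin("fbc")
        if fbc is None:
            raise MissingBoundsError(
                f"reaction {r.getId()!r} has no fbc flux bounds")
        lb = _bound_value(model, fbc.getLowerFluxBound(), r.getId(), "lower")
        ub = _bound_value(model, fbc.getUpperFluxBound(), r.getId(), "upper")
        stoich: dict[str, float] = {}
        for k in range(r.getNumReactants()):
            sr = r.getReactant(k)
            if sr.getSpecies() in met_set:
                stoich[sr.getSpecies()] = (
                    stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry())
        for k in range(r.getNumProducts()):
            sr = r.getProduct(k)
            if sr.getSpecies() in met_set:
                stoich[sr.getSpecies()] = (
                    stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry())
        warn_reversible_flag_mismatch(r.getId(), r.getReversible(), lb)
        reactions.append((r.getId(), stoich, lb, ub))
    return build_network(met_ids, reactions)


def _bound_value(model, param_id: str, rid: str, which: str) -> float:
    if not param_id:
        raise MissingBoundsError(f"reaction {rid!r} has no {which} flux bound")
    p = model.getParameter(param_id)
    if p is None or not p.isSetValue():
        raise MissingBoundsError(
            f"reaction {rid!r}: {which} bound parameter {param_id!r} unset")
    return float(p.getValue())


def read_reaction_set(path: str | Path) -> list[str]:
    """Newline-delimited reaction id list; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_reaction_set(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid in ids:
            fh.write(f"{rid}\n")


def write_flux_tsv(net: MetNet, v: np.ndarray, path: str | Path) -> None:
    """Flux vector as two-column TSV (reaction id, rate)."""
    v = np.asarray(v, float)
    if v.shape != (net.n_reactions,):
        raise ValueError("flux vector length does not match reaction count")
    with open(path, "w") as fh:
        fh.write("reaction\tflux\n")
        for rid, x in zip(net.reaction_ids, v):
            fh.write(f"{rid}\t{x:.12g}\n")
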