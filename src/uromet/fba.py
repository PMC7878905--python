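"""Constraint-based in silico gene knockouts (flux balance analysis).

A metabolic model is a stoichiometric network: reactions with flux bounds,
gene associations and organ tags over compartment-tagged metabolites.  Urine
([u]) and blood ([bc]) metabolites are boundary species — they may accumulate
and are excluded from the steady-state constraint — so urine excretion
reactions ``EX_<met>[u]`` and blood demand reactions ``DM_<met>[bc]`` simply
produce them.  FBA maximizes a target reaction flux subject to S v = 0 over
the balanced metabolites and lb <= v <= ub.

A gene knockout closes every reaction associated with the gene, in every
organ.  The healthy reference is built by first maximizing the gene's summed
reaction flux and pinning each reaction at that optimum, so healthy and
knockout models differ only in the activity of the gene's reactions.  The
direction call compares maximal target flux between the two conditions at a
relative tolerance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "MetabolicModel",
    "FluxResult",
    "KnockoutPrediction",
    "load_model",
    "model_from_dict",
    "model_to_dict",
    "save_model",
    "fba_maximize",
    "apply_knockout",
    "healthy_reference",
    "predict_direction",
    "concordance_binomial_test",
]

SCHEMA_VERSION = 1
#: compartments treated as boundary (no steady-state constraint)
BOUNDARY_COMPARTMENTS = frozenset({"u", "bc"})


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    genes: tuple[str, ...] = ()
    organ: str = ""


@dataclass
class MetabolicModel:
    """Stoichiometric model: metabolites (id -> compartment) and reactions."""

    name: str
    metabolites: dict[str, str]  # metabolite id -> compartment tag
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ValueError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"reaction {rxn.id!r}: lb > ub")
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                    )

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(f"no reaction {rxn_id!r} in model {self.name!r}")

    def reactions_for_gene(self, gene: str) -> list[Reaction]:
        return [r for r in self.reactions if gene in r.genes]

    def genes(self) -> set[str]:
        return {g for r in self.reactions for g in r.genes}

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """(S, balanced_metabolites): S rows are steady-state metabolites only."""
        balanced = [
            m for m, comp in self.metabolites.items() if comp not in BOUNDARY_COMPARTMENTS
        ]
        idx = {m: i for i, m in enumerate(balanced)}
        S = np.zeros((len(balanced), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                if met in idx:
                    S[idx[met], j] = coef
        return S, balanced

    def with_bounds(self, rxn_id: str, lb: float, ub: float) -> "MetabolicModel":
        reactions = [
            replace(r, lower_bound=lb, upper_bound=ub) if r.id == rxn_id else r
            for r in self.reactions
        ]
        if not any(r.id == rxn_id for r in reactions):
            raise KeyError(f"no reaction {rxn_id!r}")
        return MetabolicModel(self.name, dict(self.metabolites), reactions)


@dataclass
class FluxResult:
    objective: str
    status: str  # optimal | infeasible | unbounded
    value: float | None
    tolerance: float = 1e-9


@dataclass
class KnockoutPrediction:
    gene: str
    metabolite: str
    compartment: str  # urine | blood
    direction: str  # down | unchanged | up
    healthy_flux: float
    knockout_flux: float


def model_from_dict(data: dict) -> MetabolicModel:
    mets = {m["id"]: m.get("compartment", "") for m in data["metabolites"]}
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=_parse_bound(r.get("upper_bound", math.inf)),
            genes=tuple(r.get("genes", ())),
            organ=r.get("organ", ""),
        )
        for r in data["reactions"]
    ]
    return MetabolicModel(data.get("name", "model"), mets, reactions)


def _parse_bound(v) -> float:
    if isinstance(v, str):
        if v.lower() in ("inf", "infinity", "+inf"):
            return math.inf
        if v.lower() in ("-inf", "-infinity"):
            return -math.inf
        return float(v)
    return float(v)


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "name": model.name,
        "metabolites": [
            {"id": m, "compartment": c} for m, c in model.metabolites.items()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": "inf" if math.isinf(r.upper_bound) else r.upper_bound,
                "genes": list(r.genes),
                "organ": r.organ,
            }
            for r in model.reactions
        ],
    }


def load_model(path: str | Path) -> MetabolicModel:
    """Load and validate a model from the package's JSON schema."""
    with open(path) as fh:
        data = json.load(fh)
    return model_from_dict(data)


def save_model(model: MetabolicModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


def fba_maximize(model: MetabolicModel, objective: str, tolerance: float = 1e-9) -> FluxResult:
    """Maximize flux through ``objective`` subject to S v = 0 and bounds.

    Solved as a linear program (HiGHS).  Status is reported honestly:
    optimal, infeasible or unbounded; any other solver condition raises.
    """
    S, _ = model.stoichiometric_matrix()
    n = len(model.reactions)
    c = np.zeros(n)
    try:
        j = [r.id for r in model.reactions].index(objective)
    except ValueError:
        raise KeyError(f"objective reaction {objective!r} not in model") from None
    c[j] = -1.0  # linprog minimizes
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 0:
        v = res.x
        if np.abs(S @ v).max() > 1e-8:
            raise RuntimeError("optimal flux vector violates mass balance")
        return FluxResult(objective, "optimal", float(-res.fun) + 0.0, tolerance)
    if res.status == 2:
        return FluxResult(objective, "infeasible", None, tolerance)
    if res.status == 3:
        return FluxResult(objective, "unbounded", None, tolerance)
    raise RuntimeError(f"LP solver failure: {res.message}")


def _knockout_check(model: MetabolicModel, gene: str) -> list[Reaction]:
    rxns = model.reactions_for_gene(gene)
    if not rxns:
        raise KeyError(f"gene {gene!r} not present in model {model.name!r}")
    shared = [r.id for r in rxns if len(r.genes) > 1]
    if shared:
        raise ValueError(
            f"gene {gene!r} shares reaction(s) {shared} with isozymes; "
            "knockout of isozyme-bearing genes is not interpretable and is refused"
        )
    return rxns


def apply_knockout(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Close (lb = ub = 0) every reaction of ``gene`` across all organs."""
    rxns = _knockout_check(model, gene)
    ko = model
    for r in rxns:
        ko = ko.with_bounds(r.id, 0.0, 0.0)
    return MetabolicModel(f"{model.name}|KO:{gene}", ko.metabolites, ko.reactions)


def healthy_reference(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Pin the gene's reactions at their (jointly) maximal activity.

    Maximizes the summed flux of all the gene's reactions in one LP, then
    fixes each reaction at its flux in that optimum.  A gene with zero
    feasible flux is pinned at zero (degenerate but valid healthy state).
    """
    rxns = _knockout_check(model, gene)
    S, _ = model.stoichiometric_matrix()
    n = len(model.reactions)
    ids = [r.id for r in model.reactions]
    c = np.zeros(n)
    for r in rxns:
        c[ids.index(r.id)] = -1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 2:
        raise RuntimeError(f"healthy-reference maximization infeasible for {gene!r}")
    if res.status != 0:
        raise RuntimeError(f"healthy-reference LP not optimal: {res.message}")
    healthy = model
    for r in rxns:
        v = float(res.x[ids.index(r.id)])
        healthy = healthy.with_bounds(r.id, v, v)
    return MetabolicModel(f"{model.name}|healthy:{gene}", healthy.metabolites, healthy.reactions)


def _target_reaction_id(model: MetabolicModel, metabolite: str, compartment: str) -> str:
    prefix, tag = {"urine": ("EX_", "u"), "blood": ("DM_", "bc")}[compartment]
    rid = f"{prefix}{metabolite}[{tag}]"
    if any(r.id == rid for r in model.reactions):
        return rid
    raise KeyError(rid)


def _ensure_target(model: MetabolicModel, metabolite: str, compartment: str) -> tuple[MetabolicModel, str]:
    """Find or create the EX_/DM_ target reaction and open it to [0, inf)."""
    if compartment not in ("urine", "blood"):
        raise ValueError("compartment must be 'urine' or 'blood'")
    try:
        rid = _target_reaction_id(model, metabolite, compartment)
        return model.with_bounds(rid, 0.0, math.inf), rid
    except KeyError:
        pass
    # create the boundary reaction, drawing from the metabolite's internal pool
    source = metabolite if metabolite in model.metabolites else f"{metabolite}[c]"
    if source not in model.metabolites:
        raise KeyError(f"metabolite {metabolite!r} not in model")
    prefix, tag = {"urine": ("EX_", "u"), "blood": ("DM_", "bc")}[compartment]
    boundary_met = f"{metabolite}[{tag}]"
    mets = dict(model.metabolites)
    mets.setdefault(boundary_met, tag)
    rid = f"{prefix}{metabolite}[{tag}]"
    rxn = Reaction(rid, {source: -1.0, boundary_met: 1.0}, 0.0, math.inf)
    return MetabolicModel(model.name, mets, [*model.reactions, rxn]), rid


def predict_direction(
    model: MetabolicModel,
    gene: str,
    metabolite: str,
    compartment: str,
    tolerance: float = 1e-6,
) -> KnockoutPrediction:
    """Direction of the maximal urine-excretion / blood-demand flux under knockout.

    Opens the target EX_/DM_ reaction to [0, inf), maximizes it under the
    healthy-reference model and under the knockout model, and calls the
    direction at a relative tolerance (absolute floor 1e-9):
    up if KO - healthy > tol * max(1, healthy), down if below the negative of
    that, else unchanged.
    """
    opened, rid = _ensure_target(model, metabolite, compartment)
    results = {}
    for label, variant in (
        ("healthy", healthy_reference(opened, gene)),
        ("knockout", apply_knockout(opened, gene)),
    ):
        results[label] = fba_maximize(variant, rid)
    if any(r.status == "unbounded" for r in results.values()):
        raise RuntimeError(
            f"target {rid} unbounded; direction undefined (check network capacity bounds)"
        )
    if any(r.status != "optimal" for r in results.values()):
        bad = {k: v.status for k, v in results.items()}
        raise RuntimeError(f"target {rid} not solvable in both conditions: {bad}")
    healthy_v = results["healthy"].value
    ko_v = results["knockout"].value
    margin = max(tolerance * max(1.0, abs(healthy_v)), 1e-9)
    diff = ko_v - healthy_v
    direction = "up" if diff > margin else ("down" if diff < -margin else "unchanged")
    return KnockoutPrediction(gene, metabolite, compartment, direction, healthy_v, ko_v)


def concordance_binomial_test(
    predictions: Sequence[str], observations: Sequence[str], null_p: float
) -> tuple[int, float]:
    """Exact one-sided binomial test of direction concordance.

    Returns (n_match, p) with p = P(X >= n_match | n, null_p) by direct
    summation of the binomial mass function.
    """
    if len(predictions) != len(observations):
        raise ValueError("prediction and observation lists must have equal length")
    if not (0 < null_p < 1) and null_p != 1:
        raise ValueError("null_p must be in (0, 1]")
    n = len(predictions)
    n_match = sum(p == o for p, o in zip(predictions, observations))
    p = sum(
        math.comb(n, x) * null_p**x * (1 - null_p) ** (n - x) for x in range(n_match, n + 1)
    )
    return n_match, float(min(1.0, p))
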