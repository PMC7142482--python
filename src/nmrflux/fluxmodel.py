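"""Constraint-based metabolic modeling: FBA and GIMME context-specific flux.

A :class:`MetabolicModel` is a stoichiometric matrix S (metabolites x
reactions) with per-reaction flux bounds, boolean gene-protein-reaction (GPR)
rules, and a designated objective reaction (biomass/maintenance).

Flux balance analysis (FBA) solves the LP

    max  v_obj   s.t.  S v = 0,  lb <= v <= ub

GIMME integrates a boolean protein-presence profile (present = 100,
absent = 0): reactions whose mapped expression falls below a cutoff are
penalized in proportion to the flux they carry, while the objective is held
at a fraction of its FBA optimum.  Reversible reactions are split into
non-negative forward/backward parts so the penalty on |v| stays linear:

    min  sum_{i: expr_i < cutoff} (cutoff - expr_i) * (f_i + b_i)
    s.t. S (f - b) = 0,  bounds,  v_obj >= objective_fraction * z*

Reactions without a GPR rule (spontaneous/transport) are never penalized —
no protein evidence can be absent for them.  GPR rules are evaluated with
AND -> min and OR -> max over gene values, the convention of standard
gene-to-reaction mapping routines.

Models round-trip through a documented JSON schema and SBML Level 3 + FBC v2.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

DEFAULT_EXPR_CUTOFF = 50.0
DEFAULT_OBJECTIVE_FRACTION = 0.9
MASS_BALANCE_TOL = 1e-6
BOUND_TOL = 1e-9


class ModelValidationError(ValueError):
    """Raised with the complete list of schema/consistency failures."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class GprSyntaxError(ValueError):
    """Malformed GPR rule; carries the character position of the failure."""

    def __init__(self, rule: str, pos: int, msg: str):
        self.rule, self.pos = rule, pos
        super().__init__(f"GPR parse error at position {pos} in {rule!r}: {msg}")


class FluxError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str | None):
    """Parse a boolean GPR rule into a tree.

    Grammar (case-insensitive keywords): ``expr := term ('or' term)*``,
    ``term := factor ('and' factor)*``, ``factor := gene | '(' expr ')'``.
    Returns nested tuples ``("gene", id)``, ``("and", [...])``,
    ``("or", [...])``; an empty/blank rule returns ``None``.
    """
    if rule is None or not rule.strip():
        return None
    tokens = [(m.group(0), m.start()) for m in _TOKEN.finditer(rule)]
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(rule))

    def expr():
        nonlocal pos
        parts = [term()]
        while peek()[0] is not None and peek()[0].lower() == "or":
            pos += 1
            parts.append(term())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def term():
        nonlocal pos
        parts = [factor()]
        while peek()[0] is not None and peek()[0].lower() == "and":
            pos += 1
            parts.append(factor())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def factor():
        nonlocal pos
        tok, at = peek()
        if tok is None:
            raise GprSyntaxError(rule, at, "unexpected end of rule")
        if tok == "(":
            pos += 1
            node = expr()
            tok2, at2 = peek()
            if tok2 != ")":
                raise GprSyntaxError(rule, at2, "expected ')'")
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprSyntaxError(rule, at, f"unexpected token {tok!r}")
        pos += 1
        return ("gene", tok)

    tree = expr()
    tok, at = peek()
    if tok is not None:
        raise GprSyntaxError(rule, at, f"trailing token {tok!r}")
    return tree


def gpr_genes(tree) -> set[str]:
    if tree is None:
        return set()
    kind = tree[0]
    if kind == "gene":
        return {tree[1]}
    return set().union(*(gpr_genes(c) for c in tree[1]))


def eval_gpr(tree, values: Mapping[str, float]) -> float | None:
    """Evaluate a GPR tree with AND -> min, OR -> max; ``None`` for empty rules.

    Genes missing from ``values`` count as 0 (not observed).
    """
    if tree is None:
        return None
    kind = tree[0]
    if kind == "gene":
        return float(values.get(tree[1], 0.0))
    child = [eval_gpr(c, values) for c in tree[1]]
    return min(child) if kind == "and" else max(child)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """Stoichiometric model with bounds, GPR rules and one objective reaction."""

    metabolites: list[str]
    reactions: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    gpr: list[str]
    genes: list[str]
    objective_reaction: str | None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        errors = self.validation_errors()
        if errors:
            raise ModelValidationError(errors)

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        nm, nr = len(self.metabolites), len(self.reactions)
        if self.S.shape != (nm, nr):
            errs.append(f"S has shape {self.S.shape}, expected ({nm}, {nr})")
        if len(self.lb) != nr or len(self.ub) != nr:
            errs.append("bounds length does not match reaction count")
        elif np.any(self.lb > self.ub):
            bad = [self.reactions[j] for j in np.where(self.lb > self.ub)[0]]
            errs.append(f"lb > ub for reactions {bad}")
        if len(self.gpr) != nr:
            errs.append("gpr list length does not match reaction count")
        if len(set(self.metabolites)) != nm:
            errs.append("duplicate metabolite ids")
        if len(set(self.reactions)) != nr:
            errs.append("duplicate reaction ids")
        if self.objective_reaction is not None and self.objective_reaction not in self.reactions:
            errs.append(f"objective reaction {self.objective_reaction!r} not in reactions")
        declared = set(self.genes)
        for rid, rule in zip(self.reactions, self.gpr):
            try:
                used = gpr_genes(parse_gpr(rule))
            except GprSyntaxError as e:
                errs.append(f"reaction {rid}: {e}")
                continue
            undeclared = used - declared
            if undeclared:
                errs.append(f"reaction {rid}: GPR uses undeclared genes {sorted(undeclared)}")
        return errs

    def reaction_index(self, rid: str) -> int:
        return self.reactions.index(rid)

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            gpr=list(self.gpr),
            genes=list(self.genes),
        )


def reaction_expression(
    model: MetabolicModel, profile: Mapping[str, float]
) -> dict[str, float | None]:
    """Map a gene expression profile onto reactions through the GPR rules.

    Missing genes are treated as 0 and logged; reactions with an empty rule
    map to ``None`` (unconstrained — treated as high expression downstream).
    """
    missing = [g for g in model.genes if g not in profile]
    if missing:
        logger.info("genes absent from profile treated as 0: %s", missing)
    return {
        rid: eval_gpr(parse_gpr(rule), profile)
        for rid, rule in zip(model.reactions, model.gpr)
    }


# ---------------------------------------------------------------------------
# flux solutions
# ---------------------------------------------------------------------------

@dataclass
class FluxSolution:
    """Reaction-indexed flux vector with objective value and solver status."""

    fluxes: pd.Series
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    inconsistency_score: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.fluxes.rename("flux").to_frame()


_LP_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize flux through the objective reaction at steady state."""
    if model.objective_reaction is None:
        raise FluxError("model has no objective reaction")
    nr = len(model.reactions)
    c = np.zeros(nr)
    c[model.reaction_index(model.objective_reaction)] = -1.0
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(len(model.metabolites)),
        bounds=list(zip(model.lb, model.ub)),
        method="highs",
    )
    status = _LP_STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(
            pd.Series(np.nan, index=model.reactions), float("nan"), status
        )
    v = pd.Series(res.x, index=model.reactions)
    return FluxSolution(v, float(-res.fun), "optimal")


def _split_bounds(lb: float, ub: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Bounds for the non-negative forward/backward parts of v in [lb, ub]."""
    fwd = (max(lb, 0.0), max(ub, 0.0))
    bwd = (max(-ub, 0.0), max(-lb, 0.0))
    return fwd, bwd


def gimme(
    model: MetabolicModel,
    rxn_expr: Mapping[str, float | None],
    expr_cutoff: float = DEFAULT_EXPR_CUTOFF,
    objective_fraction: float = DEFAULT_OBJECTIVE_FRACTION,
) -> FluxSolution:
    """Context-specific flux minimizing use of low-expression reactions.

    ``rxn_expr`` maps reaction ids to mapped expression (``None`` for
    reactions without protein evidence requirements).  Requires a feasible
    model with positive FBA optimum z*; the returned solution keeps
    ``v_obj >= objective_fraction * z*`` and reports the inconsistency score
    ``sum (cutoff - expr_i) * |v_i|`` over penalized reactions.
    """
    if not 0 < objective_fraction <= 1:
        raise FluxError(f"objective_fraction must be in (0, 1], got {objective_fraction}")
    base = fba(model)
    if base.status != "optimal":
        raise FluxError(f"FBA on the base model is {base.status}; GIMME needs an optimum")
    if base.objective_value <= 0:
        raise FluxError(
            f"FBA optimum is {base.objective_value:g}; the objective cannot be maintained"
        )
    z_target = objective_fraction * base.objective_value

    nr = len(model.reactions)
    nm = len(model.metabolites)
    penalized = np.zeros(nr)
    for j, rid in enumerate(model.reactions):
        expr = rxn_expr.get(rid)
        if expr is not None and expr < expr_cutoff:
            penalized[j] = expr_cutoff - expr

    # variables: [f_1..f_nr, b_1..b_nr] with v = f - b
    bounds = []
    for lo, hi in zip(model.lb, model.ub):
        bounds.append(_split_bounds(lo, hi)[0])
    for lo, hi in zip(model.lb, model.ub):
        bounds.append(_split_bounds(lo, hi)[1])
    A_eq = np.hstack([model.S, -model.S])
    cost = np.concatenate([penalized, penalized])
    obj_idx = model.reaction_index(model.objective_reaction)
    a_ub = np.zeros(2 * nr)
    a_ub[obj_idx] = -1.0
    a_ub[nr + obj_idx] = 1.0
    res = linprog(
        cost,
        A_ub=a_ub[None, :],
        b_ub=np.array([-z_target]),
        A_eq=A_eq,
        b_eq=np.zeros(nm),
        bounds=bounds,
        method="highs",
    )
    status = _LP_STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(
            pd.Series(np.nan, index=model.reactions), float("nan"), status, None
        )
    v = res.x[:nr] - res.x[nr:]
    return FluxSolution(
        pd.Series(v, index=model.reactions),
        float(v[obj_idx]),
        "optimal",
        inconsistency_score=float(res.fun),
    )


def context_subnetwork(
    model: MetabolicModel, solution: FluxSolution, tol: float = 1e-9
) -> tuple[MetabolicModel, list[str]]:
    """Restrict a model to reactions carrying flux, flagging dead-end metabolites.

    A dead-end metabolite participates in exactly one active reaction.  If the
    objective reaction is inactive the submodel has no objective.
    """
    if solution.status != "optimal":
        raise FluxError(f"cannot extract a subnetwork from a {solution.status} solution")
    v = solution.fluxes.reindex(model.reactions).to_numpy()
    active = np.abs(v) > tol
    rxn_ids = [r for r, a in zip(model.reactions, active) if a]
    sub_S_cols = model.S[:, active]
    met_active = np.abs(sub_S_cols).sum(axis=1) > 0
    met_ids = [m for m, a in zip(model.metabolites, met_active) if a]
    sub_S = sub_S_cols[met_active, :]
    gpr = [g for g, a in zip(model.gpr, active) if a]
    genes = sorted(set().union(*(gpr_genes(parse_gpr(g)) for g in gpr)) if gpr else set())
    objective = model.objective_reaction if model.objective_reaction in rxn_ids else None
    sub = MetabolicModel(
        metabolites=met_ids,
        reactions=rxn_ids,
        S=sub_S,
        lb=model.lb[active].copy(),
        ub=model.ub[active].copy(),
        gpr=gpr,
        genes=genes,
        objective_reaction=objective,
    )
    participation = (np.abs(sub_S) > 0).sum(axis=1)
    dead_ends = [m for m, k in zip(met_ids, participation) if k == 1]
    return sub, dead_ends


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------
# Schema (field-compatible with the common constraint-based JSON dialect):
# {
#   "metabolites": [{"id": str}, ...],
#   "reactions":   [{"id": str, "metabolites": {met_id: coeff, ...},
#                    "lower_bound": num, "upper_bound": num,
#                    "gene_reaction_rule": str}, ...],
#   "genes":       [{"id": str}, ...],
#   "objective":   str  (reaction id)
# }

def model_to_dict(model: MetabolicModel) -> dict:
    rxns = []
    for j, rid in enumerate(model.reactions):
        coeffs = {
            model.metabolites[i]: float(model.S[i, j])
            for i in np.where(model.S[:, j] != 0)[0]
        }
        rxns.append(
            {
                "id": rid,
                "metabolites": coeffs,
                "lower_bound": float(model.lb[j]),
                "upper_bound": float(model.ub[j]),
                "gene_reaction_rule": model.gpr[j],
            }
        )
    return {
        "metabolites": [{"id": m} for m in model.metabolites],
        "reactions": rxns,
        "genes": [{"id": g} for g in model.genes],
        "objective": model.objective_reaction,
    }


def model_from_dict(data: dict) -> MetabolicModel:
    errors: list[str] = []
    for key in ("metabolites", "reactions", "genes"):
        if key not in data:
            errors.append(f"missing top-level key {key!r}")
    if errors:
        raise ModelValidationError(errors)
    mets = [m["id"] for m in data["metabolites"]]
    rids, lb, ub, gpr = [], [], [], []
    midx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(data["reactions"])))
    for j, r in enumerate(data["reactions"]):
        rids.append(r["id"])
        for key in ("lower_bound", "upper_bound"):
            if key not in r:
                errors.append(f"reaction {r.get('id', j)}: missing {key!r}")
        lb.append(float(r.get("lower_bound", 0.0)))
        ub.append(float(r.get("upper_bound", 0.0)))
        gpr.append(r.get("gene_reaction_rule", ""))
        for m, coeff in r.get("metabolites", {}).items():
            if m not in midx:
                errors.append(f"reaction {r['id']}: unknown metabolite {m!r}")
            else:
                S[midx[m], j] = float(coeff)
    if errors:
        raise ModelValidationError(errors)
    return MetabolicModel(
        metabolites=mets,
        reactions=rids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        gpr=gpr,
        genes=[g["id"] for g in data["genes"]],
        objective_reaction=data.get("objective"),
    )


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2 I/O
# ---------------------------------------------------------------------------

def _sid(prefix: str, raw: str) -> str:
    safe = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    return f"{prefix}{safe}"


def _unsid(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def write_model(model: MetabolicModel, path: str | Path, format: str = "json") -> None:
    if format == "json":
        Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))
    elif format == "sbml_fbc":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    path = Path(path)
    if format is None:
        format = "sbml_fbc" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        return model_from_dict(json.loads(path.read_text()))
    if format == "sbml_fbc":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _write_sbml(model: MetabolicModel, path: str | Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId("model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    comp = sm.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(_sid("M_", m))
        sp.setName(m)
        sp.setCompartment("c")
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    for g in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_", g))
        gp.setLabel(g)

    bounds_seen: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"fb_{len(bounds_seen)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    gene_sid = {g: _sid("G_", g) for g in model.genes}

    def assoc_from_tree(parent, tree):
        if tree[0] == "gene":
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(gene_sid[tree[1]])
        elif tree[0] == "and":
            node = parent.createAnd()
            for c in tree[1]:
                assoc_from_tree(node, c)
        else:
            node = parent.createOr()
            for c in tree[1]:
                assoc_from_tree(node, c)

    for j, rid in enumerate(model.reactions):
        rx = sm.createReaction()
        rx.setId(_sid("R_", rid))
        rx.setName(rid)
        rx.setFast(False)
        rx.setReversible(bool(model.lb[j] < 0))
        for i in np.where(model.S[:, j] != 0)[0]:
            coeff = model.S[i, j]
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(_sid("M_", model.metabolites[i]))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(model.lb[j]))
        rplug.setUpperFluxBound(bound_param(model.ub[j]))
        tree = parse_gpr(model.gpr[j])
        if tree is not None:
            gpa = rplug.createGeneProductAssociation()
            assoc_from_tree(gpa, tree)

    if model.objective_reaction is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid("R_", model.objective_reaction))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _assoc_to_tree(assoc, label_by_sid):
    import libsbml

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        return ("gene", label_by_sid.get(assoc.getGeneProduct(), assoc.getGeneProduct()))
    kind = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
    children = [
        _assoc_to_tree(assoc.getAssociation(i), label_by_sid)
        for i in range(assoc.getNumAssociations())
    ]
    return (kind, children)


def _tree_to_rule(tree, top=True) -> str:
    if tree is None:
        return ""
    if tree[0] == "gene":
        return tree[1]
    joiner = f" {tree[0]} "
    inner = joiner.join(_tree_to_rule(c, top=False) for c in tree[1])
    return inner if top else f"({inner})"


def _read_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getModel() is None:
        raise ModelValidationError([f"{path}: not a parseable SBML document"])
    sm = doc.getModel()
    mplug = sm.getPlugin("fbc")
    if mplug is None:
        raise ModelValidationError([f"{path}: missing the fbc package (fbc:listOfObjectives etc.)"])

    errors: list[str] = []
    mets = [_unsid("M_", sm.getSpecies(i).getId()) for i in range(sm.getNumSpecies())]
    midx = {m: i for i, m in enumerate(mets)}

    label_by_sid = {}
    genes = []
    for i in range(mplug.getNumGeneProducts()):
        gp = mplug.getGeneProduct(i)
        label = gp.getLabel() or _unsid("G_", gp.getId())
        label_by_sid[gp.getId()] = label
        genes.append(label)

    nr = sm.getNumReactions()
    rids, lb, ub, gprs = [], [], [], []
    S = np.zeros((len(mets), nr))
    for j in range(nr):
        rx = sm.getReaction(j)
        rid = _unsid("R_", rx.getId())
        rids.append(rid)
        rplug = rx.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound() or not rplug.isSetUpperFluxBound():
            errors.append(
                f"reaction {rid}: missing fbc:lowerFluxBound/fbc:upperFluxBound"
            )
            lb.append(0.0)
            ub.append(0.0)
        else:
            for which, setter in (
                (rplug.getLowerFluxBound(), lb),
                (rplug.getUpperFluxBound(), ub),
            ):
                p = sm.getParameter(which)
                if p is None:
                    errors.append(f"reaction {rid}: bound parameter {which!r} undefined")
                    setter.append(0.0)
                else:
                    setter.append(p.getValue())
        gpa = rplug.getGeneProductAssociation() if rplug is not None else None
        tree = _assoc_to_tree(gpa.getAssociation(), label_by_sid) if gpa is not None else None
        gprs.append(_tree_to_rule(tree))
        for ref, sign in [(rx.getReactant(i), -1.0) for i in range(rx.getNumReactants())] + [
            (rx.getProduct(i), 1.0) for i in range(rx.getNumProducts())
        ]:
            m = _unsid("M_", ref.getSpecies())
            if m not in midx:
                errors.append(f"reaction {rid}: unknown species {ref.getSpecies()!r}")
            else:
                S[midx[m], j] += sign * ref.getStoichiometry()

    objective = None
    obj = mplug.getActiveObjective()
    if obj is not None and obj.getNumFluxObjectives() > 0:
        objective = _unsid("R_", obj.getFluxObjective(0).getReaction())
    if errors:
        raise ModelValidationError(errors)
    return MetabolicModel(
        metabolites=mets,
        reactions=rids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        gpr=gprs,
        genes=genes,
        objective_reaction=objective,
    )


def write_flux_csv(
    solution: FluxSolution,
    path: str | Path,
    rxn_expr: Mapping[str, float | None] | None = None,
    expr_cutoff: float = DEFAULT_EXPR_CUTOFF,
) -> None:
    """Flux solution as CSV (reaction, flux, expression, penalized flag)."""
    df = solution.to_frame()
    if rxn_expr is not None:
        expr = pd.Series({r: rxn_expr.get(r) for r in df.index}, dtype=object)
        df["expression"] = expr
        df["penalized"] = [
            (e is not None and e < expr_cutoff) for e in expr
        ]
    df.index.name = "reaction"
    df.to_csv(path, float_format="%.10g")
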