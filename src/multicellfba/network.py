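"""Genome-scale metabolic network container, I/O and GPR evaluation.

The in-memory model is deliberately small: ordered metabolites and
reactions, signed stoichiometry, flux bounds in arbitrary units, and
boolean gene-protein-reaction (GPR) rules.  Metabolite ids carry a
compartment tag in the id itself (``glc_D[c]``) following the common
reconstruction convention; the medium compartment used by multi-cell
models is tagged ``u``.

Two serialisations are supported: a JSON dialect whose field names match
the widespread genome-scale-model JSON layout (readable by other COBRA
tooling), and SBML Level 3 with the ``fbc`` package.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse

JSON_SCHEMA_VERSION = "1"

#: default bound magnitude, arbitrary units
DEFAULT_BOUND = 1000.0


class NetworkError(ValueError):
    """Raised for malformed networks or model files."""


class GPRError(ValueError):
    """Raised for unparsable gene-protein-reaction rules."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    formula: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")
        if not self.compartment:
            raise NetworkError(f"metabolite {self.id!r}: compartment tag must be non-empty")


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: Optional[str] = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise NetworkError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        stoich = {m: float(c) for m, c in self.stoichiometry.items() if c != 0}
        if not stoich:
            raise NetworkError(f"reaction {self.id!r}: stoichiometry has no nonzero entry")
        object.__setattr__(self, "stoichiometry", stoich)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> Set[str]:
        return gpr_genes(self.gpr)


def compartment_of(met_id: str) -> Optional[str]:
    """Compartment tag embedded in a metabolite id, e.g. ``glc_D[c]`` -> ``c``."""
    m = re.search(r"\[([^\[\]]+)\]", met_id)
    return m.group(1) if m else None


def base_id(met_id: str) -> str:
    """Metabolite id with the compartment tag stripped: ``lac_L[c]`` -> ``lac_L``."""
    return re.sub(r"\[[^\[\]]+\].*$", "", met_id)


@dataclass
class MetabolicNetwork:
    """Stoichiometric model with bounds, GPRs and compartment structure."""

    metabolites: List[Metabolite]
    reactions: List[Reaction]
    boundary_compartments: Set[str] = field(default_factory=lambda: {"e"})
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise NetworkError(f"duplicate metabolite id(s): {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise NetworkError(f"duplicate reaction id(s): {dup}")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise NetworkError(
                    f"reaction {r.id!r} references unknown metabolite(s): {sorted(missing)}"
                )

    # -- lookups -----------------------------------------------------------

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.reactions:
            out |= gpr_genes(r.gpr)
        return out

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    # -- structure ---------------------------------------------------------

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """m x n sparse stoichiometric matrix in metabolite/reaction order."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, data = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                rows.append(met_index[met])
                cols.append(j)
                data.append(coef)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def is_exchange(self, reaction: Reaction) -> bool:
        """Single-metabolite boundary reaction with unit coefficient."""
        if len(reaction.stoichiometry) != 1:
            return False
        (met, coef), = reaction.stoichiometry.items()
        if abs(coef) != 1.0:
            return False
        comp = self.metabolite(met).compartment
        return comp in self.boundary_compartments

    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def subnetwork(self, reaction_ids: Iterable[str]) -> "MetabolicNetwork":
        """Induced subnetwork on a reaction subset (metabolites pruned)."""
        keep = set(reaction_ids)
        unknown = keep - set(self.reaction_ids)
        if unknown:
            raise NetworkError(f"subnetwork: unknown reaction id(s): {sorted(unknown)}")
        rxns = [r for r in self.reactions if r.id in keep]
        used = set()
        for r in rxns:
            used |= set(r.stoichiometry)
        mets = [m for m in self.metabolites if m.id in used]
        return MetabolicNetwork(
            metabolites=mets,
            reactions=rxns,
            boundary_compartments=set(self.boundary_compartments),
            id=self.id,
        )

    def with_bounds(self, bounds: Mapping[str, Tuple[float, float]]) -> "MetabolicNetwork":
        """Copy with some reaction bounds replaced."""
        rxns = [
            replace(r, lower_bound=bounds[r.id][0], upper_bound=bounds[r.id][1])
            if r.id in bounds
            else r
            for r in self.reactions
        ]
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=rxns,
            boundary_compartments=set(self.boundary_compartments),
            id=self.id,
        )


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _GPRParser:
    """Recursive-descent parser for boolean AND/OR rules over gene ids."""

    def __init__(self, rule: str):
        self.rule = rule
        self.tokens = _TOKEN_RE.findall(rule)
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRError(f"unexpected end of GPR rule: {self.rule!r}")
        self.pos += 1
        return tok

    def parse(self):
        expr = self.parse_or()
        if self.peek() is not None:
            raise GPRError(f"trailing token {self.peek()!r} in GPR rule: {self.rule!r}")
        return expr

    def parse_or(self):
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and(self):
        factors = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.parse_atom())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_atom(self):
        tok = self.next()
        if tok == "(":
            inner = self.parse_or()
            if self.next() != ")":
                raise GPRError(f"unbalanced parentheses in GPR rule: {self.rule!r}")
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRError(f"misplaced token {tok!r} in GPR rule: {self.rule!r}")
        return ("gene", tok)


def _parse_gpr(rule: str):
    return _GPRParser(rule).parse()


def _eval_ast(node, active: Set[str]) -> bool:
    kind = node[0]
    if kind == "gene":
        # unknown genes evaluate False: no evidence => not active
        return node[1] in active
    if kind == "and":
        return all(_eval_ast(c, active) for c in node[1])
    return any(_eval_ast(c, active) for c in node[1])


def _ast_genes(node, out: Set[str]) -> None:
    if node[0] == "gene":
        out.add(node[1])
    else:
        for c in node[1]:
            _ast_genes(c, out)


def evaluate_gpr(rule: str, active_genes: Iterable[str]) -> bool:
    """Evaluate a boolean GPR rule against a set of active genes.

    The empty rule evaluates ``False``: a reaction with no gene evidence can
    never be called core from expression data alone.
    """
    if not rule or not rule.strip():
        return False
    return _eval_ast(_parse_gpr(rule), set(active_genes))


def gpr_genes(rule: str) -> Set[str]:
    """Set of gene ids referenced by a GPR rule."""
    if not rule or not rule.strip():
        return set()
    out: Set[str] = set()
    _ast_genes(_parse_gpr(rule), out)
    return out


def map_core_reactions(network: MetabolicNetwork, core_genes: Iterable[str]) -> Set[str]:
    """Reactions whose GPR is satisfied by the core gene set.

    Reactions without a GPR are never returned; their inclusion in a
    context-specific model is decided by the extraction step, not by
    expression evidence.
    """
    active = set(core_genes)
    return {r.id for r in network.reactions if evaluate_gpr(r.gpr, active)}


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------


def network_to_dict(network: MetabolicNetwork, extra: Optional[dict] = None) -> dict:
    doc = {
        "id": network.id,
        "version": JSON_SCHEMA_VERSION,
        "boundary_compartments": sorted(network.boundary_compartments),
        "compartments": {
            c: c for c in sorted({m.compartment for m in network.metabolites})
        },
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                **({"subsystem": r.subsystem} if r.subsystem else {}),
            }
            for r in network.reactions
        ],
        "genes": [{"id": g} for g in sorted(network.genes)],
    }
    if extra:
        doc.update(extra)
    return doc


def _network_from_dict(doc: dict, source: str = "<dict>") -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment") or compartment_of(m["id"]) or "",
                formula=m.get("formula"),
            )
            for m in doc["metabolites"]
        ]
        rxns = []
        for r in doc["reactions"]:
            lb = r.get("lower_bound")
            ub = r.get("upper_bound")
            if lb is None or ub is None:
                # stated default: reversible unless flagged otherwise
                rev = bool(r.get("reversible", True))
                lb = -DEFAULT_BOUND if rev else 0.0
                ub = DEFAULT_BOUND
            rxns.append(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry=r["metabolites"],
                    lower_bound=float(lb),
                    upper_bound=float(ub),
                    gpr=r.get("gene_reaction_rule", r.get("gpr", "")),
                    subsystem=r.get("subsystem"),
                )
            )
    except KeyError as exc:
        raise NetworkError(f"{source}: missing required field {exc}") from exc
    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        boundary_compartments=set(doc.get("boundary_compartments", ["e"])),
        id=doc.get("id", "model"),
    )


# ---------------------------------------------------------------------------
# SBML I/O (Level 3 + fbc)
# ---------------------------------------------------------------------------

# bracketed compartment tags are not valid SBML SIds; escape them the way
# COBRA-style converters do
_SBML_ESCAPES = [("[", "__91__"), ("]", "__93__")]


def _sid(raw: str) -> str:
    out = raw
    for char, esc in _SBML_ESCAPES:
        out = out.replace(char, esc)
    out = re.sub(r"[^A-Za-z0-9_]", "_", out)
    if out and not re.match(r"[A-Za-z_]", out[0]):
        out = "_" + out
    return out


def _unsid(raw: str) -> str:
    out = raw
    for char, esc in _SBML_ESCAPES:
        out = out.replace(esc, char)
    return out


def _write_sbml(network: MetabolicNetwork, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(_sid(network.id))
    mplug = model.getPlugin("fbc")
    mplug.setStrict(False)

    for c in sorted({m.compartment for m in network.metabolites}):
        comp = model.createCompartment()
        comp.setId(_sid(c))
        comp.setConstant(True)

    for m in network.metabolites:
        sp = model.createSpecies()
        sp.setId("M_" + _sid(m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(_sid(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if m.formula:
            sp.getPlugin("fbc").setChemicalFormula(m.formula)
        # keep the authoritative id (with brackets) as species metaid-safe note
        sp.setMetaId("meta_M_" + _sid(m.id))

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            p = model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    gene_ids = sorted(network.genes)
    for g in gene_ids:
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _sid(g))
        gp.setLabel(g)

    for r in network.reactions:
        rx = model.createReaction()
        rx.setId("R_" + _sid(r.id))
        rx.setName(r.name or r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for met, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = rx.createReactant()
            else:
                ref = rx.createProduct()
            ref.setSpecies("M_" + _sid(met))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gpr.strip():
            ga = rplug.createGeneProductAssociation()

            def attach(parent, node):
                if node[0] == "gene":
                    ref = parent.createGeneProductRef()
                    ref.setGeneProduct("G_" + _sid(node[1]))
                elif node[0] == "and":
                    grp = parent.createAnd()
                    for child in node[1]:
                        attach(grp, child)
                else:
                    grp = parent.createOr()
                    for child in node[1]:
                        attach(grp, child)

            attach(ga, _parse_gpr(r.gpr))
        if r.subsystem:
            rx.setMetaId("meta_R_" + _sid(r.id))

    # model-level annotation carrying boundary compartment tags
    model.setNotes(
        "<body xmlns='http://www.w3.org/1999/xhtml'><p>boundary_compartments: "
        + ",".join(sorted(network.boundary_compartments))
        + "</p></body>"
    )
    libsbml.writeSBMLToFile(doc, str(path))


def _clip(raw: str, prefix: str) -> str:
    return raw[len(prefix):] if raw.startswith(prefix) else raw


def _assoc_to_rule(assoc, label_of: Dict[str, str]) -> str:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getGeneProduct()
        return label_of.get(gp, _unsid(_clip(gp, "G_")))
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_assoc_to_rule(assoc.getAssociation(i), label_of)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_assoc_to_rule(assoc.getAssociation(i), label_of)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise NetworkError(f"unsupported gene association element: {assoc}")


def _read_sbml(path: Path) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise NetworkError(f"{path}: SBML parse error: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise NetworkError(f"{path}: SBML file contains no model")

    mets = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        mid = _unsid(_clip(sp.getId(), "M_"))
        comp = _unsid(sp.getCompartment())
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        mets.append(
            Metabolite(id=mid, name=sp.getName() or "", compartment=comp, formula=formula)
        )

    label_of: Dict[str, str] = {}
    mplug = model.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label_of[gp.getId()] = gp.getLabel() or _unsid(_clip(gp.getId(), "G_"))

    rxns = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        rid = _unsid(_clip(rx.getId(), "R_"))
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _unsid(_clip(ref.getSpecies(), "M_"))
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _unsid(_clip(ref.getSpecies(), "M_"))
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb = ub = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                p = model.getParameter(rplug.getLowerFluxBound())
                lb = p.getValue() if p is not None else None
            if rplug.isSetUpperFluxBound():
                p = model.getParameter(rplug.getUpperFluxBound())
                ub = p.getValue() if p is not None else None
        if lb is None or ub is None:
            # stated default for reactions lacking explicit flux bounds
            rev = rx.getReversible()
            lb = -DEFAULT_BOUND if rev else 0.0
            ub = DEFAULT_BOUND
        gpr = ""
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr = _assoc_to_rule(assoc, label_of)
                if gpr.startswith("(") and gpr.endswith(")"):
                    gpr = gpr[1:-1]
        rxns.append(
            Reaction(
                id=rid,
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=gpr,
            )
        )

    boundary = {"e"}
    if model.isSetNotes():
        notes = model.getNotesString()
        m = re.search(r"boundary_compartments:\s*([\w,\s]+)<", notes)
        if m:
            boundary = {c.strip() for c in m.group(1).split(",") if c.strip()}

    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        boundary_compartments=boundary,
        id=_unsid(model.getId()) or "model",
    )


# ---------------------------------------------------------------------------
# public I/O entry points
# ---------------------------------------------------------------------------


def read_network(path, fmt: Optional[str] = None) -> MetabolicNetwork:
    """Read a model from ``json`` or ``sbml``; the format is inferred from
    the suffix when not given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    fmt = fmt.lower()
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise NetworkError(f"{path}: malformed JSON: {exc}") from exc
        return _network_from_dict(doc, source=str(path))
    if fmt == "sbml":
        return _read_sbml(path)
    raise NetworkError(f"unknown network format {fmt!r} (expected 'json' or 'sbml')")


def write_network(network: MetabolicNetwork, path, fmt: Optional[str] = None,
                  extra: Optional[dict] = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    fmt = fmt.lower()
    if fmt == "json":
        path.write_text(json.dumps(network_to_dict(network, extra=extra), indent=1,
                                   sort_keys=False) + "\n")
    elif fmt == "sbml":
        _write_sbml(network, path)
    else:
        raise NetworkError(f"unknown network format {fmt!r} (expected 'json' or 'sbml')")
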