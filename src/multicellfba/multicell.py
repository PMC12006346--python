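"""Multi-cell population model assembly.

The generic reconstruction is *multiplicated*: every retained cell type
gets its own namespaced copy of all internal reactions, and the generic
boundary exchanges are rewired through one shared medium compartment
(tag ``u``).  A generic exchange ``met[e] <=> (environment)`` becomes,
for each cell type *t*, a transport ``met[e]_t <=> met[u]`` plus a
single shared environment exchange ``met[u] <=> (environment)``.  Cell
types therefore interact only through the medium.

Model completion follows the core-extraction route: the union of the
namespaced per-type core reactions (plus each type's biomass-maintenance
reaction and the medium exchanges of available medium components) is
handed to the FASTCORE-style extraction, yielding one flux-consistent
multi-cell population model per condition.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .consistency import (
    DEFAULT_EPSILON,
    InconsistentCoreError,
    extract_core_subnetwork,
    find_consistent_subnetwork,
)
from .expression import CoreSet
from .network import (
    MetabolicNetwork,
    Metabolite,
    NetworkError,
    Reaction,
    base_id,
    network_to_dict,
)

MEDIUM_COMPARTMENT = "u"
BIOMASS_ID = "BIOMASS_maintenance"


@dataclass
class MultiCellModel:
    """Namespaced multi-cell network with cell-count weights."""

    network: MetabolicNetwork
    cell_types: List[str]
    weights: Dict[str, int]
    biomass_reaction: Dict[str, str]
    reaction_namespace: Dict[str, str]  # reaction id -> cell type or "medium"
    condition: str = ""
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.cell_types:
            if self.weights.get(t, -1) < 0:
                raise NetworkError(f"cell type {t!r}: weight must be non-negative")
            if t not in self.biomass_reaction:
                raise NetworkError(f"cell type {t!r}: missing biomass reaction")

    # -- views -------------------------------------------------------------

    def reactions_of(self, cell_type: str) -> List[str]:
        return [r for r, ns in self.reaction_namespace.items()
                if ns == cell_type and self.network.has_reaction(r)]

    def medium_exchanges(self) -> Dict[str, str]:
        """Medium-species base id -> environment exchange reaction id."""
        out = {}
        for r in self.network.reactions:
            if self.reaction_namespace.get(r.id) == "medium":
                met = next(iter(r.stoichiometry))
                out[base_id(met)] = r.id
        return out

    def transports_of(self, met_base: str) -> Dict[str, str]:
        """Cell type -> transport reaction id for one medium species."""
        medium_met = f"{met_base}[{MEDIUM_COMPARTMENT}]"
        out: Dict[str, str] = {}
        for r in self.network.reactions:
            ns = self.reaction_namespace.get(r.id)
            if ns in (None, "medium"):
                continue
            if medium_met in r.stoichiometry and len(r.stoichiometry) == 2:
                out[ns] = r.id
        return out

    def namespace_of_metabolite(self, met_id: str) -> str:
        if met_id.endswith(f"[{MEDIUM_COMPARTMENT}]"):
            return "medium"
        for t in self.cell_types:
            if met_id.endswith(f"_{t}"):
                return t
        raise KeyError(f"metabolite {met_id!r} carries no known namespace")


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------


def namespaced(identifier: str, cell_type: str) -> str:
    return f"{identifier}_{cell_type}"


def medium_species_id(met_id: str) -> str:
    return f"{base_id(met_id)}[{MEDIUM_COMPARTMENT}]"


def expand_model(
    generic: MetabolicNetwork, cell_types: Sequence[str]
) -> Tuple[MetabolicNetwork, Dict[str, str]]:
    """Multiplicate a generic network per cell type around a shared medium.

    Returns the expanded network (boundary compartment ``u``) and the
    reaction namespace map (reaction id -> cell type label or "medium").
    """
    if not cell_types:
        raise NetworkError("expand_model: need at least one cell type")
    if len(set(cell_types)) != len(cell_types):
        raise NetworkError("expand_model: duplicate cell-type labels")
    exchanges = {r.id for r in generic.exchange_reactions()}
    if not exchanges:
        raise NetworkError("expand_model: generic network has no exchange reactions")

    metabolites: List[Metabolite] = []
    reactions: List[Reaction] = []
    namespace: Dict[str, str] = {}
    seen_ids: Set[str] = set()

    # shared medium species, one per exchanged metabolite
    medium_ids: Dict[str, str] = {}
    for r in generic.reactions:
        if r.id not in exchanges:
            continue
        (met, _), = r.stoichiometry.items()
        mid = medium_species_id(met)
        if mid not in medium_ids.values():
            gm = generic.metabolite(met)
            metabolites.append(
                Metabolite(id=mid, name=gm.name, compartment=MEDIUM_COMPARTMENT,
                           formula=gm.formula)
            )
        medium_ids[met] = mid

    for t in cell_types:
        for m in generic.metabolites:
            nid = namespaced(m.id, t)
            if nid in seen_ids:
                raise NetworkError(f"expand_model: namespace collision on {nid!r}")
            seen_ids.add(nid)
            metabolites.append(replace(m, id=nid))
        for r in generic.reactions:
            rid = namespaced(r.id, t)
            if rid in namespace:
                raise NetworkError(f"expand_model: namespace collision on {rid!r}")
            if r.id in exchanges:
                (met, coef), = r.stoichiometry.items()
                stoich = {namespaced(met, t): coef, medium_ids[met]: -coef}
            else:
                stoich = {namespaced(met, t): coef for met, coef in r.stoichiometry.items()}
            reactions.append(replace(r, id=rid, stoichiometry=stoich))
            namespace[rid] = t

    for r in generic.reactions:
        if r.id not in exchanges:
            continue
        (met, coef), = r.stoichiometry.items()
        rid = f"{r.id}_u"
        if rid in namespace:
            raise NetworkError(f"expand_model: namespace collision on {rid!r}")
        reactions.append(replace(r, id=rid, stoichiometry={medium_ids[met]: coef}, gpr=""))
        namespace[rid] = "medium"

    expanded = MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        boundary_compartments={MEDIUM_COMPARTMENT},
        id=f"{generic.id}_multicell",
    )
    return expanded, namespace


# ---------------------------------------------------------------------------
# build
# ---------------------------------------------------------------------------


def build_multicell_model(
    generic: MetabolicNetwork,
    coresets: Sequence[CoreSet],
    epsilon: float = DEFAULT_EPSILON,
    medium_metabolites: Optional[Iterable[str]] = None,
    biomass_reaction: str = BIOMASS_ID,
    penalties: Optional[Mapping[str, float]] = None,
) -> MultiCellModel:
    """Assemble and complete the multi-cell model of one condition.

    ``medium_metabolites`` (base ids) restricts which environment
    exchanges are forced into the core; by default all of them are,
    i.e. every exchanged metabolite is treated as available.
    """
    if not coresets:
        raise NetworkError("build_multicell_model: no core sets given")
    conditions = {cs.condition for cs in coresets}
    if len(conditions) > 1:
        raise NetworkError(
            f"build_multicell_model: core sets span multiple conditions: {sorted(conditions)}"
        )
    condition = next(iter(conditions))
    cell_types = [cs.cell_type for cs in coresets]
    if not generic.has_reaction(biomass_reaction):
        raise NetworkError(
            f"generic network lacks biomass-maintenance reaction {biomass_reaction!r}"
        )
    unknown = set().union(*(cs.core_reactions for cs in coresets)) - set(generic.reaction_ids)
    if unknown:
        raise NetworkError(f"core reactions not in generic network: {sorted(unknown)}")

    # consistency of the generic model first, then of the assembly
    generic_consistent = generic.subnetwork(
        find_consistent_subnetwork(generic, epsilon).consistent_reactions
    )

    expanded, namespace = expand_model(generic_consistent, cell_types)
    consistency = find_consistent_subnetwork(expanded, epsilon)
    consistent_net = expanded.subnetwork(consistency.consistent_reactions)

    core: Set[str] = set()
    for cs in coresets:
        for rid in cs.core_reactions:
            nid = namespaced(rid, cs.cell_type)
            if consistent_net.has_reaction(nid):
                core.add(nid)
        bio = namespaced(biomass_reaction, cs.cell_type)
        if not consistent_net.has_reaction(bio):
            raise InconsistentCoreError(
                f"biomass-maintenance reaction of cell type {cs.cell_type!r} "
                f"cannot be activated in the assembled model"
            )
        core.add(bio)
    for r in expanded.reactions:
        if namespace[r.id] != "medium":
            continue
        if medium_metabolites is not None:
            met = next(iter(r.stoichiometry))
            if base_id(met) not in set(medium_metabolites):
                continue
        if consistent_net.has_reaction(r.id):
            core.add(r.id)

    pen = dict(penalties) if penalties else None
    protected = {
        r.id for r in expanded.reactions
        if namespace[r.id] == "medium" and consistent_net.has_reaction(r.id)
    }
    kept = extract_core_subnetwork(
        consistent_net, core, epsilon, penalties=pen, protected=protected
    )
    final = consistent_net.subnetwork(kept)

    for cs in coresets:
        bio = namespaced(biomass_reaction, cs.cell_type)
        if not final.has_reaction(bio):
            raise InconsistentCoreError(
                f"cell type {cs.cell_type!r}: biomass reaction dropped during extraction"
            )

    provenance = {
        "generic_model_id": generic.id,
        "generic_model_sha256": hashlib.sha256(
            json.dumps(network_to_dict(generic), sort_keys=True).encode()
        ).hexdigest(),
        "epsilon": repr(epsilon),
    }
    return MultiCellModel(
        network=final,
        cell_types=list(cell_types),
        weights={cs.cell_type: cs.n_cells for cs in coresets},
        biomass_reaction={
            cs.cell_type: namespaced(biomass_reaction, cs.cell_type) for cs in coresets
        },
        reaction_namespace={rid: namespace[rid] for rid in final.reaction_ids},
        condition=condition,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# comparisons and summaries
# ---------------------------------------------------------------------------


def jaccard_similarity(a: MultiCellModel, b: MultiCellModel) -> float:
    """|A n B| / |A u B| over reaction-id sets of two multi-cell models."""
    if sorted(a.cell_types) != sorted(b.cell_types):
        raise NetworkError(
            "jaccard_similarity: models have different cell-type namespaces: "
            f"{sorted(a.cell_types)} vs {sorted(b.cell_types)}"
        )
    ra, rb = set(a.network.reaction_ids), set(b.network.reaction_ids)
    union = ra | rb
    if not union:
        return 1.0
    return len(ra & rb) / len(union)


def submodel_sizes(model: MultiCellModel) -> Dict[str, Tuple[int, int]]:
    """Per cell type: (number of reactions incl. transports, number of
    namespaced metabolites)."""
    out: Dict[str, Tuple[int, int]] = {}
    for t in model.cell_types:
        rxns = [r for r in model.network.reactions
                if model.reaction_namespace.get(r.id) == t]
        mets = {m for r in rxns for m in r.stoichiometry
                if not m.endswith(f"[{MEDIUM_COMPARTMENT}]")}
        out[t] = (len(rxns), len(mets))
    return out


def serialize_multicell(model: MultiCellModel) -> dict:
    """JSON document: network dialect plus a multicell extension block."""
    return network_to_dict(
        model.network,
        extra={
            "multicell": {
                "condition": model.condition,
                "cell_types": model.cell_types,
                "weights": model.weights,
                "biomass_reactions": model.biomass_reaction,
                "reaction_namespace": model.reaction_namespace,
                "provenance": model.provenance,
            }
        },
    )


def deserialize_multicell(doc: dict) -> MultiCellModel:
    from .network import _network_from_dict  # shared dialect reader

    if "multicell" not in doc:
        raise NetworkError("document lacks a 'multicell' extension block")
    mc = doc["multicell"]
    return MultiCellModel(
        network=_network_from_dict(doc),
        cell_types=list(mc["cell_types"]),
        weights={k: int(v) for k, v in mc["weights"].items()},
        biomass_reaction=dict(mc["biomass_reactions"]),
        reaction_namespace=dict(mc["reaction_namespace"]),
        condition=mc.get("condition", ""),
        provenance=dict(mc.get("provenance", {})),
    )
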