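"""Metabolic readouts derived from a flux solution.

*FluxSum* is the per-metabolite turnover estimate: the sum of producing
(incoming) fluxes, ``sum_j max(S_ij v_j, 0)``.  At steady state it
equals the consuming sum, so it measures how actively a metabolite is
cycled.  Pathway FluxSum sums the estimate over a pathway's key
metabolites.

Two exchange tables follow the conventions of the figures they emulate:

* medium uptake/secretion — positive = uptake by the cell population,
  negative = secretion into the environment;
* inter-cellular exchange — per cell type, negative = production/release
  of the metabolite into the shared medium, positive = uptake from it;
  a final "medium" row carries the net accumulation (secretion to the
  environment), so each table sums to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fba import SUPPORT_TOL, FluxSolution
from .multicell import MEDIUM_COMPARTMENT, MultiCellModel, namespaced
from .network import MetabolicNetwork, NetworkError, base_id


@dataclass(frozen=True)
class PathwayKey:
    """A pathway scored by the FluxSum of its key metabolites.

    Key metabolites are given as compartment-tagged base ids
    (e.g. ``pyr[c]``); scoping to a cell type namespaces them.
    """

    name: str
    key_metabolites: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.key_metabolites:
            raise NetworkError(f"pathway {self.name!r}: empty key metabolite list")


def default_pathway_keys() -> List[PathwayKey]:
    """Energy-pathway keys for the bundled toy network."""
    return [
        PathwayKey("glycolysis", ("g6p[c]", "pyr[c]", "lac_L[c]")),
        PathwayKey("TCA", ("cit[m]", "akg[m]", "succ[m]")),
        PathwayKey("OXPHOS", ("nadh[m]", "atp[c]")),
        PathwayKey("FAO", ("accoa[c]", "accoa[m]")),
    ]


def read_pathway_keys(path) -> List[PathwayKey]:
    """Pathway-key CSV (columns pathway, metabolite) -> keys."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "pathway" not in cols or "metabolite" not in cols:
        raise NetworkError(f"{path}: pathway key file needs 'pathway' and 'metabolite' columns")
    out = []
    for name, grp in df.groupby(cols["pathway"], sort=True):
        out.append(PathwayKey(str(name), tuple(grp[cols["metabolite"]].astype(str))))
    return out


# ---------------------------------------------------------------------------
# FluxSum
# ---------------------------------------------------------------------------


def flux_sum(
    solution: FluxSolution,
    network: MetabolicNetwork,
    metabolite_id: str,
    restrict_to: Optional[Iterable[str]] = None,
) -> float:
    """Sum of producing fluxes of one metabolite (non-negative).

    ``restrict_to`` limits the producing reactions considered, used for
    per-cell-type scoping.
    """
    if not any(m.id == metabolite_id for m in network.metabolites):
        raise NetworkError(f"unknown metabolite {metabolite_id!r}")
    allowed = set(restrict_to) if restrict_to is not None else None
    total = 0.0
    for r in network.reactions:
        coef = r.stoichiometry.get(metabolite_id)
        if coef is None:
            continue
        if allowed is not None and r.id not in allowed:
            continue
        total += max(coef * solution.flux(r.id), 0.0)
    return total


def pathway_flux_sum(
    solution: FluxSolution,
    model: MultiCellModel,
    key: PathwayKey,
    scope: Optional[str] = None,
) -> float:
    """Pathway FluxSum over the whole model or one cell type.

    Whole-model values are the sum of the per-type values, since every
    key metabolite instance lives in exactly one cell-type namespace.
    """
    types = [scope] if scope is not None else model.cell_types
    unknown = set(types) - set(model.cell_types)
    if unknown:
        raise NetworkError(f"unknown cell type scope: {sorted(unknown)}")
    met_ids = set(model.network.metabolite_ids)
    total = 0.0
    resolved = 0
    for t in types:
        for met in key.key_metabolites:
            mid = namespaced(met, t)
            if mid not in met_ids:
                continue
            resolved += 1
            total += flux_sum(solution, model.network, mid)
    if resolved == 0:
        raise NetworkError(
            f"pathway {key.name!r}: no key metabolite resolves in scope "
            f"{scope if scope is not None else 'whole-model'}"
        )
    return total


def pathway_flux_sum_table(
    solution: FluxSolution,
    model: MultiCellModel,
    keys: Optional[Sequence[PathwayKey]] = None,
) -> pd.DataFrame:
    """Tidy table: pathway x scope (each cell type and whole model)."""
    keys = list(keys) if keys is not None else default_pathway_keys()
    rows = []
    for key in keys:
        for scope in [*model.cell_types, None]:
            try:
                value = pathway_flux_sum(solution, model, key, scope)
            except NetworkError:
                continue
            rows.append(
                {
                    "pathway": key.name,
                    "scope": scope if scope is not None else "whole-model",
                    "flux_sum": value,
                }
            )
    return pd.DataFrame(rows, columns=["pathway", "scope", "flux_sum"])


# ---------------------------------------------------------------------------
# exchange reports
# ---------------------------------------------------------------------------


def medium_exchange_report(
    solution: FluxSolution, model: MultiCellModel, tol: float = SUPPORT_TOL
) -> pd.DataFrame:
    """Medium uptake (+) / secretion (-) rates per exchanged metabolite.

    Species with |flux| <= tol are omitted.
    """
    rows = []
    for met, rid in sorted(model.medium_exchanges().items()):
        v = solution.flux(rid)  # positive = secretion to environment
        if abs(v) <= tol:
            continue
        rows.append(
            {
                "metabolite": met,
                "scope": "medium",
                "rate": -v,
                "direction": "uptake" if v < 0 else "secretion",
            }
        )
    return pd.DataFrame(rows, columns=["metabolite", "scope", "rate", "direction"])


def intercellular_exchange_report(
    solution: FluxSolution, model: MultiCellModel, metabolite_base_id: str
) -> pd.DataFrame:
    """Per-cell-type exchange of one medium species.

    Negative = production/release by the cell type, positive = uptake;
    the "medium" row is the net accumulation (secretion to the
    environment).  Rows sum to zero by mass balance of the medium
    species.
    """
    exchanges = model.medium_exchanges()
    if metabolite_base_id not in exchanges:
        raise NetworkError(
            f"metabolite {metabolite_base_id!r} has no medium species in the model"
        )
    transports = model.transports_of(metabolite_base_id)
    rows = []
    for t in model.cell_types:
        rid = transports.get(t)
        release = solution.flux(rid) if rid else 0.0  # positive = into medium
        rows.append(
            {
                "metabolite": metabolite_base_id,
                "scope": t,
                "rate": -release,
                "direction": "production" if release > 0 else
                ("uptake" if release < 0 else "none"),
            }
        )
    env = solution.flux(exchanges[metabolite_base_id])
    rows.append(
        {
            "metabolite": metabolite_base_id,
            "scope": "medium",
            "rate": env,
            "direction": "accumulation" if env > 0 else ("depletion" if env < 0 else "none"),
        }
    )
    return pd.DataFrame(rows, columns=["metabolite", "scope", "rate", "direction"])


def write_report(df: pd.DataFrame, path) -> None:
    """Byte-stable TSV output (fixed float formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
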