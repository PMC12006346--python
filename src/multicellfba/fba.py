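"""Medium constraints, weighted biomass-maintenance FBA and
minimal-cardinality flux selection.

The solve proceeds in three stages:

1. *solo maxima* — for each cell type, maximise its biomass-maintenance
   flux alone (no floors);
2. *weighted optimum* — impose a floor of 10% of each type's solo
   maximum and maximise the cell-count-weighted sum of biomass fluxes,
   distributing the shared medium across the population;
3. *cardinality minimisation* — among flux vectors attaining the
   weighted optimum (within a relative tolerance) and all floors, pick
   one with as few active reactions as possible (exact mixed-integer
   program for models up to a size threshold, iteratively reweighted
   1-norm heuristic above it).

Sign convention: environment exchanges are written ``met[u] -> (out)``,
so negative flux is uptake; a medium entry of ``b`` sets the exchange
lower bound to ``-b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from ._lp import FEAS_TOL, LinearSystem, SolverError, optimize_flux, solve_lp
from .multicell import MultiCellModel
from .network import DEFAULT_BOUND, NetworkError, base_id

#: fraction of the solo maximum each cell type must maintain
MAINTENANCE_FLOOR = 0.1

#: relative tolerance when fixing the weighted optimum
OBJECTIVE_REL_TOL = 1e-6

#: models with at most this many reactions use the exact MILP
MILP_SIZE_THRESHOLD = 400

#: |flux| above this counts toward the support size
SUPPORT_TOL = 1e-6


class MediumError(NetworkError):
    """Medium definition does not match the model."""


@dataclass
class MediumDefinition:
    """Medium composition mapped directly to maximal uptake bounds (a.u.).

    ``o2_glucose_ratio`` overrides the oxygen bound with
    ratio x glucose bound (default 2, the organoid-culture setting; 5
    approximates the physiological brain ratio).  ``special_bounds``
    holds the biomass-enabling trace uptakes (thymidine-triphosphate and
    linoleate default to 1).
    """

    entries: Dict[str, float]
    o2_glucose_ratio: float = 2.0
    special_bounds: Dict[str, float] = field(
        default_factory=lambda: {"thymd": 1.0, "lnlc": 1.0}
    )
    glucose_id: str = "glc_D"
    oxygen_id: str = "o2"

    def __post_init__(self) -> None:
        if self.o2_glucose_ratio <= 0:
            raise MediumError("o2_glucose_ratio must be positive")
        for src in (self.entries, self.special_bounds):
            for met, b in src.items():
                if b < 0:
                    raise MediumError(f"uptake bound for {met!r} must be >= 0")

    def uptake_bounds(self) -> Dict[str, float]:
        """Effective per-species maximal uptake bounds (oxygen resolved)."""
        out = dict(self.special_bounds)
        out.update(self.entries)
        if self.glucose_id not in out:
            raise MediumError(f"medium lists no glucose entry ({self.glucose_id!r})")
        out[self.oxygen_id] = self.o2_glucose_ratio * out[self.glucose_id]
        return out


def read_medium(path, **kwargs) -> MediumDefinition:
    """Medium table (CSV/TSV with columns metabolite, bound) -> definition."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "metabolite" not in cols or "bound" not in cols:
        raise MediumError(f"{path}: medium table needs 'metabolite' and 'bound' columns")
    entries = dict(zip(df[cols["metabolite"]].astype(str), df[cols["bound"]].astype(float)))
    return MediumDefinition(entries=entries, **kwargs)


# ---------------------------------------------------------------------------
# medium application
# ---------------------------------------------------------------------------


def apply_medium(model: MultiCellModel, medium: MediumDefinition) -> MultiCellModel:
    """Constrain environment exchanges to the medium composition.

    Listed species get uptake bound = entry; unlisted species get uptake
    bound 0 with secretion unrestricted; the oxygen bound is always
    ``o2_glucose_ratio`` x glucose bound.
    """
    exchanges = model.medium_exchanges()
    for required, label in ((medium.glucose_id, "glucose"), (medium.oxygen_id, "oxygen")):
        if required not in exchanges:
            raise MediumError(
                f"model has no environment exchange for {label} ({required!r})"
            )
    bounds = medium.uptake_bounds()
    unknown = set(bounds) - set(exchanges)
    if unknown - set(medium.special_bounds):
        raise MediumError(
            f"medium species without environment exchange: {sorted(unknown)}"
        )
    new_bounds: Dict[str, Tuple[float, float]] = {}
    for met, rid in exchanges.items():
        uptake = bounds.get(met, 0.0)
        rxn = model.network.reaction(rid)
        ub = rxn.upper_bound if rxn.upper_bound > 0 else DEFAULT_BOUND
        new_bounds[rid] = (-uptake, ub)
    return replace(model, network=model.network.with_bounds(new_bounds))


# ---------------------------------------------------------------------------
# weighted biomass FBA
# ---------------------------------------------------------------------------


@dataclass
class WeightedBiomassResult:
    objective_value: float
    per_type_max_biomass: Dict[str, float]
    floors: Dict[str, float]
    fluxes: pd.Series


@dataclass
class FluxSolution:
    """Steady-state flux vector with the solve's provenance."""

    fluxes: pd.Series  # indexed by reaction id
    objective_value: float
    per_type_max_biomass: Dict[str, float]
    support_size: int
    solver_metadata: Dict[str, object] = field(default_factory=dict)

    def flux(self, rid: str) -> float:
        return float(self.fluxes.get(rid, 0.0))


def _floor_constraints(
    system: LinearSystem, model: MultiCellModel, floors: Mapping[str, float]
) -> np.ndarray:
    lo = system.lb.copy()
    for t, f in floors.items():
        j = system.index[model.biomass_reaction[t]]
        lo[j] = max(lo[j], f)
    return lo


def maximize_weighted_biomass(
    model: MultiCellModel, floor_fraction: float = MAINTENANCE_FLOOR
) -> WeightedBiomassResult:
    """Two-stage weighted biomass-maintenance FBA.

    Stage 1 records each cell type's solo biomass maximum; stage 2
    maximises the cell-count-weighted biomass sum subject to per-type
    floors of ``floor_fraction`` x solo maximum.
    """
    system = LinearSystem.from_network(model.network)
    per_type_max: Dict[str, float] = {}
    for t in model.cell_types:
        try:
            val, _ = optimize_flux(system, {model.biomass_reaction[t]: 1.0}, sense="max")
        except SolverError as exc:
            raise SolverError(f"solo biomass FBA failed for cell type {t!r}: {exc}") from exc
        per_type_max[t] = val
    floors = {t: floor_fraction * per_type_max[t] for t in model.cell_types}
    lo = _floor_constraints(system, model, floors)
    objective = {
        model.biomass_reaction[t]: float(model.weights[t]) for t in model.cell_types
    }
    try:
        val, v = optimize_flux(system, objective, sense="max", lb=lo)
    except SolverError as exc:
        raise SolverError(
            "weighted biomass FBA infeasible under maintenance floors; a medium "
            f"component cannot cover all cell types: {exc}"
        ) from exc
    return WeightedBiomassResult(
        objective_value=val,
        per_type_max_biomass=per_type_max,
        floors=floors,
        fluxes=pd.Series(v, index=system.reaction_ids),
    )


# ---------------------------------------------------------------------------
# minimal-cardinality flux
# ---------------------------------------------------------------------------


def _objective_row(system: LinearSystem, objective: Mapping[str, float]) -> np.ndarray:
    row = np.zeros(system.n)
    for rid, w in objective.items():
        row[system.index[rid]] = w
    return row


def _solve_milp_cardinality(
    system: LinearSystem,
    lo: np.ndarray,
    hi: np.ndarray,
    obj_row: np.ndarray,
    fixed_objective: float,
    rel_tol: float,
) -> np.ndarray:
    n, m = system.n, system.m
    big_m = np.maximum(np.abs(lo), np.abs(hi))
    big_m[big_m == 0] = 1.0
    # variables: v (n), y (n binary)
    A_eq = sparse.hstack([system.S, sparse.csr_matrix((m, n))])
    eye = sparse.identity(n, format="csr")
    Mdiag = sparse.diags(big_m)
    cons = [
        LinearConstraint(A_eq.tocsc(), 0.0, 0.0),
        # v - M y <= 0
        LinearConstraint(sparse.hstack([eye, -Mdiag]).tocsc(), -np.inf, 0.0),
        # -v - M y <= 0
        LinearConstraint(sparse.hstack([-eye, -Mdiag]).tocsc(), -np.inf, 0.0),
        LinearConstraint(
            sparse.csr_matrix(np.concatenate([obj_row, np.zeros(n)])).tocsc(),
            fixed_objective - rel_tol * max(1.0, abs(fixed_objective)),
            np.inf,
        ),
    ]
    # tiny index-ordered weights bias ties toward lexicographically early
    # reaction supports without affecting the cardinality optimum
    order = np.argsort(np.argsort(system.reaction_ids))
    c = np.concatenate([np.zeros(n), 1.0 + 1e-7 * order])
    integrality = np.concatenate([np.zeros(n), np.ones(n)])
    res = milp(
        c=c,
        constraints=cons,
        integrality=integrality,
        bounds=Bounds(np.concatenate([lo, np.zeros(n)]),
                      np.concatenate([hi, np.ones(n)])),
    )
    if res.status != 0:
        raise SolverError(f"cardinality MILP failed: status={res.status} ({res.message})")
    return res.x[:n]


def _solve_l1_cardinality(
    system: LinearSystem,
    lo: np.ndarray,
    hi: np.ndarray,
    obj_row: np.ndarray,
    fixed_objective: float,
    rel_tol: float,
    n_reweight: int = 5,
) -> np.ndarray:
    """Iteratively reweighted 1-norm surrogate of the zero norm."""
    n, m = system.n, system.m
    eye = sparse.identity(n, format="csr")
    A_eq = sparse.hstack([system.S, sparse.csr_matrix((m, n))]).tocsr()
    b_eq = np.zeros(m)
    A_ub = sparse.vstack([
        sparse.hstack([eye, -eye]),
        sparse.hstack([-eye, -eye]),
        sparse.csr_matrix(np.concatenate([-obj_row, np.zeros(n)])),
    ]).tocsr()
    b_ub = np.concatenate(
        [np.zeros(2 * n), [-(fixed_objective - rel_tol * max(1.0, abs(fixed_objective)))]]
    )
    bounds = list(zip(lo, hi)) + [(0.0, None)] * n
    w = np.ones(n)
    v = None
    for _ in range(n_reweight):
        x = solve_lp(np.concatenate([np.zeros(n), w]), A_eq=A_eq, b_eq=b_eq,
                     A_ub=A_ub, b_ub=b_ub, bounds=bounds)
        v = x[:n]
        w = 1.0 / (np.abs(v) + 1e-6)
    return v


def _polish_support(
    system: LinearSystem,
    lo: np.ndarray,
    hi: np.ndarray,
    obj_row: np.ndarray,
    fixed_objective: float,
    rel_tol: float,
    v: np.ndarray,
) -> np.ndarray:
    """Verify the support: re-solve with near-zero fluxes pinned to zero."""
    support = np.abs(v) > SUPPORT_TOL
    lo2, hi2 = lo.copy(), hi.copy()
    lo2[~support] = 0.0
    hi2[~support] = 0.0
    n, m = system.n, system.m
    A_ub = sparse.csr_matrix(-obj_row)
    b_ub = np.array([-(fixed_objective - rel_tol * max(1.0, abs(fixed_objective)))])
    try:
        x = solve_lp(np.zeros(n), A_eq=system.S, b_eq=np.zeros(m),
                     A_ub=A_ub, b_ub=b_ub, bounds=list(zip(lo2, hi2)))
        return x
    except SolverError:
        return v


def minimal_cardinality_flux(
    model: MultiCellModel,
    fixed_objective: float,
    per_type_max_biomass: Optional[Mapping[str, float]] = None,
    floor_fraction: float = MAINTENANCE_FLOOR,
    rel_tol: float = OBJECTIVE_REL_TOL,
    method: str = "auto",
    milp_threshold: int = MILP_SIZE_THRESHOLD,
) -> FluxSolution:
    """Flux vector attaining the weighted objective with minimal support.

    ``method``: "milp" (exact), "l1" (reweighted heuristic) or "auto"
    (exact up to ``milp_threshold`` reactions).
    """
    system = LinearSystem.from_network(model.network)
    if per_type_max_biomass is None:
        per_type_max_biomass = maximize_weighted_biomass(
            model, floor_fraction
        ).per_type_max_biomass
    floors = {t: floor_fraction * per_type_max_biomass[t] for t in model.cell_types}
    lo = _floor_constraints(system, model, floors)
    hi = system.ub.copy()
    objective = {
        model.biomass_reaction[t]: float(model.weights[t]) for t in model.cell_types
    }
    obj_row = _objective_row(system, objective)

    if method == "auto":
        method = "milp" if system.n <= milp_threshold else "l1"
    if method == "milp":
        v = _solve_milp_cardinality(system, lo, hi, obj_row, fixed_objective, rel_tol)
    elif method == "l1":
        v = _solve_l1_cardinality(system, lo, hi, obj_row, fixed_objective, rel_tol)
        v = _polish_support(system, lo, hi, obj_row, fixed_objective, rel_tol, v)
    else:
        raise ValueError(f"unknown cardinality method {method!r}")

    v = np.where(np.abs(v) <= SUPPORT_TOL, 0.0, v)
    fluxes = pd.Series(v, index=system.reaction_ids)
    return FluxSolution(
        fluxes=fluxes,
        objective_value=float(obj_row @ v),
        per_type_max_biomass=dict(per_type_max_biomass),
        support_size=int((np.abs(v) > SUPPORT_TOL).sum()),
        solver_metadata={
            "method": method,
            "rel_tol": rel_tol,
            "floor_fraction": floor_fraction,
            "fixed_objective": fixed_objective,
            "support_tol": SUPPORT_TOL,
            "status": "optimal",
        },
    )


def solve_model(
    model: MultiCellModel,
    medium: Optional[MediumDefinition] = None,
    floor_fraction: float = MAINTENANCE_FLOOR,
    method: str = "auto",
) -> FluxSolution:
    """Convenience: apply medium, run both FBA stages, minimise cardinality."""
    constrained = apply_medium(model, medium) if medium is not None else model
    weighted = maximize_weighted_biomass(constrained, floor_fraction)
    return minimal_cardinality_flux(
        constrained,
        fixed_objective=weighted.objective_value,
        per_type_max_biomass=weighted.per_type_max_biomass,
        floor_fraction=floor_fraction,
        method=method,
    )


# ---------------------------------------------------------------------------
# minimal substrate requirement
# ---------------------------------------------------------------------------


def minimal_substrate_requirement(
    model: MultiCellModel,
    substrate_exchange_id: str,
    fixed_objective: float,
    per_type_max_biomass: Optional[Mapping[str, float]] = None,
    floor_fraction: float = MAINTENANCE_FLOOR,
    rel_tol: float = OBJECTIVE_REL_TOL,
) -> float:
    """Minimal uptake of one medium substrate compatible with the objective.

    Minimises the uptake flux of the named environment exchange subject to
    the weighted biomass objective (within ``rel_tol``) and all floors.
    Returns the uptake as a non-negative number (0 when the objective is
    attainable without the substrate).
    """
    if not model.network.has_reaction(substrate_exchange_id):
        raise NetworkError(f"no such exchange reaction: {substrate_exchange_id!r}")
    system = LinearSystem.from_network(model.network)
    if per_type_max_biomass is None:
        per_type_max_biomass = maximize_weighted_biomass(
            model, floor_fraction
        ).per_type_max_biomass
    floors = {t: floor_fraction * per_type_max_biomass[t] for t in model.cell_types}
    lo = _floor_constraints(system, model, floors)
    objective = {
        model.biomass_reaction[t]: float(model.weights[t]) for t in model.cell_types
    }
    obj_row = _objective_row(system, objective)
    A_ub = sparse.csr_matrix(-obj_row)
    b_ub = np.array([-(fixed_objective - rel_tol * max(1.0, abs(fixed_objective)))])
    # exchange flux is negative for uptake; maximising it minimises uptake
    val, _ = optimize_flux(
        system, {substrate_exchange_id: 1.0}, sense="max",
        extra_ub=(A_ub, b_ub), lb=lo,
    )
    return max(0.0, -val)


# ---------------------------------------------------------------------------
# solution checks
# ---------------------------------------------------------------------------


def check_solution(
    model: MultiCellModel,
    solution: FluxSolution,
    floor_fraction: float = MAINTENANCE_FLOOR,
    tol: float = 1e-6,
) -> None:
    """Assert steady state, bounds and maintenance floors; raise on violation."""
    system = LinearSystem.from_network(model.network)
    v = solution.fluxes.reindex(system.reaction_ids).to_numpy()
    residual = np.abs(system.S @ v)
    if residual.size and residual.max() > tol:
        raise SolverError(f"steady-state violation: max |S v| = {residual.max():.3g}")
    if ((v - system.ub) > tol).any() or ((system.lb - v) > tol).any():
        raise SolverError("flux bounds violated")
    for t in model.cell_types:
        floor = floor_fraction * solution.per_type_max_biomass[t]
        if solution.flux(model.biomass_reaction[t]) < floor - tol:
            raise SolverError(f"maintenance floor violated for cell type {t!r}")
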