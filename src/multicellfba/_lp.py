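"""Thin deterministic LP layer over scipy's HiGHS interface.

All optimisation in the package goes through this module so that solver
options, tolerances and determinism live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .network import MetabolicNetwork

#: solver feasibility tolerance used when interpreting LP results
FEAS_TOL = 1e-9


class SolverError(RuntimeError):
    """LP/MILP failure with solver status attached."""


@dataclass
class LinearSystem:
    """Compiled steady-state view of a network: S v = 0, lb <= v <= ub."""

    S: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: List[str]
    index: Dict[str, int]

    @classmethod
    def from_network(cls, network: MetabolicNetwork) -> "LinearSystem":
        rids = network.reaction_ids
        return cls(
            S=network.stoichiometric_matrix().tocsr(),
            lb=np.array([r.lower_bound for r in network.reactions], dtype=float),
            ub=np.array([r.upper_bound for r in network.reactions], dtype=float),
            reaction_ids=rids,
            index={r: j for j, r in enumerate(rids)},
        )

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    @property
    def m(self) -> int:
        return self.S.shape[0]


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[sparse.spmatrix] = None,
    b_eq: Optional[np.ndarray] = None,
    A_ub: Optional[sparse.spmatrix] = None,
    b_ub: Optional[np.ndarray] = None,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
) -> np.ndarray:
    """Minimise c'x; raise SolverError unless optimal."""
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        # dual simplex: vertex solutions keep 1-norm supports sparse
        method="highs-ds",
    )
    if res.status != 0:
        raise SolverError(f"LP failed: status={res.status} ({res.message.strip()})")
    return res.x


def optimize_flux(
    system: LinearSystem,
    objective: Dict[str, float],
    sense: str = "max",
    extra_eq: Optional[Tuple[sparse.spmatrix, np.ndarray]] = None,
    extra_ub: Optional[Tuple[sparse.spmatrix, np.ndarray]] = None,
    lb: Optional[np.ndarray] = None,
    ub: Optional[np.ndarray] = None,
) -> Tuple[float, np.ndarray]:
    """FBA-style LP: optimise a linear flux objective at steady state."""
    lo = system.lb if lb is None else lb
    hi = system.ub if ub is None else ub
    c = np.zeros(system.n)
    for rid, w in objective.items():
        c[system.index[rid]] = w
    sign = -1.0 if sense == "max" else 1.0
    A_eq: sparse.spmatrix = system.S
    b_eq = np.zeros(system.m)
    if extra_eq is not None:
        A_eq = sparse.vstack([A_eq, extra_eq[0]])
        b_eq = np.concatenate([b_eq, extra_eq[1]])
    A_ub = b_ub = None
    if extra_ub is not None:
        A_ub, b_ub = extra_ub
    x = solve_lp(sign * c, A_eq=A_eq.tocsr(), b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                 bounds=list(zip(lo, hi)))
    return float(c @ x), x


def flux_range(system: LinearSystem, rid: str) -> Tuple[float, float]:
    """Min and max steady-state flux of one reaction (2 LPs)."""
    lo, _ = optimize_flux(system, {rid: 1.0}, sense="min")
    hi, _ = optimize_flux(system, {rid: 1.0}, sense="max")
    return lo, hi
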