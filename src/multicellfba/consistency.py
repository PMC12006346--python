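"""Flux-consistency testing and core-based subnetwork extraction.

``find_consistent_subnetwork`` is an LP-based consistency scan in the
FASTCC family: it identifies every reaction able to carry a steady-state
flux of magnitude at least ``epsilon`` within bounds.  A reaction that
cannot is *blocked* and removed.

``extract_core_subnetwork`` is a FASTCORE-style extraction: starting from
a set of core reactions that must be present, it alternates between an
LP that pushes flux through as many pending core reactions as possible
(LP-7) and a weighted 1-norm LP that activates them while penalising
flux through non-core reactions (LP-10).  The result is a compact
flux-consistent superset of the core.  Compactness is heuristic, as in
the original algorithm; on small networks it is minimal or within one
reaction of minimal.

Reversible reactions are handled by temporary bound flipping inside the
LPs; reaction identities in the returned sets are always those of the
input network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse

from ._lp import FEAS_TOL, LinearSystem, SolverError, solve_lp
from .network import MetabolicNetwork, NetworkError

logger = logging.getLogger(__name__)

#: default flux-activation threshold, a.u.
DEFAULT_EPSILON = 1e-4

#: |v| above this is counted as carrying flux in LP support extraction
_SUPPORT_TOL = 1e-8


class InconsistentCoreError(NetworkError):
    """A core reaction cannot carry flux in the (consistent) network."""


@dataclass
class ConsistencyResult:
    consistent_reactions: Set[str]
    removed_reactions: Set[str]
    epsilon: float
    lp_count: int = 0

    @property
    def is_fully_consistent(self) -> bool:
        return not self.removed_reactions


# ---------------------------------------------------------------------------
# LP building blocks
# ---------------------------------------------------------------------------


def _lp7(system: LinearSystem, J: Sequence[int], epsilon: float,
         lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Maximise the number of reactions in J carrying forward flux >= eps.

    Variables: v (fluxes) and z_j for j in J with 0 <= z_j <= eps and
    z_j <= v_j; maximise sum z.  Returns the flux vector.
    """
    n, m, k = system.n, system.m, len(J)
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_eq = sparse.hstack([system.S, sparse.csr_matrix((m, k))]).tocsr()
    b_eq = np.zeros(m)
    # z_j - v_j <= 0
    rows = np.arange(k)
    A_ub = sparse.hstack(
        [
            sparse.csr_matrix((-np.ones(k), (rows, np.asarray(J))), shape=(k, n)),
            sparse.identity(k, format="csr"),
        ]
    ).tocsr()
    b_ub = np.zeros(k)
    bounds = list(zip(lb, ub)) + [(0.0, epsilon)] * k
    x = solve_lp(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds)
    return x[:n]


def _lp10(system: LinearSystem, K: Sequence[int], P: Sequence[int], epsilon: float,
          lb: np.ndarray, ub: np.ndarray,
          weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Activate every reaction in K (v_k >= eps) while minimising the
    weighted 1-norm of flux through the penalty set P."""
    n, m, p = system.n, system.m, len(P)
    w = np.ones(p) if weights is None else weights
    c = np.concatenate([np.zeros(n), w])
    A_eq = sparse.hstack([system.S, sparse.csr_matrix((m, p))]).tocsr()
    b_eq = np.zeros(m)
    rows = np.arange(p)
    Pj = np.asarray(P)
    sel = sparse.csr_matrix((np.ones(p), (rows, Pj)), shape=(p, n))
    eye = sparse.identity(p, format="csr")
    #  v_p - z_p <= 0   and   -v_p - z_p <= 0
    A_ub = sparse.vstack([
        sparse.hstack([sel, -eye]),
        sparse.hstack([-sel, -eye]),
    ]).tocsr()
    b_ub = np.zeros(2 * p)
    lo = lb.copy()
    for k in K:
        lo[k] = max(lo[k], epsilon)
    bounds = list(zip(lo, ub)) + [(0.0, None)] * p
    x = solve_lp(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds)
    return x[:n]


def _support(v: np.ndarray, tol: float = _SUPPORT_TOL) -> Set[int]:
    return set(np.flatnonzero(np.abs(v) > tol))


def _sorted(ids: Iterable[int], system: LinearSystem) -> List[int]:
    # deterministic iteration: lexicographic by reaction id
    return sorted(ids, key=lambda j: system.reaction_ids[j])


# ---------------------------------------------------------------------------
# consistency scan (FASTCC-style)
# ---------------------------------------------------------------------------


def find_consistent_subnetwork(
    network: MetabolicNetwork, epsilon: float = DEFAULT_EPSILON
) -> ConsistencyResult:
    """Partition reactions into flux-consistent and blocked at ``epsilon``."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    system = LinearSystem.from_network(network)
    n = system.n
    lb, ub = system.lb.copy(), system.ub.copy()
    irreversible = {j for j in range(n) if network.reactions[j].lower_bound >= 0}
    lp_count = 0

    def lp7(J: Sequence[int]) -> np.ndarray:
        nonlocal lp_count
        lp_count += 1
        return _lp7(system, J, epsilon, lb, ub)

    sup_tol = 0.99 * epsilon
    A: Set[int] = set()

    # first pass: push flux through all irreversible reactions at once
    J = _sorted(irreversible, system)
    if J:
        try:
            v = lp7(J)
        except SolverError as exc:
            raise NetworkError(f"network admits no steady state: {exc}") from exc
        A |= _support(v, sup_tol)
    blocked_irr = set(J) - A
    J_set = set(range(n)) - A - blocked_irr

    flipped = False
    singleton = False
    while J_set:
        if singleton:
            Ji = [_sorted(J_set, system)[0]]
        else:
            Ji = _sorted(J_set, system)
        v = lp7(Ji)
        A |= _support(v, sup_tol)
        if J_set & A:
            J_set -= A
            flipped = False
        else:
            Ji_rev = [j for j in Ji if j not in irreversible]
            if flipped or not Ji_rev:
                flipped = False
                if singleton:
                    # tested alone in both directions: blocked
                    J_set -= set(Ji)
                else:
                    singleton = True
            else:
                for j in Ji_rev:
                    lb[j], ub[j] = -system.ub[j], -system.lb[j]
                flipped = True

    consistent = {system.reaction_ids[j] for j in A}
    removed = set(network.reaction_ids) - consistent
    if removed:
        logger.info("consistency scan removed %d/%d reactions", len(removed), n)
    return ConsistencyResult(
        consistent_reactions=consistent,
        removed_reactions=removed,
        epsilon=epsilon,
        lp_count=lp_count,
    )


# ---------------------------------------------------------------------------
# core extraction (FASTCORE-style)
# ---------------------------------------------------------------------------


def extract_core_subnetwork(
    network: MetabolicNetwork,
    core: Iterable[str],
    epsilon: float = DEFAULT_EPSILON,
    penalties: Optional[Dict[str, float]] = None,
    prune: bool = True,
    protected: Optional[Iterable[str]] = None,
) -> Set[str]:
    """Compact flux-consistent reaction set containing every core reaction.

    ``network`` must itself be flux-consistent at ``epsilon`` (run
    :func:`find_consistent_subnetwork` first).  ``penalties`` optionally
    re-weights the cost of adding specific non-core reactions (default 1
    for every non-core reaction).

    The 1-norm surrogate inside the extraction can favour flux-dense
    detours (e.g. a high-ATP-yield chain) over support-sparse ones, so
    with ``prune`` (default) a deterministic greedy pass afterwards drops
    every non-core addition whose removal keeps the core flux-consistent.
    ``protected`` reactions (e.g. boundary exchanges) are never pruned.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    core = set(core)
    unknown = core - set(network.reaction_ids)
    if unknown:
        raise NetworkError(f"core reaction(s) not in network: {sorted(unknown)}")
    if not core:
        return set()

    system = LinearSystem.from_network(network)
    n = system.n
    lb, ub = system.lb.copy(), system.ub.copy()
    irreversible = {j for j in range(n) if network.reactions[j].lower_bound >= 0}
    C = {system.index[r] for r in core}
    N = set(range(n))

    pen = np.ones(n)
    if penalties:
        for rid, w in penalties.items():
            if w < 0:
                raise ValueError(f"penalty for {rid!r} must be non-negative")
            pen[system.index[rid]] = w

    sup_tol = 0.99 * epsilon

    def find_sparse_mode(J: Set[int], P: Set[int], singleton: bool) -> Set[int]:
        if not J:
            return set()
        Ji = [_sorted(J, system)[0]] if singleton else _sorted(J, system)
        v = _lp7(system, Ji, epsilon, lb, ub)
        K = [j for j in Ji if v[j] >= sup_tol]
        if not K:
            return set()
        Pl = _sorted(P, system)
        v = _lp10(system, K, Pl, epsilon, lb, ub,
                  weights=pen[np.asarray(Pl)] if Pl else None)
        return _support(v)

    flipped = False
    singleton = False
    J = C & irreversible
    P = N - C
    supp = find_sparse_mode(J, P, singleton=False)
    missing = J - supp
    if missing:
        raise InconsistentCoreError(
            "irreversible core reaction(s) cannot be activated: "
            + ", ".join(sorted(system.reaction_ids[j] for j in missing))
        )
    A = set(supp)
    J = C - A

    while J:
        P = P - A
        supp = find_sparse_mode(J, P, singleton)
        A |= supp
        if J & A:
            J -= A
            flipped = False
            singleton = False
        else:
            if singleton:
                Jrev = {_sorted(J, system)[0]} - irreversible
            else:
                Jrev = J - irreversible
            if not Jrev or flipped:
                if singleton:
                    rid = system.reaction_ids[_sorted(J, system)[0]]
                    raise InconsistentCoreError(
                        f"core reaction {rid!r} cannot be activated"
                    )
                flipped = False
                singleton = True
            else:
                for j in Jrev:
                    lb[j], ub[j] = -system.ub[j], -system.lb[j]
                flipped = True

    result = {system.reaction_ids[j] for j in A}
    if prune:
        keep = core | (set(protected) & result if protected else set())
        result = _prune_additions(network, result, C_ids=keep, epsilon=epsilon)
    return result


def _prune_additions(
    network: MetabolicNetwork, kept: Set[str], C_ids: Set[str], epsilon: float
) -> Set[str]:
    """Greedy removal of non-core additions, lexicographic order.

    A candidate is dropped when the remaining induced subnetwork still
    supports every core reaction at ``epsilon``; anything newly blocked
    by the drop is removed along with it.
    """
    current = set(kept)
    for rid in sorted(kept - C_ids):
        if rid not in current:
            continue
        trial = current - {rid}
        res = find_consistent_subnetwork(network.subnetwork(trial), epsilon)
        if C_ids <= res.consistent_reactions:
            current = res.consistent_reactions
    return current
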