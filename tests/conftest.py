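"""Shared fixtures and independent LP oracles.

The oracle helpers here deliberately build their LPs straight from a
network's stoichiometry with scipy.optimize.linprog, bypassing the
package's solver layer, so they stay independent of the code they
check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pytest
from scipy.optimize import linprog

from multicellfba.expression import CoreSet
from multicellfba.multicell import MultiCellModel
from multicellfba.network import MetabolicNetwork, Metabolite, Reaction
from multicellfba.synthetic import (
    make_toy_network,
    run_scenario,
    scenario_lactate_shuttle,
)

# ---------------------------------------------------------------------------
# toy networks
# ---------------------------------------------------------------------------


def _met(mid: str) -> Metabolite:
    comp = mid[mid.index("[") + 1 : mid.index("]")] if "[" in mid else "c"
    return Metabolite(id=mid, compartment=comp)


def build_network(reactions, boundary=("e",), model_id="test") -> MetabolicNetwork:
    """reactions: list of (id, stoich, (lb, ub)) tuples."""
    mets = sorted({m for _, stoich, _ in reactions for m in stoich})
    return MetabolicNetwork(
        metabolites=[_met(m) for m in mets],
        reactions=[
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
            for rid, stoich, (lb, ub) in reactions
        ],
        boundary_compartments=set(boundary),
        id=model_id,
    )


@pytest.fixture(scope="session")
def toy_network() -> MetabolicNetwork:
    return make_toy_network()


@pytest.fixture
def chain_network() -> MetabolicNetwork:
    """EX_A -> A -> B -> EX_B, all bounds (0, 10)."""
    return build_network(
        [
            ("EX_A", {"A[e]": 1}, (0, 10)),
            ("T_A", {"A[e]": -1, "A[c]": 1}, (0, 10)),
            ("R_AB", {"A[c]": -1, "B[c]": 1}, (0, 10)),
            ("T_B", {"B[c]": -1, "B[e]": 1}, (0, 10)),
            ("EX_B", {"B[e]": -1}, (0, 10)),
        ]
    )


@pytest.fixture
def diamond_network() -> MetabolicNetwork:
    """Two parallel 2-reaction routes between A and B."""
    return build_network(
        [
            ("EX_A", {"A[c]": 1}, (0, 10)),
            ("R1a", {"A[c]": -1, "X[c]": 1}, (0, 10)),
            ("R1b", {"X[c]": -1, "B[c]": 1}, (0, 10)),
            ("R2a", {"A[c]": -1, "Y[c]": 1}, (0, 10)),
            ("R2b", {"Y[c]": -1, "B[c]": 1}, (0, 10)),
            ("EX_B", {"B[c]": -1}, (0, 10)),
        ],
        boundary=("c",),  # single-compartment toy; EX_* are the boundary
    )


def full_core_multicell(network=None, weights=None, cell_types=("cell",)):
    """Multi-cell model from the toy generic with every GPR-bearing and
    internal reaction in each type's core (extraction keeps everything)."""
    from multicellfba.multicell import build_multicell_model

    network = network or make_toy_network()
    exchange = {r.id for r in network.exchange_reactions()}
    core = set(network.reaction_ids) - exchange
    weights = weights or {t: 1 for t in cell_types}
    coresets = [
        CoreSet(condition="cond", cell_type=t, core_genes=set(),
                core_reactions=core, n_cells=weights[t])
        for t in cell_types
    ]
    return build_multicell_model(network, coresets)


@pytest.fixture(scope="session")
def single_type_model() -> MultiCellModel:
    return full_core_multicell()


@pytest.fixture(scope="session")
def baseline_outcome():
    return run_scenario(scenario_lactate_shuttle(seed=11))


@pytest.fixture(scope="session")
def disrupted_outcome():
    return run_scenario(scenario_lactate_shuttle(seed=11, disrupted=True))


# ---------------------------------------------------------------------------
# independent LP oracles
# ---------------------------------------------------------------------------


def oracle_flux_range(network: MetabolicNetwork, rxn_id: str):
    """Min/max steady-state flux of one reaction, solved from scratch."""
    mets = {m.id: i for i, m in enumerate(network.metabolites)}
    n = len(network.reactions)
    S = np.zeros((len(mets), n))
    for j, r in enumerate(network.reactions):
        for m, c in r.stoichiometry.items():
            S[mets[m], j] = c
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    j = network.reaction_ids.index(rxn_id)
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(n)
        c[j] = sign
        res = linprog(c, A_eq=S, b_eq=np.zeros(len(mets)), bounds=bounds,
                      method="highs")
        assert res.status == 0, res.message
        out.append(res.x[j])
    return out[0], out[1]  # (min, max)


def oracle_consistent_set(network: MetabolicNetwork, epsilon: float):
    """Brute-force consistency: per-reaction max/min flux on the full
    network (a blocked reaction carries zero in every steady state, so
    one FVA pass is exact)."""
    out = set()
    for rid in network.reaction_ids:
        lo, hi = oracle_flux_range(network, rid)
        if hi >= epsilon or lo <= -epsilon:
            out.add(rid)
    return out


def oracle_subnetwork_consistent(network: MetabolicNetwork, rxn_ids, epsilon: float):
    """Is the induced subnetwork flux-consistent at epsilon?"""
    sub = network.subnetwork(rxn_ids)
    return oracle_consistent_set(sub, epsilon) == set(rxn_ids)


def oracle_minimal_consistent_supersets(network: MetabolicNetwork, core, epsilon: float):
    """Exhaustively enumerate minimal flux-consistent supersets of core."""
    core = set(core)
    others = sorted(set(network.reaction_ids) - core)
    best, best_size = [], None
    for k in range(len(others) + 1):
        if best_size is not None and len(core) + k > best_size:
            break
        for extra in itertools.combinations(others, k):
            cand = core | set(extra)
            if oracle_subnetwork_consistent(network, cand, epsilon):
                best.append(cand)
                best_size = len(cand)
        if best:
            break
    return best


def random_small_network(rng: np.random.Generator) -> MetabolicNetwork:
    """Random <=10-reaction network with mixed reversibility, exchanges
    and internal conversions (dead ends and blocked cycles arise often)."""
    n_int = int(rng.integers(2, 5))
    internal = [f"M{i}[c]" for i in range(n_int)]
    boundary = [f"M{i}[e]" for i in range(int(rng.integers(1, 3)))]
    mets = internal + boundary
    n_rxn = int(rng.integers(4, 11))
    reactions = []
    for b in boundary:
        lb, ub = (0.0, 10.0) if rng.random() < 0.5 else (-10.0, 10.0)
        reactions.append((f"EX_{b[:-3]}", {b: -1.0}, (lb, ub)))
    while len(reactions) < n_rxn:
        k = len(reactions)
        n_sub = int(rng.integers(1, 3))
        subs = rng.choice(mets, size=n_sub, replace=False)
        prods = [m for m in rng.choice(mets, size=int(rng.integers(1, 3)), replace=False)
                 if m not in subs]
        stoich = {m: -float(rng.integers(1, 3)) for m in subs}
        for m in prods:
            stoich[m] = float(rng.integers(1, 3))
        lb, ub = (0.0, 10.0) if rng.random() < 0.6 else (-10.0, 10.0)
        reactions.append((f"R{k}", stoich, (lb, ub)))
    return build_network(reactions[:10], boundary=("e",), model_id="random")
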