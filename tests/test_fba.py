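"""Medium rules, two-stage weighted biomass FBA, cardinality minimisation
and minimal substrate requirements."""

import numpy as np
import pytest

from multicellfba.fba import (
    MediumDefinition,
    MediumError,
    apply_medium,
    check_solution,
    maximize_weighted_biomass,
    minimal_cardinality_flux,
    minimal_substrate_requirement,
    read_medium,
    solve_model,
)
from multicellfba.multicell import MultiCellModel
from multicellfba.synthetic import toy_medium

from conftest import build_network, full_core_multicell

#: hand-derived optima of the toy network (see synthetic module docstring):
#: 10 glucose -> 20 ATP glycolytic; 20 O2 -> 100 ATP oxidative; 10 ATP/biomass
TOY_OPT_AEROBIC = 12.0
TOY_OPT_FERMENTATIVE = 2.0


# ---------------------------------------------------------------------------
# medium application
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("ratio,expected", [(2.0, 20.0), (5.0, 50.0)])
def test_oxygen_bound_is_ratio_times_glucose(single_type_model, ratio, expected):
    medium = toy_medium(glucose=10.0, o2_glucose_ratio=ratio)
    constrained = apply_medium(single_type_model, medium)
    ex = constrained.medium_exchanges()
    o2 = constrained.network.reaction(ex["o2"])
    glc = constrained.network.reaction(ex["glc_D"])
    assert -glc.lower_bound == 10.0
    assert -o2.lower_bound == expected


def test_unlisted_species_closed_for_uptake(single_type_model):
    constrained = apply_medium(single_type_model, toy_medium())
    ex = constrained.medium_exchanges()
    lac = constrained.network.reaction(ex["lac_L"])
    assert lac.lower_bound == 0.0  # no uptake
    assert lac.upper_bound > 0.0  # secretion unrestricted


def test_medium_requires_glucose_and_oxygen_exchanges(single_type_model):
    with pytest.raises(MediumError, match="glucose"):
        apply_medium(single_type_model,
                     MediumDefinition(entries={"glc_D": 10}, glucose_id="glucose_x"))


def test_medium_table_round_trip(tmp_path):
    p = tmp_path / "medium.csv"
    p.write_text("metabolite,bound\nglc_D,10\n")
    med = read_medium(p, o2_glucose_ratio=5.0)
    assert med.uptake_bounds()["o2"] == 50.0
    assert med.uptake_bounds()["thymd"] == 1.0  # biomass-enabling default


def test_negative_bound_rejected():
    with pytest.raises(MediumError):
        MediumDefinition(entries={"glc_D": -1.0})


# ---------------------------------------------------------------------------
# weighted biomass FBA
# ---------------------------------------------------------------------------


def test_single_type_reduces_to_plain_fba(single_type_model):
    constrained = apply_medium(single_type_model, toy_medium())
    res = maximize_weighted_biomass(constrained)
    assert res.objective_value == pytest.approx(TOY_OPT_AEROBIC, rel=1e-9)
    assert res.per_type_max_biomass["cell"] == pytest.approx(TOY_OPT_AEROBIC, rel=1e-9)


def test_single_type_matches_cobra_oracle(single_type_model, tmp_path):
    """Dual route: the same constrained model solved by cobra + GLPK."""
    import json

    import cobra

    from multicellfba.multicell import serialize_multicell
    from multicellfba.network import network_to_dict

    constrained = apply_medium(single_type_model, toy_medium())
    path = tmp_path / "model.json"
    path.write_text(json.dumps(network_to_dict(constrained.network)))
    cm = cobra.io.load_json_model(str(path))
    cm.solver = "glpk"
    cm.objective = "BIOMASS_maintenance_cell"
    sol = cm.optimize()
    assert sol.status == "optimal"
    ours = maximize_weighted_biomass(constrained).objective_value
    assert ours == pytest.approx(sol.objective_value, rel=1e-6)


def test_two_identical_types_weighted_split():
    """Weights (9, 1) on identical types sharing the medium: floors give
    each type 10% of its solo maximum (12), the rest goes to the heavy
    type.  Hand LP: B_a = 10.8, B_b = 1.2, objective 9*10.8 + 1.2."""
    model = full_core_multicell(cell_types=("a", "b"), weights={"a": 9, "b": 1})
    constrained = apply_medium(model, toy_medium())
    res = maximize_weighted_biomass(constrained)
    assert res.per_type_max_biomass == pytest.approx(
        {"a": TOY_OPT_AEROBIC, "b": TOY_OPT_AEROBIC}, rel=1e-9
    )
    assert res.objective_value == pytest.approx(9 * 10.8 + 1.2, rel=1e-6)
    b_a = res.fluxes["BIOMASS_maintenance_a"]
    b_b = res.fluxes["BIOMASS_maintenance_b"]
    assert b_a == pytest.approx(10.8, rel=1e-6)
    assert b_b == pytest.approx(1.2, rel=1e-6)  # floor binds


def test_zero_weight_type_still_gets_its_floor():
    model = full_core_multicell(cell_types=("a", "b"), weights={"a": 9, "b": 1})
    model.weights["b"] = 0  # excluded from the objective, not from the floors
    constrained = apply_medium(model, toy_medium())
    res = maximize_weighted_biomass(constrained)
    assert (res.fluxes["BIOMASS_maintenance_b"]
            >= 0.1 * res.per_type_max_biomass["b"] - 1e-9)


def test_objective_bracketed_by_floor_relaxations(single_type_model):
    constrained = apply_medium(single_type_model, toy_medium())
    res = maximize_weighted_biomass(constrained)
    w_sum = sum(constrained.weights[t] * res.per_type_max_biomass[t]
                for t in constrained.cell_types)
    assert res.objective_value <= w_sum + 1e-9
    assert res.objective_value >= 0.1 * w_sum - 1e-9


def test_raising_o2_ratio_never_decreases_optimum(single_type_model):
    values = []
    for ratio in (1.0, 2.0, 5.0):
        constrained = apply_medium(single_type_model, toy_medium(o2_glucose_ratio=ratio))
        values.append(maximize_weighted_biomass(constrained).objective_value)
    assert values == sorted(values)


# ---------------------------------------------------------------------------
# minimal-cardinality flux
# ---------------------------------------------------------------------------


def _diamond_multicell():
    net = build_network(
        [
            ("EX_A", {"A[c]": 1}, (0, 10)),
            ("R1a", {"A[c]": -1, "X[c]": 1}, (0, 10)),
            ("R1b", {"X[c]": -1, "B[c]": 1}, (0, 10)),
            ("R2a", {"A[c]": -1, "Y[c]": 1}, (0, 10)),
            ("R2b", {"Y[c]": -1, "B[c]": 1}, (0, 10)),
            ("SINK", {"B[c]": -1}, (0, 10)),
            # bounded futile cycle detached from the objective
            ("C1", {"P[c]": -1, "Q[c]": 1}, (0, 5)),
            ("C2", {"Q[c]": -1, "P[c]": 1}, (0, 5)),
        ],
        boundary=("c",),
    )
    return MultiCellModel(
        network=net, cell_types=["cell"], weights={"cell": 1},
        biomass_reaction={"cell": "SINK"},
        reaction_namespace={r: "cell" for r in net.reaction_ids},
    )


@pytest.mark.parametrize("method", ["milp", "l1"])
def test_diamond_single_route_and_silent_cycle(method):
    model = _diamond_multicell()
    sol = minimal_cardinality_flux(model, fixed_objective=10.0, method=method)
    assert sol.objective_value == pytest.approx(10.0, rel=1e-6)
    active = set(sol.fluxes[sol.fluxes.abs() > 1e-6].index)
    assert sol.flux("C1") == 0.0 and sol.flux("C2") == 0.0
    assert ({"R1a", "R1b"} <= active) != ({"R2a", "R2b"} <= active)
    assert sol.support_size == 4


def test_heuristic_support_close_to_milp(single_type_model):
    constrained = apply_medium(single_type_model, toy_medium())
    weighted = maximize_weighted_biomass(constrained)
    exact = minimal_cardinality_flux(
        constrained, weighted.objective_value,
        per_type_max_biomass=weighted.per_type_max_biomass, method="milp",
    )
    heur = minimal_cardinality_flux(
        constrained, weighted.objective_value,
        per_type_max_biomass=weighted.per_type_max_biomass, method="l1",
    )
    assert heur.support_size <= exact.support_size + 1
    assert heur.objective_value == pytest.approx(exact.objective_value, rel=1e-6)


def test_solution_invariants(baseline_outcome):
    check_solution(baseline_outcome.model, baseline_outcome.solution)


def test_minimal_cardinality_deterministic():
    model = _diamond_multicell()
    a = minimal_cardinality_flux(model, 10.0, method="milp")
    b = minimal_cardinality_flux(model, 10.0, method="milp")
    assert (a.fluxes == b.fluxes).all()


# ---------------------------------------------------------------------------
# minimal substrate requirement
# ---------------------------------------------------------------------------


def test_minimal_oxygen_zero_when_fermentation_suffices(single_type_model):
    constrained = apply_medium(single_type_model, toy_medium())
    ex = constrained.medium_exchanges()
    need = minimal_substrate_requirement(constrained, ex["o2"],
                                         fixed_objective=TOY_OPT_FERMENTATIVE)
    assert need == pytest.approx(0.0, abs=1e-6)


def test_minimal_oxygen_at_full_objective_hand_value(single_type_model):
    """At the aerobic optimum every O2 is needed: 100 oxidative ATP at
    5 ATP/O2 means exactly 20 O2 for glucose bound 10 (ratio 2.0)."""
    constrained = apply_medium(single_type_model, toy_medium())
    ex = constrained.medium_exchanges()
    need = minimal_substrate_requirement(constrained, ex["o2"],
                                         fixed_objective=TOY_OPT_AEROBIC)
    # the 1e-6 relative slack on the fixed objective propagates into O2
    assert need == pytest.approx(20.0, abs=1e-3)
    assert need <= -constrained.network.reaction(ex["o2"]).lower_bound + 1e-9


def test_solve_model_end_to_end(single_type_model):
    sol = solve_model(single_type_model, toy_medium())
    assert sol.objective_value == pytest.approx(TOY_OPT_AEROBIC, rel=1e-6)
    check_solution(single_type_model, sol)
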