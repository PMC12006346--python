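"""Network container, I/O round trips, GPR semantics and core mapping."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multicellfba.network import (
    GPRError,
    MetabolicNetwork,
    Metabolite,
    NetworkError,
    Reaction,
    base_id,
    compartment_of,
    evaluate_gpr,
    gpr_genes,
    map_core_reactions,
    read_network,
    write_network,
)


def _assert_same_network(a: MetabolicNetwork, b: MetabolicNetwork):
    assert [m.id for m in a.metabolites] == [m.id for m in b.metabolites]
    assert [m.compartment for m in a.metabolites] == [m.compartment for m in b.metabolites]
    assert [r.id for r in a.reactions] == [r.id for r in b.reactions]
    for ra, rb in zip(a.reactions, b.reactions):
        assert ra.stoichiometry == rb.stoichiometry
        assert (ra.lower_bound, ra.upper_bound) == (rb.lower_bound, rb.upper_bound)
    assert a.boundary_compartments == b.boundary_compartments


@pytest.mark.parametrize("fmt", ["json", "sbml"])
def test_round_trip_identity(toy_network, tmp_path, fmt):
    path = tmp_path / ("net.json" if fmt == "json" else "net.xml")
    write_network(toy_network, path, fmt=fmt)
    back = read_network(path, fmt=fmt)
    _assert_same_network(toy_network, back)
    # GPRs must stay logically identical (SBML may reparenthesise)
    for ra, rb in zip(toy_network.reactions, back.reactions):
        assert gpr_genes(ra.gpr) == gpr_genes(rb.gpr)
        for sub in ({}, gpr_genes(ra.gpr), set(list(gpr_genes(ra.gpr))[:1])):
            assert evaluate_gpr(ra.gpr, sub) == evaluate_gpr(rb.gpr, sub)


def test_json_missing_bounds_defaults(tmp_path):
    doc = {
        "metabolites": [{"id": "A[c]", "compartment": "c"},
                        {"id": "B[c]", "compartment": "c"}],
        "reactions": [
            {"id": "R1", "metabolites": {"A[c]": -1, "B[c]": 1}},
            {"id": "R2", "metabolites": {"B[c]": -1, "A[c]": 1}, "reversible": False},
        ],
    }
    path = tmp_path / "m.json"
    path.write_text(json.dumps(doc))
    net = read_network(path)
    assert (net.reaction("R1").lower_bound, net.reaction("R1").upper_bound) == (-1000, 1000)
    assert (net.reaction("R2").lower_bound, net.reaction("R2").upper_bound) == (0, 1000)


def test_duplicate_reaction_id_rejected(tmp_path):
    doc = {
        "metabolites": [{"id": "A[c]", "compartment": "c"}],
        "reactions": [
            {"id": "R1", "metabolites": {"A[c]": 1}, "lower_bound": 0, "upper_bound": 1},
            {"id": "R1", "metabolites": {"A[c]": -1}, "lower_bound": 0, "upper_bound": 1},
        ],
    }
    path = tmp_path / "dup.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(NetworkError, match="duplicate"):
        read_network(path)


def test_malformed_and_unknown_format(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(NetworkError, match="malformed"):
        read_network(bad)
    ok = tmp_path / "ok.json"
    ok.write_text("{}")
    with pytest.raises(NetworkError, match="format"):
        read_network(ok, fmt="hdf5")
    with pytest.raises(FileNotFoundError):
        read_network(tmp_path / "absent.json")


def test_reaction_invariants():
    with pytest.raises(NetworkError, match="lower_bound"):
        Reaction(id="R", stoichiometry={"A[c]": 1}, lower_bound=1, upper_bound=0)
    with pytest.raises(NetworkError, match="nonzero"):
        Reaction(id="R", stoichiometry={"A[c]": 0.0})
    with pytest.raises(NetworkError, match="unknown metabolite"):
        MetabolicNetwork(
            metabolites=[Metabolite(id="A[c]", compartment="c")],
            reactions=[Reaction(id="R", stoichiometry={"B[c]": 1})],
        )


@pytest.mark.parametrize(
    "rule,active,expected",
    [
        ("G1 and G2", {"G1"}, False),
        ("G1 and G2", {"G1", "G2"}, True),
        ("G1 or G2", {"G2"}, True),
        ("(G1 and G2) or G3", {"G3"}, True),
        ("(G1 and G2) or G3", {"G1"}, False),
        ("G1 AND (G2 OR G3)", {"G1", "G3"}, True),
        ("", {"G1"}, False),
        ("G1", set(), False),
        ("GX or G1", {"G1"}, True),  # unknown operand is simply inactive
    ],
)
def test_gpr_evaluation(rule, active, expected):
    assert evaluate_gpr(rule, active) is expected


@pytest.mark.parametrize("rule", ["G1 and", "(G1 or G2", "and G1", "G1 ) G2"])
def test_gpr_parse_errors_name_the_rule(rule):
    with pytest.raises(GPRError, match="G1"):
        evaluate_gpr(rule, {"G1"})


def test_gpr_matches_cobra_semantics(toy_network):
    """Independent oracle: cobra's GPR evaluator on the same rules."""
    import itertools

    from cobra.core.gene import GPR

    genes = sorted(toy_network.genes)
    rng_subsets = [set(c) for c in itertools.islice(
        itertools.combinations(genes, 2), 20)] + [set(), set(genes)]
    for r in toy_network.reactions:
        if not r.gpr:
            continue
        gpr = GPR.from_string(r.gpr)
        for active in rng_subsets:
            knockouts = gpr_genes(r.gpr) - active
            assert evaluate_gpr(r.gpr, active) == gpr.eval(knockouts)


def test_map_core_reactions_cases():
    net = MetabolicNetwork(
        metabolites=[Metabolite(id="A[c]", compartment="c")],
        reactions=[
            Reaction(id="R1", stoichiometry={"A[c]": 1}, gpr="G1"),
            Reaction(id="R2", stoichiometry={"A[c]": -1}, gpr="G1 and G2"),
            Reaction(id="R3", stoichiometry={"A[c]": 1}, gpr="G2 or G3"),
            Reaction(id="R4", stoichiometry={"A[c]": -1}, gpr=""),
        ],
    )
    # enumerated truth table for core {G1, G3}
    assert map_core_reactions(net, {"G1", "G3"}) == {"R1", "R3"}
    assert map_core_reactions(net, set()) == set()
    # saturation: every gene active -> every GPR-bearing reaction
    assert map_core_reactions(net, net.genes) == {"R1", "R2", "R3"}


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    core=st.sets(st.sampled_from(["G1", "G2", "G3", "G4"])),
    extra=st.sampled_from(["G1", "G2", "G3", "G4"]),
)
def test_map_core_reactions_monotone(core, extra):
    """Adding a gene to the core never removes a mapped reaction."""
    net = MetabolicNetwork(
        metabolites=[Metabolite(id="A[c]", compartment="c")],
        reactions=[
            Reaction(id="R1", stoichiometry={"A[c]": 1}, gpr="G1 and (G2 or G3)"),
            Reaction(id="R2", stoichiometry={"A[c]": -1}, gpr="G2 or (G3 and G4)"),
            Reaction(id="R3", stoichiometry={"A[c]": 1}, gpr="G4"),
        ],
    )
    before = map_core_reactions(net, core)
    after = map_core_reactions(net, core | {extra})
    assert before <= after


def test_exchange_predicate(toy_network):
    found = {r.id for r in toy_network.exchange_reactions()}
    assert found == {"EX_glc_D", "EX_o2", "EX_lac_L", "EX_ac", "EX_bhb",
                     "EX_lnlc", "EX_thymd"}
    # transports touch the boundary but are not single-metabolite
    assert not toy_network.is_exchange(toy_network.reaction("GLCt"))


def test_id_helpers():
    assert compartment_of("lac_L[c]_astro") == "c"
    assert base_id("lac_L[c]") == "lac_L"
    assert base_id("glc_D[u]") == "glc_D"
    assert compartment_of("nogene") is None
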