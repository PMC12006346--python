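"""Expression I/O, stratified pseudobulk and discretization."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from multicellfba.expression import (
    DiscretizationParams,
    ExpressionError,
    ExpressionMatrix,
    build_core_sets,
    discretize,
    discretize_full,
    filter_cell_types,
    pseudobulk,
    read_expression,
    write_expression,
)
from multicellfba.synthetic import make_toy_network


def _matrix(counts, genes, cells, cell_type, condition) -> ExpressionMatrix:
    return ExpressionMatrix(
        counts=sparse.csr_matrix(np.asarray(counts)),
        gene_ids=genes,
        cell_ids=cells,
        cell_type=np.array(cell_type, dtype=object),
        condition=np.array(condition, dtype=object),
    )


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    counts = [[5, 0, 2, 1], [0, 3, 0, 4], [1, 1, 1, 1]]
    return _matrix(
        counts,
        genes=["G1", "G2", "G3"],
        cells=["c1", "c2", "c3", "c4"],
        cell_type=["astro", "astro", "neuron", "neuron"],
        condition=["WT", "PD", "WT", "PD"],
    )


def test_mtx_round_trip(small_matrix, tmp_path):
    paths = write_expression(small_matrix, tmp_path)
    back = read_expression(paths["matrix"], paths["genes"], paths["cells"], paths["labels"])
    assert back.gene_ids == small_matrix.gene_ids
    assert back.cell_ids == small_matrix.cell_ids
    assert (back.counts != small_matrix.counts).nnz == 0
    assert list(back.cell_type) == list(small_matrix.cell_type)
    assert list(back.condition) == list(small_matrix.condition)


def test_read_errors(small_matrix, tmp_path):
    paths = write_expression(small_matrix, tmp_path)
    labels = pd.read_csv(paths["labels"], sep="\t")
    labels.iloc[1:].to_csv(paths["labels"], sep="\t", index=False)
    with pytest.raises(ExpressionError, match="missing cell id"):
        read_expression(paths["matrix"], paths["genes"], paths["cells"], paths["labels"])


def test_empty_matrix_rejected():
    with pytest.raises(ExpressionError, match="no cells"):
        _matrix(np.zeros((2, 0)), ["G1", "G2"], [], [], [])


def test_dimension_mismatch_rejected():
    with pytest.raises(ExpressionError, match="gene ids"):
        _matrix(np.ones((2, 2)), ["G1"], ["c1", "c2"], ["a", "a"], ["x", "x"])


# ---------------------------------------------------------------------------
# cell-type filtering
# ---------------------------------------------------------------------------


def test_filter_requires_presence_in_every_condition():
    """A type absent from one condition is excluded everywhere when
    shared presence is required (the study's oligodendrocyte rule)."""
    counts = np.ones((1, 5))
    m = _matrix(counts, ["G1"], [f"c{i}" for i in range(5)],
                ["oligo", "astro", "astro", "astro", "astro"],
                ["WT", "WT", "WT", "PD", "PD"])
    retained = filter_cell_types(m, min_cells=1, require_shared=True)
    assert retained == {"WT": ["astro"], "PD": ["astro"]}
    per_cond = filter_cell_types(m, min_cells=1, require_shared=False)
    assert per_cond["WT"] == ["astro", "oligo"]
    assert per_cond["PD"] == ["astro"]


def test_filter_identity_and_min_cells(small_matrix):
    assert filter_cell_types(small_matrix, 1, True) == {
        "WT": ["astro", "neuron"], "PD": ["astro", "neuron"]
    }
    with pytest.warns(UserWarning):
        assert filter_cell_types(small_matrix, 50, True) == {"WT": [], "PD": []}


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------


def test_pseudobulk_single_cell_zero_gene():
    m = _matrix([[0], [7]], ["G0", "G1"], ["c1"], ["t"], ["x"])
    assert pseudobulk(m, "x", "t")["G0"] == 0.0


def test_pseudobulk_hand_computed_mean():
    """Two cells, library 10k each, counts 10 and 30 for one gene:
    value = mean(log2(11), log2(31)) under CP10K + log2(x+1)."""
    counts = np.zeros((2, 2))
    counts[0] = [10, 30]
    counts[1] = [10_000 - 10, 10_000 - 30]  # filler keeps library at 10k
    m = _matrix(counts, ["G", "FILL"], ["c1", "c2"], ["t", "t"], ["x", "x"])
    expected = (math.log2(11) + math.log2(31)) / 2
    assert pseudobulk(m, "x", "t")["G"] == pytest.approx(expected, rel=1e-12)


def test_pseudobulk_library_size_invariance():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=(6, 5))
    m1 = _matrix(counts, [f"G{i}" for i in range(6)], [f"c{i}" for i in range(5)],
                 ["t"] * 5, ["x"] * 5)
    m2 = _matrix(counts * 2, [f"G{i}" for i in range(6)], [f"c{i}" for i in range(5)],
                 ["t"] * 5, ["x"] * 5)
    pd.testing.assert_series_equal(pseudobulk(m1, "x", "t"), pseudobulk(m2, "x", "t"))


def test_pseudobulk_empty_stratum(small_matrix):
    with pytest.raises(ExpressionError, match="empty stratum"):
        pseudobulk(small_matrix, "WT", "oligo")


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def _mixture_profile(seed, n_low=120, n_high=80, mu_low=1.0, mu_high=6.0, sd=0.6):
    rng = np.random.default_rng(seed)
    low = rng.normal(mu_low, sd, n_low).clip(min=0.01)
    high = rng.normal(mu_high, sd, n_high).clip(min=0.01)
    expr = pd.Series(
        np.concatenate([low, high]),
        index=[f"L{i}" for i in range(n_low)] + [f"H{i}" for i in range(n_high)],
    )
    return expr


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_discretize_recovers_upper_mixture_component(seed):
    """Well-separated two-component mixture (separation > 4 sd): the
    returned core recovers >= 99% of the upper component and admits
    <= 1% contamination from the lower one."""
    expr = _mixture_profile(seed)
    core = discretize(expr)
    high = {g for g in expr.index if g.startswith("H")}
    low = set(expr.index) - high
    assert len(core & high) / len(high) >= 0.99
    assert len(core & low) / len(low) <= 0.01


def test_all_zero_gene_never_core():
    expr = _mixture_profile(3)
    expr["ZERO"] = 0.0
    assert "ZERO" not in discretize(expr)


def test_explicit_threshold_is_sharp():
    """Raising one gene just above the upper threshold adds exactly it."""
    params = DiscretizationParams(upper=5.0, lower=2.0)
    expr = pd.Series({"a": 1.0, "b": 3.0, "c": 4.9})
    before = discretize(expr, params)
    assert before == set()
    expr["c"] = 5.1
    assert discretize(expr, params) == {"c"}


def test_discretize_order_invariance():
    expr = _mixture_profile(4)
    shuffled = expr.sample(frac=1.0, random_state=0)
    res_a = discretize_full(expr)
    res_b = discretize_full(shuffled)
    assert res_a.core == res_b.core
    assert res_a.upper_threshold == pytest.approx(res_b.upper_threshold)


def test_discretize_monotone_in_upper_threshold():
    expr = _mixture_profile(5)
    cores = [
        discretize(expr, DiscretizationParams(upper=u, lower=0.5))
        for u in (5.5, 4.5, 3.5)
    ]
    assert cores[0] <= cores[1] <= cores[2]


def test_degenerate_distribution_falls_back():
    expr = pd.Series({f"G{i}": 2.0 for i in range(20)})
    with pytest.warns(UserWarning, match="degenerate|percentile"):
        res = discretize_full(expr)
    assert res.method == "percentile"
    assert res.core == set()  # nothing strictly above the common value


def test_build_core_sets_maps_genes_to_reactions():
    net = make_toy_network()
    rng = np.random.default_rng(6)
    genes = ["HK2", "PKM", "LDHA", "SLC2A1", "NDUFA1", "ATP5F1A", "CS", "OGDH"]
    fillers = [f"F{i}" for i in range(30)]
    high = {"HK2", "PKM", "LDHA", "SLC2A1"}
    counts = np.vstack(
        [rng.poisson(80 if g in high else 1, size=40) for g in genes + fillers]
    )
    m = _matrix(counts, genes + fillers, [f"c{i}" for i in range(40)],
                ["astro"] * 40, ["WT"] * 40)
    (cs,) = build_core_sets(m, net, "WT", ["astro"])
    assert {"HK2", "PKM", "LDHA", "SLC2A1"} <= cs.core_genes
    assert {"HEX1", "PYK", "LDH_L", "GLCt"} <= cs.core_reactions
    assert "OXPHOSm" not in cs.core_reactions
    assert cs.n_cells == 40
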