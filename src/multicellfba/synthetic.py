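"""Synthetic study inputs: a toy central-carbon network and simulated
single-cell counts.

The toy network is a miniature generic reconstruction covering
glycolysis, the TCA cycle, oxidative phosphorylation, fatty-acid
oxidation, the lactate/acetate/3-hydroxybutyrate exchanges and a
biomass-maintenance reaction.  Its stoichiometric coefficients are fixed
constants chosen for clean, hand-verifiable optima rather than
literature P/O ratios: lumped lower glycolysis yields 2 ATP and 2
cytosolic NADH per glucose, full oxidation of one glucose costs 6 O2
and yields 32 ATP, so with the default medium (glucose 10, O2 = 2 x
glucose) the weighted biomass optimum is exactly 12 and the fermentative
optimum (O2 = 0) exactly 2.

The count simulator draws negative-binomial UMI counts with dropout from
per-cell-type expression programs; the bundled lactate-shuttle scenario
pairs a glycolytic astrocyte-like program with an oxidative neuron-like
program so that the end-to-end pipeline recovers astrocyte lactate
export and neuronal lactate uptake through the shared medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .expression import DiscretizationParams, ExpressionMatrix, build_core_sets
from .fba import FluxSolution, MediumDefinition, solve_model
from .multicell import MultiCellModel, build_multicell_model, namespaced
from .network import MetabolicNetwork, Metabolite, Reaction
from .reports import PathwayKey, intercellular_exchange_report, pathway_flux_sum

REV = (-1000.0, 1000.0)
FWD = (0.0, 1000.0)


# ---------------------------------------------------------------------------
# toy generic network
# ---------------------------------------------------------------------------


def make_toy_network() -> MetabolicNetwork:
    """~30-reaction central-carbon network with compartments c/m and
    boundary compartment e; fully flux-consistent by construction."""

    def met(mid: str, name: str = "") -> Metabolite:
        comp = mid[mid.index("[") + 1 : mid.index("]")]
        return Metabolite(id=mid, name=name or mid, compartment=comp)

    metabolites = [
        # boundary
        met("glc_D[e]", "D-glucose"), met("o2[e]", "oxygen"),
        met("lac_L[e]", "L-lactate"), met("ac[e]", "acetate"),
        met("bhb[e]", "3-hydroxybutyrate"), met("lnlc[e]", "linoleate"),
        met("thymd[e]", "thymidine-triphosphate"),
        # cytoplasm
        met("glc_D[c]"), met("g6p[c]", "glucose-6-phosphate"), met("pyr[c]", "pyruvate"),
        met("lac_L[c]"), met("ac[c]"), met("accoa[c]", "acetyl-CoA"),
        met("nadh[c]"), met("nad[c]"), met("atp[c]"), met("adp[c]"),
        met("bhb[c]"), met("lnlc[c]"), met("thymd[c]"), met("o2[c]"),
        # mitochondria
        met("pyr[m]"), met("accoa[m]"), met("cit[m]", "citrate"),
        met("akg[m]", "alpha-ketoglutarate"), met("succ[m]", "succinate"),
        met("oaa[m]", "oxaloacetate"), met("nadh[m]"), met("nad[m]"),
        met("o2[m]"), met("bhb[m]"),
    ]

    def rxn(rid, stoich, bounds=FWD, gpr="", subsystem=None):
        return Reaction(id=rid, stoichiometry=stoich, lower_bound=bounds[0],
                        upper_bound=bounds[1], gpr=gpr, subsystem=subsystem)

    reactions = [
        # environment exchanges
        rxn("EX_glc_D", {"glc_D[e]": -1}, REV, subsystem="exchange"),
        rxn("EX_o2", {"o2[e]": -1}, REV, subsystem="exchange"),
        rxn("EX_lac_L", {"lac_L[e]": -1}, REV, subsystem="exchange"),
        rxn("EX_ac", {"ac[e]": -1}, REV, subsystem="exchange"),
        rxn("EX_bhb", {"bhb[e]": -1}, REV, subsystem="exchange"),
        rxn("EX_lnlc", {"lnlc[e]": -1}, REV, subsystem="exchange"),
        rxn("EX_thymd", {"thymd[e]": -1}, REV, subsystem="exchange"),
        # transports
        rxn("GLCt", {"glc_D[e]": -1, "glc_D[c]": 1}, FWD, "SLC2A1", "transport"),
        rxn("O2t", {"o2[e]": -1, "o2[c]": 1}, FWD, "", "transport"),
        rxn("O2tm", {"o2[c]": -1, "o2[m]": 1}, FWD, "", "transport"),
        rxn("L_LACt", {"lac_L[c]": -1, "lac_L[e]": 1}, REV,
            "SLC16A1 or SLC16A7", "transport"),
        rxn("ACt", {"ac[c]": -1, "ac[e]": 1}, REV, "SLC16A3", "transport"),
        rxn("BHBtm", {"bhb[m]": -1, "bhb[c]": 1}, REV, "", "transport"),
        rxn("BHBt", {"bhb[c]": -1, "bhb[e]": 1}, REV, "SLC16A6", "transport"),
        rxn("LNLCt", {"lnlc[e]": -1, "lnlc[c]": 1}, FWD, "CD36", "transport"),
        rxn("THMDt", {"thymd[e]": -1, "thymd[c]": 1}, FWD, "SLC29A1", "transport"),
        rxn("PYRtm", {"pyr[c]": -1, "pyr[m]": 1}, FWD, "MPC1 and MPC2", "transport"),
        # glycolysis (lumped): 2 ATP + 2 NADH_c per glucose
        rxn("HEX1", {"glc_D[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1},
            FWD, "HK1 or HK2", "glycolysis"),
        rxn("PYK", {"g6p[c]": -1, "adp[c]": -3, "nad[c]": -2,
                    "pyr[c]": 2, "atp[c]": 3, "nadh[c]": 2},
            FWD, "PKM", "glycolysis"),
        rxn("LDH_L", {"pyr[c]": -1, "nadh[c]": -1, "lac_L[c]": 1, "nad[c]": 1},
            REV, "LDHA", "glycolysis"),
        # cytosolic acetyl-CoA handling
        rxn("ACOAH", {"accoa[c]": -1, "ac[c]": 1}, FWD, "ACOT12", "FAO"),
        rxn("ACS", {"ac[c]": -1, "atp[c]": -1, "accoa[c]": 1, "adp[c]": 1},
            FWD, "ACSS2", "FAO"),
        rxn("ACLY", {"cit[m]": -1, "atp[c]": -1, "accoa[c]": 1, "oaa[m]": 1,
                     "adp[c]": 1}, FWD, "ACLY", "FAO"),
        # fatty-acid oxidation (lumped beta-oxidation of linoleate)
        rxn("FAOX", {"lnlc[c]": -1, "atp[c]": -1, "nad[m]": -8,
                     "accoa[m]": 9, "nadh[m]": 8, "adp[c]": 1},
            FWD, "CPT1A", "FAO"),
        # redox shuttle (lumped malate-aspartate)
        rxn("NADHtm", {"nadh[c]": -1, "nad[m]": -1, "nad[c]": 1, "nadh[m]": 1},
            FWD, "MDH1", "OXPHOS"),
        # pyruvate oxidation and TCA
        rxn("PDHm", {"pyr[m]": -1, "nad[m]": -1, "accoa[m]": 1, "nadh[m]": 1},
            FWD, "PDHA1", "TCA"),
        rxn("CSm", {"accoa[m]": -1, "oaa[m]": -1, "cit[m]": 1}, FWD, "CS", "TCA"),
        rxn("ICDHxm", {"cit[m]": -1, "nad[m]": -1, "akg[m]": 1, "nadh[m]": 1},
            FWD, "IDH3A", "TCA"),
        rxn("AKGDm", {"akg[m]": -1, "nad[m]": -1, "succ[m]": 1, "nadh[m]": 1},
            FWD, "OGDH", "TCA"),
        rxn("SUCD_MDHm", {"succ[m]": -1, "nad[m]": -2, "oaa[m]": 1, "nadh[m]": 2},
            FWD, "SDHA", "TCA"),
        # oxidative phosphorylation: 5 ATP per O2 (2 NADH)
        rxn("OXPHOSm", {"o2[m]": -1, "nadh[m]": -2, "adp[c]": -5,
                        "nad[m]": 2, "atp[c]": 5},
            FWD, "NDUFA1 and ATP5F1A", "OXPHOS"),
        # ketone body synthesis/utilisation
        rxn("BDHm", {"accoa[m]": -2, "nadh[m]": -1, "bhb[m]": 1, "nad[m]": 1},
            REV, "BDH1", "ketone"),
        # biomass maintenance: 10 ATP + trace thymidine/linoleate per unit
        rxn("BIOMASS_maintenance",
            {"atp[c]": -10, "thymd[c]": -0.05, "lnlc[c]": -0.05, "adp[c]": 10},
            FWD, "", "biomass"),
    ]
    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        boundary_compartments={"e"},
        id="toy_central_carbon",
    )


def toy_medium(glucose: float = 10.0, o2_glucose_ratio: float = 2.0) -> MediumDefinition:
    """Default toy medium: glucose-limited, O2 tied to glucose, trace
    thymidine and linoleate to allow biomass maintenance."""
    return MediumDefinition(
        entries={"glc_D": glucose},
        o2_glucose_ratio=o2_glucose_ratio,
        special_bounds={"thymd": 1.0, "lnlc": 1.0},
    )


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


@dataclass
class CellTypeProgram:
    """Expression program of one simulated cell type.

    ``mean_expression`` gives expected UMI counts per cell and gene at
    unit library factor; ``dispersion`` is the negative-binomial size
    parameter (infinity = Poisson); ``dropout_rate`` zeroes each entry
    independently; ``library_sigma`` scales per-cell lognormal library
    factors (mean 1)."""

    label: str
    mean_expression: Dict[str, float]
    dispersion: float = 2.0
    dropout_rate: float = 0.1
    n_cells: int = 300
    library_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def simulate_counts(
    programs: Sequence[CellTypeProgram],
    seed: int,
    condition: str = "baseline",
) -> ExpressionMatrix:
    """Draw a gene x cell UMI matrix from cell-type programs.

    Counts are gamma-Poisson (negative binomial) per gene and cell,
    scaled by per-cell library factors and thinned by dropout.
    Reproducible given the seed.
    """
    if not programs:
        raise ValueError("no cell-type programs given")
    genes = sorted(set().union(*(p.mean_expression for p in programs)))
    rng = np.random.default_rng(seed)
    blocks = []
    cell_ids: List[str] = []
    cell_type: List[str] = []
    for prog in programs:
        mu = np.array([prog.mean_expression.get(g, 0.0) for g in genes])[:, None]
        factors = rng.lognormal(
            mean=-prog.library_sigma**2 / 2, sigma=prog.library_sigma, size=prog.n_cells
        )[None, :]
        lam = mu * factors
        if np.isfinite(prog.dispersion):
            shape = prog.dispersion
            lam = np.where(lam > 0, rng.gamma(shape, 1.0, size=lam.shape) * lam / shape, 0.0)
        counts = rng.poisson(lam)
        if prog.dropout_rate > 0:
            keep = rng.random(counts.shape) >= prog.dropout_rate
            counts = counts * keep
        blocks.append(sparse.csr_matrix(counts))
        cell_ids.extend(f"{prog.label}_{i}" for i in range(prog.n_cells))
        cell_type.extend([prog.label] * prog.n_cells)
    return ExpressionMatrix(
        counts=sparse.hstack(blocks, format="csr"),
        gene_ids=genes,
        cell_ids=cell_ids,
        cell_type=np.array(cell_type, dtype=object),
        condition=np.array([condition] * len(cell_ids), dtype=object),
    )


# ---------------------------------------------------------------------------
# lactate-shuttle scenario
# ---------------------------------------------------------------------------

_HIGH = 60.0
_LOW = 0.4
_HOUSE = 80.0

_GLYCOLYTIC_GENES = ["SLC2A1", "HK2", "PKM", "LDHA", "SLC16A1", "ACOT12", "SLC16A3"]
_OXIDATIVE_GENES = [
    "MPC1", "MPC2", "PDHA1", "CS", "IDH3A", "OGDH", "SDHA", "MDH1",
    "NDUFA1", "ATP5F1A",
]
_NEURON_IMPORT_GENES = ["SLC16A7", "LDHA"]
_HOUSEKEEPING = ["ACTB", "RPL13", "RPS18", "MALAT1", "EEF1A1", "TPT1"]
_ASTRO_MARKERS = ["GFAP", "S100B", "VIM", "SOX9", "HES5", "AQP4"]
_NEURON_MARKERS = ["TH", "MAP2", "SYT1", "NR4A2", "KCNJ6", "SNAP25"]
_OTHER_GENES = [
    "HK1", "ACSS2", "ACLY", "CPT1A", "CD36", "SLC29A1", "BDH1", "SLC16A6",
    "HMGB2", "XBP1", "ATF5", "GAD1", "GAD2", "PAX2", "LMX1B", "SOX6",
    "CALB1", "EN2", "SOX10", "PDGFRA", "HES6", "SLC6A3", "AGTR1", "NES",
]


def _program_means(high: Sequence[str], markers: Sequence[str]) -> Dict[str, float]:
    genes = set(
        _GLYCOLYTIC_GENES + _OXIDATIVE_GENES + _NEURON_IMPORT_GENES
        + _HOUSEKEEPING + _ASTRO_MARKERS + _NEURON_MARKERS + _OTHER_GENES
    )
    means = {g: _LOW for g in genes}
    for g in _HOUSEKEEPING:
        means[g] = _HOUSE
    for g in high:
        means[g] = _HIGH
    for g in markers:
        means[g] = _HIGH
    return means


def astrocyte_program(n_cells: int = 300) -> CellTypeProgram:
    """Glycolytic, lactate-exporting astrocyte-like program."""
    return CellTypeProgram(
        label="astrocyte",
        mean_expression=_program_means(_GLYCOLYTIC_GENES, _ASTRO_MARKERS),
        n_cells=n_cells,
    )


def neuron_program(n_cells: int = 300, disrupted: bool = False) -> CellTypeProgram:
    """Oxidative, lactate-importing neuron-like program.

    The ``disrupted`` variant silences the oxidative axis (complex I /
    ATP synthase and upstream mitochondrial program), emulating
    respiratory dysfunction: the pipeline then reconstructs a neuron
    sub-model that must fall back on glycolysis.
    """
    high = list(_NEURON_IMPORT_GENES) + ([] if disrupted else list(_OXIDATIVE_GENES))
    return CellTypeProgram(
        label="neuron",
        mean_expression=_program_means(high, _NEURON_MARKERS),
        n_cells=n_cells,
    )


@dataclass
class ShuttleScenario:
    network: MetabolicNetwork
    expression: ExpressionMatrix
    medium: MediumDefinition
    expected: Dict[str, str]
    condition: str = "baseline"


def scenario_lactate_shuttle(
    seed: int, disrupted: bool = False, n_cells: int = 300
) -> ShuttleScenario:
    """Toy network + simulated counts designed to exhibit the
    astrocyte-to-neuron lactate shuttle (or its disrupted variant)."""
    condition = "disrupted" if disrupted else "baseline"
    programs = [astrocyte_program(n_cells), neuron_program(n_cells, disrupted)]
    expression = simulate_counts(programs, seed=seed, condition=condition)
    expected = {
        "astrocyte_lactate": "negative (production/release)",
        "neuron_lactate": "positive (uptake)" if not disrupted else "non-positive",
        "note": "neuron upper-glycolysis FluxSum rises in the disrupted variant",
    }
    return ShuttleScenario(
        network=make_toy_network(),
        expression=expression,
        medium=toy_medium(),
        expected=expected,
        condition=condition,
    )


@dataclass
class ScenarioOutcome:
    model: MultiCellModel
    solution: FluxSolution
    lactate_report: pd.DataFrame
    astrocyte_lactate_rate: float
    neuron_lactate_rate: float
    neuron_upper_glycolysis_flux_sum: float


def run_scenario(
    scenario: ShuttleScenario,
    epsilon: float = 1e-4,
    params: Optional[DiscretizationParams] = None,
) -> ScenarioOutcome:
    """End-to-end run of one scenario: core sets -> multi-cell model ->
    constrained minimal-cardinality FBA -> lactate exchange readout."""
    coresets = build_core_sets(
        scenario.expression,
        scenario.network,
        scenario.condition,
        sorted(set(scenario.expression.cell_type)),
        params,
    )
    model = build_multicell_model(
        scenario.network,
        coresets,
        epsilon=epsilon,
        medium_metabolites=set(scenario.medium.uptake_bounds()),
    )
    solution = solve_model(model, scenario.medium)
    report = intercellular_exchange_report(solution, model, "lac_L")
    rates = dict(zip(report["scope"], report["rate"]))
    try:
        upper_gly = pathway_flux_sum(
            solution, model, PathwayKey("upper_glycolysis", ("g6p[c]",)), scope="neuron"
        )
    except Exception:
        upper_gly = 0.0  # neuron sub-model carries no glucose-phosphorylation arm
    return ScenarioOutcome(
        model=model,
        solution=solution,
        lactate_report=report,
        astrocyte_lactate_rate=float(rates.get("astrocyte", 0.0)),
        neuron_lactate_rate=float(rates.get("neuron", 0.0)),
        neuron_upper_glycolysis_flux_sum=float(upper_gly),
    )
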