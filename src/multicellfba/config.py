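"""Run configuration, provenance capture and pipeline orchestration.

A run is fully described by a :class:`RunConfig` (paths + numeric
parameters).  ``run_pipeline`` executes, per condition: core-set
construction -> multi-cell model assembly -> medium-constrained
weighted-biomass FBA -> minimal-cardinality flux -> reports, and writes
everything into a run directory named after the config hash, so a
changed configuration can never overwrite an earlier run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .expression import (
    DiscretizationParams,
    build_core_sets,
    filter_cell_types,
    read_expression,
)
from .fba import MediumDefinition, read_medium, solve_model
from .multicell import (
    MultiCellModel,
    build_multicell_model,
    deserialize_multicell,
    jaccard_similarity,
    serialize_multicell,
    submodel_sizes,
)
from .network import read_network
from .reports import (
    PathwayKey,
    default_pathway_keys,
    intercellular_exchange_report,
    medium_exchange_report,
    pathway_flux_sum_table,
    read_pathway_keys,
    write_report,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    network_path: str
    matrix_path: str
    genes_path: str
    cells_path: str
    labels_path: str
    medium_path: str
    pathway_keys_path: Optional[str] = None
    out_dir: str = "runs"
    epsilon: float = 1e-4
    o2_glucose_ratio: float = 2.0
    min_cells: int = 1
    require_shared: bool = True
    floor_fraction: float = 0.1
    cardinality_method: str = "auto"
    exchange_metabolites: List[str] = field(default_factory=lambda: ["lac_L"])
    biomass_reaction: str = "BIOMASS_maintenance"
    discretization: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def validate(self) -> None:
        for name in ("network_path", "matrix_path", "genes_path", "cells_path",
                     "labels_path", "medium_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name}: file not found: {p}")
        if self.pathway_keys_path and not Path(self.pathway_keys_path).exists():
            raise ConfigError(f"pathway_keys_path: file not found: {self.pathway_keys_path}")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.o2_glucose_ratio <= 0:
            raise ConfigError("o2_glucose_ratio must be positive")
        if self.min_cells < 1:
            raise ConfigError("min_cells must be >= 1")
        if not 0 < self.floor_fraction < 1:
            raise ConfigError("floor_fraction must be in (0, 1)")

    def hash(self) -> str:
        digest = hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()
        return digest[:12]


def _file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    run_dir = Path(config.out_dir) / f"run_{config.hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    current = stage("read inputs")
    try:
        network = read_network(config.network_path)
        expression = read_expression(
            config.matrix_path, config.genes_path, config.cells_path, config.labels_path
        )
        medium = read_medium(
            config.medium_path, o2_glucose_ratio=config.o2_glucose_ratio
        )
        keys = (
            read_pathway_keys(config.pathway_keys_path)
            if config.pathway_keys_path
            else default_pathway_keys()
        )
        params = DiscretizationParams(**config.discretization)

        current = stage("filter cell types")
        retained = filter_cell_types(
            expression, min_cells=config.min_cells, require_shared=config.require_shared
        )

        metadata: Dict[str, object] = {
            "package_version": __version__,
            "config": asdict(config),
            "config_hash": config.hash(),
            "input_hashes": {
                "network": _file_sha256(config.network_path),
                "matrix": _file_sha256(config.matrix_path),
                "medium": _file_sha256(config.medium_path),
            },
            "retained_cell_types": retained,
            "conditions": {},
        }

        for condition, cell_types in sorted(retained.items()):
            if not cell_types:
                continue
            cond_dir = run_dir / condition
            cond_dir.mkdir(exist_ok=True)

            current = stage(f"[{condition}] core sets")
            coresets = build_core_sets(expression, network, condition, cell_types, params)

            current = stage(f"[{condition}] build multi-cell model")
            model = build_multicell_model(
                network,
                coresets,
                epsilon=config.epsilon,
                medium_metabolites=set(medium.uptake_bounds()),
                biomass_reaction=config.biomass_reaction,
            )
            (cond_dir / "model.json").write_text(
                json.dumps(serialize_multicell(model), indent=1) + "\n"
            )

            current = stage(f"[{condition}] FBA")
            solution = solve_model(
                model, medium, floor_fraction=config.floor_fraction,
                method=config.cardinality_method,
            )
            flux_df = solution.fluxes.rename("flux").rename_axis("reaction").reset_index()
            write_report(flux_df, cond_dir / "fluxes.tsv")

            current = stage(f"[{condition}] reports")
            write_report(
                medium_exchange_report(solution, model), cond_dir / "medium_exchange.tsv"
            )
            for met in config.exchange_metabolites:
                write_report(
                    intercellular_exchange_report(solution, model, met),
                    cond_dir / f"exchange_{met}.tsv",
                )
            write_report(
                pathway_flux_sum_table(solution, model, keys),
                cond_dir / "pathway_flux_sum.tsv",
            )

            metadata["conditions"][condition] = {
                "cell_types": cell_types,
                "weights": model.weights,
                "submodel_sizes": {
                    t: list(s) for t, s in submodel_sizes(model).items()
                },
                "core_thresholds": {cs.cell_type: cs.thresholds for cs in coresets},
                "objective_value": solution.objective_value,
                "support_size": solution.support_size,
                "solver": solution.solver_metadata,
            }
    except Exception as exc:
        raise PipelineError(f"pipeline stage {current!r} failed: {exc}") from exc

    (run_dir / "metadata.json").write_text(json.dumps(metadata, indent=1, sort_keys=True) + "\n")
    return run_dir


# ---------------------------------------------------------------------------
# run comparison
# ---------------------------------------------------------------------------


def _load_run(run_dir: Path) -> Dict[str, object]:
    meta = json.loads((run_dir / "metadata.json").read_text())
    conditions = {}
    for cond in meta["conditions"]:
        cdir = run_dir / cond
        conditions[cond] = {
            "model": deserialize_multicell(json.loads((cdir / "model.json").read_text())),
            "pathways": pd.read_csv(cdir / "pathway_flux_sum.tsv", sep="\t"),
            "medium": pd.read_csv(cdir / "medium_exchange.tsv", sep="\t"),
        }
    return {"metadata": meta, "conditions": conditions}


def compare_conditions(run_a, run_b) -> Dict[str, pd.DataFrame]:
    """Pairwise Jaccard matrix plus aligned FluxSum / exchange deltas."""
    a, b = _load_run(Path(run_a)), _load_run(Path(run_b))
    ha = a["metadata"]["input_hashes"]["network"]
    hb = b["metadata"]["input_hashes"]["network"]
    if ha != hb:
        raise PipelineError(
            "compare_conditions: runs derive from different generic networks"
        )
    entries = [("a", c, d) for c, d in a["conditions"].items()] + [
        ("b", c, d) for c, d in b["conditions"].items()
    ]
    names = [f"{tag}:{cond}" for tag, cond, _ in entries]
    jac = pd.DataFrame(index=names, columns=names, dtype=float)
    for n1, (_, _, d1) in zip(names, entries):
        for n2, (_, _, d2) in zip(names, entries):
            jac.loc[n1, n2] = jaccard_similarity(d1["model"], d2["model"])

    def _delta(key: str, on: List[str], val: str) -> pd.DataFrame:
        frames = []
        for (tag, cond, d) in entries:
            df = d[key].copy()
            df["run"] = f"{tag}:{cond}"
            frames.append(df)
        wide = pd.concat(frames).pivot_table(index=on, columns="run", values=val,
                                             fill_value=0.0)
        return wide

    pathways = _delta("pathways", ["pathway", "scope"], "flux_sum")
    medium = _delta("medium", ["metabolite"], "rate")
    return {"jaccard": jac, "pathway_flux_sum": pathways, "medium_exchange": medium}
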