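"""Single-cell expression handling: I/O, cell-type filtering, pseudobulk
normalisation and discretization into per-stratum core gene sets.

A *stratum* is one (condition, cell type) pair.  Each stratum yields one
pseudobulk expression profile (library-size normalised to counts per 10k,
log2(x+1), averaged over the stratum's cells) which is discretized into
core / unknown / inactive genes.  Core genes are mapped onto reactions
through GPR rules to produce a :class:`CoreSet` per stratum, the input of
multi-cell model building.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.stats import norm

from .network import MetabolicNetwork, map_core_reactions


class ExpressionError(ValueError):
    """Raised for malformed expression inputs."""


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x cell UMI counts with per-cell cell-type and condition labels."""

    counts: sparse.csr_matrix  # genes x cells, non-negative integers
    gene_ids: List[str]
    cell_ids: List[str]
    cell_type: np.ndarray  # str per cell
    condition: np.ndarray  # str per cell

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if n_cells == 0:
            raise ExpressionError("no cells in expression matrix")
        if n_genes == 0:
            raise ExpressionError("no genes in expression matrix")
        if len(self.gene_ids) != n_genes:
            raise ExpressionError(
                f"counts have {n_genes} genes but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise ExpressionError(
                f"counts have {n_cells} cells but {len(self.cell_ids)} cell ids"
            )
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        for name, arr in (("cell_type", self.cell_type), ("condition", self.condition)):
            if arr.shape != (n_cells,):
                raise ExpressionError(
                    f"{name} labels: expected {n_cells} entries, got {arr.shape}"
                )
        if (self.counts.data < 0).any():
            raise ExpressionError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def conditions(self) -> List[str]:
        return sorted(set(self.condition))

    def cell_types(self) -> List[str]:
        return sorted(set(self.cell_type))

    def stratum_mask(self, condition: str, cell_type: str) -> np.ndarray:
        return (self.condition == condition) & (self.cell_type == cell_type)

    def stratum_sizes(self) -> pd.DataFrame:
        """Cell counts per (condition, cell_type)."""
        df = pd.DataFrame({"condition": self.condition, "cell_type": self.cell_type})
        return (
            df.groupby(["condition", "cell_type"], sort=True)
            .size()
            .rename("n_cells")
            .reset_index()
        )


@dataclass
class CoreSet:
    """Core genes/reactions of one (condition, cell type) stratum."""

    condition: str
    cell_type: str
    core_genes: Set[str]
    core_reactions: Set[str]
    n_cells: int
    thresholds: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ExpressionError(
                f"CoreSet {self.condition}/{self.cell_type}: n_cells must be >= 1"
            )


# ---------------------------------------------------------------------------
# I/O: sparse matrix-exchange triplet + annotation tables
# ---------------------------------------------------------------------------


def read_expression(matrix_path, genes_path, cells_path, labels_path) -> ExpressionMatrix:
    """Read an MTX counts matrix (genes x cells) plus annotations.

    ``genes_path`` and ``cells_path`` are headerless single-column text
    files; ``labels_path`` is a TSV with columns cell_id, cell_type,
    condition.
    """
    for p in (matrix_path, genes_path, cells_path, labels_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    counts = sparse.csr_matrix(spio.mmread(matrix_path))
    genes = pd.read_csv(genes_path, header=None, sep="\t")[0].astype(str).tolist()
    cells = pd.read_csv(cells_path, header=None, sep="\t")[0].astype(str).tolist()
    if counts.shape[0] != len(genes) or counts.shape[1] != len(cells):
        raise ExpressionError(
            f"matrix is {counts.shape[0]}x{counts.shape[1]} but annotations list "
            f"{len(genes)} genes and {len(cells)} cells"
        )
    labels = pd.read_csv(labels_path, sep="\t")
    required = {"cell_id", "cell_type", "condition"}
    if not required <= set(labels.columns):
        raise ExpressionError(
            f"labels file must have columns {sorted(required)}, got {list(labels.columns)}"
        )
    labels = labels.set_index("cell_id")
    missing = [c for c in cells if c not in labels.index]
    if missing:
        raise ExpressionError(f"labels file missing cell id(s): {missing[:5]}")
    labels = labels.loc[cells]
    return ExpressionMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=cells,
        cell_type=labels["cell_type"].to_numpy(dtype=object),
        condition=labels["condition"].to_numpy(dtype=object),
    )


def write_expression(matrix: ExpressionMatrix, out_dir) -> Dict[str, Path]:
    """Write the MTX triplet + label table consumed by :func:`read_expression`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "counts.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
        "labels": out / "labels.tsv",
    }
    spio.mmwrite(paths["matrix"], sparse.coo_matrix(matrix.counts))
    pd.Series(matrix.gene_ids).to_csv(paths["genes"], index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(paths["cells"], index=False, header=False)
    pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "cell_type": matrix.cell_type,
            "condition": matrix.condition,
        }
    ).to_csv(paths["labels"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# cell-type filtering
# ---------------------------------------------------------------------------


def filter_cell_types(
    matrix: ExpressionMatrix, min_cells: int = 1, require_shared: bool = True
) -> Dict[str, List[str]]:
    """Retained cell-type labels per condition.

    A cell type is kept when its cluster has at least ``min_cells`` cells —
    in every condition when ``require_shared`` (small clusters absent from
    one condition are dropped everywhere), otherwise per condition.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    sizes = matrix.stratum_sizes().pivot(
        index="cell_type", columns="condition", values="n_cells"
    ).fillna(0)
    conditions = list(sizes.columns)
    retained: Dict[str, List[str]] = {}
    for cond in conditions:
        if require_shared:
            keep = sizes.index[(sizes >= min_cells).all(axis=1)]
        else:
            keep = sizes.index[sizes[cond] >= min_cells]
        retained[cond] = sorted(keep)
        if not retained[cond]:
            warnings.warn(f"no cell types retained for condition {cond!r}")
    return retained


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------


def pseudobulk(
    matrix: ExpressionMatrix,
    condition: str,
    cell_type: str,
    normalization: str = "mean_cpm_log",
) -> pd.Series:
    """Per-gene pseudobulk expression of one stratum.

    Each cell is library-size normalised to counts-per-10k and
    log2(x+1)-transformed; the stratum value is the mean over its cells.
    The transform-then-average order damps single-cell outliers; doubling
    every count in every cell leaves the values unchanged.
    """
    if normalization != "mean_cpm_log":
        raise ValueError(f"unknown normalization {normalization!r}")
    mask = matrix.stratum_mask(condition, cell_type)
    if not mask.any():
        raise ExpressionError(f"empty stratum: condition={condition!r} cell_type={cell_type!r}")
    sub = matrix.counts[:, mask].toarray().astype(float)
    libsize = sub.sum(axis=0)
    libsize[libsize == 0] = 1.0  # cells with no counts contribute zeros
    cp10k = sub / libsize * 1e4
    logged = np.log2(cp10k + 1.0)
    return pd.Series(logged.mean(axis=1), index=matrix.gene_ids, name=f"{condition}/{cell_type}")


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


@dataclass
class DiscretizationParams:
    """Tunables of the two-threshold discretization.

    The nonzero log-expression values of a stratum are modelled as a
    two-component Gaussian mixture (low = unexpressed/leaky, high =
    expressed).  The upper threshold is the smallest value whose posterior
    probability of the high component reaches ``p_core``; the lower
    threshold the largest value whose posterior of the low component
    reaches ``p_inactive``.  Genes above the upper threshold are core,
    below the lower threshold (or zero) inactive, in between unknown.

    When the mixture is degenerate (too few distinct nonzero values, or
    components closer than ``min_separation`` pooled standard deviations)
    the scheme falls back to percentile thresholds and warns.
    Explicit ``upper``/``lower`` override everything.
    """

    p_core: float = 0.9
    p_inactive: float = 0.9
    fallback_core_pct: float = 66.0
    fallback_inactive_pct: float = 33.0
    min_separation: float = 1.0
    min_nonzero: int = 8
    upper: Optional[float] = None
    lower: Optional[float] = None


@dataclass
class DiscretizationResult:
    core: Set[str]
    inactive: Set[str]
    unknown: Set[str]
    upper_threshold: float
    lower_threshold: float
    method: str


def _fit_two_gaussians(x: np.ndarray, n_iter: int = 200, tol: float = 1e-8):
    """Deterministic 2-component 1-D Gaussian mixture EM.

    Initialised from the data midpoint split, so the fit depends only on
    the multiset of values (gene/cell order invariant).
    """
    x = np.sort(x)
    lo0, hi0 = x[: len(x) // 2], x[len(x) // 2:]
    mu = np.array([lo0.mean(), hi0.mean()])
    sd = np.array([max(lo0.std(), 1e-3), max(hi0.std(), 1e-3)])
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    for _ in range(n_iter):
        dens = w * norm.pdf(x[:, None], mu, sd)
        tot = dens.sum(axis=1)
        tot[tot == 0] = 1e-300
        resp = dens / tot[:, None]
        nk = resp.sum(axis=0)
        nk[nk == 0] = 1e-12
        mu = (resp * x[:, None]).sum(axis=0) / nk
        sd = np.sqrt((resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk)
        sd = np.maximum(sd, 1e-3)
        w = nk / len(x)
        ll = np.log(tot).sum()
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    order = np.argsort(mu)
    return w[order], mu[order], sd[order]


def discretize_full(
    expr: Mapping[str, float] | pd.Series,
    params: Optional[DiscretizationParams] = None,
) -> DiscretizationResult:
    """Partition genes into core / unknown / inactive from pseudobulk values."""
    params = params or DiscretizationParams()
    series = pd.Series(expr, dtype=float)
    if series.empty:
        raise ExpressionError("discretize: empty expression vector")
    values = series.to_numpy()
    nonzero = values[values > 0]

    method = "mixture"
    upper = params.upper
    lower = params.lower
    if upper is None or lower is None:
        fit_ok = False
        if len(np.unique(nonzero)) >= params.min_nonzero:
            w, mu, sd = _fit_two_gaussians(nonzero)
            pooled = np.sqrt(0.5 * (sd[0] ** 2 + sd[1] ** 2))
            if (mu[1] - mu[0]) >= params.min_separation * pooled and min(w) > 0.02:
                # posterior-threshold crossings on a grid between the modes
                grid = np.linspace(mu[0], mu[1], 2001)
                dens = w * norm.pdf(grid[:, None], mu, sd)
                post_hi = dens[:, 1] / dens.sum(axis=1)
                hi_idx = np.flatnonzero(post_hi >= params.p_core)
                lo_idx = np.flatnonzero((1.0 - post_hi) >= params.p_inactive)
                if hi_idx.size and lo_idx.size:
                    t_hi = float(grid[hi_idx[0]])
                    t_lo = float(grid[lo_idx[-1]])
                    if t_lo <= t_hi:
                        fit_ok = True
        if not fit_ok:
            warnings.warn(
                "discretize: degenerate expression distribution; "
                "falling back to percentile thresholds"
            )
            method = "percentile"
            ref = nonzero if nonzero.size else values
            t_hi = float(np.percentile(ref, params.fallback_core_pct))
            t_lo = float(np.percentile(ref, params.fallback_inactive_pct))
        upper = t_hi if upper is None else upper
        lower = t_lo if lower is None else lower
    else:
        method = "explicit"
    if lower > upper:
        lower = upper

    core = set(series.index[values > upper])
    inactive = set(series.index[(values < lower) | (values == 0)]) - core
    unknown = set(series.index) - core - inactive
    return DiscretizationResult(
        core=core,
        inactive=inactive,
        unknown=unknown,
        upper_threshold=float(upper),
        lower_threshold=float(lower),
        method=method,
    )


def discretize(
    expr: Mapping[str, float] | pd.Series,
    params: Optional[DiscretizationParams] = None,
) -> Set[str]:
    """Core gene set of one stratum (see :func:`discretize_full`)."""
    return discretize_full(expr, params).core


# ---------------------------------------------------------------------------
# end-to-end core-set construction
# ---------------------------------------------------------------------------


def build_core_sets(
    matrix: ExpressionMatrix,
    network: MetabolicNetwork,
    condition: str,
    cell_types: Sequence[str],
    params: Optional[DiscretizationParams] = None,
) -> List[CoreSet]:
    """One :class:`CoreSet` per retained cell type of a condition."""
    out: List[CoreSet] = []
    for ct in cell_types:
        expr = pseudobulk(matrix, condition, ct)
        res = discretize_full(expr, params)
        n_cells = int(matrix.stratum_mask(condition, ct).sum())
        out.append(
            CoreSet(
                condition=condition,
                cell_type=ct,
                core_genes=res.core,
                core_reactions=map_core_reactions(network, res.core),
                n_cells=n_cells,
                thresholds={
                    "upper": res.upper_threshold,
                    "lower": res.lower_threshold,
                },
            )
        )
    return out
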