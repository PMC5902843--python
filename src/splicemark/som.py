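"""Hexagonal self-organizing map over the genes x cell-types enrichment matrix.

An online Kohonen SOM on a hexagonal lattice: each presented gene vector
picks its best-matching unit (BMU, minimum Euclidean distance, ties to the
lowest node index) and the codebook is pulled toward it with a Gaussian
neighborhood on hex-grid distance,

    w_j <- w_j + alpha(t) * exp(-d_grid(j, bmu)^2 / (2 sigma(t)^2)) * (x - w_j)

with alpha and sigma decaying linearly over epochs. Nodes are then grouped
by hierarchical clustering of codebook vectors and each cell type is
assigned to the node cluster where its mean enrichment is maximal.

Grid layout is odd-row offset ("pointy-top" hexagons); node (col, row) has
Cartesian center (col + 0.5*(row % 2), row * sqrt(3)/2), and hex-grid
distance is the Euclidean distance between centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

DEFAULT_GRID = (12, 8)  # desk-scale default; the full-scale map is 40 x 25
FULL_SCALE_GRID = (40, 25)  # the genome-scale layout
DEFAULT_K = 6
DEFAULT_EPOCHS = 100


@dataclass
class SOMConfig:
    nx: int = DEFAULT_GRID[0]
    ny: int = DEFAULT_GRID[1]
    epochs: int = DEFAULT_EPOCHS
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    sigma_start: Optional[float] = None  # default: grid diagonal / 3
    sigma_end: float = 1.0
    row_scaling: str = "unit-variance"  # {"none", "unit-variance", "z-score"}

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.row_scaling not in ("none", "unit-variance", "z-score"):
            raise ValueError(f"unknown row_scaling {self.row_scaling!r}")

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny


@dataclass
class SOMModel:
    config: SOMConfig
    codebook: np.ndarray  # (n_nodes, dim)
    grid_xy: np.ndarray  # (n_nodes, 2) Cartesian hexagon centers
    seed: int
    quantization_error_init: float
    quantization_error_final: float
    columns: Optional[List[str]] = None  # training column order (cell types)


@dataclass
class ClusterAssignment:
    node_cluster: np.ndarray  # (n_nodes,) labels 1..k
    celltype_cluster: Dict[str, int]
    cluster_genes: Dict[int, List[str]]


# --------------------------------------------------------------------- grid

def hex_grid_coords(nx: int, ny: int) -> np.ndarray:
    """Cartesian centers of an odd-row offset hex grid, node index = row*nx + col."""
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    x = cols + 0.5 * (rows % 2)
    y = rows * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


def grid_distances(grid_xy: np.ndarray) -> np.ndarray:
    diff = grid_xy[:, None, :] - grid_xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


# ----------------------------------------------------------------- training

def scale_rows(X: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return X.astype(float)
    X = X.astype(float)
    if mode == "z-score":
        mu = X.mean(axis=1, keepdims=True)
        X = X - mu
    sd = X.std(axis=1, ddof=0, keepdims=True)
    return X / np.where(sd == 0, 1.0, sd)


def best_matching_unit(codebook: np.ndarray, x: np.ndarray) -> int:
    """Index of the nearest codebook vector; ties go to the lowest index."""
    d2 = ((codebook - x) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def quantization_error(codebook: np.ndarray, X: np.ndarray) -> float:
    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def train_som(
    matrix: pd.DataFrame,
    config: Optional[SOMConfig] = None,
    seed: int = 0,
) -> SOMModel:
    """Online SOM training on the (scaled) rows of ``matrix``.

    Presentation order is reshuffled every epoch from the run seed; the
    codebook is initialized uniformly at random inside the per-dimension
    data range (so a single-row input makes every node start at that row).
    """
    config = config or SOMConfig()
    X = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite values")
    X = scale_rows(X, config.row_scaling)
    n, dim = X.shape
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    codebook = lo + rng.random((config.n_nodes, dim)) * (hi - lo)
    grid_xy = hex_grid_coords(config.nx, config.ny)
    gdist = grid_distances(grid_xy)
    qe_init = quantization_error(codebook, X)

    diag = float(np.sqrt(((grid_xy.max(axis=0) - grid_xy.min(axis=0)) ** 2).sum()))
    sigma_start = config.sigma_start if config.sigma_start is not None else diag / 3.0
    epochs = config.epochs
    for epoch in range(epochs):
        t = epoch / (epochs - 1) if epochs > 1 else 0.0
        alpha = config.alpha_start + t * (config.alpha_end - config.alpha_start)
        sigma = sigma_start + t * (config.sigma_end - sigma_start)
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            bmu = best_matching_unit(codebook, x)
            h = np.exp(-(gdist[bmu] ** 2) / (2.0 * sigma * sigma))
            codebook += (alpha * h)[:, None] * (x - codebook)
    return SOMModel(
        config=config,
        codebook=codebook,
        grid_xy=grid_xy,
        seed=seed,
        quantization_error_init=qe_init,
        quantization_error_final=quantization_error(codebook, X),
        columns=list(matrix.columns),
    )


def map_rows(model: SOMModel, matrix: pd.DataFrame) -> np.ndarray:
    """BMU index for every (scaled) row of ``matrix``.

    Columns are aligned to the model's training column order, so cell-type
    order in the frame is immaterial.
    """
    if model.columns is not None:
        matrix = matrix[[c for c in model.columns]]
    X = scale_rows(matrix.to_numpy(dtype=float), model.config.row_scaling)
    d2 = ((X[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


# ----------------------------------------------------------------- grouping

def group_nodes(
    model: SOMModel, k: int = DEFAULT_K, k_range: Tuple[int, int] = (2, 12)
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Complete-linkage clustering of codebook vectors into ``k`` node groups.

    Also reports a homogeneity curve (within-cluster variance explained,
    1 - SSW/SST) over ``k_range`` to support choosing k.
    """
    n_nodes = model.codebook.shape[0]
    if k > n_nodes:
        raise ValueError(f"k={k} exceeds number of nodes ({n_nodes})")
    link = hierarchy.linkage(model.codebook, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    rows = []
    for kk in range(k_range[0], min(k_range[1], n_nodes) + 1):
        lab = hierarchy.fcluster(link, t=kk, criterion="maxclust")
        rows.append({"k": kk, "homogeneity": _homogeneity(model.codebook, lab)})
    return labels, pd.DataFrame(rows)


def _homogeneity(X: np.ndarray, labels: np.ndarray) -> float:
    grand = X.mean(axis=0)
    sst = float(((X - grand) ** 2).sum())
    if sst == 0:
        return 1.0
    ssw = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        ssw += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return 1.0 - ssw / sst


# --------------------------------------------------------------- assignment

def build_gene_matrix(records: pd.DataFrame, etype: str = "SE") -> pd.DataFrame:
    """Genes x cell-types matrix of enrichment/kb for genes with >=1 site of
    ``etype``; missing entries are 0, rows in lexicographic gene order."""
    if "type" in records.columns:
        records = records[records["type"] == etype]
    elif "event_id" in records.columns:
        records = records[records["event_id"].str.endswith(f"_{etype}")]
    if records.empty:
        raise ValueError("no enrichment records for the requested event type")
    mat = records.pivot_table(
        index="gene_id", columns="celltype", values="enrichment_per_kb", aggfunc="mean"
    ).fillna(0.0)
    return mat.sort_index()


def assign_celltypes(
    matrix: pd.DataFrame, model: SOMModel, node_labels: np.ndarray
) -> ClusterAssignment:
    """Assign each cell type to its most enriched node cluster.

    For each cell type, the mean enrichment over the genes mapping to each
    cluster's nodes is computed and the argmax cluster assigned (ties to
    the lowest cluster label).
    """
    bmus = map_rows(model, matrix)
    gene_cluster = node_labels[bmus]
    cluster_genes: Dict[int, List[str]] = {}
    for gene, lab in zip(matrix.index, gene_cluster):
        cluster_genes.setdefault(int(lab), []).append(str(gene))
    celltype_cluster: Dict[str, int] = {}
    labs = sorted(cluster_genes)
    for ct in matrix.columns:
        col = matrix[ct].to_numpy(dtype=float)
        means = [col[gene_cluster == lab].mean() for lab in labs]
        celltype_cluster[str(ct)] = labs[int(np.argmax(means))]
    return ClusterAssignment(
        node_cluster=node_labels,
        celltype_cluster=celltype_cluster,
        cluster_genes=cluster_genes,
    )


# -------------------------------------------------------------- statistics

@dataclass
class ClusterStats:
    cluster: int
    log2_fold_change: float
    p_value: float
    p_label: str
    n_se: int
    n_non_se: int


def cluster_se_stats(
    cluster: int,
    se_values: Sequence[float],
    non_se_values: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    eps: float = 1e-8,
) -> ClusterStats:
    """log2 fold change of SE vs non-SE enrichment plus a permutation p-value.

    log2FC = log2((mean_SE + eps) / (mean_nonSE + eps)); the p-value is the
    two-sided permutation probability of an absolute mean difference at
    least as large as observed, reported as (b+1)/(n_perm+1) so it is never
    zero and is labelled "< 1/n_perm" when no permutation exceeds.
    """
    a = np.asarray(se_values, dtype=float)
    b = np.asarray(non_se_values, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    log2fc = float(np.log2((a.mean() + eps) / (b.mean() + eps)))
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = abs(perm[: len(a)].mean() - perm[len(a):].mean())
        if diff >= obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    label = f"< {1.0 / n_perm:g}" if exceed == 0 else f"{p:.4g}"
    return ClusterStats(
        cluster=cluster,
        log2_fold_change=log2fc,
        p_value=float(p),
        p_label=label,
        n_se=len(a),
        n_non_se=len(b),
    )
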