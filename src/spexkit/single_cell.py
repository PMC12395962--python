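"""Clustering recipes for proteomics (intensity) and transcriptomics
(count) cell tables.

The transcriptomics recipe is: UMI QC filter (default minimum 20 total
counts per cell) -> median-total-count normalization + log1p -> per-feature
z-scoring -> PCA with the component count picked from the singular-value
spectrum -> KNN graph (K = floor(sqrt(n)) by default) -> Leiden.

The proteomics recipe transforms intensities (arcsinh with a configurable
cofactor, or log1p), optionally winsorizes / z-scores per feature, and
clusters with a PhenoGraph-style Jaccard shared-neighbor graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from .types import ValidationError

__all__ = [
    "ClusteringParams",
    "qc_filter_umi",
    "normalize_log",
    "transform_scale",
    "pca_select",
    "graph_cluster",
    "annotate_clusters",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusteringParams:
    """Knobs shared by the clustering recipes.

    ``knn_k=None`` means automatic: ``floor(sqrt(n_cells))``.
    """

    transform: str = "arcsinh"  # arcsinh | log | none
    arcsinh_cofactor: float = 5.0
    scaling: str = "zscore"  # winsorize | zscore | none
    winsor_limits: tuple[float, float] = (1.0, 99.0)
    knn_k: int | None = None
    resolution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transform not in {"arcsinh", "log", "none"}:
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.scaling not in {"winsorize", "zscore", "none"}:
            raise ValidationError(f"unknown scaling {self.scaling!r}")
        if self.arcsinh_cofactor <= 0:
            raise ValidationError("arcsinh_cofactor must be positive")
        lo, hi = self.winsor_limits
        if not lo < hi:
            raise ValidationError("winsor limits must satisfy low < high")
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")

    def resolve_k(self, n_cells: int) -> int:
        return self.knn_k if self.knn_k is not None else int(np.floor(np.sqrt(n_cells)))


def qc_filter_umi(table: AnnData, min_total: int = 20) -> AnnData:
    """Drop cells with fewer than ``min_total`` total counts.

    Order is preserved; the filter parameters and the number of removed
    cells are recorded in ``uns["qc_filter"]``.
    """
    X = np.asarray(table.X)
    if X.min() < 0:
        raise ValidationError("UMI QC expects non-negative counts")
    totals = X.sum(axis=1)
    keep = totals >= min_total
    if keep.sum() == 0:
        warnings.warn("all cells fall below the UMI threshold; table is empty")
    out = table[keep].copy()
    out.uns["qc_filter"] = {
        "min_total": int(min_total),
        "n_removed": int((~keep).sum()),
    }
    return out


def normalize_log(table: AnnData) -> AnnData:
    """Scale each cell to the median total count, then log1p.

    The pre-normalization median total is the common target; after scaling
    every cell's total equals it exactly, then ``x <- ln(1 + x)``.
    """
    X = np.asarray(table.X, dtype=float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError(
            "zero-total cell present; run the UMI QC filter before normalizing"
        )
    median_total = float(np.median(totals))
    out = table.copy()
    out.X = np.log1p(X * (median_total / totals)[:, None])
    out.uns["normalize_log"] = {"median_total": median_total}
    return out


def transform_scale(table: AnnData, params: ClusteringParams | None = None) -> AnnData:
    """Variance-stabilizing transform plus per-feature scaling (proteomics).

    arcsinh: ``x <- asinh(x / cofactor)``; log: ``x <- ln(1 + x)``.
    Winsorizing clips each feature at the stated percentiles; z-scoring
    standardizes each feature (features with zero spread map to 0).
    """
    params = params or ClusteringParams()
    X = np.asarray(table.X, dtype=float).copy()
    if params.transform == "arcsinh":
        X = np.arcsinh(X / params.arcsinh_cofactor)
    elif params.transform == "log":
        X = np.log1p(X)
    if params.scaling == "winsorize":
        lo, hi = np.percentile(X, params.winsor_limits, axis=0)
        X = np.clip(X, lo, hi)
    elif params.scaling == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd_safe
        X[:, sd == 0] = 0.0
    out = table.copy()
    out.X = X
    out.uns["transform_scale"] = {
        "transform": params.transform,
        "arcsinh_cofactor": params.arcsinh_cofactor,
        "scaling": params.scaling,
    }
    return out


def _elbow_by_chord(values: np.ndarray) -> tuple[int, float]:
    """Component count at the elbow of a decreasing curve.

    The elbow is the point of maximum perpendicular distance to the chord
    joining the first and last values; on a sharply kneed spectrum it lands
    on the first noise-floor value, so the count of retained components is
    its index.  Also returns the bow depth relative to the leading value
    (a near-linear spectrum bows ~0 and has no meaningful elbow).
    """
    k = len(values)
    if k < 3:
        return k, 1.0
    span = values[0] - values[-1]
    if span <= 0:
        return k, 0.0
    # normalize both axes to [0, 1] so the chord geometry is scale-free
    x = np.arange(k, dtype=float) / (k - 1)
    y = (values - values[-1]) / span
    chord = np.array([1.0, y[-1] - y[0]])  # (1, -1) after normalization
    norm = np.linalg.norm(chord)
    pts = np.column_stack([x - x[0], y - y[0]])
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    knee = int(np.argmax(dist))
    return max(1, knee), float(dist.max())


def pca_select(
    table: AnnData, max_components: int = 50, standardize: bool = True
) -> AnnData:
    """PCA with the component count chosen from the singular-value curve.

    The retained count is the elbow of the singular-value spectrum
    (maximum perpendicular distance to the first-to-last chord), bounded by
    ``max_components``.  The embedding lands in ``obsm["X_pca"]`` and the
    chosen count in ``uns["pca"]``.
    """
    from sklearn.decomposition import PCA

    if table.n_obs < 3:
        raise ValidationError("PCA needs at least 3 cells")
    if table.n_vars < 3:
        raise ValidationError("PCA needs at least 3 features")
    X = np.asarray(table.X, dtype=float)
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    k_max = min(max_components, table.n_obs - 1, table.n_vars)
    pca = PCA(n_components=k_max, svd_solver="full")
    emb = pca.fit_transform(X)
    # elbow on the full spectrum so truncation cannot fake a knee
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    knee, depth = _elbow_by_chord(sv)
    n_keep = min(knee, k_max)
    # a noise-bulk spectrum is flat (small max/min ratio) and bows weakly
    if depth < 0.1 or sv[0] < 3 * sv[-1]:
        warnings.warn("singular-value spectrum has no clear elbow; keeping k_max")
        n_keep = k_max
    out = table.copy()
    out.obsm["X_pca"] = emb[:, :n_keep]
    out.uns["pca"] = {
        "n_components": int(n_keep),
        "singular_values": sv.tolist(),
    }
    return out


def _knn_indices(X: np.ndarray, k: int) -> np.ndarray:
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    return idx[:, 1:]  # drop self


def _leiden_on_edges(
    n: int,
    edges: np.ndarray,
    weights: np.ndarray,
    resolution: float,
    seed: int,
) -> np.ndarray:
    import igraph as ig
    import leidenalg

    g = ig.Graph(n=n, edges=[tuple(e) for e in edges])
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights.tolist(),
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def graph_cluster(
    table: AnnData,
    params: ClusteringParams | None = None,
    method: str = "leiden",
    use_rep: str | None = None,
) -> AnnData:
    """KNN-graph community detection; labels land in ``obs["cluster"]``.

    ``method="leiden"``: Leiden on the KNN graph (unit edge weights).
    ``method="phenograph"``: edges reweighted by the Jaccard index of the
    two endpoints' neighbor sets before community detection.  Labels are
    contiguous from 0; the run is seeded.
    """
    if method not in {"leiden", "phenograph"}:
        raise ValidationError(f"unknown clustering method {method!r}")
    params = params or ClusteringParams()
    if use_rep is None:
        use_rep = "X_pca" if "X_pca" in table.obsm else None
    X = (
        np.asarray(table.obsm[use_rep], dtype=float)
        if use_rep
        else np.asarray(table.X, dtype=float)
    )
    n = X.shape[0]
    k = params.resolve_k(n)
    if k >= n:
        raise ValidationError(f"K={k} must be smaller than n_cells={n}")
    if k < 1:
        raise ValidationError("K must be >= 1")

    knn = _knn_indices(X, k)
    src = np.repeat(np.arange(n), k)
    dst = knn.ravel()
    # undirected, deduplicated edge list
    und = np.sort(np.column_stack([src, dst]), axis=1)
    und = np.unique(und, axis=0)

    if method == "leiden":
        w = np.ones(len(und))
    else:
        nbr_sets = [set(row) | {i} for i, row in enumerate(knn)]
        w = np.array(
            [
                len(nbr_sets[i] & nbr_sets[j]) / len(nbr_sets[i] | nbr_sets[j])
                for i, j in und
            ]
        )
        keep = w > 0
        und, w = und[keep], w[keep]

    membership = _leiden_on_edges(n, und, w, params.resolution, params.seed)
    # relabel to contiguous ids ordered by first appearance
    _, contiguous = np.unique(membership, return_inverse=True)
    order = pd.unique(contiguous)
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in contiguous])

    out = table.copy()
    out.obs["cluster"] = pd.Categorical(labels.astype(str))
    out.uns["graph_cluster"] = {
        "method": method,
        "knn_k": int(k),
        "resolution": params.resolution,
        "seed": params.seed,
        "n_clusters": int(labels.max()) + 1,
    }
    return out


def annotate_clusters(
    table: AnnData,
    mapping: dict,
    cluster_column: str = "cluster",
    out_column: str = "cell_type",
) -> AnnData:
    """Rename clusters into biological labels; merging is allowed.

    Unmapped clusters keep their stringified ids.  A mapping key that does
    not correspond to an observed cluster is an error.
    """
    if cluster_column not in table.obs:
        raise ValidationError(f"no {cluster_column!r} column; cluster first")
    clusters = table.obs[cluster_column].astype(str)
    observed = set(clusters)
    mapping = {str(k): str(v) for k, v in mapping.items()}
    unknown = set(mapping) - observed
    if unknown:
        raise ValidationError(
            f"mapping references unknown clusters {sorted(unknown)}; "
            f"observed clusters are {sorted(observed)}"
        )
    out = table.copy()
    out.obs[out_column] = pd.Categorical(
        [mapping.get(c, c) for c in clusters]
    )
    return out
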