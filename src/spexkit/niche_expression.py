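"""Neighborhood-composition niches and spatially informed expression.

A cell's *neighborhood composition* is the per-type count of cells inside
a circle of radius epsilon centered on it (the cell itself included).
Clustering those composition vectors yields spatial niches — recurring
local communities such as tertiary lymphoid structures or tumor-immune
interfaces.

Cells can also be grouped by their local colocation quotient toward a
target type (avoidant below 0.5, attractive above 1.5 by default) and the
groups compared by differential expression, or scored for pathway activity
by ordinary least squares against a gene-by-pathway weight matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from scipy.spatial import cKDTree

from .single_cell import ClusteringParams, graph_cluster
from .types import (
    DEResult,
    IMAGE_ID_KEY,
    NicheResult,
    PathwayModel,
    SPATIAL_KEY,
    ValidationError,
    validate_cell_table,
)

__all__ = [
    "SpatialGrouping",
    "neighborhood_composition",
    "detect_niches",
    "stratify_by_clq",
    "differential_expression",
    "pathway_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialGrouping:
    """Per-cell spatial group labels (empty string = ungrouped)."""

    basis: str  # "clq_call" or "niche"
    labels: np.ndarray  # object array aligned to the cell table

    def group_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.labels == name)


def neighborhood_composition(
    table: AnnData,
    radius_um: float,
    type_column: str = "cell_type",
    include_self: bool = True,
) -> NicheResult:
    """Per-cell counts of each type within ``radius_um`` (self included).

    Counts never cross ``image_id`` boundaries.  Each row sums to the
    cell's neighbor count at that radius plus one for itself.
    """
    if radius_um <= 0:
        raise ValidationError("radius_um must be positive")
    validate_cell_table(table, require=(type_column,))
    labels = np.asarray(table.obs[type_column]).astype(object)
    types = sorted(set(labels.tolist()))
    t_index = {t: k for k, t in enumerate(types)}
    labels_idx = np.array([t_index[t] for t in labels])
    coords = np.asarray(table.obsm[SPATIAL_KEY], dtype=float)
    image_ids = np.asarray(table.obs[IMAGE_ID_KEY])

    comp = np.zeros((table.n_obs, len(types)), dtype=int)
    for img in pd.unique(image_ids):
        idx = np.flatnonzero(image_ids == img)
        tree = cKDTree(coords[idx])
        neighborhoods = tree.query_ball_point(coords[idx], r=radius_um)
        for local_i, nbrs in enumerate(neighborhoods):
            gi = idx[local_i]
            members = idx[np.asarray(nbrs, dtype=int)]
            if not include_self:
                members = members[members != gi]
            np.add.at(comp[gi], labels_idx[members], 1)

    df = pd.DataFrame(comp, index=table.obs_names, columns=types)
    return NicheResult(composition=df, radius_um=radius_um)


def detect_niches(
    composition: NicheResult,
    method: str = "leiden",
    resolution: float = 1.0,
    seed: int = 0,
    normalize: bool = False,
    knn_k: int | None = None,
) -> NicheResult:
    """Cluster neighborhood compositions into spatial niches.

    Raw counts are clustered by default; ``normalize=True`` switches to
    per-cell fractions.  Niche ids are contiguous from 0 and a per-niche
    mean composition table is attached.
    """
    comp = composition.composition.to_numpy(dtype=float)
    n = comp.shape[0]
    if n == 1:
        niche = np.zeros(1, dtype=int)
    else:
        feats = comp
        if normalize:
            feats = comp / comp.sum(axis=1, keepdims=True)
        dummy = AnnData(X=feats)
        params = ClusteringParams(
            transform="none", scaling="none", resolution=resolution,
            seed=seed, knn_k=knn_k,
        )
        clustered = graph_cluster(dummy, params, method=method, use_rep=None)
        niche = clustered.obs["cluster"].astype(int).to_numpy()
    profiles = (
        composition.composition.assign(_niche=niche).groupby("_niche").mean()
    )
    profiles.index.name = "niche"
    return NicheResult(
        composition=composition.composition,
        radius_um=composition.radius_um,
        niche=niche,
        niche_profiles=profiles,
    )


def stratify_by_clq(
    table: AnnData,
    local_clq_values: np.ndarray,
    low: float = 0.5,
    high: float = 1.5,
) -> SpatialGrouping:
    """Label cells avoidant / attractive by their local CLQ.

    Strictly below ``low`` -> "avoidant"; strictly above ``high`` ->
    "attractive"; in between (or NaN) -> ungrouped.
    """
    if low >= high:
        raise ValidationError("low threshold must be below high threshold")
    vals = np.asarray(local_clq_values, dtype=float)
    if len(vals) != table.n_obs:
        raise ValidationError("local CLQ array does not align with the table")
    labels = np.full(len(vals), "", dtype=object)
    with np.errstate(invalid="ignore"):
        labels[vals < low] = "avoidant"
        labels[vals > high] = "attractive"
    if not np.any(labels != ""):
        warnings.warn("no cell crosses either CLQ threshold; grouping is empty")
    return SpatialGrouping(basis="clq_call", labels=labels)


def differential_expression(
    table: AnnData,
    grouping: SpatialGrouping,
    group1: str,
    group2: str,
    test: str = "ttest",
    min_cells: int = 3,
) -> DEResult:
    """Per-gene two-sample test between two spatial groups.

    Default is Welch's t-test on the (log-normalized) expression values —
    the convention of standard single-cell marker ranking — with a
    Benjamini–Hochberg adjustment across genes.  ``test="wilcoxon"``
    switches to the rank-sum test.  The log2 fold change uses a 1e-9
    pseudocount on the group means.  The result is sorted by |statistic|.
    """
    from statsmodels.stats.multitest import multipletests

    if test not in {"ttest", "wilcoxon"}:
        raise ValidationError(f"unknown test {test!r}")
    i1 = grouping.group_indices(group1)
    i2 = grouping.group_indices(group2)
    if len(np.intersect1d(i1, i2)) > 0:
        raise ValidationError("groups overlap; they must be disjoint")
    if len(i1) < min_cells or len(i2) < min_cells:
        raise ValidationError(
            f"each group needs >= {min_cells} cells "
            f"(got {len(i1)} vs {len(i2)})"
        )
    X = np.asarray(table.X, dtype=float)
    X1, X2 = X[i1], X[i2]
    if test == "ttest":
        stat, pval = stats.ttest_ind(X1, X2, axis=0, equal_var=False)
    else:
        stat = np.empty(X.shape[1])
        pval = np.empty(X.shape[1])
        for g in range(X.shape[1]):
            res = stats.mannwhitneyu(X1[:, g], X2[:, g], alternative="two-sided")
            stat[g], pval[g] = res.statistic, res.pvalue
    pval = np.where(np.isnan(pval), 1.0, pval)
    stat = np.where(np.isnan(stat), 0.0, stat)
    # fold change on the expression scale: log-normalized group means are
    # mapped back through expm1 before the ratio (single-cell convention)
    eps = 1e-9
    log2fc = np.log2(
        (np.expm1(X1.mean(axis=0)) + eps) / (np.expm1(X2.mean(axis=0)) + eps)
    )
    _, padj, _, _ = multipletests(pval, method="fdr_bh")
    df = pd.DataFrame(
        {
            "gene": table.var_names,
            "statistic": stat,
            "log2fc": log2fc,
            "pval": pval,
            "pval_adj": padj,
        }
    ).sort_values("statistic", key=np.abs, ascending=False, ignore_index=True)
    return DEResult(
        table=df, group1=group1, group2=group2,
        n1=len(i1), n2=len(i2), test=test,
    )


def pathway_scores(
    table: AnnData,
    model: PathwayModel,
    aggregate_by: str | None = None,
) -> pd.DataFrame:
    """Per-cell pathway activity by a multilinear (OLS) fit.

    Each cell's expression vector over the model's genes is regressed on
    the gene-by-pathway weight matrix; the fitted coefficient per pathway
    is that cell's activity score.  With ``aggregate_by`` set to an obs
    column, the per-group mean score table is returned instead (and the
    per-cell table stored in ``obsm`` is left to the caller).
    """
    genes = [g for g in model.gene_names if g in set(table.var_names)]
    if not genes:
        raise ValidationError("no overlap between model genes and table features")
    W = model.weights.loc[genes].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(W)
    if rank < W.shape[1]:
        raise ValidationError(
            f"pathway weight matrix is rank-deficient over the {len(genes)} "
            f"shared genes (rank {rank} < {W.shape[1]} pathways); "
            "collinear pathways cannot be separated"
        )
    X = np.asarray(table[:, genes].X, dtype=float)
    coefs, *_ = np.linalg.lstsq(W, X.T, rcond=None)  # pathways x cells
    scores = pd.DataFrame(
        coefs.T, index=table.obs_names, columns=model.pathway_names
    )
    if aggregate_by is not None:
        if aggregate_by not in table.obs:
            raise ValidationError(f"no obs column {aggregate_by!r} to aggregate by")
        scores = scores.groupby(
            np.asarray(table.obs[aggregate_by]).astype(str)
        ).mean()
        scores.index.name = aggregate_by
    return scores
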