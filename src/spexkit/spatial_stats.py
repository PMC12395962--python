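"""Colocation-quotient (CLQ) spatial statistics and permutation tests.

The colocation quotient measures, for an ordered cell-type pair A -> B,
the local density of B around A relative to B's global density.  For each
type-A cell i the local quotient is

    LCLQ(A_i -> B) = ( sum_j w_ij * delta_ij / sum_j w_ij ) / ( N_b' / (N - 1) )

where the sums run over i's radius neighborhood, delta_ij indicates that
cell j is type B, w_ij is a uniform or Gaussian distance-decay weight, N is
the total cell count and N_b' the count of candidate B neighbors (N_b for
A != B; N_b - 1 for the self-pair A == A, since a cell cannot neighbor
itself — this keeps 1 the no-association value).  The global CLQ(A -> B)
is the mean of the defined local quotients over A cells; A cells with an
empty neighborhood are excluded from the mean and counted.

LCLQ = 1 means the neighborhood proportion of B equals its global
proportion: no spatial relationship.  Values > 1 indicate attraction,
< 1 avoidance.

Significance comes from a label-permutation test: coordinates stay fixed,
cell-type labels are shuffled jointly (within each image), and the observed
statistic joins the null distribution, so with ``n_perm`` permutations

    P_attractive = (#{CLQ_perm >= CLQ_obs} + 1) / (n_perm + 1)
    P_avoidant   = (#{CLQ_perm <= CLQ_obs} + 1) / (n_perm + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy.spatial import cKDTree

from .types import (
    CLQResult,
    IMAGE_ID_KEY,
    NeighborGraph,
    SPATIAL_KEY,
    ValidationError,
    validate_cell_table,
)

__all__ = [
    "build_neighbor_graph",
    "local_clq",
    "global_clq",
    "clq_significance",
    "cooccurrence_permutation",
    "classify_immune_phenotype",
    "ImmunePhenotypeResult",
]

logger = logging.getLogger(__name__)


def build_neighbor_graph(
    table: AnnData,
    radius_um: float,
    kernel: str = "uniform",
    sigma_um: float | None = None,
) -> NeighborGraph:
    """All ordered cell pairs within ``radius_um``, stratified by image.

    Pairs never cross ``image_id`` boundaries.  ``kernel="uniform"`` gives
    constant weights (which cancel in the neighborhood proportion);
    ``kernel="gaussian"`` gives ``w_ij = exp(-d_ij^2 / (2 sigma^2))`` with
    ``sigma_um`` defaulting to ``radius_um / 3``.
    """
    if radius_um <= 0:
        raise ValidationError("radius_um must be positive")
    if kernel not in {"uniform", "gaussian"}:
        raise ValidationError(f"unknown kernel {kernel!r}")
    validate_cell_table(table)
    coords = np.asarray(table.obsm[SPATIAL_KEY], dtype=float)
    image_ids = np.asarray(table.obs[IMAGE_ID_KEY])
    if sigma_um is None:
        sigma_um = radius_um / 3.0

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    dists: list[np.ndarray] = []
    for img in pd.unique(image_ids):
        idx = np.flatnonzero(image_ids == img)
        tree = cKDTree(coords[idx])
        pairs = tree.query_pairs(radius_um, output_type="ndarray")
        if len(pairs) == 0:
            continue
        gi, gj = idx[pairs[:, 0]], idx[pairs[:, 1]]
        d = np.linalg.norm(coords[gi] - coords[gj], axis=1)
        # store both orderings: the structure is symmetric
        rows.append(np.concatenate([gi, gj]))
        cols.append(np.concatenate([gj, gi]))
        dists.append(np.concatenate([d, d]))

    if rows:
        i = np.concatenate(rows)
        j = np.concatenate(cols)
        d = np.concatenate(dists)
    else:
        i = j = np.empty(0, dtype=np.intp)
        d = np.empty(0)

    if kernel == "uniform":
        w = np.ones_like(d)
    else:
        w = np.exp(-(d**2) / (2.0 * sigma_um**2))

    return NeighborGraph(
        radius_um=radius_um,
        pairs=np.column_stack([i, j]),
        distances=d,
        weights=w,
        n_cells=table.n_obs,
        kernel=kernel,
        sigma_um=sigma_um if kernel == "gaussian" else None,
    )


def _type_counts(labels: np.ndarray, types: list) -> dict:
    vals, counts = np.unique(labels, return_counts=True)
    out = dict.fromkeys(types, 0)
    out.update(zip(vals.tolist(), counts.tolist()))
    return out


def _expected_proportion(n_total: int, n_b: int, same_type: bool) -> float:
    n_b_eff = n_b - 1 if same_type else n_b
    if n_b_eff <= 0:
        raise ValidationError(
            "expected proportion undefined: no candidate target cells "
            f"(N_b={n_b}, self-pair={same_type})"
        )
    return n_b_eff / (n_total - 1)


def local_clq(
    graph: NeighborGraph,
    table: AnnData,
    type_a: str,
    type_b: str,
    type_column: str = "cell_type",
) -> np.ndarray:
    """Per-cell local colocation quotient of ``type_a`` toward ``type_b``.

    Returns an array over all cells: NaN for non-A cells and for A cells
    with an empty neighborhood.
    """
    validate_cell_table(table, require=(type_column,))
    labels = np.asarray(table.obs[type_column]).astype(object)
    n = table.n_obs
    if graph.n_cells != n:
        raise ValidationError("graph and table have different cell counts")
    for t in (type_a, type_b):
        if t not in set(labels):
            raise ValidationError(f"cell type {t!r} absent from {type_column!r}")

    is_a = labels == type_a
    is_b = labels == type_b
    expected = _expected_proportion(n, int(is_b.sum()), type_a == type_b)

    i, j = graph.pairs[:, 0], graph.pairs[:, 1]
    w = graph.weights
    num = np.bincount(i, weights=w * is_b[j], minlength=n)
    den = np.bincount(i, weights=w, minlength=n)

    out = np.full(n, np.nan)
    ok = is_a & (den > 0)
    out[ok] = (num[ok] / den[ok]) / expected
    return out


def global_clq(
    graph: NeighborGraph,
    table: AnnData,
    type_a: str,
    type_b: str,
    type_column: str = "cell_type",
) -> float:
    """Mean of the defined local quotients of A cells toward B."""
    lclq = local_clq(graph, table, type_a, type_b, type_column)
    labels = np.asarray(table.obs[type_column]).astype(object)
    vals = lclq[labels == type_a]
    defined = vals[~np.isnan(vals)]
    n_excluded = int(np.isnan(vals).sum())
    if len(defined) == 0:
        raise ValidationError(
            f"global CLQ {type_a!r}->{type_b!r} undefined: no {type_a!r} cell "
            "has any neighbor at this radius"
        )
    if n_excluded:
        logger.info(
            "global CLQ %s->%s: %d neighborless %s cells excluded",
            type_a, type_b, n_excluded, type_a,
        )
    return float(defined.mean())


def _clq_matrix_from_labels(
    W: sparse.csr_matrix,
    den: np.ndarray,
    labels_idx: np.ndarray,
    n_types: int,
    type_counts: np.ndarray,
) -> np.ndarray:
    """Global CLQ for every ordered type pair, from integer-coded labels.

    Vectorized core shared by the observed statistic and the permutation
    null: per-cell weighted neighbor counts per type come from one sparse
    matmul against the one-hot label matrix.
    """
    n = len(labels_idx)
    onehot = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), labels_idx)), shape=(n, n_types)
    )
    counts = np.asarray(W @ onehot.todense())  # cells x types, weighted
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = counts / den[:, None]  # NaN where den == 0

    clq = np.full((n_types, n_types), np.nan)
    for a in range(n_types):
        rows = prop[labels_idx == a]  # A cells x types
        defined = rows[~np.isnan(rows[:, 0])]
        if len(defined) == 0:
            continue
        mean_prop = defined.mean(axis=0)
        for b in range(n_types):
            n_b_eff = type_counts[b] - (1 if a == b else 0)
            if n_b_eff <= 0:
                continue
            clq[a, b] = mean_prop[b] / (n_b_eff / (n - 1))
    return clq


def clq_significance(
    graph: NeighborGraph,
    table: AnnData,
    pairs: list[tuple[str, str]] | None = None,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    type_column: str = "cell_type",
) -> CLQResult:
    """Permutation test of global CLQ for the requested type pairs.

    Cell-type labels are shuffled jointly across cells (within each image,
    coordinates fixed); one shared permutation serves every pair per
    iteration.  The observed value joins the null, so each p-value is a
    multiple of ``1/(n_perm + 1)`` and the smallest attainable p is
    ``1/(n_perm + 1)``.  A pair is called attractive when
    ``P_attractive < alpha``, avoidant when ``P_avoidant < alpha``, else ns.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    validate_cell_table(table, require=(type_column,))
    labels = np.asarray(table.obs[type_column]).astype(object)
    types = sorted(set(labels.tolist()))
    t_index = {t: k for k, t in enumerate(types)}
    labels_idx = np.array([t_index[t] for t in labels])
    n_types = len(types)
    n = table.n_obs
    counts = np.bincount(labels_idx, minlength=n_types)

    if pairs is None:
        pairs = [(a, b) for a in types for b in types]
    for a, b in pairs:
        if a not in t_index or b not in t_index:
            raise ValidationError(f"pair ({a!r}, {b!r}) references unknown type")

    W = graph.to_sparse()
    den = np.asarray(W.sum(axis=1)).ravel()

    obs = _clq_matrix_from_labels(W, den, labels_idx, n_types, counts)

    rng = np.random.default_rng(seed)
    image_ids = np.asarray(table.obs[IMAGE_ID_KEY])
    image_groups = [np.flatnonzero(image_ids == img) for img in pd.unique(image_ids)]

    ge = np.zeros((n_types, n_types), dtype=int)  # #{perm >= obs}
    le = np.zeros((n_types, n_types), dtype=int)
    null_values = np.empty((n_perm, n_types, n_types))
    for it in range(n_perm):
        perm = labels_idx.copy()
        for idx in image_groups:
            perm[idx] = perm[rng.permutation(idx)]
        null = _clq_matrix_from_labels(W, den, perm, n_types, counts)
        null_values[it] = null
        with np.errstate(invalid="ignore"):
            ge += (null >= obs) & ~np.isnan(null)
            le += (null <= obs) & ~np.isnan(null)

    p_att = (ge + 1) / (n_perm + 1)
    p_avo = (le + 1) / (n_perm + 1)

    glob = pd.DataFrame(obs, index=types, columns=types)
    p_att_df = pd.DataFrame(p_att, index=types, columns=types)
    p_avo_df = pd.DataFrame(p_avo, index=types, columns=types)
    call = pd.DataFrame("ns", index=types, columns=types)
    call = call.where(~(p_att_df < alpha), "attractive")
    call = call.where(~((p_avo_df < alpha) & (call == "ns")), "avoidant")

    wanted = set(pairs)
    for a in types:
        for b in types:
            if (a, b) not in wanted or np.isnan(glob.loc[a, b]):
                p_att_df.loc[a, b] = np.nan
                p_avo_df.loc[a, b] = np.nan
                call.loc[a, b] = "ns" if (a, b) in wanted else ""

    local = {
        (a, b): local_clq(graph, table, a, b, type_column)
        for a, b in pairs
        if not np.isnan(glob.loc[a, b])
    }
    # null distributions: the observed statistic heads each pair's null,
    # giving n_perm + 1 values in total
    null_clq = {
        (a, b): np.concatenate(
            [[glob.loc[a, b]], null_values[:, t_index[a], t_index[b]]]
        )
        for a, b in pairs
        if not np.isnan(glob.loc[a, b])
    }
    return CLQResult(
        global_clq=glob,
        local_clq=local,
        p_attractive=p_att_df,
        p_avoidant=p_avo_df,
        call=call,
        n_permutations=n_perm,
        null_clq=null_clq,
    )


def cooccurrence_permutation(
    table: AnnData,
    radius_um: float = 20.0,
    n_perm: int = 999,
    seed: int = 0,
    type_column: str = "cell_type",
) -> pd.DataFrame:
    """Population-level interaction test over all ordered type pairs.

    The statistic for (A, B) is the mean number of type-B neighbors per
    type-A cell within ``radius_um``.  The null comes from phenotype-
    randomized controls (labels permuted, coordinates fixed, per image);
    two one-sided empirical p-values carry the +1 correction.  Pairs whose
    reference type is absent are skipped with a warning.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    validate_cell_table(table, require=(type_column,))
    graph = build_neighbor_graph(table, radius_um, kernel="uniform")
    labels = np.asarray(table.obs[type_column]).astype(object)
    types = sorted(set(labels.tolist()))
    t_index = {t: k for k, t in enumerate(types)}
    labels_idx = np.array([t_index[t] for t in labels])
    n_types = len(types)
    n = table.n_obs

    A = graph.to_sparse()  # 0/1 adjacency (uniform weights)

    def stat_matrix(lab_idx: np.ndarray) -> np.ndarray:
        onehot = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), lab_idx)), shape=(n, n_types)
        )
        nbr_counts = np.asarray(A @ onehot.todense())  # cells x types
        out = np.full((n_types, n_types), np.nan)
        for a in range(n_types):
            sel = lab_idx == a
            if sel.sum() == 0:
                continue
            out[a] = nbr_counts[sel].mean(axis=0)
        return out

    obs = stat_matrix(labels_idx)

    rng = np.random.default_rng(seed)
    image_ids = np.asarray(table.obs[IMAGE_ID_KEY])
    image_groups = [np.flatnonzero(image_ids == img) for img in pd.unique(image_ids)]
    ge = np.zeros((n_types, n_types), dtype=int)
    le = np.zeros((n_types, n_types), dtype=int)
    for _ in range(n_perm):
        perm = labels_idx.copy()
        for idx in image_groups:
            perm[idx] = perm[rng.permutation(idx)]
        null = stat_matrix(perm)
        ge += null >= obs
        le += null <= obs
    p_att = (ge + 1) / (n_perm + 1)
    p_avo = (le + 1) / (n_perm + 1)

    rows = []
    for a in types:
        if (labels == a).sum() == 0:  # pragma: no cover - defensive
            warnings.warn(f"type {a!r} absent; pair skipped")
            continue
        for b in types:
            ai, bi = t_index[a], t_index[b]
            rows.append(
                {
                    "type_a": a,
                    "type_b": b,
                    "mean_neighbors": obs[ai, bi],
                    "p_attractive": p_att[ai, bi],
                    "p_avoidant": p_avo[ai, bi],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ImmunePhenotypeResult:
    """Per-sample tumor immune phenotype: desert / excluded / inflamed."""

    table: pd.DataFrame  # sample, immune_fraction, clq features, phenotype
    gmm_means: np.ndarray | None  # component means in log-CLQ space
    desert_threshold: float


def classify_immune_phenotype(
    per_sample: pd.DataFrame,
    desert_threshold: float = 0.10,
    seed: int = 0,
) -> ImmunePhenotypeResult:
    """Split samples into immune desert / excluded / inflamed classes.

    ``per_sample`` needs columns ``immune_fraction``, ``clq_immune_tumor``
    and ``clq_tumor_immune``.  Samples at or below the desert threshold on
    immune fraction are called desert outright.  The rest are fit with a
    2-component Gaussian mixture on the log-CLQ pair; the component with the
    greater mean immune->tumor CLQ is labeled inflamed, the other excluded.
    """
    from sklearn.mixture import GaussianMixture

    required = {"immune_fraction", "clq_immune_tumor", "clq_tumor_immune"}
    missing = required - set(per_sample.columns)
    if missing:
        raise ValidationError(f"per-sample table lacks columns {sorted(missing)}")
    df = per_sample.copy()
    df["phenotype"] = ""
    desert = df["immune_fraction"] <= desert_threshold
    df.loc[desert, "phenotype"] = "desert"

    nondesert = df.loc[~desert]
    if len(nondesert) < 4:
        raise ValidationError(
            f"only {len(nondesert)} non-desert samples; >= 4 needed for the "
            "mixture fit — consider manual thresholding"
        )
    feats = np.log(
        nondesert[["clq_immune_tumor", "clq_tumor_immune"]].to_numpy()
    )
    if not np.all(np.isfinite(feats)):
        raise ValidationError("non-positive CLQ value; cannot take logs for the GMM")
    if np.allclose(feats.std(axis=0), 0):
        raise ValidationError(
            "all non-desert samples identical in CLQ space; mixture fit is singular"
        )
    gmm = GaussianMixture(
        n_components=2, n_init=10, random_state=seed, covariance_type="full"
    ).fit(feats)
    comp = gmm.predict(feats)
    inflamed_comp = int(np.argmax(gmm.means_[:, 0]))  # greater immune->tumor CLQ
    calls = np.where(comp == inflamed_comp, "inflamed", "excluded")
    df.loc[~desert, "phenotype"] = calls
    return ImmunePhenotypeResult(
        table=df, gmm_means=gmm.means_, desert_threshold=desert_threshold
    )
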