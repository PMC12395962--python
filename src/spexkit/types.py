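"""Shared data model for spexkit.

The central container for per-cell data is :class:`anndata.AnnData`, used
with a fixed set of conventions (the "cell table"):

* ``X`` — cells x features matrix (marker intensities or transcript counts);
* ``obsm["spatial"]`` — per-cell ``(x, y)`` coordinates in micrometres,
  ``x = column * pixel_size``, ``y = row * pixel_size``, origin at the image
  top-left with y increasing downward;
* ``obs["image_id"]`` — batch provenance; every spatial computation is
  stratified by this column and never crosses images;
* ``obs["cell_type"]`` / ``obs["cluster"]`` / ``obs["niche"]`` — per-cell
  labels written by the analysis stages;
* ``uns`` — parameter records and result tables.

Images and derived spatial structures get small dedicated dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = [
    "MultichannelImage",
    "NeighborGraph",
    "CLQResult",
    "NicheResult",
    "PathwayModel",
    "DEResult",
    "make_cell_table",
    "validate_cell_table",
    "validate_label_mask",
    "SPATIAL_KEY",
    "IMAGE_ID_KEY",
]

SPATIAL_KEY = "spatial"
IMAGE_ID_KEY = "image_id"


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class MultichannelImage:
    """A channel-first intensity stack with named channels.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, height, width)`` with finite,
        non-negative intensities.
    channel_names
        One unique name per channel.
    pixel_size_um
        Physical edge length of one pixel, in micrometres.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"image data must be (channel, row, col); got shape {self.data.shape}"
            )
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("image intensities must be finite")
        if np.any(self.data < 0):
            raise ValidationError("image intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (row, col) shape."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's 2-D intensity array by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]

    def with_data(self, data: np.ndarray) -> "MultichannelImage":
        """Copy carrying new intensities but the same names / pixel size."""
        return MultichannelImage(data, list(self.channel_names), self.pixel_size_um)


def validate_label_mask(labels: np.ndarray) -> np.ndarray:
    """Check a 2-D instance-segmentation mask (0 = background) and return it.

    Label ids are positive integers, not necessarily contiguous.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValidationError(f"label mask must be 2-D; got shape {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValidationError("label mask must have an integer dtype")
    if labels.min() < 0:
        raise ValidationError("label mask must be non-negative (0 = background)")
    return labels


@dataclass
class NeighborGraph:
    """Radius neighborhood structure over one cell table.

    ``pairs`` holds ordered index pairs ``(i, j)``, ``i != j``, with
    Euclidean distance ``d_ij <= radius_um``, restricted to cells sharing an
    ``image_id``.  Weights are 1 for the uniform kernel (a constant cancels
    in the neighborhood proportion) or a Gaussian distance decay
    ``exp(-d^2 / (2 sigma^2))``.
    """

    radius_um: float
    pairs: np.ndarray  # (m, 2) int array of ordered (i, j)
    distances: np.ndarray  # (m,) micrometres
    weights: np.ndarray  # (m,) non-negative
    n_cells: int
    kernel: str = "uniform"
    sigma_um: float | None = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not (len(self.pairs) == len(self.distances) == len(self.weights)):
            raise ValidationError("pairs, distances and weights must align")
        if np.any(self.weights < 0):
            raise ValidationError("weights must be non-negative")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_sparse(self):
        """Weights as a CSR matrix ``W[i, j] = w_ij`` over all cells."""
        from scipy import sparse

        return sparse.csr_matrix(
            (self.weights, (self.pairs[:, 0], self.pairs[:, 1])),
            shape=(self.n_cells, self.n_cells),
        )


@dataclass
class CLQResult:
    """Global and local colocation quotients with permutation significance.

    ``global_clq`` is a types x types DataFrame of CLQ(A -> B); ``local_clq``
    maps ``(A, B)`` pairs to per-cell arrays (NaN outside type-A cells and
    for neighborless A cells).  p-values carry the +1 correction, so each is
    a multiple of ``1 / (n_permutations + 1)``.
    """

    global_clq: pd.DataFrame
    local_clq: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    p_attractive: pd.DataFrame | None = None
    p_avoidant: pd.DataFrame | None = None
    call: pd.DataFrame | None = None
    n_permutations: int = 0
    n_excluded: pd.DataFrame | None = None
    # per-pair null distribution: the observed value followed by the
    # permuted values, so len == n_permutations + 1
    null_clq: dict[tuple[str, str], np.ndarray] | None = None

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (type_a, type_b, clq, p_attractive, p_avoidant, call)."""
        rows = []
        for a in self.global_clq.index:
            for b in self.global_clq.columns:
                row = {
                    "type_a": a,
                    "type_b": b,
                    "clq": self.global_clq.loc[a, b],
                }
                if self.p_attractive is not None:
                    row["p_attractive"] = self.p_attractive.loc[a, b]
                    row["p_avoidant"] = self.p_avoidant.loc[a, b]
                    row["call"] = self.call.loc[a, b]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class NicheResult:
    """Neighborhood cell-type compositions and (optionally) niche labels."""

    composition: pd.DataFrame  # cells x types integer counts, self included
    radius_um: float
    niche: np.ndarray | None = None  # per-cell community label, contiguous from 0
    niche_profiles: pd.DataFrame | None = None  # per-niche mean composition


@dataclass
class PathwayModel:
    """Gene-by-pathway weight matrix for multilinear activity scoring."""

    weights: pd.DataFrame  # genes x pathways

    def __post_init__(self) -> None:
        w = self.weights
        if w.index.duplicated().any():
            raise ValidationError("duplicate gene names in pathway model")
        if w.columns.duplicated().any():
            raise ValidationError("duplicate pathway names in pathway model")
        if (w.to_numpy() != 0).sum(axis=0).min() == 0:
            raise ValidationError("every pathway needs at least one nonzero weight")

    @property
    def gene_names(self) -> list[str]:
        return list(self.weights.index)

    @property
    def pathway_names(self) -> list[str]:
        return list(self.weights.columns)

    @classmethod
    def from_csv(cls, path) -> "PathwayModel":
        """Load weights from CSV with a leading ``gene`` column."""
        df = pd.read_csv(path)
        if df.columns[0].lower() != "gene":
            raise ValidationError(
                "pathway weight CSV must start with a 'gene' column; "
                f"got {df.columns[0]!r}"
            )
        df = df.set_index(df.columns[0])
        return cls(df.astype(float))


@dataclass
class DEResult:
    """Per-gene differential-expression table between two cell groups."""

    table: pd.DataFrame  # gene, statistic, log2fc, pval, pval_adj
    group1: str
    group2: str
    n1: int
    n2: int
    test: str = "ttest"

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


def make_cell_table(
    X: np.ndarray,
    coords: np.ndarray,
    feature_names: list[str] | None = None,
    cell_ids: list[str] | None = None,
    image_id: str | np.ndarray = "image0",
    **obs_columns,
) -> AnnData:
    """Assemble a cell table (AnnData) following the spexkit conventions."""
    X = np.asarray(X)
    coords = np.asarray(coords, dtype=float)
    n = X.shape[0]
    if coords.shape != (n, 2):
        raise ValidationError(f"coords must be ({n}, 2); got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValidationError("coords must be finite")
    if feature_names is None:
        feature_names = [f"feature{i}" for i in range(X.shape[1])]
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n)]
    obs = pd.DataFrame(index=pd.Index([str(c) for c in cell_ids], name="cell_id"))
    obs[IMAGE_ID_KEY] = image_id if not np.isscalar(image_id) else [image_id] * n
    for name, col in obs_columns.items():
        if isinstance(col, (pd.Series, pd.Categorical)):
            obs[name] = (
                col.values if isinstance(col, pd.Series) else col
            )
        else:
            obs[name] = np.asarray(col)
    adata = AnnData(
        X=X.astype(float),
        obs=obs,
        var=pd.DataFrame(index=pd.Index([str(f) for f in feature_names], name="feature")),
    )
    adata.obsm[SPATIAL_KEY] = coords
    return adata


def validate_cell_table(
    adata: AnnData,
    require: tuple[str, ...] = (),
) -> AnnData:
    """Check the cell-table conventions, raising a named error on violation.

    ``require`` lists obs columns (e.g. ``("cell_type",)``) that must exist.
    """
    if SPATIAL_KEY not in adata.obsm:
        raise ValidationError(
            f"cell table lacks obsm[{SPATIAL_KEY!r}] (per-cell x, y in micrometres)"
        )
    coords = np.asarray(adata.obsm[SPATIAL_KEY])
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValidationError(
            f"obsm[{SPATIAL_KEY!r}] must be (n_cells, 2); got {coords.shape}"
        )
    if not np.all(np.isfinite(coords)):
        raise ValidationError("cell coordinates must be finite")
    if IMAGE_ID_KEY not in adata.obs:
        raise ValidationError(f"cell table lacks obs[{IMAGE_ID_KEY!r}]")
    for col in require:
        if col not in adata.obs:
            raise ValidationError(f"cell table lacks required obs column {col!r}")
    # cell ids unique within each image
    dup = adata.obs.reset_index().groupby(IMAGE_ID_KEY, observed=True)[
        adata.obs.index.name or "index"
    ].apply(lambda s: s.duplicated().any())
    if dup.any():
        raise ValidationError("cell ids must be unique within each image_id")
    return adata
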