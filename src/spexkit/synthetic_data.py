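"""Ground-truth generators for every downstream stage.

Three families of synthetic inputs:

* labeled 2-D point patterns with controlled spatial structure (complete
  spatial randomness, parent-offspring attraction, hard-core avoidance, or
  disjoint rectangular blocks) for the spatial statistics;
* multichannel images with Gaussian-profile nuclei at known centers plus a
  ground-truth label mask, for segmentation and feature extraction;
* count / intensity expression matrices with planted clusters, fold
  changes, and pathway activities, for clustering, differential expression
  and pathway scoring.

All generators are deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .types import (
    MultichannelImage,
    PathwayModel,
    ValidationError,
    make_cell_table,
)

__all__ = [
    "PatternSpec",
    "gen_labeled_pattern",
    "gen_synthetic_image",
    "gen_expression",
    "nucleus_kernel",
]

_MAX_REJECTION_ATTEMPTS = 10_000


@dataclass
class PatternSpec:
    """Recipe for a labeled point pattern.

    mode
        ``csr`` — independent uniform positions per type (strength ignored);
        ``attraction`` — type-B offspring placed within
        ``interaction_radius_um`` of type-A parents, Thomas-process style,
        with the attracted fraction growing with ``strength``;
        ``avoidance`` — type-B kept at least ``interaction_radius_um`` away
        from every type-A cell by rejection sampling;
        ``blocks`` — each type confined to its own rectangular region.
    n_cells_per_type
        Exact requested count per type name.
    field_size_um
        (width, height) of the observation window.
    """

    mode: str
    n_cells_per_type: dict[str, int]
    field_size_um: tuple[float, float] = (500.0, 500.0)
    interaction_radius_um: float = 20.0
    strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"csr", "attraction", "avoidance", "blocks"}:
            raise ValidationError(f"unknown pattern mode {self.mode!r}")
        if not self.n_cells_per_type:
            raise ValidationError("n_cells_per_type must be non-empty")
        if any(n <= 0 for n in self.n_cells_per_type.values()):
            raise ValidationError("all per-type counts must be positive")
        w, h = self.field_size_um
        if w <= 0 or h <= 0:
            raise ValidationError("field_size_um must be positive")
        if self.strength < 0:
            raise ValidationError("strength must be >= 0")


def gen_labeled_pattern(spec: PatternSpec) -> AnnData:
    """Draw a labeled point pattern and return it as a cell table.

    The returned AnnData has an empty-feature ``X`` (cells x 0), coordinates
    in ``obsm["spatial"]`` and the type label in ``obs["cell_type"]``.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.field_size_um
    types = list(spec.n_cells_per_type)
    coords_parts: list[np.ndarray] = []
    labels: list[str] = []

    if spec.mode == "csr":
        for t in types:
            n = spec.n_cells_per_type[t]
            coords_parts.append(rng.uniform((0, 0), (w, h), size=(n, 2)))
            labels += [t] * n
    elif spec.mode == "blocks":
        # vertical strips, one per type, separated by an interaction_radius gap
        n_types = len(types)
        gap = spec.interaction_radius_um
        strip = (w - gap * (n_types - 1)) / n_types
        if strip <= 0:
            raise ValidationError("field too narrow for the requested block gap")
        for k, t in enumerate(types):
            n = spec.n_cells_per_type[t]
            x0 = k * (strip + gap)
            xs = rng.uniform(x0, x0 + strip, size=n)
            ys = rng.uniform(0, h, size=n)
            coords_parts.append(np.column_stack([xs, ys]))
            labels += [t] * n
    elif spec.mode == "attraction":
        # first type acts as parents; later types are offspring clustered
        # around them with probability strength / (strength + 1)
        parent_t = types[0]
        n_parent = spec.n_cells_per_type[parent_t]
        parents = rng.uniform((0, 0), (w, h), size=(n_parent, 2))
        coords_parts.append(parents)
        labels += [parent_t] * n_parent
        p_attract = spec.strength / (spec.strength + 1.0)
        for t in types[1:]:
            n = spec.n_cells_per_type[t]
            pts = np.empty((n, 2))
            attracted = rng.random(n) < p_attract
            n_attr = int(attracted.sum())
            if n_attr:
                which = rng.integers(0, n_parent, size=n_attr)
                r = spec.interaction_radius_um * np.sqrt(rng.random(n_attr))
                theta = rng.uniform(0, 2 * np.pi, size=n_attr)
                offs = parents[which] + np.column_stack(
                    [r * np.cos(theta), r * np.sin(theta)]
                )
                pts[attracted] = np.clip(offs, (0, 0), (w, h))
            pts[~attracted] = rng.uniform((0, 0), (w, h), size=(n - n_attr, 2))
            coords_parts.append(pts)
            labels += [t] * n
    else:  # avoidance
        avoid_t = types[0]
        n_avoid = spec.n_cells_per_type[avoid_t]
        anchors = rng.uniform((0, 0), (w, h), size=(n_avoid, 2))
        coords_parts.append(anchors)
        labels += [avoid_t] * n_avoid
        r2 = spec.interaction_radius_um ** 2
        for t in types[1:]:
            n = spec.n_cells_per_type[t]
            pts = np.empty((n, 2))
            for i in range(n):
                for _ in range(_MAX_REJECTION_ATTEMPTS):
                    cand = rng.uniform((0, 0), (w, h))
                    if np.min(np.sum((anchors - cand) ** 2, axis=1)) > r2:
                        pts[i] = cand
                        break
                else:
                    raise ValidationError(
                        f"could not place cell {i} of type {t!r} outside the "
                        f"exclusion radius after {_MAX_REJECTION_ATTEMPTS} attempts"
                    )
            coords_parts.append(pts)
            labels += [t] * n

    coords = np.vstack(coords_parts)
    adata = make_cell_table(
        X=np.empty((len(coords), 0)),
        coords=coords,
        feature_names=[],
        cell_type=pd.Categorical(labels),
    )
    adata.uns["pattern_spec"] = {
        "mode": spec.mode,
        "field_size_um": list(spec.field_size_um),
        "interaction_radius_um": spec.interaction_radius_um,
        "strength": spec.strength,
        "seed": spec.seed,
    }
    return adata


def nucleus_kernel(radius_px: int, sigma_px: float) -> np.ndarray:
    """Gaussian intensity profile of one rendered nucleus.

    Returns a ``(2r+1, 2r+1)`` array of ``exp(-d^2 / (2 sigma^2))`` values,
    zeroed outside the disc of radius ``radius_px``.  The per-cell mean
    intensity that feature extraction recovers equals the marker amplitude
    times the mean of this kernel over its nonzero support.
    """
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = xx**2 + yy**2
    kern = np.exp(-d2 / (2.0 * sigma_px**2))
    kern[d2 > r * r] = 0.0
    return kern


@dataclass
class MarkerSpec:
    """One marker channel: per-cell-type mean amplitude."""

    name: str
    means: dict[str, float] = field(default_factory=dict)
    default: float = 0.0


def gen_synthetic_image(
    n_cells: int,
    channels: list[MarkerSpec] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    nucleus_radius_px: int = 5,
    nucleus_sigma_px: float = 2.5,
    pixel_size_um: float = 1.0,
    cell_types: list[str] | None = None,
) -> tuple[MultichannelImage, np.ndarray, AnnData]:
    """Render nuclei at random non-overlapping centers with known truth.

    Returns ``(image, label_mask, cell_table)``.  Channel 0 is always the
    nuclear channel ("dna", amplitude 100 for every cell); additional marker
    channels express with cell-type-specific amplitudes.  Additive Gaussian
    noise (sd ``noise_sd``) is clipped at zero.  The label mask marks each
    nucleus disc with ids 1..n in placement order.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = shape
    r = nucleus_radius_px
    margin = r + 1
    if h <= 2 * margin or w <= 2 * margin:
        raise ValidationError("image too small for the requested nucleus radius")

    # non-overlapping placement by rejection sampling
    centers = np.empty((n_cells, 2))  # (row, col)
    min_d2 = (2 * r + 2) ** 2
    for i in range(n_cells):
        for _ in range(_MAX_REJECTION_ATTEMPTS):
            cand = rng.uniform((margin, margin), (h - margin, w - margin))
            if i == 0 or np.min(np.sum((centers[:i] - cand) ** 2, axis=1)) > min_d2:
                centers[i] = cand
                break
        else:
            raise ValidationError(
                f"could not place {n_cells} non-overlapping nuclei of radius "
                f"{r}px in a {h}x{w} image"
            )
    centers = np.round(centers).astype(int)

    if cell_types is None:
        type_names = ["A"]
    else:
        type_names = cell_types
    assigned = [type_names[i % len(type_names)] for i in range(n_cells)]

    channels = channels or []
    names = ["dna"] + [c.name for c in channels]
    data = np.zeros((len(names), h, w))
    mask = np.zeros((h, w), dtype=np.int32)
    kern = nucleus_kernel(r, nucleus_sigma_px)
    foot = kern > 0

    for i, (cy, cx) in enumerate(centers):
        sl = (slice(cy - r, cy + r + 1), slice(cx - r, cx + r + 1))
        data[0][sl] += 100.0 * kern
        mask[sl][foot] = i + 1
        for ci, ch in enumerate(channels, start=1):
            amp = ch.means.get(assigned[i], ch.default)
            data[ci][sl] += amp * kern

    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)

    img = MultichannelImage(data, names, pixel_size_um)
    coords = centers[:, ::-1].astype(float) * pixel_size_um  # (x, y)
    table = make_cell_table(
        X=np.empty((n_cells, 0)),
        coords=coords,
        feature_names=[],
        cell_type=pd.Categorical(assigned),
    )
    table.uns["nucleus_radius_px"] = r
    table.uns["nucleus_sigma_px"] = nucleus_sigma_px
    return img, mask, table


def gen_expression(
    n_cells: int,
    n_genes: int,
    cluster_means: np.ndarray | None = None,
    de_spec: list[dict] | None = None,
    pathway_model: PathwayModel | None = None,
    dispersion: float = 0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
    field_size_um: tuple[float, float] = (500.0, 500.0),
) -> AnnData:
    """Expression matrix with planted clusters, fold changes and pathways.

    Without ``pathway_model``, counts are drawn negative-binomial around the
    per-cluster mean vectors (``var = mu + dispersion * mu^2``), cells are
    assigned to clusters in round-robin order, and ``de_spec`` entries of the
    form ``{"gene": name_or_index, "group1": c, "group2": c, "fold": f}``
    multiply the group-1 mean of the named gene by ``f``.

    With ``pathway_model``, expression is continuous:
    ``X = baseline + activities @ W.T + N(0, noise_sd)``, with the per-cell
    true activities recorded in ``obsm["true_activity"]``.

    Cells get uniform random spatial coordinates so the table is a valid
    spexkit cell table.
    """
    rng = np.random.default_rng(seed)

    if pathway_model is not None:
        W = pathway_model.weights.to_numpy()
        genes = pathway_model.gene_names
        if n_genes != len(genes):
            raise ValidationError(
                f"n_genes={n_genes} does not match pathway model ({len(genes)} genes)"
            )
        acts = rng.normal(0.0, 1.0, size=(n_cells, W.shape[1]))
        X = acts @ W.T
        if noise_sd > 0:
            X = X + rng.normal(0.0, noise_sd, size=X.shape)
        coords = rng.uniform((0, 0), field_size_um, size=(n_cells, 2))
        adata = make_cell_table(X, coords, feature_names=genes)
        adata.obsm["true_activity"] = acts
        adata.uns["true_pathways"] = pathway_model.pathway_names
        return adata

    if cluster_means is None:
        cluster_means = np.full((1, n_genes), 5.0)
    cluster_means = np.atleast_2d(np.asarray(cluster_means, dtype=float))
    if cluster_means.shape[1] != n_genes:
        raise ValidationError(
            f"cluster_means has {cluster_means.shape[1]} genes, expected {n_genes}"
        )
    n_clusters = cluster_means.shape[0]
    clusters = np.arange(n_cells) % n_clusters
    gene_names = [f"gene{i}" for i in range(n_genes)]

    mu = cluster_means[clusters].copy()
    for de in de_spec or []:
        g = de["gene"]
        gi = gene_names.index(g) if isinstance(g, str) else int(g)
        fold = float(de["fold"])
        mu[clusters == int(de["group1"]), gi] *= fold

    mu = np.clip(mu, 1e-9, None)
    if dispersion > 0:
        # NB with var = mu + dispersion * mu^2  <=>  shape n = 1/dispersion
        size = 1.0 / dispersion
        p = size / (size + mu)
        X = rng.negative_binomial(size, p).astype(float)
    else:
        X = rng.poisson(mu).astype(float)

    coords = rng.uniform((0, 0), field_size_um, size=(n_cells, 2))
    adata = make_cell_table(X, coords, feature_names=gene_names)
    adata.obs["true_cluster"] = pd.Categorical(clusters.astype(str))
    adata.uns["dispersion"] = dispersion
    return adata
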