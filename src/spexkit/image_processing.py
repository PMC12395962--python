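"""Image preprocessing, watershed segmentation, label repair and
per-cell feature extraction.

The pipeline a multichannel tissue image goes through: optional global
background correction (an Otsu mask of a background channel, scaled by a
user factor, subtracted from the other channels), median or non-local-means
denoising, marker-based watershed segmentation of the nuclear channels,
rule-based morphology filtering, the ``rescue_cells`` repair pass that
re-segments classically with parameters derived from the existing labels,
boundary expansion to capture cytoplasm, and mean-intensity feature
extraction into a cell table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Protocol

import numpy as np
from anndata import AnnData
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import feature, filters, measure, restoration, segmentation
from skimage.transform import rescale as _sk_rescale, resize as _sk_resize

from .types import (
    MultichannelImage,
    ValidationError,
    make_cell_table,
    validate_label_mask,
)

__all__ = [
    "MorphologyFilterSpec",
    "Segmenter",
    "background_correct",
    "median_denoise",
    "nlm_denoise",
    "watershed_segment",
    "filter_labels",
    "rescue_cells",
    "expand_labels",
    "extract_features",
    "rescale_image",
]

logger = logging.getLogger(__name__)


class Segmenter(Protocol):
    """Pluggable segmentation contract: image in, instance label mask out.

    External deep-learning segmenters (StarDist, Cellpose, ...) can be
    wrapped to this signature and dropped into the pipeline in place of
    :func:`watershed_segment`.
    """

    def __call__(self, img: MultichannelImage, nuclear_channels: list[str]) -> np.ndarray: ...


@dataclass
class MorphologyFilterSpec:
    """Area (pixels) and optional solidity gates for segmented labels."""

    min_area_px: int = 0
    max_area_px: int = 2**31
    min_solidity: float | None = None

    def __post_init__(self) -> None:
        if self.min_area_px > self.max_area_px:
            raise ValidationError("min_area_px must not exceed max_area_px")
        if self.min_solidity is not None and not 0 <= self.min_solidity <= 1:
            raise ValidationError("min_solidity must lie in [0, 1]")


def _select_channels(img: MultichannelImage, channels) -> list[int]:
    if channels is None:
        return list(range(img.n_channels))
    idx = []
    for c in channels:
        if c not in img.channel_names:
            raise ValidationError(f"channel {c!r} not in {img.channel_names}")
        idx.append(img.channel_names.index(c))
    return idx


def background_correct(
    img: MultichannelImage, background_channel: str, factor: float = 1.0
) -> MultichannelImage:
    """Subtract an Otsu-masked background channel from all other channels.

    The background channel is binarized by Otsu's threshold (256 bins on
    min-max scaled intensities); the binary mask times ``factor`` is
    subtracted from every other channel and the result clipped at zero.
    The background channel itself passes through unchanged.
    """
    if factor < 0:
        raise ValidationError("factor must be >= 0")
    bg = img.channel(background_channel)
    if bg.max() == bg.min():
        raise ValidationError(
            "background channel is constant; Otsu threshold undefined — "
            "supply a manual threshold instead"
        )
    thresh = filters.threshold_otsu(bg, nbins=256)
    correction = (bg > thresh).astype(float) * factor
    bi = img.channel_names.index(background_channel)
    out = img.data.copy()
    for ci in range(img.n_channels):
        if ci == bi:
            continue
        out[ci] = np.clip(out[ci] - correction, 0.0, None)
    return img.with_data(out)


def median_denoise(
    img: MultichannelImage, kernel_px: int = 3, channels: list[str] | None = None
) -> MultichannelImage:
    """Median filter on the selected channels; others pass through."""
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ValidationError("kernel_px must be an odd integer >= 3")
    footprint = np.ones((kernel_px, kernel_px), dtype=bool)
    out = img.data.copy()
    for ci in _select_channels(img, channels):
        out[ci] = ndi.median_filter(out[ci], footprint=footprint, mode="reflect")
    return img.with_data(out)


def nlm_denoise(
    img: MultichannelImage,
    patch_px: int = 5,
    search_px: int = 11,
    h: float = 0.1,
    channels: list[str] | None = None,
) -> MultichannelImage:
    """Non-local-means denoising on the selected channels.

    Pixel values are replaced by weighted means of similar patches sampled
    within the search window; ``h`` controls the similarity bandwidth
    relative to each channel's intensity range.
    """
    if h <= 0:
        raise ValidationError("h must be positive")
    if search_px < patch_px:
        raise ValidationError("search_px must be >= patch_px")
    out = img.data.copy()
    for ci in _select_channels(img, channels):
        ch = out[ci]
        scale = ch.max() - ch.min()
        if scale == 0:
            continue
        norm = (ch - ch.min()) / scale
        den = restoration.denoise_nl_means(
            norm,
            patch_size=patch_px,
            patch_distance=(search_px - 1) // 2,
            h=h,
            fast_mode=True,
        )
        out[ci] = np.clip(den * scale + ch.min(), 0.0, None)
    return img.with_data(out)


def watershed_segment(
    img: MultichannelImage,
    nuclear_channels: list[str],
    min_distance_px: int = 5,
    threshold: float | str = "otsu",
) -> np.ndarray:
    """Marker-based watershed nuclei segmentation.

    Nuclear channels are summed, the foreground binarized (Otsu or a fixed
    value), the Euclidean distance transform computed, seeds placed at
    local maxima separated by at least ``min_distance_px``, and the
    watershed run on the negated distance map restricted to the foreground.
    Returns an int32 label mask with ids 1..K (0 = background).
    """
    idx = _select_channels(img, nuclear_channels)
    nuc = img.data[idx].sum(axis=0)
    if threshold == "otsu":
        if nuc.max() == nuc.min():
            warnings.warn("nuclear image is constant; returning an empty mask")
            return np.zeros(img.shape, dtype=np.int32)
        thr = filters.threshold_otsu(nuc, nbins=256)
    else:
        thr = float(threshold)
    fg = nuc > thr
    if not fg.any():
        warnings.warn("empty foreground after thresholding; returning an empty mask")
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    peaks = feature.peak_local_max(
        dist, min_distance=max(1, int(min_distance_px)), labels=fg,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    if markers.max() == 0:  # pragma: no cover - peak_local_max on nonempty fg
        markers, _ = ndi.label(fg)
    labels = segmentation.watershed(-dist, markers, mask=fg)
    return labels.astype(np.int32)


def filter_labels(mask: np.ndarray, spec: MorphologyFilterSpec) -> np.ndarray:
    """Zero out labels failing the area / solidity rules; survivors keep ids."""
    mask = validate_label_mask(mask)
    out = mask.copy()
    for region in measure.regionprops(mask):
        ok = spec.min_area_px <= region.area <= spec.max_area_px
        if ok and spec.min_solidity is not None:
            ok = region.solidity >= spec.min_solidity
        if not ok:
            out[mask == region.label] = 0
    return out


def rescue_cells(
    mask: np.ndarray,
    img: MultichannelImage,
    nuclear_channels: list[str],
    overlap_max: float = 0.0,
    area_window: tuple[float, float] = (0.25, 4.0),
) -> np.ndarray:
    """Recover cells a primary segmenter missed, without touching its labels.

    Prototypical cell size (median label area) and intensity (median of
    per-label mean nuclear intensity) are derived from the current mask.
    A classical watershed pass is parameterized from them — foreground
    threshold at half the prototypical intensity, seed separation at half
    the prototype's equivalent diameter — and candidate labels whose pixel
    overlap with existing labels is at most ``overlap_max`` (as a fraction
    of the candidate's area) and whose area falls within ``area_window``
    times the prototype are merged in under fresh ids.
    """
    mask = validate_label_mask(mask)
    if mask.max() == 0:
        raise ValidationError("rescue_cells needs >= 1 existing label to derive a prototype")
    if not 0 <= overlap_max <= 1:
        raise ValidationError("overlap_max must lie in [0, 1]")

    idx = _select_channels(img, nuclear_channels)
    nuc = img.data[idx].sum(axis=0)

    regions = measure.regionprops(mask, intensity_image=nuc)
    proto_area = float(np.median([r.area for r in regions]))
    proto_intensity = float(np.median([r.intensity_mean for r in regions]))
    equiv_diam = float(np.sqrt(4.0 * proto_area / np.pi))

    candidates = watershed_segment(
        img,
        nuclear_channels,
        min_distance_px=max(1, int(round(0.5 * equiv_diam))),
        threshold=0.5 * proto_intensity,
    )

    out = mask.copy()
    next_id = int(mask.max()) + 1
    existing = mask > 0
    lo, hi = area_window
    for region in measure.regionprops(candidates):
        sel = candidates == region.label
        overlap = (sel & existing).sum() / region.area
        if overlap > overlap_max:
            continue
        if not lo * proto_area <= region.area <= hi * proto_area:
            continue
        out[sel & ~existing] = next_id
        next_id += 1
    return out


def expand_labels(mask: np.ndarray, distance_px: int) -> np.ndarray:
    """Grow each label into the background by up to ``distance_px`` pixels.

    Contested background pixels go to the Euclidean-nearest label; exact
    distance ties go to the lower label id.  Existing labels are never
    overwritten.  Monotone in distance: the expansion at ``d`` is a subset
    of the expansion at ``d + 1``.
    """
    mask = validate_label_mask(mask)
    if distance_px < 0:
        raise ValidationError("distance_px must be >= 0")
    if distance_px == 0 or mask.max() == 0:
        return mask.copy()

    dist, (ir, ic) = ndi.distance_transform_edt(mask == 0, return_indices=True)
    out = mask.copy()
    grow = (mask == 0) & (dist <= distance_px)
    out[grow] = mask[ir[grow], ic[grow]]

    # enforce the lower-id tie rule on exactly equidistant pixels
    pts = np.column_stack(np.nonzero(mask))
    tree = cKDTree(pts)
    labels_at = mask[pts[:, 0], pts[:, 1]]
    rows, cols = np.nonzero(grow)
    d_star = dist[rows, cols]
    for r, c, d in zip(rows, cols, d_star):
        nbrs = tree.query_ball_point((r, c), d * (1 + 1e-12) + 1e-9)
        cand = labels_at[nbrs]
        dd = np.sum((pts[nbrs] - (r, c)) ** 2, axis=1)
        at_min = cand[np.isclose(dd, dd.min())]
        out[r, c] = at_min.min()
    return out


def extract_features(
    mask: np.ndarray, img: MultichannelImage, statistic: str = "mean"
) -> AnnData:
    """Per-cell channel intensities, centroid coordinates, and area.

    One row per label; ``X`` holds the per-channel ``statistic`` ("mean",
    the default, or "median") over the label's pixels, coordinates are the
    intensity-unweighted centroid in micrometres
    ((x, y) = (col, row) * pixel_size), and ``obs["area_px"]`` the pixel
    count.
    """
    if statistic not in {"mean", "median"}:
        raise ValidationError(f"unknown statistic {statistic!r}")
    mask = validate_label_mask(mask)
    if mask.shape != img.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match image shape {img.shape}"
        )
    label_ids = np.unique(mask)
    label_ids = label_ids[label_ids > 0]
    n = len(label_ids)
    X = np.zeros((n, img.n_channels))
    coords = np.zeros((n, 2))
    areas = np.zeros(n, dtype=int)
    if n:
        agg = ndi.mean if statistic == "mean" else ndi.median
        for ci in range(img.n_channels):
            X[:, ci] = agg(img.data[ci], labels=mask, index=label_ids)
        centroids = ndi.center_of_mass(np.ones_like(mask), labels=mask, index=label_ids)
        centroids = np.asarray(centroids)  # (row, col)
        coords = centroids[:, ::-1] * img.pixel_size_um  # (x, y)
        areas = ndi.sum_labels(np.ones_like(mask), labels=mask, index=label_ids).astype(int)
    table = make_cell_table(
        X=X,
        coords=coords.reshape(n, 2),
        feature_names=img.channel_names,
        cell_ids=[f"cell{lid}" for lid in label_ids],
        area_px=areas,
        label=label_ids,
    )
    table.uns["pixel_size_um"] = img.pixel_size_um
    return table


def rescale_image(
    img: MultichannelImage, factor: float
) -> MultichannelImage:
    """Bilinear up/down-sampling for resolution matching."""
    if factor <= 0:
        raise ValidationError("scale factor must be positive")
    out = np.stack(
        [
            _sk_rescale(ch, factor, order=1, preserve_range=True, anti_aliasing=factor < 1)
            for ch in img.data
        ]
    )
    return MultichannelImage(
        np.clip(out, 0.0, None),
        list(img.channel_names),
        img.pixel_size_um / factor,
    )


def rescale_labels(mask: np.ndarray, factor: float) -> np.ndarray:
    """Nearest-neighbor rescaling for label images."""
    mask = validate_label_mask(mask)
    if factor <= 0:
        raise ValidationError("scale factor must be positive")
    new_shape = tuple(max(1, int(round(s * factor))) for s in mask.shape)
    return _sk_resize(
        mask, new_shape, order=0, preserve_range=True, anti_aliasing=False
    ).astype(mask.dtype)
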