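"""Readers and writers for the standard on-disk formats.

Images come in as OME-TIFF or OME-ZARR (channel names and pixel size taken
from metadata when present, with documented fallbacks); cell tables round-
trip through H5AD or AnnData ZARR and export to flat CSV.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from xml.etree import ElementTree

import anndata as ad
import numpy as np
import pandas as pd
from anndata import AnnData

from .types import (
    IMAGE_ID_KEY,
    MultichannelImage,
    SPATIAL_KEY,
    ValidationError,
    validate_cell_table,
)

__all__ = [
    "read_image",
    "write_image",
    "read_cell_table",
    "write_cell_table",
    "FormatError",
]

logger = logging.getLogger(__name__)


class FormatError(IOError):
    """Raised when a file cannot be parsed as the expected format."""


def _parse_ome_xml(xml: str) -> tuple[list[str] | None, float | None]:
    """Channel names and pixel size (um) from an OME-XML header."""
    try:
        root = ElementTree.fromstring(xml)
    except ElementTree.ParseError:
        return None, None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    prefix = "ome:" if ns else ""
    names: list[str] | None = None
    pixel_size = None
    pixels = root.find(f".//{prefix}Pixels", ns)
    if pixels is not None:
        ch_names = [
            c.get("Name") for c in pixels.findall(f"{prefix}Channel", ns)
        ]
        if ch_names and all(n is not None for n in ch_names):
            names = [str(n) for n in ch_names]
        psx = pixels.get("PhysicalSizeX")
        if psx is not None:
            pixel_size = float(psx)
    return names, pixel_size


def _read_ome_tiff(path: Path) -> MultichannelImage:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            ome_xml = tif.ome_metadata
    except Exception as exc:
        raise FormatError(f"cannot read {path} as OME-TIFF: {exc}") from exc
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a (channel, row, col) stack; got shape {data.shape}"
        )
    if data.shape[0] == 0:
        raise ValidationError(f"{path}: image has zero channels")
    names = pixel_size = None
    if ome_xml:
        names, pixel_size = _parse_ome_xml(ome_xml)
    if names is None or len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    if pixel_size is None:
        warnings.warn(f"{path}: no pixel-size metadata; assuming 1.0 um/px")
        pixel_size = 1.0
    return MultichannelImage(np.clip(data, 0.0, None), names, pixel_size)


def _read_ome_zarr(path: Path) -> MultichannelImage:
    import zarr

    try:
        group = zarr.open_group(str(path), mode="r")
        arr = np.asarray(group["0"][:], dtype=float)
        attrs = dict(group.attrs)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as OME-ZARR: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected (channel, row, col); got {arr.shape}")
    names = None
    channels = attrs.get("omero", {}).get("channels")
    if channels:
        labels = [c.get("label") for c in channels]
        if all(l is not None for l in labels) and len(labels) == arr.shape[0]:
            names = [str(l) for l in labels]
    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    pixel_size = None
    multiscales = attrs.get("multiscales")
    if multiscales:
        try:
            transforms = multiscales[0]["datasets"][0]["coordinateTransformations"]
            scale = next(t["scale"] for t in transforms if t["type"] == "scale")
            pixel_size = float(scale[-1])
        except (KeyError, IndexError, StopIteration):
            pixel_size = None
    if pixel_size is None:
        warnings.warn(f"{path}: no pixel-size metadata; assuming 1.0 um/px")
        pixel_size = 1.0
    return MultichannelImage(np.clip(arr, 0.0, None), names, pixel_size)


def read_image(path) -> MultichannelImage:
    """Read an OME-TIFF file or OME-ZARR store as a multichannel image.

    Channel names fall back to ``ch0..chN-1`` and pixel size to 1.0 um/px
    (with a warning) when the metadata is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.is_dir():
        return _read_ome_zarr(path)
    return _read_ome_tiff(path)


def write_image(img: MultichannelImage, path) -> Path:
    """Write an image as OME-TIFF (.tif/.tiff path) or OME-ZARR (directory)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(
            path,
            img.data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "CYX",
                "Channel": {"Name": img.channel_names},
                "PhysicalSizeX": img.pixel_size_um,
                "PhysicalSizeY": img.pixel_size_um,
            },
        )
    else:
        import zarr

        group = zarr.open_group(str(path), mode="w")
        group.create_array("0", data=img.data.astype(np.float32))
        group.attrs["omero"] = {
            "channels": [{"label": n} for n in img.channel_names]
        }
        group.attrs["multiscales"] = [
            {
                "datasets": [
                    {
                        "path": "0",
                        "coordinateTransformations": [
                            {
                                "type": "scale",
                                "scale": [1.0, img.pixel_size_um, img.pixel_size_um],
                            }
                        ],
                    }
                ]
            }
        ]
    return path


def read_cell_table(path) -> AnnData:
    """Read a cell table from H5AD or AnnData ZARR and validate conventions.

    A table missing spatial coordinates (or, for legacy files, carrying
    them as obs columns ``x``/``y``) is repaired when possible and rejected
    with a named error otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if path.is_dir():
            adata = ad.read_zarr(path)
        else:
            adata = ad.read_h5ad(path)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as a cell table: {exc}") from exc
    if SPATIAL_KEY not in adata.obsm:
        if {"x", "y"} <= set(adata.obs.columns):
            adata.obsm[SPATIAL_KEY] = adata.obs[["x", "y"]].to_numpy(dtype=float)
        else:
            raise ValidationError(
                f"{path}: cell table has neither obsm[{SPATIAL_KEY!r}] nor "
                "obs columns 'x' and 'y' (per-cell coordinates in micrometres)"
            )
    if IMAGE_ID_KEY not in adata.obs:
        adata.obs[IMAGE_ID_KEY] = "image0"
    return validate_cell_table(adata)


def write_cell_table(table: AnnData, path, format: str | None = None) -> Path:
    """Write a cell table as H5AD, AnnData ZARR, or flat CSV.

    The format is inferred from the path suffix when not given.  H5AD and
    ZARR round-trip ``X``, coordinates and annotations exactly; CSV is a
    flattened per-cell export (obs columns, x, y, then features).
    """
    path = Path(path)
    if format is None:
        format = {
            ".h5ad": "h5ad",
            ".zarr": "zarr",
            ".csv": "csv",
        }.get(path.suffix.lower())
        if format is None:
            raise ValidationError(
                f"cannot infer format from {path.suffix!r}; pass format="
            )
    validate_cell_table(table)
    if format == "h5ad":
        table.write_h5ad(path)
    elif format == "zarr":
        table.write_zarr(path)
    elif format == "csv":
        coords = np.asarray(table.obsm[SPATIAL_KEY])
        df = table.obs.copy()
        df["x"], df["y"] = coords[:, 0], coords[:, 1]
        feats = pd.DataFrame(
            np.asarray(table.X), index=table.obs_names, columns=table.var_names
        )
        pd.concat([df, feats], axis=1).to_csv(path, index_label="cell_id")
    else:
        raise ValidationError(f"unknown cell-table format {format!r}")
    return path
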