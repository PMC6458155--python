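"""TIFF and table I/O helpers.

Images travel as multi-page TIFF, either channel-interleaved in one file
or as one file per channel; intensities are stored as float32 by default
and quantized to 16-bit only on request.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .core import InvalidParameterError, MultichannelImage

__all__ = ["save_image", "load_image", "save_channels", "load_channels"]


def _export_array(data: np.ndarray, dtype: str) -> np.ndarray:
    if dtype == "float32":
        return data.astype(np.float32)
    if dtype == "uint16":
        peak = data.max()
        scale = 65535.0 / peak if peak > 0 else 1.0
        return np.clip(np.rint(data * scale), 0, 65535).astype(np.uint16)
    raise InvalidParameterError("dtype must be 'float32' or 'uint16'")


def save_image(
    image: MultichannelImage, path: str | Path, dtype: str = "float32"
) -> None:
    """Write a channel-interleaved TIFF (axes CYX or CZYX)."""
    axes = "CZYX" if image.is_3d else "CYX"
    tifffile.imwrite(
        str(path),
        _export_array(image.data, dtype),
        photometric="minisblack",
        metadata={"axes": axes, "voxel_size_um": list(image.voxel_size_um)},
    )


def load_image(
    path: str | Path, voxel_size_um: Sequence[float] | None = None
) -> MultichannelImage:
    """Read a channel-interleaved TIFF written by :func:`save_image`."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if voxel_size_um is None:
        voxel_size_um = meta.get("voxel_size_um", (1.0,) * (data.ndim - 1))
    return MultichannelImage(np.asarray(data, dtype=float), tuple(voxel_size_um))


def save_channels(
    image: MultichannelImage, directory: str | Path, stem: str, dtype: str = "float32"
) -> list[Path]:
    """Write one TIFF per channel (``<stem>_<channel>.tif``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, plane in zip(image.channel_names, image.data):
        p = directory / f"{stem}_{name}.tif"
        tifffile.imwrite(str(p), _export_array(plane, dtype))
        paths.append(p)
    return paths


def load_channels(
    paths: Sequence[str | Path],
    channel_names: Sequence[str] = ("R", "G", "B"),
    voxel_size_um: Sequence[float] | None = None,
) -> MultichannelImage:
    """Assemble a multichannel image from per-channel TIFF files."""
    planes = [tifffile.imread(str(p)) for p in paths]
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise InvalidParameterError("channel files have mismatched shapes")
    data = np.stack([np.asarray(p, dtype=float) for p in planes])
    if voxel_size_um is None:
        voxel_size_um = (1.0,) * (data.ndim - 1)
    return MultichannelImage(data, tuple(voxel_size_um), tuple(channel_names))
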