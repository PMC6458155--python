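"""Core containers shared across the toolkit.

Images are stored channel-first (``(C, Y, X)`` for planar data,
``(C, Z, Y, X)`` for volumetric data) as non-negative floating-point
intensities.  Quantization to integer bit depths happens only at TIFF
export, never inside the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

import numpy as np

DEFAULT_CHANNELS: Tuple[str, ...] = ("R", "G", "B")


class InvalidParameterError(ValueError):
    """Raised when an operation receives parameters outside its domain."""


@dataclass
class MultichannelImage:
    """A 2D or 3D multichannel intensity image with physical voxel size.

    Parameters
    ----------
    data : ndarray
        Channel-first array, ``(C, Y, X)`` or ``(C, Z, Y, X)``.
    voxel_size_um : tuple of float
        Physical size of one voxel in micrometres, ordered to match the
        spatial axes of ``data`` (``(dy, dx)`` or ``(dz, dy, dx)``).
    channel_names : tuple of str
        Channel labels, ``("R", "G", "B")`` by default.
    """

    data: np.ndarray
    voxel_size_um: Tuple[float, ...] = (1.0, 1.0)
    channel_names: Tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise InvalidParameterError(
                f"expected (C, Y, X) or (C, Z, Y, X) data, got shape {self.data.shape}"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != self.data.ndim - 1:
            raise InvalidParameterError(
                "voxel_size_um must have one entry per spatial axis"
            )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise InvalidParameterError(
                "channel_names length must match the channel axis"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> Tuple[int, ...]:
        return self.data.shape[1:]

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 4

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel's spatial array (a view, not a copy)."""
        if isinstance(name_or_index, str):
            name_or_index = self.channel_names.index(name_or_index)
        return self.data[name_or_index]

    def with_data(self, data: np.ndarray) -> "MultichannelImage":
        """New image sharing metadata but holding different pixel data."""
        return replace(self, data=np.asarray(data, dtype=float))

    def as_rgb(self, gain: float | Sequence[float] = 1.0) -> np.ndarray:
        """Channel-last float RGB rendering clipped to [0, 1].

        ``gain`` scales channels for display only; stored data is untouched.
        """
        g = np.broadcast_to(np.asarray(gain, dtype=float), (self.n_channels,))
        scaled = self.data * g[(slice(None),) + (None,) * (self.data.ndim - 1)]
        return np.clip(np.moveaxis(scaled, 0, -1), 0.0, 1.0)


def as_multichannel(image: "MultichannelImage | np.ndarray") -> MultichannelImage:
    if isinstance(image, MultichannelImage):
        return image
    arr = np.asarray(image, dtype=float)
    return MultichannelImage(arr, voxel_size_um=(1.0,) * (arr.ndim - 1))
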