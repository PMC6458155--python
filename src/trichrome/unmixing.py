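"""Trichromatic linear unmixing and colorimetric coordinates.

Spectral bleed-through between the red, green and blue detection channels
is modelled as a unit-diagonal linear system mapping the corrected (true)
channel intensities to the raw (measured) ones::

    R_raw = R_corr + a_GR * G_corr + a_BR * B_corr
    G_raw = a_RG * R_corr + G_corr + a_BG * B_corr
    B_raw = a_RB * R_corr + a_GB * G_corr + B_corr

The six off-diagonal coefficients ``a_XY`` quantify the leak of channel X
into channel Y.  Unmixing inverts this 3x3 system per pixel.  The
coefficients are estimated from reference regions of interest (ROIs):
either the ROIs of maximal per-channel intensity, or the barycentres of
per-population ROI clouds, are taken as anchors and projected onto the
pure corners of the ternary colour diagram; the matrix follows by
normalising each anchor and rescaling its diagonal entry to one.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from matplotlib.colors import rgb_to_hsv
from scipy.cluster.hierarchy import fcluster, linkage

from .core import InvalidParameterError, MultichannelImage, as_multichannel

__all__ = [
    "MixingModel",
    "RoiColorSample",
    "sample_rois",
    "estimate_mixing_model",
    "unmix",
    "forward_mix",
    "to_ternary",
    "hue_saturation",
    "count_resolvable_colors",
]

_COEF_NAMES = ("a_GR", "a_BR", "a_RG", "a_BG", "a_RB", "a_GB")


class SingularModelError(InvalidParameterError):
    """The mixing matrix (or anchor system) is not invertible."""


@dataclass(frozen=True)
class MixingModel:
    """Unit-diagonal 3x3 bleed-through model, corrected -> raw.

    ``a_XY`` is the fraction of channel X's corrected intensity that leaks
    into raw channel Y.  ``literal_green_equation`` selects a variant in
    which the green channel's third term multiplies G rather than B (the
    row becomes ``[a_RG, 1 + a_BG, 0]``); the default treats the B->G leak
    as a standard off-diagonal term.
    """

    a_GR: float = 0.0
    a_BR: float = 0.0
    a_RG: float = 0.0
    a_BG: float = 0.0
    a_RB: float = 0.0
    a_GB: float = 0.0
    literal_green_equation: bool = False

    @property
    def matrix(self) -> np.ndarray:
        if self.literal_green_equation:
            green_row = [self.a_RG, 1.0 + self.a_BG, 0.0]
        else:
            green_row = [self.a_RG, 1.0, self.a_BG]
        return np.array(
            [
                [1.0, self.a_GR, self.a_BR],
                green_row,
                [self.a_RB, self.a_GB, 1.0],
            ]
        )

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def require_invertible(self, cond_max: float = 1e12) -> None:
        if not np.isfinite(self.condition_number) or self.condition_number > cond_max:
            raise SingularModelError(
                f"mixing matrix is singular or ill-conditioned (cond={self.condition_number:.3g})"
            )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "MixingModel":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise InvalidParameterError("mixing matrix must be 3x3")
        if not np.allclose(np.diag(m), 1.0):
            raise InvalidParameterError("mixing matrix must have a unit diagonal")
        return cls(
            a_GR=m[0, 1], a_BR=m[0, 2],
            a_RG=m[1, 0], a_BG=m[1, 2],
            a_RB=m[2, 0], a_GB=m[2, 1],
        )

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in _COEF_NAMES}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MixingModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class RoiColorSample:
    """Mean (r, g, b) intensity of one region of interest."""

    mean_rgb: tuple
    region_id: int | str = 0
    population: str | None = None  # "R" | "G" | "B" in barycentre mode

    def __post_init__(self):
        rgb = tuple(float(v) for v in self.mean_rgb)
        if len(rgb) != 3 or any(v < 0 for v in rgb):
            raise InvalidParameterError("ROI mean must be a non-negative RGB triple")
        object.__setattr__(self, "mean_rgb", rgb)


def sample_rois(
    image: MultichannelImage | np.ndarray,
    rois: Sequence[np.ndarray],
    populations: Sequence[str] | None = None,
) -> list[RoiColorSample]:
    """Per-ROI channel means.

    ``rois`` are boolean masks over the spatial axes or integer index
    arrays of shape ``(n, ndim_spatial)``.
    """
    img = as_multichannel(image)
    if len(rois) == 0:
        raise InvalidParameterError("at least one ROI is required")
    samples = []
    for i, roi in enumerate(rois):
        roi = np.asarray(roi)
        if roi.dtype == bool:
            if roi.shape != img.spatial_shape:
                raise InvalidParameterError("boolean ROI shape must match the image")
            if not roi.any():
                raise InvalidParameterError(f"ROI {i} is empty")
            values = img.data[:, roi]
        else:
            if roi.size == 0:
                raise InvalidParameterError(f"ROI {i} is empty")
            idx = tuple(roi.T)
            values = img.data[(slice(None),) + idx]
        pop = populations[i] if populations is not None else None
        samples.append(
            RoiColorSample(tuple(values.mean(axis=1)), region_id=i, population=pop)
        )
    return samples


def _anchors_from_samples(
    samples: Sequence[RoiColorSample],
    mode: Literal["max_roi", "barycentre"],
) -> np.ndarray:
    """Return a 3x3 array whose columns are the R, G, B anchors."""
    arr = np.array([s.mean_rgb for s in samples], dtype=float)
    if mode == "max_roi":
        if len(samples) < 3:
            raise InvalidParameterError("max_roi mode needs at least 3 samples")
        cols = [arr[np.argmax(arr[:, c])] for c in range(3)]
    elif mode == "barycentre":
        cols = []
        for pop in ("R", "G", "B"):
            members = arr[[s.population == pop for s in samples]]
            if members.size == 0:
                raise InvalidParameterError(
                    f"barycentre mode needs samples assigned to population {pop!r}"
                )
            cols.append(members.mean(axis=0))
    else:
        raise InvalidParameterError(f"unknown estimation mode {mode!r}")
    return np.stack(cols, axis=1)


def estimate_mixing_model(
    samples: Sequence[RoiColorSample],
    mode: Literal["max_roi", "barycentre"] = "max_roi",
) -> MixingModel:
    """Estimate the bleed-through model from reference ROI samples.

    The three anchors (max-intensity ROI per channel, or per-population
    barycentres) are normalised to unit sum — i.e. projected to the
    ternary diagram, so estimation is exposure-invariant — and each is
    identified with a pure colour corner.  Dividing each anchor by its
    diagonal entry yields the unit-diagonal mixing matrix directly.
    """
    anchors = _anchors_from_samples(samples, mode)
    sums = anchors.sum(axis=0)
    if np.any(sums <= 0):
        raise SingularModelError("an anchor has zero total intensity")
    anchors = anchors / sums
    diag = np.diag(anchors)
    if np.any(diag <= 0):
        raise SingularModelError("anchor system is degenerate (zero diagonal)")
    m = anchors / diag  # rescale each column so its own-channel entry is 1
    if abs(np.linalg.det(m)) < 1e-12:
        raise SingularModelError("anchors are coplanar; cannot invert the system")
    return MixingModel.from_matrix(m)


def forward_mix(
    image: MultichannelImage | np.ndarray, model: MixingModel
) -> MultichannelImage:
    """Apply the mixing model in the forward (corrected -> raw) direction."""
    img = as_multichannel(image)
    model.require_invertible()
    raw = np.tensordot(model.matrix, img.data, axes=(1, 0))
    return img.with_data(raw)


def unmix(
    raw: MultichannelImage | np.ndarray,
    model: MixingModel,
    negatives: Literal["clip", "keep"] = "clip",
) -> MultichannelImage:
    """Invert the bleed-through model per pixel (raw -> corrected).

    Negative solutions — which arise from noise — are clipped to zero by
    default; pass ``negatives="keep"`` to preserve linearity exactly.
    """
    img = as_multichannel(raw)
    model.require_invertible()
    inv = np.linalg.inv(model.matrix)
    corrected = np.tensordot(inv, img.data, axes=(1, 0))
    if negatives == "clip":
        corrected = np.clip(corrected, 0.0, None)
    elif negatives != "keep":
        raise InvalidParameterError("negatives must be 'clip' or 'keep'")
    return img.with_data(corrected)


def to_ternary(pixels: np.ndarray) -> np.ndarray:
    """Ternary colour coordinates (f_R, f_G, f_B): channels over their sum.

    Accepts any ``(..., 3)`` array.  Zero-sum pixels have no defined
    colour and are returned as NaN so callers can exclude them.
    """
    rgb = np.asarray(pixels, dtype=float)
    if rgb.shape[-1] != 3:
        raise InvalidParameterError("expected trailing axis of length 3")
    total = rgb.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, rgb / total, np.nan)
    return frac


def hue_saturation(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hue (degrees, [0, 360)) and saturation ([0, 1]) of RGB pixels.

    Standard HSV conversion; gray pixels (r = g = b) have saturation 0 and
    hue reported as NaN (undefined).
    """
    rgb = np.asarray(pixels, dtype=float)
    if rgb.shape[-1] != 3:
        raise InvalidParameterError("expected trailing axis of length 3")
    peak = rgb.max(axis=-1, keepdims=True)
    scaled = np.where(peak > 0, rgb / np.where(peak > 0, peak, 1.0), 0.0)
    hsv = rgb_to_hsv(np.clip(scaled, 0.0, 1.0))
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    hue = np.where(sat > 0, hue, np.nan)
    return hue, sat


def count_resolvable_colors(
    samples: np.ndarray, cluster_radius: float
) -> int:
    """Number of distinct colour modes among ternary samples.

    Radius-based agglomeration: single-linkage clustering cut at
    ``cluster_radius`` (Euclidean distance in the ternary plane).  Two
    samples belong to one mode if a chain of steps each shorter than the
    radius connects them.
    """
    pts = np.asarray(samples, dtype=float)
    pts = pts[~np.isnan(pts).any(axis=1)]
    if pts.shape[0] == 0:
        raise InvalidParameterError("no valid samples")
    if pts.shape[0] == 1:
        return 1
    z = linkage(pts, method="single")
    labels = fcluster(z, t=cluster_radius, criterion="distance")
    return int(labels.max())
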