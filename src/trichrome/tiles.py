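"""Tile preprocessing and translation-only mosaic assembly.

Serial two-photon mosaics are acquired as overlapping tiles whose edges
carry scanning artifacts and whose illumination falls off towards the
borders of the field of view.  The pipeline is: crop the tile margins,
estimate a per-channel illumination profile by averaging many tiles and
blurring with a large Gaussian kernel, divide tiles by the normalised
profile (flat-field correction), refine tile placement by normalised
cross-correlation around the nominal grid offsets, and paste the tiles
onto a common canvas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter

from .core import InvalidParameterError

__all__ = [
    "Tile",
    "IlluminationProfile",
    "RegistrationFailure",
    "crop_edges",
    "estimate_illumination_profile",
    "flatfield_correct",
    "register_tile_pair",
    "assemble_mosaic",
    "stitch_grid",
]


@dataclass
class Tile:
    """One mosaic tile: channel-first pixels plus its grid bookkeeping."""

    pixels: np.ndarray  # (C, Y, X) or (C, Z, Y, X)
    grid_index: tuple = (0, 0)
    nominal_offset_px: tuple = (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (3, 4):
            raise InvalidParameterError("tile pixels must be (C, Y, X) or (C, Z, Y, X)")
        self.grid_index = tuple(int(i) for i in self.grid_index)
        self.nominal_offset_px = tuple(int(o) for o in self.nominal_offset_px)

    @property
    def spatial_shape(self) -> tuple:
        return self.pixels.shape[1:]


@dataclass
class IlluminationProfile:
    """Per-channel smooth illumination field, normalised to a maximum of 1."""

    field: np.ndarray  # (C, Y, X)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        if np.any(self.field <= 0):
            raise InvalidParameterError("illumination profile must be strictly positive")


class RegistrationFailure(RuntimeError):
    """Cross-correlation found no usable overlap; caller should fall back."""


def crop_edges(tile: Tile, margin_px: int) -> Tile:
    """Remove ``margin_px`` pixels from every lateral edge of every channel."""
    if margin_px < 0:
        raise InvalidParameterError("margin must be non-negative")
    if margin_px == 0:
        return replace(tile, pixels=tile.pixels.copy())
    lat = tile.pixels.shape[-2:]
    if any(2 * margin_px >= s for s in lat):
        raise InvalidParameterError(
            f"margin {margin_px} too large for lateral shape {lat}"
        )
    sl = (Ellipsis, slice(margin_px, -margin_px), slice(margin_px, -margin_px))
    return replace(tile, pixels=tile.pixels[sl].copy())


def estimate_illumination_profile(
    tiles: Sequence[Tile], blur_sigma_px: float | None = None
) -> IlluminationProfile:
    """Average all tiles per channel, blur heavily, normalise to max 1.

    The blur sigma defaults to one eighth of the tile width: large with
    respect to labelled structures, small with respect to the vignetting
    scale, so structure averages out while the illumination field remains.
    """
    if len(tiles) == 0:
        raise InvalidParameterError("cannot estimate a profile from zero tiles")
    stack = np.stack([t.pixels for t in tiles], axis=0)
    mean = stack.mean(axis=0)  # (C, ..., Y, X)
    if blur_sigma_px is None:
        blur_sigma_px = mean.shape[-1] / 8.0
    if blur_sigma_px <= 0:
        raise InvalidParameterError("blur sigma must be positive")
    # Blur laterally only; a 3D tile's planes share one lateral profile.
    if mean.ndim == 4:
        mean = mean.mean(axis=1)
    sigma = (0.0, blur_sigma_px, blur_sigma_px)
    # edge replication: reflected/zero padding would bend the smoothed
    # field near the tile borders, exactly where vignetting matters
    smooth = gaussian_filter(mean, sigma=sigma, mode="nearest")
    peaks = smooth.reshape(smooth.shape[0], -1).max(axis=1)
    if np.any(peaks <= 0):
        raise InvalidParameterError("a channel has a non-positive profile maximum")
    return IlluminationProfile(smooth / peaks[:, None, None])


def flatfield_correct(tile: Tile, profile: IlluminationProfile) -> Tile:
    """Divide each channel by the normalised illumination profile."""
    field = profile.field
    if field.shape[0] != tile.pixels.shape[0] or field.shape[-2:] != tile.pixels.shape[-2:]:
        raise InvalidParameterError("profile shape does not match the tile")
    if tile.pixels.ndim == 4:
        corrected = tile.pixels / field[:, None, :, :]
    else:
        corrected = tile.pixels / field
    return replace(tile, pixels=corrected)


def _intensity(tile: Tile) -> np.ndarray:
    """Channel-summed intensity used for registration."""
    return tile.pixels.sum(axis=0)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def _overlap_slices(shape_a, shape_b, offset):
    """Slices of a and b overlapping when b sits at ``offset`` relative to a."""
    sl_a, sl_b = [], []
    for sa, sb, o in zip(shape_a, shape_b, offset):
        lo = max(0, o)
        hi = min(sa, sb + o)
        if hi <= lo:
            return None
        sl_a.append(slice(lo, hi))
        sl_b.append(slice(lo - o, hi - o))
    return tuple(sl_a), tuple(sl_b)


def register_tile_pair(
    a: Tile,
    b: Tile,
    expected_offset_px: Sequence[int],
    search_radius_px: int = 10,
    min_overlap_px: int = 8,
) -> tuple[tuple, float]:
    """Best integer offset of ``b`` relative to ``a`` near the nominal offset.

    Exhaustive normalised cross-correlation over every integer offset in
    the ``(2r+1)^d`` window centred on ``expected_offset_px``.  Returns
    the winning offset and its correlation score in [-1, 1].  Candidates
    whose overlap is thinner than ``min_overlap_px`` along any axis are
    skipped — a sliver a few pixels wide can correlate perfectly by
    accident (e.g. two vignette-corrected background edges).  Raises
    :class:`RegistrationFailure` when no candidate offset has a usable
    overlap.
    """
    ia, ib = _intensity(a), _intensity(b)
    if ia.ndim != ib.ndim:
        raise InvalidParameterError("tiles must share dimensionality")
    expected = np.asarray(expected_offset_px, dtype=int)
    if expected.shape != (ia.ndim,):
        raise InvalidParameterError("expected offset must have one entry per spatial axis")
    if search_radius_px < 0:
        raise InvalidParameterError("search radius must be non-negative")
    best_score, best_offset = -np.inf, None
    deltas = np.arange(-search_radius_px, search_radius_px + 1)
    grids = np.meshgrid(*([deltas] * ia.ndim), indexing="ij")
    candidates = np.stack([g.ravel() for g in grids], axis=1) + expected
    for offset in candidates:
        sl = _overlap_slices(ia.shape, ib.shape, offset)
        if sl is None:
            continue
        ov_a, ov_b = ia[sl[0]], ib[sl[1]]
        if min(s.stop - s.start for s in sl[0]) < min_overlap_px:
            continue
        score = _ncc(ov_a, ov_b)
        if score > best_score:
            best_score, best_offset = score, tuple(int(o) for o in offset)
    if best_offset is None:
        raise RegistrationFailure("no overlap of sufficient size in the search window")
    return best_offset, best_score


def _feather_weight(shape) -> np.ndarray:
    """Weight rising linearly from every edge; used for feather blending."""
    ramps = [np.minimum(np.arange(s), np.arange(s)[::-1]) + 1.0 for s in shape]
    grids = np.meshgrid(*ramps, indexing="ij")
    return np.minimum.reduce(grids)


def assemble_mosaic(
    tiles: Sequence[Tile],
    offsets: Sequence[Sequence[int]],
    blend: Literal["feather", "max", "overwrite"] = "feather",
) -> np.ndarray:
    """Paste tiles at integer offsets onto a canvas sized to their bounding box.

    Overlap handling: ``overwrite`` keeps the last tile pasted, ``max``
    the per-pixel maximum, ``feather`` a linear cross-fade weighted by the
    distance to each tile's edge (a convex combination, so overlapping
    identical tiles reproduce themselves exactly).
    Returns the channel-first mosaic array; offsets may be negative.
    """
    if len(tiles) == 0:
        raise InvalidParameterError("no tiles to assemble")
    if len(offsets) != len(tiles):
        raise InvalidParameterError("one offset per tile is required")
    offsets = [np.asarray(o, dtype=int) for o in offsets]
    ndim = tiles[0].pixels.ndim - 1
    origin = np.min([o for o in offsets], axis=0)
    extent = np.max(
        [o + np.array(t.spatial_shape) for o, t in zip(offsets, tiles)], axis=0
    )
    shape = tuple(extent - origin)
    n_chan = tiles[0].pixels.shape[0]
    canvas = np.zeros((n_chan,) + shape)
    if blend == "feather":
        weights = np.zeros(shape)
    for tile, off in zip(tiles, offsets):
        rel = off - origin
        sl = tuple(slice(r, r + s) for r, s in zip(rel, tile.spatial_shape))
        target = (slice(None),) + sl
        if blend == "overwrite":
            canvas[target] = tile.pixels
        elif blend == "max":
            canvas[target] = np.maximum(canvas[target], tile.pixels)
        elif blend == "feather":
            w = _feather_weight(tile.spatial_shape)
            canvas[target] += tile.pixels * w
            weights[sl] += w
        else:
            raise InvalidParameterError(f"unknown blend mode {blend!r}")
    if blend == "feather":
        nonzero = weights > 0
        canvas[:, nonzero] /= weights[nonzero]
    return canvas


def stitch_grid(
    tiles: Sequence[Tile],
    search_radius_px: int = 10,
    score_threshold: float = 0.3,
    blend: Literal["feather", "max", "overwrite"] = "feather",
) -> tuple[np.ndarray, dict, "list[dict]"]:
    """Register adjacent tiles pairwise and assemble a globally placed mosaic.

    Pairwise offsets between grid neighbours are refined by
    :func:`register_tile_pair`; pairs scoring below ``score_threshold``
    (or failing outright) fall back to the nominal offset.  Global
    positions accumulate along a maximum-correlation spanning tree rooted
    at the first tile.  Returns (mosaic, offsets-by-grid-index, pairwise
    registration records).
    """
    by_index = {t.grid_index: t for t in tiles}
    graph = nx.Graph()
    graph.add_nodes_from(by_index)
    records = []
    for idx, tile in by_index.items():
        for axis in range(len(idx)):
            nb = list(idx)
            nb[axis] += 1
            nb = tuple(nb)
            if nb not in by_index:
                continue
            other = by_index[nb]
            nominal = np.array(other.nominal_offset_px) - np.array(tile.nominal_offset_px)
            try:
                offset, score = register_tile_pair(
                    tile, other, nominal, search_radius_px
                )
                used_fallback = score < score_threshold
            except RegistrationFailure:
                offset, score, used_fallback = tuple(nominal), float("nan"), True
            if used_fallback:
                offset = tuple(int(v) for v in nominal)
            records.append(
                {"a": idx, "b": nb, "offset": offset, "score": score,
                 "fallback": used_fallback}
            )
            graph.add_edge(idx, nb, offset=np.array(offset), src=idx,
                           weight=-(score if np.isfinite(score) else -1.0))
    tree = nx.minimum_spanning_tree(graph, weight="weight")
    root = tiles[0].grid_index
    positions = {root: np.array(tiles[0].nominal_offset_px) * 0}
    for parent, child in nx.bfs_edges(tree, root):
        data = tree.edges[parent, child]
        step = data["offset"] if data["src"] == parent else -data["offset"]
        positions[child] = positions[parent] + step
    ordered = [by_index[i] for i in by_index]
    mosaic = assemble_mosaic(ordered, [positions[i] for i in by_index], blend=blend)
    return mosaic, {i: tuple(int(v) for v in positions[i]) for i in by_index}, records
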