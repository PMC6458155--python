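"""Multiplexed axon-projection quantification.

After spectral unmixing, each channel of a tricolour projection dataset
is enhanced (square-root transform plus histogram matching to a
reference section), segmented into a binary signal mask (multi-Otsu
thresholding followed by small-component removal), and made
colour-exclusive by discarding pixels detected in any other channel.
Signal is then aggregated over non-overlapping super-pixels (30 x 30 px,
i.e. 24 x 24 µm at 0.8 µm pixels) into projection strength maps; the
three maps merge into an interdigitation map whose super-pixels are
classified as single (R, G, B), dual (RG, GB, RB) or triple (RGB)
projections by nearest reference point in RGB space.  Confidence maps
record the exclusive-to-total signal ratio per super-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.morphology import remove_small_objects

from .core import InvalidParameterError, MultichannelImage, as_multichannel

__all__ = [
    "CLASS_ORDER",
    "REFERENCE_POINTS",
    "SignalMask",
    "ProjectionStrengthMap",
    "ConfidenceMap",
    "InterdigitationMap",
    "enhance_channel",
    "histogram_from_plane",
    "multiotsu_thresholds",
    "segment_channel",
    "exclusive_masks",
    "strength_map",
    "confidence_map",
    "interdigitation_map",
    "classify_superpixels",
    "region_proportions",
    "quantify_projections",
]

#: Categorical classes in fixed order; ties in classification resolve to
#: the earliest class in this order.
CLASS_ORDER = ("R", "G", "B", "RG", "GB", "RB", "RGB")

#: Reference points in RGB contribution space, one per class.
REFERENCE_POINTS = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.5, 0.5, 0.0],
        [0.0, 0.5, 0.5],
        [0.5, 0.0, 0.5],
        [0.33, 0.33, 0.33],
    ]
)

EMPTY_CLASS = -1  # integer code for super-pixels without any signal


@dataclass
class SignalMask:
    """Binary signal mask of one channel."""

    mask: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class ProjectionStrengthMap:
    """Per-super-pixel signal fraction in [0, 1]."""

    values: np.ndarray
    block_px: int
    channel: str = ""


@dataclass
class ConfidenceMap:
    """Exclusive/total signal ratio per super-pixel; NaN marks no-signal blocks."""

    values: np.ndarray
    block_px: int


@dataclass
class InterdigitationMap:
    """Stacked (3, gy, gx) strength triples plus the categorical class grid."""

    strengths: np.ndarray
    classes: np.ndarray  # integer codes into CLASS_ORDER, EMPTY_CLASS if empty
    block_px: int

    def render(self, gain: float | Sequence[float] = 1.0) -> np.ndarray:
        """Channel-last RGB rendering with a display gain; stored values
        are never altered by rendering."""
        g = np.broadcast_to(np.asarray(gain, dtype=float), (3,))
        return np.clip(np.moveaxis(self.strengths * g[:, None, None], 0, -1), 0, 1)

    def class_labels(self) -> np.ndarray:
        """String labels per super-pixel ('empty' where no signal)."""
        labels = np.empty(self.classes.shape, dtype=object)
        labels[...] = "empty"
        for code, name in enumerate(CLASS_ORDER):
            labels[self.classes == code] = name
        return labels


# ---------------------------------------------------------------------------
# enhancement and segmentation
# ---------------------------------------------------------------------------


def histogram_from_plane(plane: np.ndarray, nbins: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """(counts, bin centres) histogram of a plane, for use as a matching reference."""
    counts, edges = np.histogram(np.asarray(plane).ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def _match_to_histogram(values: np.ndarray, counts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Monotone quantile mapping of ``values`` onto a reference histogram."""
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise InvalidParameterError("reference histogram is empty")
    ref_cdf = np.cumsum(counts) / counts.sum()
    flat = values.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = (np.arange(flat.size) + 0.5) / flat.size
    # identical input values must map identically: average their ranks
    uniq, inverse = np.unique(flat, return_inverse=True)
    mean_rank = np.zeros(uniq.size)
    np.add.at(mean_rank, inverse, ranks)
    mean_rank /= np.bincount(inverse)
    matched = np.interp(mean_rank[inverse], ref_cdf, centers)
    return matched.reshape(values.shape)


def enhance_channel(
    plane: np.ndarray,
    reference_histogram: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Square-root transform followed by histogram matching.

    The square root compresses the heavy-tailed fluorescence intensity
    distribution; matching to a fixed reference histogram (taken from a
    reference section, itself square-root transformed) standardises
    contrast across sections.  Both steps are monotone, so pixel rank
    order is preserved.  With no reference the square-rooted plane is
    returned unchanged.
    """
    plane = np.asarray(plane, dtype=float)
    if np.any(plane < 0):
        raise InvalidParameterError("intensities must be non-negative")
    rooted = np.sqrt(plane)
    if reference_histogram is None:
        return rooted
    counts, centers = reference_histogram
    return _match_to_histogram(rooted, counts, centers)


def multiotsu_thresholds(
    counts: np.ndarray, centers: np.ndarray, n_classes: int = 3
) -> np.ndarray:
    """Exact multi-Otsu thresholds of a histogram.

    Maximises the between-class variance over every way of cutting the
    histogram into ``n_classes`` contiguous, non-empty classes, by
    dynamic programming over class boundaries in float64 (so the global
    maximiser is found exactly, not approximately).  Each returned
    threshold is the centre of the last bin of its lower class; ties
    resolve to the lowest cut positions.
    """
    counts = np.asarray(counts, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    if n_classes < 2:
        raise InvalidParameterError("need at least two classes")
    if counts.ndim != 1 or counts.shape != centers.shape:
        raise InvalidParameterError("counts and centers must be matching 1D arrays")
    if counts.sum() <= 0:
        raise InvalidParameterError("histogram is empty")
    n = len(counts)
    if np.count_nonzero(counts) < n_classes:
        raise InvalidParameterError("fewer populated bins than classes")
    w = np.concatenate([[0.0], np.cumsum(counts)])
    m = np.concatenate([[0.0], np.cumsum(counts * centers)])

    def segment_score(i: np.ndarray, j: int) -> np.ndarray:
        # sum over the class of w_class * mu_class^2 (up to the constant
        # total); empty classes are not allowed
        dw = w[j] - w[i]
        dm = m[j] - m[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(dw > 0, dm**2 / np.where(dw > 0, dw, 1.0), -np.inf)
        return score

    starts = np.arange(n + 1)
    best = np.array([segment_score(np.array([0]), j)[0] for j in range(n + 1)])
    back: list[np.ndarray] = []
    for _ in range(n_classes - 1):
        new_best = np.full(n + 1, -np.inf)
        argmax = np.zeros(n + 1, dtype=int)
        for j in range(1, n + 1):
            cand = best[:j] + segment_score(starts[:j], j)
            k = int(np.argmax(cand))  # first maximum: lowest cut wins ties
            new_best[j], argmax[j] = cand[k], k
        back.append(argmax)
        best = new_best
    cuts = []
    j = n
    for argmax in reversed(back):
        j = int(argmax[j])
        cuts.append(j)
    cuts.reverse()
    return centers[np.array(cuts) - 1]


def segment_channel(
    plane: np.ndarray,
    n_classes: int = 3,
    signal_class_rule: Literal["top_class", "top_k"] = "top_class",
    top_k: int = 1,
    min_component_px: int = 4,
    nbins: int = 256,
    channel: str = "",
) -> SignalMask:
    """Separate fluorescence signal from background in one channel plane.

    Multi-Otsu clustering partitions the intensity histogram into
    ``n_classes`` classes by maximising between-class variance; the top
    class (or top ``k`` classes) is retained as signal.  Connected
    components smaller than ``min_component_px`` pixels (8-connectivity)
    are removed as noise.
    """
    plane = np.asarray(plane, dtype=float)
    if n_classes < 2:
        raise InvalidParameterError("need at least two intensity classes")
    if len(np.unique(plane)) < n_classes:
        raise InvalidParameterError(
            "plane has fewer distinct values than requested classes"
        )
    counts, centers = histogram_from_plane(plane, nbins=nbins)
    thresholds = multiotsu_thresholds(counts, centers, n_classes)
    if signal_class_rule == "top_class":
        k = 1
    elif signal_class_rule == "top_k":
        k = int(top_k)
        if not 1 <= k < n_classes:
            raise InvalidParameterError("top_k must lie in [1, n_classes)")
    else:
        raise InvalidParameterError(f"unknown signal class rule {signal_class_rule!r}")
    # a threshold is the last bin centre of its lower class: strictly
    # greater values are signal
    mask = plane > thresholds[-k]
    if min_component_px > 1:
        # keep components of at least min_component_px pixels
        mask = remove_small_objects(mask, max_size=min_component_px - 1, connectivity=2)
    return SignalMask(mask=mask, channel=channel)


# ---------------------------------------------------------------------------
# masks and maps
# ---------------------------------------------------------------------------


def exclusive_masks(masks: Sequence[SignalMask]) -> list[SignalMask]:
    """Remove from each mask every pixel set in any other channel.

    The outputs are pairwise disjoint by construction.
    """
    arrays = [m.mask for m in masks]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise InvalidParameterError("masks must share one shape")
    out = []
    for i, m in enumerate(masks):
        others = np.zeros_like(m.mask)
        for j, other in enumerate(arrays):
            if j != i:
                others |= other
        out.append(SignalMask(mask=m.mask & ~others, channel=m.channel))
    return out


def _block_sums(arr: np.ndarray, block_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block sums and per-block pixel counts, edge blocks included."""
    h, w = arr.shape
    gy, gx = -(-h // block_px), -(-w // block_px)
    row_idx = np.arange(0, h, block_px)
    col_idx = np.arange(0, w, block_px)
    sums = np.add.reduceat(np.add.reduceat(arr.astype(float), row_idx, axis=0), col_idx, axis=1)
    ones = np.ones_like(arr, dtype=float)
    areas = np.add.reduceat(np.add.reduceat(ones, row_idx, axis=0), col_idx, axis=1)
    assert sums.shape == (gy, gx)
    return sums, areas


def strength_map(mask: SignalMask, block_px: int = 30) -> ProjectionStrengthMap:
    """Signal-pixel fraction over non-overlapping super-pixels.

    Edge blocks are normalised by their actual pixel count rather than
    the nominal block area, avoiding boundary bias.
    """
    if block_px < 1:
        raise InvalidParameterError("block size must be at least 1 pixel")
    sums, areas = _block_sums(mask.mask, block_px)
    return ProjectionStrengthMap(values=sums / areas, block_px=block_px, channel=mask.channel)


def confidence_map(
    exclusive: SignalMask, total: SignalMask, block_px: int = 30
) -> ConfidenceMap:
    """Exclusive over total signal pixels per super-pixel.

    Super-pixels without any signal carry NaN (a no-signal flag) rather
    than 0, and are excluded from summaries.
    """
    if exclusive.mask.shape != total.mask.shape:
        raise InvalidParameterError("mask shapes differ")
    if np.any(exclusive.mask & ~total.mask):
        raise InvalidParameterError("exclusive mask contains pixels outside the total mask")
    ex_sums, _ = _block_sums(exclusive.mask, block_px)
    tot_sums, _ = _block_sums(total.mask, block_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(tot_sums > 0, ex_sums / np.where(tot_sums > 0, tot_sums, 1.0), np.nan)
    return ConfidenceMap(values=values, block_px=block_px)


def interdigitation_map(
    r: ProjectionStrengthMap, g: ProjectionStrengthMap, b: ProjectionStrengthMap
) -> InterdigitationMap:
    """Merge three strength maps into one classified interdigitation map."""
    if not (r.values.shape == g.values.shape == b.values.shape):
        raise InvalidParameterError("strength map grids differ")
    if not (r.block_px == g.block_px == b.block_px):
        raise InvalidParameterError("strength map block sizes differ")
    strengths = np.stack([r.values, g.values, b.values])
    classes = classify_superpixels(strengths)
    return InterdigitationMap(strengths=strengths, classes=classes, block_px=r.block_px)


def classify_superpixels(strengths: np.ndarray) -> np.ndarray:
    """Nearest-reference classification of super-pixel strength triples.

    The triple is normalised to relative contributions (sum one) and the
    Euclidean distance to the seven reference points is minimised; ties
    resolve to the earliest class in ``CLASS_ORDER``.  Super-pixels with
    zero total strength are coded ``EMPTY_CLASS``.
    """
    strengths = np.asarray(strengths, dtype=float)
    if strengths.shape[0] != 3:
        raise InvalidParameterError("expected a (3, ...) strength stack")
    total = strengths.sum(axis=0)
    safe = np.where(total > 0, total, 1.0)
    contrib = strengths / safe  # (3, ...)
    flat = contrib.reshape(3, -1).T  # (n, 3)
    d2 = ((flat[:, None, :] - REFERENCE_POINTS[None, :, :]) ** 2).sum(axis=-1)
    codes = np.argmin(d2, axis=1).astype(int)  # argmin takes the first minimum
    codes = codes.reshape(total.shape)
    return np.where(total > 0, codes, EMPTY_CLASS)


def region_proportions(
    classes: np.ndarray, region_mask: np.ndarray | None = None
) -> pd.Series:
    """Class proportions over in-region, non-empty super-pixels (sum to 1)."""
    classes = np.asarray(classes)
    if region_mask is None:
        region_mask = np.ones(classes.shape, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != classes.shape:
        raise InvalidParameterError("region mask shape does not match the class grid")
    if not region_mask.any():
        raise InvalidParameterError("empty region")
    selected = classes[region_mask]
    selected = selected[selected != EMPTY_CLASS]
    if selected.size == 0:
        raise InvalidParameterError("no signal-bearing super-pixels in the region")
    counts = np.bincount(selected, minlength=len(CLASS_ORDER)).astype(float)
    return pd.Series(counts / counts.sum(), index=list(CLASS_ORDER))


# ---------------------------------------------------------------------------
# full workflow
# ---------------------------------------------------------------------------


@dataclass
class ProjectionQuantification:
    masks: list[SignalMask]
    exclusive: list[SignalMask]
    strengths: list[ProjectionStrengthMap]
    confidences: list[ConfidenceMap]
    interdigitation: InterdigitationMap


def quantify_projections(
    image: MultichannelImage | np.ndarray,
    block_px: int = 30,
    n_classes: int = 3,
    min_component_px: int = 4,
    exclusive: bool = True,
    reference_histograms: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    enhance: bool = False,
) -> ProjectionQuantification:
    """End-to-end projection quantification of an unmixed tricolour plane.

    Set ``exclusive=False`` to build strength maps from the raw masks
    (appropriate for fiber-tract analysis, where structures are larger
    than single axons and shared pixels are informative).
    """
    img = as_multichannel(image)
    if img.n_channels != 3 or img.is_3d:
        raise InvalidParameterError("expected a 2D three-channel image")
    masks = []
    for c in range(3):
        plane = img.data[c]
        if enhance:
            ref = reference_histograms[c] if reference_histograms else None
            plane = enhance_channel(plane, ref)
        masks.append(
            segment_channel(
                plane,
                n_classes=n_classes,
                min_component_px=min_component_px,
                channel=img.channel_names[c],
            )
        )
    excl = exclusive_masks(masks)
    basis = excl if exclusive else masks
    strengths = [strength_map(m, block_px) for m in basis]
    confidences = [confidence_map(e, m, block_px) for e, m in zip(excl, masks)]
    inter = interdigitation_map(*strengths)
    return ProjectionQuantification(
        masks=masks,
        exclusive=excl,
        strengths=strengths,
        confidences=confidences,
        interdigitation=inter,
    )
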