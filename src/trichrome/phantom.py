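"""Synthetic multicolor image phantoms with exact ground truth.

Every downstream stage of the toolkit is exercised on phantoms generated
here: filamentous "axon" populations with controllable pixel-level
overlap, space-filling polyhedral "astrocyte territories" with engulfed
dark somata, bead fields displaced by a known chromatic-shift model,
vignetted tile grids, planar astrocyte interfaces, and clouds of ternary
colour combinations.  Generators are deterministic for a fixed seed and
record the ground truth needed to score each analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree
from skimage.draw import line
from skimage.morphology import disk

from .chromatic import ChromaticShiftModel
from .core import InvalidParameterError, MultichannelImage
from .interfaces import InterfacePair
from .tiles import Tile
from .unmixing import MixingModel

__all__ = [
    "PhantomGroundTruth",
    "generate_projection_phantom",
    "generate_territory_phantom",
    "apply_mixing_and_noise",
    "generate_bead_field",
    "tile_and_vignette",
    "generate_interface_phantom",
    "generate_color_combinations",
    "territory_adjacency",
]


@dataclass
class PhantomGroundTruth:
    """Ground truth accompanying a phantom; only the relevant fields are set."""

    true_mixing: MixingModel | None = None
    territory_label_volume: np.ndarray | None = None
    territory_color: np.ndarray | None = None  # (n_territories, 3)
    soma_positions_um: np.ndarray | None = None  # (n, 3)
    contacted_soma_labels: np.ndarray | None = None  # owning territory per soma
    axon_membership: np.ndarray | None = None  # (3, Y, X) bool
    true_superpixel_composition: np.ndarray | None = None  # (3, gy, gx)
    superpixel_block_px: int | None = None
    true_shift_model: ChromaticShiftModel | None = None
    illumination_profile: np.ndarray | None = None  # (C, ty, tx), max 1
    true_tile_offsets: list | None = None
    extras: dict = field(default_factory=dict)

    def multi_population_fraction(self) -> float:
        """Fraction of signal pixels carrying two or more population ids."""
        if self.axon_membership is None:
            raise InvalidParameterError("no axon membership recorded")
        counts = self.axon_membership.sum(axis=0)
        signal = counts >= 1
        if not signal.any():
            return 0.0
        return float((counts >= 2).sum() / signal.sum())


# ---------------------------------------------------------------------------
# filamentous projection phantom
# ---------------------------------------------------------------------------


def _filament_path(
    rng: np.random.Generator,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    curvature: float,
    length_px: float,
    step_px: float = 2.0,
) -> np.ndarray:
    """Smoothed random walk reflected at ``bounds`` ((ymin, ymax), (xmin, xmax))."""
    (ymin, ymax), (xmin, xmax) = bounds
    pos = np.array([rng.uniform(ymin, ymax), rng.uniform(xmin, xmax)])
    heading = rng.uniform(0.0, 2.0 * np.pi)
    n_steps = max(2, int(round(length_px / step_px)))
    pts = np.empty((n_steps + 1, 2))
    pts[0] = pos
    for i in range(n_steps):
        heading += curvature * rng.normal()
        pos = pos + step_px * np.array([np.sin(heading), np.cos(heading)])
        # reflect off the walls so filaments stay inside their zone
        if pos[0] < ymin or pos[0] > ymax:
            pos[0] = np.clip(2 * np.clip(pos[0], ymin, ymax) - pos[0], ymin, ymax)
            heading = -heading
        if pos[1] < xmin or pos[1] > xmax:
            pos[1] = np.clip(2 * np.clip(pos[1], xmin, xmax) - pos[1], xmin, xmax)
            heading = np.pi - heading
        pts[i + 1] = pos
    return pts


def _offset_along_normal(path: np.ndarray, distance: float) -> np.ndarray:
    """Shift a polyline by ``distance`` along its local normal everywhere."""
    tangent = np.gradient(path, axis=0)
    norms = np.linalg.norm(tangent, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangent /= norms
    normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
    return path + distance * normal


def _stamp_path(canvas: np.ndarray, path: np.ndarray) -> None:
    ij = np.rint(path).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, canvas.shape[0] - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, canvas.shape[1] - 1)
    for (r0, c0), (r1, c1) in zip(ij[:-1], ij[1:]):
        rr, cc = line(r0, c0, r1, c1)
        canvas[rr, cc] = True


def generate_projection_phantom(
    shape: tuple[int, int] = (1800, 1800),
    n_per_population: tuple[int, int, int] = (20, 20, 20),
    curvature: float = 0.1,
    width_px: float = 3.0,
    overlap_fraction: float = 0.0,
    seed: int = 0,
    block_px: int = 30,
    amplitude: float = 1.0,
    background: float = 0.0,
    length_px: float | None = None,
) -> tuple[MultichannelImage, PhantomGroundTruth]:
    """Three filamentous axon populations with controllable pixel overlap.

    Each population is a set of smoothed random-walk tubes of radius
    ``width_px`` rendered at constant ``amplitude`` into its own channel
    (a flat-top cross-section keeps the per-pixel membership ground truth
    exact).  With ``overlap_fraction == 0`` the populations are confined
    to three disjoint vertical strips, so no pixel carries two ids.  With
    ``overlap_fraction > 0`` a computed number of tube pairs is rendered
    as parallel duplicates offset by one tube radius across two
    populations, so the expected fraction of multi-population signal
    pixels equals the request (incidental filament crossings add a little
    more).

    Returns the image and a ground truth holding the per-pixel membership
    stack and the per-super-pixel composition at ``block_px``.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2 or any(s <= 0 for s in shape):
        raise InvalidParameterError("shape must be two positive integers")
    if any(s % block_px for s in shape):
        raise InvalidParameterError("shape must be divisible by the super-pixel block")
    n_pop = tuple(int(n) for n in n_per_population)
    if len(n_pop) != 3 or any(n <= 0 for n in n_pop):
        raise InvalidParameterError("n_per_population must be three positive counts")
    if not 0.0 <= overlap_fraction < 0.6:
        raise InvalidParameterError("overlap_fraction must lie in [0, 0.6)")
    rng = np.random.default_rng(seed)
    h, w = shape
    if length_px is None:
        length_px = 0.7 * min(shape)
    radius = max(1, int(round(width_px)))
    margin = radius + 1

    paths: list[list[np.ndarray]] = [[], [], []]
    if overlap_fraction == 0.0:
        # disjoint vertical strips, inset so dilation cannot cross over
        for pop in range(3):
            x0, x1 = pop * w / 3 + margin, (pop + 1) * w / 3 - margin
            bounds = ((margin, h - margin), (x0, x1))
            for _ in range(n_pop[pop]):
                paths[pop].append(
                    _filament_path(rng, bounds, curvature, length_px)
                )
    else:
        bounds = ((margin, h - margin), (margin, w - margin))
        n_min = min(n_pop)
        # s duplicate pairs, tubes offset by one radius: per pair the
        # intersection band is w wide against a 3w union, so
        # multi/total = s/(6n - s) and s = 6nf/(1+f); the one-radius
        # offset keeps each channel's exclusive crescent a full radius
        # wide, robust to pixel quantisation
        s_total = int(round(6 * n_min * overlap_fraction / (1 + overlap_fraction)))
        s_total = min(s_total, (3 * n_min) // 2)
        pair_ids = [(0, 1), (1, 2), (0, 2)]
        s_per_pair = [s_total // 3] * 3
        for i in range(s_total % 3):
            s_per_pair[i] += 1
        used = [0, 0, 0]
        for (pa, pb), s_pair in zip(pair_ids, s_per_pair):
            for _ in range(s_pair):
                path = _filament_path(rng, bounds, curvature, length_px)
                paths[pa].append(path)
                paths[pb].append(_offset_along_normal(path, float(radius)))
                used[pa] += 1
                used[pb] += 1
        for pop in range(3):
            for _ in range(max(0, n_pop[pop] - used[pop])):
                paths[pop].append(_filament_path(rng, bounds, curvature, length_px))

    structure = disk(radius)
    membership = np.zeros((3,) + shape, dtype=bool)
    for pop in range(3):
        canvas = np.zeros(shape, dtype=bool)
        for path in paths[pop]:
            _stamp_path(canvas, path)
        membership[pop] = binary_dilation(canvas, structure=structure)

    # constant background emulates diffuse tissue fluorescence; zero keeps
    # the noiseless segmentation closure exact
    data = membership.astype(float) * amplitude + background
    gy, gx = h // block_px, w // block_px
    comp = (
        membership.reshape(3, gy, block_px, gx, block_px)
        .mean(axis=(2, 4))
        .astype(float)
    )
    image = MultichannelImage(data, voxel_size_um=(0.8, 0.8))
    truth = PhantomGroundTruth(
        axon_membership=membership,
        true_superpixel_composition=comp,
        superpixel_block_px=block_px,
    )
    return image, truth


# ---------------------------------------------------------------------------
# astrocyte territory phantom
# ---------------------------------------------------------------------------

# palette of colour-combination intensity triples (expression levels of the
# three fluorescent proteins); black is excluded
_LEVELS = (0.0, 0.5, 1.0)
_COLOR_PALETTE = np.array(
    [
        (r, g, b)
        for r in _LEVELS
        for g in _LEVELS
        for b in _LEVELS
        if (r, g, b) != (0.0, 0.0, 0.0)
    ]
)


def generate_territory_phantom(
    shape: tuple[int, int, int] = (48, 64, 64),
    n_territories: int = 24,
    n_colors: int = 8,
    somata_per_territory: float = 12.8,
    seed: int = 0,
    voxel_size_um: tuple[float, float, float] = (1.5, 0.8, 0.8),
    soma_radius_vox: int = 2,
) -> tuple[MultichannelImage, PhantomGroundTruth]:
    """Space-filling astrocyte territories with engulfed dark somata.

    The volume is partitioned into contiguous territories by a
    nearest-seed (Voronoi) rule; each territory is filled with one of
    ``n_colors`` colour-combination triples.  Contacted cell bodies
    appear as dark spheres carved out of their territory's intensity; the
    count per territory is Poisson with the requested mean (12.8 by
    default, the density scale reported for cortical protoplasmic
    astrocytes).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise InvalidParameterError("shape must be three positive integers")
    n_vox = int(np.prod(shape))
    if not 1 <= n_territories <= n_vox:
        raise InvalidParameterError("n_territories must be in [1, voxel count]")
    if n_colors < 2:
        raise InvalidParameterError("at least two colour combinations are required")
    if n_colors > len(_COLOR_PALETTE):
        raise InvalidParameterError(
            f"at most {len(_COLOR_PALETTE)} colour combinations are available"
        )
    rng = np.random.default_rng(seed)

    seeds = rng.uniform(0.0, 1.0, size=(n_territories, 3)) * np.array(shape)
    coords = np.stack(
        np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    _, labels = cKDTree(seeds).query(coords)
    labels = labels.reshape(shape).astype(np.int32)

    color_ids = rng.integers(0, n_colors, size=n_territories)
    palette = _COLOR_PALETTE[rng.permutation(len(_COLOR_PALETTE))[:n_colors]]
    territory_color = palette[color_ids]

    data = territory_color[labels].transpose(3, 0, 1, 2).astype(float)

    soma_positions, soma_labels = [], []
    dark = np.zeros(shape, dtype=bool)
    zz, yy, xx = np.meshgrid(
        *[np.arange(-soma_radius_vox, soma_radius_vox + 1)] * 3, indexing="ij"
    )
    ball = zz**2 + yy**2 + xx**2 <= soma_radius_vox**2
    flat_labels = labels.ravel()
    for t in range(n_territories):
        members = np.flatnonzero(flat_labels == t)
        if members.size == 0:
            continue
        k = rng.poisson(somata_per_territory)
        for voxel in rng.choice(members, size=min(k, members.size), replace=False):
            center = np.unravel_index(voxel, shape)
            sl_vol, sl_ball = [], []
            for c, s, b in zip(center, shape, ball.shape):
                lo, hi = c - soma_radius_vox, c + soma_radius_vox + 1
                sl_vol.append(slice(max(lo, 0), min(hi, s)))
                sl_ball.append(slice(max(0, -lo), b - max(0, hi - s)))
            dark[tuple(sl_vol)] |= ball[tuple(sl_ball)]
            soma_positions.append((np.array(center) + 0.5) * np.array(voxel_size_um))
            soma_labels.append(t)
    data[:, dark] = 0.0

    image = MultichannelImage(data, voxel_size_um=voxel_size_um)
    truth = PhantomGroundTruth(
        territory_label_volume=labels,
        territory_color=territory_color,
        soma_positions_um=np.array(soma_positions).reshape(-1, 3),
        contacted_soma_labels=np.array(soma_labels, dtype=int),
        extras={"seed_points": seeds, "color_ids": color_ids},
    )
    return image, truth


def territory_adjacency(labels: np.ndarray) -> set[tuple[int, int]]:
    """Face-adjacent territory pairs derived from a label volume."""
    labels = np.asarray(labels)
    pairs: set[tuple[int, int]] = set()
    for axis in range(labels.ndim):
        a = np.moveaxis(labels, axis, 0)[:-1].ravel()
        b = np.moveaxis(labels, axis, 0)[1:].ravel()
        diff = a != b
        for x, y in zip(a[diff], b[diff]):
            pairs.add((int(min(x, y)), int(max(x, y))))
    return pairs


# ---------------------------------------------------------------------------
# detector model, bead fields, tiling
# ---------------------------------------------------------------------------


def apply_mixing_and_noise(
    image: MultichannelImage | np.ndarray,
    model: MixingModel,
    gain: float = 0.0,
    read_noise_sd: float = 0.0,
    seed: int | None = None,
) -> MultichannelImage:
    """Forward-mix an image and corrupt it with shot and read noise.

    ``raw = M @ corrected`` per pixel, then Poisson noise on intensities
    scaled by ``gain`` (photons per intensity unit; 0 disables shot
    noise) and additive Gaussian read noise, clipped at zero.
    """
    from .unmixing import forward_mix  # local import to avoid cycle at module load

    if gain < 0:
        raise InvalidParameterError("gain must be non-negative")
    if read_noise_sd < 0:
        raise InvalidParameterError("read noise s.d. must be non-negative")
    raw = forward_mix(image, model)
    data = raw.data
    rng = np.random.default_rng(seed)
    if gain > 0:
        data = rng.poisson(np.clip(data, 0, None) * gain) / gain
    if read_noise_sd > 0:
        data = data + rng.normal(0.0, read_noise_sd, size=data.shape)
    return raw.with_data(np.clip(data, 0.0, None))


def generate_bead_field(
    n: int,
    fov_um: float,
    true_model: ChromaticShiftModel,
    loc_noise_sd_um: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Nanocrystal centroid-pair table displaced by a known shift model.

    Positions are uniform over a centred square field of view of side
    ``fov_um``; the second beam's centroid is displaced by the model
    evaluated at the position plus isotropic Gaussian localisation noise.
    Columns: x, y, dx, dy, dz (µm).
    """
    if n < 3:
        raise InvalidParameterError("need at least as many beads as model parameters")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-fov_um / 2.0, fov_um / 2.0, size=(n, 2))
    dx, dy = true_model.lateral_shift(xy[:, 0], xy[:, 1])
    dz = true_model.axial_shift(xy[:, 0], xy[:, 1])
    if loc_noise_sd_um > 0:
        noise = rng.normal(0.0, loc_noise_sd_um, size=(n, 3))
        dx, dy, dz = dx + noise[:, 0], dy + noise[:, 1], dz + noise[:, 2]
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "dx": dx, "dy": dy, "dz": dz})


def tile_and_vignette(
    image: MultichannelImage | np.ndarray,
    tile_px: int,
    overlap_fraction: float = 0.1,
    profile_sigma_px: float | None = None,
) -> tuple[list[Tile], PhantomGroundTruth]:
    """Cut a 2D image into an overlapping tile grid with Gaussian vignetting.

    The pitch is ``tile_px * (1 - overlap_fraction)``; a final row/column
    flush with the image edge is added when the pitch does not divide
    evenly.  Each tile is multiplied by a centred Gaussian illumination
    profile of width ``profile_sigma_px`` normalised to 1 at its peak
    (``None`` gives flat illumination).  True offsets and the profile are
    recorded as ground truth.
    """
    from .core import as_multichannel

    img = as_multichannel(image)
    if img.is_3d:
        raise InvalidParameterError("tiling is defined for 2D images")
    if not 0.0 <= overlap_fraction < 0.5:
        raise InvalidParameterError("overlap_fraction must lie in [0, 0.5)")
    h, w = img.spatial_shape
    tile_px = int(tile_px)
    if tile_px <= 0 or tile_px > h or tile_px > w:
        raise InvalidParameterError("tile size must be positive and fit in the image")
    pitch = max(1, int(round(tile_px * (1.0 - overlap_fraction))))

    def _starts(size: int) -> list[int]:
        starts = list(range(0, size - tile_px + 1, pitch))
        if starts[-1] != size - tile_px:
            starts.append(size - tile_px)
        return starts

    ys, xs = _starts(h), _starts(w)
    if profile_sigma_px is None:
        profile2d = np.ones((tile_px, tile_px))
    else:
        c = (tile_px - 1) / 2.0
        yy, xx = np.meshgrid(np.arange(tile_px), np.arange(tile_px), indexing="ij")
        profile2d = np.exp(
            -((yy - c) ** 2 + (xx - c) ** 2) / (2.0 * profile_sigma_px**2)
        )
        profile2d /= profile2d.max()
    profile = np.broadcast_to(profile2d, (img.n_channels,) + profile2d.shape).copy()

    tiles, offsets = [], []
    for r, y0 in enumerate(ys):
        for c, x0 in enumerate(xs):
            crop = img.data[:, y0 : y0 + tile_px, x0 : x0 + tile_px]
            tiles.append(
                Tile(crop * profile2d, grid_index=(r, c), nominal_offset_px=(y0, x0))
            )
            offsets.append((y0, x0))
    truth = PhantomGroundTruth(
        illumination_profile=profile,
        true_tile_offsets=offsets,
        extras={"grid_shape": (len(ys), len(xs)), "pitch_px": pitch},
    )
    return tiles, truth


# ---------------------------------------------------------------------------
# interface and colour-combination phantoms
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def generate_interface_phantom(
    separation_um: float = 40.0,
    offset_um: float = 3.0,
    tilt_deg: float = 20.0,
    n_points: int = 500,
    footprint_radius_um: float = 20.0,
    noise_sd_um: float = 0.5,
    seed: int = 0,
    rigid_motion: bool = True,
) -> tuple[InterfacePair, dict]:
    """Planar astrocyte-astrocyte interface with known tilt and offset.

    Two somata ``separation_um`` apart define the Voronoi axis; the true
    interface is a disc of radius ``footprint_radius_um`` centred
    ``offset_um`` beyond the midpoint towards the second soma and tilted
    by ``tilt_deg`` about a random in-plane direction.  Points are
    sampled uniformly on the disc and perturbed by isotropic Gaussian
    noise.  An optional random rigid motion removes any axis alignment.

    Returns the pair and a truth dict with the exact tilt, offset, and
    the noiseless point cloud.
    """
    if n_points < 6:
        raise InvalidParameterError("at least 6 interface points are required")
    if not 0.0 <= tilt_deg < 90.0:
        raise InvalidParameterError("tilt must lie in [0, 90) degrees")
    rng = np.random.default_rng(seed)
    a1 = np.zeros(3)
    a2 = np.array([0.0, 0.0, separation_um])
    center = np.array([0.0, 0.0, separation_um / 2.0 + offset_um])
    theta = np.radians(tilt_deg)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    e1 = np.array([np.cos(theta) * np.cos(phi), np.cos(theta) * np.sin(phi), np.sin(theta)])
    e2 = np.array([-np.sin(phi), np.cos(phi), 0.0])
    radii = footprint_radius_um * np.sqrt(rng.uniform(0.0, 1.0, n_points))
    angles = rng.uniform(0.0, 2.0 * np.pi, n_points)
    uv = np.stack([radii * np.cos(angles), radii * np.sin(angles)], axis=1)
    clean = center + uv[:, :1] * e1 + uv[:, 1:] * e2
    noisy = clean + rng.normal(0.0, noise_sd_um, size=clean.shape) if noise_sd_um > 0 else clean.copy()
    if rigid_motion:
        rot = _random_rotation(rng)
        shift = rng.uniform(-100.0, 100.0, size=3)
        a1, a2 = rot @ a1 + shift, rot @ a2 + shift
        clean = clean @ rot.T + shift
        noisy = noisy @ rot.T + shift
    pair = InterfacePair(soma_a1=a1, soma_a2=a2, points=noisy)
    truth = {
        "tilt_deg": float(tilt_deg),
        "offset_um": float(offset_um),
        "clean_points": clean,
        "noise_sd_um": float(noise_sd_um),
    }
    return pair, truth


def _simplex_lattice(resolution: int) -> np.ndarray:
    pts = [
        (i / resolution, j / resolution, (resolution - i - j) / resolution)
        for i in range(resolution + 1)
        for j in range(resolution + 1 - i)
    ]
    return np.array(pts)


def generate_color_combinations(
    n_combos: int = 20,
    per_combo: int = 100,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Ternary colour samples drawn around well-separated combination modes.

    Modes are taken from the coarsest simplex lattice holding at least
    ``n_combos`` points, so the minimal inter-mode distance is known.
    Samples get isotropic Gaussian noise and are renormalised onto the
    simplex.  Returns (samples, truth) where truth holds the mode centres
    and their minimal pairwise separation.
    """
    if n_combos < 1:
        raise InvalidParameterError("need at least one combination")
    resolution = 1
    while (resolution + 1) * (resolution + 2) // 2 < n_combos:
        resolution += 1
    lattice = _simplex_lattice(resolution)
    centers = lattice[:n_combos]
    rng = np.random.default_rng(seed)
    samples = np.repeat(centers, per_combo, axis=0)
    samples = samples + rng.normal(0.0, noise_sd, size=samples.shape)
    samples = np.clip(samples, 0.0, None)
    sums = samples.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    samples /= sums
    if n_combos > 1:
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        min_sep = float(d[np.triu_indices(n_combos, 1)].min())
    else:
        min_sep = np.inf
    truth = {"centers": centers, "min_separation": min_sep, "noise_sd": noise_sd}
    return samples, truth
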