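"""3D astrocyte-astrocyte interface geometry.

Neighbouring astrocytes tile the neuropil; the surface of contact
between a pair can be compared to the null expectation of a Voronoi
tessellation seeded at the two somata.  The segment between the somata
A1 and A2 defines the Voronoi axis (oriented A1 -> A2); the Voronoi
plane is perpendicular to it through the midpoint M.  Two scalar
parameters summarise the interface point cloud:

* bias — the percentage of interface points on the A2 side of the
  Voronoi plane (50% for an equiparted tiling);
* orientation — the angle in [0, 90] degrees between the Voronoi plane
  and the plane fitted to the interface.

The fitted plane also defines an interface frame in which the residual
surface relief is modelled by a biharmonic (thin-plate spline)
interpolant, yielding amplitude and gradient maps over the interface
footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay, QhullError

from .core import InvalidParameterError

__all__ = [
    "InterfacePair",
    "VoronoiFrame",
    "InterfaceMetrics",
    "BiharmonicSurface",
    "build_voronoi_frame",
    "bias_parameter",
    "fit_interface_plane",
    "interface_frame",
    "biharmonic_surface",
    "fit_biharmonic",
    "analyze_pair",
]


@dataclass
class InterfacePair:
    """Two soma positions and the interface point cloud, all in µm."""

    soma_a1: np.ndarray
    soma_a2: np.ndarray
    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.soma_a1 = np.asarray(self.soma_a1, dtype=float).reshape(3)
        self.soma_a2 = np.asarray(self.soma_a2, dtype=float).reshape(3)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if np.allclose(self.soma_a1, self.soma_a2):
            raise InvalidParameterError("somata must be distinct points")

    def swapped(self) -> "InterfacePair":
        return InterfacePair(self.soma_a2.copy(), self.soma_a1.copy(), self.points.copy())


@dataclass
class VoronoiFrame:
    """Orthonormal frame attached to the soma pair.

    ``axis`` is the unit vector A1 -> A2, ``midpoint`` the centre of the
    segment, and (``u``, ``v``, ``axis``) a right-handed basis; the
    Voronoi plane is spanned by u and v through the midpoint.
    """

    axis: np.ndarray
    midpoint: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World coordinates -> (u, v, w) with w along the Voronoi axis."""
        rel = np.asarray(points, dtype=float) - self.midpoint
        return rel @ np.stack([self.u, self.v, self.axis], axis=1)


@dataclass
class InterfaceMetrics:
    bias_pct: float
    orientation_deg: float
    plane_coefficients: np.ndarray  # w = c0 + c1 u + c2 v  (Voronoi frame)
    residual_rms_um: float
    n_points: int


def _orthonormal_complement(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # pick the cardinal direction least aligned with the axis as helper
    helper = np.zeros(3)
    helper[np.argmin(np.abs(axis))] = 1.0
    u = np.cross(helper, axis)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def build_voronoi_frame(pair: InterfacePair) -> VoronoiFrame:
    """Voronoi axis, midpoint, and right-handed in-plane basis of a pair."""
    delta = pair.soma_a2 - pair.soma_a1
    norm = np.linalg.norm(delta)
    if norm == 0:
        raise InvalidParameterError("coincident somata")
    axis = delta / norm
    midpoint = 0.5 * (pair.soma_a1 + pair.soma_a2)
    u, v = _orthonormal_complement(axis)
    return VoronoiFrame(axis=axis, midpoint=midpoint, u=u, v=v)


def bias_parameter(pair: InterfacePair, frame: VoronoiFrame | None = None) -> float:
    """Percentage of interface points on the A2 side of the Voronoi plane.

    Points exactly on the plane count half, which keeps the estimate
    unbiased under mirror symmetry.
    """
    if len(pair.points) == 0:
        raise InvalidParameterError("no interface points")
    frame = frame or build_voronoi_frame(pair)
    signed = (pair.points - frame.midpoint) @ frame.axis
    above = (signed > 0).sum() + 0.5 * (signed == 0).sum()
    return float(100.0 * above / len(signed))


def _polynomial_design(u: np.ndarray, v: np.ndarray, degree: int) -> tuple[np.ndarray, list]:
    terms = [(i, j) for total in range(degree + 1) for i in range(total + 1)
             for j in [total - i]]
    cols = [u**i * v**j for i, j in terms]
    return np.column_stack(cols), terms


def fit_interface_plane(
    pair: InterfacePair,
    frame: VoronoiFrame | None = None,
    degree: int = 1,
) -> tuple[InterfaceMetrics, np.ndarray]:
    """Fit the interface as a plane (or polynomial surface) in the Voronoi frame.

    For ``degree == 1`` the plane is fitted by orthogonal least squares
    (principal components of the point cloud): under isotropic point
    noise the orthogonal fit is unbiased, whereas regressing the axial
    offset w on the in-plane coordinates attenuates steep tilts.  For
    higher degrees the axial offset is regressed on a polynomial in
    (u, v) and the degree-1 part defines the plane.  The orientation
    parameter is the angle between the fitted plane and the Voronoi
    plane — equivalently between their normals — folded into [0, 90]
    degrees.  Returns the metrics together with the polynomial
    coefficient vector (``[c0, cu, cv]`` for degree 1).
    """
    frame = frame or build_voronoi_frame(pair)
    uvw = frame.to_frame(pair.points)
    if len(uvw) < 6:
        raise InvalidParameterError("at least 6 interface points are required")
    u, v, w = uvw[:, 0], uvw[:, 1], uvw[:, 2]
    design, terms = _polynomial_design(u, v, degree)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InvalidParameterError(
            "interface points do not span the Voronoi plane; polynomial fit is rank-deficient"
        )
    if degree == 1:
        centroid = uvw.mean(axis=0)
        _, _, vt = np.linalg.svd(uvw - centroid, full_matrices=False)
        normal = vt[-1]
        if normal[2] < 0:
            normal = -normal
        resid = (uvw - centroid) @ normal  # perpendicular residuals
        if abs(normal[2]) > 1e-12:
            c_u, c_v = -normal[0] / normal[2], -normal[1] / normal[2]
            c_0 = centroid[2] + (normal[0] * centroid[0] + normal[1] * centroid[1]) / normal[2]
        else:  # plane contains the Voronoi axis; graph form degenerates
            c_u = c_v = np.inf
            c_0 = np.nan
        coef = np.array([c_0, c_u, c_v])
        cos_angle = abs(normal[2])
    else:
        coef, *_ = np.linalg.lstsq(design, w, rcond=None)
        resid = w - design @ coef
        c_u = coef[terms.index((1, 0))]
        c_v = coef[terms.index((0, 1))]
        c_0 = coef[terms.index((0, 0))]
        # plane w = c0 + cu*u + cv*v has normal (-cu, -cv, 1)/|.| in the frame
        cos_angle = 1.0 / np.sqrt(1.0 + c_u**2 + c_v**2)
    orientation = float(np.degrees(np.arccos(np.clip(cos_angle, -1.0, 1.0))))
    metrics = InterfaceMetrics(
        bias_pct=bias_parameter(pair, frame),
        orientation_deg=orientation,
        plane_coefficients=np.array([c_0, c_u, c_v]),
        residual_rms_um=float(np.sqrt((resid**2).mean())),
        n_points=len(uvw),
    )
    return metrics, coef


def interface_frame(
    frame: VoronoiFrame, plane_coefficients: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the fitted interface plane and its origin.

    Returns ``(basis, origin)`` where ``basis`` rows are (s, t, n): two
    in-plane directions and the unit normal of the interface plane, and
    ``origin`` is the plane's point above the midpoint, all in world
    coordinates.
    """
    c0, cu, cv = np.asarray(plane_coefficients, dtype=float)
    normal_f = np.array([-cu, -cv, 1.0])
    normal_f /= np.linalg.norm(normal_f)
    world = np.stack([frame.u, frame.v, frame.axis], axis=1)
    normal_w = world @ normal_f
    s_w, t_w = _orthonormal_complement(normal_w)
    origin = frame.midpoint + c0 * frame.axis
    return np.stack([s_w, t_w, normal_w]), origin


@dataclass
class BiharmonicSurface:
    """Thin-plate interpolant of interface relief plus sampled maps."""

    interpolant: Callable
    points_st: np.ndarray  # (n, 2) in-plane coordinates
    offsets: np.ndarray  # (n,) normal offsets
    grid_s: np.ndarray
    grid_t: np.ndarray
    amplitude_map: np.ndarray  # NaN outside the footprint
    gradient_map: np.ndarray  # magnitude of the surface slope, NaN outside
    footprint: np.ndarray  # bool

    @property
    def interpolation_residual(self) -> float:
        return float(np.abs(self.interpolant(self.points_st) - self.offsets).max())


def fit_biharmonic(
    points_st: np.ndarray,
    offsets: np.ndarray,
    grid_step: float = 0.5,
    footprint: np.ndarray | None = None,
) -> BiharmonicSurface:
    """Exact thin-plate-spline interpolation of normal offsets over a plane.

    The amplitude map samples the interpolant on a regular (s, t) grid;
    the gradient map is the slope magnitude obtained by central
    differences.  The footprint defaults to the convex hull of the input
    points; a boolean mask over the grid may override it.
    """
    points_st = np.asarray(points_st, dtype=float).reshape(-1, 2)
    offsets = np.asarray(offsets, dtype=float).ravel()
    if len(points_st) < 4:
        raise InvalidParameterError("at least 4 points are required")
    if len(points_st) != len(offsets):
        raise InvalidParameterError("one offset per point is required")
    unique, inverse = np.unique(points_st.round(9), axis=0, return_inverse=True)
    if len(unique) < len(points_st):
        for k in range(len(unique)):
            vals = offsets[inverse == k]
            if np.ptp(vals) > 1e-9:
                raise InvalidParameterError(
                    "duplicate in-plane coordinates with conflicting offsets"
                )
    interp = RBFInterpolator(points_st, offsets, kernel="thin_plate_spline", smoothing=0.0)

    lo, hi = points_st.min(axis=0), points_st.max(axis=0)
    axes = [np.arange(l, h + grid_step / 2.0, grid_step) for l, h in zip(lo, hi)]
    gs, gt = np.meshgrid(axes[0], axes[1], indexing="ij")
    grid = np.stack([gs.ravel(), gt.ravel()], axis=1)

    if footprint is None:
        try:
            hull = Delaunay(points_st)
            inside = hull.find_simplex(grid) >= 0
        except QhullError as exc:
            raise InvalidParameterError("degenerate footprint (collinear points)") from exc
        footprint_mask = inside.reshape(gs.shape)
    else:
        footprint_mask = np.asarray(footprint, dtype=bool)
        if footprint_mask.shape != gs.shape:
            raise InvalidParameterError("footprint mask shape does not match the grid")

    amplitude = np.full(gs.shape, np.nan)
    gradient = np.full(gs.shape, np.nan)
    idx = footprint_mask.ravel()
    if idx.any():
        pts = grid[idx]
        amplitude.ravel()[idx] = interp(pts)
        h = grid_step / 4.0
        dds = (interp(pts + [h, 0.0]) - interp(pts - [h, 0.0])) / (2.0 * h)
        ddt = (interp(pts + [0.0, h]) - interp(pts - [0.0, h])) / (2.0 * h)
        gradient.ravel()[idx] = np.hypot(dds, ddt)
    return BiharmonicSurface(
        interpolant=interp,
        points_st=points_st,
        offsets=offsets,
        grid_s=gs,
        grid_t=gt,
        amplitude_map=amplitude,
        gradient_map=gradient,
        footprint=footprint_mask,
    )


def biharmonic_surface(
    pair: InterfacePair,
    frame: VoronoiFrame | None = None,
    degree: int = 1,
    grid_step: float = 0.5,
    footprint: np.ndarray | None = None,
) -> BiharmonicSurface:
    """Full relief analysis: plane fit, interface frame, thin-plate maps."""
    frame = frame or build_voronoi_frame(pair)
    metrics, coef = fit_interface_plane(pair, frame, degree=1)
    basis, origin = interface_frame(frame, metrics.plane_coefficients)
    local = (pair.points - origin) @ basis.T
    return fit_biharmonic(local[:, :2], local[:, 2], grid_step=grid_step, footprint=footprint)


def analyze_pair(pair: InterfacePair, degree: int = 1) -> InterfaceMetrics:
    """Bias, orientation, and plane-fit residual for one astrocyte pair."""
    frame = build_voronoi_frame(pair)
    metrics, _ = fit_interface_plane(pair, frame, degree=degree)
    return metrics
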