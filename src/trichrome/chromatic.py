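"""Chromatic-shift metrology from bead centroid pairs.

Dual-beam two-photon excitation requires the two foci to coincide in 3D.
Second-harmonic nanocrystals localise both beams at once; the residual
displacement of the second beam's centroid relative to the first, as a
function of field position, characterises the chromatic aberration.  The
lateral components (dX, dY) are fitted with an affine model in the field
coordinates, and the axial component dZ with a polynomial in the radial
coordinate rho = sqrt(x^2 + y^2).  The lateral shift magnitude is
sqrt(dX^2 + dY^2); a quality criterion asks whether it stays below
0.6 µm over an effective sub-field of 350 µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path


import numpy as np
import pandas as pd

from .core import InvalidParameterError

__all__ = [
    "ChromaticShiftModel",
    "LateralFitSummary",
    "fit_lateral_affine",
    "fit_axial_polynomial",
    "shift_magnitude_map",
    "lateral_shift_report",
]

REQUIRED_COLUMNS = ("x", "y", "dx", "dy", "dz")


@dataclass
class ChromaticShiftModel:
    """Affine lateral + radial-polynomial axial chromatic shift model.

    ``lateral`` is a (2, 3) array: row i holds (a_i, b_i, c_i) so that
    shift_i(x, y) = a_i * x + b_i * y + c_i for dX (i = 0) and dY (i = 1).
    ``axial`` holds polynomial coefficients of dZ(rho) in ascending order.
    """

    lateral: np.ndarray = field(default_factory=lambda: np.zeros((2, 3)))
    axial: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        self.lateral = np.asarray(self.lateral, dtype=float)
        self.axial = np.atleast_1d(np.asarray(self.axial, dtype=float))
        if self.lateral.shape != (2, 3):
            raise InvalidParameterError("lateral part must be a (2, 3) coefficient array")

    def lateral_shift(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        dx = self.lateral[0, 0] * x + self.lateral[0, 1] * y + self.lateral[0, 2]
        dy = self.lateral[1, 0] * x + self.lateral[1, 1] * y + self.lateral[1, 2]
        return dx, dy

    def axial_shift(self, x, y) -> np.ndarray:
        rho = np.hypot(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return np.polynomial.polynomial.polyval(rho, self.axial)

    def lateral_magnitude(self, x, y) -> np.ndarray:
        dx, dy = self.lateral_shift(x, y)
        return np.hypot(dx, dy)

    def to_dict(self) -> dict:
        return {"lateral": self.lateral.tolist(), "axial": self.axial.tolist()}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ChromaticShiftModel":
        d = json.loads(Path(path).read_text())
        return cls(lateral=np.array(d["lateral"]), axial=np.array(d["axial"]))


@dataclass
class LateralFitSummary:
    """Residual RMS and per-coefficient standard errors of the affine fit."""

    rms_um: tuple[float, float]
    standard_errors: np.ndarray  # (2, 3), matching the coefficient layout
    n: int


def _check_table(pairs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in pairs.columns]
    if missing:
        raise InvalidParameterError(f"bead table is missing columns {missing}")
    if not np.isfinite(pairs[list(REQUIRED_COLUMNS)].to_numpy()).all():
        raise InvalidParameterError("bead table contains non-finite values")
    return pairs


def fit_lateral_affine(
    pairs: pd.DataFrame,
    reject_outliers: bool = False,
    outlier_rms_factor: float = 3.0,
) -> tuple[ChromaticShiftModel, LateralFitSummary]:
    """Least-squares affine fit of (dX, dY) against field position.

    With ``reject_outliers`` a single pass drops beads whose residual
    exceeds ``outlier_rms_factor`` times the RMS (mislocalised beads) and
    refits.  Raises on collinear bead positions (singular design).
    """
    pairs = _check_table(pairs)
    x = pairs["x"].to_numpy()
    y = pairs["y"].to_numpy()
    targets = pairs[["dx", "dy"]].to_numpy()
    if len(x) < 3:
        raise InvalidParameterError("at least 3 beads are required")

    def _solve(xv, yv, t):
        design = np.column_stack([xv, yv, np.ones_like(xv)])
        if np.linalg.matrix_rank(design) < 3:
            raise InvalidParameterError("bead positions are collinear; affine fit is singular")
        coef, *_ = np.linalg.lstsq(design, t, rcond=None)
        resid = t - design @ coef
        return design, coef, resid

    design, coef, resid = _solve(x, y, targets)
    if reject_outliers:
        rms = np.sqrt((resid**2).mean(axis=0))
        keep = (np.abs(resid) <= outlier_rms_factor * np.maximum(rms, 1e-300)).all(axis=1)
        if keep.sum() >= 3 and not keep.all():
            design, coef, resid = _solve(x[keep], y[keep], targets[keep])
    n = design.shape[0]
    dof = max(n - 3, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))  # (2, 3)
    rms = tuple(float(v) for v in np.sqrt((resid**2).mean(axis=0)))
    model = ChromaticShiftModel(lateral=coef.T)
    return model, LateralFitSummary(rms_um=rms, standard_errors=se, n=n)


def fit_axial_polynomial(
    pairs: pd.DataFrame, degree: int = 2
) -> ChromaticShiftModel:
    """Least-squares polynomial fit of dZ against radial position.

    Degree 2 by default: field curvature is quadratic to leading order.
    """
    pairs = _check_table(pairs)
    if degree < 0:
        raise InvalidParameterError("degree must be non-negative")
    rho = np.hypot(pairs["x"].to_numpy(), pairs["y"].to_numpy())
    if len(np.unique(rho)) < degree + 1:
        raise InvalidParameterError(
            f"need at least {degree + 1} distinct radii for a degree-{degree} fit"
        )
    coef = np.polynomial.polynomial.polyfit(rho, pairs["dz"].to_numpy(), degree)
    return ChromaticShiftModel(axial=coef)


def shift_magnitude_map(
    model: ChromaticShiftModel,
    fov_um: float,
    grid_step_um: float,
    effective_subfield_um: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float | None]:
    """Lateral shift magnitude sqrt(dX^2 + dY^2) over a centred square grid.

    Returns (magnitude map, x grid, y grid, max over the effective
    sub-field) — the last is None when no sub-field is requested.
    """
    if grid_step_um <= 0:
        raise InvalidParameterError("grid step must be positive")
    axis = np.arange(-fov_um / 2.0, fov_um / 2.0 + grid_step_um / 2.0, grid_step_um)
    xg, yg = np.meshgrid(axis, axis)
    mag = model.lateral_magnitude(xg, yg)
    sub_max = None
    if effective_subfield_um is not None:
        half = effective_subfield_um / 2.0
        inside = (np.abs(xg) <= half) & (np.abs(yg) <= half)
        if not inside.any():
            raise InvalidParameterError("effective sub-field smaller than the grid step")
        sub_max = float(mag[inside].max())
    return mag, xg, yg, sub_max


def lateral_shift_report(
    model: ChromaticShiftModel,
    fov_um: float,
    grid_step_um: float = 5.0,
    effective_subfield_um: float = 350.0,
    threshold_um: float = 0.6,
) -> dict:
    """Summarise the lateral shift and flag the sub-field quality criterion.

    The default criterion asks for less than 0.6 µm of colour mismatch
    over a 350 µm effective field of view.
    """
    mag, _, _, sub_max = shift_magnitude_map(
        model, fov_um, grid_step_um, effective_subfield_um
    )
    return {
        "max_shift_um": float(mag.max()),
        "subfield_um": float(effective_subfield_um),
        "subfield_max_shift_um": sub_max,
        "threshold_um": float(threshold_um),
        "meets_criterion": bool(sub_max < threshold_um),
    }
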