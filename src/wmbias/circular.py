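"""Circular arithmetic and densities on a discretized 360-degree stimulus space.

All stimulus, probe and response values live on a circular space measured in
degrees.  Two canonical forms are used throughout the package: *positional*
angles in ``[0, 360)`` and *signed* offsets in ``(-180, 180]`` (ties at the
antipode resolve to +180).  Model densities are probability masses over an
evenly spaced grid — the default grid has 360 points, one per degree,
matching the 360-valued stimulus wheels of the experiments the package
emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidAngleError,
    InvalidParameterError,
    InvalidWindowError,
    UndefinedMeanError,
)

__all__ = [
    "CircularGrid",
    "GridDensity",
    "LabColor",
    "cielab_wheel",
    "circ_mean",
    "signed_circ_dist",
    "smooth_circular",
    "vm_density",
    "vm_product_closed_form",
    "wheel_frame",
    "wrap_positive",
    "wrap_signed",
]

_MASS_TOL = 1e-12


def _check_finite(*values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise InvalidAngleError(f"angle must be finite, got {v!r}")


def wrap_signed(a):
    """Wrap an angle (degrees) into the signed interval ``(-180, 180]``.

    Idempotent, and maps the antipode to +180 so ties at 180 degrees are
    broken deterministically toward the positive side.
    """
    _check_finite(a)
    return 180.0 - np.mod(180.0 - np.asarray(a, dtype=float), 360.0)


def wrap_positive(a):
    """Wrap an angle (degrees) into the positional interval ``[0, 360)``."""
    _check_finite(a)
    return np.mod(np.asarray(a, dtype=float), 360.0)


def signed_circ_dist(a, b):
    """Signed circular distance ``a - b`` in degrees, in ``(-180, 180]``.

    Antisymmetric except at the antipode, where both orders return +180.
    """
    _check_finite(a, b)
    return wrap_signed(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class CircularGrid:
    """Evenly spaced support points on the circle.

    Parameters
    ----------
    n_points
        Number of support points; the resolution is ``360 / n_points``
        degrees per point.  Default 360 (one point per degree).
    """

    n_points: int = 360

    def __post_init__(self):
        if self.n_points < 1:
            raise InvalidParameterError("n_points must be >= 1")

    @property
    def resolution(self) -> float:
        """Degrees per support point; ``n_points * resolution == 360``."""
        return 360.0 / self.n_points

    @property
    def points(self) -> np.ndarray:
        """Support points in degrees, strictly increasing in ``[0, 360)``."""
        return np.arange(self.n_points) * self.resolution

    def nearest_index(self, angle) -> np.ndarray:
        """Index of the grid point nearest to ``angle`` (circularly)."""
        idx = np.rint(wrap_positive(angle) / self.resolution).astype(int)
        return np.mod(idx, self.n_points)


DEFAULT_GRID = CircularGrid(360)


@dataclass(frozen=True)
class GridDensity:
    """A probability mass function over a :class:`CircularGrid`.

    Masses are non-negative and sum to one (within 1e-12); construction from
    unnormalized non-negative weights goes through :meth:`from_weights`.
    """

    grid: CircularGrid
    mass: np.ndarray = field(repr=False)

    def __post_init__(self):
        mass = np.asarray(self.mass, dtype=float)
        if mass.shape != (self.grid.n_points,):
            raise InvalidParameterError(
                f"mass must have shape ({self.grid.n_points},), got {mass.shape}"
            )
        if np.any(mass < 0):
            raise InvalidParameterError("density masses must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("density masses must sum to 1")
        object.__setattr__(self, "mass", mass)

    @classmethod
    def from_weights(cls, grid: CircularGrid, weights) -> "GridDensity":
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise InvalidParameterError("weights must be finite and non-negative")
        total = w.sum()
        if total <= 0:
            raise InvalidParameterError("weights must have positive total mass")
        return cls(grid=grid, mass=w / total)

    def mean(self) -> float:
        """Circular mean in degrees; see :func:`circ_mean`."""
        return circ_mean(self)

    def mode(self) -> float:
        """Grid point (degrees) carrying the largest mass."""
        return float(self.grid.points[int(np.argmax(self.mass))])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` i.i.d. angles (degrees) from the discrete density."""
        if n < 1:
            raise InvalidParameterError("n must be >= 1")
        cdf = np.cumsum(self.mass)
        cdf[-1] = 1.0
        idx = np.searchsorted(cdf, rng.random(n), side="right")
        return self.grid.points[np.minimum(idx, self.grid.n_points - 1)]

    def to_frame(self) -> pd.DataFrame:
        """Export as a two-column table (angle, mass) for plotting."""
        return pd.DataFrame({"angle": self.grid.points, "mass": self.mass})


def vm_density(mu, kappa: float, grid: CircularGrid = DEFAULT_GRID) -> GridDensity:
    """Von Mises probability mass on ``grid``, centred at ``mu`` degrees.

    ``kappa`` is the concentration (higher = more precise memory); ``kappa=0``
    gives the uniform density.  Masses are per grid bin, normalized by the
    discrete sum over the support.
    """
    if not np.isfinite(kappa) or kappa < 0:
        raise InvalidParameterError(f"kappa must be finite and >= 0, got {kappa}")
    _check_finite(mu)
    theta = np.deg2rad(grid.points - wrap_positive(mu))
    # subtract kappa so the exponent peaks at 0 (stable for large kappa)
    w = np.exp(kappa * (np.cos(theta) - 1.0))
    return GridDensity.from_weights(grid, w)


def vm_product_closed_form(mu1, k1: float, mu2, k2: float) -> tuple[float, float]:
    """Parameters of the von Mises proportional to ``vM(mu1,k1) * vM(mu2,k2)``.

    The product of two von Mises densities is itself (up to normalization)
    von Mises, with resultant obtained by adding the two concentration
    vectors.  Returns ``(mu_joint, kappa_joint)`` with ``mu_joint`` in
    ``[0, 360)``.  Serves as the analytic oracle for the grid product.
    """
    for k in (k1, k2):
        if not np.isfinite(k) or k < 0:
            raise InvalidParameterError(f"kappa must be finite and >= 0, got {k}")
    delta = np.deg2rad(signed_circ_dist(mu2, mu1))
    kappa_joint = float(np.sqrt(k1**2 + k2**2 + 2.0 * k1 * k2 * np.cos(delta)))
    shift = np.rad2deg(np.arctan2(k2 * np.sin(delta), k1 + k2 * np.cos(delta)))
    return float(wrap_positive(np.asarray(mu1, dtype=float) + shift)), kappa_joint


def circ_mean(density: GridDensity) -> float:
    """Circular mean of a grid density, in degrees ``[0, 360)``.

    The mean is the argument of the resultant vector ``sum(mass * e^{i
    theta})``; a (near-)zero resultant — e.g. the uniform density — has no
    defined mean and raises :class:`UndefinedMeanError`.
    """
    theta = np.deg2rad(density.grid.points)
    resultant = np.sum(density.mass * np.exp(1j * theta))
    if np.abs(resultant) < 1e-9:
        raise UndefinedMeanError("circular mean undefined: resultant length ~ 0")
    return float(wrap_positive(np.rad2deg(np.angle(resultant))))


def smooth_circular(hist, window: float = 30.0, resolution: float = 1.0) -> np.ndarray:
    """Circular box-filter smoothing of per-bin proportions.

    Each output bin is the mean of the input bins within a ``window``-degree
    span centred on it (circularly wrapped).  Even windows are truncated
    symmetrically with the extra bin on the positive side, so a unit impulse
    at 0 with the default 30-degree window spreads mass 1/30 over offsets
    -15..+14.  The total is preserved.
    """
    hist = np.asarray(hist, dtype=float)
    if window >= 360.0 or window <= 0:
        raise InvalidWindowError(f"window must lie in (0, 360), got {window}")
    w = int(round(window / resolution))
    if w < 1:
        raise InvalidWindowError("window is below one bin at this resolution")
    out = np.zeros_like(hist)
    for j in range(-((w - 1) // 2), w // 2 + 1):
        out += np.roll(hist, -j)
    return out / w


class LabColor(NamedTuple):
    """A CIE L*a*b* color (lightness, green-red, blue-yellow)."""

    L: float
    a: float
    b: float


def cielab_wheel(
    n: int = 360,
    a0: float = 20.0,
    b0: float = 38.0,
    radius: float = 60.0,
    L: float = 70.0,
) -> list[LabColor]:
    """Equiluminant color wheel sampled on a circle in CIE L*a*b* space.

    ``n`` equally spaced hue angles on the circle of the given radius centred
    at ``(a0, b0)`` in the a*-b* plane, all at lightness ``L``.  Index 0 sits
    at phase 0 (the a* axis); phase and direction are conventions with no
    effect on any downstream analysis.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if radius <= 0:
        raise InvalidParameterError("radius must be > 0")
    theta = 2.0 * np.pi * np.arange(n) / n
    return [
        LabColor(L=float(L), a=float(a0 + radius * c), b=float(b0 + radius * s))
        for c, s in zip(np.cos(theta), np.sin(theta))
    ]


def wheel_frame(colors: list[LabColor] | None = None) -> pd.DataFrame:
    """Color wheel as a table with columns index, L, a, b (CSV-ready)."""
    if colors is None:
        colors = cielab_wheel()
    return pd.DataFrame(
        {
            "index": np.arange(len(colors)),
            "L": [c.L for c in colors],
            "a": [c.a for c in colors],
            "b": [c.b for c in colors],
        }
    )
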