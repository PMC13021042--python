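"""Representational observer models for continuous-report working memory.

Three accounts of how a memory report is generated after a perceptual
comparison:

* the *standard WM* baseline — a von Mises centred on the target plus a
  uniform guessing component (the classic delayed-estimation mixture);
* the *joint-density* model — when a probe is judged similar, the memory and
  probe von Mises representations are integrated by normalized pointwise
  multiplication, shifting the density's peak toward the probe (cue
  integration);
* the *mixture-density* model — reports come from the intact memory density
  with probability ``alpha`` and from the probe density otherwise (swap
  errors), skewing the response distribution without moving its peak.

All densities are masses over a discretized circular grid; the closed-form
von Mises product lives in :mod:`wmbias.circular` and is used only as a test
oracle for the grid computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import (
    DEFAULT_GRID,
    CircularGrid,
    GridDensity,
    circ_mean,
    signed_circ_dist,
    vm_density,
)
from .exceptions import InvalidParameterError

__all__ = [
    "JointParams",
    "MemoryRep",
    "MixtureParams",
    "ProbeRep",
    "StandardWMParams",
    "joint_density",
    "mixture_density",
    "model_bias",
    "sample_response",
    "standard_wm_density",
]


def _check_kappa(kappa: float, name: str) -> None:
    if not np.isfinite(kappa) or kappa < 0:
        raise InvalidParameterError(f"{name} must be finite and >= 0, got {kappa}")


def _check_unit(p: float, name: str) -> None:
    if not np.isfinite(p) or not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class MemoryRep:
    """Noisy memory representation: target angle ``s_m`` with precision ``kappa_m``."""

    s_m: float
    kappa_m: float

    def __post_init__(self):
        _check_kappa(self.kappa_m, "kappa_m")


@dataclass(frozen=True)
class ProbeRep:
    """Noisy probe representation: probe angle ``s_p`` with precision ``kappa_p``."""

    s_p: float
    kappa_p: float

    def __post_init__(self):
        _check_kappa(self.kappa_p, "kappa_p")


@dataclass(frozen=True)
class StandardWMParams:
    """Delayed-estimation mixture: von Mises precision plus uniform guess rate."""

    kappa: float
    guess_rate: float = 0.0

    def __post_init__(self):
        _check_kappa(self.kappa, "kappa")
        _check_unit(self.guess_rate, "guess_rate")


@dataclass(frozen=True)
class MixtureParams:
    """Swap-mixture parameters: ``alpha`` = proportion of memory-based reports."""

    alpha: float
    kappa_p: float

    def __post_init__(self):
        _check_unit(self.alpha, "alpha")
        _check_kappa(self.kappa_p, "kappa_p")


@dataclass(frozen=True)
class JointParams:
    """Joint-density model's single free parameter: probe precision ``kappa_p``."""

    kappa_p: float

    def __post_init__(self):
        _check_kappa(self.kappa_p, "kappa_p")


def standard_wm_density(
    params: StandardWMParams, s_m, grid: CircularGrid = DEFAULT_GRID
) -> GridDensity:
    """Baseline response density: ``(1-g) vM(s_m, kappa) + g * uniform``."""
    vm = vm_density(s_m, params.kappa, grid)
    g = params.guess_rate
    mass = (1.0 - g) * vm.mass + g / grid.n_points
    return GridDensity.from_weights(grid, mass)


def joint_density(
    mem: MemoryRep, probe: ProbeRep, grid: CircularGrid = DEFAULT_GRID
) -> GridDensity:
    """Integrated memory-probe density: normalized pointwise product.

    Computed literally as the renormalized product of the two grid von Mises
    masses.  With both concentrations zero the result is uniform (allowed).
    """
    m = vm_density(mem.s_m, mem.kappa_m, grid)
    p = vm_density(probe.s_p, probe.kappa_p, grid)
    return GridDensity.from_weights(grid, m.mass * p.mass)


def mixture_density(
    mem: MemoryRep,
    probe: ProbeRep,
    alpha: float,
    grid: CircularGrid = DEFAULT_GRID,
) -> GridDensity:
    """Swap-mixture density: ``alpha vM(s_m, kappa_m) + (1-alpha) vM(s_p, kappa_p)``."""
    _check_unit(alpha, "alpha")
    m = vm_density(mem.s_m, mem.kappa_m, grid)
    p = vm_density(probe.s_p, probe.kappa_p, grid)
    return GridDensity.from_weights(grid, alpha * m.mass + (1.0 - alpha) * p.mass)


def model_bias(density: GridDensity, s_m, s_p) -> float:
    """Displacement of the density's circular mean from the target, in degrees.

    Positive values indicate displacement toward the probe ``s_p``; for the
    joint density this equals ``atan2(kP sin d, kM + kP cos d)`` with ``d``
    the memory-probe distance.  With the probe at the target the direction is
    degenerate and the raw signed offset is returned (zero for symmetric
    densities).  An undefined circular mean propagates.
    """
    toward = float(signed_circ_dist(s_p, s_m))
    offset = float(signed_circ_dist(circ_mean(density), s_m))
    return offset if toward == 0.0 else offset * float(np.sign(toward))


def sample_response(
    density: GridDensity, rng: np.random.Generator | int, n: int
) -> np.ndarray:
    """Draw ``n`` i.i.d. response angles from a discrete response density."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return density.sample(rng, n)
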