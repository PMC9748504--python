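"""Alignment-derived constants of the continuum model.

In the fast-alignment regime the orientational degrees of freedom of the
Vicsek dynamics equilibrate to a von Mises distribution

    ``m(theta) = exp(cos(theta) / r) / Z``,   ``r = ds / nu``,

on ``[0, 2pi)``.  The continuum transport speeds are ``d_i = u0 c_i`` with

* ``c1``: first angular moment ``int cos(theta) m(theta) dtheta`` (equal to
  the Bessel ratio ``I1(1/r) / I0(1/r)``, used as an independent oracle in
  the tests);
* ``c2``: ratio of two quadratures weighted by the generalised collision
  invariant ``h = g / sin(theta)``, where ``g`` solves the two-point
  boundary-value problem ``g'' + (1/r) sin(theta) g' = sin(theta)`` on
  ``[0, pi]`` with ``g(0) = g(pi) = 0``;
* ``c3 = r`` exactly.

The orientational viscosity is ``gamma_s = (rA^2 / 8) (r + c2)``.

All quadratures use the overflow-safe weight ``exp((cos(theta) - 1) / r)``
(the normaliser cancels wherever a ratio is taken), so ratios down to the
hard floor ``r >= 1e-4`` are handled in double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import simpson
from scipy.linalg import solve_banded

__all__ = [
    "AlignmentConstants",
    "von_mises_m",
    "compute_c1",
    "solve_h",
    "compute_c2",
    "compute_gamma_s",
    "compute_di",
    "compute_constants",
]

#: below this ratio the boundary layers of m and h are too thin for the
#: default grids; callers should switch to the concentrated asymptotics
#: c1, c2 -> 1.
MIN_RATIO = 1e-4

_DEFAULT_GRID = 8001


def _check_ratio(ratio: float) -> float:
    ratio = float(ratio)
    if not (np.isfinite(ratio) and ratio > 0):
        raise ValueError(f"ratio ds/nu must be strictly positive, got {ratio}")
    if ratio < MIN_RATIO:
        raise ValueError(
            f"ratio ds/nu = {ratio} below {MIN_RATIO}: the von Mises weight is "
            "too concentrated for the quadrature grids; use the asymptotic "
            "values c1 = c2 = 1 for this overflow regime"
        )
    return ratio


def _weight(theta: np.ndarray, ratio: float) -> np.ndarray:
    """Unnormalised von Mises weight exp((cos(theta) - 1)/ratio), max 1."""
    return np.exp((np.cos(theta) - 1.0) / ratio)


def von_mises_m(theta, ratio: float):
    """von Mises density ``m(theta) = exp(cos(theta)/ratio)/Z`` on [0, 2pi)."""
    ratio = _check_ratio(ratio)
    theta = np.asarray(theta, dtype=float)
    grid = np.linspace(0.0, 2.0 * math.pi, 20001)
    z_shifted = simpson(_weight(grid, ratio), x=grid)
    return _weight(theta, ratio) / z_shifted


def compute_c1(ratio: float, *, n_grid: int = 20001) -> float:
    """First angular moment ``c1 = int_0^{2pi} cos(theta) m(theta) dtheta``."""
    ratio = _check_ratio(ratio)
    theta = np.linspace(0.0, 2.0 * math.pi, n_grid)
    w = _weight(theta, ratio)
    return float(simpson(np.cos(theta) * w, x=theta) / simpson(w, x=theta))


def solve_h(ratio: float, n_grid: int = _DEFAULT_GRID):
    """Solve the auxiliary BVP and return ``(theta, g, h)`` on ``[0, pi]``.

    ``g'' + (1/ratio) sin(theta) g' = sin(theta)``, ``g(0) = g(pi) = 0``,
    discretised with second-order central differences on a uniform grid and
    solved as a tridiagonal system; ``h = g / sin(theta)`` with endpoint
    values by L'Hopital (``h(0) = g'(0)``, ``h(pi) = -g'(pi)``, one-sided
    second-order differences).

    Any bounded ``h`` forces ``g`` to vanish where ``sin(theta)`` does,
    which fixes the homogeneous boundary conditions.
    """
    ratio = _check_ratio(ratio)
    if n_grid < 200:
        raise ValueError("n_grid must be >= 200 to resolve the boundary layer")
    theta = np.linspace(0.0, math.pi, n_grid)
    dth = theta[1] - theta[0]
    s = np.sin(theta[1:-1])
    adv = s / (ratio * 2.0 * dth)
    # rows: upper, main, lower diagonals for solve_banded
    n = n_grid - 2
    ab = np.zeros((3, n))
    ab[0, 1:] = 1.0 / dth**2 + adv[:-1]          # superdiagonal
    ab[1, :] = -2.0 / dth**2                     # diagonal
    ab[2, :-1] = 1.0 / dth**2 - adv[1:]          # subdiagonal
    g_int = solve_banded((1, 1), ab, s)
    if not np.all(np.isfinite(g_int)):
        raise RuntimeError(
            "singular tridiagonal solve: grid too coarse for this ratio"
        )
    g = np.zeros(n_grid)
    g[1:-1] = g_int

    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(np.abs(np.sin(theta)) > 1e-12, g / np.sin(theta), 0.0)
    h[0] = (-3.0 * g[0] + 4.0 * g[1] - g[2]) / (2.0 * dth)
    h[-1] = -(3.0 * g[-1] - 4.0 * g[-2] + g[-3]) / (2.0 * dth)
    return theta, g, h


def compute_c2(ratio: float, *, n_grid: int = _DEFAULT_GRID) -> float:
    """``c2``: ratio of the two ``h``-weighted quadratures on ``[0, pi]``.

    ``c2 = int sin^2 cos m h / int sin^2 m h``; the von Mises normaliser
    cancels, so the unnormalised overflow-safe weight is used directly.
    """
    ratio = _check_ratio(ratio)
    theta, _, h = solve_h(ratio, n_grid)
    w = _weight(theta, ratio) * np.sin(theta) ** 2 * h
    num = simpson(np.cos(theta) * w, x=theta)
    den = simpson(w, x=theta)
    return float(num / den)


def compute_gamma_s(rA: float, ratio: float, *, n_grid: int = _DEFAULT_GRID) -> float:
    """Orientational viscosity ``gamma_s = (rA^2/8)(ds/nu + c2)``."""
    return rA**2 / 8.0 * (ratio + compute_c2(ratio, n_grid=n_grid))


def compute_di(ratio: float, u0: float, *, n_grid: int = _DEFAULT_GRID):
    """Drift coefficients ``(d1, d2, d3) = u0 (c1, c2, c3)`` with ``c3 = ratio``."""
    return (u0 * compute_c1(ratio), u0 * compute_c2(ratio, n_grid=n_grid), u0 * ratio)


@dataclass(frozen=True)
class AlignmentConstants:
    """Bundle of the alignment-derived constants for one ``ds/nu`` ratio.

    ``Z`` is the numerically safe normaliser of the shifted weight
    ``exp((cos(theta)-1)/ratio)``; the textbook normaliser is
    ``Z * exp(1/ratio)``.
    """

    ratio: float
    c1: float
    c2: float
    c3: float
    d1: float
    d2: float
    d3: float
    gamma_s: float
    Z: float

    def __post_init__(self):
        if not (0.0 < self.c1 < 1.0):
            raise ValueError(f"c1 out of (0, 1): {self.c1}")
        if self.gamma_s <= 0:
            raise ValueError(f"gamma_s must be positive: {self.gamma_s}")


@lru_cache(maxsize=64)
def compute_constants(ratio: float, u0: float = 1.0, rA: float = 0.15,
                      n_grid: int = _DEFAULT_GRID) -> AlignmentConstants:
    """Compute and cache all alignment constants for a given ratio."""
    ratio = _check_ratio(ratio)
    theta = np.linspace(0.0, 2.0 * math.pi, 20001)
    z_shifted = float(simpson(_weight(theta, ratio), x=theta))
    c1 = compute_c1(ratio)
    c2 = compute_c2(ratio, n_grid=n_grid)
    return AlignmentConstants(
        ratio=ratio,
        c1=c1,
        c2=c2,
        c3=ratio,
        d1=u0 * c1,
        d2=u0 * c2,
        d3=u0 * ratio,
        gamma_s=rA**2 / 8.0 * (ratio + c2),
        Z=z_shifted,
    )
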