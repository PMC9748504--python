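"""Model parameters and interaction kernels.

The model couples ``M`` self-propelled agents (Vicsek-type alignment plus
short-range repulsion) to ``N`` passive obstacles tethered to fixed anchors
by Hookean springs, on the periodic square ``[0, L)^2``.  Two compactly
supported radial kernels mediate the repulsion forces:

* agent-agent:      ``psi(r) = (6 mu / (pi rR^2)) (1 - r/rR)_+^2``
* agent-obstacle:   ``phi(r) = (3 Cphi / (2 pi tau)) (1 - r/tau)_+^2``

The normalisations are chosen so that ``integral psi = mu`` and
``integral |grad phi| = Cphi``.  The module also provides the radial
(order-zero Hankel) Fourier transform ``phi_hat`` of ``phi``, the constant

    ``c0 = max_{z>0} z^2 phi_hat(z)^2``,

which controls linear stability of uniform states, and the bifurcation
parameter ``b_p = mu kappa / c0``: uniform agent/obstacle distributions are
linearly unstable exactly when ``b_p < 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import j0, roots_legendre

__all__ = [
    "ModelParams",
    "psi_eval",
    "psi_grad",
    "phi_eval",
    "phi_grad",
    "phi_hat",
    "C0Result",
    "compute_c0",
    "compute_bp",
    "read_config",
    "write_config",
]


@dataclass(frozen=True)
class ModelParams:
    """All physical constants of the discrete and continuum levels.

    Lengths are in units of the domain edge ``L`` (default 1); rates in
    inverse time units of the agent speed ``u0`` over ``L``.

    Parameters
    ----------
    N, M : int
        Number of obstacles and agents (discrete level only).
    u0 : float
        Agent self-propulsion speed.
    rR : float
        Agent-agent repulsion radius (support of ``psi``).
    rA : float
        Agent-agent alignment radius.
    nu : float
        Alignment relaxation rate.
    ds : float
        Orientational noise intensity.
    d0 : float
        Obstacle positional noise intensity (may be zero).
    tau : float
        Agent-obstacle repulsion radius (support of ``phi``).
    Cphi : float
        Agent-obstacle repulsion intensity, ``integral |grad phi| = Cphi``.
    mu : float
        Agent-agent repulsion intensity, ``integral psi = mu``.
    zeta : float
        Agent friction coefficient.
    eta : float
        Obstacle friction coefficient.
    kappa : float
        Obstacle tether (spring) stiffness.
    L : float
        Periodic domain edge length.
    rhoA : float
        Anchor density (constant, 1 in all reference runs).
    rho0 : float
        Reference uniform agent density.
    """

    N: int = 3000
    M: int = 3000
    u0: float = 1.0
    rR: float = 0.075
    rA: float = 0.1
    nu: float = 2.0
    ds: float = 0.02
    d0: float = 0.0
    tau: float = 0.15
    Cphi: float = 5.0
    mu: float = 2e-3
    zeta: float = 0.5
    eta: float = 1.0
    kappa: float = 100.0
    L: float = 1.0
    rhoA: float = 1.0
    rho0: float = 1.0

    def __post_init__(self) -> None:
        positive = ("u0", "rR", "rA", "nu", "ds", "tau", "Cphi", "mu",
                    "zeta", "eta", "kappa", "L")
        for name in positive:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name!r} must be strictly positive, got {v}")
        if self.d0 < 0:
            raise ValueError(f"d0 must be nonnegative, got {self.d0}")
        if self.N < 0 or self.M < 0:
            raise ValueError("N and M must be nonnegative integers")
        for name in ("rR", "rA", "tau"):
            if getattr(self, name) >= self.L / 2:
                raise ValueError(
                    f"{name} must be < L/2 for the minimum-image convention "
                    f"to be well defined (got {getattr(self, name)} with L={self.L})"
                )

    # -- derived ratios ----------------------------------------------------
    @property
    def gamma(self) -> float:
        """Stiffness ratio ``eta / kappa`` (small in the stiff-spring regime)."""
        return self.eta / self.kappa

    @property
    def delta(self) -> float:
        """Obstacle-noise ratio ``d0 / gamma`` (small in the low-noise regime)."""
        return self.d0 / self.gamma

    @property
    def ratio(self) -> float:
        """Noise-to-alignment ratio ``ds / nu`` feeding the alignment constants."""
        return self.ds / self.nu

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Repulsion kernels
# ---------------------------------------------------------------------------

def _check_r(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be nonnegative")
    return r


def psi_eval(r, params: ModelParams):
    """Agent-agent repulsion kernel ``psi(r)``; zero for ``r >= rR``."""
    r = _check_r(r)
    s = np.clip(1.0 - r / params.rR, 0.0, None)
    return (6.0 * params.mu / (math.pi * params.rR**2)) * s * s


def psi_grad(x, params: ModelParams):
    """Gradient of ``psi`` at the 2-vector(s) ``x`` (zero at the origin)."""
    return _radial_grad(x, params.rR, 12.0 * params.mu / (math.pi * params.rR**3))


def phi_eval(r, params: ModelParams):
    """Agent-obstacle repulsion kernel ``phi(r)``; zero for ``r >= tau``."""
    r = _check_r(r)
    s = np.clip(1.0 - r / params.tau, 0.0, None)
    return (3.0 * params.Cphi / (2.0 * math.pi * params.tau)) * s * s


def phi_grad(x, params: ModelParams):
    """Gradient of ``phi`` at the 2-vector(s) ``x`` (zero at the origin)."""
    return _radial_grad(x, params.tau, 3.0 * params.Cphi / (math.pi * params.tau**2))


def _radial_grad(x, radius: float, amplitude: float) -> np.ndarray:
    # Both kernels have the form A (1 - r/R)_+^2, so the gradient is
    # -2A/R (1 - r/R)_+ x/|x|; at x = 0 two coincident points exert no net
    # directed force and the gradient is defined as the zero vector.
    x = np.asarray(x, dtype=float)
    r = np.sqrt(np.sum(x * x, axis=-1, keepdims=True))
    s = np.clip(1.0 - r / radius, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r > 0, x / np.where(r > 0, r, 1.0), 0.0)
    return -amplitude * s * unit


# ---------------------------------------------------------------------------
# Radial Fourier transform of phi and the bifurcation constants
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _gl_nodes(n: int):
    x, w = roots_legendre(n)
    return x, w


def phi_hat(z, params: ModelParams, *, n_quad: int = 240):
    """Radial Fourier transform ``phi_hat(z) = 2 pi int_0^tau J0(z r) phi(r) r dr``.

    With the convention ``phi_hat(k) = int exp(-i k.x) phi(x) dx`` the
    transform of a rotationally invariant kernel is real and depends on
    ``|k|`` only; it is computed by Gauss-Legendre quadrature on the compact
    support ``[0, tau]``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("radial wavenumber z must be nonnegative")
    xg, wg = _gl_nodes(n_quad)
    r = 0.5 * params.tau * (xg + 1.0)           # nodes on (0, tau)
    w = 0.5 * params.tau * wg
    fr = phi_eval(r, params) * r * w            # (n_quad,)
    zr = np.multiply.outer(z, r)                # (..., n_quad)
    return 2.0 * math.pi * np.sum(j0(zr) * fr, axis=-1)


@dataclass(frozen=True)
class C0Result:
    """Result of the ``c0`` maximisation."""

    c0: float            #: max over z > 0 of z^2 phi_hat(z)^2
    z_star: float        #: maximising wavenumber
    c0_prime: float      #: c0 / Cphi^2, independent of tau and Cphi


def compute_c0(params: ModelParams, *, n_scan: int = 2000) -> C0Result:
    """Maximise ``z^2 phi_hat(z)^2`` over ``z > 0``.

    Scans ``z in (0, 40/tau]`` (the first lobe of the oscillatory-decaying
    integrand contains the global maximum for this kernel family) and
    refines the bracketed maximum with bounded scalar minimisation.
    """
    z_hi = 40.0 / params.tau
    zs = np.linspace(z_hi / n_scan, z_hi, n_scan)
    vals = zs**2 * phi_hat(zs, params) ** 2
    i = int(np.argmax(vals))
    if i == 0 or i == n_scan - 1:
        raise RuntimeError(
            "scan bracket (0, 40/tau] does not contain an interior maximum "
            "of z^2 phi_hat(z)^2"
        )

    def neg(z):
        return -(z**2 * phi_hat(float(z), params) ** 2)

    res = minimize_scalar(neg, bounds=(zs[i - 1], zs[i + 1]), method="bounded",
                          options={"xatol": 1e-10})
    c0 = float(-res.fun)
    return C0Result(c0=c0, z_star=float(res.x), c0_prime=c0 / params.Cphi**2)


def compute_bp(params: ModelParams) -> float:
    """Bifurcation parameter ``b_p = mu kappa / (Cphi^2 c0') = mu kappa / c0``.

    Uniform states are linearly unstable iff ``b_p < 1``.  ``mu = 0`` is
    admitted here (limit value 0) even though ``ModelParams`` requires a
    strictly positive ``mu`` for simulations.
    """
    return params.mu * params.kappa / compute_c0(params).c0


# ---------------------------------------------------------------------------
# Flat key = value configuration files (names as in the reference tables)
# ---------------------------------------------------------------------------

_INT_KEYS = {"N", "M"}


def read_config(path) -> ModelParams:
    """Read a flat ``key = value`` text config into :class:`ModelParams`.

    Unknown keys are rejected; missing keys keep their defaults.  Lines that
    are blank or start with ``#`` are ignored.
    """
    known = {f.name for f in fields(ModelParams)}
    kw: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        kw[key] = int(float(val)) if key in _INT_KEYS else float(val)
    return ModelParams(**kw)


def write_config(params: ModelParams, path) -> None:
    """Write ``params`` as a flat ``key = value`` text file."""
    lines = [f"{f.name} = {getattr(params, f.name)}" for f in fields(ModelParams)]
    Path(path).write_text("\n".join(lines) + "\n")
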