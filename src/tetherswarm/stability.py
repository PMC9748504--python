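"""Linear stability of uniform states of the continuum model.

Plane-wave perturbations ``exp(i k.x + alpha t)`` of the uniform state
``(rho0, Omega0)`` obey dispersion relations that factor through

    ``F(z) = (z^2 rho0 / zeta) (z^2 phi_hat(z)^2 / kappa - mu)``
    ``G(z) = 1 + (rho0 eta / (kappa^2 zeta)) z^4 phi_hat(z)^2  (>= 1)``

evaluated at ``z = |k|``.  Writing ``k0 = k.Omega0`` and ``k1 = k.Omega0_perp``,
the growth rates are the roots of

    ``(G alpha - F + i d1 k0)(alpha + i d2 k0 + |k|^2 gamma_s) + d1 d3 k1^2 = 0``.

For ``k1 = 0`` the two factors give the roots separately; for ``k1 != 0``
the quadratic is solved with a numerically stable formula.  A Routh-Hurwitz
criterion for quadratics with complex coefficients gives an algebraic
stability test equivalent to ``max Re(alpha) < 0``.

The uniform state is unstable iff ``exists z > 0: z^2 phi_hat(z)^2 > mu kappa``,
i.e. iff the bifurcation parameter ``b_p = mu kappa / c0`` is below 1.
Maximising ``Re alpha`` along ``Omega0`` and ``Omega0_perp`` yields the
predicted pattern sizes ``S_i = 2 pi / |k_i|`` in the two directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .alignment import AlignmentConstants, compute_constants
from .params import ModelParams, compute_c0, phi_hat

__all__ = [
    "DispersionInput",
    "PatternPrediction",
    "F_of",
    "G_of",
    "dispersion_roots",
    "routh_hurwitz_stable",
    "is_linearly_unstable",
    "max_growth_rate",
    "critical_bp",
    "pattern_prediction",
]

OMEGA0_DEFAULT = (math.cos(math.pi / 4), math.sin(math.pi / 4))


def F_of(z, params: ModelParams):
    """``F(z) = (z^2 rho0/zeta)(z^2 phi_hat(z)^2/kappa - mu)``; sign of the
    pressure-vs-obstacle-feedback balance at wavenumber ``z``."""
    z = np.asarray(z, dtype=float)
    ph = phi_hat(z, params)
    return z**2 * params.rho0 / params.zeta * (z**2 * ph**2 / params.kappa - params.mu)


def G_of(z, params: ModelParams):
    """``G(z) = 1 + (rho0 eta/(kappa^2 zeta)) z^4 phi_hat(z)^2 >= 1``; inertia
    of the delayed obstacle response."""
    z = np.asarray(z, dtype=float)
    ph = phi_hat(z, params)
    return 1.0 + params.rho0 * params.eta / (params.kappa**2 * params.zeta) * z**4 * ph**2


@dataclass(frozen=True)
class DispersionInput:
    """Wavevector decomposed along the reference direction ``Omega0``."""

    k: np.ndarray          #: 2-vector wavevector
    k0: float              #: k . Omega0
    k1: float              #: k . Omega0_perp
    rho0: float = 1.0
    Omega0: tuple = OMEGA0_DEFAULT

    @classmethod
    def from_k(cls, k, Omega0=OMEGA0_DEFAULT, rho0: float = 1.0) -> "DispersionInput":
        k = np.asarray(k, dtype=float)
        om = np.asarray(Omega0, dtype=float)
        om = om / np.linalg.norm(om)
        om_perp = np.array([-om[1], om[0]])
        return cls(k=k, k0=float(k @ om), k1=float(k @ om_perp),
                   rho0=rho0, Omega0=(om[0], om[1]))


def _constants(params: ModelParams) -> AlignmentConstants:
    return compute_constants(params.ratio, params.u0, params.rA)


def _quadratic_coeffs(disp: DispersionInput, params: ModelParams,
                      consts: Optional[AlignmentConstants] = None):
    """Coefficients (a, b, c) of the dispersion quadratic a alpha^2 + b alpha + c,
    obtained by expanding the factored determinant."""
    c = consts or _constants(params)
    kn = math.hypot(disp.k0, disp.k1)
    p = params if params.rho0 == disp.rho0 else params.replace(rho0=disp.rho0)
    F = float(F_of(kn, p))
    G = float(G_of(kn, p))
    s = kn**2 * c.gamma_s
    a = G
    b = complex(G * s - F, disp.k0 * (G * c.d2 + c.d1))
    cc = complex(c.d1 * c.d3 * disp.k1**2 - F * s - c.d1 * c.d2 * disp.k0**2,
                 disp.k0 * (c.d1 * s - c.d2 * F))
    return a, b, cc, F, G, s


def dispersion_roots(disp: DispersionInput, params: ModelParams):
    """Complex growth rates ``alpha`` for the wavevector in ``disp``.

    Returns ``[alpha1, alpha2]``: for ``k1 = 0`` these are the two factored
    roots (density-only and orientation-only branches); for ``k1 != 0`` the
    two roots of the coupled quadratic, larger real part first.
    """
    kn = math.hypot(disp.k0, disp.k1)
    if kn == 0.0:
        raise ValueError("|k| = 0 has no dispersion relation")
    c = _constants(params)
    if abs(disp.k1) < 1e-12 * kn:
        p = params if params.rho0 == disp.rho0 else params.replace(rho0=disp.rho0)
        F = float(F_of(kn, p))
        G = float(G_of(kn, p))
        a1 = complex(F, -c.d1 * disp.k0) / G
        a2 = complex(-(kn**2) * c.gamma_s, -c.d2 * disp.k0)
        return [a1, a2]
    a, b, cc, *_ = _quadratic_coeffs(disp, params, c)
    # stable quadratic formula: avoid cancellation in -b +/- sqrt(disc)
    disc = np.sqrt(complex(b * b - 4.0 * a * cc))
    q = -0.5 * (b + disc) if (b.conjugate() * disc).real >= 0 else -0.5 * (b - disc)
    if q == 0:  # b = c = 0
        roots = [0.0 + 0.0j, 0.0 + 0.0j]
    else:
        roots = [q / a, cc / q]
    return sorted(roots, key=lambda r: -r.real)


def routh_hurwitz_stable(disp: DispersionInput, params: ModelParams) -> bool:
    """Algebraic stability test: both inequalities must hold.

    ``G |k|^2 gamma_s - F > 0`` and
    ``H = (G|k|^2 gamma_s - F)^2 d1 d3 k1^2
         - gamma_s F |k|^2 [ (d1 - d2 G)^2 k0^2 + (G|k|^2 gamma_s - F)^2 ] > 0``.

    Equivalent to all dispersion roots having negative real part (the root
    oracle in the tests checks this on random draws).
    """
    c = _constants(params)
    kn2 = disp.k0**2 + disp.k1**2
    kn = math.sqrt(kn2)
    p = params if params.rho0 == disp.rho0 else params.replace(rho0=disp.rho0)
    F = float(F_of(kn, p))
    G = float(G_of(kn, p))
    s = kn2 * c.gamma_s
    A1 = G * s - F
    if not A1 > 0:
        return False
    if abs(disp.k1) < 1e-12 * kn:
        # factored roots: the density branch is stable iff F < 0
        return F < 0
    H = (A1**2 * c.d1 * c.d3 * disp.k1**2
         - c.gamma_s * F * kn2 * ((c.d1 - c.d2 * G) ** 2 * disp.k0**2 + A1**2))
    return H > 0


def is_linearly_unstable(params: ModelParams):
    """Instability of the uniform state: ``(unstable?, witness wavenumber)``.

    Unstable iff ``c0 > mu kappa`` (i.e. ``b_p < 1``); the witness is the
    ``c0`` maximiser, at which ``F > 0`` whenever the condition holds.
    """
    res = compute_c0(params)
    return res.c0 > params.mu * params.kappa, res.z_star


@dataclass(frozen=True)
class PatternPrediction:
    """Predicted pattern sizes and maximal growth rates in both directions.

    ``None`` entries mean no positive growth exists along that direction;
    e.g. travelling bands have ``S1_th > 0`` with ``S2_th`` absent.
    """

    k_par_th: Optional[float]
    k_perp_th: Optional[float]
    S1_th: Optional[float]
    S2_th: Optional[float]
    alpha_max_par: float
    alpha_max_perp: float


def _scan_max(fun, z_hi: float, n_scan: int) -> tuple[float, float]:
    zs = np.linspace(z_hi / n_scan, z_hi, n_scan)
    vals = np.array([fun(z) for z in zs])
    i = int(np.argmax(vals))
    lo = zs[max(i - 1, 0)]
    hi = zs[min(i + 1, n_scan - 1)]
    res = minimize_scalar(lambda z: -fun(z), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9})
    return float(res.x), float(-res.fun)


def max_growth_rate(params: ModelParams, Omega0=OMEGA0_DEFAULT,
                    *, n_scan: int = 1000) -> float:
    """Max over both scan directions of ``Re alpha``; sign decides stability."""
    pred = pattern_prediction(params, Omega0, n_scan=n_scan)
    return max(pred.alpha_max_par, pred.alpha_max_perp)


def pattern_prediction(params: ModelParams, Omega0=OMEGA0_DEFAULT,
                       *, n_scan: int = 4000, z_hi: Optional[float] = None
                       ) -> PatternPrediction:
    """Maximise ``Re alpha`` over continuous wavenumbers along ``Omega0``
    (density branch) and ``Omega0_perp`` (coupled branch).

    Scans ``z in (0, 40/tau]`` with local refinement, matching the ``c0``
    maximiser support.  A direction is reported absent when its maximal
    growth rate is not positive.
    """
    om = np.asarray(Omega0, dtype=float)
    om = om / np.linalg.norm(om)
    om_perp = np.array([-om[1], om[0]])
    z_hi = z_hi or 40.0 / params.tau
    c = _constants(params)

    def re_par(z):
        return float(F_of(z, params)) / float(G_of(z, params))

    def re_perp(z):
        disp = DispersionInput.from_k(z * om_perp, Omega0=om, rho0=params.rho0)
        return dispersion_roots(disp, params)[0].real

    z_par, a_par = _scan_max(re_par, z_hi, n_scan)
    z_perp, a_perp = _scan_max(re_perp, z_hi, n_scan)
    has_par = a_par > 0.0
    has_perp = a_perp > 0.0
    return PatternPrediction(
        k_par_th=z_par if has_par else None,
        k_perp_th=z_perp if has_perp else None,
        S1_th=2.0 * math.pi / z_par if has_par else None,
        S2_th=2.0 * math.pi / z_perp if has_perp else None,
        alpha_max_par=a_par,
        alpha_max_perp=a_perp,
    )


def critical_bp(params: ModelParams, *, n_scan: int = 800,
                rtol: float = 1e-4) -> float:
    """Locate the instability threshold by bisection on ``mu`` at fixed
    ``kappa`` and return the bifurcation parameter ``b_p`` at the crossing.

    Uses the sign of the maximal growth rate from the dispersion scan; the
    predicted crossing is at ``b_p = 1``.
    """
    c0 = compute_c0(params).c0
    mu_guess = c0 / params.kappa

    def sgn(mu):
        return max_growth_rate(params.replace(mu=mu), n_scan=n_scan)

    lo, hi = 0.5 * mu_guess, 1.5 * mu_guess
    if not (sgn(lo) > 0 and sgn(hi) < 0):
        raise RuntimeError("bisection bracket does not straddle the threshold")
    mu_star = brentq(sgn, lo, hi, rtol=rtol)
    return mu_star * params.kappa / c0
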