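"""Tail probabilities of positive linear combinations of 1-df chi-square variables.

The null distribution of a sum-of-chi-squares gene statistic under linkage
disequilibrium is Q = sum_i lambda_i * X_i with X_i iid chi-square(1) and
lambda_i the eigenvalues of the SNP correlation matrix.  Two routines compute
P(Q > x):

``imhof_sf``
    Numerical inversion of the characteristic function (Imhof's method); this
    is exact up to quadrature error.

``liu_sf``
    The Liu–Tang–Zhang four-moment match to a non-central chi-square; an
    analytic approximation, used as fallback when the quadrature fails to
    converge and as an independent sanity check of the inversion.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

from .errors import DomainError

__all__ = ["imhof_sf", "liu_sf"]


def _clean_lambdas(lambdas) -> np.ndarray:
    lam = np.asarray(lambdas, dtype=float).ravel()
    if lam.size == 0:
        raise DomainError("at least one eigenvalue is required")
    if np.any(lam < -1e-8):
        raise DomainError("negative eigenvalue beyond tolerance: weights must be >= 0")
    lam = lam[lam > 1e-12]  # zero eigenvalues contribute nothing
    if lam.size == 0:
        raise DomainError("all eigenvalues are (numerically) zero")
    return lam


def imhof_sf(x: float, lambdas, *, abs_tol: float = 1e-10) -> tuple[float, bool]:
    """Return (P(sum lambda_i X_i > x), converged_flag) by Imhof inversion.

    The Gil-Pelaez / Imhof representation for central quadratic forms is

        P(Q > x) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du,
        theta(u) = (1/2) * sum_i arctan(lambda_i u) - x u / 2,
        rho(u)   = prod_i (1 + lambda_i^2 u^2)^(1/4).

    ``converged_flag`` is False when the quadrature reports an estimated
    absolute error above ``abs_tol``; callers may then fall back to liu_sf.
    """
    lam = _clean_lambdas(lambdas)
    if x <= 0.0:
        return 1.0, True

    def phi(u: float) -> float:
        return 0.5 * float(np.sum(np.arctan(lam * u)))

    def inv_urho(u: float) -> float:
        return float(np.exp(-0.25 * np.sum(np.log1p((lam * u) ** 2)))) / u

    def integrand(u: float) -> float:
        return np.sin(phi(u) - 0.5 * x * u) * inv_urho(u)

    # The integrand oscillates at angular frequency x/2 and decays only like
    # u^(-1 - m/2), so a single infinite-interval rule stalls for small m.
    # Split: plain adaptive quadrature over the first few oscillations, then
    # QUADPACK's Fourier transform rule (QAWF) for the tail, after writing
    # sin(phi - xu/2) = sin(phi)cos(xu/2) - cos(phi)sin(xu/2).
    omega = 0.5 * x
    u0 = min(1.0 / max(lam.max(), 1e-12), 20.0 / omega)
    total_err = 0.0
    with np.errstate(over="ignore"):
        head, err = integrate.quad(
            integrand, 0.0, u0, epsabs=abs_tol, epsrel=0.0, limit=500
        )
        total_err += err
        tail_cos, err = integrate.quad(
            lambda u: np.sin(phi(u)) * inv_urho(u),
            u0, np.inf, weight="cos", wvar=omega, epsabs=abs_tol, limit=500,
        )
        total_err += err
        tail_sin, err = integrate.quad(
            lambda u: np.cos(phi(u)) * inv_urho(u),
            u0, np.inf, weight="sin", wvar=omega, epsabs=abs_tol, limit=500,
        )
        total_err += err
    p = 0.5 + (head + tail_cos - tail_sin) / np.pi
    converged = bool(np.isfinite(p)) and total_err <= max(abs_tol * 100, 1e-8)
    p = float(min(max(p, 0.0), 1.0))
    return p, converged


def liu_sf(x: float, lambdas) -> float:
    """Liu–Tang–Zhang moment-matching approximation of P(sum lambda_i X_i > x)."""
    lam = _clean_lambdas(lambdas)
    if x <= 0.0:
        return 1.0
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        ncp = s1 * a**3 - a**2
        df = a**2 - 2.0 * ncp
    else:
        df = 1.0 / s2
        a = np.sqrt(df)
        ncp = 0.0
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    mu_x = df + ncp
    sigma_x = np.sqrt(2.0 * (df + 2.0 * ncp))
    t_star = (x - mu_q) / sigma_q
    q = t_star * sigma_x + mu_x
    if ncp > 0:
        p = stats.ncx2.sf(q, df, ncp)
    else:
        p = stats.chi2.sf(q, df)
    return float(min(max(p, 0.0), 1.0))
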