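"""Closed-form phenotype integrals for normally distributed temperature optima.

Every species carries a normal distribution of temperature optima
``p(z) = N(mu, sigma2)`` whose variance is fixed (infinitesimal-model
assumption) while the mean evolves. The density and trait-mean dynamics
need integrals of growth and competition kernels against these
distributions. All of them are Gaussian–Gaussian products and therefore
have exact closed forms, which are the production path; an adaptive
quadrature oracle is provided for cross-validation in tests and for an
optional slow mode.

Notation
--------
Intrinsic phenotype growth at local temperature ``T``::

    r0(z) = (rho / w) * exp(-(T - z)^2 / (2 w^2)) - kappa,   w = b_w - a_w * mu

The tolerance width ``w`` shrinks and the peak ``rho / w`` grows as the
species' local mean optimum ``mu`` increases: warm-adapted species grow
faster over a narrower thermal band (a width–height tradeoff).

Temperature-dependent competition between phenotypes ``z`` and ``z'`` uses
the kernel ``exp(-(z - z')^2 / eta^2)`` — note the convention without a
factor of 2 in the denominator; ``eta`` is the competition width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "TraitDistribution",
    "ToleranceParams",
    "phenotype_growth",
    "mean_intrinsic_growth",
    "selection_differential_intrinsic",
    "effective_competition",
    "selection_differential_competition",
    "quadrature_oracle",
    "quadrature_oracle_2d",
]


@dataclass(frozen=True)
class TraitDistribution:
    """Normal distribution of temperature optima: mean ``mu`` (°C), variance ``sigma2`` (°C²)."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError("phenotypic variance must be positive")


@dataclass(frozen=True)
class ToleranceParams:
    """Width–height tradeoff of the thermal performance curve.

    ``rho`` sets the area under the growth Gaussian (per year · °C),
    ``b_w`` (°C) and ``a_w`` (dimensionless) give the tolerance width
    ``w = b_w - a_w * mu``, and ``kappa`` (per year) is a
    temperature-independent mortality.
    """

    rho: float
    b_w: float
    a_w: float
    kappa: float

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError("rho must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")

    def width(self, mu) -> float:
        w = self.b_w - self.a_w * np.asarray(mu, dtype=float)
        if np.any(w <= 0):
            raise ValueError("tolerance width b_w - a_w*mu must be positive (trait outside admissible range)")
        return w if np.ndim(w) else float(w)


def phenotype_growth(z, temperature, tol: ToleranceParams, mu):
    """Intrinsic per-capita growth of phenotype ``z`` at ``temperature``.

    The width and height both depend on the species' local *mean* optimum
    ``mu``, not on the individual phenotype ``z``.
    """
    w = tol.width(mu)
    z = np.asarray(z, dtype=float)
    out = (tol.rho / w) * np.exp(-((temperature - z) ** 2) / (2.0 * w**2)) - tol.kappa
    return out if np.ndim(out) else float(out)


def mean_intrinsic_growth(dist: TraitDistribution, temperature: float, tol: ToleranceParams) -> float:
    """``∫ r0(z) p(z) dz`` in closed form.

    Convolving the growth Gaussian (variance ``w²``) with the trait
    distribution (variance ``σ²``) widens the curve to variance ``w² + σ²``
    and lowers the peak accordingly::

        rho / sqrt(w² + σ²) · exp(−(T − μ)² / (2 (w² + σ²))) − kappa
    """
    w = tol.width(dist.mu)
    v = w * w + dist.sigma2
    return float(tol.rho / np.sqrt(v) * np.exp(-((temperature - dist.mu) ** 2) / (2.0 * v)) - tol.kappa)


def selection_differential_intrinsic(dist: TraitDistribution, temperature: float, tol: ToleranceParams) -> float:
    """``∫ (z − μ) r0(z) p(z) dz`` in closed form.

    The mortality constant integrates to zero against ``(z − μ) p(z)``; the
    Gaussian term pulls the mean toward the local temperature, so the sign
    equals ``sign(T − μ)`` and the value vanishes at ``μ = T``.
    """
    w = tol.width(dist.mu)
    v = w * w + dist.sigma2
    delta = temperature - dist.mu
    return float(tol.rho * dist.sigma2 * delta / v**1.5 * np.exp(-(delta**2) / (2.0 * v)))


def effective_competition(dist_i: TraitDistribution, dist_j: TraitDistribution, eta: float) -> float:
    """``∬ exp(−(z − z′)²/η²) p_i(z) p_j(z′) dz dz′`` in closed form.

    The difference ``z − z′`` is normal with mean ``μ_i − μ_j`` and variance
    ``σ_i² + σ_j²``; the kernel is a Gaussian of variance ``η²/2``, so::

        η / sqrt(η² + 2(σ_i² + σ_j²)) · exp(−(μ_i − μ_j)² / (η² + 2(σ_i² + σ_j²)))

    Symmetric in (i, j), at most 1, and strictly decreasing in ``|μ_i − μ_j|``.
    """
    if not eta > 0:
        raise ValueError("competition width eta must be positive")
    v = eta * eta + 2.0 * (dist_i.sigma2 + dist_j.sigma2)
    return float(eta / np.sqrt(v) * np.exp(-((dist_i.mu - dist_j.mu) ** 2) / v))


def selection_differential_competition(
    dist_i: TraitDistribution, dist_j: TraitDistribution, eta: float, n_j: float
) -> float:
    """Selection differential from temperature-dependent competition with species j.

    Closed form of ``−N_j ∫ (z − μ_i) [∫ a(z, z′) p_j(z′) dz′] p_i(z) dz``.
    Zero when the means coincide; otherwise pushes ``μ_i`` away from
    ``μ_j`` (character displacement), weighted by the competitor's density.
    Shares the Gaussian factor with :func:`effective_competition`::

        −N_j · α_ij · σ_i² (μ_j − μ_i) / (η²/2 + σ_i² + σ_j²)
    """
    if n_j < 0:
        raise ValueError("density must be nonnegative")
    alpha = effective_competition(dist_i, dist_j, eta)
    half_v = 0.5 * eta * eta + dist_i.sigma2 + dist_j.sigma2
    return float(-n_j * alpha * dist_i.sigma2 * (dist_j.mu - dist_i.mu) / half_v)


def quadrature_oracle(integrand, dist: TraitDistribution, rtol: float = 1e-11) -> float:
    """Adaptive numerical integral of ``integrand(z) · p(z)`` over ``μ ± 10σ``.

    Independent reference path for the closed forms above; used in tests
    and in the optional slow mode, never in production dynamics.
    """
    sigma = np.sqrt(dist.sigma2)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))

    def f(z):
        return integrand(z) * norm * np.exp(-((z - dist.mu) ** 2) / (2.0 * dist.sigma2))

    import warnings

    with warnings.catch_warnings():
        # near-zero integrals trip quad's roundoff warning; the absolute
        # error floor below covers that case
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(
            f, dist.mu - 10.0 * sigma, dist.mu + 10.0 * sigma, epsabs=0.0, epsrel=rtol, limit=200
        )
    if not np.isfinite(val) or err > max(1e3 * rtol * abs(val), 1e-12):
        raise RuntimeError(f"quadrature did not converge: value={val}, abserr={err}")
    return val


def quadrature_oracle_2d(kernel, dist_i: TraitDistribution, dist_j: TraitDistribution, rtol: float = 1e-10) -> float:
    """Nested adaptive integral of ``kernel(z, z') p_i(z) p_j(z') dz dz'``."""

    def inner(z):
        return quadrature_oracle(lambda zp: kernel(z, zp), dist_j, rtol=rtol)

    return quadrature_oracle(inner, dist_i, rtol=rtol)
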