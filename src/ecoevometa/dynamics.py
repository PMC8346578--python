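"""Right-hand side of the coupled density and trait-mean equations.

For each species ``i`` and patch ``k`` the model tracks a density
``N_i^k`` and a mean temperature optimum ``mu_i^k``. Densities change
through phenotype-averaged local growth (intrinsic thermal performance,
competition, trophic gains and losses) plus nearest-neighbour dispersal;
trait means change through selection differentials scaled by heritability
plus mass-weighted trait mixing from immigration::

    dN_i^k/dt  = N_i^k * ∫ r_i^k(z) p_i^k(z) dz + sum_l m_i^{kl} N_i^l - sum_l m_i^{lk} N_i^k
    dmu_i^k/dt = h_i^2 * ∫ (z - mu_i^k) r_i^k(z) p_i^k(z) dz
                 + h_i^2 * sum_l m_i^{kl} (N_i^l / N_i^k) (mu_i^l - mu_i^k)

All phenotype integrals use the closed forms of :mod:`ecoevometa.closures`,
evaluated on arrays. Trophic terms are phenotype-independent and therefore
contribute nothing to selection: predation changes densities, never trait
means directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np

from .climate import ClimateProfile, patch_temperatures

__all__ = [
    "CommunityParams",
    "ModelState",
    "MigrationOperator",
    "feeding_rates",
    "per_capita_growth_terms",
    "dispersal_terms",
    "assemble_rhs",
    "pack_state",
    "unpack_state",
]

CompetitionMode = Literal["constant", "temperature"]

# Densities are floored at this value inside per-capita ratios (the N^l/N^k
# trait-mixing term is singular at N = 0); tolerance widths are clipped from
# below so that a trait mean drifting outside its admissible range degrades
# growth instead of crashing the integrator.
N_FLOOR = 1e-12
W_MIN = 0.1


@dataclass
class CommunityParams:
    """Per-species parameter arrays for one replicate community.

    All arrays are indexed by species (length ``S``); resources come first,
    consumers (if any) after. ``a_const`` holds constant competition
    coefficients (nonzero only within the resource block), ``wprey`` is the
    feeding adjacency times effort weights (``W_ij * omega_ij``, consumer
    rows only), and ``eta`` is the width of the temperature-dependent
    competition kernel.
    """

    rho: np.ndarray          # growth scale, per yr·°C
    kappa: np.ndarray        # mortality, per yr
    b_w: float               # tolerance width intercept, °C
    a_w: float               # tolerance width slope, dimensionless
    sigma_g2: np.ndarray     # genetic variance, °C²
    sigma_e2: float          # environmental variance, °C²
    dispersal: np.ndarray    # dispersal distance, m/yr
    dx: float                # patch length, m
    epsilon: np.ndarray      # conversion efficiency, (0, 1]
    q: np.ndarray            # attack rate
    handling: np.ndarray     # handling time, yr
    is_consumer: np.ndarray  # bool mask
    a_const: np.ndarray      # (S, S) constant competition coefficients
    wprey: np.ndarray        # (S, S) adjacency * effort
    eta: float = 2.5         # competition kernel width, °C

    @property
    def n_species(self) -> int:
        return self.rho.size

    @property
    def resource_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.is_consumer)

    @property
    def migration(self) -> "MigrationOperator":
        return MigrationOperator(rates=self.dispersal / self.dx)

    def heritability(self, sigma_g2_eff: np.ndarray) -> np.ndarray:
        """h² = genetic / phenotypic variance, for (possibly regulated) genetic variance."""
        return sigma_g2_eff / (sigma_g2_eff + self.sigma_e2)


@dataclass
class ModelState:
    """Densities ``n`` and trait means ``mu``, both shaped (S, L), at time ``t`` (years)."""

    n: np.ndarray
    mu: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.n.shape != self.mu.shape:
            raise ValueError("density and trait matrices must share shape (S, L)")

    def copy(self) -> "ModelState":
        return ModelState(self.n.copy(), self.mu.copy(), self.t)


@dataclass
class MigrationOperator:
    """Nearest-neighbour migration at per-species rate ``m_i = d_i / dx``.

    The patch chain has zero-flux ends: patch 1 (the pole) has no patch
    beyond it, and patch L (the equator) exchanges with its own mirror
    image — climate is symmetric about the equator, so the mirror flux
    cancels exactly. Both boundaries therefore conserve abundance.
    """

    rates: np.ndarray  # (S,) per-year hop rates

    def density_flux(self, n: np.ndarray) -> np.ndarray:
        """Net dispersal term for densities: a discrete zero-flux Laplacian."""
        out = np.zeros_like(n)
        if n.shape[1] == 1:
            return out
        m = self.rates[:, None]
        out[:, 1:-1] = m * (n[:, :-2] + n[:, 2:] - 2.0 * n[:, 1:-1])
        out[:, 0] = self.rates * (n[:, 1] - n[:, 0])
        out[:, -1] = self.rates * (n[:, -2] - n[:, -1])
        return out

    def trait_flux(self, n: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """Immigrant trait mixing, before the heritability factor.

        ``sum_l m (N_l / N_k)(mu_l - mu_k)`` over real neighbours; the
        equatorial mirror neighbour has identical traits and contributes
        nothing. Densities in the denominator are floored at ``N_FLOOR``.
        """
        out = np.zeros_like(mu)
        if mu.shape[1] == 1:
            return out
        m = self.rates[:, None]
        nf = np.maximum(n, N_FLOOR)
        left = n[:, :-1] / nf[:, 1:] * (mu[:, :-1] - mu[:, 1:])    # from patch k-1 into k
        right = n[:, 1:] / nf[:, :-1] * (mu[:, 1:] - mu[:, :-1])   # from patch k+1 into k
        out[:, 1:] += m * left
        out[:, :-1] += m * right
        return out


def feeding_rates(n_col: np.ndarray, params: CommunityParams) -> np.ndarray:
    """Holling type II feeding rates ``F_ij`` in one patch.

    ``F_ij = q_i W_ij omega_ij N_j / (1 + q_i H_i sum_s W_is omega_is N_s)``;
    rows are consumers, columns prey. Zero for non-links; saturates at
    ``1 / H_i`` as prey densities grow.
    """
    n_col = np.asarray(n_col, dtype=float)
    if np.any(n_col < 0):
        raise ValueError("densities must be nonnegative")
    prey_tot = params.wprey @ n_col
    denom = 1.0 + params.q * params.handling * prey_tot
    return (params.q / denom)[:, None] * params.wprey * n_col[None, :]


def _intrinsic_terms(n, mu, temps, params, sigma2):
    """Phenotype-averaged intrinsic growth and its selection differential, all patches."""
    w = np.maximum(params.b_w - params.a_w * mu, W_MIN)
    v = w * w + sigma2
    delta = temps[None, :] - mu
    gauss = np.exp(-(delta * delta) / (2.0 * v))
    growth = params.rho[:, None] / np.sqrt(v) * gauss - params.kappa[:, None]
    selection = params.rho[:, None] * sigma2 * delta / v**1.5 * gauss
    return growth, selection


def _competition_terms(n, mu, params, sigma2, mode: CompetitionMode):
    """Density load and selection differential from resource competition.

    Competition acts only among resources; consumers interact with each
    other solely through shared prey. In constant mode the coefficients are
    phenotype-independent, so the selection contribution is exactly zero.
    """
    s = params.n_species
    comp_n = np.zeros_like(n)
    comp_sel = np.zeros_like(n)
    if mode == "constant":
        comp_n = params.a_const @ n
        return comp_n, comp_sel
    res = params.resource_idx
    mu_r = mu[res]
    n_r = n[res]
    sig_r = sigma2[res]
    eta2 = params.eta * params.eta
    dvar = eta2 + 2.0 * (sig_r[:, None, :] + sig_r[None, :, :])      # (R, R, L)
    dmu = mu_r[:, None, :] - mu_r[None, :, :]
    alpha = params.eta / np.sqrt(dvar) * np.exp(-(dmu * dmu) / dvar)
    comp_n[res] = np.einsum("ijk,jk->ik", alpha, n_r)
    # - sum_j N_j alpha_ij sigma_i^2 (mu_j - mu_i) / (eta^2/2 + sigma_i^2 + sigma_j^2)
    comp_sel[res] = sig_r * np.einsum("ijk,jk->ik", alpha * dmu / (0.5 * dvar), n_r)
    return comp_n, comp_sel


def _trophic_terms(n, params):
    """Per-capita consumption gains (consumers) and predation losses (prey).

    The per-capita loss of prey ``i`` is ``sum_j N_j F_ji / N_i``; since
    ``F_ji`` is proportional to ``N_i`` this ratio is well defined by
    continuity at ``N_i = 0`` and needs no division.
    """
    prey_tot = params.wprey @ n                                     # (S, L)
    denom = 1.0 + (params.q * params.handling)[:, None] * prey_tot
    gain = params.epsilon[:, None] * params.q[:, None] * prey_tot / denom
    pressure = (params.q[:, None] / denom) * n                      # consumers' N_j q_j / denom_j
    loss = params.wprey.T @ pressure
    return gain, loss


def per_capita_growth_terms(
    state: ModelState,
    k: int,
    params: CommunityParams,
    mode: CompetitionMode = "constant",
    climate: Optional[ClimateProfile] = None,
    temperature: Optional[float] = None,
):
    """Growth rates and selection differentials for all species in patch ``k`` (1-based).

    Convenience single-patch view of the vectorized internals; returns
    ``(rates, selection)`` arrays of length S. Pass either a climate
    profile (temperature evaluated at ``state.t``) or an explicit local
    temperature.
    """
    if temperature is None:
        if climate is None:
            raise ValueError("provide a climate profile or an explicit temperature")
        temps = patch_temperatures(state.t, climate)
    else:
        temps = np.full(state.n.shape[1], np.nan)
        temps[k - 1] = temperature
    n = np.clip(state.n, 0.0, None)
    sigma2 = params.sigma_g2[:, None] + params.sigma_e2 + np.zeros_like(n)
    g0, sel0 = _intrinsic_terms(n, state.mu, temps, params, sigma2)
    cn, csel = _competition_terms(n, state.mu, params, sigma2, mode)
    gain, loss = _trophic_terms(n, params)
    rates = g0 - cn + gain - loss
    return rates[:, k - 1], (sel0 + csel)[:, k - 1]


def dispersal_terms(state: ModelState, migration: MigrationOperator, h2: Optional[np.ndarray] = None):
    """Dispersal contributions to (dN/dt, dmu/dt); trait part scaled by heritability."""
    dn = migration.density_flux(state.n)
    dmu = migration.trait_flux(state.n, state.mu)
    if h2 is not None:
        dmu = h2 * dmu
    return dn, dmu


def assemble_rhs(
    state: ModelState,
    params: CommunityParams,
    climate: ClimateProfile,
    mode: CompetitionMode = "constant",
    variance_regulation: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
):
    """Time derivatives ``(dN/dt, dmu/dt)``, both shaped (S, L).

    ``variance_regulation(n, sigma_g2)`` may supply a density-dependent
    effective genetic variance (evolution shuts down smoothly in
    near-extinct populations); it feeds into both the phenotypic variance
    of the closures and the heritability that scales selection and
    immigrant trait mixing. With ``None`` the drawn variances are used as-is.
    """
    n = np.clip(state.n, 0.0, None)
    mu = state.mu
    temps = patch_temperatures(state.t, climate)

    sigma_g2 = np.broadcast_to(params.sigma_g2[:, None], n.shape)
    if variance_regulation is not None:
        sigma_g2 = variance_regulation(n, sigma_g2)
    sigma2 = sigma_g2 + params.sigma_e2
    h2 = params.heritability(sigma_g2)

    g0, sel0 = _intrinsic_terms(n, mu, temps, params, sigma2)
    comp_n, comp_sel = _competition_terms(n, mu, params, sigma2, mode)
    gain, loss = _trophic_terms(n, params)

    migration = params.migration
    dn = n * (g0 - comp_n + gain - loss) + migration.density_flux(state.n)
    dmu = h2 * (sel0 + comp_sel) + h2 * migration.trait_flux(n, mu)

    if not (np.all(np.isfinite(dn)) and np.all(np.isfinite(dmu))):
        bad = np.argwhere(~(np.isfinite(dn) & np.isfinite(dmu)))
        i, k = bad[0]
        raise FloatingPointError(f"non-finite derivative at t={state.t:.2f}, species {i}, patch {k + 1}")
    return dn, dmu


def pack_state(n: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return np.concatenate([n.ravel(), mu.ravel()])


def unpack_state(y: np.ndarray, s: int, l: int):
    half = s * l
    return y[:half].reshape(s, l), y[half:].reshape(s, l)
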