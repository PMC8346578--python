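"""Scenario grid, random replicate parameterization, food web, and initial conditions.

A simulation experiment is a fully factorial grid of 16 scenarios:
high/low mean dispersal × high/low mean genetic variance × four model
setups (one or two trophic levels × constant or temperature-dependent
competition). For each (scenario, seed) pair every per-species parameter
is drawn reproducibly from pre-specified distributions.

The draw stream is keyed only by (seed, dispersal level, variance level),
and all parameter groups are drawn in a fixed order regardless of the
model setup. Scenarios that differ only in trophic structure or
competition mode therefore share identical underlying parameter draws for
a given seed, giving genuinely matched comparisons across model setups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from itertools import product
from typing import Optional

import numpy as np

from .climate import ClimateProfile, patch_temperatures
from .dynamics import CommunityParams, ModelState

__all__ = [
    "Scenario",
    "FoodWeb",
    "DrawSettings",
    "ReplicateConfig",
    "scenario_grid",
    "draw_replicate",
    "build_foodweb",
    "initial_state",
]

_DISPERSAL_LEVELS = ("high", "low")
_VARIANCE_LEVELS = ("high", "low")
_TROPHIC_LEVELS = ("one", "two")
_COMPETITION_MODES = ("constant", "temperature")

#: Scenario-level means (m/yr and °C²) for the two factorial axes that set scales.
DISPERSAL_MEANS = {"high": 100.0, "low": 0.01}
GENETIC_VARIANCE_MEANS = {"high": 1e-1, "low": 1e-3}


@dataclass(frozen=True)
class Scenario:
    """One cell of the 2 × 2 × 4 factorial design."""

    dispersal_level: str = "high"
    variance_level: str = "high"
    trophic: str = "one"
    competition: str = "constant"

    def __post_init__(self) -> None:
        checks = [
            (self.dispersal_level, _DISPERSAL_LEVELS, "dispersal_level"),
            (self.variance_level, _VARIANCE_LEVELS, "variance_level"),
            (self.trophic, _TROPHIC_LEVELS, "trophic"),
            (self.competition, _COMPETITION_MODES, "competition"),
        ]
        for value, allowed, name in checks:
            if value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")

    @property
    def label(self) -> str:
        return f"{self.trophic}-{self.competition}-d{self.dispersal_level}-v{self.variance_level}"


def scenario_grid() -> list[Scenario]:
    """The full factorial of 16 scenarios, in canonical order."""
    return [
        Scenario(d, v, tr, c)
        for d, v, tr, c in product(_DISPERSAL_LEVELS, _VARIANCE_LEVELS, _TROPHIC_LEVELS, _COMPETITION_MODES)
    ]


@dataclass
class FoodWeb:
    """Bipartite consumer–resource feeding network.

    ``w`` is the (S_C, S_R) binary adjacency with exactly five links per
    consumer; ``omega`` holds the effort weights, uniform over links and
    summing to one per consumer. Every consumer is linked to the resource
    whose initial mean temperature optimum is closest to its own.
    """

    w: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        if self.w.shape != self.omega.shape:
            raise ValueError("adjacency and effort matrices must share shape")


@dataclass
class DrawSettings:
    """Means, coefficients of variation, and ranges of all parameter draws.

    Per-species parameters are log-normal around their means with the
    given CV; constant competition coefficients are uniform with
    intraspecific strength fixed at ``a_intra``. These defaults are
    package-level choices (documented in the methods note) and can be
    overridden wholesale from a run configuration.
    """

    cv: float = 0.2                 # relative spread of log-normal draws
    rho_mean: float = 1.0           # resource growth scale, per yr·°C
    kappa_mean: float = 0.1         # mortality, per yr
    q_mean: float = 5.0             # attack rate
    handling_mean: float = 2.0      # handling time, yr
    epsilon_mean: float = 0.3       # conversion efficiency
    kappa_consumer_mean: float = 0.05  # consumer mortality, per yr
    b_w_mean: float = 7.0           # tolerance width intercept, °C
    b_w_cv: float = 0.1
    a_w_mean: float = 0.08          # tolerance width slope
    eta_mean: float = 2.5           # competition kernel width, °C
    a_inter_range: tuple[float, float] = (0.15, 0.6)   # interspecific a_ij
    a_intra: float = 1.0            # intraspecific a_ii
    sigma_e2: float = 1e-2          # environmental trait variance, °C²
    consumer_rho_frac: float = 0.5  # consumer peak growth as fraction of -kappa
    patch_km: float = 200.0         # patch length, km (10,000 km pole→equator / 50)
    links_per_consumer: int = 5


@dataclass
class ReplicateConfig:
    """Everything needed to integrate one replicate; reproducible from (scenario, seed)."""

    scenario: Scenario
    seed: int
    s_per_level: int
    n_patches: int
    climate: ClimateProfile
    params: CommunityParams
    web: Optional[FoodWeb]
    settings: DrawSettings
    t0: float = -4000.0
    t_end: float = 2500.0

    def to_dict(self) -> dict:
        """Serializable description (drawn arrays are reproducible, not stored)."""
        return {
            "scenario": asdict(self.scenario),
            "seed": int(self.seed),
            "s_per_level": int(self.s_per_level),
            "n_patches": int(self.n_patches),
            "climate": asdict(self.climate),
            "settings": {
                k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self.settings).items()
            },
            "t0": self.t0,
            "t_end": self.t_end,
        }


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and coefficient of variation."""
    if cv <= 0:
        return np.full(size, float(mean))
    s2 = np.log1p(cv * cv)
    mu_log = np.log(mean) - 0.5 * s2
    return rng.lognormal(mu_log, np.sqrt(s2), size=size)


def initial_trait_means(s: int, climate: ClimateProfile) -> np.ndarray:
    """Evenly spaced initial optima: ``mu_i = (T_max - T_min) i / S + T_min``, i = 1..S."""
    i = np.arange(1, s + 1)
    return (climate.t_max - climate.t_min) * i / s + climate.t_min


def build_foodweb(s_r: int, s_c: int, mu0_consumers: np.ndarray, mu0_resources: np.ndarray,
                  rng: np.random.Generator, links: int = 5) -> FoodWeb:
    """Random bipartite web: each consumer eats its temperature-matched resource plus
    ``links - 1`` distinct others chosen uniformly; effort is uniform over links."""
    if s_r < links:
        raise ValueError(f"need at least {links} resource species, got {s_r}")
    w = np.zeros((s_c, s_r))
    for c in range(s_c):
        matched = int(np.argmin(np.abs(mu0_resources - mu0_consumers[c])))  # ties → lowest index
        others = [r for r in range(s_r) if r != matched]
        chosen = rng.choice(others, size=links - 1, replace=False)
        w[c, matched] = 1.0
        w[c, chosen] = 1.0
    omega = w / links
    return FoodWeb(w=w, omega=omega)


def draw_replicate(
    scenario: Scenario,
    seed: int,
    s_per_level: int = 50,
    n_patches: int = 50,
    climate: Optional[ClimateProfile] = None,
    settings: Optional[DrawSettings] = None,
) -> ReplicateConfig:
    """Draw one replicate's full parameterization, deterministically from (scenario, seed)."""
    settings = settings or DrawSettings()
    climate = climate or ClimateProfile(n_patches=n_patches)
    if climate.n_patches != n_patches:
        climate = replace(climate, n_patches=n_patches)

    d_idx = _DISPERSAL_LEVELS.index(scenario.dispersal_level)
    v_idx = _VARIANCE_LEVELS.index(scenario.variance_level)
    rng = np.random.default_rng([int(seed), d_idx, v_idx])

    s_r = s_per_level
    two_level = scenario.trophic == "two"
    s_c = s_per_level  # consumer draws always consumed from the stream, used only if two_level
    cv = settings.cv

    # Fixed draw order — do not reorder; it defines the matched-replicate contract.
    rho_r = _lognormal(rng, settings.rho_mean, cv, s_r)
    kappa_r = _lognormal(rng, settings.kappa_mean, cv, s_r)
    sigma_g2_r = _lognormal(rng, GENETIC_VARIANCE_MEANS[scenario.variance_level], cv, s_r)
    dispersal_r = _lognormal(rng, DISPERSAL_MEANS[scenario.dispersal_level], cv, s_r)
    b_w = float(_lognormal(rng, settings.b_w_mean, settings.b_w_cv, ()))
    a_w = float(_lognormal(rng, settings.a_w_mean, cv, ()))
    eta = float(_lognormal(rng, settings.eta_mean, cv, ()))
    lo, hi = settings.a_inter_range
    a_inter = rng.uniform(lo, hi, size=(s_r, s_r))

    kappa_c = _lognormal(rng, settings.kappa_consumer_mean, cv, s_c)
    sigma_g2_c = _lognormal(rng, GENETIC_VARIANCE_MEANS[scenario.variance_level], cv, s_c)
    dispersal_c = _lognormal(rng, DISPERSAL_MEANS[scenario.dispersal_level], cv, s_c)
    q_c = _lognormal(rng, settings.q_mean, cv, s_c)
    handling_c = _lognormal(rng, settings.handling_mean, cv, s_c)
    epsilon_c = np.clip(_lognormal(rng, settings.epsilon_mean, cv, s_c), 0.02, 1.0)

    mu0_r = initial_trait_means(s_r, climate)
    mu0_c = initial_trait_means(s_c, climate)
    web = build_foodweb(s_r, s_c, mu0_c, mu0_r, rng, links=settings.links_per_consumer) if two_level else None

    s_total = s_r + (s_c if two_level else 0)
    is_consumer = np.zeros(s_total, dtype=bool)
    a_const = np.zeros((s_total, s_total))
    a_const[:s_r, :s_r] = a_inter
    np.fill_diagonal(a_const[:s_r, :s_r], settings.a_intra)
    wprey = np.zeros((s_total, s_total))

    rho = rho_r
    kappa = kappa_r
    sigma_g2 = sigma_g2_r
    dispersal = dispersal_r
    q = np.zeros(s_total)
    handling = np.zeros(s_total)
    epsilon = np.zeros(s_total)

    if two_level:
        is_consumer[s_r:] = True
        wprey[s_r:, :s_r] = web.w * web.omega
        # Consumers' intrinsic growth must be negative for every phenotype:
        # scale the growth peak to a fraction of mortality at the narrowest
        # admissible tolerance width, so consumption is obligatory.
        w_min_adm = b_w - a_w * (climate.t_max + climate.c_min)
        if w_min_adm <= 0:
            raise ValueError("tolerance width nonpositive over the admissible trait range")
        rho_c = settings.consumer_rho_frac * kappa_c * w_min_adm
        rho = np.concatenate([rho_r, rho_c])
        kappa = np.concatenate([kappa_r, kappa_c])
        sigma_g2 = np.concatenate([sigma_g2_r, sigma_g2_c])
        dispersal = np.concatenate([dispersal_r, dispersal_c])
        q[s_r:] = q_c
        handling[s_r:] = handling_c
        epsilon[s_r:] = epsilon_c

    params = CommunityParams(
        rho=rho,
        kappa=kappa,
        b_w=b_w,
        a_w=a_w,
        sigma_g2=sigma_g2,
        sigma_e2=settings.sigma_e2,
        dispersal=dispersal,
        dx=settings.patch_km * 1000.0,
        epsilon=epsilon,
        q=q,
        handling=handling,
        is_consumer=is_consumer,
        a_const=a_const,
        wprey=wprey,
        eta=eta,
    )
    return ReplicateConfig(
        scenario=scenario,
        seed=int(seed),
        s_per_level=s_per_level,
        n_patches=n_patches,
        climate=climate,
        params=params,
        web=web,
        settings=settings,
    )


def initial_state(config: ReplicateConfig) -> ModelState:
    """Initial densities and trait means at the start of the establishment phase.

    Species are equally spaced in trait and adapted to the centres of
    their ranges: ``mu_i^k(t0)`` is patch-independent, and initial density
    follows a Gaussian of the mismatch to the patch's pre-warming
    temperature, ``N_i^k(t0) = exp(-(mu_i(t0) - T^k(0))^2 / 8)``.
    """
    climate = config.climate
    mu0_level = initial_trait_means(config.s_per_level, climate)
    levels = 2 if config.scenario.trophic == "two" else 1
    mu0 = np.concatenate([mu0_level] * levels)
    temps0 = patch_temperatures(0.0, climate)
    mu = np.repeat(mu0[:, None], config.n_patches, axis=1)
    n = np.exp(-((mu - temps0[None, :]) ** 2) / 8.0)
    return ModelState(n=n, mu=mu, t=config.t0)
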