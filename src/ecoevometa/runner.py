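"""Integrate one replicate through establishment, warming, and post-warming phases.

The simulation runs from ``t0 = -4000`` (establishment under a constant
climate) through the warming ramp (``t = 0`` to ``t_e = 300``) to
``t_end = 2500``. The forcing is time-continuous, so a single adaptive
integration would suffice; in practice the run is chunked between
snapshot times because the extinction threshold is applied at snapshots —
local densities below the threshold are hard-zeroed, and a species with
no remaining occupied patch is flagged globally extinct (irreversibly,
since recolonization requires an occupied neighbour).

Genetic variance is regulated at very low population densities: the
effective variance ramps smoothly to zero as ``N^2 / (N^2 + N_c^2)``,
which prevents near-extinct populations from evolving rapidly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import ModelState, assemble_rhs, pack_state, unpack_state
from .params import ReplicateConfig, initial_state

__all__ = [
    "variance_regulation",
    "apply_extinction_threshold",
    "Trajectory",
    "run_replicate",
    "DEFAULT_EXTINCTION_THRESHOLD",
]

DEFAULT_EXTINCTION_THRESHOLD = 1e-6
#: Variance regulation midpoint: one decade above the extinction scale.
DEFAULT_NC_FACTOR = 10.0


def variance_regulation(n, sigma_g2, n_c: float = DEFAULT_NC_FACTOR * DEFAULT_EXTINCTION_THRESHOLD):
    """Effective genetic variance at density ``n``: ``sigma_g2 * n² / (n² + n_c²)``.

    Monotone ramp with value 0 at ``n = 0``, half the drawn variance at
    ``n = n_c``, and saturation to the drawn variance for ``n >> n_c``.
    """
    n = np.asarray(n, dtype=float)
    s = n * n / (n * n + n_c * n_c)
    return sigma_g2 * s


def apply_extinction_threshold(state: ModelState, threshold: float, extinct: np.ndarray,
                               events: Optional[list] = None) -> ModelState:
    """Zero local densities below ``threshold``; flag and log extinctions.

    ``extinct`` is a per-species boolean array updated in place (global
    extinction is irreversible). Events are appended as dicts with keys
    ``time, species, scope, patch``.
    """
    if threshold <= 0:
        raise ValueError("extinction threshold must be positive")
    below = state.n < threshold
    if events is not None:
        newly_zeroed = below & (state.n > 0)
        for i, k in np.argwhere(newly_zeroed):
            events.append({"time": float(state.t), "species": int(i), "scope": "local", "patch": int(k) + 1})
    state.n[below] = 0.0
    gone = ~np.any(state.n > 0, axis=1)
    for i in np.flatnonzero(gone & ~extinct):
        if events is not None:
            events.append({"time": float(state.t), "species": int(i), "scope": "global", "patch": None})
    extinct |= gone
    return state


@dataclass
class Trajectory:
    """Snapshots of one replicate: times, densities (T, S, L), trait means (T, S, L)."""

    times: np.ndarray
    n: np.ndarray
    mu: np.ndarray
    events: list = field(default_factory=list)
    config: Optional[ReplicateConfig] = None

    def index_of(self, t: float) -> int:
        idx = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[idx], t):
            raise KeyError(f"time {t} not sampled (nearest: {self.times[idx]})")
        return idx

    def state_at(self, t: float) -> ModelState:
        i = self.index_of(t)
        return ModelState(self.n[i].copy(), self.mu[i].copy(), float(self.times[i]))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, species, patch, density, trait_mean."""
        nt, s, l = self.n.shape
        tt = np.repeat(self.times, s * l)
        ss = np.tile(np.repeat(np.arange(1, s + 1), l), nt)
        kk = np.tile(np.arange(1, l + 1), nt * s)
        return pd.DataFrame(
            {"time": tt, "species": ss, "patch": kk,
             "density": self.n.ravel(), "trait_mean": self.mu.ravel()}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_events(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.events, fh, indent=1)


def _snapshot_times(t0: float, t_end: float, cadence: float, required=(0.0, 300.0)) -> np.ndarray:
    times = np.arange(t0, t_end + 0.5 * cadence, cadence)
    extra = [t for t in (*required, t_end) if t0 <= t <= t_end]
    times = np.unique(np.concatenate([times, np.asarray(extra, dtype=float)]))
    return times


def run_replicate(
    config: ReplicateConfig,
    sampling: float = 100.0,
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
    n_c: Optional[float] = None,
    method: str = "RK45",
    rtol: float = 1e-6,
    atol: float = 1e-9,
    regulate_variance: bool = True,
    log_local_events: bool = False,
) -> Trajectory:
    """Integrate one replicate and record snapshots every ``sampling`` years.

    The snapshot grid always contains the onset of warming (t = 0), its
    end (t = t_e), and the final time. The extinction threshold is applied
    at snapshot times; the integrator restarts from the thresholded state.
    """
    s = config.params.n_species
    l = config.n_patches
    times = _snapshot_times(config.t0, config.t_end, sampling, required=(0.0, config.climate.t_e))
    if s == 0:
        return Trajectory(times=times, n=np.zeros((times.size, 0, l)),
                          mu=np.zeros((times.size, 0, l)), events=[], config=config)

    n_c = DEFAULT_NC_FACTOR * extinction_threshold if n_c is None else n_c
    reg = (lambda n, sg2: variance_regulation(n, sg2, n_c)) if regulate_variance else None
    mode = config.scenario.competition

    def rhs(t, y):
        n, mu = unpack_state(y, s, l)
        dn, dmu = assemble_rhs(ModelState(n, mu, t), config.params, config.climate,
                               mode=mode, variance_regulation=reg)
        return pack_state(dn, dmu)

    state = initial_state(config)
    extinct = np.zeros(s, dtype=bool)
    events: list = []
    ev_local = events if log_local_events else None
    apply_extinction_threshold(state, extinction_threshold, extinct, events=ev_local)

    n_out = np.empty((times.size, s, l))
    mu_out = np.empty((times.size, s, l))
    n_out[0], mu_out[0] = state.n, state.mu

    for step in range(1, times.size):
        t_a, t_b = times[step - 1], times[step]
        sol = solve_ivp(rhs, (t_a, t_b), pack_state(state.n, state.mu),
                        method=method, rtol=rtol, atol=atol, t_eval=[t_b])
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{t_a}, {t_b}]: {sol.message}; "
                f"last good state at t={state.t}"
            )
        n_new, mu_new = unpack_state(sol.y[:, -1].copy(), s, l)
        undershoot = n_new.min(initial=0.0)
        if undershoot < -extinction_threshold:
            raise RuntimeError(f"solver undershot density to {undershoot:.3e} at t={t_b}")
        np.clip(n_new, 0.0, None, out=n_new)
        state = ModelState(n_new, mu_new, float(t_b))
        apply_extinction_threshold(state, extinction_threshold, extinct, events=ev_local)
        # log global extinctions even when local logging is off
        if not log_local_events:
            for i in np.flatnonzero(extinct):
                if not any(e["species"] == i and e["scope"] == "global" for e in events):
                    events.append({"time": float(t_b), "species": int(i), "scope": "global", "patch": None})
        n_out[step], mu_out[step] = state.n, state.mu

    return Trajectory(times=times, n=n_out, mu=mu_out, events=events, config=config)
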