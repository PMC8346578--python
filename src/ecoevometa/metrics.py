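"""Diversity and trait summaries of simulated trajectories.

Covers the quantities the experiments report: local richness through
time, per-species range breadth, regional (polar/temperate/tropical)
richness and compositional turnover, global richness change, and the
community trait statistics — density-weighted trait dispersion
``V^k = sum_i n_i (mu_i - mu_bar)^2`` and trait lag
``A^k = T^k - mu_bar`` — together with their landscape- and time-averaged
values over the warming window and the lag–dispersion relationship
across replicates.

Unless a species subset is given, metrics are computed for resource
species only (consumers, when present, can be selected explicitly);
empty patches yield NaN and are excluded from averages.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import distance
from scipy import stats

from .climate import ClimateProfile, patch_temperatures
from .runner import Trajectory

__all__ = [
    "trait_dispersion",
    "trait_lag",
    "community_trait_stats",
    "integrated_lag_and_dispersion",
    "richness_and_ranges",
    "region_slices",
    "turnover",
    "global_richness_change",
    "lag_dispersion_regression",
    "DEFAULT_PRESENCE_THRESHOLD",
]

DEFAULT_PRESENCE_THRESHOLD = 1e-3
REGIONS = ("polar", "temperate", "tropical")


def _species_subset(traj: Trajectory, species: Optional[Sequence[int]]) -> np.ndarray:
    if species is not None:
        return np.asarray(species, dtype=int)
    if traj.config is not None:
        return np.flatnonzero(~traj.config.params.is_consumer)
    return np.arange(traj.n.shape[1])


def trait_dispersion(n_col: np.ndarray, mu_col: np.ndarray) -> float:
    """Density-weighted variance of mean temperature optima in one patch (°C²).

    NaN for an empty community.
    """
    n_col = np.asarray(n_col, dtype=float)
    total = n_col.sum()
    if total <= 0:
        return float("nan")
    rel = n_col / total
    mu_bar = float(rel @ mu_col)
    return float(rel @ (np.asarray(mu_col) - mu_bar) ** 2)


def trait_lag(n_col: np.ndarray, mu_col: np.ndarray, temperature: float) -> float:
    """Local temperature minus community-weighted mean optimum (°C); NaN if empty.

    Positive when the community lags behind a warming climate.
    """
    n_col = np.asarray(n_col, dtype=float)
    total = n_col.sum()
    if total <= 0:
        return float("nan")
    return float(temperature - (n_col / total) @ mu_col)


def community_trait_stats(n: np.ndarray, mu: np.ndarray, temps: np.ndarray):
    """Vectorized per-patch (lag, dispersion) for an (S, L) snapshot; NaN where empty."""
    total = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(total > 0, n / total, np.nan)
        mu_bar = np.nansum(rel * mu, axis=0)
        disp = np.nansum(rel * (mu - mu_bar[None, :]) ** 2, axis=0)
    lag = temps - mu_bar
    empty = ~(total > 0)
    lag[empty] = np.nan
    disp[empty] = np.nan
    return lag, disp


def integrated_lag_and_dispersion(
    traj: Trajectory,
    climate: Optional[ClimateProfile] = None,
    species: Optional[Sequence[int]] = None,
    absolute_lag: bool = False,
):
    """Time- and landscape-averaged (trait lag, trait dispersion) over the warming window.

    Patch averages exclude empty patches; the time average is trapezoidal
    over the snapshots in ``[0, t_e]``, yielding one (lag, dispersion)
    pair per realization. Lag is signed by default (warming gives positive
    values); set ``absolute_lag`` for the magnitude-only variant.
    """
    climate = climate or (traj.config.climate if traj.config else None)
    if climate is None:
        raise ValueError("a climate profile is required (none attached to the trajectory)")
    sel = _species_subset(traj, species)
    window = (traj.times >= 0.0) & (traj.times <= climate.t_e)
    if window.sum() < 1 or traj.times[window][0] > 0 or traj.times[window][-1] < climate.t_e:
        raise ValueError("trajectory does not cover the warming window [0, t_e]")
    ts = traj.times[window]
    lags, disps = [], []
    for i in np.flatnonzero(window):
        temps = patch_temperatures(traj.times[i], climate)
        lag, disp = community_trait_stats(traj.n[i][sel], traj.mu[i][sel], temps)
        if absolute_lag:
            lag = np.abs(lag)
        lags.append(np.nanmean(lag) if np.any(np.isfinite(lag)) else np.nan)
        disps.append(np.nanmean(disp) if np.any(np.isfinite(disp)) else np.nan)
    if ts.size == 1:
        return float(lags[0]), float(disps[0])
    span = ts[-1] - ts[0]
    return (float(np.trapezoid(lags, ts) / span), float(np.trapezoid(disps, ts) / span))


def region_slices(l: int) -> dict[str, slice]:
    """Polar / temperate / tropical thirds of the patch chain (pole at index 0).

    Boundary patches for L not divisible by 3 go by rounding the cut
    points to the nearest patch.
    """
    a = int(round(l / 3))
    b = int(round(2 * l / 3))
    return {"polar": slice(0, a), "temperate": slice(a, b), "tropical": slice(b, l)}


def richness_and_ranges(
    traj: Trajectory,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    range_times: Sequence[float] = (0.0, 300.0, 2500.0),
    species: Optional[Sequence[int]] = None,
):
    """Richness and occupancy summaries of one trajectory.

    Returns a dict of tidy tables:

    ``local_richness``
        per snapshot, mean and standard deviation over patches of the
        number of species above the presence threshold;
    ``range_breadth``
        per species at each requested time, percentage of patches occupied;
    ``regional_richness``
        per snapshot and region, number of species present in the region.
    """
    sel = _species_subset(traj, species)
    present = traj.n[:, sel, :] > presence_threshold          # (T, S', L)
    local = present.sum(axis=1)                               # (T, L)
    local_df = pd.DataFrame(
        {"time": traj.times, "mean_richness": local.mean(axis=1), "sd_richness": local.std(axis=1)}
    )
    rows = []
    for t in range_times:
        if t < traj.times[0] or t > traj.times[-1]:
            continue
        i = traj.index_of(t)
        breadth = 100.0 * present[i].mean(axis=1)
        rows.extend(
            {"species": int(s0) + 1, "time": float(t), "breadth_pct": float(b)}
            for s0, b in zip(sel, breadth)
        )
    breadth_df = pd.DataFrame(rows)
    regions = region_slices(traj.n.shape[2])
    reg_rows = []
    for name, sl in regions.items():
        richness = np.any(present[:, :, sl], axis=2).sum(axis=1)
        reg_rows.append(pd.DataFrame({"time": traj.times, "region": name, "richness": richness}))
    return {
        "local_richness": local_df,
        "range_breadth": breadth_df,
        "regional_richness": pd.concat(reg_rows, ignore_index=True),
    }


def turnover(
    traj: Trajectory,
    region: str = "polar",
    t_ref: float = 0.0,
    t_cmp: float = 2500.0,
    metric: str = "braycurtis",
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    species: Optional[Sequence[int]] = None,
) -> float:
    """Compositional dissimilarity of one region between two sampled times.

    Default is abundance-weighted Bray–Curtis on region-summed density
    vectors; ``metric="jaccard"`` uses presence/absence instead. Returns
    NaN when the region is empty at both times.
    """
    sel = _species_subset(traj, species)
    sl = region_slices(traj.n.shape[2])[region]
    v_ref = traj.n[traj.index_of(t_ref)][sel, sl].sum(axis=1)
    v_cmp = traj.n[traj.index_of(t_cmp)][sel, sl].sum(axis=1)
    if v_ref.sum() == 0 and v_cmp.sum() == 0:
        return float("nan")
    if metric == "braycurtis":
        return float(distance.braycurtis(v_ref, v_cmp))
    if metric == "jaccard":
        return float(distance.jaccard(v_ref > presence_threshold, v_cmp > presence_threshold))
    raise ValueError(f"unknown turnover metric {metric!r}")


def global_richness_change(
    traj: Trajectory,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    species: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Richness relative to the onset of warming, globally and per region.

    For each snapshot at ``t >= 0``, the fraction of the species present
    at t = 0 (in the given scope) that are still present. Captures the
    continued post-warming decline (extinction debt).
    """
    sel = _species_subset(traj, species)
    present = traj.n[:, sel, :] > presence_threshold
    t0_idx = traj.index_of(0.0)
    keep = traj.times >= 0.0
    scopes = {"global": slice(None)} | region_slices(traj.n.shape[2])
    rows = []
    for name, sl in scopes.items():
        extant = np.any(present[:, :, sl], axis=2)            # (T, S')
        base = extant[t0_idx].sum()
        rel = extant[keep].sum(axis=1) / base if base > 0 else np.full(keep.sum(), np.nan)
        rows.append(pd.DataFrame({"time": traj.times[keep], "region": name, "relative_richness": rel}))
    return pd.concat(rows, ignore_index=True)


def lag_dispersion_regression(pairs: Sequence[tuple[float, float]]):
    """OLS fit of integrated trait lag on trait dispersion across replicates.

    Returns (slope, intercept, r_squared). A negative slope indicates
    that communities with more varied temperature optima track the
    changing climate more closely.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two (lag, dispersion) pairs")
    res = stats.linregress(arr[:, 1], arr[:, 0])
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
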