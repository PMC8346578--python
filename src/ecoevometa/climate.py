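"""Deterministic temperature forcing along a latitudinal patch chain.

The landscape is a linear chain of ``L`` patches, with patch 1 at the pole
and patch ``L`` at the equator. Each patch has a constant pre-warming
temperature given by a linear latitudinal profile. Starting at ``t = 0``
temperatures ramp up smoothly over ``t_e`` years to an elevated plateau,
with polar amplification: the pole warms by ``c_max`` degrees in total, the
equator by ``c_min``. The ramp is the quintic smoothstep, so the forcing is
twice continuously differentiable everywhere — no solver restarts are needed
at the phase boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClimateProfile", "smoothstep", "local_temperature", "patch_temperatures", "export_temperatures"]


@dataclass(frozen=True)
class ClimateProfile:
    """Parameters of the temperature field.

    Parameters
    ----------
    t_min, t_max
        Initial polar and equatorial temperatures (°C). ``t_min < t_max``.
    c_max, c_min
        Total warming at the pole and at the equator (°C),
        ``c_max >= c_min >= 0`` (polar amplification).
    t_e
        Duration of the warming ramp in years (> 0).
    n_patches
        Number of patches ``L`` in the pole-to-equator chain.
    """

    t_min: float = -10.0
    t_max: float = 30.0
    c_max: float = 8.0
    c_min: float = 2.0
    t_e: float = 300.0
    n_patches: int = 50

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be below t_max (pole colder than equator)")
        if not (self.c_max >= self.c_min >= 0.0):
            raise ValueError("require c_max >= c_min >= 0 (polar amplification)")
        if not self.t_e > 0:
            raise ValueError("warming duration t_e must be positive")
        if self.n_patches < 1:
            raise ValueError("need at least one patch")


def smoothstep(tau):
    """Quintic smoothstep ramp: 0 below 0, 1 above 1, ``10τ³ − 15τ⁴ + 6τ⁵`` between.

    Continuous with continuous first and second derivatives at both ends,
    and monotone nondecreasing. Accepts scalars or arrays.
    """
    tau = np.asarray(tau, dtype=float)
    t = np.clip(tau, 0.0, 1.0)
    out = t * t * t * (10.0 + t * (-15.0 + 6.0 * t))
    return out if out.ndim else float(out)


def local_temperature(k, t, profile: ClimateProfile):
    """Temperature (°C) in patch ``k`` (1-based; 1 = pole) at time ``t`` (years).

    The field is the initial linear profile plus the patch-specific total
    warming scaled by the smoothstep ramp ``Q(t / t_e)``. Broadcasts over
    array-valued ``k`` and ``t``.
    """
    k = np.asarray(k)
    if np.any((k < 1) | (k > profile.n_patches)):
        raise IndexError(f"patch index out of range 1..{profile.n_patches}")
    frac = k / profile.n_patches
    baseline = profile.t_min + (profile.t_max - profile.t_min) * frac
    warming = profile.c_max + (profile.c_min - profile.c_max) * frac
    out = baseline + warming * smoothstep(np.asarray(t, dtype=float) / profile.t_e)
    return out if np.ndim(out) else float(out)


def patch_temperatures(t: float, profile: ClimateProfile) -> np.ndarray:
    """Temperatures of all patches (pole to equator) at time ``t``."""
    return local_temperature(np.arange(1, profile.n_patches + 1), t, profile)


def export_temperatures(profile: ClimateProfile, times, path) -> pd.DataFrame:
    """Write the temperature field on a time grid as tidy CSV (time, patch, temperature)."""
    times = np.asarray(times, dtype=float)
    patches = np.arange(1, profile.n_patches + 1)
    tt, kk = np.meshgrid(times, patches, indexing="ij")
    df = pd.DataFrame(
        {
            "time": tt.ravel(),
            "patch": kk.ravel().astype(int),
            "temperature": local_temperature(kk.ravel(), tt.ravel(), profile),
        }
    )
    df.to_csv(path, index=False)
    return df
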