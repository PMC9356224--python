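"""Average permeation path and maximal-sphere pore-radius profiling.

The pore profile is computed HOLE-style but restricted to a Z-aligned
channel: at each Z step the largest sphere centered in that plane that
touches no bead surface is found by derivative-free in-plane
maximization (Nelder-Mead with seeded restarts).  The average path is
the per-Z-bin mean XY of the ion positions accumulated over all
equilibrated umbrella frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import Bead, InvalidParameterError, IonpermError

__all__ = [
    "PathProfile",
    "PoreProfile",
    "average_path",
    "pore_profile",
    "path_axis_deviation",
]

DEFAULT_BIN_WIDTH = 0.25  # A; aligns path bins with window spacing
DEFAULT_MIN_SAMPLES = 50
DEFAULT_MAX_RADIUS = 15.0  # A; larger means "escaped the pore"


@dataclass
class PathProfile:
    z_bins: np.ndarray       # bin centers, A
    mean_xy: np.ndarray      # shape (n_bins, 2); NaN where undefined
    n_samples: np.ndarray
    min_samples: int = DEFAULT_MIN_SAMPLES

    @property
    def defined(self) -> np.ndarray:
        return self.n_samples >= self.min_samples

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_A": self.z_bins,
                "x_A": self.mean_xy[:, 0],
                "y_A": self.mean_xy[:, 1],
                "n": self.n_samples,
            }
        )


@dataclass
class PoreProfile:
    z_steps: np.ndarray
    axis_xy: np.ndarray   # shape (n_steps, 2)
    radius: np.ndarray    # A; capped at max_radius for open steps
    flags: list[str]      # "ok" | "open" | "blocked"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_A": self.z_steps,
                "x_A": self.axis_xy[:, 0],
                "y_A": self.axis_xy[:, 1],
                "radius_A": self.radius,
                "flag": self.flags,
            }
        )


def average_path(
    ion_positions: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> PathProfile:
    """Bin ion positions by Z and average X and Y per bin."""
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    pos = np.asarray(ion_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3 or len(pos) == 0:
        raise InvalidParameterError("ion_positions must be a nonempty (n, 3) array")
    z = pos[:, 2]
    lo = np.floor(z.min() / bin_width) * bin_width
    hi = np.ceil(z.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sum_x = np.bincount(idx, weights=pos[:, 0], minlength=n_bins)
    sum_y = np.bincount(idx, weights=pos[:, 1], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_xy = np.stack([sum_x / counts, sum_y / counts], axis=1)
    mean_xy[counts == 0] = np.nan
    return PathProfile(
        z_bins=0.5 * (edges[:-1] + edges[1:]),
        mean_xy=mean_xy,
        n_samples=counts,
        min_samples=min_samples,
    )


def _clearance(c_xy: np.ndarray, z: float, centers: np.ndarray,
               radii: np.ndarray) -> float:
    d = np.sqrt(
        (centers[:, 0] - c_xy[0]) ** 2
        + (centers[:, 1] - c_xy[1]) ** 2
        + (centers[:, 2] - z) ** 2
    )
    return float(np.min(d - radii))


def pore_profile(
    scaffold: Sequence[Bead],
    z_range: tuple[float, float],
    z_step: float = 0.5,
    xy_seed: tuple[float, float] = (0.0, 0.0),
    max_radius: float = DEFAULT_MAX_RADIUS,
    seed: int = 0,
    n_restarts: int = 5,
) -> PoreProfile:
    """Maximal inscribed sphere per Z plane, walked along the channel.

    Each step maximizes the clearance to all bead surfaces over the
    in-plane center, restarting Nelder-Mead from the previous optimum
    plus seeded jitters and keeping the best.  Steps whose best clearance
    is non-positive are flagged ``blocked``; steps exceeding
    ``max_radius`` are capped and flagged ``open``.
    """
    if not scaffold:
        raise InvalidParameterError("scaffold must be nonempty")
    if z_step <= 0:
        raise InvalidParameterError("z_step must be > 0")
    centers = np.array([b.xyz for b in scaffold])
    radii = np.array([b.radius for b in scaffold])
    rng = np.random.default_rng(seed)

    lo, hi = z_range
    zs = np.arange(lo, hi + 0.5 * z_step, z_step)
    axis = np.empty((len(zs), 2))
    radius = np.empty(len(zs))
    flags: list[str] = []
    current = np.asarray(xy_seed, dtype=float)
    for i, z in enumerate(zs):
        best_xy, best_r = current, _clearance(current, z, centers, radii)
        starts = [current] + [
            current + rng.normal(scale=0.5, size=2) for _ in range(n_restarts - 1)
        ]
        for s in starts:
            res = minimize(
                lambda c: -_clearance(c, z, centers, radii),
                s,
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
            )
            if -res.fun > best_r:
                best_r = -res.fun
                best_xy = np.asarray(res.x)
        axis[i] = best_xy
        if best_r <= 0:
            radius[i] = best_r
            flags.append("blocked")
        elif best_r > max_radius:
            radius[i] = max_radius
            flags.append("open")
        else:
            radius[i] = best_r
            flags.append("ok")
        current = best_xy
    return PoreProfile(z_steps=zs, axis_xy=axis, radius=radius, flags=flags)


def path_axis_deviation(
    path: PathProfile, pore: PoreProfile
) -> tuple[pd.DataFrame, float]:
    """Per-Z XY distance between path and pore axis, plus the RMS.

    The pore axis is linearly interpolated onto the path's defined bins;
    only bins inside the pore's Z span contribute.
    """
    mask = path.defined & (path.z_bins >= pore.z_steps.min()) \
        & (path.z_bins <= pore.z_steps.max())
    if not np.any(mask):
        raise InvalidParameterError("path and pore profiles do not overlap in Z")
    z = path.z_bins[mask]
    ax = np.interp(z, pore.z_steps, pore.axis_xy[:, 0])
    ay = np.interp(z, pore.z_steps, pore.axis_xy[:, 1])
    dx = path.mean_xy[mask, 0] - ax
    dy = path.mean_xy[mask, 1] - ay
    dist = np.sqrt(dx**2 + dy**2)
    rms = float(np.sqrt(np.mean(dist**2)))
    return pd.DataFrame({"z_A": z, "deviation_A": dist}), rms
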