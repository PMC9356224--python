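"""Umbrella-window construction, sample bookkeeping, and histogram QC."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import InvalidParameterError, IonpermError

__all__ = [
    "WindowSpec",
    "WindowSamples",
    "HistogramSet",
    "generate_windows",
    "bias_energy",
    "discard_equilibration",
    "build_histograms",
    "overlap_report",
    "EmptyWindowError",
]

DEFAULT_FORCE_CONSTANT = 10.0  # kcal/mol/A^2
DEFAULT_BIN_WIDTH = 0.1        # A
OVERLAP_THRESHOLD = 0.05       # QC flag level, not a hard failure


class EmptyWindowError(IonpermError):
    """A window contributed no frames to the histogram set."""


@dataclass(frozen=True)
class WindowSpec:
    """One umbrella window: harmonic restraint center and run bookkeeping."""

    center: float                  # A
    force_constant: float = DEFAULT_FORCE_CONSTANT
    n_runs: int = 5
    run_length: float = 2400.0     # ps
    equil_discard: float = 600.0   # ps discarded from the head of each run

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise InvalidParameterError("force_constant must be > 0")
        if not (0 <= self.equil_discard < self.run_length):
            raise InvalidParameterError(
                "equil_discard must lie in [0, run_length)"
            )


@dataclass
class WindowSamples:
    """Equilibrated rc samples of one window, runs concatenated."""

    spec: WindowSpec
    rc_values: np.ndarray
    per_run_counts: list[int]

    def __post_init__(self) -> None:
        self.rc_values = np.asarray(self.rc_values, dtype=float).ravel()
        if len(self.rc_values) != int(sum(self.per_run_counts)):
            raise InvalidParameterError(
                "len(rc_values) must equal sum(per_run_counts)"
            )

    @property
    def n_frames(self) -> int:
        return len(self.rc_values)


@dataclass
class HistogramSet:
    """Per-window counts on one shared bin grid."""

    bin_edges: np.ndarray
    counts: np.ndarray  # shape (n_windows, n_bins)
    window_centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise InvalidParameterError("histogram counts must be >= 0")
        if self.counts.shape[1] != len(self.bin_edges) - 1:
            raise InvalidParameterError("counts shape inconsistent with edges")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]


def generate_windows(
    z_min: float,
    z_max: float,
    spacing: float,
    force_constant: float = DEFAULT_FORCE_CONSTANT,
    extra: Sequence[tuple[float, float]] = (),
    **spec_kwargs,
) -> list[WindowSpec]:
    """Evenly spaced window centers from z_min to z_max inclusive.

    The range must be commensurate with the spacing (to 1e-9 of a grid
    step); non-commensurate input raises rather than silently truncating.
    ``extra`` appends windows at stated (center, force_constant), e.g. a
    stiffer supplemental window at a hard-to-sample position.
    """
    if z_max <= z_min:
        raise InvalidParameterError("z_max must be > z_min")
    if spacing <= 0:
        raise InvalidParameterError("spacing must be > 0")
    n_float = (z_max - z_min) / spacing
    n = round(n_float)
    if abs(n_float - n) > 1e-9:
        raise InvalidParameterError(
            f"range ({z_min}, {z_max}) is not commensurate with spacing "
            f"{spacing}: {n_float} steps"
        )
    centers = z_min + spacing * np.arange(n + 1)
    windows = [
        WindowSpec(center=float(c), force_constant=force_constant, **spec_kwargs)
        for c in centers
    ]
    for center, k in extra:
        windows.append(
            WindowSpec(center=float(center), force_constant=float(k), **spec_kwargs)
        )
    return windows


def bias_energy(spec: WindowSpec, rc: np.ndarray | float) -> np.ndarray | float:
    """Harmonic restraint energy 0.5*k*(rc - center)^2, kcal/mol."""
    return 0.5 * spec.force_constant * (np.asarray(rc, dtype=float) - spec.center) ** 2


def discard_equilibration(
    times: np.ndarray, values: np.ndarray, equil_discard: float
) -> tuple[np.ndarray, np.ndarray]:
    """Drop frames with time < equil_discard.  Idempotent."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = times >= equil_discard
    return times[keep], values[keep]


def collect_window_samples(spec: WindowSpec, runs: Sequence) -> WindowSamples:
    """Build WindowSamples from per-run trajectories, discarding equilibration.

    ``runs`` is a sequence of ``synth.Trajectory`` (single-walker).
    """
    kept = []
    per_run = []
    for traj in runs:
        _, rc = discard_equilibration(traj.times, traj.rc(), spec.equil_discard)
        kept.append(rc)
        per_run.append(len(rc))
    return WindowSamples(
        spec=spec, rc_values=np.concatenate(kept), per_run_counts=per_run
    )


def build_histograms(
    samples: Sequence[WindowSamples], bin_width: float = DEFAULT_BIN_WIDTH
) -> HistogramSet:
    """Histogram every window on one shared grid.

    Grid spans the min..max observed rc over all windows, padded one bin
    on each side; per-window counts sum to the window's frame count.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    for s in samples:
        if s.n_frames == 0:
            raise EmptyWindowError(
                f"window centered at {s.spec.center} has no frames"
            )
    lo = min(float(s.rc_values.min()) for s in samples) - bin_width
    hi = max(float(s.rc_values.max()) for s in samples) + bin_width
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((len(samples), n_bins), dtype=np.int64)
    for i, s in enumerate(samples):
        counts[i], _ = np.histogram(s.rc_values, bins=edges)
    return HistogramSet(
        bin_edges=edges,
        counts=counts,
        window_centers=np.array([s.spec.center for s in samples]),
    )


def overlap_report(
    hists: HistogramSet, threshold: float = OVERLAP_THRESHOLD
) -> pd.DataFrame:
    """Neighbor-window histogram overlap QC.

    overlap(i, i+1) = sum_b min(p_i, p_(i+1)) with each histogram
    normalized to unit mass.  Windows must be ordered by center.  Pairs
    below the threshold are flagged (QC advisory, not an error).
    """
    centers = hists.window_centers
    if centers is not None and np.any(np.diff(centers) < 0):
        raise InvalidParameterError("windows must be ordered by center")
    totals = hists.counts.sum(axis=1, keepdims=True).astype(float)
    p = hists.counts / np.where(totals > 0, totals, 1.0)
    rows = []
    for i in range(hists.n_windows - 1):
        ov = float(np.minimum(p[i], p[i + 1]).sum())
        rows.append(
            {
                "i": i,
                "j": i + 1,
                "center_i": float(centers[i]) if centers is not None else np.nan,
                "center_j": float(centers[i + 1]) if centers is not None else np.nan,
                "overlap": ov,
                "passed": ov >= threshold,
            }
        )
    return pd.DataFrame(
        rows, columns=["i", "j", "center_i", "center_j", "overlap", "passed"]
    )
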