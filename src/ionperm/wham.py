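"""Self-consistent WHAM estimation of the unbiased free-energy profile.

Standard equations, iterated to self-consistency:

    P(b) = sum_i n_i(b) / sum_j N_j * exp[(f_j - w_j(b)) / kT]
    f_j  = -kT * ln sum_b P(b) * exp[-w_j(b) / kT]

with window free energies reported relative to f_0 = 0 and the profile
min-shifted to zero.  Bins with no counts anywhere are reported as NaN
gaps, never interpolated.  Error bars come from a Monte-Carlo bootstrap
that resamples each window's empirical rc distribution at the effective
sample size implied by a stated correlation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .core import DEFAULT_TEMPERATURE, InvalidParameterError, IonpermError, kT
from .umbrella import (
    DEFAULT_BIN_WIDTH,
    HistogramSet,
    WindowSamples,
    WindowSpec,
    bias_energy,
    build_histograms,
)

__all__ = [
    "WhamResult",
    "BootstrapErrors",
    "solve_wham",
    "bootstrap_errors",
    "barrier_height",
    "effective_sample_size",
    "ConvergenceError",
    "DisconnectedSupportError",
    "UndefinedBinError",
]

DEFAULT_TOL = 1e-6      # kcal/mol on f increments
DEFAULT_MAX_ITER = 100_000


class ConvergenceError(IonpermError):
    """WHAM iteration failed to reach tolerance within max_iter."""

    def __init__(self, max_delta_f: float, max_iter: int):
        self.max_delta_f = max_delta_f
        self.max_iter = max_iter
        super().__init__(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last max |delta f| = {max_delta_f:.3e} kcal/mol)"
        )


class DisconnectedSupportError(IonpermError):
    """Histogram supports split into islands with no bridging window."""


class UndefinedBinError(IonpermError):
    """An operation hit a zero-count (gap) bin."""


@dataclass
class WhamResult:
    bin_centers: np.ndarray
    pmf: np.ndarray                    # kcal/mol, NaN at gap bins, min = 0
    window_free_energies: np.ndarray   # f_i, relative to f_0 = 0
    iterations: int
    max_delta_f: float

    def defined(self) -> np.ndarray:
        return np.isfinite(self.pmf)


@dataclass
class BootstrapErrors:
    per_bin_sd: np.ndarray
    n_trials: int
    correlation_time: float
    frame_interval: float
    bin_centers: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)


def effective_sample_size(n: int, frame_interval: float,
                          correlation_time: float) -> int:
    """ceil(N * dt / max(tau, dt)): frames per correlation time."""
    return int(math.ceil(n * frame_interval / max(correlation_time, frame_interval)))


def _check_connected(hists: HistogramSet) -> None:
    occ = hists.counts > 0
    adj = (occ @ occ.T) > 0
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        centers = hists.window_centers
        pieces = []
        for comp in range(n_comp):
            idx = np.where(labels == comp)[0]
            if centers is not None:
                pieces.append(
                    f"[{centers[idx].min():g}, {centers[idx].max():g}]"
                )
            else:
                pieces.append(f"windows {idx.tolist()}")
        raise DisconnectedSupportError(
            "histogram support is disconnected; window islands: "
            + "; ".join(pieces)
        )


def solve_wham(
    hists: HistogramSet,
    windows: Sequence[WindowSpec],
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    f_init: np.ndarray | None = None,
) -> WhamResult:
    """Iterate the WHAM equations to self-consistency.

    Convergence is declared when every window free-energy increment is
    below ``tol``.  ``f_init`` warm-starts the iteration (used by the
    bootstrap); pass None for a cold start at f = 0.
    """
    if tol <= 0:
        raise InvalidParameterError("tol must be > 0")
    if len(windows) != hists.n_windows:
        raise InvalidParameterError("windows and histogram set disagree in size")
    n_i = hists.counts.astype(float)
    if np.any(n_i.sum(axis=1) < 1):
        empty = np.where(n_i.sum(axis=1) < 1)[0]
        raise InvalidParameterError(f"windows with no counts: {empty.tolist()}")
    _check_connected(hists)

    kt = kT(temperature)
    centers = hists.bin_centers
    n_b = n_i.sum(axis=0)                      # total counts per bin
    log_nb = np.where(n_b > 0, np.log(np.where(n_b > 0, n_b, 1.0)), -np.inf)
    big_n = n_i.sum(axis=1)                    # frames per window
    # bias energy of every window at every bin center, units of kT
    w = np.stack([np.asarray(bias_energy(spec, centers)) for spec in windows])
    log_bias = -w / kt                         # shape (n_win, n_bins)
    log_n_win = np.log(big_n)[:, None]

    f = np.zeros(len(windows)) if f_init is None else np.array(f_init, dtype=float)
    occupied = n_b > 0
    delta = np.inf
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_i [ln N_i + f_i/kT - w_i(b)/kT]
        log_denom = logsumexp(log_n_win + f[:, None] / kt + log_bias, axis=0)
        log_p = log_nb - log_denom             # -inf at empty bins
        f_new = -kt * logsumexp(log_p[None, occupied] + log_bias[:, occupied],
                                axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(delta, max_iter)

    log_denom = logsumexp(log_n_win + f[:, None] / kt + log_bias, axis=0)
    log_p = log_nb - log_denom
    pmf = np.where(occupied, -kt * log_p, np.nan)
    pmf = pmf - np.nanmin(pmf)
    return WhamResult(
        bin_centers=centers,
        pmf=pmf,
        window_free_energies=f,
        iterations=it,
        max_delta_f=delta,
    )


def bootstrap_errors(
    samples: Sequence[WindowSamples],
    windows: Sequence[WindowSpec],
    temperature: float = DEFAULT_TEMPERATURE,
    correlation_time: float = 20.0,
    frame_interval: float = 2.0,
    n_trials: int = 200,
    seed: int = 0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> BootstrapErrors:
    """Monte-Carlo bootstrap error bars on the min-shifted profile.

    Per window the effective sample size is
    ``N_eff = ceil(N * frame_interval / max(correlation_time,
    frame_interval))``; each trial draws N_eff rc values with replacement
    from the window's empirical distribution, rebuilds histograms on the
    reference grid, and re-solves WHAM (warm-started at the full-data
    solution).  ``per_bin_sd`` is the across-trial standard deviation.
    """
    if n_trials < 2:
        raise InvalidParameterError("n_trials must be >= 2")
    ref_hists = build_histograms(samples, bin_width=bin_width)
    ref = solve_wham(ref_hists, windows, temperature, tol=tol, max_iter=max_iter)
    edges = ref_hists.bin_edges
    rng = np.random.default_rng(seed)

    warnings: list[str] = []
    n_eff = []
    for s in samples:
        ne = effective_sample_size(s.n_frames, frame_interval, correlation_time)
        n_eff.append(ne)
        if ne < 10:
            warnings.append(
                f"window {s.spec.center:g}: N_eff = {ne} < 10; error bars "
                "unreliable"
            )

    pmfs = np.full((n_trials, len(ref.pmf)), np.nan)
    for trial in range(n_trials):
        counts = np.zeros((len(samples), len(edges) - 1), dtype=np.int64)
        for i, (s, ne) in enumerate(zip(samples, n_eff)):
            draw = rng.choice(s.rc_values, size=ne, replace=True)
            counts[i], _ = np.histogram(draw, bins=edges)
        trial_hists = HistogramSet(
            bin_edges=edges, counts=counts,
            window_centers=ref_hists.window_centers,
        )
        try:
            res = solve_wham(
                trial_hists, windows, temperature, tol=tol, max_iter=max_iter,
                f_init=ref.window_free_energies,
            )
        except DisconnectedSupportError:
            warnings.append(f"trial {trial}: disconnected resample, skipped")
            continue
        pmfs[trial] = res.pmf

    with np.errstate(invalid="ignore"):
        sd = np.full(len(ref.pmf), np.nan)
        for b in range(len(ref.pmf)):
            vals = pmfs[:, b]
            vals = vals[np.isfinite(vals)]
            if len(vals) >= 2:
                sd[b] = float(np.std(vals, ddof=1))
    return BootstrapErrors(
        per_bin_sd=sd,
        n_trials=n_trials,
        correlation_time=correlation_time,
        frame_interval=frame_interval,
        bin_centers=ref.bin_centers,
        warnings=warnings,
    )


def barrier_height(result: WhamResult, z_range: tuple[float, float]) -> float:
    """max(pmf) - min(pmf) restricted to z_range; gaps inside are an error."""
    lo, hi = z_range
    mask = (result.bin_centers >= lo) & (result.bin_centers <= hi)
    if not np.any(mask):
        raise InvalidParameterError(f"z_range {z_range} covers no bins")
    vals = result.pmf[mask]
    if np.any(~np.isfinite(vals)):
        raise UndefinedBinError(
            f"z_range {z_range} contains undefined (zero-count) bins"
        )
    return float(vals.max() - vals.min())
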