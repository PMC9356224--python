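"""Synthetic inputs: Brownian dynamics on a designed groove potential.

This module generates everything the downstream analysis consumes —
biased and unbiased overdamped-Langevin trajectories of a single ion on
a known free-energy surface, frame streams with intermittently contacting
partner beads, and channel-lining bead geometries — so the whole pipeline
is testable against exact ground truth.

The groove potential is

    U(x, y, z) = sum_i A_i * exp(-(z - c_i)^2 / (2 w_i^2))
                 + 0.5 * k_r(z) * (x^2 + y^2)

With a z-independent radial stiffness the analytic XY integration gives
the exact 1-D free-energy profile

    F(z) = U_z(z) + kT * ln(k_r / (2 pi kT))

which is what recovery tests compare against (up to an additive offset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .core import (
    DEFAULT_TEMPERATURE,
    Bead,
    Frame,
    InvalidParameterError,
    IonpermError,
    kT,
)

__all__ = [
    "GaussianTerm",
    "GroovePotential",
    "PartnerRule",
    "LangevinParams",
    "SteeredProtocol",
    "Trajectory",
    "preset_potential",
    "simulate_langevin",
    "run_steered_init",
    "emit_partner_frames",
    "build_groove_geometry",
    "sample_windows_boltzmann",
    "InstabilityError",
    "UncoveredWindowError",
]

ION_RADIUS = 1.33  # K+-like bead radius, A


class InstabilityError(IonpermError):
    """Integration step moved a particle too far; reduce dt."""


class UncoveredWindowError(IonpermError):
    """Steered initialization failed to produce starts for some windows."""

    def __init__(self, missing: Sequence[float]):
        self.missing = list(missing)
        super().__init__(
            "steered initialization did not cover window centers: "
            + ", ".join(f"{c:g}" for c in self.missing)
        )


@dataclass(frozen=True)
class GaussianTerm:
    amplitude: float  # kcal/mol
    center: float     # A
    width: float      # A

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidParameterError("gaussian width must be > 0")


@dataclass(frozen=True)
class GroovePotential:
    """Designed free-energy surface with harmonic XY confinement."""

    z_terms: tuple[GaussianTerm, ...]
    radial_k: float  # kcal/mol/A^2, z-independent (>= 0; 0 disables confinement)
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        if self.radial_k < 0:
            raise InvalidParameterError("radial_k must be >= 0")

    def uz(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for t in self.z_terms:
            u = u + t.amplitude * np.exp(-((z - t.center) ** 2) / (2 * t.width**2))
        return u

    def duz(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        g = np.zeros_like(z)
        for t in self.z_terms:
            g = g - (
                t.amplitude
                * (z - t.center)
                / t.width**2
                * np.exp(-((z - t.center) ** 2) / (2 * t.width**2))
            )
        return g

    def energy(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        r2 = xyz[..., 0] ** 2 + xyz[..., 1] ** 2
        return self.uz(xyz[..., 2]) + 0.5 * self.radial_k * r2

    def grad(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        g = np.empty_like(xyz)
        g[..., 0] = self.radial_k * xyz[..., 0]
        g[..., 1] = self.radial_k * xyz[..., 1]
        g[..., 2] = self.duz(xyz[..., 2])
        return g

    def designed_pmf(self, z: np.ndarray | float,
                     temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray | float:
        """Exact 1-D profile from analytic XY integration (additive const incl.)."""
        u = self.uz(z)
        if self.radial_k > 0:
            u = u + kT(temperature) * math.log(
                self.radial_k / (2 * math.pi * kT(temperature))
            )
        return u

    def designed_barrier(self, z_range: tuple[float, float],
                         temperature: float = DEFAULT_TEMPERATURE,
                         n_grid: int = 4001) -> float:
        z = np.linspace(z_range[0], z_range[1], n_grid)
        f = np.asarray(self.designed_pmf(z, temperature))
        return float(f.max() - f.min())


#: Barrier design targets (kcal/mol) of the named presets.
PRESET_BARRIERS = {"open_pg": 2.0, "open_pc": 7.0, "l302a": 8.0}

_PRESETS: dict[str, tuple[tuple[GaussianTerm, ...], float]] = {
    # single-Gaussian barriers; centers follow the profile maxima of the
    # three regimes (groove center for the PG-like open groove, Z = +2.7 for
    # the PC-occluded groove, Z = +3.5 for the constricted mutant)
    "open_pg": ((GaussianTerm(2.0, 0.0, 3.0),), 2.0),
    "open_pc": ((GaussianTerm(7.0, 2.7, 3.0),), 2.0),
    "l302a": ((GaussianTerm(8.0, 3.5, 3.0),), 2.0),
}


def preset_potential(name: str) -> GroovePotential:
    """Return a named designed potential (``open_pg``, ``open_pc``, ``l302a``)."""
    try:
        terms, k_r = _PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return GroovePotential(z_terms=terms, radial_k=k_r, preset_name=name)


@dataclass(frozen=True)
class PartnerRule:
    """Placement rule for one partner bead as a function of the rc."""

    partner_id: str
    z_window: tuple[float, float]
    contact_prob: float | Callable[[np.ndarray], np.ndarray] = 1.0
    charge: float = 0.0
    radius: float = 1.0

    def prob(self, rc: np.ndarray | float) -> np.ndarray:
        rc = np.asarray(rc, dtype=float)
        inside = (rc >= self.z_window[0]) & (rc <= self.z_window[1])
        if callable(self.contact_prob):
            p = np.asarray(self.contact_prob(rc), dtype=float)
        else:
            p = np.full_like(rc, float(self.contact_prob))
        if np.any((p < 0) | (p > 1)):
            raise InvalidParameterError("contact_prob must lie in [0, 1]")
        return np.where(inside, p, 0.0)


@dataclass(frozen=True)
class LangevinParams:
    dt: float = 0.01          # ps
    diffusion: float = 0.2    # A^2/ps
    n_steps: int = 10_000
    frame_stride: int = 1
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.diffusion <= 0:
            raise InvalidParameterError("diffusion must be > 0")
        if self.frame_stride < 1:
            raise InvalidParameterError("frame_stride must be >= 1")
        if self.n_steps < 0:
            raise InvalidParameterError("n_steps must be >= 0")


@dataclass(frozen=True)
class SteeredProtocol:
    force_constant: float = 5.0  # kcal/mol/A^2
    velocity: float = 10.0       # A/ns
    start_z: float = -12.25
    end_z: float = 11.5

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise InvalidParameterError("force_constant must be > 0")
        if self.velocity <= 0:
            raise InvalidParameterError("velocity must be > 0")
        if self.start_z == self.end_z:
            raise InvalidParameterError("start_z must differ from end_z")


@dataclass(frozen=True)
class HarmonicBias:
    """Umbrella restraint 0.5*k*(rc - center)^2 acting on the rc (= ion Z)."""

    center: float
    force_constant: float

    def energy(self, rc: np.ndarray | float) -> np.ndarray | float:
        return 0.5 * self.force_constant * (np.asarray(rc, float) - self.center) ** 2

    def grad_rc(self, rc: np.ndarray | float) -> np.ndarray | float:
        return self.force_constant * (np.asarray(rc, float) - self.center)


@dataclass
class Trajectory:
    """Frame positions of the diffusing ion; reference bead fixed at origin.

    ``xyz`` has shape (n_frames, 3) for a single walker or
    (n_frames, n_walkers, 3) for an ensemble run.
    """

    times: np.ndarray
    xyz: np.ndarray
    ref_z: float = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def rc(self) -> np.ndarray:
        return self.xyz[..., 2] - self.ref_z

    def to_frames(self, ion_charge: float = 1.0) -> list[Frame]:
        if self.xyz.ndim != 2:
            raise InvalidParameterError("to_frames requires a single-walker run")
        frames = []
        for t, p in zip(self.times, self.xyz):
            frames.append(
                Frame(
                    time=float(t),
                    beads=[
                        Bead("K+", "ion", p.copy(), radius=ION_RADIUS,
                             charge=ion_charge),
                        Bead("REF", "reference",
                             np.array([0.0, 0.0, self.ref_z]), radius=1.0),
                    ],
                )
            )
        return frames


_MAX_STEP = 5.0  # A; larger single-step moves mean the integrator blew up


def simulate_langevin(
    potential: GroovePotential,
    params: LangevinParams,
    bias: HarmonicBias | None = None,
    x0: Sequence[float] | np.ndarray = (0.0, 0.0, 0.0),
) -> Trajectory:
    """Overdamped (Brownian) dynamics on the groove potential.

    Update rule per step:
    ``x <- x - (D*dt/kT) * grad(U + bias) + sqrt(2*D*dt) * xi`` with
    standard-normal ``xi`` per dimension.  Frames (including the initial
    position at t = 0) are emitted every ``frame_stride`` steps.  The same
    seed always reproduces the same trajectory.
    """
    x = np.array(x0, dtype=float)
    if x.shape != (3,) and not (x.ndim == 2 and x.shape[1] == 3):
        raise InvalidParameterError("x0 must have shape (3,) or (n_walkers, 3)")
    rng = np.random.default_rng(params.seed)
    kt = kT(params.temperature)
    mobility_dt = params.diffusion * params.dt / kt
    noise = math.sqrt(2.0 * params.diffusion * params.dt)

    n_kept = params.n_steps // params.frame_stride + 1
    out = np.empty((n_kept,) + x.shape, dtype=float)
    times = np.empty(n_kept, dtype=float)
    out[0] = x
    times[0] = 0.0
    kept = 1
    for step in range(1, params.n_steps + 1):
        g = potential.grad(x)
        if bias is not None:
            g[..., 2] = g[..., 2] + bias.grad_rc(x[..., 2])
        dx = -mobility_dt * g + noise * rng.standard_normal(x.shape)
        if np.max(np.abs(dx)) > _MAX_STEP:
            raise InstabilityError(
                f"step {step} moved a particle by more than {_MAX_STEP} A; "
                "reduce dt"
            )
        x = x + dx
        if step % params.frame_stride == 0:
            out[kept] = x
            times[kept] = step * params.dt
            kept += 1
    return Trajectory(times=times[:kept], xyz=out[:kept])


def run_steered_init(
    potential: GroovePotential,
    protocol: SteeredProtocol,
    params: LangevinParams,
    window_centers: Sequence[float],
    rc_tolerance: float = 0.25,
) -> dict[float, np.ndarray]:
    """Drag the ion with a moving harmonic restraint; harvest window starts.

    The restraint center travels from ``start_z`` to ``end_z`` at the
    protocol velocity; for each requested window center the first frame
    whose rc is within ``rc_tolerance`` of it is recorded as that
    window's starting position.
    """
    lo, hi = sorted((protocol.start_z, protocol.end_z))
    outside = [c for c in window_centers if not (lo <= c <= hi)]
    if outside:
        raise UncoveredWindowError(outside)

    rng = np.random.default_rng(params.seed)
    kt = kT(params.temperature)
    mobility_dt = params.diffusion * params.dt / kt
    noise = math.sqrt(2.0 * params.diffusion * params.dt)
    v = protocol.velocity / 1000.0  # A/ns -> A/ps
    direction = 1.0 if protocol.end_z > protocol.start_z else -1.0
    total_time = abs(protocol.end_z - protocol.start_z) / v
    n_steps = int(math.ceil(total_time / params.dt))

    x = np.array([0.0, 0.0, protocol.start_z])
    starts: dict[float, np.ndarray] = {}
    remaining = sorted(window_centers)
    for step in range(n_steps + 1):
        rc = x[2]
        still = []
        for c in remaining:
            if abs(rc - c) <= rc_tolerance:
                starts[c] = x.copy()
            else:
                still.append(c)
        remaining = still
        if not remaining:
            break
        t = step * params.dt
        center = protocol.start_z + direction * min(v * t, abs(
            protocol.end_z - protocol.start_z))
        g = potential.grad(x)
        g[2] += protocol.force_constant * (x[2] - center)
        x = x - mobility_dt * g + noise * rng.standard_normal(3)
    if remaining:
        raise UncoveredWindowError(remaining)
    return starts


def emit_partner_frames(
    frames: Sequence[Frame],
    rules: Sequence[PartnerRule],
    seed: int = 0,
) -> list[Frame]:
    """Place one bead per rule in every frame, near or far from the ion.

    With probability ``contact_prob(rc)`` (zero outside the rule's
    z-window) the partner is placed at a uniform distance in [2.0, 2.9] A
    from the ion; otherwise at a uniform distance in [4, 8] A.  Directions
    are isotropic.  Placement is deterministic given the seed.
    """
    ids = [r.partner_id for r in rules]
    if len(set(ids)) != len(ids):
        raise InvalidParameterError("partner rules must have disjoint ids")
    if not rules:
        return list(frames)
    rng = np.random.default_rng(seed)
    out: list[Frame] = []
    for frame in frames:
        ion_xyz = frame.ion.xyz
        rc = frame.rc.value
        beads = list(frame.beads)
        for rule in rules:
            p = float(rule.prob(rc))
            near = rng.random() < p
            dist = rng.uniform(2.0, 2.9) if near else rng.uniform(4.0, 8.0)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            beads.append(
                Bead(
                    id=rule.partner_id,
                    kind="partner",
                    xyz=ion_xyz + dist * direction,
                    radius=rule.radius,
                    charge=rule.charge,
                )
            )
        out.append(Frame(time=frame.time, beads=beads))
    return out


def emit_exact_contact_frames(
    total_frames: int,
    contact_counts: Mapping[str, int],
    seed: int = 0,
    frame_interval: float = 2.0,
) -> list[Frame]:
    """Frames in which each partner is within 3 A in exactly k frames.

    For every partner the k contact frames are chosen by a seeded shuffle;
    contact placements are at uniform distance in [2.0, 2.9] A from the
    ion, non-contact placements in [4, 8] A.  Used to rebuild printed
    contact tables with known ground truth.
    """
    rng = np.random.default_rng(seed)
    for pid, k in contact_counts.items():
        if not (0 <= k <= total_frames):
            raise InvalidParameterError(
                f"contact count for {pid!r} must be in [0, {total_frames}]"
            )
    near_mask = {}
    for pid, k in contact_counts.items():
        mask = np.zeros(total_frames, dtype=bool)
        mask[rng.permutation(total_frames)[:k]] = True
        near_mask[pid] = mask
    frames: list[Frame] = []
    for i in range(total_frames):
        beads = [
            Bead("K+", "ion", np.zeros(3), radius=ION_RADIUS, charge=1.0),
            Bead("REF", "reference", np.array([0.0, 0.0, 1.5]), radius=1.0),
        ]
        for pid in contact_counts:
            dist = rng.uniform(2.0, 2.9) if near_mask[pid][i] else rng.uniform(4.0, 8.0)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            beads.append(
                Bead(id=pid, kind="partner", xyz=dist * direction, radius=1.0)
            )
        frames.append(Frame(time=i * frame_interval, beads=beads))
    return frames


def build_groove_geometry(
    preset: str,
    *,
    z_min: float = -12.0,
    z_max: float = 12.0,
    z_step: float = 0.5,
    ring_radius: float = 6.0,
    bead_radius: float = 2.0,
    n_per_ring: int = 12,
    neck_z: float = 3.5,
    neck_depth: float = 2.5,
    neck_width: float = 1.5,
) -> list[Bead]:
    """Bead rings lining a Z-aligned channel.

    Presets: ``open`` (constant lumen), ``constricted`` (lumen narrows
    near ``neck_z``), ``ideal_cylinder`` (ring radius exactly
    ``ring_radius``; lumen radius = ring_radius - bead_radius).
    """
    if preset not in ("open", "constricted", "ideal_cylinder"):
        raise InvalidParameterError(f"unknown geometry preset {preset!r}")
    beads: list[Bead] = []
    zs = np.arange(z_min, z_max + 0.5 * z_step, z_step)
    angles = np.linspace(0.0, 2.0 * math.pi, n_per_ring, endpoint=False)
    for iz, z in enumerate(zs):
        if preset == "constricted":
            r_ring = ring_radius - neck_depth * math.exp(
                -((z - neck_z) ** 2) / (2 * neck_width**2)
            )
        else:
            r_ring = ring_radius
        for ia, a in enumerate(angles):
            beads.append(
                Bead(
                    id=f"SCF{iz}_{ia}",
                    kind="scaffold",
                    xyz=np.array([r_ring * math.cos(a), r_ring * math.sin(a), z]),
                    radius=bead_radius,
                )
            )
    return beads


def sample_windows_boltzmann(
    potential: GroovePotential,
    windows: Sequence,
    n_per_window: int,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
    z_pad: float = 3.0,
    dz: float = 0.005,
):
    """Draw rc samples exactly from each window's biased Boltzmann density.

    This bypasses dynamics entirely: per window i the density is
    ``p_i(z) ~ exp(-(F(z) + 0.5*k_i*(z - c_i)^2) / kT)`` on a fine grid,
    sampled by inverse CDF with within-cell jitter.  It is the independent
    oracle used to validate the free-energy estimator.

    Returns a list of ``umbrella.WindowSamples``.
    """
    from .umbrella import WindowSamples  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    kt = kT(temperature)
    centers = [w.center for w in windows]
    z = np.arange(min(centers) - z_pad, max(centers) + z_pad + dz, dz)
    f = np.asarray(potential.designed_pmf(z, temperature))
    out = []
    for w in windows:
        u = f + 0.5 * w.force_constant * (z - w.center) ** 2
        logw = -(u - u.min()) / kt
        p = np.exp(logw)
        cdf = np.cumsum(p)
        cdf /= cdf[-1]
        u01 = rng.random(n_per_window)
        idx = np.searchsorted(cdf, u01)
        samples = z[idx] + (rng.random(n_per_window) - 0.5) * dz
        out.append(
            WindowSamples(
                spec=w,
                rc_values=np.sort(samples),
                per_run_counts=[n_per_window],
            )
        )
    return out
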