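"""End-to-end scenario runs driven by a single YAML config.

A scenario is one groove preset run through every stage:
synthetic sampling -> umbrella bookkeeping -> WHAM (+bootstrap) ->
contacts -> geometry -> electrostatics, with all stage outputs written
as plain-text CSV/JSON into the output directory.  Outputs are pure
functions of the config (plus its seeds); every file carries the config
hash so stale mixtures of outputs are detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import IonpermError
from . import contacts as contacts_mod
from . import geometry as geometry_mod
from . import synth, umbrella, wham
from .electrostatics import DielectricModel, build_maps, sample_along_path, solve_lpb

__all__ = ["ScenarioConfig", "ConfigError", "StageError", "run_scenario",
            "CI_PROFILE", "FULL_PROFILE"]

log = logging.getLogger("ionperm.pipeline")


class ConfigError(IonpermError):
    """The scenario config failed validation (no compute was attempted)."""


class StageError(IonpermError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


# reduced profile for fast CI runs; full profile mirrors the window grids
# of the two experimental setups
CI_PROFILE = {
    "windows": {"z_min": -6.0, "z_max": 5.5, "spacing": 0.5,
                "force_constant": 10.0},
    "sampling": {"n_steps": 20_000, "dt": 0.01, "diffusion": 0.2,
                 "frame_stride": 10, "equil_discard_ps": 20.0},
    "bootstrap": {"n_trials": 20, "correlation_time_ps": 1.0},
    "pb": {"spacing": 1.5, "padding": 6.0},
}

FULL_PROFILE = {
    "windows": {"z_min": -10.25, "z_max": 10.5, "spacing": 0.25,
                "force_constant": 10.0},
    "sampling": {"n_steps": 120_000, "dt": 0.01, "diffusion": 0.2,
                 "frame_stride": 4, "equil_discard_ps": 100.0},
    "bootstrap": {"n_trials": 100, "correlation_time_ps": 2.0},
    "pb": {"spacing": 1.0, "padding": 8.0},
}


@dataclass
class ScenarioConfig:
    preset: str = "open_pg"
    profile: str = "ci"
    seed: int = 1
    outdir: str = "scenario_out"
    # window grid
    z_min: float = -6.0
    z_max: float = 5.5
    spacing: float = 0.5
    force_constant: float = 10.0
    extra_windows: list[tuple[float, float]] = field(default_factory=list)
    # sampling
    n_steps: int = 20_000
    dt: float = 0.01
    diffusion: float = 0.2
    frame_stride: int = 10
    equil_discard_ps: float = 20.0
    temperature: float = 310.0
    # contacts
    contact_cutoff: float = 3.0
    critical_threshold_pct: float = 50.0
    partner_z_window: tuple[float, float] = (-3.25, 1.25)
    partner_contact_prob: float = 0.829
    partner_id: str = "POPG"
    partner_charge: float = -1.0
    # bootstrap
    n_trials: int = 20
    correlation_time_ps: float = 1.0
    # geometry / electrostatics
    geometry_preset: str = "open"
    pb_spacing: float = 1.5
    pb_padding: float = 6.0
    run_electrostatics: bool = True

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ScenarioConfig":
        profile = raw.get("profile", "ci")
        if profile not in ("ci", "full"):
            raise ConfigError(f"profile must be 'ci' or 'full', got {profile!r}")
        base = CI_PROFILE if profile == "ci" else FULL_PROFILE
        merged: dict[str, Any] = {"profile": profile}
        merged.update(base["windows"])
        for k, v in base["sampling"].items():
            merged[k] = v
        merged["n_trials"] = base["bootstrap"]["n_trials"]
        merged["correlation_time_ps"] = base["bootstrap"]["correlation_time_ps"]
        merged["pb_spacing"] = base["pb"]["spacing"]
        merged["pb_padding"] = base["pb"]["padding"]
        known = set(cls.__dataclass_fields__)
        for k, v in raw.items():
            if k == "profile":
                continue
            if k not in known:
                raise ConfigError(f"unknown config key {k!r}")
            merged[k] = v
        cfg = cls(**merged)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        problems = []
        if self.preset not in synth.PRESET_BARRIERS:
            problems.append(f"unknown preset {self.preset!r}")
        if self.spacing <= 0:
            problems.append("spacing must be > 0")
        if self.z_max <= self.z_min:
            problems.append("z_max must be > z_min")
        if self.force_constant <= 0:
            problems.append("force_constant must be > 0")
        if self.n_steps <= 0:
            problems.append("n_steps must be > 0")
        if self.dt <= 0:
            problems.append("dt must be > 0")
        if not (0 < self.critical_threshold_pct <= 100):
            problems.append("critical_threshold_pct must be in (0, 100]")
        if self.contact_cutoff <= 0:
            problems.append("contact_cutoff must be > 0")
        if self.n_trials < 2:
            problems.append("n_trials must be >= 2")
        if problems:
            raise ConfigError("; ".join(problems))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(path: Path, df: pd.DataFrame, cfg_hash: str) -> None:
    path.write_text(f"# config_hash={cfg_hash}\n" + df.to_csv(index=False))


def run_scenario(config: ScenarioConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle; returns the summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    log.info("scenario preset=%s profile=%s hash=%s", config.preset,
             config.profile, cfg_hash)

    summary: dict[str, Any] = {
        "config_hash": cfg_hash,
        "version": __version__,
        "preset": config.preset,
        "seed": config.seed,
    }

    potential = synth.preset_potential(config.preset)
    run_length = config.n_steps * config.dt

    # --- stage: windows + sampling -------------------------------------
    stage = "simulate"
    try:
        windows = umbrella.generate_windows(
            config.z_min, config.z_max, config.spacing,
            force_constant=config.force_constant,
            extra=config.extra_windows,
            n_runs=1, run_length=run_length,
            equil_discard=config.equil_discard_ps,
        )
        samples = []
        trajectories = {}
        for i, w in enumerate(windows):
            params = synth.LangevinParams(
                dt=config.dt, diffusion=config.diffusion,
                n_steps=config.n_steps, frame_stride=config.frame_stride,
                seed=config.seed + i, temperature=config.temperature,
            )
            bias = synth.HarmonicBias(w.center, w.force_constant)
            traj = synth.simulate_langevin(
                potential, params, bias=bias, x0=(0.0, 0.0, w.center)
            )
            trajectories[w.center] = traj
            samples.append(umbrella.collect_window_samples(w, [traj]))
        rows = []
        for s in samples:
            rows.append({"center_A": s.spec.center,
                         "force_constant": s.spec.force_constant,
                         "n_frames": s.n_frames})
        _write_csv(outdir / "windows.csv", pd.DataFrame(rows), cfg_hash)
    except Exception as exc:  # noqa: BLE001 - stage wrapper
        raise StageError(stage, exc) from exc

    # --- stage: histograms + QC ----------------------------------------
    stage = "umbrella"
    try:
        hists = umbrella.build_histograms(samples)
        qc = umbrella.overlap_report(hists)
        _write_csv(outdir / "overlap_qc.csv", qc, cfg_hash)
        summary["min_neighbor_overlap"] = float(qc["overlap"].min())
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: wham ----------------------------------------------------
    stage = "wham"
    try:
        result = wham.solve_wham(hists, windows, temperature=config.temperature)
        frame_interval = config.dt * config.frame_stride
        errors = wham.bootstrap_errors(
            samples, windows, temperature=config.temperature,
            correlation_time=config.correlation_time_ps,
            frame_interval=frame_interval,
            n_trials=config.n_trials, seed=config.seed,
        )
        pmf_df = pd.DataFrame({
            "z_A": result.bin_centers,
            "pmf_kcal_mol": result.pmf,
            "sd_kcal_mol": errors.per_bin_sd,
        })
        _write_csv(outdir / "pmf.csv", pmf_df, cfg_hash)
        barrier = wham.barrier_height(result, (config.z_min, config.z_max))
        summary["barrier_kcal_mol"] = barrier
        summary["wham_iterations"] = result.iterations
        summary["bootstrap_warnings"] = len(errors.warnings)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: contacts -------------------------------------------------
    stage = "contacts"
    try:
        rules = [
            synth.PartnerRule(
                partner_id=config.partner_id,
                z_window=config.partner_z_window,
                contact_prob=config.partner_contact_prob,
                charge=config.partner_charge,
            )
        ]
        tables = []
        for i, w in enumerate(windows):
            traj = trajectories[w.center]
            frames = traj.to_frames()
            keep = [f for f in frames if f.time >= config.equil_discard_ps]
            frames = synth.emit_partner_frames(
                keep, rules, seed=config.seed * 100_000 + i
            )
            tables.append(
                contacts_mod.count_contacts(
                    frames, cutoff=config.contact_cutoff, window_center=w.center
                )
            )
        tables.sort(key=lambda t: t.window_center)
        ranges = contacts_mod.critical_ranges(
            tables, threshold_pct=config.critical_threshold_pct
        )
        _write_csv(outdir / "contacts.csv",
                   contacts_mod.tables_to_dataframe(tables), cfg_hash)
        _write_csv(outdir / "critical_ranges.csv",
                   contacts_mod.ranges_to_dataframe(ranges), cfg_hash)
        summary["critical_ranges"] = [
            {"partner": r.partner_id, "z_min_A": r.z_interval[0],
             "z_max_A": r.z_interval[1]}
            for r in ranges
        ]
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: geometry --------------------------------------------------
    stage = "geometry"
    try:
        positions = np.vstack([
            trajectories[w.center].xyz[
                trajectories[w.center].times >= config.equil_discard_ps
            ]
            for w in windows
        ])
        path = geometry_mod.average_path(positions, min_samples=20)
        scaffold = synth.build_groove_geometry(
            config.geometry_preset, z_min=config.z_min - 2.0,
            z_max=config.z_max + 2.0,
        )
        pore = geometry_mod.pore_profile(
            scaffold, (config.z_min, config.z_max), z_step=0.5,
            seed=config.seed,
        )
        dev, rms = geometry_mod.path_axis_deviation(path, pore)
        _write_csv(outdir / "path.csv", path.to_dataframe(), cfg_hash)
        _write_csv(outdir / "pore.csv", pore.to_dataframe(), cfg_hash)
        _write_csv(outdir / "path_axis_deviation.csv", dev, cfg_hash)
        summary["path_axis_rms_A"] = rms
        summary["min_pore_radius_A"] = float(np.min(pore.radius))
        summary["min_pore_radius_z_A"] = float(
            pore.z_steps[int(np.argmin(pore.radius))]
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage: electrostatics -------------------------------------------
    stage = "electrostatics"
    if config.run_electrostatics:
        try:
            from .core import Bead

            charged = [b for b in scaffold]
            # one negative in-groove headgroup bead at the partner window middle
            mid = 0.5 * (config.partner_z_window[0] + config.partner_z_window[1])
            charged.append(
                Bead(id=config.partner_id, kind="partner",
                     xyz=np.array([2.0, 0.0, mid]), radius=1.0,
                     charge=config.partner_charge)
            )
            model = DielectricModel()
            maps = build_maps(
                charged, model, spacing=config.pb_spacing,
                padding=config.pb_padding,
            )
            field_ = solve_lpb(maps)
            ep = sample_along_path(field_, path)
            _write_csv(outdir / "path_ep.csv", ep, cfg_hash)
            summary["ep_min_kcal_mol_e"] = float(ep["phi_kcal_mol_e"].min())
            summary["ep_max_kcal_mol_e"] = float(ep["phi_kcal_mol_e"].max())
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
    )
    log.info("scenario complete: barrier=%.3f kcal/mol",
             summary["barrier_kcal_mol"])
    return summary
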