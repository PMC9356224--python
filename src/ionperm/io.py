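"""Plain-text serialization of beads, frames, and per-window samples.

Bead frames are written as PDB-format ATOM records with two repurposed
columns: the occupancy column holds the bead radius (A) and the B-factor
column holds the bead charge (e).  Because PDB name fields are too short
for free-form bead ids, every PDB carries a sidecar CSV mapping atom
serial -> (bead id, kind); the reader prefers the sidecar and falls back
to the truncated PDB fields when it is missing.

Per-window reaction-coordinate samples are CSV with columns
``run_id, time_ps, rc_A`` (units stated in the header comment).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Bead, Frame, InvalidParameterError

_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s} {res:<3s} A{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}\n"
)

_KIND_RES = {"ion": "ION", "reference": "REF", "partner": "PTN", "scaffold": "SCF"}
_RES_KIND = {v: k for k, v in _KIND_RES.items()}


def write_beads_pdb(path: str | Path, frames: Sequence[Frame] | Sequence[Bead]) -> None:
    """Write frames (as MODEL blocks) or a bare bead list to PDB + sidecar CSV."""
    path = Path(path)
    if len(frames) and isinstance(frames[0], Bead):
        frames = [Frame(time=0.0, beads=list(frames))] if _has_ion(frames) else None
        if frames is None:
            raise InvalidParameterError(
                "bare bead lists without ion/reference must use write_scaffold_pdb"
            )
    lines = [
        "REMARK   units: coordinates A, occupancy=bead radius A, "
        "B-factor=bead charge e\n"
    ]
    sidecar_rows = []
    for imodel, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {imodel:>4d}\n")
        for serial, bead in enumerate(frame.beads, start=1):
            lines.append(_atom_line(serial, bead))
            if imodel == 1:
                sidecar_rows.append(
                    {"serial": serial, "bead_id": bead.id, "kind": bead.kind}
                )
        lines.append("ENDMDL\n")
    lines.append("END\n")
    path.write_text("".join(lines))
    _sidecar_path(path).write_text(
        pd.DataFrame(sidecar_rows).to_csv(index=False)
    )


def write_scaffold_pdb(path: str | Path, beads: Sequence[Bead]) -> None:
    """Write a bead list (no ion/reference requirement) to PDB + sidecar."""
    path = Path(path)
    lines = [
        "REMARK   units: coordinates A, occupancy=bead radius A, "
        "B-factor=bead charge e\n"
    ]
    sidecar_rows = []
    for serial, bead in enumerate(beads, start=1):
        lines.append(_atom_line(serial, bead))
        sidecar_rows.append({"serial": serial, "bead_id": bead.id, "kind": bead.kind})
    lines.append("END\n")
    path.write_text("".join(lines))
    _sidecar_path(path).write_text(pd.DataFrame(sidecar_rows).to_csv(index=False))


def read_beads_pdb(path: str | Path) -> list[list[Bead]]:
    """Read a PDB written by this module; returns one bead list per MODEL.

    A file without MODEL records yields a single bead list.
    """
    path = Path(path)
    sidecar: dict[int, tuple[str, str]] = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        df = pd.read_csv(sc_path)
        sidecar = {
            int(r.serial): (str(r.bead_id), str(r.kind)) for r in df.itertuples()
        }
    models: list[list[Bead]] = []
    current: list[Bead] = []
    in_model = False
    for line in path.read_text().splitlines():
        if line.startswith("MODEL"):
            in_model = True
            current = []
        elif line.startswith("ENDMDL"):
            models.append(current)
            current = []
        elif line.startswith(("ATOM", "HETATM")):
            serial = int(line[6:11])
            name = line[12:16].strip()
            res = line[17:20].strip()
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            occ = float(line[54:60])
            bfac = float(line[60:66])
            if serial in sidecar:
                bead_id, kind = sidecar[serial]
            else:
                bead_id, kind = name, _RES_KIND.get(res, "scaffold")
            current.append(
                Bead(id=bead_id, kind=kind, xyz=np.array(xyz), radius=occ, charge=bfac)
            )
    if current and not in_model:
        models.append(current)
    if not models and current:
        models.append(current)
    return models


def read_frames_pdb(path: str | Path, sidecar_times: Sequence[float] | None = None
                    ) -> list[Frame]:
    """Read frames from a PDB; times come from the trajectory sidecar CSV."""
    path = Path(path)
    models = read_beads_pdb(path)
    times_path = path.with_suffix(".times.csv")
    if sidecar_times is not None:
        times = list(sidecar_times)
    elif times_path.exists():
        times = pd.read_csv(times_path, comment="#")["time_ps"].tolist()
    else:
        times = list(range(len(models)))
    return [Frame(time=float(t), beads=m) for t, m in zip(times, models)]


def write_frames(path: str | Path, frames: Sequence[Frame]) -> None:
    """Write frames as PDB models plus a sidecar CSV of times and ion track."""
    path = Path(path)
    write_beads_pdb(path, frames)
    rows = []
    for f in frames:
        ion = f.ion
        rows.append(
            {
                "time_ps": f.time,
                "ion_x_A": ion.xyz[0],
                "ion_y_A": ion.xyz[1],
                "ion_z_A": ion.xyz[2],
                "rc_A": f.rc.value,
            }
        )
    csv = "# units: time ps, coordinates A\n" + pd.DataFrame(rows).to_csv(index=False)
    path.with_suffix(".times.csv").write_text(csv)


def _atom_line(serial: int, bead: Bead) -> str:
    return _PDB_ATOM.format(
        serial=serial,
        name=str(bead.id)[:4],
        res=_KIND_RES[bead.kind],
        resseq=serial % 10000,
        x=bead.xyz[0],
        y=bead.xyz[1],
        z=bead.xyz[2],
        occ=bead.radius,
        b=bead.charge,
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".beads.csv")


def _has_ion(beads: Iterable[Bead]) -> bool:
    kinds = {b.kind for b in beads}
    return "ion" in kinds and "reference" in kinds


# ---------------------------------------------------------------------------
# per-window sample files


def write_window_samples_csv(path: str | Path,
                             run_ids: Sequence[int],
                             times: Sequence[float],
                             rc: Sequence[float]) -> None:
    """Write a per-window sample series as CSV (run_id, time_ps, rc_A)."""
    df = pd.DataFrame({"run_id": run_ids, "time_ps": times, "rc_A": rc})
    Path(path).write_text(
        "# units: time ps, reaction coordinate A\n" + df.to_csv(index=False)
    )


def read_window_samples_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
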