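"""Shared domain types, unit conventions, and physical constants.

Unit discipline (used everywhere in the package):

* lengths in angstrom (A)
* energies in kcal/mol
* times in picoseconds (ps)
* charges in elementary charge units (e)
* temperatures in kelvin (K)

Sign convention for the membrane normal: +Z points to the extracellular
side of the reference bead; Z = 0 is the Z position of the reference bead
(the analog of the mid-membrane anchor residue's C-alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KB",
    "COULOMB_K",
    "DEFAULT_TEMPERATURE",
    "Constants",
    "kT",
    "ReactionCoordinate",
    "Bead",
    "Frame",
    "IonpermError",
    "InvalidParameterError",
]

#: Boltzmann constant, kcal/(mol*K).  Frozen literal; not configurable so
#: that downstream numbers are bit-for-bit reproducible.
KB: float = 1.9872041e-3

#: Coulomb constant, kcal*A/(mol*e^2).  Frozen literal.
COULOMB_K: float = 332.0636

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE: float = 310.0

BEAD_KINDS = ("ion", "reference", "partner", "scaffold")


class IonpermError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(IonpermError, ValueError):
    """A parameter violated a documented precondition."""


@dataclass(frozen=True)
class Constants:
    """Physical constants bundle; fields are frozen package literals."""

    kB: float = KB
    coulomb_k: float = COULOMB_K
    temperature: float = DEFAULT_TEMPERATURE


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kB*T in kcal/mol.

    Parameters
    ----------
    temperature:
        Absolute temperature in K; must be positive.
    """
    if not np.isfinite(temperature) or temperature <= 0:
        raise InvalidParameterError(
            f"temperature must be positive and finite, got {temperature!r}"
        )
    return KB * temperature


@dataclass(frozen=True)
class ReactionCoordinate:
    """Signed Z offset of the ion relative to the reference bead.

    ``value = ion_z - ref_z``; positive values are on the extracellular
    side of the reference.
    """

    ion_z: float
    ref_z: float

    @property
    def value(self) -> float:
        return self.ion_z - self.ref_z


@dataclass
class Bead:
    """A coarse bead: the stand-in for an atom, residue, or lipid headgroup."""

    id: str
    kind: str
    xyz: np.ndarray
    radius: float = 0.0
    charge: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in BEAD_KINDS:
            raise InvalidParameterError(
                f"bead kind must be one of {BEAD_KINDS}, got {self.kind!r}"
            )
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise InvalidParameterError("bead xyz must be a length-3 vector")
        if self.radius < 0:
            raise InvalidParameterError("bead radius must be >= 0")


@dataclass
class Frame:
    """One time point: beads plus the derived reaction coordinate.

    Exactly one bead of kind ``ion`` and one of kind ``reference`` are
    required; the reaction coordinate is always derived from their Z
    positions (never stored independently), so the two ways of computing
    it agree by construction.
    """

    time: float
    beads: list[Bead] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_ion = sum(1 for b in self.beads if b.kind == "ion")
        n_ref = sum(1 for b in self.beads if b.kind == "reference")
        if n_ion != 1 or n_ref != 1:
            raise InvalidParameterError(
                f"frame requires exactly one ion and one reference bead "
                f"(got {n_ion} ion, {n_ref} reference)"
            )

    @property
    def ion(self) -> Bead:
        return next(b for b in self.beads if b.kind == "ion")

    @property
    def reference(self) -> Bead:
        return next(b for b in self.beads if b.kind == "reference")

    @property
    def rc(self) -> ReactionCoordinate:
        return ReactionCoordinate(ion_z=float(self.ion.xyz[2]),
                                  ref_z=float(self.reference.xyz[2]))

    def partner_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.beads:
            if b.kind == "partner":
                seen.setdefault(b.id)
        return list(seen)

    def partner_beads(self, partner_id: str) -> list[Bead]:
        return [b for b in self.beads if b.kind == "partner" and b.id == partner_id]


def min_partner_distance(frame: Frame, partner_id: str) -> float:
    """Minimum ion-to-bead distance over the partner's beads (inf if absent)."""
    ion_xyz = frame.ion.xyz
    beads = frame.partner_beads(partner_id)
    if not beads:
        return float("inf")
    pts = np.array([b.xyz for b in beads])
    return float(np.min(np.linalg.norm(pts - ion_xyz, axis=1)))
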