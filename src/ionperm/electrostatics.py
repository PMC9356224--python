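"""Finite-difference linearized Poisson-Boltzmann on a membrane-slab model.

Discretized equation (lengths A, energies kcal/mol, charges e):

    div(eps * grad phi) - eps_w * kappa^2(r) * phi = -4*pi*C*rho

with C the Coulomb constant, so a point charge q in uniform dielectric
with no screening recovers phi(r) = C*q/(eps*r), and with screening the
Debye-Hueckel form C*q*exp(-kappa*r)/(eps*r).  phi is in kcal/(mol*e).

The dielectric map is a membrane slab (hydrophobic core flanked by
headgroup layers) perforated by a water-filled cylindrical hole; mobile
ions (nonzero kappa^2) exist only in water that is outside beads and
outside the membrane slab.  Bead interiors get the protein dielectric.

The linear system (7-point stencil, harmonic-mean face dielectrics,
Dirichlet boundary from Debye-Hueckel superposition of the source
charges) is symmetric positive definite and solved with conjugate
gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import cg

from .core import (
    COULOMB_K,
    DEFAULT_TEMPERATURE,
    Bead,
    InvalidParameterError,
    IonpermError,
    kT,
)
from .geometry import PathProfile

__all__ = [
    "DielectricModel",
    "GridSpec",
    "Maps",
    "EPField",
    "debye_kappa2",
    "build_maps",
    "solve_lpb",
    "sample_along_path",
    "SolverError",
]

AVOGADRO = 6.02214076e23


class SolverError(IonpermError):
    """The linear solver failed to converge."""


@dataclass(frozen=True)
class DielectricModel:
    """Slab + cylindrical-hole dielectric and ion-accessibility model."""

    eps_protein: float = 2.0
    eps_core: float = 2.0
    eps_head: float = 30.0
    eps_water: float = 80.0
    core_thickness: float = 26.0   # A, full thickness of the hydrophobic core
    head_thickness: float = 8.0    # A, per leaflet
    hole_radius: float = 18.0      # A
    hole_axis_xy: tuple[float, float] = (0.0, 0.0)
    ionic_strength: float = 0.150  # mol/L
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("eps_protein", "eps_core", "eps_head", "eps_water"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.core_thickness < 0 or self.head_thickness < 0:
            raise InvalidParameterError("layer thicknesses must be >= 0")
        if self.ionic_strength < 0:
            raise InvalidParameterError("ionic_strength must be >= 0")

    @property
    def kappa2_bulk(self) -> float:
        return debye_kappa2(self.ionic_strength, self.eps_water, self.temperature)


def debye_kappa2(ionic_strength: float, eps: float,
                 temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse squared Debye length, A^-2, for a 1:1 electrolyte.

    kappa^2 = 8*pi*C*n / (eps*kB*T) with n the per-species number density
    in A^-3 (n = N_A * I * 1e-27 for ionic strength I in mol/L).  At
    I = 0.150 M, eps = 80, T = 310 K this gives a Debye length of ~8.1 A.
    """
    n = AVOGADRO * ionic_strength * 1e-27
    return 8.0 * math.pi * COULOMB_K * n / (eps * kT(temperature))


@dataclass(frozen=True)
class GridSpec:
    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.shape[d])
            for d in range(3)
        )


@dataclass
class Maps:
    """Node maps of dielectric, screening, and spread charge."""

    grid: GridSpec
    eps: np.ndarray      # node dielectric
    kappa2: np.ndarray   # A^-2; zero wherever mobile ions are excluded
    charge: np.ndarray   # e per node
    eps_water: float
    kappa2_bulk: float


@dataclass
class EPField:
    grid: GridSpec
    phi: np.ndarray      # kcal/(mol*e)
    eps: np.ndarray
    kappa2: np.ndarray


def build_maps(
    beads: Sequence[Bead],
    model: DielectricModel,
    spacing: float = 1.0,
    padding: float = 20.0,
    box: tuple[Sequence[float], Sequence[float]] | None = None,
) -> Maps:
    """Assign dielectric/screening/charge values to every grid node.

    Priority per node: inside a bead -> protein dielectric, no ions;
    else inside the hydrophobic core and outside the hole -> core
    dielectric, no ions; else inside a headgroup layer and outside the
    hole -> headgroup dielectric, no ions; else water with bulk Debye
    screening (the cylindrical hole is therefore ion-accessible water).
    """
    if spacing <= 0:
        raise InvalidParameterError("spacing must be > 0")
    if box is None:
        if not beads:
            raise InvalidParameterError("need beads or an explicit box")
        pts = np.array([b.xyz for b in beads])
        lo = pts.min(axis=0) - padding
        hi = pts.max(axis=0) + padding
    else:
        lo = np.asarray(box[0], dtype=float)
        hi = np.asarray(box[1], dtype=float)
    shape = tuple(int(math.floor((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    grid = GridSpec(origin=tuple(lo), spacing=spacing, shape=shape)
    x, y, z = grid.axes()

    for b in beads:
        if np.any(b.xyz < lo) or np.any(b.xyz > lo + spacing * (np.array(shape) - 1)):
            raise InvalidParameterError(f"bead {b.id!r} lies outside the grid box")

    eps = np.full(shape, model.eps_water)
    kappa2 = np.full(shape, model.kappa2_bulk)

    zz = z[None, None, :]
    xy_r = np.sqrt(
        (x[:, None, None] - model.hole_axis_xy[0]) ** 2
        + (y[None, :, None] - model.hole_axis_xy[1]) ** 2
    )
    half_core = model.core_thickness / 2.0
    in_core = (np.abs(zz) <= half_core) if model.core_thickness > 0 else \
        np.zeros((1, 1, shape[2]), dtype=bool)
    in_head = (
        (np.abs(zz) > half_core)
        & (np.abs(zz) <= half_core + model.head_thickness)
    ) if model.head_thickness > 0 else np.zeros((1, 1, shape[2]), dtype=bool)
    outside_hole = xy_r > model.hole_radius
    core_mask = np.broadcast_to(in_core, shape) & outside_hole
    head_mask = np.broadcast_to(in_head, shape) & outside_hole
    eps[core_mask] = model.eps_core
    eps[head_mask] = model.eps_head
    kappa2[core_mask | head_mask] = 0.0

    # bead interiors override the slab
    for b in beads:
        if b.radius <= 0:
            continue
        ilo = np.maximum(
            np.floor((b.xyz - b.radius - lo) / spacing).astype(int), 0
        )
        ihi = np.minimum(
            np.ceil((b.xyz + b.radius - lo) / spacing).astype(int) + 1,
            np.array(shape),
        )
        sl = tuple(slice(ilo[d], ihi[d]) for d in range(3))
        gx, gy, gz = np.meshgrid(
            x[sl[0]], y[sl[1]], z[sl[2]], indexing="ij"
        )
        inside = (
            (gx - b.xyz[0]) ** 2 + (gy - b.xyz[1]) ** 2 + (gz - b.xyz[2]) ** 2
            <= b.radius**2
        )
        eps[sl][inside] = model.eps_protein
        kappa2[sl][inside] = 0.0

    charge = np.zeros(shape)
    for b in beads:
        if b.charge == 0.0:
            continue
        _spread_trilinear(charge, grid, b.xyz, b.charge)

    return Maps(
        grid=grid, eps=eps, kappa2=kappa2, charge=charge,
        eps_water=model.eps_water, kappa2_bulk=model.kappa2_bulk,
    )


def _spread_trilinear(charge: np.ndarray, grid: GridSpec, xyz: np.ndarray,
                      q: float) -> None:
    rel = (np.asarray(xyz) - np.asarray(grid.origin)) / grid.spacing
    i0 = np.floor(rel).astype(int)
    frac = rel - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                idx = (
                    min(i0[0] + dx, charge.shape[0] - 1),
                    min(i0[1] + dy, charge.shape[1] - 1),
                    min(i0[2] + dz, charge.shape[2] - 1),
                )
                charge[idx] += q * w


def _boundary_phi(maps: Maps) -> np.ndarray:
    """Dirichlet boundary values: screened-Coulomb superposition of sources."""
    grid = maps.grid
    phi = np.zeros(grid.shape)
    qs = np.argwhere(maps.charge != 0.0)
    if len(qs) == 0:
        return phi
    x, y, z = grid.axes()
    kappa = math.sqrt(maps.kappa2_bulk)
    faces: list[tuple[slice | int, ...]] = []
    nx, ny, nz = grid.shape
    faces = [
        (0, slice(None), slice(None)),
        (nx - 1, slice(None), slice(None)),
        (slice(None), 0, slice(None)),
        (slice(None), ny - 1, slice(None)),
        (slice(None), slice(None), 0),
        (slice(None), slice(None), nz - 1),
    ]
    gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
    for face in faces:
        fx, fy, fz = gx[face], gy[face], gz[face]
        acc = np.zeros_like(fx)
        for (i, j, k) in qs:
            q = maps.charge[i, j, k]
            r = np.sqrt((fx - x[i]) ** 2 + (fy - y[j]) ** 2 + (fz - z[k]) ** 2)
            r = np.maximum(r, 0.5 * grid.spacing)
            acc += COULOMB_K * q * np.exp(-kappa * r) / (maps.eps_water * r)
        phi[face] = acc
    return phi


def solve_lpb(maps: Maps, rtol: float = 1e-8, maxiter: int = 20_000) -> EPField:
    """Solve the linearized PB system on the grid; returns the potential field.

    Dirichlet boundary values come from Debye-Hueckel superposition of
    the source charges (with bulk screening); interior nodes satisfy the
    7-point finite-difference equation with harmonic-mean face
    dielectrics.  Conjugate gradients on the SPD system.
    """
    grid = maps.grid
    h = grid.spacing
    nx, ny, nz = grid.shape
    if nx < 3 or ny < 3 or nz < 3:
        raise InvalidParameterError("grid too small to solve (need >= 3 nodes/axis)")
    phi_b = _boundary_phi(maps)
    if not np.any(maps.charge) and not np.any(phi_b):
        return EPField(grid=grid, phi=np.zeros(grid.shape), eps=maps.eps,
                       kappa2=maps.kappa2)

    eps = maps.eps

    def hmean(a, b):
        return 2.0 * a * b / (a + b)

    # face dielectrics along each axis
    fx = hmean(eps[:-1, :, :], eps[1:, :, :])   # between i and i+1
    fy = hmean(eps[:, :-1, :], eps[:, 1:, :])
    fz = hmean(eps[:, :, :-1], eps[:, :, 1:])

    interior = np.ones(grid.shape, dtype=bool)
    interior[0, :, :] = interior[-1, :, :] = False
    interior[:, 0, :] = interior[:, -1, :] = False
    interior[:, :, 0] = interior[:, :, -1] = False
    idx_map = -np.ones(grid.shape, dtype=np.int64)
    n_unknown = int(interior.sum())
    idx_map[interior] = np.arange(n_unknown)

    ii, jj, kk = np.nonzero(interior)
    rows_d = idx_map[ii, jj, kk]
    diag = (
        fx[ii - 1, jj, kk] + fx[ii, jj, kk]
        + fy[ii, jj - 1, kk] + fy[ii, jj, kk]
        + fz[ii, jj, kk - 1] + fz[ii, jj, kk]
        + h * h * maps.eps_water * maps.kappa2[ii, jj, kk]
    )
    b = 4.0 * math.pi * COULOMB_K * maps.charge[ii, jj, kk] / h

    rows: list[np.ndarray] = [rows_d]
    cols: list[np.ndarray] = [rows_d]
    vals: list[np.ndarray] = [diag]
    for di, dj, dk, face in (
        (-1, 0, 0, fx[ii - 1, jj, kk]),
        (1, 0, 0, fx[ii, jj, kk]),
        (0, -1, 0, fy[ii, jj - 1, kk]),
        (0, 1, 0, fy[ii, jj, kk]),
        (0, 0, -1, fz[ii, jj, kk - 1]),
        (0, 0, 1, fz[ii, jj, kk]),
    ):
        ni, nj, nk = ii + di, jj + dj, kk + dk
        nbr = idx_map[ni, nj, nk]
        is_unknown = nbr >= 0
        rows.append(rows_d[is_unknown])
        cols.append(nbr[is_unknown])
        vals.append(-face[is_unknown])
        # Dirichlet neighbors contribute to the RHS
        bmask = ~is_unknown
        np.add.at(b, rows_d[bmask], face[bmask] * phi_b[ni[bmask], nj[bmask],
                                                        nk[bmask]])

    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown),
    ).tocsr()
    precond = sparse.diags(1.0 / A.diagonal())
    x, info = cg(A, b, rtol=rtol, atol=0.0, maxiter=maxiter, M=precond)
    if info != 0:
        raise SolverError(f"conjugate gradients failed to converge (info={info})")

    phi = phi_b.copy()
    phi[interior] = x
    return EPField(grid=grid, phi=phi, eps=maps.eps, kappa2=maps.kappa2)


def sample_along_path(field: EPField, path: PathProfile) -> pd.DataFrame:
    """Trilinear interpolation of phi at each defined path bin.

    Returns a DataFrame with columns ``z_A, phi_kcal_mol_e``.
    """
    x, y, z = field.grid.axes()
    interp = RegularGridInterpolator((x, y, z), field.phi, bounds_error=True)
    mask = path.defined
    pts = np.column_stack(
        [path.mean_xy[mask, 0], path.mean_xy[mask, 1], path.z_bins[mask]]
    )
    outside = []
    for p, zb in zip(pts, path.z_bins[mask]):
        if not (
            x[0] <= p[0] <= x[-1] and y[0] <= p[1] <= y[-1]
            and z[0] <= p[2] <= z[-1]
        ):
            outside.append(float(zb))
    if outside:
        raise InvalidParameterError(
            f"path bins outside the potential grid at z = {outside}"
        )
    vals = interp(pts)
    return pd.DataFrame({"z_A": path.z_bins[mask], "phi_kcal_mol_e": vals})
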