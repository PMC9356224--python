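import math

import numpy as np
import pytest

from ionperm.core import COULOMB_K, Bead, InvalidParameterError, kT
from ionperm.electrostatics import (
    DielectricModel,
    EPField,
    GridSpec,
    build_maps,
    debye_kappa2,
    sample_along_path,
    solve_lpb,
)
from ionperm.geometry import PathProfile


def _point_charge(q=1.0, xyz=(0.0, 0.0, 0.0)):
    return Bead("q", "partner", np.asarray(xyz, float), radius=0.0, charge=q)


def _uniform_water(ionic_strength=0.0):
    return DielectricModel(core_thickness=0.0, head_thickness=0.0,
                           ionic_strength=ionic_strength)


def _shell_mean(field, r):
    x, y, z = field.grid.axes()
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    shell = np.abs(np.sqrt(X**2 + Y**2 + Z**2) - r) < 1e-9
    return float(field.phi[shell].mean())


class TestDebyeScreening:
    def test_debye_length_matches_independent_si_computation(self):
        # SI: lambda^2 = eps0*epsr*kB*T / (2*NA*e^2*I*1000)
        eps0, e, kb, na = 8.8541878128e-12, 1.602176634e-19, 1.380649e-23, \
            6.02214076e23
        lam_si = math.sqrt(eps0 * 80.0 * kb * 310.0 / (2 * na * e**2 * 150.0)) \
            * 1e10
        lam_pkg = 1.0 / math.sqrt(debye_kappa2(0.150, 80.0, 310.0))
        assert lam_pkg == pytest.approx(lam_si, rel=5e-3)
        assert lam_pkg == pytest.approx(8.0, abs=0.15)

    def test_zero_ionic_strength_no_screening(self):
        assert debye_kappa2(0.0, 80.0, 310.0) == 0.0


class TestBuildMaps:
    def test_membrane_slab_regions(self):
        model = DielectricModel()
        box = (np.array([-30.0, -30.0, -30.0]), np.array([30.0, 30.0, 30.0]))
        maps = build_maps([], model, spacing=1.0, box=box)
        x, y, z = maps.grid.axes()

        def node(px, py, pz):
            return (int(np.argmin(np.abs(x - px))),
                    int(np.argmin(np.abs(y - py))),
                    int(np.argmin(np.abs(z - pz))))

        # mid-plane, 25 A off-axis: outside the 18 A hole -> core, no ions
        i = node(25, 0, 0)
        assert maps.eps[i] == model.eps_core
        assert maps.kappa2[i] == 0.0
        # on-axis water column inside the hole: screened water
        i = node(0, 0, 0)
        assert maps.eps[i] == model.eps_water
        assert maps.kappa2[i] > 0.0
        # headgroup layer outside the hole
        i = node(25, 0, 15)
        assert maps.eps[i] == model.eps_head
        assert maps.kappa2[i] == 0.0
        # bulk solvent above the slab
        i = node(0, 0, 25)
        assert maps.eps[i] == model.eps_water
        assert maps.kappa2[i] > 0.0

    def test_no_membrane_is_uniform_water(self):
        maps = build_maps([_point_charge()], _uniform_water(0.150), spacing=2.0,
                          padding=10.0)
        assert np.all(maps.eps == 80.0)
        assert np.all(maps.kappa2 == maps.kappa2_bulk)

    def test_bead_interior_gets_protein_eps(self):
        bead = Bead("B", "scaffold", np.zeros(3), radius=3.0, charge=0.0)
        maps = build_maps([bead], _uniform_water(0.150), spacing=1.0,
                          padding=8.0)
        x, y, z = maps.grid.axes()
        i0 = (int(np.argmin(np.abs(x))), int(np.argmin(np.abs(y))),
              int(np.argmin(np.abs(z))))
        assert maps.eps[i0] == 2.0
        assert maps.kappa2[i0] == 0.0

    def test_bead_outside_box_rejected(self):
        bead = _point_charge(xyz=(100.0, 0.0, 0.0))
        box = (np.array([-5.0] * 3), np.array([5.0] * 3))
        with pytest.raises(InvalidParameterError):
            build_maps([bead], _uniform_water(), spacing=1.0, box=box)

    def test_charge_conserved_by_spreading(self):
        maps = build_maps([_point_charge(q=-1.0, xyz=(0.3, -0.2, 0.7))],
                          _uniform_water(), spacing=1.0, padding=8.0)
        assert maps.charge.sum() == pytest.approx(-1.0)


class TestSolveLpb:
    def test_coulomb_limit(self):
        maps = build_maps([_point_charge()], _uniform_water(0.0), spacing=1.0,
                          padding=16.0)
        field = solve_lpb(maps)
        for r in (3.0, 5.0, 10.0):
            exact = COULOMB_K / (80.0 * r)
            assert _shell_mean(field, r) == pytest.approx(exact, rel=0.05)

    def test_debye_hueckel_limit(self):
        # kappa^-1 ~ 8 A at 150 mM
        model = _uniform_water(0.150)
        maps = build_maps([_point_charge()], model, spacing=1.0, padding=16.0)
        field = solve_lpb(maps)
        kappa = math.sqrt(model.kappa2_bulk)
        for r in (3.0, 5.0, 10.0):  # 3*spacing <= r <= box/3
            exact = COULOMB_K * math.exp(-kappa * r) / (80.0 * r)
            assert _shell_mean(field, r) == pytest.approx(exact, rel=0.05)

    def test_superposition(self):
        model = _uniform_water(0.150)
        box = (np.array([-12.0] * 3), np.array([12.0] * 3))
        q1 = _point_charge(1.0, (-3.0, 0.0, 0.0))
        q2 = _point_charge(-1.0, (3.0, 0.0, 1.0))
        f1 = solve_lpb(build_maps([q1], model, spacing=1.0, box=box))
        f2 = solve_lpb(build_maps([q2], model, spacing=1.0, box=box))
        f12 = solve_lpb(build_maps([q1, q2], model, spacing=1.0, box=box))
        np.testing.assert_allclose(f12.phi, f1.phi + f2.phi, atol=1e-5)

    def test_zero_sources_zero_field(self):
        bead = Bead("B", "scaffold", np.zeros(3), radius=2.0, charge=0.0)
        maps = build_maps([bead], _uniform_water(0.150), spacing=1.5,
                          padding=8.0)
        field = solve_lpb(maps)
        assert np.all(field.phi == 0.0)

    def test_grid_refinement_convergence(self):
        # halving the spacing changes the sampled potential by <= 5% RMS
        model = _uniform_water(0.150)
        box = (np.array([-10.0] * 3), np.array([10.0] * 3))
        q = _point_charge(1.0, (0.0, 0.0, 0.0))
        path = PathProfile(
            z_bins=np.arange(-6.0, 6.1, 1.0),
            mean_xy=np.tile([5.0, 0.0], (13, 1)),
            n_samples=np.full(13, 100), min_samples=10,
        )
        coarse = sample_along_path(
            solve_lpb(build_maps([q], model, spacing=1.0, box=box)), path
        )["phi_kcal_mol_e"].to_numpy()
        fine = sample_along_path(
            solve_lpb(build_maps([q], model, spacing=0.5, box=box)), path
        )["phi_kcal_mol_e"].to_numpy()
        rel = np.sqrt(np.mean((coarse - fine) ** 2)) / np.sqrt(np.mean(fine**2))
        assert rel <= 0.05


class TestSampleAlongPath:
    def _uniform_field(self, c):
        grid = GridSpec(origin=(-5.0, -5.0, -5.0), spacing=1.0, shape=(11, 11, 11))
        phi = np.full(grid.shape, c)
        return EPField(grid=grid, phi=phi, eps=np.full(grid.shape, 80.0),
                       kappa2=np.zeros(grid.shape))

    def _straight_path(self, zlo=-4.0, zhi=4.0, step=1.0, xy=(0.0, 0.0)):
        z = np.arange(zlo, zhi + 0.5 * step, step)
        return PathProfile(
            z_bins=z, mean_xy=np.tile(xy, (len(z), 1)),
            n_samples=np.full(len(z), 100), min_samples=10,
        )

    def test_uniform_field_samples_constant(self):
        df = sample_along_path(self._uniform_field(2.5), self._straight_path())
        assert np.all(df["phi_kcal_mol_e"] == 2.5)

    def test_out_of_grid_bins_listed(self):
        path = self._straight_path(zlo=-20.0, zhi=20.0, step=5.0)
        with pytest.raises(InvalidParameterError, match="outside"):
            sample_along_path(self._uniform_field(0.0), path)

    def test_negative_charge_beside_path_dips_and_decays(self):
        model = _uniform_water(0.150)
        box = (np.array([-10.0, -10.0, -14.0]), np.array([10.0, 10.0, 14.0]))
        q = _point_charge(-1.0, (2.0, 0.0, 0.0))
        field = solve_lpb(build_maps([q], model, spacing=1.0, box=box))
        path = self._straight_path(zlo=-10.0, zhi=10.0, step=1.0)
        df = sample_along_path(field, path)
        phi = df["phi_kcal_mol_e"].to_numpy()
        z = df["z_A"].to_numpy()
        imin = int(np.argmin(phi))
        assert z[imin] == pytest.approx(0.0)  # nearest approach
        assert np.all(phi < 0)
        # monotone decay of |phi| on each side over 5 bins
        assert np.all(np.diff(phi[imin:imin + 6]) > 0)
        assert np.all(np.diff(phi[imin - 5:imin + 1]) < 0)

    def test_popg_like_charge_makes_path_more_negative(self):
        # groove with a negative headgroup bead vs without: potential along
        # the path is strictly lower near the bead
        model = DielectricModel(hole_radius=8.0)
        box = (np.array([-12.0, -12.0, -16.0]), np.array([12.0, 12.0, 16.0]))
        popg = Bead("POPG", "partner", np.array([2.0, 0.0, -1.0]), radius=1.0,
                    charge=-1.0)
        neutral_scaffold = Bead("S", "scaffold", np.array([6.0, 0.0, 0.0]),
                                radius=2.0, charge=0.0)
        with_lipid = solve_lpb(
            build_maps([neutral_scaffold, popg], model, spacing=1.0, box=box)
        )
        without = solve_lpb(
            build_maps([neutral_scaffold], model, spacing=1.0, box=box)
        )
        path = self._straight_path(zlo=-7.0, zhi=5.0, step=1.0)
        a = sample_along_path(with_lipid, path)["phi_kcal_mol_e"].to_numpy()
        b = sample_along_path(without, path)["phi_kcal_mol_e"].to_numpy()
        near = np.abs(path.z_bins - (-1.0)) <= 6.0
        assert np.all(a[near] < b[near])
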