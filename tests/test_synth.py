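import math

import numpy as np
import pytest

from ionperm import synth
from ionperm.core import InvalidParameterError, kT
from ionperm.synth import (
    GaussianTerm,
    GroovePotential,
    HarmonicBias,
    InstabilityError,
    LangevinParams,
    PartnerRule,
    SteeredProtocol,
    UncoveredWindowError,
)

from conftest import make_frame


class TestGroovePotential:
    def test_preset_barriers_match_design(self):
        for name, target in synth.PRESET_BARRIERS.items():
            pot = synth.preset_potential(name)
            barrier = pot.designed_barrier((-12.25, 11.5))
            assert barrier == pytest.approx(target, abs=0.05)

    def test_unknown_preset(self):
        with pytest.raises(InvalidParameterError):
            synth.preset_potential("closed")

    def test_energy_finite_everywhere(self):
        pot = synth.preset_potential("open_pc")
        xyz = np.random.default_rng(0).uniform(-50, 50, size=(100, 3))
        assert np.all(np.isfinite(pot.energy(xyz)))

    def test_gradient_matches_finite_difference(self):
        pot = synth.preset_potential("l302a")
        rng = np.random.default_rng(1)
        x = rng.uniform(-5, 5, size=(10, 3))
        g = pot.grad(x)
        eps = 1e-6
        for d in range(3):
            xp = x.copy(); xp[:, d] += eps
            xm = x.copy(); xm[:, d] -= eps
            num = (pot.energy(xp) - pot.energy(xm)) / (2 * eps)
            np.testing.assert_allclose(g[:, d], num, atol=1e-5)

    def test_designed_pmf_is_uz_plus_radial_entropy(self):
        pot = GroovePotential(z_terms=(GaussianTerm(2.0, 0.0, 3.0),), radial_k=2.0)
        z = np.linspace(-5, 5, 11)
        expected = pot.uz(z) + kT(310) * math.log(2.0 / (2 * math.pi * kT(310)))
        np.testing.assert_allclose(pot.designed_pmf(z), expected)


class TestLangevin:
    def test_zero_steps_gives_initial_frame_only(self, flat_potential):
        traj = synth.simulate_langevin(
            flat_potential, LangevinParams(n_steps=0, seed=1), x0=(1.0, 2.0, 3.0)
        )
        assert traj.n_frames == 1
        np.testing.assert_allclose(traj.xyz[0], [1.0, 2.0, 3.0])

    def test_seed_determinism(self, open_pg):
        params = LangevinParams(n_steps=500, seed=11)
        a = synth.simulate_langevin(open_pg, params)
        b = synth.simulate_langevin(open_pg, params)
        np.testing.assert_array_equal(a.xyz, b.xyz)

    def test_instability_error_advises_dt(self):
        steep = GroovePotential(z_terms=(), radial_k=1000.0)
        with pytest.raises(InstabilityError, match="dt"):
            synth.simulate_langevin(
                steep, LangevinParams(n_steps=10, seed=0), x0=(50.0, 0.0, 0.0)
            )

    def test_free_diffusion_msd(self, flat_potential):
        # ensemble of walkers: MSD along z after time t is 2*D*t
        d = 0.2
        params = LangevinParams(dt=0.01, diffusion=d, n_steps=200,
                                frame_stride=200, seed=3)
        traj = synth.simulate_langevin(flat_potential, params,
                                       x0=np.zeros((1500, 3)))
        t = traj.times[-1]
        dz2 = traj.xyz[-1][:, 2] ** 2
        msd, se = dz2.mean(), dz2.std(ddof=1) / math.sqrt(len(dz2))
        assert abs(msd - 2 * d * t) < 3 * se

    def test_harmonic_window_variance(self, flat_potential):
        # quick version; the tight 5% check lives in the acceptance suite
        k = 10.0
        params = LangevinParams(dt=0.01, diffusion=0.2, n_steps=30_000, seed=7)
        traj = synth.simulate_langevin(
            flat_potential, params, bias=HarmonicBias(0.0, k)
        )
        var = traj.rc()[1000:].var()
        assert var == pytest.approx(kT(310) / k, rel=0.10)


class TestSteeredInit:
    def test_covers_all_mutant_style_windows(self, flat_potential):
        centers = [-12.25 + 0.25 * i for i in range(96)]
        protocol = SteeredProtocol(force_constant=5.0, velocity=10.0,
                                   start_z=-12.25, end_z=11.5)
        params = LangevinParams(dt=0.05, diffusion=0.2, seed=2)
        starts = synth.run_steered_init(flat_potential, protocol, params, centers)
        assert sorted(starts) == pytest.approx(centers)

    def test_slow_pull_tracks_restraint(self, open_pg):
        protocol = SteeredProtocol(force_constant=5.0, velocity=50.0,
                                   start_z=-2.0, end_z=2.0)
        params = LangevinParams(dt=0.02, diffusion=0.2, seed=4)
        starts = synth.run_steered_init(open_pg, protocol, params, [0.0])
        assert abs(starts[0.0][2] - 0.0) <= 0.25

    def test_window_outside_range_errors(self, flat_potential):
        protocol = SteeredProtocol(start_z=-2.0, end_z=2.0)
        with pytest.raises(UncoveredWindowError, match="5"):
            synth.run_steered_init(
                flat_potential, protocol, LangevinParams(seed=0), [0.0, 5.0]
            )

    def test_equal_endpoints_rejected(self):
        with pytest.raises(InvalidParameterError):
            SteeredProtocol(start_z=1.0, end_z=1.0)


class TestPartnerFrames:
    def _frames(self, n, rc=0.0):
        return [make_frame(2.0 * i, (0.0, 0.0, rc)) for i in range(n)]

    def test_prob_one_means_contact_every_frame(self):
        rule = PartnerRule("P", z_window=(-1, 1), contact_prob=1.0)
        frames = synth.emit_partner_frames(self._frames(200), [rule], seed=0)
        from ionperm.core import min_partner_distance

        assert all(min_partner_distance(f, "P") < 3.0 for f in frames)

    def test_table_like_fraction_within_binomial_error(self):
        p = 0.829
        n = 4500
        rule = PartnerRule("POPG", z_window=(-5, 5), contact_prob=p)
        frames = synth.emit_partner_frames(self._frames(n), [rule], seed=1)
        from ionperm.core import min_partner_distance

        frac = sum(min_partner_distance(f, "POPG") < 3.0 for f in frames) / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_outside_z_window_never_contacts(self):
        rule = PartnerRule("P", z_window=(5, 6), contact_prob=1.0)
        frames = synth.emit_partner_frames(self._frames(50, rc=0.0), [rule], seed=0)
        from ionperm.core import min_partner_distance

        assert all(min_partner_distance(f, "P") >= 4.0 for f in frames)

    def test_empty_rules_identity(self):
        frames = self._frames(5)
        assert synth.emit_partner_frames(frames, [], seed=0) == frames

    def test_duplicate_ids_rejected(self):
        rules = [PartnerRule("P", (0, 1)), PartnerRule("P", (1, 2))]
        with pytest.raises(InvalidParameterError):
            synth.emit_partner_frames(self._frames(1), rules, seed=0)

    def test_exact_contact_frames(self):
        frames = synth.emit_exact_contact_frames(100, {"A": 37, "B": 0}, seed=5)
        from ionperm.core import min_partner_distance

        n_a = sum(min_partner_distance(f, "A") < 3.0 for f in frames)
        n_b = sum(min_partner_distance(f, "B") < 3.0 for f in frames)
        assert (n_a, n_b) == (37, 0)


class TestGrooveGeometry:
    def test_ideal_cylinder_lumen(self):
        beads = synth.build_groove_geometry("ideal_cylinder", ring_radius=6.0,
                                            bead_radius=2.0)
        # clearance from the axis to the nearest bead surface is exactly 4
        pts = np.array([b.xyz for b in beads])
        r = np.array([b.radius for b in beads])
        for z in (-5.0, 0.0, 3.5):
            d = np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2 + (pts[:, 2] - z) ** 2)
            assert np.min(d - r) == pytest.approx(4.0, abs=1e-9)

    def test_constricted_neck_location(self):
        beads = synth.build_groove_geometry("constricted")
        pts = np.array([b.xyz for b in beads])
        r = np.array([b.radius for b in beads])
        zs = np.arange(-10, 10.01, 0.25)
        clearance = [
            np.min(np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2
                           + (pts[:, 2] - z) ** 2) - r)
            for z in zs
        ]
        assert abs(zs[int(np.argmin(clearance))] - 3.5) <= 0.5

    def test_open_preset_variation_below_1A(self):
        beads = synth.build_groove_geometry("open")
        pts = np.array([b.xyz for b in beads])
        r = np.array([b.radius for b in beads])
        zs = np.arange(-8, 8.01, 0.5)
        clearance = np.array([
            np.min(np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2
                           + (pts[:, 2] - z) ** 2) - r)
            for z in zs
        ])
        assert clearance.max() - clearance.min() <= 1.0

    def test_unknown_preset(self):
        with pytest.raises(InvalidParameterError):
            synth.build_groove_geometry("wormhole")


class TestSelfConsistency:
    def test_unbiased_histogram_matches_designed_pmf(self, open_pg):
        # long unbiased run: -kT ln(hist) must match the designed profile
        params = LangevinParams(dt=0.01, diffusion=0.2, n_steps=400_000,
                                frame_stride=10, seed=12)
        traj = synth.simulate_langevin(open_pg, params, x0=(0.0, 0.0, -2.0))
        rc = traj.rc()[100:]
        counts, edges = np.histogram(rc, bins=np.arange(-8, 8.01, 0.25))
        centers = 0.5 * (edges[:-1] + edges[1:])
        well = counts >= 200
        est = -kT(310) * np.log(counts[well])
        ref = np.asarray(open_pg.designed_pmf(centers[well]))
        diff = est - ref
        diff -= diff.mean()
        assert np.sqrt(np.mean(diff**2)) <= 0.3

    def test_boltzmann_window_sampler_statistics(self, flat_potential):
        # flat profile + harmonic bias: samples are Gaussian at the center
        from ionperm.umbrella import WindowSpec

        w = WindowSpec(center=1.0, force_constant=10.0)
        (s,) = synth.sample_windows_boltzmann(flat_potential, [w], 50_000, seed=9)
        assert s.rc_values.mean() == pytest.approx(1.0, abs=0.01)
        assert s.rc_values.var() == pytest.approx(kT(310) / 10.0, rel=0.03)
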