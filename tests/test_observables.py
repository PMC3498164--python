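"""Size, dynamics, scattering, contact-map and profile observables."""

import numpy as np
import pytest

import bondfluct as bf
from bondfluct.engine import SimulationConfig, TrajectoryRecord
from bondfluct.lattice import minimum_image
from bondfluct.observables import StructureFactorCurve

from conftest import homopolymer


def synthetic_traj(positions, record_every=10, accepts=None, attempts=None):
    """Wrap a (n_rec, N, 3) position series into a TrajectoryRecord."""
    positions = np.asarray(positions, dtype=np.int64)
    n_rec, n, _ = positions.shape
    cfg = SimulationConfig(
        T=1.0, mcs_total=(n_rec - 1) * record_every, record_every=record_every,
        equilibration_mcs=0, seed=0,
    )
    times = np.arange(n_rec, dtype=np.int64) * record_every
    zeros = np.zeros((n_rec, n))
    att = np.ones((n_rec, n), dtype=np.int64) if attempts is None else attempts
    acc = np.ones((n_rec, n), dtype=np.int64) if accepts is None else accepts
    return TrajectoryRecord(cfg, homopolymer(n), times, positions, zeros, att, acc)


class TestRadiusOfGyration:
    def test_single_residue_zero(self):
        assert bf.radius_of_gyration(np.array([[3, 4, 5]])) == 0.0

    def test_two_point_case(self):
        rod2 = bf.make_conformation("rod", 2)
        assert bf.radius_of_gyration(rod2) == pytest.approx(1.5)

    def test_pairwise_identity(self, rng):
        """Rg^2 equals (1/2N^2) sum_ij r_ij^2."""
        for _ in range(5):
            pos = rng.integers(-20, 20, size=(10, 3)).astype(float)
            d = pos[:, None, :] - pos[None, :, :]
            pairwise = np.sqrt((d**2).sum(axis=2) .sum() / (2 * 100))
            assert bf.radius_of_gyration(pos) == pytest.approx(pairwise, abs=1e-12)


class TestComDynamics:
    def test_ballistic_series_exponent_one(self):
        pos = np.zeros((40, 1, 3), dtype=np.int64)
        pos[:, 0, 0] = np.arange(40) * 10  # COM moves linearly with t
        fit = bf.com_rms_displacement(synthetic_traj(pos))
        assert fit.k == pytest.approx(1.0, abs=1e-9)
        assert not fit.frozen

    def test_frozen_chain_flagged(self):
        pos = np.tile(np.array([[1, 2, 3]], dtype=np.int64), (40, 1, 1))
        fit = bf.com_rms_displacement(synthetic_traj(pos))
        assert fit.frozen and fit.k == 0.0

    def test_too_few_points_raises(self):
        pos = np.zeros((3, 1, 3), dtype=np.int64)
        pos[:, 0, 0] = [0, 5, 9]
        with pytest.raises(ValueError, match="fit window"):
            bf.com_rms_displacement(synthetic_traj(pos))

    def test_free_residue_diffuses(self, zero_matrix):
        """A single unconstrained residue performs an unbiased lattice walk:
        every attempt is accepted and the COM exponent is 1/2."""
        trajs = []
        for s in range(20):
            cfg = SimulationConfig(
                T=1.0, mcs_total=10_000, L=32, record_every=100, seed=600 + s
            )
            trajs.append(bf.run_simulation(cfg, homopolymer(1), zero_matrix))
        for tr in trajs:
            assert tr.accepts[-1].sum() == tr.attempts[-1].sum()  # nothing to block
        fit = bf.com_rms_displacement(trajs)
        assert fit.k == pytest.approx(0.5, abs=0.05)


class TestStructureFactor:
    def test_single_scatterer_flat(self, qgrid):
        c = bf.structure_factor([np.array([[0, 0, 0]])], qgrid)
        assert np.allclose(c.S, 1.0)

    def test_coherent_low_q_limit(self, qgrid):
        conf = bf.build_initial_conformation(30, 32, rng_seed=1)
        c = bf.structure_factor([conf], np.array([1e-4, 2e-4, 1.0]))
        assert c.S[0] == pytest.approx(30, rel=1e-3)

    def test_rotation_invariance(self, qgrid):
        conf = bf.build_initial_conformation(30, 32, rng_seed=2)
        pos = conf.positions
        rotated = pos[:, [1, 2, 0]] * np.array([1, -1, 1])  # lattice symmetry
        a = bf.structure_factor([pos], qgrid)
        b = bf.structure_factor([rotated], qgrid)
        assert np.allclose(a.S, b.S, rtol=1e-12)  # Debye mode is exact

    def test_direction_sampling_approximates_exact(self, qgrid):
        conf = bf.build_initial_conformation(30, 32, rng_seed=3)
        exact = bf.structure_factor([conf], qgrid)
        approx = bf.structure_factor([conf], qgrid, n_directions=4000, seed=9)
        assert np.allclose(approx.S, exact.S, rtol=0.1)

    def test_empty_ensemble_rejected(self, qgrid):
        with pytest.raises(ValueError):
            bf.structure_factor([], qgrid)


class TestEffectiveDimension:
    @pytest.mark.parametrize("expo", [2.0, 3.0])
    def test_constructed_power_law(self, expo):
        q = np.geomspace(0.2, 1.2, 40)
        curve = StructureFactorCurve(q, q**-expo, 0, 1)
        fit = bf.fit_effective_dimension(curve)
        assert fit.De == pytest.approx(expo, abs=1e-9)
        assert fit.nu == pytest.approx(1 / expo, abs=1e-9)

    def test_window_outside_grid_raises(self):
        q = np.geomspace(2.0, 5.0, 20)
        curve = StructureFactorCurve(q, q**-2.0, 0, 1)
        with pytest.raises(ValueError):
            bf.fit_effective_dimension(curve)


class TestContactMap:
    def test_stretched_rod_has_no_contacts(self):
        rod = bf.make_conformation("rod", 20)
        assert not bf.contact_map(rod).any()  # bonded pairs sit at r^2 = 9

    def test_boundary_distance_counts_as_contact(self):
        pos = np.array([[0, 0, 0], [2, 1, 1], [0, 2, 2]])  # r^2(0,2) = 8
        c = bf.ChainConformation(pos, 16)
        m = bf.contact_map(c)
        assert m[0, 2] and m[2, 0]
        assert not m.diagonal().any()

    def test_matches_brute_force(self, rng):
        c = bf.build_initial_conformation(30, 12, rng_seed=4)
        m = bf.contact_map(c)
        w = c.positions % c.L
        for i in range(c.n):
            for j in range(c.n):
                d = minimum_image(w[i] - w[j], c.L)
                expected = i != j and (d * d).sum() <= 8
                assert m[i, j] == expected


class TestResidueProfiles:
    def test_zero_matrix_zero_energy(self, zero_matrix):
        cfg = SimulationConfig(T=0.5, mcs_total=200, record_every=20, seed=8)
        traj = bf.run_simulation(cfg, homopolymer(10), zero_matrix)
        prof = bf.residue_profiles(traj)
        assert np.all(prof.energy == 0.0)
        assert np.all((prof.mobility >= 0) & (prof.mobility <= 1))

    def test_frozen_chain_zero_mobility(self):
        pos = np.tile(np.arange(0, 30, 3, dtype=np.int64)[:, None], (1, 3))[None]
        pos = np.repeat(pos, 5, axis=0)
        att = np.cumsum(np.full((5, 10), 10, dtype=np.int64), axis=0)
        acc = np.zeros((5, 10), dtype=np.int64)
        traj = synthetic_traj(pos, accepts=acc, attempts=att)
        assert np.all(bf.residue_profiles(traj).mobility == 0.0)

    def test_homopolymer_profiles_symmetric_under_reversal(self, attract_matrix):
        """A homopolymer is its own reverse, so mean per-residue energy and
        mobility must be symmetric under i <-> N-1-i within sampling noise."""
        profs = []
        for s in range(20):
            cfg = SimulationConfig(
                T=0.02, mcs_total=1000, L=16, record_every=50, seed=700 + s
            )
            traj = bf.run_simulation(cfg, homopolymer(12, residue=1), attract_matrix)
            profs.append(bf.residue_profiles(traj))
        for arr in (
            np.array([p.mobility for p in profs]),
            np.array([p.energy for p in profs]),
        ):
            m = arr.mean(axis=0)
            se = arr.std(axis=0, ddof=1) / np.sqrt(len(arr))
            z = np.abs(m - m[::-1]) / np.maximum(
                np.sqrt(se**2 + se[::-1] ** 2), 1e-12
            )
            assert z.max() < 4.0
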