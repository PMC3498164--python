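"""Metropolis engine: acceptance rule, MCS accounting, kernel correctness."""

import dataclasses
import math

import numpy as np
import pytest

import bondfluct as bf
from bondfluct.energetics import EnergyModel
from bondfluct.engine import SimulationConfig, mcs_step, metropolis_accept

from conftest import homopolymer


class TestMetropolisRule:
    def test_downhill_and_flat_always_accepted(self):
        for u in (0.0, 0.5, 0.999999):
            assert metropolis_accept(0.0, 1.0, u)
            assert metropolis_accept(-3.0, 0.01, u)

    def test_uphill_threshold_exp_minus_one(self):
        # dE = T: threshold exp(-1) ~ 0.3679
        assert metropolis_accept(1.0, 1.0, 0.3)
        assert not metropolis_accept(1.0, 1.0, 0.4)

    def test_frozen_limit(self):
        assert not metropolis_accept(1e-6, 1e-12, 1e-300)

    def test_detailed_balance_ratio(self, rng):
        """Empirical forward/reverse acceptance ratio converges to the
        Boltzmann factor for a fixed energy pair."""
        dE, T, trials = 0.8, 0.5, 100_000
        u = rng.random(trials)
        p_forward = np.mean([metropolis_accept(dE, T, x) for x in u])
        p_reverse = np.mean([metropolis_accept(-dE, T, x) for x in u])
        target = math.exp(-dE / T)
        se = math.sqrt(target * (1 - target) / trials)
        assert p_reverse == 1.0
        assert abs(p_forward / p_reverse - target) < 3 * se


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(T=0.0, mcs_total=10)
        with pytest.raises(ValueError):
            SimulationConfig(T=1.0, mcs_total=10, record_every=0)
        with pytest.raises(ValueError):
            SimulationConfig(T=1.0, mcs_total=10, equilibration_mcs=10)
        with pytest.raises(ValueError):
            SimulationConfig(T=1.0, mcs_total=10, sweep="zigzag")

    def test_default_equilibration_is_half(self):
        assert SimulationConfig(T=1.0, mcs_total=1000).equilibration() == 500


class TestMcsAccounting:
    def test_exactly_n_attempts_per_mcs(self, zero_matrix, rng):
        c = bf.build_initial_conformation(20, 16, rng_seed=1)
        model = EnergyModel(zero_matrix, homopolymer(20))
        att, acc = mcs_step(c, model, 1.0, rng)
        assert att.sum() == 20
        assert np.all(acc <= att)

    def test_permuted_sweep_touches_every_residue(self, zero_matrix, rng):
        c = bf.build_initial_conformation(20, 16, rng_seed=1)
        model = EnergyModel(zero_matrix, homopolymer(20))
        att, _ = mcs_step(c, model, 1.0, rng, sweep="permuted")
        assert np.all(att == 1)

    def test_zero_mcs_gives_initial_state_only(self, zero_matrix, h3_seq):
        cfg = SimulationConfig(T=1.0, mcs_total=0, seed=5)
        traj = bf.run_simulation(cfg, h3_seq, zero_matrix)
        assert len(traj.times) == 1 and traj.times[0] == 0


class TestKernel:
    def test_bit_reproducible_given_seed(self, random_matrix, h3_seq):
        cfg = SimulationConfig(T=0.02, mcs_total=300, record_every=50, seed=77)
        a = bf.run_simulation(cfg, h3_seq, random_matrix)
        b = bf.run_simulation(cfg, h3_seq, random_matrix)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.accepts, b.accepts)
        c = bf.run_simulation(dataclasses.replace(cfg, seed=78), h3_seq, random_matrix)
        assert not np.array_equal(a.positions, c.positions)

    def test_zero_matrix_energy_identically_zero(self, zero_matrix, h3_seq):
        cfg = SimulationConfig(T=0.01, mcs_total=500, record_every=100, seed=2)
        traj = bf.run_simulation(cfg, h3_seq, zero_matrix)
        assert np.all(traj.residue_energies == 0.0)

    def test_kernel_frames_satisfy_invariants_and_python_energies(
        self, random_matrix, h3_seq
    ):
        """Every recorded kernel frame passes the full geometric audit, and
        the kernel's per-residue energies equal the Python energetics path."""
        cfg = SimulationConfig(T=0.02, mcs_total=400, record_every=40, seed=13)
        traj = bf.run_simulation(cfg, h3_seq, random_matrix)
        model = EnergyModel(random_matrix, h3_seq)
        for k in range(len(traj.times)):
            c = bf.ChainConformation(traj.positions[k].copy(), cfg.L)
            c.validate()
            py = np.array([bf.residue_energy(c, model, i) for i in range(c.n)])
            assert np.allclose(py, traj.residue_energies[k], atol=1e-10, rtol=0)

    def test_kernel_agrees_with_python_reference_statistically(
        self, attract_matrix
    ):
        """Mean steady-state energy of a small attractive chain matches
        between the compiled kernel and the pure-Python reference step."""
        n, T, n_mcs, seeds = 8, 0.02, 400, 12
        seq = homopolymer(n)
        model = EnergyModel(attract_matrix, seq)

        kernel_e, python_e = [], []
        for s in range(seeds):
            cfg = SimulationConfig(
                T=T, mcs_total=n_mcs, L=16, record_every=20, seed=900 + s
            )
            traj = bf.run_simulation(cfg, seq, attract_matrix)
            kernel_e.append(traj.total_energy()[traj.steady_mask()].mean())

            rng = np.random.default_rng(900 + s)
            c = bf.build_initial_conformation(n, 16, rng_seed=int(rng.integers(2**31)))
            es = []
            for step in range(1, n_mcs + 1):
                mcs_step(c, model, T, rng)
                if step % 20 == 0 and step >= n_mcs // 2:
                    es.append(bf.total_energy(c, model))
            python_e.append(np.mean(es))

        ka, pa = np.array(kernel_e), np.array(python_e)
        se = math.sqrt(ka.var(ddof=1) / seeds + pa.var(ddof=1) / seeds)
        assert abs(ka.mean() - pa.mean()) < 3 * se

    def test_acceptance_rate_monotone_in_temperature(self, attract_matrix):
        """Averaged over seeds, lowering T can only reduce the acceptance
        rate of an attractive chain."""
        n, seeds = 16, 20
        seq = homopolymer(n)
        rates = {}
        for T in (0.005, 0.02, 0.1):
            vals = []
            for s in range(seeds):
                cfg = SimulationConfig(
                    T=T, mcs_total=200, L=16, record_every=200, seed=50 + s
                )
                traj = bf.run_simulation(cfg, seq, attract_matrix)
                vals.append(traj.accepts[-1].sum() / traj.attempts[-1].sum())
            rates[T] = np.mean(vals)
        assert rates[0.005] <= rates[0.02] <= rates[0.1]

    def test_ergodicity_small_chain_state_coverage(self, zero_matrix):
        """A short athermal chain visits nearly all of its enumerable
        conformations (modulo translation) in 10^6 attempts."""
        n = 3
        seq = homopolymer(n)
        cfg = SimulationConfig(
            T=1.0, mcs_total=333_334, L=16, record_every=1, seed=1
        )
        traj = bf.run_simulation(cfg, seq, zero_matrix)

        # enumerate valid states: bond pairs (b1, b2) with ends not overlapping
        bonds = np.array(sorted(bf.BOND_VECTORS["classic"]))
        b1 = bonds[:, None, :]
        b2 = bonds[None, :, :]
        cheb = np.abs(b1 + b2).max(axis=2)  # residue 0 -> residue 2 separation
        total_states = int((cheb >= 2).sum())

        d = np.diff(traj.positions, axis=1)  # (frames, 2, 3)
        seen = {tuple(f.ravel()) for f in d}
        assert len(seen) >= 0.95 * total_states


class TestTrajectoryIO:
    def test_roundtrip_with_frames(self, tmp_path, random_matrix, h3_seq):
        cfg = SimulationConfig(T=0.05, mcs_total=200, record_every=100, seed=4)
        traj = bf.run_simulation(cfg, h3_seq, random_matrix)
        p = tmp_path / "run.traj"
        bf.write_trajectory(traj, p)
        back = bf.read_trajectory(p)
        assert np.array_equal(back.times, traj.times)
        assert np.array_equal(back.positions, traj.positions)
        assert np.array_equal(back.accepts, traj.accepts)
        assert np.allclose(back.residue_energies, traj.residue_energies)
        assert back.config == traj.config
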