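"""Unit tests for the lattice simulator: energy algebra, Metropolis
acceptance, contact-process events and sweep-level invariants."""

import itertools
import math

import numpy as np
import pytest

import cpim
from cpim.core import (CPIMParams, ConfigurationError, LatticeState, UNDIFF,
                       cp_event, delta_energy, hamiltonian, init_lattice,
                       metropolis_flip, run_simulation, sweep)


def lattice_from(rows, **kw):
    return LatticeState(np.array(rows, dtype=np.int8), **kw)


class TestParamsAndInit:
    @pytest.mark.parametrize("kw", [
        dict(L=1), dict(T=0.0), dict(T=-1.0), dict(J=2), dict(b=1.5),
        dict(d=-0.1), dict(neighborhood=6), dict(mode="bogus"),
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            CPIMParams(**kw)

    def test_cpim_seeding_single_center_cell(self):
        lat = init_lattice(CPIMParams(L=5, mode="cpim"))
        assert lat.grid[2, 2] == UNDIFF
        assert np.sum(lat.grid != 0) == 1
        assert lat.boundary == "open"

    def test_pure_ising_init_reproducible_and_full(self):
        p = CPIMParams(L=4, mode="pure_ising", seed=9)
        a, b = init_lattice(p), init_lattice(p)
        assert np.array_equal(a.grid, b.grid)
        assert np.all(np.abs(a.grid) == 1)
        assert a.boundary == "periodic"

    def test_pure_ising_init_mean_spin_near_zero(self):
        lat = init_lattice(CPIMParams(L=100, mode="pure_ising", seed=3))
        # iid +-1: standard error of the mean is 1/sqrt(10^4)
        assert abs(lat.grid.mean()) < 3 / 100

    def test_illegal_codes_rejected(self):
        with pytest.raises(ValueError, match="illegal site codes"):
            lattice_from([[0, 7], [1, -1]])


class TestHamiltonian:
    def test_uniform_open_3x3_ferromagnetic(self):
        lat = lattice_from(np.ones((3, 3)))
        # 12 nearest-neighbour pairs, each contributing -1
        assert hamiltonian(lat, J=1) == -12.0

    def test_checkerboard_antiferromagnetic_ground_state(self):
        g = np.fromfunction(lambda i, j: 1 - 2 * ((i + j) % 2), (3, 3))
        lat = lattice_from(g)
        assert hamiltonian(lat, J=-1) == -12.0

    def test_single_or_no_differentiated_site_zero_energy(self):
        lat = lattice_from([[0, 2, 0], [2, 1, 0], [0, 0, 2]])
        assert hamiltonian(lat, J=1) == 0.0

    def test_vacant_and_undifferentiated_neighbors_excluded(self):
        lat = lattice_from([[1, 2, 1], [0, 1, 0], [1, 1, 1]])
        lat2 = lattice_from([[1, 0, 1], [0, 1, 0], [1, 1, 1]])
        assert hamiltonian(lat, J=1) == hamiltonian(lat2, J=1)

    def test_delta_equals_hamiltonian_difference_on_random_lattices(self, rng):
        """Exact energy-bookkeeping identity, all sites of random lattices."""
        for _ in range(40):
            grid = rng.choice(np.array([0, 2, 1, -1], np.int8), size=(6, 6))
            for nbh in (4, 8):
                lat = LatticeState(grid.copy())
                for i, j in np.argwhere(np.abs(lat.grid) == 1):
                    before = hamiltonian(lat, 1, nbh)
                    dH = delta_energy(lat, (i, j), 1, nbh)
                    flipped = lat.copy()
                    flipped.grid[i, j] *= -1
                    assert hamiltonian(flipped, 1, nbh) - before == dH

    def test_delta_energy_examples(self):
        lat = lattice_from([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        assert delta_energy(lat, (1, 1), J=1) == 8.0
        lat = lattice_from([[0, 1, 0], [1, 1, -1], [0, -1, 0]])
        assert delta_energy(lat, (1, 1), J=1) == 0.0
        assert delta_energy(lat, (1, 1), J=-1) == 0.0
        lat = lattice_from([[0, 1, 0], [1, 1, 1], [0, 2, 0]])
        assert delta_energy(lat, (1, 1), J=1) == 6.0

    def test_delta_energy_requires_differentiated_site(self):
        lat = lattice_from([[2, 1], [1, 1]])
        with pytest.raises(ValueError, match="not differentiated"):
            delta_energy(lat, (0, 0), J=1)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        lat = lattice_from([[0, -1, 0], [-1, 1, -1], [0, -1, 0]])
        assert delta_energy(lat, (1, 1), J=1) < 0
        assert metropolis_flip(lat, (1, 1), T=0.01, J=1, rng=rng)
        assert lat.grid[1, 1] == -1

    def test_uphill_acceptance_rate_matches_boltzmann_weight(self, rng):
        base = lattice_from([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        T = 2.27
        expected = math.exp(-8.0 / T)
        n, acc = 30000, 0
        for _ in range(n):
            lat = base.copy()
            acc += metropolis_flip(lat, (1, 1), T=T, J=1, rng=rng)
        rate = acc / n
        assert rate == pytest.approx(expected, abs=3 * math.sqrt(
            expected * (1 - expected) / n))

    def test_frozen_at_low_temperature(self, rng):
        lat = lattice_from([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        assert not any(metropolis_flip(lat.copy(), (1, 1), T=1e-6, J=1,
                                       rng=rng) for _ in range(2000))

    def test_invalid_temperature(self, rng):
        lat = lattice_from([[1, 1], [1, 1]])
        with pytest.raises(ConfigurationError):
            metropolis_flip(lat, (0, 0), T=0.0, J=1, rng=rng)


class TestContactProcess:
    def test_isolated_vacant_site_stays_vacant(self, rng):
        p = CPIMParams(L=3, b=1.0)
        lat = lattice_from(np.zeros((3, 3)))
        for _ in range(50):
            ev = cp_event(lat, (1, 1), p, rng)
            assert ev.colonizations == 0
        assert np.all(lat.grid == 0)

    def test_certain_colonization_at_b_one(self, rng):
        p = CPIMParams(L=3, b=1.0)
        lat = lattice_from([[0, 2, 0], [0, 0, 0], [0, 0, 0]])
        ev = cp_event(lat, (1, 1), p, rng)
        assert ev.colonizations == 1 and lat.grid[1, 1] == UNDIFF

    def test_colonization_law_per_neighbor(self, rng):
        """P(colonize) = 1-(1-b)^k with k occupied neighbours."""
        b, k, n = 0.3, 3, 20000
        p = CPIMParams(L=3, b=b)
        expected = 1 - (1 - b) ** k
        hits = 0
        for _ in range(n):
            lat = lattice_from([[0, 2, 0], [1, 0, -1], [0, 0, 0]])
            hits += cp_event(lat, (1, 1), p, rng).colonizations
        assert hits / n == pytest.approx(expected, abs=3 * math.sqrt(
            expected * (1 - expected) / n))

    def test_no_death_at_zero_rate(self, rng):
        p = CPIMParams(L=2, d=0.0, g=0.0)
        lat = lattice_from([[2, 1], [0, 0]])
        for site in ((0, 0), (0, 1)):
            for _ in range(200):
                assert cp_event(lat, site, p, rng).deaths == 0
        assert lat.grid[0, 0] == UNDIFF

    def test_differentiation_balanced_states(self, rng):
        p = CPIMParams(L=2, d=0.0, g=1.0)
        signs = []
        for _ in range(4000):
            lat = lattice_from([[2, 0], [0, 0]])
            cp_event(lat, (0, 0), p, rng)
            signs.append(int(lat.grid[0, 0]))
        assert abs(np.mean(signs)) < 3 / math.sqrt(len(signs))


class TestSweepAndRun:
    def test_empty_lattice_is_absorbing(self, rng):
        p = CPIMParams(L=4, b=1.0, sweeps=5)
        lat = lattice_from(np.zeros((4, 4)))
        sweep(lat, p, rng)
        assert np.all(lat.grid == 0) and lat.sweep_count == 1

    def test_occupancy_non_decreasing_without_death(self, rng):
        p = CPIMParams(L=8, d=0.0, b=0.2)
        lat = init_lattice(p)
        prev = 1
        for _ in range(10):
            sweep(lat, p, rng)
            occ = int(np.sum(lat.grid != 0))
            assert occ >= prev
            prev = occ

    def test_full_lattice_death_count_binomial(self, rng):
        d = 0.05
        p = CPIMParams(L=16, d=d, b=0.5)
        lat = lattice_from(np.ones((16, 16)))
        ev = sweep(lat, p, rng)
        mean = d * 16 * 16
        sd = math.sqrt(16 * 16 * d * (1 - d))
        assert abs(ev.deaths - mean) < 4 * sd

    def test_seeded_runs_bit_identical(self):
        p = CPIMParams(L=32, T=2.3, sweeps=150, seed=17)
        a = run_simulation(p)
        b = run_simulation(p)
        assert np.array_equal(a.lattice.grid, b.lattice.grid)
        assert a.series.equals(b.series)

    def test_strong_coupling_orders_colony(self):
        """Well below the critical coupling the colony is near-uniform."""
        vals = []
        for seed in range(5):
            p = CPIMParams(L=48, T=1.1, b=0.03, d=1e-5, sweeps=3000,
                           seed=seed)
            res = run_simulation(p, stop_at_edge=False)
            last = res.series.iloc[-1]
            n_diff = last.n_plus + last.n_minus
            vals.append(abs(last.M) / n_diff)
        assert np.mean(vals) > 0.8

    def test_weak_coupling_disorders_colony(self):
        p = CPIMParams(L=48, T=7.0, b=0.03, d=1e-5, sweeps=1500, seed=2)
        res = run_simulation(p, stop_at_edge=False)
        last = res.series.iloc[-1]
        assert abs(last.M) / (last.n_plus + last.n_minus) < 0.1

    def test_stop_at_edge(self):
        p = CPIMParams(L=24, b=0.2, sweeps=5000, seed=5)
        res = run_simulation(p, stop_at_edge=True)
        assert res.stopped_at_edge
        border = np.concatenate([res.lattice.grid[0], res.lattice.grid[-1],
                                 res.lattice.grid[:, 0],
                                 res.lattice.grid[:, -1]])
        assert np.any(border != 0)
        assert len(res.series) < 5000

    def test_zero_temperature_quench_energy_monotone(self):
        p = CPIMParams(L=24, mode="pure_ising", sweeps=60, seed=8)
        res = cpim.run_simulation(p, stop_at_edge=False,
                                  accept_only_downhill=True)
        energy = res.series["energy"].to_numpy()
        assert np.all(np.diff(energy) <= 1e-9)

    def test_kernel_energy_bookkeeping_matches_hamiltonian(self):
        """Incrementally tracked energy equals the recomputed Hamiltonian."""
        p = CPIMParams(L=16, T=2.5, b=0.1, d=0.01, sweeps=200, seed=4)
        res = run_simulation(p, stop_at_edge=False)
        final = res.series["energy"].iloc[-1]
        assert hamiltonian(res.lattice, p.J) == pytest.approx(final)


class TestGroundStates:
    def test_exhaustive_enumeration_L3(self):
        """Uniform (J=+1) and checkerboard (J=-1) minimize H over all
        2^9 fully differentiated 3x3 configurations."""
        best = {1: (np.inf, []), -1: (np.inf, [])}
        for bits in itertools.product([1, -1], repeat=9):
            grid = np.array(bits, np.int8).reshape(3, 3)
            lat = LatticeState(grid)
            for J in (1, -1):
                H = hamiltonian(lat, J)
                cur = best[J]
                if H < cur[0] - 1e-12:
                    best[J] = (H, [grid])
                elif H == cur[0]:
                    cur[1].append(grid)
        ferro_minima = best[1][1]
        assert len(ferro_minima) == 2
        assert all(np.all(g == g[0, 0]) for g in ferro_minima)
        checker = np.fromfunction(lambda i, j: 1 - 2 * ((i + j) % 2), (3, 3))
        af_minima = best[-1][1]
        assert len(af_minima) == 2
        assert any(np.array_equal(g, checker) for g in af_minima)


class TestBoltzmannDistribution:
    @pytest.mark.parametrize("T,J", [(1.0, 1), (2.27, 1), (5.0, 1),
                                     (1.0, -1), (2.27, -1), (5.0, -1)])
    def test_two_by_two_matches_boltzmann(self, T, J):
        """Empirical configuration frequencies on the 2x2 periodic lattice
        match exp(-H/T)/Z with Z enumerated over all 16 spin states."""
        states = list(itertools.product([1, -1], repeat=4))
        energies = np.array([
            hamiltonian(LatticeState(np.array(s, np.int8).reshape(2, 2),
                                     boundary="periodic", mode="pure_ising"),
                        J) for s in states])
        w = np.exp(-energies / T)
        probs = w / w.sum()

        p = CPIMParams(L=2, T=T, J=J, mode="pure_ising", seed=0)
        rng = np.random.default_rng(hash((T, J)) % 2**31)
        n_chains, burn = 1500, 25
        counts = np.zeros(16)
        for _ in range(n_chains):
            lat = LatticeState(
                rng.choice(np.array([1, -1], np.int8), size=(2, 2)),
                boundary="periodic", mode="pure_ising")
            for _ in range(burn):
                sweep(lat, p, rng)
            counts[states.index(tuple(int(v) for v in
                                      lat.grid.ravel()))] += 1
        for k in range(16):
            sigma = math.sqrt(n_chains * probs[k] * (1 - probs[k]))
            # 3-sigma multinomial band, widened for near-zero cells
            assert abs(counts[k] - n_chains * probs[k]) <= 3 * sigma + 3
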