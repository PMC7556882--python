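"""Pair potentials, system energies/forces, lambda coupling, accounting."""

import math

import numpy as np
import pytest

from mdasim import (
    AlchemicalSpec,
    ElectrostaticsParams,
    EnergyModel,
    EvalCounter,
    HeadEndpoint,
    InvalidExchangeError,
    SingularSeparationError,
    coulomb_rf_energy,
    forces,
    lj_pair_energy,
    make_lambda_state,
    softcore_lj_energy,
    system_energy,
)
from mdasim.exchange import apply_exchange


class TestLJPair:
    def test_zero_crossing_and_minimum(self):
        assert lj_pair_energy(1.0, 1.0, 1.0) == pytest.approx(0.0, abs=1e-14)
        assert lj_pair_energy(2 ** (1 / 6), 1.0, 1.0) == pytest.approx(-1.0)

    def test_shifted_value_matches_direct_arithmetic(self):
        # independent evaluation of the closed form at r = 0.9, cutoff 2.5
        r, eps, sig, rc = 0.9, 1.0, 1.0, 2.5
        expected = 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6) - 4 * eps * (
            (sig / rc) ** 12 - (sig / rc) ** 6
        )
        assert lj_pair_energy(r, eps, sig, cutoff=rc, shifted=True) == pytest.approx(
            expected, rel=1e-14
        )

    def test_zero_beyond_cutoff_and_singular_origin(self):
        assert lj_pair_energy(3.0, 1.0, 1.0, cutoff=2.5, shifted=True) == 0.0
        with pytest.raises(SingularSeparationError):
            lj_pair_energy(0.0, 1.0, 1.0)


class TestSoftcore:
    def test_vanishes_at_lambda_zero_everywhere(self):
        for r in (0.0, 0.3, 1.0, 5.0):
            assert softcore_lj_energy(r, 1.0, 1.0, 0.0, 5.0) == 0.0

    def test_reduces_to_lj_at_lambda_one(self):
        r = np.linspace(0.3, 2.4, 100)
        sc = softcore_lj_energy(r, 1.0, 1.0, 1.0, 5.0, cutoff=2.5, shifted=True)
        lj = lj_pair_energy(r, 1.0, 1.0, cutoff=2.5, shifted=True)
        assert np.max(np.abs(sc - lj)) <= 1e-12 * np.max(np.abs(lj))

    def test_midpoint_value_matches_direct_arithmetic(self):
        # A = sigma^2 / (r^2 + delta (1 - lambda)) = 1 / 3.5 at these inputs
        a = 1.0 / 3.5
        expected = 4 * 1.0 * 0.5 * (a**6 - a**3)
        assert softcore_lj_energy(1.0, 1.0, 1.0, 0.5, 5.0) == pytest.approx(
            expected, rel=1e-14
        )

    def test_finite_at_overlap_for_partial_coupling(self):
        # finite for every r >= 0 whenever lambda < 1 and delta > 0
        rs = np.linspace(0.0, 2.4, 60)
        for lam in np.linspace(0.0, 0.999, 25):
            u = softcore_lj_energy(rs, 2.0, 1.1, lam, 5.0)
            assert np.all(np.isfinite(u))

    def test_grid_continuity_in_lambda_and_r(self):
        # continuity via grid refinement: halving the spacing (about) halves
        # the largest neighboring difference, in both lambda and r
        def max_jumps(n_lam, n_r):
            rs = np.linspace(0.5, 2.4, n_r)
            lams = np.linspace(0.0, 1.0, n_lam)
            us = np.array([softcore_lj_energy(rs, 2.0, 1.1, lam, 5.0) for lam in lams])
            assert np.all(np.isfinite(us))
            return (
                float(np.max(np.abs(np.diff(us, axis=0)))),
                float(np.max(np.abs(np.diff(us, axis=1)))),
            )

        # a jump discontinuity would keep the max difference ~constant under
        # refinement; a continuous function shrinks it toward halving
        coarse = max_jumps(101, 81)
        fine = max_jumps(201, 161)
        assert fine[0] <= 0.75 * coarse[0]
        assert fine[1] <= 0.75 * coarse[1]


class TestCoulombRF:
    def test_no_charge_and_shift_construction(self):
        params = ElectrostaticsParams(dielectric_screening=15.0, cutoff=2.5)
        assert coulomb_rf_energy(1.0, 0.0, 1.0, params) == 0.0
        assert coulomb_rf_energy(2.5, 1.0, 1.0, params) == pytest.approx(0.0, abs=1e-14)
        assert coulomb_rf_energy(3.0, 1.0, 1.0, params) == 0.0

    def test_value_matches_direct_arithmetic(self):
        params = ElectrostaticsParams(
            dielectric_screening=15.0, rf_dielectric=78.0, cutoff=2.5,
            coulomb_prefactor=1.0,
        )
        r = 1.25  # = 0.5 r_c
        k_rf = (78.0 - 15.0) / ((2 * 78.0 + 15.0) * 2.5**3)
        c_rf = 1 / 2.5 + k_rf * 2.5**2
        expected = (1.0 / 15.0) * (1 / r + k_rf * r**2 - c_rf)
        assert coulomb_rf_energy(r, 1.0, 1.0, params) == pytest.approx(expected, rel=1e-14)

    def test_conductor_limit(self):
        params = ElectrostaticsParams(rf_dielectric=float("inf"), cutoff=2.0)
        assert params.k_rf == pytest.approx(1.0 / (2 * 8.0))


def _brute_force_energy(system, topologies, table, elec):
    """O(N^2) pure-python double loop, the independent oracle."""
    box = system.box
    ev = ec = eb = 0.0
    for i in range(system.n - 1):
        for j in range(i + 1, system.n):
            if system.molecule_id[i] == system.molecule_id[j]:
                continue
            dr = box.min_image(system.positions[i] - system.positions[j])
            r = math.sqrt(float(np.dot(dr, dr)))
            ti, tj = system.bead_type[i], system.bead_type[j]
            ev += lj_pair_energy(
                r, table.epsilon[ti, tj], table.sigma[ti, tj],
                cutoff=table.cutoff, shifted=table.shift_at_cutoff,
            )
            ec += coulomb_rf_energy(r, system.charge[i], system.charge[j], elec)
    for t in topologies:
        for (i, j, k, r0) in t.bonds:
            dr = box.min_image(system.positions[i] - system.positions[j])
            r = math.sqrt(float(np.dot(dr, dr)))
            eb += 0.5 * k * (r - r0) ** 2
        for (i, j, k, ka, th0) in t.angles:
            u = box.min_image(system.positions[i] - system.positions[j])
            v = box.min_image(system.positions[k] - system.positions[j])
            c = float(np.dot(u, v) / math.sqrt(np.dot(u, u) * np.dot(v, v)))
            eb += 0.5 * ka * (c - math.cos(th0)) ** 2
    return ev, ec, eb


class TestSystemEnergy:
    def test_matches_brute_force_all_pairs(self, membrane_copy):
        _, system, topologies, table, elec = membrane_copy
        e = system_energy(system, topologies, table, elec)
        ev, ec, eb = _brute_force_energy(system, topologies, table, elec)
        assert e.vdw == pytest.approx(ev, rel=1e-12, abs=1e-12)
        assert e.coulomb == pytest.approx(ec, rel=1e-12, abs=1e-12)
        assert e.bonded == pytest.approx(eb, rel=1e-12, abs=1e-12)

    def test_decomposition_closes(self, membrane_model):
        _, system, topologies, model = membrane_model
        e, _ = model.evaluate(system, count=False)
        assert abs(e.total - (e.vdw + e.coulomb + e.bonded)) <= 1e-10 * abs(e.total)

    def test_lambda_endpoints_match_relabeled_systems(self, membrane_model):
        import copy

        preset, system, topologies, model = membrane_model
        pair = (0, next(i for i, t in enumerate(topologies) if t.species == "B"))
        spec = AlchemicalSpec(
            HeadEndpoint(0, 0.0), HeadEndpoint(1, preset.head_b_charge),
            delta_lambda=0.5, plateau_steps=0,
        )
        state = make_lambda_state(system, topologies, pair, spec)
        plain, _ = model.evaluate(system, count=False)
        at0, _ = model.evaluate(system, state, 0.0, count=False)
        assert at0.total == pytest.approx(plain.total, rel=1e-12)

        swapped = system.copy()
        topo2 = copy.deepcopy(topologies)
        apply_exchange(swapped, topo2, state)
        model2 = EnergyModel(model.pair_table, model.electrostatics, topo2)
        plain1, _ = model2.evaluate(swapped, count=False)
        at1, _ = model.evaluate(system, state, 1.0, count=False)
        assert at1.total == pytest.approx(plain1.total, rel=1e-12)

    def test_same_species_pair_is_invalid(self, membrane_model):
        preset, system, topologies, model = membrane_model
        a_ids = [i for i, t in enumerate(topologies) if t.species == "A"]
        spec = AlchemicalSpec(HeadEndpoint(0, 0.0), HeadEndpoint(1, preset.head_b_charge))
        with pytest.raises(InvalidExchangeError):
            make_lambda_state(system, topologies, (a_ids[0], a_ids[1]), spec)


class TestForces:
    def test_isolated_particle_feels_nothing(self):
        from mdasim import PairTable, ParticleSystem, SimulationBox
        from mdasim.model import MoleculeTopology

        box = SimulationBox([10.0, 10.0])
        ps = ParticleSystem(
            np.array([[5.0, 5.0]]), np.zeros((1, 2)), np.ones(1),
            np.zeros(1, dtype=np.int64), np.zeros(1), np.zeros(1, dtype=np.int64),
            box, ("X",),
        )
        table = PairTable(np.ones((1, 1)), np.ones((1, 1)), cutoff=2.5, labels=("X",))
        f = forces(ps, [MoleculeTopology("X", [0])], table,
                   ElectrostaticsParams(cutoff=2.5), counter=EvalCounter())
        assert np.all(f == 0.0)

    @pytest.mark.parametrize("coupling,lam", [(None, 0.0), ("linear", 0.37), ("softcore", 0.37)])
    def test_matches_finite_differences(self, membrane_model, coupling, lam):
        preset, system, topologies, model = membrane_model
        state = None
        if coupling is not None:
            pair = (0, next(i for i, t in enumerate(topologies) if t.species == "B"))
            spec = AlchemicalSpec(
                HeadEndpoint(0, 0.0), HeadEndpoint(1, preset.head_b_charge),
                delta_lambda=0.5, plateau_steps=0,
                softcore_delta=22.6, vdw_coupling=coupling,
            )
            state = make_lambda_state(system, topologies, pair, spec)
        e0, f = model.evaluate(system, state, lam, count=False)
        h = 1e-6
        rng = np.random.default_rng(5)
        picks = rng.choice(system.n, size=8, replace=False)
        for i in picks:
            for k in range(system.dim):
                plus = system.copy()
                plus.positions[i, k] += h
                minus = system.copy()
                minus.positions[i, k] -= h
                ep, _ = model.evaluate(plus, state, lam, count=False)
                em, _ = model.evaluate(minus, state, lam, count=False)
                fd = -(ep.total - em.total) / (2 * h)
                scale = max(1.0, abs(f[i, k]))
                assert abs(fd - f[i, k]) / scale < 1e-6

    def test_newtons_third_law(self, membrane_model):
        _, system, topologies, model = membrane_model
        _, f = model.evaluate(system, count=False)
        assert np.max(np.abs(f.sum(axis=0))) < 1e-9

    def test_counter_advances_once_per_call(self, membrane_model):
        _, system, topologies, model = membrane_model
        start = model.counter.count
        for _ in range(5):
            model.evaluate(system)
        assert model.counter.count == start + 5
        model.evaluate(system, count=False)
        assert model.counter.count == start + 5
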