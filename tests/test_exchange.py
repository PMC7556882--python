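"""Exchange moves: pair selection, Metropolis acceptance, AT work,
restore contracts, MC/MDAS equivalence, sampler orchestration."""

import copy

import numpy as np
import pytest
from scipy import stats

from mdasim import (
    AlchemicalSpec,
    EnergyModel,
    EvalCounter,
    HeadEndpoint,
    NoUnlikePairError,
    RunConfig,
    ScaledSpringWell,
    ThermostatSpec,
    alchemical_trajectory,
    alchemical_work,
    apply_exchange,
    make_lambda_state,
    mc_exchange_attempt,
    mdas_attempt,
    run_sampler,
    select_exchange_pair,
    species_counts,
    total_charge,
)
from mdasim.benchmarks import (
    arrangement_chi_square,
    enumerate_arrangements,
    frozen_cluster,
    run_exchange_chain,
)
from mdasim.exchange import _accept


class TestSelectExchangePair:
    def test_uniform_over_unlike_pairs(self):
        system, topologies, model, _ = frozen_cluster(seed=1)
        rng = np.random.default_rng(0)
        counts = {}
        n_draws = 90_000
        for _ in range(n_draws):
            pair = select_exchange_pair(system, topologies, rng)
            counts[pair] = counts.get(pair, 0) + 1
        assert len(counts) == 9  # |A| x |B| unlike pairs
        observed = np.array(list(counts.values()))
        _, p = stats.chisquare(observed)
        assert p > 0.05

    def test_unique_pair_and_missing_species(self):
        system, topologies, model, _ = frozen_cluster(seed=1, n_a=1, n_b=1)
        rng = np.random.default_rng(0)
        assert select_exchange_pair(system, topologies, rng) == (0, 1)
        system2, topologies2, _, _ = frozen_cluster(seed=1, n_a=2, n_b=0)
        with pytest.raises(NoUnlikePairError):
            select_exchange_pair(system2, topologies2, rng)


class TestMetropolisRule:
    def test_always_accepts_downhill(self, rng):
        assert all(_accept(-3.0, 1.0, rng) for _ in range(100))

    def test_unit_barrier_accepts_at_exp_minus_one(self, rng):
        # dU = kT -> acceptance probability exp(-1)
        n = 100_000
        hits = sum(_accept(1.0, 1.0, rng) for _ in range(n))
        p = np.exp(-1.0)
        assert abs(hits / n - p) < 4 * np.sqrt(p * (1 - p) / n)


class TestMCExchange:
    def test_identical_species_parameterization_always_accepts(self, rng):
        system, topologies, model, th = frozen_cluster(seed=3)
        # make B heads indistinguishable from A heads: dU = 0 exactly
        system.bead_type[:] = 0
        for _ in range(50):
            pair = select_exchange_pair(system, topologies, rng)
            outcome, _ = mc_exchange_attempt(system, topologies, pair, th, rng, model)
            assert outcome.work.total == 0.0
            assert outcome.accepted

    def test_rejected_move_leaves_system_untouched(self):
        system, topologies, model, th = frozen_cluster(seed=3)
        rng = np.random.default_rng(0)
        snap_types = system.bead_type.copy()
        snap_pos = system.positions.copy()
        rejected = 0
        for _ in range(200):
            pair = select_exchange_pair(system, topologies, rng)
            before = system.bead_type.copy()
            outcome, _ = mc_exchange_attempt(system, topologies, pair, th, rng, model)
            if not outcome.accepted:
                rejected += 1
                assert np.array_equal(system.bead_type, before)
        assert rejected > 0  # the chain does reject at these energetics
        assert np.array_equal(system.positions, snap_pos)  # never moves coords
        assert np.sum(system.bead_type == 0) == np.sum(snap_types == 0)

    def test_composition_and_charge_invariant(self, membrane_model, rng):
        preset, system, topologies, model = membrane_model
        th = ThermostatSpec(preset.kT, "langevin", 0.1)
        q0 = total_charge(system)
        comp0 = species_counts(topologies)
        for _ in range(60):
            pair = select_exchange_pair(system, topologies, rng)
            mc_exchange_attempt(system, topologies, pair, th, rng, model)
            assert total_charge(system) == pytest.approx(q0, abs=1e-12)
            assert species_counts(topologies) == comp0

    def test_frozen_cluster_samples_exact_boltzmann(self):
        # short-chain version of the equilibrium check (enumeration oracle)
        system, topologies, model, th = frozen_cluster(seed=2)
        probs = enumerate_arrangements(system, topologies, model, th.temperature)
        counts = run_exchange_chain(
            system, topologies, model, th, 150_000, seed=5, sampler="mc"
        )
        _, p = arrangement_chi_square(counts, probs)
        assert p > 0.01


class TestAlchemicalTrajectory:
    def test_identical_endpoints_do_zero_work(self, rng):
        system, topologies, model, th = frozen_cluster(seed=4)
        system.bead_type[:] = 0  # U is lambda-independent
        spec = AlchemicalSpec(HeadEndpoint(0, 0.0), HeadEndpoint(0, 0.0),
                              delta_lambda=0.1, plateau_steps=3)
        th_run = ThermostatSpec(1.0, "langevin", 1.0)
        record, trial, final, state = alchemical_trajectory(
            system, topologies, (0, 3), spec, th_run, 0.005, rng, model
        )
        assert record.work.total == 0.0

    def test_single_step_work_equals_metropolis_delta_u(self, membrane_model, rng):
        preset, system, topologies, model = membrane_model
        th = ThermostatSpec(preset.kT, "langevin", 0.1)
        pair = (0, next(i for i, t in enumerate(topologies) if t.species == "B"))
        spec = AlchemicalSpec(HeadEndpoint(0, 0.0), HeadEndpoint(1, preset.head_b_charge),
                              delta_lambda=1.0, plateau_steps=0)
        state = make_lambda_state(system, topologies, pair, spec)
        delta = model.exchange_delta(system, state, count=False)
        record, _, _, _ = alchemical_trajectory(
            system, topologies, pair, spec, th, 0.005, rng, model
        )
        assert record.work.total == pytest.approx(delta.total, rel=1e-9, abs=1e-9)
        assert record.force_evals == 1

    def test_work_decomposition_closes_every_attempt(self, membrane_model, rng):
        preset, system, topologies, model = membrane_model
        th = ThermostatSpec(preset.kT, "langevin", 0.1)
        spec = AlchemicalSpec(HeadEndpoint(0, 0.0), HeadEndpoint(1, preset.head_b_charge),
                              delta_lambda=0.2, plateau_steps=5)
        for _ in range(10):
            outcome, _ = mdas_attempt(system, topologies, spec, th, 0.005, rng, model)
            w = outcome.work
            assert abs(w.total - (w.vdw + w.coulomb + w.bonded)) <= max(
                1e-10 * abs(w.total), 1e-12
            )

    def test_translated_well_quasistatic_work_vanishes(self, rng):
        # moving a harmonic well's center costs no free energy; for long
        # plateaus the mean work approaches dF = 0
        kT = 1.0
        well = ScaledSpringWell(2.0, 2.0, center=100.0, center1=100.5)
        th = ThermostatSpec(kT, "langevin", 1.0)
        spec = AlchemicalSpec(HeadEndpoint(0, 0.0), HeadEndpoint(0, 0.0),
                              delta_lambda=0.1, plateau_steps=40)
        system = well.equilibrium_system(kT, rng)
        works = []
        for _ in range(400):
            well.resample(system, kT, rng)
            record, _, _ = alchemical_work(system, well.evaluate_at, spec, th, 0.05, rng)
            works.append(record.work.total)
        works = np.asarray(works)
        stderr = works.std(ddof=1) / np.sqrt(works.size)
        # mean dissipated work is small and the Jarzynski estimator hits 1
        assert works.mean() < 0.15
        est = np.exp(-works / kT)
        est_err = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - 1.0) < 3 * est_err


class TestMdasAttempt:
    def test_rejection_restores_phase_space_point_exactly(self, membrane_model):
        preset, system, topologies, model = membrane_model
        # impossible move: gigantic work via a bogus very cold thermostat
        th = ThermostatSpec(1e-6, "langevin", 0.1)
        spec = AlchemicalSpec(HeadEndpoint(0, 0.0), HeadEndpoint(1, preset.head_b_charge),
                              delta_lambda=0.5, plateau_steps=10)
        rng = np.random.default_rng(7)
        pos, vel = system.positions.copy(), system.velocities.copy()
        types = system.bead_type.copy()
        species = [t.species for t in topologies]
        rejections = 0
        for _ in range(5):
            outcome, _ = mdas_attempt(system, topologies, spec, th, 0.005, rng, model)
            if not outcome.accepted:
                rejections += 1
                assert np.array_equal(system.positions, pos)
                assert np.array_equal(system.velocities, vel)
                assert np.array_equal(system.bead_type, types)
                assert [t.species for t in topologies] == species
            else:  # accepted moves evolve the state; refresh the snapshot
                pos, vel = system.positions.copy(), system.velocities.copy()
                types = system.bead_type.copy()
                species = [t.species for t in topologies]
        assert rejections > 0

    def test_single_step_mdas_equals_mc_decision_for_decision(self, membrane_model):
        preset, system, topologies, model = membrane_model
        th = ThermostatSpec(preset.kT, "langevin", 0.1)
        spec = AlchemicalSpec(HeadEndpoint(0, 0.0), HeadEndpoint(1, preset.head_b_charge),
                              delta_lambda=1.0, plateau_steps=0)

        def run_chain(kind, n=2000):
            sys_c = system.copy()
            topo_c = copy.deepcopy(topologies)
            model_c = EnergyModel(model.pair_table, model.electrostatics, topo_c,
                                  counter=EvalCounter())
            rng_pairs = np.random.default_rng(11)
            rng_acc = np.random.default_rng(22)
            decisions = []
            for _ in range(n):
                if kind == "mc":
                    pair = select_exchange_pair(sys_c, topo_c, rng_pairs)
                    out, _ = mc_exchange_attempt(sys_c, topo_c, pair, th, rng_acc, model_c)
                else:
                    out, _ = mdas_attempt(sys_c, topo_c, spec, th, 0.005, rng_acc,
                                          model_c, rng_pairs=rng_pairs)
                decisions.append((out.pair, out.accepted))
            return decisions, model_c.counter.count

        mc_seq, mc_cost = run_chain("mc")
        mdas_seq, mdas_cost = run_chain("mdas")
        assert mc_seq == mdas_seq
        assert mc_cost == mdas_cost  # both cost one evaluation per attempt

    def test_work_decreases_and_acceptance_rises_with_gradualness(self, membrane_model):
        # fixed start, many attempts at decreasing delta-lambda under a fixed
        # total AT budget trend: finer schedules dissipate less
        preset, system, topologies, model = membrane_model
        th = ThermostatSpec(preset.kT, "langevin", 0.1)
        mean_work = {}
        acc = {}
        for dlam, M in ((1.0, 0), (0.1, 4), (0.05, 12)):
            spec = AlchemicalSpec(
                HeadEndpoint(0, 0.0), HeadEndpoint(1, preset.head_b_charge),
                delta_lambda=dlam, plateau_steps=M,
            )
            sys_c = system.copy()
            topo_c = copy.deepcopy(topologies)
            model_c = EnergyModel(model.pair_table, model.electrostatics, topo_c,
                                  counter=EvalCounter())
            rng = np.random.default_rng(31)
            works, hits = [], 0
            for _ in range(150):
                out, _ = mdas_attempt(sys_c, topo_c, spec, th, 0.005, rng, model_c)
                works.append(out.work.total)
                hits += out.accepted
            mean_work[dlam] = np.mean(works)
            acc[dlam] = hits / 150
        assert mean_work[0.05] <= mean_work[1.0]
        assert acc[0.05] >= acc[1.0]


class TestRunSampler:
    def test_md_mode_makes_no_attempts(self):
        cfg = RunConfig(n_lipids_a=6, n_lipids_b=6, mode="md",
                        md_segment_steps=50, n_attempts=4, seed=0)
        result = run_sampler(cfg)
        assert result.n_attempts == 0
        assert len(result.work) == 0
        assert result.force_evals == 4 * 50
        assert len(result.frames) == 4

    def test_reference_schedule_costs(self):
        # 2000-step segments; 1000-step AT (lambda moved every ten steps)
        cfg = RunConfig(n_lipids_a=6, n_lipids_b=6, mode="mdas",
                        md_segment_steps=2000, n_attempts=2,
                        delta_lambda=0.01, plateau_steps=9, seed=1)
        result = run_sampler(cfg)
        assert result.force_evals == 2 * 3000
        cfg2 = RunConfig(n_lipids_a=6, n_lipids_b=6, mode="mcmd",
                         md_segment_steps=2000, n_attempts=2, seed=1)
        result2 = run_sampler(cfg2)
        assert result2.force_evals == 2 * 2001

    def test_frames_are_stamped_and_only_from_md_segments(self):
        cfg = RunConfig(n_lipids_a=6, n_lipids_b=6, mode="mcmd",
                        md_segment_steps=100, n_attempts=5, seed=2)
        result = run_sampler(cfg)
        stamps = [f.force_evals for f in result.frames]
        assert len(stamps) == 5
        assert all(b > a for a, b in zip(stamps, stamps[1:]))
        # frame k is recorded right after segment k, before the attempt
        assert stamps[0] == 100

    def test_composition_and_charge_conserved_through_a_run(self):
        cfg = RunConfig(n_lipids_a=6, n_lipids_b=6, mode="mdas",
                        md_segment_steps=50, n_attempts=10,
                        delta_lambda=0.2, plateau_steps=2, seed=3)
        result = run_sampler(cfg)
        assert species_counts(result.topologies) == {"A": 6, "B": 6}
        assert total_charge(result.system) == pytest.approx(0.0, abs=1e-12)
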