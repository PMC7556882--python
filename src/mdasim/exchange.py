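"""Identity-exchange moves: single-step Metropolis and alchemical-trajectory
(gradual, work-based) exchanges, plus the sampler orchestration.

Two hybrid samplers are provided on top of plain MD:

* **MC-MD** — alternate a straightforward MD segment with a single-step
  Metropolis exchange of a randomly selected unlike pair of molecules,
  accepted with ``min(1, exp(-dU/kT))``.
* **MDAS** (MD with alchemical steps) — replace the single-step exchange by
  an alchemical trajectory (AT): lambda is raised 0 -> 1 in increments
  ``delta_lambda``, with M thermostatted MD steps at each fixed lambda.  The
  accumulated nonequilibrium work

      w = sum_i [ U(lam_i + dlam)(x_i) - U(lam_i)(x_i) ]

  (potential-energy jumps only; velocities are continuous since no mass
  changes) enters the acceptance ``min(1, exp(-w/kT))``.  Acceptance on work
  makes the AT an exact candidate move: accepted moves continue from the
  lambda = 1 phase-space point, rejected ones restore the pre-AT positions
  *and* velocities exactly.

Cost accounting: every MD step (plateau steps included) and every lambda
increment is one potential evaluation; a full AT therefore costs
``(M + 1) / delta_lambda`` and a single-step exchange costs 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dynamics import IntegrationBlowUpError, run_md_segment
from .energy import (
    EnergyBreakdown,
    EnergyModel,
    InvalidExchangeError,
    LambdaState,
    make_lambda_state,
)
from .model import (
    AlchemicalSpec,
    HeadEndpoint,
    MoleculeTopology,
    ParticleSystem,
    ThermostatSpec,
)

__all__ = [
    "NoUnlikePairError",
    "MoveOutcome",
    "WorkRecord",
    "select_exchange_pair",
    "derive_exchange_spec",
    "apply_exchange",
    "mc_exchange_attempt",
    "alchemical_work",
    "alchemical_trajectory",
    "mdas_attempt",
    "run_sampler",
    "SamplerResult",
]

#: signature of a lambda-resolved evaluator: (system, lam, count) -> (breakdown, forces)
LambdaEvaluator = Callable[[ParticleSystem, float, bool], tuple[EnergyBreakdown, np.ndarray]]


class NoUnlikePairError(RuntimeError):
    """No pair of unlike-species molecules exists to exchange."""


@dataclass
class MoveOutcome:
    """Result of one exchange attempt (single-step or AT)."""

    accepted: bool
    work: EnergyBreakdown  # dU for a single-step move; AT work otherwise
    pair: tuple[int, int]
    force_evals_used: int
    rng_draws_used: int = 0


@dataclass
class WorkRecord:
    """Accumulated AT work with its vdW/Coulomb/bonded decomposition."""

    work: EnergyBreakdown
    pair: tuple[int, int] | None
    force_evals: int
    accepted: bool | None = None


def select_exchange_pair(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    rng: np.random.Generator,
    species: tuple[str, str] | None = None,
) -> tuple[int, int]:
    """Uniformly select one molecule of each of two unlike species.

    Returns molecule indices ``(a, b)``; every one of the |A| x |B| unlike
    pairs has equal probability.
    """
    if species is None:
        present = sorted({t.species for t in topologies})
        if len(present) != 2:
            raise NoUnlikePairError(
                f"need exactly two species to select a pair, found {present}"
            )
        species = (present[0], present[1])
    group_a = [m for m, t in enumerate(topologies) if t.species == species[0]]
    group_b = [m for m, t in enumerate(topologies) if t.species == species[1]]
    if not group_a or not group_b:
        raise NoUnlikePairError(
            f"no unlike pair: {len(group_a)} of {species[0]!r}, "
            f"{len(group_b)} of {species[1]!r}"
        )
    a = group_a[int(rng.integers(len(group_a)))]
    b = group_b[int(rng.integers(len(group_b)))]
    return a, b


def derive_exchange_spec(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    pair: tuple[int, int],
    like: AlchemicalSpec | None = None,
) -> AlchemicalSpec:
    """AlchemicalSpec whose endpoints are the current head parameters of
    ``pair``; schedule fields (delta_lambda, M, soft-core) are copied from
    ``like`` when given, otherwise default to a single-step exchange."""
    ha = topologies[pair[0]].head_index
    hb = topologies[pair[1]].head_index
    ea = HeadEndpoint(int(system.bead_type[ha]), float(system.charge[ha]))
    eb = HeadEndpoint(int(system.bead_type[hb]), float(system.charge[hb]))
    if like is None:
        return AlchemicalSpec(ea, eb)
    return AlchemicalSpec(
        ea, eb,
        delta_lambda=like.delta_lambda,
        plateau_steps=like.plateau_steps,
        softcore_delta=like.softcore_delta,
        vdw_coupling=like.vdw_coupling,
    )


def apply_exchange(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    state: LambdaState,
) -> None:
    """Swap the head-bead identities (type + charge) and species labels of
    the tagged pair in place.  Composition and total charge are unchanged."""
    ha, hb = state.head_a, state.head_b
    system.bead_type[ha], system.bead_type[hb] = (
        system.bead_type[hb],
        system.bead_type[ha],
    )
    system.charge[ha], system.charge[hb] = system.charge[hb], system.charge[ha]
    ta, tb = topologies[state.mol_a], topologies[state.mol_b]
    ta.species, tb.species = tb.species, ta.species


def _accept(work_total: float, kT: float, rng: np.random.Generator) -> bool:
    """Metropolis decision min(1, exp(-w/kT)); always consumes one draw."""
    p = math.exp(min(-work_total / kT, 0.0))
    return rng.random() < p


def mc_exchange_attempt(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    pair: tuple[int, int],
    thermostat: ThermostatSpec,
    rng: np.random.Generator,
    model: EnergyModel,
) -> tuple[MoveOutcome, tuple[EnergyBreakdown, np.ndarray] | None]:
    """Single-step Metropolis identity exchange of ``pair`` (in place).

    dU is the energy difference between the swapped and current identity
    assignments at fixed coordinates; acceptance is ``min(1, exp(-dU/kT))``.
    Velocities are untouched either way.  Costs one potential evaluation.

    Returns ``(outcome, delta_eval)`` where ``delta_eval`` is the
    ``(d_breakdown, d_forces)`` correction to apply to any cached evaluation
    if (and only if) the move was accepted, else ``None``.
    """
    spec = derive_exchange_spec(system, topologies, pair)
    state = make_lambda_state(system, topologies, pair, spec)
    e0, f0, e1, f1 = model.exchange_terms(system, state)
    delta = e1 - e0
    accepted = _accept(delta.total, thermostat.temperature, rng)
    outcome = MoveOutcome(accepted, delta, pair, force_evals_used=1, rng_draws_used=1)
    if accepted:
        apply_exchange(system, topologies, state)
        return outcome, (delta, f1 - f0)
    return outcome, None


def alchemical_work(
    system: ParticleSystem,
    evaluate_at: LambdaEvaluator,
    spec: AlchemicalSpec,
    thermostat: ThermostatSpec,
    dt: float,
    rng: np.random.Generator,
    initial: tuple[EnergyBreakdown, np.ndarray] | None = None,
    pair: tuple[int, int] | None = None,
) -> tuple[WorkRecord, ParticleSystem, tuple[EnergyBreakdown, np.ndarray]]:
    """Run one alchemical trajectory and accumulate the work, generically.

    ``evaluate_at(system, lam, count)`` must return the potential breakdown
    and forces at coupling ``lam``.  The input ``system`` is never modified;
    the evolved trial state is returned together with its final
    (breakdown, forces) at lambda = 1.  ``initial`` supplies the lambda = 0
    evaluation at the current state (normally cached from the preceding MD
    segment); when omitted it is computed here without being counted.

    Work is accumulated term by term as potential-energy jumps at each
    lambda increment, evaluated at the instantaneous configuration; the
    plateau MD between increments contributes no work.
    """
    trial = system.copy()
    e, f = initial if initial is not None else evaluate_at(trial, 0.0, False)
    n_win = spec.n_windows
    M = spec.plateau_steps
    w = EnergyBreakdown(0.0, 0.0, 0.0)
    for win in range(n_win):
        lam = win / n_win
        if M > 0:
            e, f = run_md_segment(
                trial, M, dt, thermostat, rng,
                lambda s: evaluate_at(s, lam, True),
                initial=(e, f),
            )
        lam_next = (win + 1) / n_win
        e_next, f_next = evaluate_at(trial, lam_next, True)
        w = w + (e_next - e)
        if not math.isfinite(w.total):
            raise IntegrationBlowUpError(
                f"non-finite work at lambda = {lam_next:.6g}"
            )
        e, f = e_next, f_next
    record = WorkRecord(w, pair, force_evals=(M + 1) * n_win)
    return record, trial, (e, f)


def alchemical_trajectory(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    pair: tuple[int, int],
    spec: AlchemicalSpec,
    thermostat: ThermostatSpec,
    dt: float,
    rng: np.random.Generator,
    model: EnergyModel,
    initial: tuple[EnergyBreakdown, np.ndarray] | None = None,
) -> tuple[WorkRecord, ParticleSystem, tuple[EnergyBreakdown, np.ndarray], LambdaState]:
    """Alchemical trajectory for an identity exchange of ``pair``.

    The pre-AT state is left untouched for a possible restore; the evolved
    lambda = 1 trial state is returned (identities still unswapped in its
    arrays — :func:`apply_exchange` commits them on acceptance).
    """
    spec = derive_exchange_spec(system, topologies, pair, like=spec)
    state = make_lambda_state(system, topologies, pair, spec)
    evaluate_at: LambdaEvaluator = lambda s, lam, count: model.evaluate(
        s, state, lam, count=count
    )
    record, trial, final = alchemical_work(
        system, evaluate_at, spec, thermostat, dt, rng, initial=initial, pair=pair
    )
    return record, trial, final, state


def mdas_attempt(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    spec: AlchemicalSpec,
    thermostat: ThermostatSpec,
    dt: float,
    rng: np.random.Generator,
    model: EnergyModel,
    pair: tuple[int, int] | None = None,
    rng_pairs: np.random.Generator | None = None,
    rng_dynamics: np.random.Generator | None = None,
    initial: tuple[EnergyBreakdown, np.ndarray] | None = None,
) -> tuple[MoveOutcome, tuple[EnergyBreakdown, np.ndarray] | None]:
    """One MDAS exchange attempt (in place on ``system``).

    Selects an unlike pair (unless given), runs the AT, and accepts with
    ``min(1, exp(-w/kT))``.  On acceptance the system continues from the
    lambda = 1 configuration and velocities with the identities swapped; on
    rejection positions and velocities are exactly the pre-AT phase-space
    point (the trial copy is discarded).

    Returns ``(outcome, final_eval)``; ``final_eval`` is the cached
    (breakdown, forces) of the post-move state when accepted, else ``None``
    (any pre-attempt cache remains valid on rejection).
    """
    if pair is None:
        pair = select_exchange_pair(system, topologies, rng_pairs or rng)
    record, trial, final, state = alchemical_trajectory(
        system, topologies, pair, spec, thermostat, dt,
        rng_dynamics if rng_dynamics is not None else rng, model, initial=initial,
    )
    accepted = _accept(record.work.total, thermostat.temperature, rng)
    outcome = MoveOutcome(
        accepted, record.work, pair,
        force_evals_used=record.force_evals,
        rng_draws_used=1,
    )
    if accepted:
        system.positions[:] = trial.positions
        system.velocities[:] = trial.velocities
        apply_exchange(system, topologies, state)
        return outcome, final
    return outcome, None


# ---------------------------------------------------------------------------
# sampler orchestration


@dataclass
class SamplerResult:
    """Everything a run produces: frames, logs, final state, cost."""

    frames: list  # list[Frame]
    work: "object"  # pandas.DataFrame work log
    energy: "object"  # pandas.DataFrame energy log
    system: ParticleSystem
    topologies: list[MoleculeTopology]
    force_evals: int
    n_attempts: int = 0
    n_accepted: int = 0

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_attempts if self.n_attempts else float("nan")


def run_sampler(
    config,
    system: ParticleSystem | None = None,
    topologies: list[MoleculeTopology] | None = None,
):
    """Run a full md / mcmd / mdas sampling schedule from a :class:`RunConfig`.

    Alternates straightforward-MD segments with exchange attempts (none in
    ``md`` mode).  Only conventional-MD configurations are emitted as
    sampling frames, each stamped with the cumulative force-evaluation
    count; every attempt is logged with its work decomposition and cost.
    """
    import pandas as pd

    from .config import RunConfig, build_components
    from .io import Frame

    assert isinstance(config, RunConfig)
    comps = build_components(config)
    rng_dyn, rng_pairs, rng_accept, rng_build = comps.streams

    if system is None or topologies is None:
        system, topologies = comps.build_initial(rng_build)
    counter = comps.counter
    model = EnergyModel(comps.pair_table, comps.electrostatics, topologies, counter=counter)
    provider = lambda s: model.evaluate(s)

    thermostat = comps.thermostat
    sched = comps.schedule
    frames: list[Frame] = []
    work_rows: list[dict] = []
    energy_rows: list[dict] = []
    n_acc = 0
    cached = model.evaluate(system, count=False)

    if getattr(config, "equilibration_steps", 0) > 0:
        cached = run_md_segment(
            system, config.equilibration_steps, sched.dt, thermostat, rng_dyn,
            provider, initial=cached,
        )
        counter.reset()  # production accounting starts after equilibration

    total_steps = 0
    for attempt in range(sched.n_attempts):
        cached = run_md_segment(
            system, sched.md_segment_steps, sched.dt, thermostat, rng_dyn,
            provider, initial=cached,
        )
        total_steps += sched.md_segment_steps
        e, _ = cached
        kin = system.kinetic_energy()
        energy_rows.append(
            dict(
                step=total_steps, force_evals=counter.count,
                total=e.total, vdw=e.vdw, coulomb=e.coulomb, bonded=e.bonded,
                kinetic=kin, temperature=system.instantaneous_kT(),
            )
        )
        frames.append(Frame.from_system(system, force_evals=counter.count))

        if sched.mode == "md":
            continue
        if sched.mode == "mcmd":
            pair = select_exchange_pair(system, topologies, rng_pairs)
            outcome, delta = mc_exchange_attempt(
                system, topologies, pair, thermostat, rng_accept, model
            )
            if outcome.accepted and delta is not None:
                d_e, d_f = delta
                cached = (cached[0] + d_e, cached[1] + d_f)
        else:  # mdas
            outcome, final = mdas_attempt(
                system, topologies, comps.alchemical, thermostat, sched.dt,
                rng_accept, model, rng_pairs=rng_pairs, rng_dynamics=rng_dyn,
                initial=cached,
            )
            if outcome.accepted and final is not None:
                cached = final
        n_acc += int(outcome.accepted)
        work_rows.append(
            dict(
                attempt_index=attempt,
                pair_a=outcome.pair[0], pair_b=outcome.pair[1],
                w_total=outcome.work.total, w_vdw=outcome.work.vdw,
                w_coulomb=outcome.work.coulomb, w_bonded=outcome.work.bonded,
                accepted=outcome.accepted,
                cumulative_force_evals=counter.count,
            )
        )

    work_df = pd.DataFrame(
        work_rows,
        columns=[
            "attempt_index", "pair_a", "pair_b", "w_total", "w_vdw",
            "w_coulomb", "w_bonded", "accepted", "cumulative_force_evals",
        ],
    )
    energy_df = pd.DataFrame(
        energy_rows,
        columns=[
            "step", "force_evals", "total", "vdw", "coulomb", "bonded",
            "kinetic", "temperature",
        ],
    )
    n_att = sched.n_attempts if sched.mode != "md" else 0
    return SamplerResult(
        frames, work_df, energy_df, system, topologies,
        force_evals=counter.count, n_attempts=n_att, n_accepted=n_acc,
    )
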