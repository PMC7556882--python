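"""Standard validation studies for the exchange samplers.

These are the package's built-in correctness and efficiency benchmarks, all
cheap enough for a workstation:

* **accounting** — per-attempt force-evaluation costs of the reference
  sampling schedule (2000-step segments; 1000-step AT with lambda moved
  every ten steps): 3000 evaluations per MDAS attempt, 2001 per MC-MD.
* **frozen-cluster equilibrium** — a six-particle, two-species cluster with
  frozen coordinates; exchange-only chains must reproduce the exact
  Boltzmann weights of the 20 species arrangements (enumeration oracle).
* **Jarzynski spring** — nonequilibrium work over a harmonic spring change
  k0 -> k1 satisfies <exp(-w/kT)> = exp(-dF/kT) with
  dF = (kT/2) ln(k1/k0) at every plateau length M, while the mean
  (dissipated) work decreases as M grows.
* **mixing benchmark** — demixed toy membrane relaxed by plain MD, MC-MD
  and MDAS; exponential fits of max[g(r)] against force evaluations give
  per-method relaxation rates and speedup ratios, plus acceptance rates.
* **analysis recovery** — the fitting and acceptance estimators re-derive
  known parameters from synthetic data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .analysis import (
    acceptance_from_work,
    fit_exponential,
    max_gr_series,
    speedup,
    MixingSeries,
)
from .config import RunConfig
from .energy import EnergyModel, EvalCounter
from .exchange import (
    alchemical_work,
    mc_exchange_attempt,
    mdas_attempt,
    run_sampler,
    select_exchange_pair,
)
from .harmonic import ScaledSpringWell
from .model import (
    AlchemicalSpec,
    ElectrostaticsParams,
    HeadEndpoint,
    MoleculeTopology,
    PairTable,
    ParticleSystem,
    SimulationBox,
    ThermostatSpec,
)

__all__ = [
    "reference_schedule_costs",
    "frozen_cluster",
    "enumerate_arrangements",
    "arrangement_key",
    "run_exchange_chain",
    "arrangement_chi_square",
    "jarzynski_spring_study",
    "MixingBenchmarkResult",
    "mixing_benchmark",
    "fit_recovery_study",
    "acceptance_quadrature_study",
]


# ---------------------------------------------------------------------------
# reference-schedule cost accounting


def reference_schedule_costs(seed: int = 0) -> dict[str, int]:
    """Per-attempt force-evaluation cost of the reference schedule.

    Runs one MDAS attempt (2000-step segment + 1000-step AT: delta_lambda =
    0.01 with 9 plateau steps per window) and one MC-MD attempt (2000-step
    segment + single-step exchange) on a small membrane and reports the
    measured evaluation counts.
    """
    out = {}
    for mode in ("mdas", "mcmd"):
        cfg = RunConfig(
            n_lipids_a=10, n_lipids_b=10, mode=mode, md_segment_steps=2000,
            n_attempts=1, delta_lambda=0.01, plateau_steps=9, seed=seed,
        )
        result = run_sampler(cfg)
        out[f"{mode}_force_evals_per_attempt"] = int(result.force_evals)
    return out


# ---------------------------------------------------------------------------
# frozen-cluster equilibrium (enumeration oracle)


def frozen_cluster(
    seed: int = 0, n_a: int = 3, n_b: int = 3, kT: float = 1.0
) -> tuple[ParticleSystem, list[MoleculeTopology], EnergyModel, ThermostatSpec]:
    """Six single-bead molecules (3 A + 3 B) at quenched random positions.

    Unlike-species contacts are more favorable (epsilon 1.3 vs 1.0), so the
    20 possible species arrangements carry distinct Boltzmann weights while
    exchange acceptance stays high.  Coordinates are never propagated: only
    the species labels move, which makes exact enumeration possible.
    """
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    # compact cluster: neighbors inside the first LJ shell so arrangements
    # have clearly distinct energies (yet within ~kT, keeping acceptance high)
    box = SimulationBox([3.4, 3.4])
    pos = np.zeros((n, 2))
    placed = 0
    while placed < n:
        cand = rng.random(2) * box.lengths
        if placed:
            dr = box.min_image(pos[:placed] - cand[None, :])
            if np.min(np.sum(dr * dr, axis=1)) < 1.0:
                continue
        pos[placed] = cand
        placed += 1
    eps = np.array([[1.0, 1.3], [1.3, 1.0]])
    sig = np.ones((2, 2))
    table = PairTable(eps, sig, cutoff=2.5, shift_at_cutoff=True, labels=("A", "B"))
    elec = ElectrostaticsParams(cutoff=2.5)
    types = np.array([0] * n_a + [1] * n_b, dtype=np.int64)
    system = ParticleSystem(
        pos, np.zeros((n, 2)), np.ones(n), types, np.zeros(n),
        np.arange(n, dtype=np.int64), box, ("A", "B"),
    )
    topologies = [
        MoleculeTopology("A" if i < n_a else "B", [i]) for i in range(n)
    ]
    model = EnergyModel(table, elec, topologies, counter=EvalCounter())
    thermostat = ThermostatSpec(kT, "none", 1.0)
    return system, topologies, model, thermostat


def arrangement_key(topologies: list[MoleculeTopology]) -> str:
    return "".join(t.species for t in topologies)


def enumerate_arrangements(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    model: EnergyModel,
    kT: float,
) -> dict[str, float]:
    """Exact Boltzmann probability of every species arrangement.

    Enumerates all assignments of the A labels over the molecules (the
    composition is fixed) and computes each arrangement's total potential
    energy with the coordinates frozen.
    """
    n = len(topologies)
    n_a = sum(1 for t in topologies if t.species == "A")
    work = system.copy()
    log_w: dict[str, float] = {}
    for subset in itertools.combinations(range(n), n_a):
        labels = ["B"] * n
        for m in subset:
            labels[m] = "A"
        for m, t in enumerate(topologies):
            head = t.head_index
            work.bead_type[head] = 0 if labels[m] == "A" else 1
        e, _ = model.evaluate(work, count=False)
        log_w["".join(labels)] = -e.total / kT
    keys = sorted(log_w)
    logs = np.array([log_w[k] for k in keys])
    logs -= logs.max()
    w = np.exp(logs)
    w /= w.sum()
    return dict(zip(keys, w))


def run_exchange_chain(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    model: EnergyModel,
    thermostat: ThermostatSpec,
    n_moves: int,
    seed: int,
    sampler: str = "mc",
    delta_lambda: float = 0.5,
    thin: int = 20,
) -> dict[str, int]:
    """Exchange-only Markov chain over species arrangements (frozen coords).

    ``sampler='mc'`` uses single-step Metropolis exchanges, ``'mdas'`` uses
    work-based AT moves with M = 0 plateau steps (coordinates never move, so
    the accumulated work telescopes to the single-step energy difference —
    the two chains sample the same stationary distribution).  Returns visit
    counts of each arrangement, recorded every ``thin`` moves.
    """
    ss = np.random.SeedSequence(seed)
    rng_pairs, rng_accept = (np.random.default_rng(s) for s in ss.spawn(2))
    spec = AlchemicalSpec(
        HeadEndpoint(0, 0.0), HeadEndpoint(1, 0.0),
        delta_lambda=delta_lambda if sampler == "mdas" else 1.0,
        plateau_steps=0,
    )
    counts: dict[str, int] = {}
    for move in range(n_moves):
        if sampler == "mc":
            pair = select_exchange_pair(system, topologies, rng_pairs)
            mc_exchange_attempt(system, topologies, pair, thermostat, rng_accept, model)
        else:
            mdas_attempt(
                system, topologies, spec, thermostat, 0.005, rng_accept, model,
                rng_pairs=rng_pairs,
            )
        if (move + 1) % thin == 0:
            key = arrangement_key(topologies)
            counts[key] = counts.get(key, 0) + 1
    return counts


def arrangement_chi_square(
    counts: dict[str, int], probabilities: dict[str, float]
) -> tuple[float, float]:
    """Chi-square statistic and p-value of observed arrangement counts
    against the exact enumeration probabilities."""
    n = sum(counts.values())
    keys = sorted(probabilities)
    observed = np.array([counts.get(k, 0) for k in keys], dtype=float)
    expected = np.array([probabilities[k] * n for k in keys])
    chi2, p = stats.chisquare(observed, expected)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Jarzynski spring study


def jarzynski_spring_study(
    plateau_lengths: tuple[int, ...] = (1, 10, 100),
    n_trajectories: int = 10000,
    k0: float = 1.0,
    k1: float = 4.0,
    kT: float = 1.0,
    delta_lambda: float = 0.2,
    dt: float = 0.02,
    seed: int = 0,
) -> dict[int, dict[str, float]]:
    """Nonequilibrium work statistics for the spring change k0 -> k1.

    For each plateau length M, ``n_trajectories`` ATs are launched from
    exact lambda = 0 equilibrium samples and propagated with a Langevin
    thermostat.  Reports the mean work, the Jarzynski estimator
    <exp(-w/kT)> with its standard error, and the exact target
    exp(-dF/kT) = (k0/k1)^(1/2).
    """
    thermostat = ThermostatSpec(kT, "langevin", 1.0)
    ss = np.random.SeedSequence(seed)
    out: dict[int, dict[str, float]] = {}
    for M, child in zip(plateau_lengths, ss.spawn(len(plateau_lengths))):
        rng = np.random.default_rng(child)
        well = ScaledSpringWell(k0, k1, center=100.0)
        spec = AlchemicalSpec(
            HeadEndpoint(0, 0.0), HeadEndpoint(0, 0.0),
            delta_lambda=delta_lambda, plateau_steps=int(M),
        )
        system = well.equilibrium_system(kT, rng)
        works = np.empty(n_trajectories)
        for i in range(n_trajectories):
            well.resample(system, kT, rng)
            record, _, _ = alchemical_work(
                system, well.evaluate_at, spec, thermostat, dt, rng
            )
            works[i] = record.work.total
        est = np.exp(-works / kT)
        out[int(M)] = dict(
            mean_work=float(works.mean()),
            jarzynski_estimate=float(est.mean()),
            jarzynski_stderr=float(est.std(ddof=1) / math.sqrt(est.size)),
            target=float(math.exp(-well.free_energy_difference(kT) / kT)),
            free_energy_difference=float(well.free_energy_difference(kT)),
        )
    return out


# ---------------------------------------------------------------------------
# mixing benchmark (the efficiency study)


@dataclass
class MixingBenchmarkResult:
    """Rates, speedups and acceptances of the three samplers on the demixed
    toy membrane, everything per force evaluation."""

    rate_md: float
    rate_md_stderr: float
    rate_mdas: float
    rate_mdas_stderr: float
    speedup_mdas_vs_md: float
    speedup_mdas_vs_md_stderr: float
    acceptance_mdas: float
    acceptance_mcmd: float
    plateau: float
    n_attempts_mdas: int
    n_attempts_mcmd: int
    rate_mcmd: float | None = None
    rate_mcmd_stderr: float | None = None
    speedup_mcmd_vs_md: float | None = None
    speedup_mcmd_vs_md_stderr: float | None = None


def mixing_benchmark(
    seed: int = 0,
    n_a: int = 50,
    n_b: int = 50,
    md_segments: int = 1200,
    mcmd_attempts: int = 1200,
    mdas_attempts: int = 600,
    segment_steps: int = 125,
    equilibration_steps: int = 20000,
    reference_attempts: int = 300,
    selection: str = "HB",
    frames_per_point: int = 5,
    bin_width: float = 0.1,
    r_max: float = 4.0,
    r_min_exclusion: float = 0.5,
) -> MixingBenchmarkResult:
    """Relaxation of the demixed membrane under MD, MC-MD and MDAS.

    All three samplers start from the same demixed configuration and spend
    a comparable force-evaluation budget.  The mixing observable is the
    tallest peak of the charged-head g(r), fitted against cumulative force
    evaluations with the plateau fixed from a mixed-start MC-MD reference
    run (exchange sampling equilibrates composition quickly, so the
    reference converges within a short run).  The MDAS schedule here is a
    short AT (delta_lambda = 0.1, M = 12), appropriate for this toy where
    the neighbor-cage relaxation is local and fast.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    common = dict(
        n_lipids_a=n_a, n_lipids_b=n_b, md_segment_steps=segment_steps,
        equilibration_steps=equilibration_steps,
    )
    res_md = run_sampler(RunConfig(mode="md", n_attempts=md_segments,
                                   seed=seeds[0], **common))
    res_mc = run_sampler(RunConfig(mode="mcmd", n_attempts=mcmd_attempts,
                                   seed=seeds[1], **common))
    res_as = run_sampler(RunConfig(mode="mdas", n_attempts=mdas_attempts,
                                   delta_lambda=0.1, plateau_steps=12,
                                   seed=seeds[2], **common))
    res_ref = run_sampler(RunConfig(mode="mcmd", n_attempts=reference_attempts,
                                    initial_state="mixed", seed=seeds[3],
                                    **common))

    kw = dict(
        selection=selection, frames_per_point=frames_per_point,
        bin_width=bin_width, r_max=r_max, r_min_exclusion=r_min_exclusion,
    )
    ref_series = max_gr_series(res_ref.frames, **kw)
    plateau = float(ref_series.max_gr.mean())

    fit_md = fit_exponential(max_gr_series(res_md.frames, **kw), fix_plateau=plateau)
    fit_as = fit_exponential(max_gr_series(res_as.frames, **kw), fix_plateau=plateau)
    s_as, s_as_err = speedup(fit_as, fit_md)
    result = MixingBenchmarkResult(
        rate_md=fit_md.rate,
        rate_md_stderr=fit_md.rate_stderr,
        rate_mdas=fit_as.rate,
        rate_mdas_stderr=fit_as.rate_stderr,
        speedup_mdas_vs_md=s_as,
        speedup_mdas_vs_md_stderr=s_as_err,
        acceptance_mdas=res_as.acceptance_rate,
        acceptance_mcmd=res_mc.acceptance_rate,
        plateau=plateau,
        n_attempts_mdas=res_as.n_attempts,
        n_attempts_mcmd=res_mc.n_attempts,
    )
    # MC-MD relaxes within the first few blocks at this attempt frequency;
    # its rate is often unresolvable, so it is reported only when the fit
    # converges (the headline comparisons are MDAS vs MD and the acceptances)
    try:
        fit_mc = fit_exponential(
            max_gr_series(res_mc.frames, **kw), fix_plateau=plateau
        )
        result.rate_mcmd = fit_mc.rate
        result.rate_mcmd_stderr = fit_mc.rate_stderr
        s_mc, s_mc_err = speedup(fit_mc, fit_md)
        result.speedup_mcmd_vs_md = s_mc
        result.speedup_mcmd_vs_md_stderr = s_mc_err
    except Exception:
        pass
    return result


# ---------------------------------------------------------------------------
# analysis recovery studies


def fit_recovery_study(
    seed: int = 0,
    n_points: int = 200,
    noise: float = 0.05,
    n_replicates: int = 1,
) -> dict[str, float]:
    """Recover a known exponential-relaxation rate from synthetic series.

    Returns the exact-recovery relative error on a noiseless series and the
    mean relative error of the rate over noisy replicates (Gaussian noise of
    relative amplitude ``noise``).
    """
    rng = np.random.default_rng(seed)
    y_inf, a, k = 2.0, 3.0, 1.0 / 500.0
    t = np.linspace(0.0, 2500.0, n_points)
    t[0] = 1.0  # force_evals must be strictly increasing and positive
    y_true = y_inf + a * np.exp(-k * t)

    fit0 = fit_exponential(MixingSeries(t, y_true))
    exact_rel_err = abs(fit0.rate - k) / k

    errs = []
    for _ in range(n_replicates):
        y = y_true + rng.normal(0.0, noise * y_true.mean(), size=t.size)
        fit = fit_exponential(MixingSeries(t, y))
        errs.append(abs(fit.rate - k) / k)
    return dict(
        exact_rate_rel_err=float(exact_rel_err),
        noisy_rate_rel_err=float(np.mean(errs)),
        true_rate=k,
    )


def acceptance_quadrature_study(
    seed: int = 0,
    mu: float = 2.0,
    sigma: float = 1.5,
    kT: float = 1.0,
    n_samples: int = 100000,
) -> dict[str, float]:
    """Work-based acceptance estimate versus numerical quadrature.

    Work samples are drawn from N(mu, sigma^2); the estimator
    mean[min(1, exp(-w/kT))] must agree with the integral
    E[min(1, exp(-w/kT))] computed by quadrature.
    """
    rng = np.random.default_rng(seed)
    w = rng.normal(mu, sigma, n_samples)
    est, stderr = acceptance_from_work(w, kT, n_boot=200, rng=rng)

    def integrand(x: float) -> float:
        p = math.exp(-((x - mu) ** 2) / (2 * sigma**2)) / (sigma * math.sqrt(2 * math.pi))
        return p * min(1.0, math.exp(-x / kT))

    target, _ = integrate.quad(integrand, mu - 12 * sigma, mu + 12 * sigma, limit=200)
    return dict(estimate=float(est), stderr=float(stderr), quadrature=float(target))
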