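"""NVT propagation: velocity-Verlet core plus Langevin (BAOAB) and
stochastic velocity-rescaling thermostats.

Every integration step consumes exactly one potential/force evaluation;
forces are reused across the two velocity half-kicks, which is what makes
"force evaluations" a faithful cost unit for method comparisons.
"""

from __future__ import annotations

import math
from typing import Callable, Protocol

import numpy as np

from .energy import EnergyBreakdown
from .model import ParticleSystem, ThermostatSpec

__all__ = [
    "IntegrationBlowUpError",
    "ForceProvider",
    "velocity_verlet_step",
    "thermostat_step",
    "run_md_segment",
]


class IntegrationBlowUpError(RuntimeError):
    """The integrator produced non-finite coordinates."""


class ForceProvider(Protocol):
    """Anything that evaluates a system's potential and forces in one pass."""

    def __call__(self, system: ParticleSystem) -> tuple[EnergyBreakdown, np.ndarray]: ...


def _wrap_inplace(system: ParticleSystem) -> None:
    pos, box = system.positions, system.box
    for k in range(box.dim):
        if box.periodic[k]:
            L = box.lengths[k]
            pos[:, k] %= L
            # tiny negative inputs can round the modulo up to exactly L
            pos[pos[:, k] >= L, k] = 0.0


def _check_finite(system: ParticleSystem, step: int, dx: np.ndarray) -> None:
    if not np.all(np.isfinite(system.positions)):
        maxdx = float(np.nanmax(np.abs(dx))) if dx.size else 0.0
        raise IntegrationBlowUpError(
            f"non-finite coordinates at step {step}; max displacement {maxdx:.3g}"
        )


def velocity_verlet_step(
    system: ParticleSystem,
    dt: float,
    force_provider: ForceProvider,
    forces_current: np.ndarray,
    step_index: int = 0,
) -> tuple[EnergyBreakdown, np.ndarray]:
    """One plain velocity-Verlet step (in place); returns the end-of-step
    energy breakdown and forces (one force evaluation)."""
    inv_m = 1.0 / system.masses[:, None]
    system.velocities += 0.5 * dt * forces_current * inv_m
    dx = dt * system.velocities
    system.positions += dx
    _check_finite(system, step_index, dx)
    _wrap_inplace(system)
    breakdown, f_new = force_provider(system)
    system.velocities += 0.5 * dt * f_new * inv_m
    return breakdown, f_new


def thermostat_step(
    system: ParticleSystem,
    thermostat: ThermostatSpec,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the velocity-only part of the thermostat (no force evaluation).

    ``langevin`` applies the exact Ornstein-Uhlenbeck update over ``dt``
    (the O part of BAOAB) with friction ``gamma = 1/coupling``;
    ``velocity_rescaling`` applies the stochastic kinetic-energy rescaling
    of the canonical-sampling-through-velocity-rescaling scheme with
    relaxation time ``coupling``.
    """
    if thermostat.scheme == "none":
        raise ValueError("thermostat_step requires scheme != 'none'")
    v = system.velocities
    kT = thermostat.temperature
    if thermostat.scheme == "langevin":
        gamma = 1.0 / thermostat.coupling
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt(1.0 - c1 * c1)
        sd = np.sqrt(kT / system.masses)[:, None]
        v *= c1
        v += c2 * sd * rng.standard_normal(v.shape)
    else:  # velocity_rescaling
        ndof = system.n * system.dim
        kin = system.kinetic_energy()
        if ndof == 0 or kin <= 0:
            return v
        kbar = 0.5 * ndof * kT
        c = math.exp(-dt / thermostat.coupling)
        r1 = rng.standard_normal()
        s = rng.chisquare(ndof - 1) if ndof > 1 else 0.0
        ratio = kbar / (ndof * kin)
        alpha2 = (
            c
            + (1.0 - c) * (r1 * r1 + s) * ratio
            + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ratio)
        )
        v *= math.sqrt(max(alpha2, 0.0))
    return v


def run_md_segment(
    system: ParticleSystem,
    n_steps: int,
    dt: float,
    thermostat: ThermostatSpec,
    rng: np.random.Generator,
    force_provider: ForceProvider,
    initial: tuple[EnergyBreakdown, np.ndarray] | None = None,
    observers: list[Callable[[int, ParticleSystem, EnergyBreakdown], None]] | None = None,
    observer_stride: int = 1,
) -> tuple[EnergyBreakdown, np.ndarray]:
    """Propagate ``n_steps`` NVT steps in place; returns the final
    (breakdown, forces) pair so callers can chain segments without
    re-evaluating.

    ``initial`` supplies the (breakdown, forces) at the current state; when
    omitted it is computed once (an extra evaluation).  Exactly ``n_steps``
    force evaluations are consumed by the loop itself.  With the Langevin
    thermostat the step is the BAOAB splitting; with velocity rescaling a
    velocity-Verlet step followed by the rescaling; with ``scheme='none'``
    plain velocity Verlet.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    state = initial if initial is not None else force_provider(system)
    breakdown, f = state
    if n_steps == 0:
        return breakdown, f

    scheme = thermostat.scheme
    inv_m = 1.0 / system.masses[:, None] if system.n else np.zeros((0, system.dim))
    if scheme == "langevin":
        gamma = 1.0 / thermostat.coupling
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt(1.0 - c1 * c1)
        sd = np.sqrt(thermostat.temperature / system.masses)[:, None]

    for step in range(n_steps):
        if scheme == "langevin":
            v = system.velocities
            v += 0.5 * dt * f * inv_m
            system.positions += 0.5 * dt * v
            v *= c1
            v += c2 * sd * rng.standard_normal(v.shape)
            dx = 0.5 * dt * v
            system.positions += dx
            _check_finite(system, step, dx)
            _wrap_inplace(system)
            breakdown, f = force_provider(system)
            v += 0.5 * dt * f * inv_m
        else:
            breakdown, f = velocity_verlet_step(
                system, dt, force_provider, f, step_index=step
            )
            if scheme == "velocity_rescaling":
                thermostat_step(system, thermostat, dt, rng)
        if observers and (step + 1) % observer_stride == 0:
            for obs in observers:
                obs(step + 1, system, breakdown)
    return breakdown, f
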