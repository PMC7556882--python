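"""Analytic harmonic benchmark potential for the work machinery.

A single particle in a harmonic well whose spring constant (or center)
interpolates linearly in lambda.  The free-energy difference of a spring
change k0 -> k1 along one coupled axis is known in closed form,

    dF = (kT / 2) ln(k1 / k0),

so the nonequilibrium work generated by :func:`mdasim.exchange.alchemical_work`
can be checked against the Jarzynski equality  <exp(-w/kT)> = exp(-dF/kT)
and against the quasi-static limit (mean work -> dF as the plateau length
grows).
"""

from __future__ import annotations

import math

import numpy as np

from .energy import EnergyBreakdown, EvalCounter
from .model import ParticleSystem, SimulationBox, maxwell_velocities

__all__ = ["ScaledSpringWell"]


class ScaledSpringWell:
    """U(x; lam) = 1/2 [(1-lam) k0 + lam k1] (x_axis - center)^2  (+ optional
    lambda-linear center translation).  Only ``axis`` is coupled; the other
    coordinates are free.
    """

    def __init__(
        self,
        k0: float,
        k1: float,
        center: float,
        axis: int = 0,
        center1: float | None = None,
        counter: EvalCounter | None = None,
    ) -> None:
        if k0 <= 0 or k1 <= 0:
            raise ValueError("spring constants must be positive")
        self.k0, self.k1 = float(k0), float(k1)
        self.center0 = float(center)
        self.center1 = float(center1) if center1 is not None else float(center)
        self.axis = axis
        self.counter = counter if counter is not None else EvalCounter()

    def spring(self, lam: float) -> tuple[float, float]:
        k = (1.0 - lam) * self.k0 + lam * self.k1
        c = (1.0 - lam) * self.center0 + lam * self.center1
        return k, c

    def evaluate_at(
        self, system: ParticleSystem, lam: float, count: bool = True
    ) -> tuple[EnergyBreakdown, np.ndarray]:
        k, c = self.spring(lam)
        x = system.positions[:, self.axis] - c
        u = 0.5 * k * float(np.dot(x, x))
        f = np.zeros_like(system.positions)
        f[:, self.axis] = -k * x
        if count:
            self.counter.add(1)
        return EnergyBreakdown(0.0, 0.0, u), f

    def provider(self, lam: float):
        """Fixed-lambda force provider for plain MD segments."""
        return lambda system: self.evaluate_at(system, lam, True)

    def free_energy_difference(self, kT: float) -> float:
        """dF(lam 0 -> 1); center translation contributes nothing."""
        return 0.5 * kT * math.log(self.k1 / self.k0)

    def equilibrium_system(
        self, kT: float, rng: np.random.Generator, box_length: float = 200.0
    ) -> ParticleSystem:
        """One particle drawn from the lam = 0 canonical distribution."""
        box = SimulationBox([box_length, box_length])
        pos = np.full((1, 2), box_length / 2.0)
        pos[0, self.axis] = self.center0 + rng.normal(0.0, math.sqrt(kT / self.k0))
        vel = maxwell_velocities(1, 2, np.ones(1), kT, rng)
        return ParticleSystem(
            pos, vel, np.ones(1), np.zeros(1, dtype=np.int64),
            np.zeros(1), np.zeros(1, dtype=np.int64), box, ("X",),
        )

    def resample(self, system: ParticleSystem, kT: float, rng: np.random.Generator) -> None:
        """Redraw the lam = 0 equilibrium state in place (fast per-AT reset)."""
        L = system.box.lengths[0]
        system.positions[0, :] = L / 2.0
        system.positions[0, self.axis] = self.center0 + rng.normal(
            0.0, math.sqrt(kT / self.k0)
        )
        system.velocities[0, :] = rng.standard_normal(system.dim) * math.sqrt(kT)
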