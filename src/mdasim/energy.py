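"""Potential energies and forces, including lambda-coupled exchange terms.

The total potential is a sum of three terms that are tracked separately
throughout (the same split the work analysis reports):

* ``vdw``     — 6-12 Lennard-Jones, cut off and (by default) shifted so the
  potential is continuous at the cutoff;
* ``coulomb`` — reaction-field electrostatics, shifted to zero at its cutoff;
* ``bonded``  — harmonic bonds and cosine-harmonic angles.

During an identity-exchange move the interactions of the two tagged head
beads are coupled to lambda.  Coulomb terms always mix linearly between the
two endpoint parameterizations, ``U(lam) = (1-lam) U_A + lam U_B``.  vdW
terms mix linearly by default; a soft-core form is available (and required
when an endpoint bead has epsilon = 0, i.e. a vanishing particle):

    U_soft(r) = 4 eps lam (A^6 - A^3),   A = sigma^2 / (r^2 + delta (1-lam))

which stays finite at overlap for lam < 1 and reduces to plain LJ at lam = 1.
All other pairs are lambda-independent, so a lambda increment only requires
re-evaluating the O(N) tagged interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import (
    AlchemicalSpec,
    ElectrostaticsParams,
    MoleculeTopology,
    PairTable,
    ParticleSystem,
    ValidationError,
)

__all__ = [
    "EvalCounter",
    "global_counter",
    "EnergyBreakdown",
    "LambdaState",
    "make_lambda_state",
    "InvalidExchangeError",
    "SingularSeparationError",
    "lj_pair_energy",
    "softcore_lj_energy",
    "coulomb_rf_energy",
    "EnergyModel",
    "system_energy",
    "forces",
]


class SingularSeparationError(ValueError):
    """Pair energy requested at zero separation."""


class InvalidExchangeError(ValueError):
    """Exchange requested between molecules that cannot be exchanged."""


class EvalCounter:
    """Counts potential/force evaluations, the cost unit of all comparisons."""

    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count = 0

    def add(self, k: int = 1) -> None:
        self.count += k

    def reset(self) -> None:
        self.count = 0


#: Module-level default counter used when no explicit counter is supplied.
global_counter = EvalCounter()


@dataclass(frozen=True)
class EnergyBreakdown:
    """Potential energy split into vdW / Coulomb / bonded terms."""

    vdw: float
    coulomb: float
    bonded: float

    @property
    def total(self) -> float:
        return self.vdw + self.coulomb + self.bonded

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.vdw - other.vdw,
            self.coulomb - other.coulomb,
            self.bonded - other.bonded,
        )

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.vdw + other.vdw,
            self.coulomb + other.coulomb,
            self.bonded + other.bonded,
        )


# ---------------------------------------------------------------------------
# scalar pair potentials (closed forms, used directly and as presets)


def lj_pair_energy(r, epsilon, sigma, cutoff=None, shifted=False):
    """6-12 Lennard-Jones pair energy; zero beyond ``cutoff`` when given.

    ``shifted`` subtracts the value at the cutoff so the potential is
    continuous there.  Accepts scalars or arrays in ``r``.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise SingularSeparationError("LJ energy undefined at r <= 0")
    sr6 = (sigma / r) ** 6
    u = 4.0 * epsilon * (sr6**2 - sr6)
    if cutoff is not None:
        if shifted:
            src6 = (sigma / cutoff) ** 6
            u = u - 4.0 * epsilon * (src6**2 - src6)
        u = np.where(r < cutoff, u, 0.0)
    return u if u.ndim else float(u)


def softcore_lj_energy(r, epsilon, sigma, lam, delta, cutoff=None, shifted=False):
    """Soft-core LJ: ``4 eps lam (A^6 - A^3)`` with ``A = sigma^2/(r^2 + delta(1-lam))``.

    Finite for all r >= 0 when ``lam < 1`` and ``delta > 0``; identical to
    :func:`lj_pair_energy` at ``lam = 1`` and identically zero at ``lam = 0``.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValidationError("lambda must lie in [0, 1]")
    if delta < 0:
        raise ValidationError("softcore delta must be >= 0")
    r = np.asarray(r, dtype=np.float64)
    pad = delta * (1.0 - lam)
    if lam == 1.0 and np.any(r <= 0):
        raise SingularSeparationError("soft-core reduces to LJ at lam=1; r=0 singular")
    a = sigma**2 / (r**2 + pad)
    u = 4.0 * epsilon * lam * (a**6 - a**3)
    if cutoff is not None:
        if shifted:
            ac = sigma**2 / (cutoff**2 + pad)
            u = u - 4.0 * epsilon * lam * (ac**6 - ac**3)
        u = np.where(r < cutoff, u, 0.0)
    return u if u.ndim else float(u)


def coulomb_rf_energy(r, q_i, q_j, params: ElectrostaticsParams):
    """Reaction-field Coulomb pair energy, exactly zero at and beyond the cutoff."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise SingularSeparationError("Coulomb energy undefined at r <= 0")
    pref = params.coulomb_prefactor / params.dielectric_screening
    u = pref * q_i * q_j * (1.0 / r + params.k_rf * r**2 - params.c_rf)
    u = np.where(r < params.cutoff, u, 0.0)
    return u if u.ndim else float(u)


# ---------------------------------------------------------------------------
# lambda state for exchange moves


@dataclass(frozen=True)
class LambdaState:
    """Tags the two molecules being exchanged and the coupling definition.

    At lambda = 0 the head of molecule ``mol_a`` carries ``spec.endpoint_a``
    and the head of ``mol_b`` carries ``spec.endpoint_b``; at lambda = 1 the
    assignments are swapped.
    """

    mol_a: int
    mol_b: int
    head_a: int
    head_b: int
    spec: AlchemicalSpec


def make_lambda_state(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    pair: tuple[int, int],
    spec: AlchemicalSpec,
) -> LambdaState:
    """Validate an exchange pair and build its :class:`LambdaState`."""
    ma, mb = pair
    ta, tb = topologies[ma], topologies[mb]
    if ta.species == tb.species:
        raise InvalidExchangeError(
            f"molecules {ma} and {mb} are both species {ta.species!r}"
        )
    ha, hb = ta.head_index, tb.head_index
    ea, eb = spec.endpoint_a, spec.endpoint_b
    if (
        system.bead_type[ha] != ea.bead_type
        or system.bead_type[hb] != eb.bead_type
        or abs(system.charge[ha] - ea.charge) > 1e-12
        or abs(system.charge[hb] - eb.charge) > 1e-12
    ):
        raise InvalidExchangeError(
            "current head parameters do not match the alchemical endpoints "
            f"(heads {ha}, {hb})"
        )
    return LambdaState(ma, mb, ha, hb, spec)


# ---------------------------------------------------------------------------
# full-system evaluation


class EnergyModel:
    """Evaluator bound to one interaction parameterization and topology set.

    ``evaluate`` returns the :class:`EnergyBreakdown` and per-particle force
    array in one pass (one "force evaluation" in the cost accounting).
    """

    def __init__(
        self,
        pair_table: PairTable,
        electrostatics: ElectrostaticsParams,
        topologies: list[MoleculeTopology],
        counter: EvalCounter | None = None,
    ) -> None:
        self.pair_table = pair_table
        self.electrostatics = electrostatics
        self.topologies = topologies
        self.counter = counter if counter is not None else global_counter

        bonds = [b for t in topologies for b in t.bonds]
        angles = [a for t in topologies for a in t.angles]
        self._bond_idx = np.array(
            [(b[0], b[1]) for b in bonds], dtype=np.int64
        ).reshape(-1, 2)
        self._bond_k = np.array([b[2] for b in bonds], dtype=np.float64)
        self._bond_r0 = np.array([b[3] for b in bonds], dtype=np.float64)
        self._angle_idx = np.array(
            [(a[0], a[1], a[2]) for a in angles], dtype=np.int64
        ).reshape(-1, 3)
        self._angle_k = np.array([a[3] for a in angles], dtype=np.float64)
        self._angle_cos0 = np.array(
            [np.cos(a[4]) for a in angles], dtype=np.float64
        )

    # -- internals --------------------------------------------------------

    def _tagged_terms(
        self,
        system: ParticleSystem,
        state: LambdaState,
        lam: float,
        f: np.ndarray,
    ) -> tuple[float, float]:
        """Lambda-mixed vdW + Coulomb of the tagged heads; forces into ``f``."""
        pt, el, spec = self.pair_table, self.electrostatics, state.spec
        box = system.box
        args = (system.positions, box.lengths, box.periodic, system.bead_type,
                system.molecule_id, state.head_a, state.head_b)
        ea, eb = spec.endpoint_a, spec.endpoint_b
        if ea == eb:
            # degenerate exchange: U is lambda-independent, evaluate one state
            # at full weight (keeps w = 0 exact for identical endpoints)
            lam = 0.0
        softcore = spec.vdw_coupling == "softcore"
        if softcore:
            evdw = _kernels.tagged_vdw(
                *args, ea.bead_type, eb.bead_type,
                pt.epsilon, pt.sigma, pt.cutoff, pt.shift_at_cutoff,
                True, 1.0 - lam, spec.softcore_delta, 1.0, f,
            )
            evdw += _kernels.tagged_vdw(
                *args, eb.bead_type, ea.bead_type,
                pt.epsilon, pt.sigma, pt.cutoff, pt.shift_at_cutoff,
                True, lam, spec.softcore_delta, 1.0, f,
            )
        else:
            evdw = _kernels.tagged_vdw(
                *args, ea.bead_type, eb.bead_type,
                pt.epsilon, pt.sigma, pt.cutoff, pt.shift_at_cutoff,
                False, 0.0, 0.0, 1.0 - lam, f,
            )
            evdw += _kernels.tagged_vdw(
                *args, eb.bead_type, ea.bead_type,
                pt.epsilon, pt.sigma, pt.cutoff, pt.shift_at_cutoff,
                False, 0.0, 0.0, lam, f,
            )
        cpre = el.coulomb_prefactor / el.dielectric_screening
        cargs = (system.positions, box.lengths, box.periodic, system.charge,
                 system.molecule_id, state.head_a, state.head_b)
        ecoul = _kernels.tagged_coulomb(
            *cargs, ea.charge, eb.charge,
            cpre, el.k_rf, el.c_rf, el.cutoff, 1.0 - lam, f,
        )
        ecoul += _kernels.tagged_coulomb(
            *cargs, eb.charge, ea.charge,
            cpre, el.k_rf, el.c_rf, el.cutoff, lam, f,
        )
        return evdw, ecoul

    # -- public surface ----------------------------------------------------

    def evaluate(
        self,
        system: ParticleSystem,
        lam_state: LambdaState | None = None,
        lam: float = 0.0,
        count: bool = True,
    ) -> tuple[EnergyBreakdown, np.ndarray]:
        """Total potential breakdown and forces, optionally lambda-coupled."""
        pt, el = self.pair_table, self.electrostatics
        box = system.box
        f = np.zeros_like(system.positions)
        skip_a = lam_state.head_a if lam_state is not None else -1
        skip_b = lam_state.head_b if lam_state is not None else -1
        cpre = el.coulomb_prefactor / el.dielectric_screening
        evdw, ecoul = _kernels.nonbonded(
            system.positions, box.lengths, box.periodic,
            system.bead_type, system.charge, system.molecule_id,
            pt.epsilon, pt.sigma, pt.cutoff, pt.shift_at_cutoff,
            cpre, el.k_rf, el.c_rf, el.cutoff,
            skip_a, skip_b, f,
        )
        ebond = _kernels.bonded(
            system.positions, box.lengths, box.periodic,
            self._bond_idx, self._bond_k, self._bond_r0,
            self._angle_idx, self._angle_k, self._angle_cos0,
            f,
        )
        if lam_state is not None:
            tv, tc = self._tagged_terms(system, lam_state, lam, f)
            evdw += tv
            ecoul += tc
        if count:
            self.counter.add(1)
        return EnergyBreakdown(evdw, ecoul, ebond), f

    def exchange_terms(
        self, system: ParticleSystem, state: LambdaState, count: bool = True
    ) -> tuple[EnergyBreakdown, np.ndarray, EnergyBreakdown, np.ndarray]:
        """Tagged-head interaction terms for both identity assignments.

        Returns ``(e_current, f_current, e_swapped, f_swapped)`` where the
        energies/forces cover only the interactions involving the two tagged
        head beads.  Only these O(N) terms differ between the assignments,
        so this is one (counted) potential evaluation; cached full forces can
        be updated as ``f + f_swapped - f_current`` after an accepted swap.
        """
        f0 = np.zeros_like(system.positions)
        f1 = np.zeros_like(system.positions)
        v0, c0 = self._tagged_terms(system, state, 0.0, f0)
        v1, c1 = self._tagged_terms(system, state, 1.0, f1)
        if count:
            self.counter.add(1)
        return (
            EnergyBreakdown(v0, c0, 0.0),
            f0,
            EnergyBreakdown(v1, c1, 0.0),
            f1,
        )

    def exchange_delta(
        self, system: ParticleSystem, state: LambdaState, count: bool = True
    ) -> EnergyBreakdown:
        """Single-step exchange energy difference, U(swapped) - U(current)."""
        e0, _, e1, _ = self.exchange_terms(system, state, count=count)
        return e1 - e0


def system_energy(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    pair_table: PairTable,
    electrostatics: ElectrostaticsParams,
    lam_state: LambdaState | None = None,
    lam: float = 0.0,
) -> EnergyBreakdown:
    """Total potential energy breakdown (convenience wrapper, not counted)."""
    model = EnergyModel(pair_table, electrostatics, topologies)
    breakdown, _ = model.evaluate(system, lam_state, lam, count=False)
    return breakdown


def forces(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    pair_table: PairTable,
    electrostatics: ElectrostaticsParams,
    lam_state: LambdaState | None = None,
    lam: float = 0.0,
    counter: EvalCounter | None = None,
) -> np.ndarray:
    """Analytic forces; increments the force-evaluation counter by one."""
    model = EnergyModel(pair_table, electrostatics, topologies, counter=counter)
    _, f = model.evaluate(system, lam_state, lam, count=True)
    return f
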