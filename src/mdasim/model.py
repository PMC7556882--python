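"""Domain types for the coarse-grained identity-exchange simulator.

Reduced units are used throughout: the Lennard-Jones ``sigma`` of the
reference bead is the unit of length, its well depth ``epsilon`` the unit
of energy, and the bead mass the unit of mass.  Temperatures are specified
as ``kT`` in energy units.  Presets that mirror a Martini-style
parameterization store the conversion they used (sigma = 0.47 nm,
epsilon = 3.5 kJ/mol) in their docstrings.

The central container is :class:`ParticleSystem`: flat per-particle arrays
(positions, velocities, masses, integer bead-type codes, charges, molecule
ids) plus a periodic :class:`SimulationBox`.  Molecules are described
separately by :class:`MoleculeTopology` records holding global particle
indices (head bead first) and bonded terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ValidationError",
    "PlacementError",
    "SimulationBox",
    "ParticleSystem",
    "MoleculeTopology",
    "MoleculeTemplate",
    "PairTable",
    "ElectrostaticsParams",
    "ThermostatSpec",
    "HeadEndpoint",
    "AlchemicalSpec",
    "SamplerSchedule",
    "build_system",
    "maxwell_velocities",
    "species_counts",
    "total_charge",
]


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class PlacementError(RuntimeError):
    """Molecules could not be placed in the box without overlap."""


# ---------------------------------------------------------------------------
# geometry


@dataclass
class SimulationBox:
    """Orthorhombic periodic box in 2 or 3 dimensions."""

    lengths: np.ndarray
    periodic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.float64).ravel()
        if self.lengths.size not in (2, 3):
            raise ValidationError(
                f"box dimensionality must be 2 or 3, got {self.lengths.size}"
            )
        if not np.all(self.lengths > 0):
            raise ValidationError("all box lengths must be positive")
        if self.periodic is None:
            self.periodic = np.ones(self.lengths.size, dtype=bool)
        else:
            self.periodic = np.asarray(self.periodic, dtype=bool).ravel()
            if self.periodic.size != self.lengths.size:
                raise ValidationError("periodic flags must match dimensionality")

    @property
    def dim(self) -> int:
        return int(self.lengths.size)

    @property
    def volume(self) -> float:
        """Area in 2D, volume in 3D."""
        return float(np.prod(self.lengths))

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Map coordinates into the primary image [0, L) along periodic axes."""
        out = np.array(positions, dtype=np.float64, copy=True)
        for k in range(self.dim):
            if self.periodic[k]:
                L = self.lengths[k]
                out[:, k] %= L
                # tiny negative inputs can round the modulo up to exactly L
                out[out[:, k] >= L, k] = 0.0
        return out

    def min_image(self, dr: np.ndarray) -> np.ndarray:
        """Minimum-image displacement vectors (vectorized over leading axes)."""
        dr = np.asarray(dr, dtype=np.float64)
        out = dr.copy()
        for k in range(self.dim):
            if self.periodic[k]:
                L = self.lengths[k]
                out[..., k] -= L * np.round(out[..., k] / L)
        return out

    def copy(self) -> "SimulationBox":
        return SimulationBox(self.lengths.copy(), self.periodic.copy())


# ---------------------------------------------------------------------------
# particles and molecules


@dataclass
class ParticleSystem:
    """State evolved by the sampler: per-particle arrays plus the box.

    ``bead_type`` holds integer codes indexing into ``type_labels`` (and into
    the rows/columns of the interaction :class:`PairTable`).
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    bead_type: np.ndarray
    charge: np.ndarray
    molecule_id: np.ndarray
    box: SimulationBox
    type_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, self.box.dim)
        n = self.positions.shape[0]
        self.velocities = np.asarray(self.velocities, dtype=np.float64).reshape(n, self.box.dim)
        self.masses = np.asarray(self.masses, dtype=np.float64).reshape(n)
        self.bead_type = np.asarray(self.bead_type, dtype=np.int64).reshape(n)
        self.charge = np.asarray(self.charge, dtype=np.float64).reshape(n)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64).reshape(n)
        self.type_labels = tuple(self.type_labels)

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])

    @property
    def dim(self) -> int:
        return self.box.dim

    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite positions")
        if not np.all(np.isfinite(self.velocities)):
            raise ValidationError("non-finite velocities")
        if self.n and not np.all(self.masses > 0):
            raise ValidationError("masses must be positive")
        for k in range(self.dim):
            if self.box.periodic[k] and self.n:
                x = self.positions[:, k]
                if x.min() < 0 or x.max() >= self.box.lengths[k]:
                    raise ValidationError("positions not wrapped into primary image")

    def wrap(self) -> None:
        self.positions = self.box.wrap(self.positions)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(),
            self.velocities.copy(),
            self.masses.copy(),
            self.bead_type.copy(),
            self.charge.copy(),
            self.molecule_id.copy(),
            self.box.copy(),
            self.type_labels,
        )

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[:, None] * self.velocities**2))

    def instantaneous_kT(self) -> float:
        """Kinetic temperature, 2 K / (N d) in reduced energy units."""
        dof = self.n * self.dim
        if dof == 0:
            return 0.0
        return 2.0 * self.kinetic_energy() / dof


@dataclass
class MoleculeTopology:
    """One molecule: species label, global bead indices (head first), bonded terms.

    ``bonds``  — tuples ``(i, j, k_spring, r0)`` with global indices.
    ``angles`` — tuples ``(i, j, k, k_theta, theta0)``; the angle potential is
    cosine-harmonic, ``U = k_theta/2 (cos(theta) - cos(theta0))^2``, which is
    regular at straight (theta0 = pi) equilibrium geometries.
    """

    species: str
    particle_indices: np.ndarray
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.particle_indices = np.asarray(self.particle_indices, dtype=np.int64).ravel()
        if self.particle_indices.size == 0:
            raise ValidationError("a molecule needs at least one bead")
        if len(set(self.particle_indices.tolist())) != self.particle_indices.size:
            raise ValidationError("duplicate bead indices within a molecule")

    @property
    def head_index(self) -> int:
        """Global index of the head bead (first entry by convention)."""
        return int(self.particle_indices[0])


@dataclass(frozen=True)
class MoleculeTemplate:
    """Blueprint used by :func:`build_system` for one species of linear molecule.

    Beads are listed head first; consecutive beads are bonded with a harmonic
    spring, and every consecutive triple gets a cosine-harmonic angle.
    """

    species: str
    bead_types: tuple[int, ...]
    charges: tuple[float, ...]
    bond_k: float = 80.0
    bond_r0: float = 1.0
    angle_k: float = 7.0
    angle_theta0: float = math.pi


# ---------------------------------------------------------------------------
# interaction tables


@dataclass
class PairTable:
    """Lennard-Jones parameters per bead-type pair plus the vdW cutoff."""

    epsilon: np.ndarray
    sigma: np.ndarray
    cutoff: float
    shift_at_cutoff: bool = True
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.epsilon.shape != self.sigma.shape or self.epsilon.ndim != 2:
            raise ValidationError("epsilon and sigma must be square matrices of equal shape")
        if not np.allclose(self.epsilon, self.epsilon.T):
            raise ValidationError("epsilon matrix must be symmetric")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValidationError("sigma matrix must be symmetric")
        if np.any(self.epsilon < 0):
            raise ValidationError("epsilon entries must be >= 0")
        if np.any(self.sigma <= 0):
            raise ValidationError("sigma entries must be > 0")
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be > 0")
        self.labels = tuple(self.labels)

    @property
    def n_types(self) -> int:
        return int(self.epsilon.shape[0])


@dataclass
class ElectrostaticsParams:
    """Reaction-field Coulomb treatment with a shifted cutoff.

    The pair energy is ``C q_i q_j / eps_r * (1/r + k_rf r^2 - c_rf)`` inside
    the cutoff and zero beyond it, with ``k_rf`` set by the continuum
    dielectric ``eps_rf`` beyond the cutoff and ``c_rf`` chosen so the energy
    vanishes exactly at ``r = r_c``.
    """

    dielectric_screening: float = 15.0
    rf_dielectric: float = 78.0
    cutoff: float = 2.5
    coulomb_prefactor: float = 1.0

    def __post_init__(self) -> None:
        if self.dielectric_screening <= 0:
            raise ValidationError("dielectric_screening must be > 0")
        if self.cutoff <= 0:
            raise ValidationError("electrostatics cutoff must be > 0")

    @property
    def k_rf(self) -> float:
        rc3 = self.cutoff**3
        if math.isinf(self.rf_dielectric):
            return 1.0 / (2.0 * rc3)
        er, erf = self.dielectric_screening, self.rf_dielectric
        return (erf - er) / ((2.0 * erf + er) * rc3)

    @property
    def c_rf(self) -> float:
        return 1.0 / self.cutoff + self.k_rf * self.cutoff**2


@dataclass
class ThermostatSpec:
    """Canonical-ensemble control: target kT, scheme, and coupling constant.

    ``coupling`` is the friction time 1/gamma for ``langevin`` and the
    relaxation time tau for stochastic ``velocity_rescaling``.
    """

    temperature: float
    scheme: str = "langevin"
    coupling: float = 1.0

    _SCHEMES = ("langevin", "velocity_rescaling", "none")

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature (kT) must be > 0")
        if self.scheme not in self._SCHEMES:
            raise ValidationError(f"unknown thermostat scheme {self.scheme!r}")
        if self.scheme != "none" and self.coupling <= 0:
            raise ValidationError("thermostat coupling must be > 0")


# ---------------------------------------------------------------------------
# alchemical move specification


@dataclass(frozen=True)
class HeadEndpoint:
    """Head-bead parameterization of one species: bead type code and charge."""

    bead_type: int
    charge: float


@dataclass
class AlchemicalSpec:
    """Definition of one identity-exchange move A <-> B.

    The coupling parameter lambda runs 0 -> 1 in steps of ``delta_lambda``;
    ``plateau_steps`` (M) MD steps are run at each fixed lambda before the
    next increment.  ``delta_lambda = 1`` with ``plateau_steps = 0`` is a
    single-step Monte Carlo exchange.
    """

    endpoint_a: HeadEndpoint
    endpoint_b: HeadEndpoint
    delta_lambda: float = 1.0
    plateau_steps: int = 0
    softcore_delta: float = 0.0
    vdw_coupling: str = "linear"  # "linear" | "softcore"

    def __post_init__(self) -> None:
        if not (0 < self.delta_lambda <= 1):
            raise ValidationError("delta_lambda must lie in (0, 1]")
        inv = 1.0 / self.delta_lambda
        if abs(inv - round(inv)) > 1e-9:
            raise ValidationError(
                f"1/delta_lambda must be a positive integer, got {inv!r}"
            )
        if self.plateau_steps < 0:
            raise ValidationError("plateau_steps (M) must be >= 0")
        if self.softcore_delta < 0:
            raise ValidationError("softcore_delta must be >= 0")
        if self.vdw_coupling not in ("linear", "softcore"):
            raise ValidationError(f"unknown vdw_coupling {self.vdw_coupling!r}")

    @property
    def n_windows(self) -> int:
        return int(round(1.0 / self.delta_lambda))


@dataclass
class SamplerSchedule:
    """Sampling loop layout: mode, segment length, attempt count, time step."""

    mode: str = "mdas"  # "md" | "mcmd" | "mdas"
    md_segment_steps: int = 2000
    n_attempts: int = 10
    dt: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("md", "mcmd", "mdas"):
            raise ValidationError(f"unknown sampler mode {self.mode!r}")
        if self.md_segment_steps < 0:
            raise ValidationError("md_segment_steps must be >= 0")
        if self.n_attempts < 0:
            raise ValidationError("n_attempts must be >= 0")
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")


# ---------------------------------------------------------------------------
# construction helpers


def maxwell_velocities(
    n: int, dim: int, masses: np.ndarray, kT: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw velocities from the Maxwell distribution at temperature kT."""
    if n == 0:
        return np.zeros((0, dim))
    sd = np.sqrt(kT / np.asarray(masses, dtype=np.float64))[:, None]
    return rng.standard_normal((n, dim)) * sd


def species_counts(topologies: list[MoleculeTopology]) -> dict[str, int]:
    out: dict[str, int] = {}
    for t in topologies:
        out[t.species] = out.get(t.species, 0) + 1
    return out


def total_charge(system: ParticleSystem) -> float:
    return float(system.charge.sum())


def _molecule_sites(
    n_mol: int,
    box: SimulationBox,
    mol_span: float,
    grid: tuple[int, int] | None = None,
) -> np.ndarray:
    """Anchor points for molecules on a rectangular grid filling the box.

    ``mol_span`` is the extent of one molecule along the second axis; grid
    cells are sized so neighboring molecules cannot overlap at build time.
    ``grid`` pins the (n_cols, n_rows) layout (used by builders that need a
    specific column structure, e.g. exact half-box demixing).
    """
    if n_mol == 0:
        return np.zeros((0, box.dim))
    Lx = box.lengths[0]
    Ly = box.lengths[1]
    # rows must clear the molecule span, columns the bead diameter
    rows_max = int(math.floor(Ly / (mol_span + 0.9)))
    cols_max = int(math.floor(Lx / 0.9))
    if rows_max < 1 or cols_max < 1 or rows_max * cols_max < n_mol:
        raise PlacementError(
            f"box {Lx:.2f} x {Ly:.2f} cannot hold {n_mol} molecules of span "
            f"{mol_span:.2f} (grid capacity {max(rows_max, 0) * max(cols_max, 0)})"
        )
    if grid is not None:
        n_cols, n_rows = grid
        if n_cols * n_rows < n_mol or n_cols > cols_max or n_rows > rows_max:
            raise PlacementError(
                f"requested grid {n_cols} x {n_rows} cannot hold {n_mol} "
                f"molecules of span {mol_span:.2f} in box {Lx:.2f} x {Ly:.2f}"
            )
    else:
        n_cols = max(
            int(math.ceil(n_mol / rows_max)),
            int(round(math.sqrt(n_mol * Lx / Ly))),
            1,
        )
        n_cols = min(n_cols, cols_max)
        n_rows = int(math.ceil(n_mol / n_cols))
    dx = Lx / n_cols
    dy = Ly / n_rows
    sites = np.zeros((n_mol, box.dim))
    for m in range(n_mol):
        col, row = m % n_cols, m // n_cols
        sites[m, 0] = (col + 0.5) * dx
        sites[m, 1] = row * dy + 0.45
    return sites


def build_system(
    composition: dict[str, int],
    templates: dict[str, MoleculeTemplate],
    box: SimulationBox,
    pair_table: PairTable,
    electrostatics: ElectrostaticsParams,
    seed: int | np.random.Generator = 0,
    *,
    species_layout: list[str] | None = None,
    counterion_type: int | None = None,
    counterion_charge: float = 1.0,
    counterion_mass: float = 1.0,
    kT: float | None = None,
    min_separation: float = 0.8,
    grid: tuple[int, int] | None = None,
) -> tuple[ParticleSystem, list[MoleculeTopology]]:
    """Place molecules on a grid and return a validated system.

    ``species_layout`` fixes the species at each grid site in order; when
    omitted the species sequence is a seeded random permutation of the
    composition.  If ``counterion_type`` is given, monovalent counterions are
    added (by rejection sampling into free space) until the total charge is
    exactly zero.  Velocities are Maxwell-distributed at ``kT`` when given,
    zero otherwise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for sp, cnt in composition.items():
        if cnt < 0:
            raise ValidationError(f"negative count for species {sp!r}")
        if cnt > 0 and sp not in templates:
            raise ValidationError(f"no template for species {sp!r}")

    if species_layout is None:
        layout = [sp for sp, cnt in sorted(composition.items()) for _ in range(cnt)]
        rng.shuffle(layout)
    else:
        layout = list(species_layout)
        from collections import Counter

        if Counter(layout) != Counter(
            {sp: cnt for sp, cnt in composition.items() if cnt > 0}
        ):
            raise ValidationError("species_layout inconsistent with composition")

    n_mol = len(layout)
    max_beads = max((len(templates[sp].bead_types) for sp in set(layout)), default=1)
    span = (max_beads - 1) * max(
        (templates[sp].bond_r0 for sp in set(layout)), default=1.0
    )
    sites = _molecule_sites(n_mol, box, span, grid=grid)

    pos_rows: list[np.ndarray] = []
    type_rows: list[int] = []
    charge_rows: list[float] = []
    mol_rows: list[int] = []
    topologies: list[MoleculeTopology] = []
    idx = 0
    for m, sp in enumerate(layout):
        tmpl = templates[sp]
        nb = len(tmpl.bead_types)
        indices = np.arange(idx, idx + nb)
        for b in range(nb):
            p = sites[m].copy()
            p[1] += b * tmpl.bond_r0
            pos_rows.append(p)
            type_rows.append(tmpl.bead_types[b])
            charge_rows.append(tmpl.charges[b])
            mol_rows.append(m)
        bonds = [
            (int(indices[b]), int(indices[b + 1]), tmpl.bond_k, tmpl.bond_r0)
            for b in range(nb - 1)
        ]
        angles = [
            (int(indices[b]), int(indices[b + 1]), int(indices[b + 2]), tmpl.angle_k, tmpl.angle_theta0)
            for b in range(nb - 2)
        ]
        topologies.append(MoleculeTopology(sp, indices, bonds, angles))
        idx += nb

    positions = np.asarray(pos_rows, dtype=np.float64).reshape(-1, box.dim)
    charges = np.asarray(charge_rows, dtype=np.float64)
    types = np.asarray(type_rows, dtype=np.int64)
    mol_ids = np.asarray(mol_rows, dtype=np.int64)

    # counterions: neutralize total molecular charge with monovalent ions
    net = charges.sum() if charges.size else 0.0
    if counterion_type is not None and abs(net) > 1e-12:
        n_ions_f = -net / counterion_charge
        n_ions = int(round(n_ions_f))
        if n_ions < 0 or abs(n_ions - n_ions_f) > 1e-9:
            raise ValidationError(
                f"cannot neutralize charge {net:+.3f} with ions of charge "
                f"{counterion_charge:+.2f}"
            )
        ion_pos = _place_ions(positions, box, n_ions, rng, min_separation)
        positions = np.vstack([positions, ion_pos]) if positions.size else ion_pos
        types = np.concatenate([types, np.full(n_ions, counterion_type, dtype=np.int64)])
        charges = np.concatenate([charges, np.full(n_ions, counterion_charge)])
        mol_ids = np.concatenate([mol_ids, np.arange(n_mol, n_mol + n_ions)])

    n = positions.shape[0] if positions.ndim == 2 else 0
    positions = box.wrap(positions.reshape(n, box.dim))
    masses = np.ones(n)
    if kT is not None:
        velocities = maxwell_velocities(n, box.dim, masses, kT, rng)
    else:
        velocities = np.zeros((n, box.dim))

    system = ParticleSystem(
        positions, velocities, masses, types, charges, mol_ids, box,
        pair_table.labels,
    )
    system.validate()
    _check_separation(system, topologies, min_separation)
    return system, topologies


def _place_ions(
    positions: np.ndarray,
    box: SimulationBox,
    n_ions: int,
    rng: np.random.Generator,
    min_separation: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Uniform random ion positions, rejection-sampled away from other beads."""
    placed: list[np.ndarray] = []
    existing = positions.reshape(-1, box.dim)
    for _ in range(n_ions):
        for attempt in range(max_tries):
            cand = rng.random(box.dim) * box.lengths
            pool = existing if not placed else np.vstack([existing, np.asarray(placed)])
            if pool.size:
                dr = box.min_image(pool - cand[None, :])
                if np.min(np.sum(dr * dr, axis=1)) < min_separation**2:
                    continue
            placed.append(cand)
            break
        else:
            density = (existing.shape[0] + len(placed)) / box.volume
            raise PlacementError(
                f"could not place ion {len(placed) + 1}/{n_ions}: "
                f"bead density {density:.3f}/sigma^d too high"
            )
    return np.asarray(placed).reshape(n_ions, box.dim)


def _check_separation(
    system: ParticleSystem, topologies: list[MoleculeTopology], min_separation: float
) -> None:
    """Reject builds with non-bonded overlaps below ``min_separation``."""
    n = system.n
    if n < 2:
        return
    dr = system.positions[:, None, :] - system.positions[None, :, :]
    dr = system.box.min_image(dr)
    d2 = np.sum(dr * dr, axis=-1)
    same_mol = system.molecule_id[:, None] == system.molecule_id[None, :]
    d2[same_mol] = np.inf
    np.fill_diagonal(d2, np.inf)
    dmin = math.sqrt(float(d2.min()))
    if dmin < min_separation:
        density = n / system.box.volume
        raise PlacementError(
            f"overcrowded box: minimum inter-molecular separation {dmin:.3f} "
            f"< {min_separation} sigma at density {density:.3f}/sigma^d"
        )
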