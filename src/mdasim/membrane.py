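"""Toy binary lipid membrane: a Martini-like 2D monolayer of two 3-bead
lipid species that differ only in their head bead.

Species A carries a neutral P-type-like head ("HA"); species B a
unit-negative Q-type-like head ("HB"); both share the same 2-bead tail
("T").  Each charged lipid is neutralized by one explicit monovalent
counterion ("I").  There is no explicit solvent: the Langevin friction of
the thermostat plays the role of the solvent bath.

Parameter conventions (documented Martini-flavoured presets in reduced
units, sigma = 0.47 nm, epsilon = 3.5 kJ/mol):

* vdW cutoff 2.34 sigma  (1.1 nm), potential shifted at the cutoff;
* reaction-field electrostatics, screening constant 15, same cutoff;
* Coulomb prefactor 84.4 = 138.935 kJ mol^-1 nm e^-2 / (0.47 nm x 3.5 kJ/mol);
* kT = 0.80 (335 K);
* soft-core delta preset 22.6 sigma^2  (5.0 nm^2).

Unlike-head contacts are made slightly favorable (epsilon 1.25 vs 1.0) so
the uniformly mixed state is the equilibrium the demixed start must relax
to; mixing by plain MD is then diffusion-limited while identity exchanges
short-circuit it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel, EvalCounter
from .model import (
    ElectrostaticsParams,
    MoleculeTemplate,
    MoleculeTopology,
    PairTable,
    ParticleSystem,
    SimulationBox,
    ValidationError,
    _molecule_sites,
    build_system,
    maxwell_velocities,
)

__all__ = [
    "BEAD_LABELS",
    "HEAD_A", "HEAD_B", "TAIL", "ION",
    "MembranePreset",
    "interaction_tables",
    "lipid_templates",
    "default_box",
    "plan_grid",
    "build_demixed_membrane",
    "build_mixed_reference",
    "relax_overlaps",
    "minimum_separation",
]

BEAD_LABELS: tuple[str, ...] = ("HA", "HB", "T", "I")
HEAD_A, HEAD_B, TAIL, ION = 0, 1, 2, 3

#: reduced-unit conversions of the Martini-flavoured SI presets
CUTOFF = 1.1 / 0.47            # 2.34 sigma
COULOMB_PREFACTOR = 138.935 / (0.47 * 3.5)  # 84.4
SOFTCORE_DELTA = 5.0 / 0.47**2  # 22.6 sigma^2
KT_DEFAULT = 0.80              # 335 K at epsilon = 3.5 kJ/mol


@dataclass
class MembranePreset:
    """Composition and interaction parameterization of the toy membrane."""

    n_a: int = 50
    n_b: int = 50
    beads_per_lipid: int = 3
    head_b_charge: float = -0.5
    counterion_charge: float = 0.5
    kT: float = KT_DEFAULT
    epsilon_like_heads: float = 1.0
    epsilon_unlike_heads: float = 1.25
    epsilon_tail: float = 1.0
    epsilon_head_tail: float = 0.85
    epsilon_ion: float = 0.75
    # the charged head is slightly bulkier: an instantaneous identity swap
    # grows a bead inside a compressed neighbor cage (steric work), which a
    # gradual alchemical trajectory relaxes away
    sigma_head_b: float = 1.1
    cutoff: float = CUTOFF
    dielectric_screening: float = 15.0
    rf_dielectric: float = float("inf")
    coulomb_prefactor: float = COULOMB_PREFACTOR
    bond_k: float = 79.0
    bond_r0: float = 1.0
    angle_k: float = 7.0
    angle_theta0: float = math.pi
    lattice_dx: float = 1.9
    lattice_dy: float = 3.6

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValidationError("molecule counts must be >= 0")
        if self.beads_per_lipid != 3:
            raise ValidationError("the toy lipid is head + 2 tail beads")


def interaction_tables(preset: MembranePreset) -> tuple[PairTable, ElectrostaticsParams]:
    """LJ matrix over (HA, HB, T, I) and the reaction-field parameters."""
    e = np.empty((4, 4))
    e[:] = preset.epsilon_ion  # ion rows/columns default
    e[HEAD_A, HEAD_A] = e[HEAD_B, HEAD_B] = preset.epsilon_like_heads
    e[HEAD_A, HEAD_B] = e[HEAD_B, HEAD_A] = preset.epsilon_unlike_heads
    e[TAIL, TAIL] = preset.epsilon_tail
    for h in (HEAD_A, HEAD_B):
        e[h, TAIL] = e[TAIL, h] = preset.epsilon_head_tail
    radii = np.ones(4)
    radii[HEAD_B] = preset.sigma_head_b
    sig = 0.5 * (radii[:, None] + radii[None, :])  # Lorentz combination
    table = PairTable(e, sig, cutoff=preset.cutoff, shift_at_cutoff=True,
                      labels=BEAD_LABELS)
    elec = ElectrostaticsParams(
        dielectric_screening=preset.dielectric_screening,
        rf_dielectric=preset.rf_dielectric,
        cutoff=preset.cutoff,
        coulomb_prefactor=preset.coulomb_prefactor,
    )
    return table, elec


def lipid_templates(preset: MembranePreset) -> dict[str, MoleculeTemplate]:
    common = dict(
        bond_k=preset.bond_k, bond_r0=preset.bond_r0,
        angle_k=preset.angle_k, angle_theta0=preset.angle_theta0,
    )
    return {
        "A": MoleculeTemplate("A", (HEAD_A, TAIL, TAIL), (0.0, 0.0, 0.0), **common),
        "B": MoleculeTemplate(
            "B", (HEAD_B, TAIL, TAIL), (preset.head_b_charge, 0.0, 0.0), **common
        ),
    }


def plan_grid(preset: MembranePreset) -> tuple[int, int]:
    """Molecule grid (n_cols, n_rows) with every column filled completely.

    A divisor of the molecule count closest to the square-ish ideal is
    preferred, so that half-box species assignments split exactly between
    columns; awkward counts fall back to a ragged grid.
    """
    n = preset.n_a + preset.n_b
    if n == 0:
        return (1, 1)
    ideal = math.sqrt(n * preset.lattice_dy / preset.lattice_dx)
    divisors = [d for d in range(1, n + 1) if n % d == 0]
    good = [d for d in divisors if 0.4 * ideal <= d <= 2.5 * ideal]
    if good:
        n_cols = min(good, key=lambda d: abs(d - ideal))
    else:
        n_cols = max(1, int(round(ideal)))
    n_rows = int(math.ceil(n / n_cols))
    return (n_cols, n_rows)


def default_box(preset: MembranePreset) -> SimulationBox:
    """Box sized from the planned grid and the preset lattice spacings."""
    n_cols, n_rows = plan_grid(preset)
    return SimulationBox([n_cols * preset.lattice_dx, n_rows * preset.lattice_dy])


def _build(
    preset: MembranePreset,
    box: SimulationBox | None,
    seed,
    layout_fn,
    relax: bool,
) -> tuple[ParticleSystem, list[MoleculeTopology]]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = plan_grid(preset) if box is None else None
    box = box if box is not None else default_box(preset)
    table, elec = interaction_tables(preset)
    templates = lipid_templates(preset)
    n = preset.n_a + preset.n_b
    span = (preset.beads_per_lipid - 1) * preset.bond_r0
    sites = _molecule_sites(n, box, span, grid=grid)
    layout = layout_fn(sites, box, rng)
    system, topologies = build_system(
        {"A": preset.n_a, "B": preset.n_b},
        templates, box, table, elec, rng,
        species_layout=layout,
        counterion_type=ION,
        counterion_charge=preset.counterion_charge,
        kT=None,
        grid=grid,
    )
    if relax:
        relax_overlaps(system, topologies, table, elec)
    system.velocities = maxwell_velocities(
        system.n, system.dim, system.masses, preset.kT, rng
    )
    return system, topologies


def build_demixed_membrane(
    preset: MembranePreset,
    box: SimulationBox | None = None,
    seed=0,
    relax: bool = True,
) -> tuple[ParticleSystem, list[MoleculeTopology]]:
    """Phase-separated start: species A occupies the low-x half of the box,
    species B the high-x half — far from the mixed equilibrium."""

    def layout(sites, box, rng):
        order = np.lexsort((sites[:, 1], sites[:, 0]))  # by x, then y
        out = [""] * len(sites)
        for rank, site in enumerate(order):
            out[site] = "A" if rank < preset.n_a else "B"
        return out

    return _build(preset, box, seed, layout, relax)


def build_mixed_reference(
    preset: MembranePreset,
    box: SimulationBox | None = None,
    seed=0,
    relax: bool = True,
) -> tuple[ParticleSystem, list[MoleculeTopology]]:
    """Equilibrium-like reference: species assigned to lattice sites by a
    uniform random permutation."""

    def layout(sites, box, rng):
        labels = np.array(["A"] * preset.n_a + ["B"] * preset.n_b)
        rng.shuffle(labels)
        return labels.tolist()

    return _build(preset, box, seed, layout, relax)


def relax_overlaps(
    system: ParticleSystem,
    topologies: list[MoleculeTopology],
    pair_table: PairTable,
    electrostatics: ElectrostaticsParams,
    n_steps: int = 200,
    max_disp: float = 0.05,
) -> None:
    """Short steepest-descent burst (displacement-capped) removing any
    residual build overlaps; does not touch velocities."""
    model = EnergyModel(pair_table, electrostatics, topologies, counter=EvalCounter())
    for _ in range(n_steps):
        _, f = model.evaluate(system, count=True)
        fmax = float(np.abs(f).max()) if f.size else 0.0
        if fmax < 1.0:
            break
        step = f * (max_disp / fmax)
        system.positions += step
        system.wrap()


def minimum_separation(system: ParticleSystem) -> float:
    """Smallest inter-molecular bead distance (diagnostic for build quality)."""
    if system.n < 2:
        return float("inf")
    dr = system.positions[:, None, :] - system.positions[None, :, :]
    dr = system.box.min_image(dr)
    d2 = np.sum(dr * dr, axis=-1)
    same = system.molecule_id[:, None] == system.molecule_id[None, :]
    d2[same] = np.inf
    return float(np.sqrt(d2.min()))
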