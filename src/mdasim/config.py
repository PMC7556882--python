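"""Run configuration: a flat key = value text format, validated at load time.

Every key maps onto a module parameter (composition, interactions,
thermostat, sampler schedule, alchemical schedule, analysis defaults).
Unknown keys and constraint violations are rejected with the offending key
named.  ``build_components`` materializes the validated domain objects and
the named RNG streams derived from the single root seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from .energy import EvalCounter
from .membrane import (
    HEAD_A,
    HEAD_B,
    MembranePreset,
    SOFTCORE_DELTA,
    build_demixed_membrane,
    build_mixed_reference,
    interaction_tables,
)
from .model import (
    AlchemicalSpec,
    ElectrostaticsParams,
    HeadEndpoint,
    PairTable,
    SamplerSchedule,
    ThermostatSpec,
    ValidationError,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "build_components"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


@dataclass
class RunConfig:
    """Flat, fully-defaulted run configuration."""

    # composition / initial state
    n_lipids_a: int = 50
    n_lipids_b: int = 50
    initial_state: str = "demixed"  # demixed | mixed
    # interactions
    temperature: float = 0.80
    epsilon_unlike_heads: float = 1.25
    head_b_charge: float = -0.5
    cutoff: float = 1.1 / 0.47
    dielectric_screening: float = 15.0
    rf_dielectric: float = float("inf")
    coulomb_prefactor: float = 138.935 / (0.47 * 3.5)
    # thermostat (Langevin friction time 1/gamma; the implicit solvent is
    # chosen viscous so lateral mixing by diffusion is slow)
    thermostat: str = "langevin"
    thermostat_coupling: float = 0.1
    # sampler schedule
    mode: str = "mdas"  # md | mcmd | mdas
    md_segment_steps: int = 2000
    n_attempts: int = 10
    dt: float = 0.005
    seed: int = 0
    # plain-MD equilibration before production; its force evaluations are
    # not part of the production accounting (counter starts at production)
    equilibration_steps: int = 0
    # alchemical schedule (reference schedule: 1000-step AT, lambda moved
    # every 10 steps -> 9 plateau steps per 0.01 window)
    delta_lambda: float = 0.01
    plateau_steps: int = 9
    softcore_delta: float = SOFTCORE_DELTA
    vdw_coupling: str = "linear"
    # analysis defaults
    rdf_bin_width: float = 0.05
    rdf_r_min_exclusion: float = 0.5
    frames_per_point: int = 10


_FIELDS = {f.name: f for f in fields(RunConfig)}


def _coerce(key: str, raw: str):
    f = _FIELDS[key]
    tname = f.type if isinstance(f.type, str) else f.type.__name__
    try:
        if tname == "int":
            return int(raw)
        if tname == "float":
            return float(raw)
        return raw
    except ValueError as exc:
        raise ConfigError(f"key {key!r}: cannot parse {raw!r} as {tname}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a flat ``key = value`` config file."""
    path = Path(path)
    values: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in stripped.split("=", 1))
        if key not in _FIELDS:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        if key in values:
            raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
        values[key] = _coerce(key, raw)
    config = RunConfig(**values)
    validate_config(config)
    return config


def save_config(config: RunConfig, path) -> None:
    """Write the effective configuration as a flat key = value file."""
    lines = [
        f"{f.name} = {getattr(config, f.name)}"
        for f in fields(RunConfig)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def validate_config(config: RunConfig) -> None:
    """Check every parameter against the module preconditions it feeds."""
    try:
        build_components(config)
    except (ValidationError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    if config.initial_state not in ("demixed", "mixed"):
        raise ConfigError(f"key 'initial_state': unknown value {config.initial_state!r}")
    for key in ("rdf_bin_width", "rdf_r_min_exclusion"):
        if getattr(config, key) <= 0:
            raise ConfigError(f"key {key!r}: must be > 0")
    if config.frames_per_point < 1:
        raise ConfigError("key 'frames_per_point': must be >= 1")


@dataclass
class Components:
    """Validated domain objects materialized from a :class:`RunConfig`."""

    config: RunConfig
    preset: MembranePreset
    pair_table: PairTable
    electrostatics: ElectrostaticsParams
    thermostat: ThermostatSpec
    schedule: SamplerSchedule
    alchemical: AlchemicalSpec
    counter: EvalCounter
    streams: tuple  # (dynamics, pairs, accept, build) generators

    def build_initial(self, rng: np.random.Generator):
        builder = (
            build_demixed_membrane
            if self.config.initial_state == "demixed"
            else build_mixed_reference
        )
        return builder(self.preset, seed=rng)


def build_components(config: RunConfig) -> Components:
    preset = MembranePreset(
        n_a=config.n_lipids_a,
        n_b=config.n_lipids_b,
        head_b_charge=config.head_b_charge,
        kT=config.temperature,
        epsilon_unlike_heads=config.epsilon_unlike_heads,
        cutoff=config.cutoff,
        dielectric_screening=config.dielectric_screening,
        rf_dielectric=config.rf_dielectric,
        coulomb_prefactor=config.coulomb_prefactor,
    )
    pair_table, electrostatics = interaction_tables(preset)
    thermostat = ThermostatSpec(
        temperature=config.temperature,
        scheme=config.thermostat,
        coupling=config.thermostat_coupling,
    )
    schedule = SamplerSchedule(
        mode=config.mode,
        md_segment_steps=config.md_segment_steps,
        n_attempts=config.n_attempts,
        dt=config.dt,
        seed=config.seed,
    )
    alchemical = AlchemicalSpec(
        HeadEndpoint(HEAD_A, 0.0),
        HeadEndpoint(HEAD_B, config.head_b_charge),
        delta_lambda=config.delta_lambda,
        plateau_steps=config.plateau_steps,
        softcore_delta=config.softcore_delta,
        vdw_coupling=config.vdw_coupling,
    )
    ss = np.random.SeedSequence(config.seed)
    streams = tuple(np.random.default_rng(s) for s in ss.spawn(4))
    return Components(
        config, preset, pair_table, electrostatics, thermostat, schedule,
        alchemical, EvalCounter(), streams,
    )
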