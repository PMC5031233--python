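"""Harmonic normal-mode conformational sampling.

Conformers are generated by evolving every vibrational mode as an
independent harmonic oscillator.  The total thermal energy
E = N_vib * k_B * T / 2 is stochastically distributed over the modes (flat
Dirichlet on the energy simplex), each mode receives a uniform random phase,
and each mode's amplitude follows from E_i = k_i A_i^2 / 2 in mass-weighted
coordinates (k_i = lambda_i).

Each mode advances by 1/ncycle of its own period per emitted sample, so the
phase argument at block step s is 2*pi*s/ncycle + phi_i for every mode:
a single oscillation is sampled uniformly and never biased toward turning
points.  Every nreset emitted samples, the mode energies and phases are
redrawn (energies first, then phases).
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import constants
from .chem_io import LabeledGeometry
from .normal_modes import NormalModeSet

__all__ = [
    "SamplerConfig",
    "ModeState",
    "total_energy",
    "distribute_energy",
    "amplitudes",
    "assign_phases",
    "generate",
    "generate_multi",
]


@dataclasses.dataclass
class SamplerConfig:
    temperature_K: float = 300.0
    ncycle: int = 10
    nreset: int = 2
    n_samples: int = 2000
    seed: int = 0
    coherent: bool = False  # all-zero phases (single-frequency excitation)

    def __post_init__(self):
        if self.ncycle < 2:
            raise ValueError("ncycle must be at least 2")
        if self.nreset < 1:
            raise ValueError("nreset must be at least 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if self.temperature_K < 0:
            raise ValueError("temperature must be non-negative")


@dataclasses.dataclass
class ModeState:
    """Current per-mode energies, phases and mass-weighted amplitudes."""

    energies: np.ndarray    # hartree
    phases: np.ndarray      # radians, [0, 2*pi)
    amplitudes: np.ndarray  # bohr * sqrt(m_e)


def total_energy(n_vib: int, temperature_K: float) -> float:
    """Thermal energy E = N_vib * k_B * T / 2 in hartree."""
    if temperature_K < 0:
        raise ValueError("temperature must be non-negative")
    return n_vib * constants.BOLTZMANN_HARTREE_PER_K * temperature_K / 2.0


def distribute_energy(e_total: float, n_vib: int, rng: np.random.Generator) -> np.ndarray:
    """Split e_total over n_vib modes, uniformly on the simplex."""
    if e_total < 0:
        raise ValueError("total energy must be non-negative")
    if n_vib == 1:
        return np.array([e_total])
    w = rng.dirichlet(np.ones(n_vib))
    e = w * e_total
    # exact conservation after rounding
    e *= e_total / e.sum() if e.sum() > 0 else 1.0
    return e


def amplitudes(energies: np.ndarray, force_constants: np.ndarray) -> np.ndarray:
    """A_i = sqrt(2 E_i / k_i) (mass-weighted units when k_i = lambda_i)."""
    k = np.asarray(force_constants, dtype=float)
    if np.any(k <= 0):
        raise ValueError("force constants must be positive")
    return np.sqrt(2.0 * np.asarray(energies, dtype=float) / k)


def assign_phases(n_vib: int, rng: np.random.Generator, coherent: bool = False) -> np.ndarray:
    """I.i.d. uniform phases on [0, 2*pi); all zero in coherent mode."""
    if coherent:
        return np.zeros(n_vib)
    return rng.uniform(0.0, 2.0 * np.pi, size=n_vib)


def generate(
    geom: LabeledGeometry,
    modes: NormalModeSet,
    cfg: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> list[LabeledGeometry]:
    """Emit cfg.n_samples distorted conformers around one minimum.

    Deterministic given cfg.seed (or an explicitly supplied generator, used
    by generate_multi to chain ensembles).
    """
    if np.any(modes.eigenvalues <= 0):
        raise ValueError("sampling requires a minimum: all eigenvalues positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_vib = modes.n_vib
    e_total = total_energy(n_vib, cfg.temperature_K)
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(geom.masses, 3))
    samples: list[LabeledGeometry] = []
    state = None
    step_in_block = 0
    for s in range(cfg.n_samples):
        if s % cfg.nreset == 0:
            energies = distribute_energy(e_total, n_vib, rng)
            phases = assign_phases(n_vib, rng, cfg.coherent)
            amps = amplitudes(energies, modes.eigenvalues)
            state = ModeState(energies, phases, amps)
            step_in_block = 0
        step_in_block += 1
        arg = 2.0 * np.pi * step_in_block / cfg.ncycle + state.phases
        s_internal = state.amplitudes * np.sin(arg)
        dq = modes.eigenvectors @ s_internal       # mass-weighted Cartesian
        dx = (dq * inv_sqrt_m).reshape(-1, 3)      # Cartesian, bohr
        samples.append(
            geom.with_coords(
                geom.coords + dx,
                comment=f"sample {s} seed {cfg.seed} T {cfg.temperature_K} "
                f"ncycle {cfg.ncycle} nreset {cfg.nreset}",
            )
        )
    return samples


def generate_multi(
    seeds: Sequence[tuple[LabeledGeometry, NormalModeSet]],
    cfg: SamplerConfig,
) -> list[LabeledGeometry]:
    """Concatenated ensembles from several seed minima.

    cfg.n_samples is the total count, split as evenly as possible over the
    seed geometries (earlier seeds absorb the remainder).
    """
    n_seeds = len(seeds)
    if n_seeds == 0:
        raise ValueError("need at least one seed minimum")
    base, rem = divmod(cfg.n_samples, n_seeds)
    out: list[LabeledGeometry] = []
    for i, (geom, modes) in enumerate(seeds):
        count = base + (1 if i < rem else 0)
        if count == 0:
            continue
        sub = dataclasses.replace(cfg, n_samples=count, seed=cfg.seed + i)
        out.extend(generate(geom, modes, sub))
    return out
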