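"""Metropolis Monte Carlo sampling of partially connected systems.

Single-molecule moves only: whole-molecule translations, rigid-body rotations
(proposed symmetrically under inversion, preserving detailed balance), and
single-site displacements for flexible molecules.  An optional harmonic bias
on the collective variable implements umbrella restraints.  Step sizes adapt
toward a 40% acceptance rate during equilibration and are frozen for
production, so the production chain satisfies detailed balance with respect
to exp(-beta (V + V_bias)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import (
    Configuration,
    EnergyModel,
    SystemSpec,
    small_rotation_matrix,
    system_digest,
)

__all__ = [
    "MoveSet",
    "BiasSpec",
    "SampleSet",
    "ProtocolError",
    "metropolis_accept",
    "metropolis_step",
    "run_sampling",
]


class ProtocolError(RuntimeError):
    """Sampling protocol produced no usable samples."""


@dataclass
class MoveSet:
    """Move amplitudes and per-species selection weights."""

    max_translation: float = 0.3
    max_rotation: float = 0.5  # radians, rigid molecules
    species_weights: Mapping[str, float] | None = None  # default: all 1

    def __post_init__(self) -> None:
        if self.max_translation <= 0:
            raise ValueError("max_translation must be > 0")
        if self.species_weights is not None:
            w = list(self.species_weights.values())
            if any(x < 0 for x in w):
                raise ValueError("species weights must be nonnegative")
            if all(x == 0 for x in w):
                raise ValueError("at least one species weight must be positive")


@dataclass(frozen=True)
class BiasSpec:
    """Restraint on the CV: none, or harmonic 0.5*k_umb*(s - r0)^2."""

    kind: str = "none"  # "none" | "harmonic"
    k_umb: float = 0.0
    r0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "harmonic"):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.kind == "harmonic" and self.k_umb <= 0:
            raise ValueError("harmonic bias requires k_umb > 0")

    def energy(self, cv: float) -> float:
        if self.kind == "none":
            return 0.0
        return 0.5 * self.k_umb * (cv - self.r0) ** 2


@dataclass
class SampleSet:
    """Seed-stamped CV/energy samples from one MC run."""

    cv_samples: np.ndarray
    energy_samples: np.ndarray
    bias_energy_samples: np.ndarray
    bias: BiasSpec
    n_steps: int
    n_equil: int
    sample_stride: int
    seed: int
    acceptance_rate: float
    temperature: float
    dimension: int
    system_digest: str

    def __post_init__(self) -> None:
        if not (
            len(self.cv_samples) == len(self.energy_samples) == len(self.bias_energy_samples)
        ):
            raise ValueError("sample sequences must have equal lengths")
        if not (0.0 <= self.acceptance_rate <= 1.0):
            raise ValueError("acceptance_rate outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.cv_samples)


def metropolis_accept(delta: float, beta: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-beta*delta))."""
    if not math.isfinite(delta):
        return delta < 0  # +inf -> reject, -inf -> accept
    if delta <= 0:
        return True
    return rng.random() < math.exp(-beta * delta)


class _MCState:
    """Mutable sampling state bound to one EnergyModel."""

    def __init__(
        self,
        model: EnergyModel,
        pos: np.ndarray,
        moves: MoveSet,
        bias: BiasSpec,
        rng: np.random.Generator,
    ):
        self.model = model
        self.pos = pos.copy()
        self.moves = moves
        self.bias = bias
        self.rng = rng
        self.energy = model.total_energy(self.pos)
        self.cv = model.cv_value(self.pos) if model.sys.cv is not None else 0.0
        # per-species step sizes: species see very different landscapes (a
        # biased solute must not inherit the step scale of a free solvent)
        ns = len(model.species_labels)
        self.step_trans = np.full(ns, moves.max_translation)
        self.step_rot = np.full(ns, moves.max_rotation)

        weights = np.ones(model.n_molecules)
        if moves.species_weights is not None:
            for m in range(model.n_molecules):
                label = model.species_labels[model.mol_species[m]]
                weights[m] = moves.species_weights.get(label, 1.0)
        if weights.sum() == 0:
            raise ValueError("all molecules have zero move weight")
        self._mol_cdf = np.cumsum(weights / weights.sum())
        cv = model.sys.cv
        self._cv_species = set()
        self._coms: dict[str, np.ndarray] = {}
        self._cv_nsites: dict[str, int] = {}
        if cv is not None:
            self._cv_species = {cv.species_a, cv.species_b}
            self._cv_other = {cv.species_a: cv.species_b, cv.species_b: cv.species_a}
            for lab in self._cv_species:
                self._coms[lab] = model.species_com(self.pos, lab)
                self._cv_nsites[lab] = model.species_site_index[lab].size
        # acceptance bookkeeping per (species, move kind) for adaptation
        self._acc = {(s, k): [0, 0] for s in range(ns) for k in ("t", "r")}

    def _pick_molecule(self) -> int:
        return int(np.searchsorted(self._mol_cdf, self.rng.random()))

    def step(self, adapt: bool = False) -> bool:
        model = self.model
        mol = self._pick_molecule()
        idx = model.mol_sites[mol]
        tpl_rigid = model.mol_rigid[mol]
        multi = idx.size > 1
        kind = "t"
        if multi and self.rng.random() < 0.5:
            kind = "r" if tpl_rigid else "s"

        spec_idx = model.mol_species[mol]
        species_label = model.species_labels[spec_idx]
        in_cv = species_label in self._cv_species
        com_shift = None  # COM displacement of the CV species, if any
        step_t = self.step_trans[spec_idx]

        old_rows = self.pos[idx].copy()
        if kind == "t":
            disp = self.rng.uniform(-step_t, step_t, size=model.dim)
            e_old = model.mol_env_energy(self.pos, mol)
            self.pos[idx] = old_rows + disp
            e_new = model.mol_env_energy(self.pos, mol)
            if in_cv:
                com_shift = disp * (idx.size / self._cv_nsites[species_label])
        elif kind == "r":
            # rotation about the molecule centroid: species COM shifts only if
            # the species has other molecules (not the case for CV solutes)
            rot = small_rotation_matrix(model.dim, self.step_rot[spec_idx], self.rng)
            com = old_rows.mean(axis=0)
            e_old = model.mol_env_energy(self.pos, mol)
            self.pos[idx] = com + (old_rows - com) @ rot.T
            e_new = model.mol_env_energy(self.pos, mol)
            if in_cv:
                com_shift = np.zeros(model.dim)
        else:  # flexible single-site displacement
            site = int(idx[self.rng.integers(idx.size)])
            disp = self.rng.uniform(-step_t, step_t, size=model.dim)
            e_old = model.site_env_energy(self.pos, site)
            if model.bonds_i.size:
                e_old += model._bond_energy(self.pos, model._site_bond_mask[site])
            self.pos[site] = self.pos[site] + disp
            e_new = model.site_env_energy(self.pos, site)
            if model.bonds_i.size:
                e_new += model._bond_energy(self.pos, model._site_bond_mask[site])
            if in_cv:
                com_shift = disp / self._cv_nsites[species_label]

        d_pot = e_new - e_old
        cv_new = self.cv
        d_bias = 0.0
        new_com = None
        if in_cv:
            if model.sys.cv.kind == "com_distance":
                new_com = self._coms[species_label] + com_shift
                d = new_com - self._coms[self._cv_other[species_label]]
                d = model.displacement(d)
                cv_new = float(np.sqrt(d @ d))
            else:
                cv_new = model.cv_value(self.pos)
            d_bias = self.bias.energy(cv_new) - self.bias.energy(self.cv)

        accepted = metropolis_accept(d_pot + d_bias, model.beta, self.rng)
        if accepted:
            self.energy += d_pot
            self.cv = cv_new
            if in_cv and new_com is not None:
                self._coms[species_label] = new_com
        else:
            self.pos[idx] = old_rows

        if adapt:
            key = (spec_idx, "r" if kind == "r" else "t")
            rec = self._acc[key]
            rec[0] += int(accepted)
            rec[1] += 1
            if rec[1] >= 100:
                rate = rec[0] / rec[1]
                factor = 1.15 if rate > 0.4 else 0.87
                if key[1] == "t":
                    self.step_trans[spec_idx] = float(
                        np.clip(self.step_trans[spec_idx] * factor, 1e-3, 0.5 * self.model.box)
                    )
                else:
                    self.step_rot[spec_idx] = float(
                        np.clip(self.step_rot[spec_idx] * factor, 1e-3, np.pi)
                    )
                rec[0] = rec[1] = 0
        return accepted

    def resync(self) -> None:
        self.energy = self.model.total_energy(self.pos)
        if self.model.sys.cv is not None:
            for lab in self._cv_species:
                self._coms[lab] = self.model.species_com(self.pos, lab)
            self.cv = self.model.cv_value(self.pos)


def metropolis_step(
    cfg: Configuration,
    sys: SystemSpec,
    moves: MoveSet,
    bias: BiasSpec,
    rng: np.random.Generator,
) -> tuple[Configuration, bool]:
    """One Metropolis step on a Configuration (convenience wrapper).

    Builds the energy model on every call; use :func:`run_sampling` for runs.
    """
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        state = _MCState(EnergyModel(sys), cfg.positions, moves, bias, rng)
        accepted = state.step()
    return Configuration(state.pos), accepted


def run_sampling(
    sys: SystemSpec,
    moves: MoveSet,
    bias: BiasSpec,
    n_steps: int,
    n_equil: int,
    sample_stride: int,
    seed: int,
    initial: Configuration | None = None,
    resync_every: int = 4000,
) -> SampleSet:
    """Run one MC chain and record CV/energy every ``sample_stride`` steps.

    ``n_steps`` is the total step count; the first ``n_equil`` steps are
    discarded (and used for step-size adaptation toward 40% acceptance).
    Bitwise reproducible for a given seed and initial configuration.
    """
    if not (n_steps > n_equil >= 0):
        raise ValueError("need n_steps > n_equil >= 0")
    if sample_stride < 1:
        raise ValueError("sample_stride must be >= 1")
    from .model import build_initial  # local to avoid import noise at module load

    model = EnergyModel(sys)
    rng = np.random.default_rng(seed)
    if initial is None:
        cv_target = bias.r0 if bias.kind == "harmonic" else None
        initial = build_initial(sys, seed, cv_target=cv_target)

    cv_out, e_out, b_out = [], [], []
    n_acc_prod = 0
    n_prod = 0
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        state = _MCState(model, initial.positions, moves, bias, rng)
        for step in range(1, n_steps + 1):
            in_equil = step <= n_equil
            acc = state.step(adapt=in_equil)
            if step % resync_every == 0:
                state.resync()
            if not in_equil:
                n_prod += 1
                n_acc_prod += int(acc)
                if (step - n_equil) % sample_stride == 0:
                    cv_out.append(state.cv)
                    e_out.append(state.energy)
                    b_out.append(bias.energy(state.cv))
    if not cv_out:
        raise ProtocolError("no samples recorded: check n_steps/n_equil/sample_stride")

    return SampleSet(
        cv_samples=np.asarray(cv_out),
        energy_samples=np.asarray(e_out),
        bias_energy_samples=np.asarray(b_out),
        bias=bias,
        n_steps=n_steps,
        n_equil=n_equil,
        sample_stride=sample_stride,
        seed=seed,
        acceptance_rate=n_acc_prod / max(1, n_prod),
        temperature=sys.temperature,
        dimension=sys.dimension,
        system_digest=system_digest(sys),
    )
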