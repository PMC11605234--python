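"""Canonical self-contained test systems.

Every test and validation run in this package is generated here, from five
named fixtures:

* ``sph2d``      — two spherical LJ solutes in a 2D periodic LJ solvent at
                   reduced density 0.4, kT = 1 (the spherical-solute
                   reduction checks).
* ``dumbbell3d`` — two rigid two-site LJ dumbbells (bond 0.5 sigma) in a 3D
                   LJ solvent at density 0.3 (the rigid-solute equivalence
                   check).
* ``flexdimer2d``— two flexible two-site solutes (harmonic bond) in the 2D
                   solvent (conformational component is nonzero here).
* ``tiny1d``     — 1D micro-system (two solutes + <=2 solvent particles),
                   oracle-tractable by dense quadrature.
* ``tiny2d``     — 2D micro-system, likewise.

Densities, temperatures and cutoffs are the fixture's fixed study
conditions; boxes are sized from the solvent count at fixed density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import Protocol, scheme_system
from .model import Bond, CVSpec, MoleculeTemplate, SiteType, Species, SystemSpec
from .oracle import TinySystem

__all__ = ["FixtureSpec", "FIXTURE_NAMES", "make_fixture", "LJ"]

FIXTURE_NAMES = ("sph2d", "dumbbell3d", "flexdimer2d", "tiny1d", "tiny2d")

LJ = SiteType(name="LJ", lj_epsilon=1.0, lj_sigma=1.0)


@dataclass
class FixtureSpec:
    """One canonical system: solutes, solvent, box, and a default protocol."""

    name: str
    solute_a: Species
    solute_b: Species
    solvent: Species | None
    box_length: float
    temperature: float
    cutoff: float
    dimension: int
    periodic: bool
    protocol: Protocol
    tiny: TinySystem | None = None  # oracle twin, when tractable

    def system(self, scheme: str = "FULL") -> SystemSpec:
        return scheme_system(
            self.solute_a,
            self.solute_b,
            self.solvent,
            scheme,
            self.box_length,
            self.temperature,
            dimension=self.dimension,
            periodic=self.periodic,
            cutoff=self.cutoff,
        )


def _single_site(label: str, site: SiteType, dim: int) -> Species:
    tpl = MoleculeTemplate(sites=(site,), geometry=(tuple([0.0] * dim),), rigid=False)
    return Species(label=label, template=tpl, n_molecules=1)


def _solvent(site: SiteType, n_v: int, dim: int) -> Species:
    tpl = MoleculeTemplate(sites=(site,), geometry=(tuple([0.0] * dim),), rigid=False)
    return Species(label="V", template=tpl, n_molecules=n_v)


def _dumbbell(label: str, site: SiteType, bond: float) -> Species:
    half = 0.5 * bond
    tpl = MoleculeTemplate(
        sites=(site, site),
        geometry=((-half, 0.0, 0.0), (half, 0.0, 0.0)),
        rigid=True,
    )
    return Species(label=label, template=tpl, n_molecules=1)


def _flexdimer(label: str, site: SiteType, r0: float, k: float) -> Species:
    half = 0.5 * r0
    tpl = MoleculeTemplate(
        sites=(site, site),
        geometry=((-half, 0.0), (half, 0.0)),
        bonds=(Bond(i=0, j=1, k=k, r0=r0),),
        rigid=False,
    )
    return Species(label=label, template=tpl, n_molecules=1)


def make_fixture(name: str, n_v: int | None = None, seed: int = 0) -> FixtureSpec:
    """Build one of the named fixtures; ``seed`` sets the protocol seed base."""
    if name == "sph2d":
        nv = 30 if n_v is None else n_v
        rho = 0.4
        L = float(np.sqrt(max(nv, 30) / rho))
        protocol = Protocol(
            window_centers=tuple(np.linspace(0.8, 3.6, 9)),
            k_umb=25.0,
            n_steps=60_000,
            n_equil=15_000,
            sample_stride=10,
            seed_base=seed,
            bins=(0.8, 3.7, 40),
        )
        return FixtureSpec(
            name=name,
            solute_a=_single_site("A", LJ, 2),
            solute_b=_single_site("B", LJ, 2),
            solvent=_solvent(LJ, nv, 2) if nv else None,
            box_length=L,
            temperature=1.0,
            cutoff=3.0,
            dimension=2,
            periodic=True,
            protocol=protocol,
        )
    if name == "dumbbell3d":
        nv = 30 if n_v is None else n_v
        rho = 0.3
        L = float((max(nv, 30) / rho) ** (1.0 / 3.0))
        protocol = Protocol(
            window_centers=tuple(np.linspace(0.85, 2.05, 8)),
            k_umb=40.0,
            n_steps=60_000,
            n_equil=15_000,
            sample_stride=10,
            seed_base=seed,
            bins=(0.85, 2.15, 26),
        )
        return FixtureSpec(
            name=name,
            solute_a=_dumbbell("A", LJ, 0.5),
            solute_b=_dumbbell("B", LJ, 0.5),
            solvent=_solvent(LJ, nv, 3) if nv else None,
            box_length=L,
            temperature=1.0,
            cutoff=2.2,
            dimension=3,
            periodic=True,
            protocol=protocol,
        )
    if name == "flexdimer2d":
        nv = 30 if n_v is None else n_v
        rho = 0.4
        L = float(np.sqrt(max(nv, 30) / rho))
        protocol = Protocol(
            window_centers=tuple(np.linspace(0.8, 3.6, 9)),
            k_umb=25.0,
            n_steps=60_000,
            n_equil=15_000,
            sample_stride=10,
            seed_base=seed,
            bins=(0.8, 3.7, 40),
        )
        return FixtureSpec(
            name=name,
            solute_a=_flexdimer("A", LJ, 0.8, 20.0),
            solute_b=_flexdimer("B", LJ, 0.8, 20.0),
            solvent=_solvent(LJ, nv, 2) if nv else None,
            box_length=L,
            temperature=1.0,
            cutoff=3.0,
            dimension=2,
            periodic=True,
            protocol=protocol,
        )
    if name == "tiny1d":
        nv = 1 if n_v is None else n_v
        if nv > 2:
            raise ValueError("tiny fixtures admit at most 2 solvent particles")
        L, kT, cut = 10.0, 1.0, 3.0
        particles = [(LJ, "A"), (LJ, "B")] + [(LJ, "V")] * nv
        tiny = TinySystem(
            dimension=1, box_length=L, temperature=kT, h=0.1,
            particles=tuple(particles), periodic=True, cutoff=cut,
        )
        protocol = Protocol(
            window_centers=tuple(np.linspace(0.9, 4.5, 7)),
            k_umb=15.0,
            n_steps=40_000,
            n_equil=8_000,
            sample_stride=5,
            seed_base=seed,
            bins=(0.8, 4.7, 30),
        )
        return FixtureSpec(
            name=name,
            solute_a=_single_site("A", LJ, 1),
            solute_b=_single_site("B", LJ, 1),
            solvent=_solvent(LJ, nv, 1) if nv else None,
            box_length=L,
            temperature=kT,
            cutoff=cut,
            dimension=1,
            periodic=True,
            protocol=protocol,
            tiny=tiny,
        )
    if name == "tiny2d":
        nv = 1 if n_v is None else n_v
        if nv > 2:
            raise ValueError("tiny fixtures admit at most 2 solvent particles")
        L, kT, cut = 5.0, 1.0, 2.4
        particles = [(LJ, "A"), (LJ, "B")] + [(LJ, "V")] * nv
        tiny = TinySystem(
            dimension=2, box_length=L, temperature=kT, h=0.1,
            particles=tuple(particles), periodic=True, cutoff=cut,
        )
        protocol = Protocol(
            window_centers=tuple(np.linspace(0.9, 2.2, 6)),
            k_umb=25.0,
            n_steps=40_000,
            n_equil=8_000,
            sample_stride=5,
            seed_base=seed,
            bins=(0.85, 2.3, 24),
        )
        return FixtureSpec(
            name=name,
            solute_a=_single_site("A", LJ, 2),
            solute_b=_single_site("B", LJ, 2),
            solvent=_solvent(LJ, nv, 2) if nv else None,
            box_length=L,
            temperature=kT,
            cutoff=cut,
            dimension=2,
            periodic=True,
            protocol=protocol,
            tiny=tiny,
        )
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
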