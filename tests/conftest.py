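"""Shared fixtures: small systems and synthetic sample sets."""

from __future__ import annotations

import numpy as np
import pytest

from pcmc.fixtures import LJ, make_fixture
from pcmc.model import CouplingMatrix, CVSpec, MoleculeTemplate, Species, SystemSpec
from pcmc.sampler import BiasSpec, SampleSet


def single_site_species(label: str, dim: int, site=LJ, n: int = 1) -> Species:
    tpl = MoleculeTemplate(sites=(site,), geometry=(tuple([0.0] * dim),))
    return Species(label=label, template=tpl, n_molecules=n)


def pair_system(dim=2, box=10.0, lam=1.0, temperature=1.0, cutoff=3.0, periodic=True):
    """Two single-site LJ species A and B with coupling lam."""
    return SystemSpec(
        species=(single_site_species("A", dim), single_site_species("B", dim)),
        coupling=CouplingMatrix({("A", "B"): lam}),
        box_length=box,
        temperature=temperature,
        cv=CVSpec(kind="com_distance", species_a="A", species_b="B"),
        periodic=periodic,
        cutoff=cutoff,
        dimension=dim,
    )


def synthetic_samples(cv, seed=0, bias=None, temperature=1.0, dimension=1) -> SampleSet:
    """Wrap a CV series as a SampleSet (energies are irrelevant placeholders)."""
    cv = np.asarray(cv, dtype=float)
    b = bias or BiasSpec()
    return SampleSet(
        cv_samples=cv,
        energy_samples=np.zeros_like(cv),
        bias_energy_samples=np.array([b.energy(x) for x in cv]),
        bias=b,
        n_steps=cv.size,
        n_equil=0,
        sample_stride=1,
        seed=seed,
        acceptance_rate=0.5,
        temperature=temperature,
        dimension=dimension,
        system_digest="synthetic",
    )


@pytest.fixture(scope="session")
def tiny1d():
    return make_fixture("tiny1d", n_v=1, seed=3)


@pytest.fixture(scope="session")
def tiny2d():
    return make_fixture("tiny2d", n_v=1, seed=3)
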