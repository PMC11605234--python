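"""System definition and energy evaluation for partially connected mixtures.

A *system* is a mixture of species (each a set of identical molecules built
from typed interaction sites) together with a symmetric species-pair coupling
matrix.  An entry ``lam(A, B) = 0`` switches off every site-site interaction
between species A and B while leaving all other interactions untouched; this
is the "partially connected" coupling that makes unphysical reference states
(disjoint solvation, cavity coupling) expressible as ordinary simulations.

Reduced units throughout: lengths in units of a reference sigma, energies in
units of kT at the reference temperature (the temperature field of a
:class:`SystemSpec` is kT in these units, and beta = 1/kT).  There are no
masses: every free energy here is a configurational integral.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SiteType",
    "Bond",
    "MoleculeTemplate",
    "Species",
    "CouplingMatrix",
    "CVSpec",
    "SystemSpec",
    "Configuration",
    "OverlapError",
    "DensityError",
    "StructureError",
    "pair_energy",
    "pair_potential",
    "total_energy",
    "cv_value",
    "build_initial",
    "system_digest",
    "EnergyModel",
]


class OverlapError(ValueError):
    """Coupled sites at zero separation with a nonzero potential."""


class DensityError(RuntimeError):
    """Random placement failed: box too dense for the overlap criterion."""


class StructureError(ValueError):
    """Configuration inconsistent with the system specification."""


@dataclass(frozen=True)
class SiteType:
    """An interaction site type: Lennard-Jones parameters plus point charge."""

    name: str
    lj_epsilon: float
    lj_sigma: float
    charge: float = 0.0

    def __post_init__(self) -> None:
        if self.lj_sigma <= 0:
            raise ValueError(f"site {self.name!r}: lj_sigma must be > 0")
        if self.lj_epsilon < 0:
            raise ValueError(f"site {self.name!r}: lj_epsilon must be >= 0")


@dataclass(frozen=True)
class Bond:
    """Harmonic bond between two sites of one molecule: 0.5*k*(r - r0)^2."""

    i: int
    j: int
    k: float
    r0: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond must join two distinct sites")


@dataclass(frozen=True)
class MoleculeTemplate:
    """Blueprint of one molecule: sites, reference geometry, bonded terms.

    ``rigid=True`` means the internal geometry is frozen exactly (the molecule
    is sampled by center-of-mass translation plus rotation); rigid templates
    must not carry bonded terms.
    """

    sites: tuple[SiteType, ...]
    geometry: tuple[tuple[float, ...], ...]
    bonds: tuple[Bond, ...] = ()
    rigid: bool = False

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.geometry):
            raise ValueError("geometry must provide one coordinate per site")
        if self.rigid and self.bonds:
            raise ValueError("rigid templates carry no bonded terms")
        n = len(self.sites)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError("bond references a site outside the molecule")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def dimension(self) -> int:
        return len(self.geometry[0])

    def geometry_array(self) -> np.ndarray:
        g = np.asarray(self.geometry, dtype=float)
        return g - g.mean(axis=0)  # centered on the (unweighted) centroid


@dataclass(frozen=True)
class Species:
    """A labelled population of identical molecules."""

    label: str
    template: MoleculeTemplate
    n_molecules: int

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError(f"species {self.label!r}: n_molecules must be >= 1")


class CouplingMatrix:
    """Symmetric species-pair coupling weights, lam in [0, 1].

    Intra-species interactions are implicitly always fully on; pairs absent
    from the map are decoupled (lam = 0).
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._entries: dict[frozenset[str], float] = {}
        for (a, b), lam in (entries or {}).items():
            self.set(a, b, lam)

    def set(self, a: str, b: str, lam: float) -> None:
        if a == b:
            raise ValueError("intra-species coupling is implicit; do not set the diagonal")
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"coupling lam({a},{b})={lam} outside [0, 1]")
        key = frozenset((a, b))
        if key in self._entries and self._entries[key] != lam:
            raise ValueError(f"asymmetric coupling entries for pair ({a},{b})")
        self._entries[key] = lam

    def lam(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._entries.get(frozenset((a, b)), 0.0)

    def on_pairs(self) -> set[frozenset[str]]:
        return {k for k, v in self._entries.items() if v > 0.0}

    def items(self) -> list[tuple[tuple[str, str], float]]:
        out = []
        for key, lam in self._entries.items():
            a, b = sorted(key)
            out.append(((a, b), lam))
        return sorted(out)

    def __eq__(self, other) -> bool:
        return isinstance(other, CouplingMatrix) and self._entries == other._entries

    def __repr__(self) -> str:
        return f"CouplingMatrix({dict(self.items())!r})"


@dataclass(frozen=True)
class CVSpec:
    """Collective variable: distance between two species (COM or site-site)."""

    kind: str  # "com_distance" | "site_site_distance"
    species_a: str
    species_b: str
    site_a: int = 0
    site_b: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("com_distance", "site_site_distance"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.species_a == self.species_b:
            raise ValueError("CV must reference two distinct species")


@dataclass(frozen=True)
class SystemSpec:
    """Full description of a (possibly partially connected) mixture."""

    species: tuple[Species, ...]
    coupling: CouplingMatrix
    box_length: float
    temperature: float  # kT in reduced units
    cv: CVSpec | None = None
    periodic: bool = True
    cutoff: float = 3.0
    dimension: int = 3

    def __post_init__(self) -> None:
        labels = [s.label for s in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError("species labels must be unique")
        if self.temperature <= 0:
            raise ValueError("temperature (kT) must be > 0")
        if self.periodic and self.box_length <= 2.0 * self.cutoff:
            raise ValueError(
                f"periodic box_length={self.box_length} must exceed 2*cutoff={2 * self.cutoff}"
                " for the minimum-image convention"
            )
        if self.dimension not in (1, 2, 3):
            raise ValueError("dimension must be 1, 2 or 3")
        for s in self.species:
            if s.template.dimension != self.dimension:
                raise ValueError(
                    f"species {s.label!r} template is {s.template.dimension}-D,"
                    f" system is {self.dimension}-D"
                )
        if self.periodic:
            for s in self.species:
                if any(st.charge != 0.0 for st in s.template.sites):
                    raise ValueError("charges are only supported in nonperiodic systems")
        if self.cv is not None:
            known = set(labels)
            if self.cv.species_a not in known or self.cv.species_b not in known:
                raise ValueError("CV references a species not present in the system")

    @property
    def beta(self) -> float:
        return 1.0 / self.temperature

    def species_by_label(self, label: str) -> Species:
        for s in self.species:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def n_sites(self) -> int:
        return sum(s.n_molecules * s.template.n_sites for s in self.species)


@dataclass
class Configuration:
    """Per-site coordinates of one system state, shape (n_sites, dimension).

    Coordinates are never wrapped: minimum image is applied in every distance
    evaluation, so molecules stay contiguous across periodic boundaries.
    """

    positions: np.ndarray

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy())


# ---------------------------------------------------------------------------
# pair potential


def pair_potential(
    r: np.ndarray | float,
    eps: np.ndarray | float,
    sig: np.ndarray | float,
    qq: np.ndarray | float = 0.0,
    cutoff: float = np.inf,
) -> np.ndarray | float:
    """Truncated (unshifted) Lennard-Jones + Coulomb at separation r.

    Vectorized over all arguments; returns 0 beyond the cutoff.  r must be
    strictly positive where eps or qq is nonzero (guarded by callers).
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        safe_r = np.where(r > 0, r, 1.0)
        sr6 = (sig / safe_r) ** 6
        u = 4.0 * eps * (sr6 * sr6 - sr6) + qq / safe_r
    # tolerant comparison: distances landing on the cutoff up to rounding are
    # treated consistently on either side of a 1-ulp perturbation
    u = np.where(r <= cutoff + 1e-9, u, 0.0)
    at_zero = r <= 0
    if np.any(at_zero):
        interacting = (np.asarray(eps) != 0) | (np.asarray(qq) != 0)
        u = np.where(at_zero, np.where(interacting, np.inf, 0.0), u)
    return u


def _lorentz_berthelot(t1: SiteType, t2: SiteType) -> tuple[float, float, float]:
    sig = 0.5 * (t1.lj_sigma + t2.lj_sigma)
    eps = float(np.sqrt(t1.lj_epsilon * t2.lj_epsilon))
    qq = t1.charge * t2.charge
    return eps, sig, qq


def pair_energy(
    t1: SiteType, t2: SiteType, r: float, lam: float = 1.0, cutoff: float = 3.0
) -> float:
    """Site-site pair energy with Lorentz-Berthelot combination, scaled by lam.

    lam = 0 returns exactly 0 (decoupled sites may overlap).
    """
    if lam == 0.0:
        return 0.0
    eps, sig, qq = _lorentz_berthelot(t1, t2)
    if r <= 0.0:
        if eps != 0.0 or qq != 0.0:
            raise OverlapError(
                f"sites {t1.name!r}/{t2.name!r} at r={r} with lam={lam} and nonzero potential"
            )
        return 0.0
    return float(lam * pair_potential(r, eps, sig, qq, cutoff))


# ---------------------------------------------------------------------------
# flattened energy model


class EnergyModel:
    """Flattened per-site arrays for fast energy evaluation.

    Precomputes the full n_sites x n_sites combined LJ parameters, charges and
    effective coupling weights (species lam, zero diagonal, zero on
    bond-excluded intramolecular pairs), plus per-molecule neighbour index
    lists for O(n) single-molecule move deltas.
    """

    def __init__(self, sys: SystemSpec):
        self.sys = sys
        self.dim = sys.dimension
        self.box = sys.box_length
        self.periodic = sys.periodic
        self.cutoff = sys.cutoff
        self.beta = sys.beta

        site_eps: list[float] = []
        site_sig: list[float] = []
        site_q: list[float] = []
        self.site_species: list[int] = []  # species index per site
        self.site_molecule: list[int] = []  # global molecule index per site
        self.mol_sites: list[np.ndarray] = []  # site indices per molecule
        self.mol_species: list[int] = []  # species index per molecule
        self.mol_rigid: list[bool] = []
        self.species_labels = [s.label for s in sys.species]
        self.species_site_index: dict[str, np.ndarray] = {}
        bonds_i, bonds_j, bonds_k, bonds_r0 = [], [], [], []

        offset = 0
        mol_index = 0
        for si, sp in enumerate(sys.species):
            tpl = sp.template
            species_sites = []
            for _ in range(sp.n_molecules):
                idx = np.arange(offset, offset + tpl.n_sites)
                species_sites.append(idx)
                self.mol_sites.append(idx)
                self.mol_species.append(si)
                self.mol_rigid.append(tpl.rigid)
                for st in tpl.sites:
                    site_eps.append(st.lj_epsilon)
                    site_sig.append(st.lj_sigma)
                    site_q.append(st.charge)
                    self.site_species.append(si)
                    self.site_molecule.append(mol_index)
                for b in tpl.bonds:
                    bonds_i.append(offset + b.i)
                    bonds_j.append(offset + b.j)
                    bonds_k.append(b.k)
                    bonds_r0.append(b.r0)
                offset += tpl.n_sites
                mol_index += 1
            self.species_site_index[sp.label] = np.concatenate(species_sites)

        self.n_sites = offset
        self.n_molecules = mol_index
        eps = np.asarray(site_eps)
        sig = np.asarray(site_sig)
        q = np.asarray(site_q)
        self.eps_ij = np.sqrt(np.outer(eps, eps))
        self.sig_ij = 0.5 * (sig[:, None] + sig[None, :])
        self.qq_ij = np.outer(q, q)

        spec_idx = np.asarray(self.site_species)
        ns = len(sys.species)
        lam_species = np.ones((ns, ns))
        for a in range(ns):
            for b in range(ns):
                if a != b:
                    lam_species[a, b] = sys.coupling.lam(
                        self.species_labels[a], self.species_labels[b]
                    )
        lam = lam_species[spec_idx[:, None], spec_idx[None, :]].astype(float)
        np.fill_diagonal(lam, 0.0)
        # 1-2 exclusion: bonded intramolecular pairs carry no nonbonded term
        for i, j in zip(bonds_i, bonds_j):
            lam[i, j] = 0.0
            lam[j, i] = 0.0
        self.lam_ij = lam

        self.bonds_i = np.asarray(bonds_i, dtype=int)
        self.bonds_j = np.asarray(bonds_j, dtype=int)
        self.bonds_k = np.asarray(bonds_k, dtype=float)
        self.bonds_r0 = np.asarray(bonds_r0, dtype=float)

        iu = np.triu_indices(self.n_sites, k=1)
        self._iu = iu
        self._pair_active = self.lam_ij[iu] > 0.0
        # per-molecule complement index lists and bond masks
        self._mol_others = [
            np.setdiff1d(np.arange(self.n_sites), idx, assume_unique=True)
            for idx in self.mol_sites
        ]
        self._mol_bond_mask = [
            np.isin(self.bonds_i, idx) | np.isin(self.bonds_j, idx) for idx in self.mol_sites
        ]
        self._rc2 = (self.cutoff + 1e-9) ** 2
        self._has_charges = bool(np.any(self.qq_ij != 0.0))
        self._any_zero_eps = bool(np.any(eps == 0.0))
        self._inv_box = 1.0 / self.box
        self._build_move_tables()

    def _build_move_tables(self) -> None:
        """Precomputed neighbour blocks for O(neighbours) move deltas."""
        n = self.n_sites
        self._mol_env: list[tuple] = []  # (j_idx, lam, eps (k,nj), sig2, qq)
        self._site_env: list[tuple] = []  # per site: (j_idx, lam, eps, sig2, qq)
        self._mol_intra: list[tuple] = []  # (loc_i, loc_j, lam, eps, sig2, qq)
        sig2_ij = self.sig_ij**2
        for m, idx in enumerate(self.mol_sites):
            others = self._mol_others[m]
            lam_row = self.lam_ij[idx[0], others]  # inter-species lam: same for all sites
            act = others[lam_row > 0.0]
            lam = self.lam_ij[idx[0], act]
            self._mol_env.append(
                (act, lam, self.eps_ij[np.ix_(idx, act)], sig2_ij[np.ix_(idx, act)],
                 self.qq_ij[np.ix_(idx, act)])
            )
            li, lj = np.triu_indices(idx.size, k=1)
            gi, gj = idx[li], idx[lj]
            keep = self.lam_ij[gi, gj] > 0.0
            self._mol_intra.append(
                (li[keep], lj[keep], self.lam_ij[gi, gj][keep], self.eps_ij[gi, gj][keep],
                 sig2_ij[gi, gj][keep], self.qq_ij[gi, gj][keep])
            )
        for s in range(n):
            lam_row = self.lam_ij[s]
            act = np.nonzero(lam_row > 0.0)[0]
            self._site_env.append(
                (act, lam_row[act], self.eps_ij[s, act], sig2_ij[s, act], self.qq_ij[s, act])
            )
        self._site_bond_mask = [
            (self.bonds_i == s) | (self.bonds_j == s) for s in range(n)
        ] if self.bonds_i.size else None

    def _u_from_r2(self, r2, eps, sig2, qq):
        """LJ(+Coulomb) from squared distances; r2 = 0 under eps > 0 gives +inf.

        Callers run under a permissive numpy error state (the divide at r2 = 0
        is intentional: it produces the +inf that rejects coupled overlaps).
        """
        s6 = (sig2 / r2) ** 3
        u = 4.0 * eps * s6 * (s6 - 1.0)
        if self._any_zero_eps:
            u = np.where(np.isnan(u), 0.0, u)  # 0 * inf from eps == 0 at overlap
        if self._has_charges:
            u = u + qq / np.sqrt(r2)
        return np.where(r2 <= self._rc2, u, 0.0)

    def mol_env_energy(self, pos: np.ndarray, mol: int) -> float:
        """Interactions between one molecule and its coupled environment."""
        act, lam, eps, sig2, qq = self._mol_env[mol]
        if act.size == 0:
            return 0.0
        d = pos[self.mol_sites[mol]][:, None, :] - pos[act][None, :, :]
        if self.periodic:
            d -= self.box * np.round(d * self._inv_box)
        r2 = (d * d).sum(axis=-1)
        u = self._u_from_r2(r2, eps, sig2, qq)
        return float(u @ lam if u.ndim == 1 else (u @ lam).sum())

    def site_env_energy(self, pos: np.ndarray, site: int) -> float:
        """Interactions between one site and everything coupled to it."""
        act, lam, eps, sig2, qq = self._site_env[site]
        if act.size == 0:
            return 0.0
        d = pos[act] - pos[site]
        if self.periodic:
            d -= self.box * np.round(d * self._inv_box)
        r2 = (d * d).sum(axis=-1)
        u = self._u_from_r2(r2, eps, sig2, qq)
        return float(u @ lam)

    def mol_intra_energy(self, pos: np.ndarray, mol: int) -> float:
        """Intramolecular nonbonded (non-excluded) pairs plus bonded terms."""
        idx = self.mol_sites[mol]
        if idx.size == 1:
            return 0.0
        li, lj, lam, eps, sig2, qq = self._mol_intra[mol]
        e = 0.0
        if li.size:
            d = pos[idx[li]] - pos[idx[lj]]
            if self.periodic:
                d -= self.box * np.round(d * self._inv_box)
            r2 = (d * d).sum(axis=-1)
            e += float(self._u_from_r2(r2, eps, sig2, qq) @ lam)
        if self.bonds_i.size:
            e += self._bond_energy(pos, self._mol_bond_mask[mol])
        return e

    # -- geometry helpers

    def displacement(self, dx: np.ndarray) -> np.ndarray:
        if self.periodic:
            dx = dx - self.box * np.round(dx / self.box)
        return dx

    def distances(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Pairwise minimum-image distances between position sets a and b."""
        d = self.displacement(a[:, None, :] - b[None, :, :])
        return np.sqrt(np.sum(d * d, axis=-1))

    # -- energies

    def _bond_energy(self, pos: np.ndarray, mask: np.ndarray | None = None) -> float:
        if self.bonds_i.size == 0:
            return 0.0
        bi, bj = self.bonds_i, self.bonds_j
        bk, br0 = self.bonds_k, self.bonds_r0
        if mask is not None:
            bi, bj, bk, br0 = bi[mask], bj[mask], bk[mask], br0[mask]
            if bi.size == 0:
                return 0.0
        d = self.displacement(pos[bi] - pos[bj])
        r = np.sqrt(np.sum(d * d, axis=-1))
        return float(np.sum(0.5 * bk * (r - br0) ** 2))

    def total_energy(self, pos: np.ndarray) -> float:
        i, j = self._iu
        act = self._pair_active
        ia, ja = i[act], j[act]
        d = self.displacement(pos[ia] - pos[ja])
        r = np.sqrt(np.sum(d * d, axis=-1))
        u = pair_potential(r, self.eps_ij[ia, ja], self.sig_ij[ia, ja],
                           self.qq_ij[ia, ja], self.cutoff)
        e = float(np.sum(self.lam_ij[ia, ja] * u))
        return e + self._bond_energy(pos)

    def molecule_energy(self, pos: np.ndarray, mol: int) -> float:
        """Energy of all terms involving molecule ``mol`` (inter + intra)."""
        idx = self.mol_sites[mol]
        others = self._mol_others[mol]
        lam = self.lam_ij[np.ix_(idx, others)]
        act = lam > 0.0
        e = 0.0
        if np.any(act):
            r = self.distances(pos[idx], pos[others])
            u = pair_potential(
                r, self.eps_ij[np.ix_(idx, others)], self.sig_ij[np.ix_(idx, others)],
                self.qq_ij[np.ix_(idx, others)], self.cutoff,
            )
            e += float(np.sum(np.where(act, lam * u, 0.0)))
        if idx.size > 1:
            sub = np.ix_(idx, idx)
            lam_in = np.triu(self.lam_ij[sub], k=1)
            if np.any(lam_in > 0):
                r_in = self.distances(pos[idx], pos[idx])
                np.fill_diagonal(r_in, np.inf)
                u_in = pair_potential(
                    r_in, self.eps_ij[sub], self.sig_ij[sub], self.qq_ij[sub], self.cutoff
                )
                e += float(np.sum(np.triu(np.where(lam_in > 0, lam_in * u_in, 0.0), k=1)))
            e += self._bond_energy(pos, self._mol_bond_mask[mol])
        return e

    def site_energy(self, pos: np.ndarray, site: int) -> float:
        """Energy of all terms involving one site (for flexible-site moves)."""
        others = np.concatenate(
            (np.arange(site), np.arange(site + 1, self.n_sites))
        )
        lam = self.lam_ij[site, others]
        act = lam > 0.0
        e = 0.0
        if np.any(act):
            d = self.displacement(pos[others[act]] - pos[site])
            r = np.sqrt(np.sum(d * d, axis=-1))
            u = pair_potential(
                r, self.eps_ij[site, others[act]], self.sig_ij[site, others[act]],
                self.qq_ij[site, others[act]], self.cutoff,
            )
            e += float(np.sum(lam[act] * u))
        if self.bonds_i.size:
            bmask = (self.bonds_i == site) | (self.bonds_j == site)
            e += self._bond_energy(pos, bmask)
        return e

    # -- collective variable

    def species_com(self, pos: np.ndarray, label: str) -> np.ndarray:
        return pos[self.species_site_index[label]].mean(axis=0)

    def cv_value(self, pos: np.ndarray) -> float:
        cv = self.sys.cv
        if cv is None:
            raise StructureError("system has no CV defined")
        if cv.kind == "com_distance":
            d = self.species_com(pos, cv.species_a) - self.species_com(pos, cv.species_b)
        else:
            ia = self.species_site_index[cv.species_a][cv.site_a]
            ib = self.species_site_index[cv.species_b][cv.site_b]
            d = pos[ia] - pos[ib]
        d = self.displacement(d)
        return float(np.sqrt(np.sum(d * d)))


# ---------------------------------------------------------------------------
# public operations (thin wrappers over EnergyModel)


def _check_cfg(cfg: Configuration, sys: SystemSpec) -> None:
    if cfg.positions.shape != (sys.n_sites, sys.dimension):
        raise StructureError(
            f"configuration shape {cfg.positions.shape} does not match system"
            f" ({sys.n_sites} sites, {sys.dimension}-D)"
        )


def total_energy(cfg: Configuration, sys: SystemSpec) -> float:
    """Total potential energy: coupled inter-species pairs + intra terms."""
    _check_cfg(cfg, sys)
    return EnergyModel(sys).total_energy(cfg.positions)


def cv_value(cfg: Configuration, sys: SystemSpec) -> float:
    """Value of the system's collective variable (minimum-image distance)."""
    _check_cfg(cfg, sys)
    return EnergyModel(sys).cv_value(cfg.positions)


def random_rotation_matrix(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (proper orthogonal matrix) in 2D/3D."""
    if dim == 1:
        return np.ones((1, 1))
    if dim == 2:
        th = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])
    # QR of a Gaussian matrix with sign fix gives Haar-uniform O(3) -> SO(3)
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def small_rotation_matrix(dim: int, max_angle: float, rng: np.random.Generator) -> np.ndarray:
    """Small rotation, symmetric under inversion (angle uniform in +-max)."""
    if dim == 1:
        return np.ones((1, 1))
    ang = rng.uniform(-max_angle, max_angle)
    if dim == 2:
        c, s = np.cos(ang), np.sin(ang)
        return np.array([[c, -s], [s, c]])
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)


def build_initial(
    sys: SystemSpec,
    seed: int,
    cv_target: float | None = None,
    max_retries: int = 200,
    max_restarts: int = 40,
) -> Configuration:
    """Random non-overlapping placement (coupled pairs only), seed-deterministic.

    Molecules are inserted one by one at random positions/orientations and
    rejected while any *coupled* site pair sits closer than 0.7 sigma_ij;
    decoupled species interpenetrate freely.  When ``cv_target`` is given the
    two CV species are placed first, separated by exactly that distance (a
    deterministic start for umbrella windows).
    """
    model = EnergyModel(sys)
    rng = np.random.default_rng(seed)
    dim = sys.dimension
    L = sys.box_length
    center = np.full(dim, 0.5 * L)

    for _ in range(max_restarts):
        pos = np.zeros((sys.n_sites, dim))
        placed: list[int] = []  # molecule indices already placed
        ok = True
        order = list(range(model.n_molecules))
        pinned: dict[int, np.ndarray] = {}
        if cv_target is not None and sys.cv is not None:
            # first molecule of each CV species, separated along x
            mol_a = next(
                m for m in order
                if model.species_labels[model.mol_species[m]] == sys.cv.species_a
            )
            mol_b = next(
                m for m in order
                if model.species_labels[model.mol_species[m]] == sys.cv.species_b
            )
            off = np.zeros(dim)
            off[0] = 0.5 * cv_target
            pinned[mol_a] = center - off
            pinned[mol_b] = center + off
            order = [mol_a, mol_b] + [m for m in order if m not in (mol_a, mol_b)]

        for mol in order:
            idx = model.mol_sites[mol]
            tpl = sys.species[model.mol_species[mol]].template
            geom = tpl.geometry_array()
            success = False
            for _try in range(max_retries):
                com = pinned.get(mol)
                if com is None:
                    com = rng.uniform(0.0, L, size=dim)
                rot = random_rotation_matrix(dim, rng) if tpl.n_sites > 1 else np.eye(dim)
                trial = com + geom @ rot.T
                clash = False
                for other in placed:
                    oidx = model.mol_sites[other]
                    lam = model.lam_ij[np.ix_(idx, oidx)]
                    if not np.any(lam > 0):
                        continue
                    r = model.distances(trial, pos[oidx])
                    lim = 0.7 * model.sig_ij[np.ix_(idx, oidx)]
                    if np.any((r < lim) & (lam > 0)):
                        clash = True
                        break
                if not clash:
                    pos[idx] = trial
                    placed.append(mol)
                    success = True
                    break
                if mol in pinned:
                    # pinned COM: only reorientation can resolve the clash
                    continue
            if not success:
                ok = False
                break
        if ok:
            return Configuration(pos)
    raise DensityError(
        f"could not place {model.n_molecules} molecules in box L={L} after"
        f" {max_restarts} restarts (overlap criterion 0.7 sigma)"
    )


# ---------------------------------------------------------------------------
# digest


def _spec_as_dict(sys: SystemSpec) -> dict:
    return {
        "dimension": sys.dimension,
        "box_length": sys.box_length,
        "periodic": sys.periodic,
        "temperature": sys.temperature,
        "cutoff": sys.cutoff,
        "cv": None
        if sys.cv is None
        else {
            "kind": sys.cv.kind,
            "species_a": sys.cv.species_a,
            "species_b": sys.cv.species_b,
            "site_a": sys.cv.site_a,
            "site_b": sys.cv.site_b,
        },
        "coupling": [[a, b, lam] for (a, b), lam in sys.coupling.items()],
        "species": [
            {
                "label": s.label,
                "count": s.n_molecules,
                "rigid": s.template.rigid,
                "sites": [
                    [st.name, st.lj_epsilon, st.lj_sigma, st.charge] for st in s.template.sites
                ],
                "geometry": [list(g) for g in s.template.geometry],
                "bonds": [[b.i, b.j, b.k, b.r0] for b in s.template.bonds],
            }
            for s in sys.species
        ],
    }


def system_digest(sys: SystemSpec) -> str:
    """Stable content hash of a SystemSpec (stamped into every SampleSet)."""
    blob = json.dumps(_spec_as_dict(sys), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
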