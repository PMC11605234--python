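"""Exact brute-force evaluation of configurational integrals on tiny systems.

Every estimator in this package is validated against dense-grid quadrature of
micro-systems with at most four mobile single-site particles in one or two
dimensions: log configurational integrals for arbitrary coupling-edge
subsets, constrained (fixed-solute) free energy profiles, second/third-order
mixing free energies, and cluster cumulant functions (CCFs).

The CCF of a diagram G is defined by Moebius inversion over the Boolean
lattice of its coupling edges,

    K[G] = sum_{S subseteq edges(G)} (-1)^{|edges(G)| - |S|} ln Z(S),

which reproduces the second-order mixing free energy for a single edge and
telescopes so that the sum of K over all connected subdiagrams of a complete
n-diagram reconstructs the n-th order mixing free energy.  Diagrams with
"white" circles carry a collective-variable dependence: those species are
held at fixed positions separated by r instead of being integrated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .free_energy import PMFProfile
from .model import SiteType, pair_potential

__all__ = [
    "TinySystem",
    "Diagram",
    "SizeError",
    "brute_logZ",
    "brute_pmf",
    "cv_density",
    "mixing_free_energy",
    "ccf",
    "verify_jsi_ccf_identity",
    "delta_line_collapse_check",
    "binned_pair_profile",
]

NODE_BUDGET = 10_000_000


class SizeError(ValueError):
    """Quadrature node budget exceeded; the system is not oracle-tractable."""


@dataclass(frozen=True)
class TinySystem:
    """An oracle-tractable micro-system of single-site particles.

    ``particles`` maps each particle to (site type, species label); several
    particles may share a species (e.g. a two-particle solvent).  The grid
    spacing h must resolve the smallest LJ sigma (h <= sigma/10).
    """

    dimension: int
    box_length: float
    temperature: float
    h: float
    particles: tuple[tuple[SiteType, str], ...]
    periodic: bool = True
    cutoff: float = np.inf

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError("tiny systems support dimension 1 or 2")
        if len(self.particles) > 6:
            raise ValueError("tiny systems hold at most a few particles")
        sig_min = min(t.lj_sigma for t, _ in self.particles)
        if self.h > sig_min / 10 + 1e-12:
            raise ValueError(f"grid h={self.h} too coarse; need h <= sigma/10 = {sig_min / 10}")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def beta(self) -> float:
        return 1.0 / self.temperature

    @property
    def species_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, lab in self.particles:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def with_h(self, h: float) -> "TinySystem":
        return replace(self, h=h)


@dataclass(frozen=True)
class Diagram:
    """A mixture diagram: species circles, coupling edges, optional white set.

    White circles (0 or 2 of them) carry the CV dependence: they are held at
    fixed positions separated by the CV value instead of being integrated.
    """

    circles: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    white: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.white) not in (0, 2):
            raise ValueError("white set must contain exactly 0 or 2 circles")
        circles = set(self.circles)
        for e in self.edges:
            if not e <= circles:
                raise ValueError(f"edge {sorted(e)} references a circle outside the diagram")
            if len(e) != 2:
                raise ValueError("edges join two distinct circles")
        if not set(self.white) <= circles:
            raise ValueError("white circles must be diagram circles")

    def is_connected(self) -> bool:
        nodes = set(self.circles)
        if len(nodes) <= 1:
            return True
        adj: dict[str, set[str]] = {c: set() for c in nodes}
        for e in self.edges:
            a, b = sorted(e)
            adj[a].add(b)
            adj[b].add(a)
        seen = {next(iter(nodes))}
        frontier = list(seen)
        while frontier:
            c = frontier.pop()
            for m in adj[c]:
                if m not in seen:
                    seen.add(m)
                    frontier.append(m)
        return seen == nodes


# ---------------------------------------------------------------------------
# quadrature core


def _normalize_edges(edges) -> set[frozenset[str]]:
    out = set()
    for e in edges:
        fe = frozenset(e)
        if len(fe) != 2:
            raise ValueError(f"edge {e!r} must join two distinct species")
        out.add(fe)
    return out


def _grid(tiny: TinySystem) -> tuple[np.ndarray, np.ndarray]:
    """1D grid points and per-point log integration weights for one axis."""
    L, h = tiny.box_length, tiny.h
    if tiny.periodic:
        n = int(round(L / h))
        pts = np.arange(n) * (L / n)
        logw = np.full(n, np.log(L / n))
    else:
        n = int(round(L / h))
        pts = np.linspace(0.0, L, n + 1)
        w = np.full(n + 1, h)
        w[0] = w[-1] = 0.5 * h
        logw = np.log(w)
    return pts, logw


def _candidates(tiny: TinySystem) -> tuple[np.ndarray, np.ndarray]:
    """All candidate positions (M, d) and their log weights (M,) for one particle."""
    pts, logw = _grid(tiny)
    if tiny.dimension == 1:
        return pts[:, None], logw
    xx, yy = np.meshgrid(pts, pts, indexing="ij")
    cand = np.stack([xx.ravel(), yy.ravel()], axis=1)
    lw = (logw[:, None] + logw[None, :]).ravel()
    return cand, lw


def _min_image_dist(a: np.ndarray, b: np.ndarray, tiny: TinySystem) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    if tiny.periodic:
        L = tiny.box_length
        d = d - L * np.round(d / L)
    return np.sqrt(np.sum(d * d, axis=-1))


def _pair_u(t1: SiteType, t2: SiteType, r: np.ndarray, cutoff: float) -> np.ndarray:
    sig = 0.5 * (t1.lj_sigma + t2.lj_sigma)
    eps = float(np.sqrt(t1.lj_epsilon * t2.lj_epsilon))
    qq = t1.charge * t2.charge
    return pair_potential(r, eps, sig, qq, cutoff)


def _logZ(
    tiny: TinySystem,
    edges,
    fixed: dict[int, np.ndarray] | None = None,
    pair_override: dict[frozenset[int], callable] | None = None,
) -> float:
    """log of the quadrature estimate of the configurational integral.

    ``edges`` is the set of coupled species pairs (intra-species pairs are
    always coupled).  ``fixed`` maps particle indices to frozen positions
    (white circles); only the remaining particles are integrated.
    ``pair_override`` replaces the pair energy function u(r) for specific
    particle pairs (used by the delta-line collapse check).
    """
    edges = _normalize_edges(edges)
    fixed = fixed or {}
    n = len(tiny.particles)
    mobile = [p for p in range(n) if p not in fixed]

    cand, logw = _candidates(tiny)
    M = cand.shape[0]
    if M ** len(mobile) > NODE_BUDGET:
        raise SizeError(
            f"{len(mobile)} mobile particles x {M} nodes exceeds the"
            f" {NODE_BUDGET} quadrature node budget"
        )

    def lam(p: int, q: int) -> float:
        _, la = tiny.particles[p]
        _, lb = tiny.particles[q]
        if la == lb:
            return 1.0
        return 1.0 if frozenset((la, lb)) in edges else 0.0

    def u_pq(p: int, q: int, r: np.ndarray) -> np.ndarray:
        if pair_override:
            fn = pair_override.get(frozenset((p, q)))
            if fn is not None:
                return fn(r)
        return _pair_u(tiny.particles[p][0], tiny.particles[q][0], r, tiny.cutoff)

    k = len(mobile)
    shape = tuple([M] * k)
    axis_of = {p: ax for ax, p in enumerate(mobile)}
    logZ_const = 0.0  # fixed-fixed pair energies and weight normalizations

    E = np.zeros(shape) if k else np.zeros(())
    for p, q in itertools.combinations(range(n), 2):
        if lam(p, q) == 0.0:
            continue
        p_fixed, q_fixed = p in fixed, q in fixed
        if p_fixed and q_fixed:
            r = _min_image_dist(fixed[p][None, :], fixed[q][None, :], tiny)[0, 0]
            logZ_const += -tiny.beta * float(u_pq(p, q, np.asarray(r)))
        elif p_fixed or q_fixed:
            fp, mq = (p, q) if p_fixed else (q, p)
            r = _min_image_dist(fixed[fp][None, :], cand, tiny)[0]
            u = u_pq(p, q, r)
            sh = [1] * k
            sh[axis_of[mq]] = M
            E = E + u.reshape(sh)
        else:
            # broadcast the (M, M) pair matrix onto axes (axis_of[p], axis_of[q])
            r = _min_image_dist(cand, cand, tiny)
            u = u_pq(p, q, r)
            ax_p, ax_q = axis_of[p], axis_of[q]
            shp = [1] * k
            shp[ax_p] = M
            shp[ax_q] = M
            if ax_p > ax_q:
                u = u.T
            E = E + u.reshape(shp)
    logweight = 0.0
    if k:
        # sum of per-particle log weights, broadcast across axes
        lw_total = np.zeros(shape)
        for ax in range(k):
            sh = [1] * k
            sh[ax] = M
            lw_total = lw_total + logw.reshape(sh)
        val = logsumexp(-tiny.beta * E + lw_total)
    else:
        val = 0.0
    return float(val + logZ_const)


# ---------------------------------------------------------------------------
# public operations


def brute_logZ(tiny: TinySystem, edges, return_refinement: bool = False):
    """ln of the trapezoid-rule configurational integral over all particles.

    With ``return_refinement=True`` also returns the change under h -> h/2
    (a direct grid-convergence report).
    """
    val = _logZ(tiny, edges)
    if not return_refinement:
        return val
    val2 = _logZ(tiny.with_h(tiny.h / 2), edges)
    return val, val2 - val


def _fixed_solute_positions(tiny: TinySystem, a: str, b: str, r: float) -> dict[int, np.ndarray]:
    idx_a = [p for p, (_, lab) in enumerate(tiny.particles) if lab == a]
    idx_b = [p for p, (_, lab) in enumerate(tiny.particles) if lab == b]
    if len(idx_a) != 1 or len(idx_b) != 1:
        raise ValueError("white species must consist of a single particle each")
    d = tiny.dimension
    c = np.full(d, 0.5 * tiny.box_length)
    if tiny.periodic:
        # snap onto a quadrature node so lattice translation symmetry of the
        # grid is exact for grid-commensurate separations
        step = tiny.box_length / round(tiny.box_length / tiny.h)
        c = np.round(c / step) * step
    off = np.zeros(d)
    off[0] = r
    return {idx_a[0]: c, idx_b[0]: c + off}


def _pmf_values(tiny: TinySystem, edges, r_values, solute_a: str, solute_b: str) -> np.ndarray:
    """Unanchored F(r) = -kT ln Z(r) values at arbitrary separations."""
    out = np.empty(len(r_values), dtype=float)
    for i, r in enumerate(np.asarray(r_values, dtype=float)):
        fixed = _fixed_solute_positions(tiny, solute_a, solute_b, float(r))
        out[i] = -tiny.temperature * _logZ(tiny, edges, fixed=fixed)
    return out


def brute_pmf(
    tiny: TinySystem, edges, r_grid, solute_a: str = "A", solute_b: str = "B"
) -> PMFProfile:
    """Exact constrained profile F(r) = -kT ln Z(r), solutes held fixed.

    Solute A sits at the box center and B at distance r along x (translation
    invariance makes the choice of origin immaterial in a periodic box); all
    remaining particles are integrated by quadrature.  The profile is
    orientation-fixed, i.e. already in the Jacobian-corrected convention, and
    anchored to zero at the largest r.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    vals = _pmf_values(tiny, edges, r_grid, solute_a, solute_b)
    vals = vals - vals[-1]
    return PMFProfile(
        grid=r_grid,
        values=vals,
        errors=np.zeros_like(vals),
        n_samples=np.zeros(r_grid.size, dtype=int),
        anchor="zero_at_rmax",
        jacobian_corrected=True,
        dimension=tiny.dimension,
    )


def cv_density(
    tiny: TinySystem, edges, bin_edges, solute_a: str = "A", solute_b: str = "B",
    refine: int = 8,
) -> np.ndarray:
    """Expected histogram probabilities of the A-B distance, all species mobile.

    This is the exact oracle for a *binned, sampled* CV histogram: for each
    bin it integrates r^{d-1} exp(-beta F(r)) over the bin (F from
    :func:`brute_pmf`), times the angular multiplicity, and normalizes across
    bins.  ``refine`` sub-points per bin resolve the within-bin variation.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    d = tiny.dimension
    sub_r, sub_w = [], []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        x = np.linspace(lo, hi, refine + 1)
        w = np.full(refine + 1, (hi - lo) / refine)
        w[0] *= 0.5
        w[-1] *= 0.5
        sub_r.append(x)
        sub_w.append(w)
    all_r = np.concatenate(sub_r)
    vals = _pmf_values(tiny, edges, all_r, solute_a, solute_b)
    beta_f = (vals - vals.min()) / tiny.temperature
    dens = all_r ** (d - 1) * np.exp(-beta_f)
    p = []
    k = 0
    for w in sub_w:
        p.append(float(np.sum(dens[k : k + w.size] * w)))
        k += w.size
    p = np.asarray(p)
    return p / p.sum()


def mixing_free_energy(tiny: TinySystem, order: int) -> float:
    """Second- or third-order mixing free energy by quadrature (kT units).

    F2(A,B) = F_{A+B coupled} - F_A - F_B; F3 is the alternating combination
    of the complete subdiagram free energies.  Species in isolation are
    evaluated by integrating only that species' particles in the same box.
    """
    labels = tiny.species_labels
    if order == 2:
        if len(labels) != 2:
            raise ValueError("order-2 mixing free energy needs exactly 2 species")
    elif order == 3:
        if len(labels) != 3:
            raise ValueError("order-3 mixing free energy needs exactly 3 species")
    else:
        raise ValueError("order must be 2 or 3")

    def lnz(subset: tuple[str, ...]) -> float:
        keep = [pt for pt in tiny.particles if pt[1] in subset]
        sub = replace(tiny, particles=tuple(keep))
        edges = [(a, b) for a, b in itertools.combinations(subset, 2)]
        return _logZ(sub, edges)

    kT = tiny.temperature
    if order == 2:
        a, b = labels
        return -kT * (lnz((a, b)) - lnz((a,)) - lnz((b,)))
    a, b, c = labels
    val = (
        lnz((a, b, c))
        - lnz((a, b))
        - lnz((a, c))
        - lnz((b, c))
        + lnz((a,))
        + lnz((b,))
        + lnz((c,))
    )
    return -kT * val


def ccf(diagram: Diagram, tiny: TinySystem, r: float | None = None) -> float:
    """Cluster cumulant function of a diagram by Moebius inversion (ln units).

    White circles require the CV value ``r``; black-only diagrams must not be
    given one.  Disconnected diagrams evaluate to ~0 (factorization makes the
    inclusion-exclusion telescope), which is itself a checked property.
    """
    if diagram.white and r is None:
        raise ValueError("diagram has white circles: a CV value r is required")
    if not diagram.white and r is not None:
        raise ValueError("diagram has no white circles: r is not meaningful")
    keep = [pt for pt in tiny.particles if pt[1] in diagram.circles]
    if len(keep) == 0:
        raise ValueError("diagram circles match no particles in the tiny system")
    sub = replace(tiny, particles=tuple(keep))
    fixed = None
    if diagram.white:
        fixed = _fixed_solute_positions(sub, diagram.white[0], diagram.white[1], float(r))
    edge_list = sorted(tuple(sorted(e)) for e in diagram.edges)
    total = 0.0
    ne = len(edge_list)
    for k in range(ne + 1):
        for subset in itertools.combinations(edge_list, k):
            sign = (-1) ** (ne - k)
            total += sign * _logZ(sub, subset, fixed=fixed)
    return float(total)


@dataclass
class IdentityReport:
    """Numerical comparison of two independent routes to the same profile."""

    r_grid: np.ndarray
    route_direct: np.ndarray  # anchored at r_max
    route_ccf: np.ndarray  # anchored at r_max
    max_abs_dev: float
    detail: dict = field(default_factory=dict)


def verify_jsi_ccf_identity(
    tiny: TinySystem, r_grid, solute_a: str = "A", solute_b: str = "B", solvent: str = "V"
) -> IdentityReport:
    """Check the CCF decomposition of the joint solvation interaction.

    Route 1 computes -beta F_JSI(r) directly as ln Q_full(r) - ln Q_disj(r)
    (full coupling vs duplicated-solvent disjoint coupling).  Route 2 sums
    the three cluster cumulant functions K3[D3](r) - K3[D4](r) + K2[D3](r).
    Both routes are reported anchored at the largest r, which removes the
    common constant (-ln Q_V).
    """
    r_grid = np.asarray(r_grid, dtype=float)
    labels = {lab for _, lab in tiny.particles}
    if not {solute_a, solute_b, solvent} <= labels:
        raise ValueError("tiny system must contain the two solutes and the solvent")

    # duplicated-solvent twin of the tiny system
    dup_particles = []
    for t, lab in tiny.particles:
        if lab == solvent:
            dup_particles.append((t, "W_A"))
        else:
            dup_particles.append((t, lab))
    for t, lab in tiny.particles:
        if lab == solvent:
            dup_particles.append((t, "W_B"))
    tiny_dup = replace(tiny, particles=tuple(dup_particles))

    full_edges = [(solute_a, solute_b), (solute_a, solvent), (solute_b, solvent)]
    disj_edges = [(solute_a, solute_b), (solute_a, "W_A"), (solute_b, "W_B")]

    d3 = Diagram(
        circles=(solute_a, solute_b, solvent),
        edges=frozenset(frozenset(e) for e in full_edges),
        white=(solute_a, solute_b),
    )
    d3_cav = Diagram(
        circles=(solute_a, solute_b, solvent),
        edges=frozenset({frozenset((solute_a, solvent)), frozenset((solute_b, solvent))}),
        white=(solute_a, solute_b),
    )
    d4 = Diagram(
        circles=(solute_a, solute_b, "W_A", "W_B"),
        edges=frozenset(frozenset(e) for e in disj_edges),
        white=(solute_a, solute_b),
    )

    direct = np.empty_like(r_grid)
    route2 = np.empty_like(r_grid)
    for i, r in enumerate(r_grid):
        fixed_full = _fixed_solute_positions(tiny, solute_a, solute_b, float(r))
        fixed_disj = _fixed_solute_positions(tiny_dup, solute_a, solute_b, float(r))
        ln_full = _logZ(tiny, full_edges, fixed=fixed_full)
        ln_disj = _logZ(tiny_dup, disj_edges, fixed=fixed_disj)
        direct[i] = ln_full - ln_disj
        k3_d3 = ccf(d3, tiny, r=float(r))
        k2_d3 = ccf(d3_cav, tiny, r=float(r))
        k3_d4 = ccf(d4, tiny_dup, r=float(r))
        route2[i] = k3_d3 - k3_d4 + k2_d3
    direct_a = direct - direct[-1]
    route2_a = route2 - route2[-1]
    dev = float(np.max(np.abs(direct_a - route2_a)))
    return IdentityReport(
        r_grid=r_grid,
        route_direct=direct_a,
        route_ccf=route2_a,
        max_abs_dev=dev,
        detail={"constant_direct_minus_ccf": float(np.mean(direct - route2))},
    )


@dataclass
class CollapseReport:
    """Duplicated-species quadrature vs the undivided integral, per partitioning."""

    ln_z_original: float
    partition_results: dict[str, float]
    max_abs_dev: float


def delta_line_collapse_check(
    tiny: TinySystem, species: str = "V", partner: str = "A"
) -> CollapseReport:
    """Verify that splitting one species' potential across two coordinate-
    identified copies leaves the configurational integral unchanged.

    The duplicated species' two copies share instantaneous coordinates (the
    coordinate-identification device), so any partitioning of the
    partner-species potential between the copies must reproduce the
    undivided integral.  Checked for three partitionings: everything on copy
    one, a 35/65 linear split, and a repulsive/attractive (WCA) split.
    """
    pidx = [p for p, (_, lab) in enumerate(tiny.particles) if lab == species]
    aidx = [p for p, (_, lab) in enumerate(tiny.particles) if lab == partner]
    if not pidx or not aidx:
        raise ValueError("species/partner labels not found in tiny system")
    edges = [(partner, species)]
    ln_orig = _logZ(tiny, edges)

    results: dict[str, float] = {}

    def collapsed_lnZ(split) -> float:
        # evaluate the same integral with each partner-species pair energy
        # routed through two potential partitions evaluated on the identified
        # coordinate and summed (u = u' + u'')
        override = {}
        for p in pidx:
            for a in aidx:
                t1 = tiny.particles[a][0]
                t2 = tiny.particles[p][0]

                def u_fn(r, t1=t1, t2=t2):
                    u1, u2 = split(t1, t2, r)
                    return u1 + u2

                override[frozenset((a, p))] = u_fn
        return _logZ(tiny, edges, pair_override=override)

    def split_all_copy1(t1, t2, r):
        u = _pair_u(t1, t2, r, tiny.cutoff)
        return u, np.zeros_like(u)

    def split_linear(t1, t2, r):
        u = _pair_u(t1, t2, r, tiny.cutoff)
        return 0.35 * u, 0.65 * u

    def split_wca(t1, t2, r):
        u = _pair_u(t1, t2, r, tiny.cutoff)
        sig = 0.5 * (t1.lj_sigma + t2.lj_sigma)
        eps = float(np.sqrt(t1.lj_epsilon * t2.lj_epsilon))
        rmin = 2.0 ** (1.0 / 6.0) * sig
        inside = np.asarray(r) < rmin
        rep = np.where(inside, u + eps, 0.0)
        att = np.where(inside, -eps, u)
        return rep, att

    for name, split in (
        ("all_on_copy1", split_all_copy1),
        ("linear_35_65", split_linear),
        ("wca_rep_att", split_wca),
    ):
        results[name] = collapsed_lnZ(split)

    dev = max(abs(v - ln_orig) for v in results.values())
    return CollapseReport(ln_z_original=ln_orig, partition_results=results, max_abs_dev=dev)


def binned_pair_profile(
    t1: SiteType,
    t2: SiteType,
    bin_edges,
    dimension: int,
    temperature: float,
    cutoff: float = np.inf,
    refine: int = 64,
) -> np.ndarray:
    """Expected binned PMF of an isolated interacting pair, anchored at r_max.

    The exact reference for a histogram of the pair distance: per bin,
    -kT ln of the Boltzmann-weighted shell integral over the bin, normalized
    by the shell volume (i.e. the Jacobian-corrected binned pair potential).
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    kT = float(temperature)
    vals = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        x = np.linspace(lo, hi, refine + 1)
        w = np.full(refine + 1, (hi - lo) / refine)
        w[0] *= 0.5
        w[-1] *= 0.5
        u = _pair_u(t1, t2, x, cutoff)
        shell = x ** (dimension - 1)
        num = np.sum(shell * np.exp(-u / kT) * w)
        den = np.sum(shell * w)
        vals.append(-kT * np.log(num / den))
    vals = np.asarray(vals)
    return vals - vals[-1]
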