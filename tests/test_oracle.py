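"""Quadrature oracles: configurational integrals, CCFs, exact identities."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate

from pcmc.fixtures import LJ, make_fixture
from pcmc.model import SiteType
from pcmc.oracle import (
    Diagram,
    SizeError,
    TinySystem,
    brute_logZ,
    brute_pmf,
    ccf,
    delta_line_collapse_check,
    mixing_free_energy,
    verify_jsi_ccf_identity,
)

IDEAL = SiteType(name="ideal", lj_epsilon=0.0, lj_sigma=1.0)


def tiny_1d(particles, L=10.0, h=0.1, cutoff=np.inf, periodic=True, kT=1.0):
    return TinySystem(
        dimension=1, box_length=L, temperature=kT, h=h,
        particles=tuple(particles), periodic=periodic, cutoff=cutoff,
    )


class TestBruteLogZ:
    def test_free_particle_log_volume(self):
        t = tiny_1d([(IDEAL, "A")])
        assert brute_logZ(t, []) == pytest.approx(np.log(10.0), abs=1e-12)

    def test_decoupled_particles_factorize(self):
        t = tiny_1d([(LJ, "A"), (LJ, "B")])
        lnz = brute_logZ(t, [])  # no A-B edge
        single = brute_logZ(tiny_1d([(LJ, "A")]), [])
        assert lnz == pytest.approx(2 * single, abs=1e-10)

    def test_coupled_pair_vs_adaptive_quadrature(self):
        # ring of circumference L: Z = L * int_0^L exp(-bu(min(s, L-s))) ds
        t = tiny_1d([(LJ, "A"), (LJ, "B")], h=0.05)
        lnz = brute_logZ(t, [("A", "B")])

        def integrand(s):
            r = min(s, 10.0 - s)
            return np.exp(-4.0 * (r**-12 - r**-6))

        val, _ = integrate.quad(integrand, 0.0, 10.0, limit=400,
                                points=[2 ** (1 / 6), 10 - 2 ** (1 / 6), 5.0])
        assert lnz == pytest.approx(np.log(10.0 * val), abs=1e-6)

    def test_grid_convergence_under_refinement(self):
        # convergence is super-algebraic once the core rise is resolved;
        # h = sigma/20 brings the refinement delta below 1e-6 kT
        t = tiny_1d([(LJ, "A"), (LJ, "B")], h=0.05)
        _, delta = brute_logZ(t, [("A", "B")], return_refinement=True)
        assert abs(delta) < 1e-6

    def test_node_budget_enforced(self):
        t = tiny_1d([(LJ, "A"), (LJ, "B"), (LJ, "V"), (LJ, "V")], L=10.0, h=0.1)
        with pytest.raises(SizeError):
            brute_logZ(t, [("A", "B")])

    def test_disconnected_edge_sets_factorize(self, tiny2d):
        # 2D, two particles: empty edge set = product of singles
        t = replace(tiny2d.tiny, particles=tiny2d.tiny.particles[:2])
        lnz = brute_logZ(t, [])
        s1 = brute_logZ(replace(t, particles=t.particles[:1]), [])
        s2 = brute_logZ(replace(t, particles=t.particles[1:]), [])
        assert lnz == pytest.approx(s1 + s2, abs=1e-10)


class TestBrutePMF:
    def test_no_solvent_profile_is_pair_potential(self):
        t = tiny_1d([(LJ, "A"), (LJ, "B")], cutoff=3.0)
        r = np.array([0.9, 1.2, 2.0, 3.5, 4.5])
        p = brute_pmf(t, [("A", "B")], r)
        u = np.array([4.0 * (x**-12 - x**-6) if x <= 3.0 else 0.0 for x in r])
        assert np.allclose(p.values, u - u[-1], atol=1e-8)
        assert p.jacobian_corrected

    def test_cavity_profile_finite_through_overlap(self):
        # A-B decoupled: the profile exists and is smooth below sigma_AB
        t = tiny_1d([(LJ, "A"), (LJ, "B"), (LJ, "V")], cutoff=3.0)
        r = np.array([0.1, 0.3, 0.5, 0.8, 2.0, 4.0])
        p = brute_pmf(t, [("A", "V"), ("B", "V")], r)
        assert np.all(np.isfinite(p.values))
        assert np.max(np.abs(p.values)) < 5.0

    def test_disjoint_duplicated_solvent_equals_gas(self, tiny1d):
        tiny = tiny1d.tiny
        step = tiny.box_length / round(tiny.box_length / tiny.h)
        r = step * np.arange(9, 46, 9)
        gas = brute_pmf(replace(tiny, particles=tiny.particles[:2]), [("A", "B")], r)
        dup = (
            tiny.particles[:2]
            + tuple((t, "W_A") for t, lab in tiny.particles if lab == "V")
            + tuple((t, "W_B") for t, lab in tiny.particles if lab == "V")
        )
        disj = brute_pmf(
            replace(tiny, particles=dup), [("A", "B"), ("A", "W_A"), ("B", "W_B")], r
        )
        assert np.allclose(disj.values, gas.values, atol=1e-8)


class TestMixingFreeEnergy:
    def test_zero_interactions(self):
        t = tiny_1d([(IDEAL, "A"), (IDEAL, "B")])
        assert mixing_free_energy(t, order=2) == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_in_species_exchange(self):
        t1 = tiny_1d([(LJ, "A"), (LJ, "B")], h=0.1)
        t2 = tiny_1d([(LJ, "B"), (LJ, "A")], h=0.1)
        assert mixing_free_energy(t1, 2) == pytest.approx(mixing_free_energy(t2, 2), abs=1e-12)

    def test_order3_alternating_sum_of_logz(self):
        # independent route: seven brute_logZ evaluations on sub-systems
        t = tiny_1d([(LJ, "A"), (LJ, "B"), (LJ, "V")], h=0.1, cutoff=3.0)
        f3 = mixing_free_energy(t, order=3)

        def lnz(labels):
            keep = tuple(p for p in t.particles if p[1] in labels)
            edges = list(itertools.combinations(labels, 2))
            return brute_logZ(replace(t, particles=keep), edges)

        expected = -(
            lnz(("A", "B", "V"))
            - lnz(("A", "B")) - lnz(("A", "V")) - lnz(("B", "V"))
            + lnz(("A",)) + lnz(("B",)) + lnz(("V",))
        )
        assert f3 == pytest.approx(expected, abs=1e-10)


class TestCCF:
    def test_single_edge_reduces_to_second_order_mixing(self):
        t = tiny_1d([(LJ, "A"), (LJ, "B")], h=0.1, cutoff=3.0)
        k = ccf(Diagram(circles=("A", "B"), edges=frozenset({frozenset(("A", "B"))})), t)
        f2 = mixing_free_energy(t, order=2)
        assert k == pytest.approx(-t.beta * f2, abs=1e-10)

    def test_zero_potential_edge_gives_zero(self):
        t = tiny_1d([(LJ, "A"), (IDEAL, "V")], h=0.1)
        k = ccf(Diagram(circles=("A", "V"), edges=frozenset({frozenset(("A", "V"))})), t)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_disconnected_diagram_vanishes(self):
        # two separate coupled pairs: inclusion-exclusion telescopes to zero
        t = tiny_1d([(LJ, "A"), (LJ, "B"), (LJ, "C"), (LJ, "D")], L=5.0, h=0.1)
        d = Diagram(
            circles=("A", "B", "C", "D"),
            edges=frozenset({frozenset(("A", "B")), frozenset(("C", "D"))}),
        )
        assert not d.is_connected()
        assert ccf(d, t) == pytest.approx(0.0, abs=1e-10)

    def test_triangle_expansion_reconstructs_f3(self, tiny1d):
        t = tiny1d.tiny
        f3 = mixing_free_energy(t, order=3)
        labels = ("A", "B", "V")
        all_edges = [frozenset(e) for e in itertools.combinations(labels, 2)]
        k_sum = 0.0
        for sub in (all_edges[:2], all_edges[::2], all_edges[1:], all_edges):
            k_sum += ccf(Diagram(circles=labels, edges=frozenset(sub)), t)
        assert k_sum == pytest.approx(-t.beta * f3, abs=1e-8)

    def test_white_circles_require_r(self):
        t = tiny_1d([(LJ, "A"), (LJ, "B")], h=0.1)
        d = Diagram(
            circles=("A", "B"), edges=frozenset({frozenset(("A", "B"))}), white=("A", "B")
        )
        with pytest.raises(ValueError):
            ccf(d, t)
        with pytest.raises(ValueError):
            ccf(Diagram(circles=("A", "B"), edges=frozenset({frozenset(("A", "B"))})), t, r=2.0)


class TestIdentityChecks:
    def test_jsi_ccf_identity_no_solvent_both_zero(self):
        t = tiny_1d([(LJ, "A"), (LJ, "B"), (IDEAL, "V")], h=0.1, cutoff=3.0)
        # solvent decoupled by zero potential: both routes are flat zero
        rep = verify_jsi_ccf_identity(t, np.linspace(0.9, 4.5, 5))
        assert np.allclose(rep.route_direct, 0.0, atol=1e-10)
        assert np.allclose(rep.route_ccf, 0.0, atol=1e-10)

    def test_jsi_ccf_identity_one_solvent(self, tiny1d):
        rep = verify_jsi_ccf_identity(tiny1d.tiny, np.linspace(0.9, 4.5, 9))
        assert rep.max_abs_dev < 1e-6

    def test_delta_line_collapse(self, tiny1d):
        rep = delta_line_collapse_check(tiny1d.tiny)
        assert len(rep.partition_results) >= 2
        assert rep.max_abs_dev < 1e-10

    def test_delta_line_collapse_ideal(self):
        t = tiny_1d([(IDEAL, "A"), (IDEAL, "V")], h=0.1)
        rep = delta_line_collapse_check(t)
        assert rep.ln_z_original == pytest.approx(2 * np.log(10.0), abs=1e-10)
        assert rep.max_abs_dev < 1e-12
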