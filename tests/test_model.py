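"""Energy model: pair potentials, coupling, CV, placement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcmc.fixtures import LJ, make_fixture
from pcmc.model import (
    Configuration,
    CouplingMatrix,
    CVSpec,
    DensityError,
    EnergyModel,
    MoleculeTemplate,
    OverlapError,
    SiteType,
    Species,
    StructureError,
    SystemSpec,
    build_initial,
    cv_value,
    pair_energy,
    total_energy,
)

from conftest import pair_system, single_site_species


class TestPairEnergy:
    def test_lj_root_at_sigma(self):
        assert pair_energy(LJ, LJ, r=1.0, lam=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum(self):
        rmin = 2.0 ** (1.0 / 6.0)
        assert pair_energy(LJ, LJ, rmin, lam=1.0) == pytest.approx(-1.0, rel=1e-12)

    def test_decoupled_pair_is_zero(self):
        assert pair_energy(LJ, LJ, r=0.3, lam=0.0) == 0.0
        assert pair_energy(LJ, LJ, r=0.0, lam=0.0) == 0.0  # overlap allowed

    def test_coupled_overlap_raises(self):
        with pytest.raises(OverlapError):
            pair_energy(LJ, LJ, r=0.0, lam=1.0)

    def test_beyond_cutoff_zero(self):
        assert pair_energy(LJ, LJ, r=3.5, lam=1.0, cutoff=3.0) == 0.0

    def test_lorentz_berthelot_combination(self):
        big = SiteType(name="big", lj_epsilon=4.0, lj_sigma=2.0)
        # sigma_12 = 1.5, eps_12 = 2; at the combined minimum the energy is -eps_12
        rmin = 2.0 ** (1.0 / 6.0) * 1.5
        assert pair_energy(LJ, big, rmin, lam=1.0, cutoff=10.0) == pytest.approx(-2.0)


class TestTotalEnergy:
    def test_pair_at_minimum(self):
        sys = pair_system(dim=2)
        rmin = 2.0 ** (1.0 / 6.0)
        cfg = Configuration(np.array([[1.0, 1.0], [1.0 + rmin, 1.0]]))
        assert total_energy(cfg, sys) == pytest.approx(-1.0, rel=1e-12)

    def test_decoupled_pair(self):
        sys = pair_system(dim=2, lam=0.0)
        cfg = Configuration(np.array([[1.0, 1.0], [2.0, 1.0]]))
        assert total_energy(cfg, sys) == 0.0

    def test_three_particles_vs_hand_summation(self):
        # one A, two V, all coupled: explicit independent pairwise sum
        sys = SystemSpec(
            species=(single_site_species("A", 2), single_site_species("V", 2, n=2)),
            coupling=CouplingMatrix({("A", "V"): 1.0}),
            box_length=10.0,
            temperature=1.0,
            periodic=True,
            cutoff=3.0,
            dimension=2,
        )
        pos = np.array([[1.0, 1.0], [2.1, 1.3], [9.4, 1.0]])
        cfg = Configuration(pos.copy())

        def lj(r):
            return 4.0 * (r**-12 - r**-6) if r <= 3.0 else 0.0

        def mi(d):
            return d - 10.0 * round(d / 10.0)

        expected = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.hypot(mi(pos[i, 0] - pos[j, 0]), mi(pos[i, 1] - pos[j, 1]))
                expected += lj(r)
        assert total_energy(cfg, sys) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_raises(self):
        sys = pair_system(dim=2)
        with pytest.raises(StructureError):
            total_energy(Configuration(np.zeros((3, 2))), sys)

    def test_decoupling_linearity(self):
        # lam(A,B) = 0: energy equals the sum of the two isolated subsystems
        rng = np.random.default_rng(5)
        a = Species(label="A", template=make_fixture("flexdimer2d").solute_a.template,
                    n_molecules=1)
        b = Species(label="B", template=a.template, n_molecules=1)
        v = single_site_species("V", 2, n=4)
        w = single_site_species("W", 2, n=4)
        sys_ab = SystemSpec(
            species=(a, v, b, w),
            coupling=CouplingMatrix({("A", "V"): 1.0, ("B", "W"): 1.0, ("A", "B"): 0.0}),
            box_length=10.0, temperature=1.0, periodic=True, cutoff=3.0, dimension=2,
        )
        pos = rng.uniform(0, 10, size=(12, 2))
        e_joint = total_energy(Configuration(pos.copy()), sys_ab)
        sys_a = SystemSpec(
            species=(a, v), coupling=CouplingMatrix({("A", "V"): 1.0}),
            box_length=10.0, temperature=1.0, periodic=True, cutoff=3.0, dimension=2,
        )
        sys_b = SystemSpec(
            species=(b, w), coupling=CouplingMatrix({("B", "W"): 1.0}),
            box_length=10.0, temperature=1.0, periodic=True, cutoff=3.0, dimension=2,
        )
        e_a = total_energy(Configuration(pos[:6].copy()), sys_a)
        e_b = total_energy(Configuration(pos[6:].copy()), sys_b)
        assert e_joint == pytest.approx(e_a + e_b, rel=1e-12, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_relabeling_identical_molecules(self, seed):
        # swapping two molecules of the same species leaves the energy unchanged
        sys = SystemSpec(
            species=(single_site_species("A", 2), single_site_species("V", 2, n=4)),
            coupling=CouplingMatrix({("A", "V"): 1.0}),
            box_length=10.0, temperature=1.0, periodic=True, cutoff=3.0, dimension=2,
        )
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 10, size=(5, 2))
        e1 = total_energy(Configuration(pos.copy()), sys)
        swapped = pos.copy()
        swapped[[1, 3]] = swapped[[3, 1]]
        e2 = total_energy(Configuration(swapped), sys)
        assert e1 == pytest.approx(e2, rel=1e-12, abs=1e-12)

    @given(st.floats(-20, 20), st.floats(-20, 20))
    @settings(max_examples=20, deadline=None)
    def test_translational_invariance_nonperiodic(self, dx, dy):
        sys = pair_system(dim=2, periodic=False)
        rng = np.random.default_rng(1)
        pos = rng.uniform(2, 8, size=(2, 2))
        e1 = total_energy(Configuration(pos.copy()), sys)
        e2 = total_energy(Configuration(pos + np.array([dx, dy])), sys)
        assert e1 == pytest.approx(e2, rel=1e-10, abs=1e-10)

    def test_lattice_translation_invariance_periodic(self):
        sys = pair_system(dim=2, periodic=True, box=10.0)
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 10, size=(2, 2))
        e1 = total_energy(Configuration(pos.copy()), sys)
        e2 = total_energy(Configuration(pos + 10.0), sys)
        assert e1 == pytest.approx(e2, rel=1e-10)


class TestCV:
    def test_simple_distance(self):
        sys = pair_system(dim=3, periodic=False)
        cfg = Configuration(np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]))
        assert cv_value(cfg, sys) == pytest.approx(3.0)

    def test_minimum_image(self):
        sys = pair_system(dim=3, box=10.0, periodic=True)
        cfg = Configuration(np.array([[0.0, 0.0, 0.0], [9.0, 0.0, 0.0]]))
        assert cv_value(cfg, sys) == pytest.approx(1.0)

    def test_com_arithmetic(self):
        two = MoleculeTemplate(sites=(LJ, LJ), geometry=((0.0, 0.0, 0.0), (2.0, 0.0, 0.0)))
        sys = SystemSpec(
            species=(
                Species(label="A", template=two, n_molecules=1),
                single_site_species("B", 3),
            ),
            coupling=CouplingMatrix({("A", "B"): 1.0}),
            box_length=20.0,
            temperature=1.0,
            cv=CVSpec(kind="com_distance", species_a="A", species_b="B"),
            periodic=False,
            cutoff=3.0,
            dimension=3,
        )
        cfg = Configuration(
            np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        )
        assert cv_value(cfg, sys) == pytest.approx(4.0)


class TestBuildInitial:
    def test_coupled_overlap_rejection(self):
        fx = make_fixture("sph2d", n_v=20, seed=0)
        sys = fx.system("FULL")
        cfg = build_initial(sys, seed=4)
        model = EnergyModel(sys)
        r = model.distances(cfg.positions, cfg.positions)
        lam = model.lam_ij
        np.fill_diagonal(r, np.inf)
        assert np.all(r[lam > 0] >= 0.7 * model.sig_ij[lam > 0] - 1e-12)

    def test_disjoint_decoupled_may_overlap(self):
        fx = make_fixture("sph2d", n_v=30, seed=0)
        sys = fx.system("DISJOINT")
        cfg = build_initial(sys, seed=8)
        model = EnergyModel(sys)
        r = model.distances(cfg.positions, cfg.positions)
        np.fill_diagonal(r, np.inf)
        lam = model.lam_ij
        # coupled pairs respect the criterion ...
        assert np.all(r[lam > 0] >= 0.7 * model.sig_ij[lam > 0] - 1e-12)
        # ... while some decoupled (W_A, W_B) pair sits closer than it
        wa = model.species_site_index["W_A"]
        wb = model.species_site_index["W_B"]
        assert np.min(r[np.ix_(wa, wb)]) < 0.7

    def test_same_seed_identical(self):
        fx = make_fixture("sph2d", n_v=10, seed=0)
        sys = fx.system("FULL")
        c1 = build_initial(sys, seed=9)
        c2 = build_initial(sys, seed=9)
        assert np.array_equal(c1.positions, c2.positions)

    def test_density_error(self):
        # 60 coupled disks cannot fit a 6.2-sigma box at 0.7 sigma separation
        sys = SystemSpec(
            species=(single_site_species("A", 2), single_site_species("V", 2, n=60)),
            coupling=CouplingMatrix({("A", "V"): 1.0}),
            box_length=6.2, temperature=1.0, periodic=True, cutoff=3.0, dimension=2,
        )
        with pytest.raises(DensityError):
            build_initial(sys, seed=0, max_retries=30, max_restarts=3)

    def test_cv_target_respected(self):
        fx = make_fixture("sph2d", n_v=10, seed=0)
        sys = fx.system("FULL")
        cfg = build_initial(sys, seed=1, cv_target=2.5)
        assert cv_value(cfg, sys) == pytest.approx(2.5, abs=1e-9)


class TestRigidTemplates:
    def test_rigid_with_bonds_rejected(self):
        from pcmc.model import Bond

        with pytest.raises(ValueError):
            MoleculeTemplate(
                sites=(LJ, LJ),
                geometry=((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
                bonds=(Bond(0, 1, 10.0, 1.0),),
                rigid=True,
            )

    def test_rigid_geometry_preserved_by_moves(self):
        from pcmc.sampler import BiasSpec, MoveSet, metropolis_step

        fx = make_fixture("dumbbell3d", n_v=0, seed=0)
        sys = fx.system("GAS")
        cfg = build_initial(sys, seed=2, cv_target=1.5)
        rng = np.random.default_rng(0)
        moves = MoveSet(max_translation=0.4, max_rotation=0.8)
        for _ in range(150):
            cfg, _ = metropolis_step(cfg, sys, moves, BiasSpec(), rng)
        for sl in (slice(0, 2), slice(2, 4)):
            d = np.linalg.norm(cfg.positions[sl][0] - cfg.positions[sl][1])
            assert d == pytest.approx(0.5, rel=1e-10)


class TestCouplingMatrix:
    def test_symmetry(self):
        cm = CouplingMatrix({("A", "B"): 0.5})
        assert cm.lam("B", "A") == 0.5

    def test_diagonal_not_storable(self):
        with pytest.raises(ValueError):
            CouplingMatrix({("A", "A"): 1.0})

    def test_default_decoupled(self):
        cm = CouplingMatrix({})
        assert cm.lam("A", "B") == 0.0
        assert cm.lam("A", "A") == 1.0
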