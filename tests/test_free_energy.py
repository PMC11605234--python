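"""PMF estimators: histogram, WHAM, Jacobian correction, block errors."""

import numpy as np
import pytest

from pcmc.free_energy import (
    CoverageError,
    DegenerateProfileError,
    PMFProfile,
    block_error,
    histogram_pmf,
    jacobian_correct,
    subtract,
    wham,
)
from pcmc.sampler import BiasSpec

from conftest import synthetic_samples


def _finite_dev(p: PMFProfile, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = p.mask & np.isfinite(ref)
    return (p.values - ref)[m], p.errors[m]


class TestHistogramPMF:
    def test_uniform_samples_flat(self):
        rng = np.random.default_rng(0)
        s = synthetic_samples(rng.uniform(1.0, 3.0, 40_000), seed=0)
        p = histogram_pmf(s, bins=np.linspace(1.0, 3.0, 21))
        dev = p.values[p.mask]
        err = p.errors[p.mask]
        assert np.all(np.abs(dev) <= np.maximum(3 * err, 0.02) + 1e-12)

    def test_double_well_density_recovered(self):
        # inverse-CDF samples from p(x) ~ exp(-(x^2-1)^2): -ln p within 3 sigma
        rng = np.random.default_rng(1)
        x = np.linspace(-2.2, 2.2, 4001)
        logp = -((x**2 - 1.0) ** 2)
        pdf = np.exp(logp)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        samples = np.interp(rng.uniform(size=60_000), cdf, x)
        s = synthetic_samples(samples, seed=1)
        edges = np.linspace(-2.0, 2.0, 25)
        p = histogram_pmf(s, bins=edges)
        # exact binned reference: -ln of the generating density mass per bin
        mass = np.array(
            [np.trapezoid(pdf[(x >= lo) & (x <= hi)], x[(x >= lo) & (x <= hi)])
             for lo, hi in zip(edges[:-1], edges[1:])]
        )
        mass /= np.trapezoid(pdf[(x >= edges[0]) & (x <= edges[-1])],
                             x[(x >= edges[0]) & (x <= edges[-1])])
        ref = -np.log(mass)
        ref = ref - ref[np.max(np.nonzero(p.mask))]
        dev, err = _finite_dev(p, ref)
        assert np.all(np.abs(dev) <= np.maximum(3 * err, 0.03))

    def test_biased_samples_rejected(self):
        s = synthetic_samples(np.linspace(0, 1, 100), bias=BiasSpec("harmonic", 10.0, 0.5))
        with pytest.raises(ValueError):
            histogram_pmf(s)

    def test_degenerate_single_bin(self):
        s = synthetic_samples(np.full(1000, 1.5), seed=0)
        with pytest.raises(DegenerateProfileError):
            histogram_pmf(s, bins=np.linspace(0, 3, 10))


class TestWHAM:
    def test_single_unbiased_window_equals_histogram(self):
        rng = np.random.default_rng(2)
        s = synthetic_samples(rng.normal(2.0, 0.5, 30_000), seed=2)
        edges = np.linspace(0.5, 3.5, 31)
        ph = histogram_pmf(s, bins=edges)
        pw = wham([s], bins=edges)
        m = ph.mask & pw.mask
        assert np.allclose(ph.values[m], pw.values[m], atol=1e-12)

    def test_two_windows_flat_landscape(self):
        # flat underlying free energy: window samples are pure bias Boltzmann
        rng = np.random.default_rng(3)
        k = 8.0
        wins = []
        for i, r0 in enumerate((1.5, 2.1)):
            cv = rng.normal(r0, np.sqrt(1.0 / k), 20_000)
            wins.append(
                synthetic_samples(cv, seed=10 + i, bias=BiasSpec("harmonic", k, r0))
            )
        p = wham(wins, bins=np.linspace(1.0, 2.6, 25))
        dev = p.values[p.mask]
        err = p.errors[p.mask]
        assert np.all(np.abs(dev) <= np.maximum(3 * err, 0.05))

    def test_five_windows_recover_parabola(self):
        # F(x) = x^2/2; window k biased samples are exact Gaussians
        rng = np.random.default_rng(4)
        k = 10.0
        wins = []
        for i, r0 in enumerate(np.linspace(-2.0, 2.0, 5)):
            var = 1.0 / (1.0 + k)
            mean = k * r0 / (1.0 + k)
            cv = rng.normal(mean, np.sqrt(var), 25_000)
            wins.append(
                synthetic_samples(cv, seed=20 + i, bias=BiasSpec("harmonic", k, r0))
            )
        edges = np.linspace(-2.2, 2.2, 33)
        p = wham(wins, bins=edges)
        ref = 0.5 * p.grid**2
        ref = ref - ref[np.max(np.nonzero(p.mask))]
        dev, err = _finite_dev(p, ref)
        assert np.all(np.abs(dev) <= np.maximum(3 * err, 0.06))

    def test_window_permutation_invariance(self):
        rng = np.random.default_rng(5)
        k = 10.0
        wins = []
        for i, r0 in enumerate((1.0, 1.5, 2.0)):
            cv = rng.normal(r0, np.sqrt(1.0 / k), 10_000)
            wins.append(
                synthetic_samples(cv, seed=30 + i, bias=BiasSpec("harmonic", k, r0))
            )
        edges = np.linspace(0.6, 2.4, 20)
        p1 = wham(wins, bins=edges)
        p2 = wham(wins[::-1], bins=edges)
        m = p1.mask & p2.mask
        assert np.allclose(p1.values[m], p2.values[m], atol=1e-6)

    def test_non_overlapping_windows_raise(self):
        rng = np.random.default_rng(6)
        w1 = synthetic_samples(
            rng.normal(1.0, 0.05, 5000), seed=40, bias=BiasSpec("harmonic", 400.0, 1.0)
        )
        w2 = synthetic_samples(
            rng.normal(3.0, 0.05, 5000), seed=41, bias=BiasSpec("harmonic", 400.0, 3.0)
        )
        with pytest.raises(CoverageError):
            wham([w1, w2], bins=np.linspace(0.5, 3.5, 40))


class TestJacobian:
    def test_1d_identity(self):
        rng = np.random.default_rng(7)
        s = synthetic_samples(rng.uniform(1, 3, 20_000), seed=7, dimension=1)
        p = histogram_pmf(s, bins=np.linspace(1, 3, 15))
        q = jacobian_correct(p)
        assert np.allclose(q.values[q.mask], p.values[p.mask], atol=1e-12)
        assert q.jacobian_corrected

    def test_3d_ideal_pair_flat_after_correction(self):
        # p(r) ~ r^2 for a noninteracting pair: corrected profile is flat
        rng = np.random.default_rng(8)
        u = rng.uniform(size=120_000)
        lo, hi = 1.0, 3.0
        r = (lo**3 + u * (hi**3 - lo**3)) ** (1.0 / 3.0)
        s = synthetic_samples(r, seed=8, dimension=3)
        p = histogram_pmf(s, bins=np.linspace(lo, hi, 21))
        q = jacobian_correct(p)
        dev = q.values[q.mask]
        err = q.errors[q.mask]
        assert np.all(np.abs(dev) <= np.maximum(3 * err, 0.03))

    def test_2d_ideal_pair_slope_removed(self):
        # raw profile of p(r) ~ r is -ln(2 pi r) + const; correction removes it
        rng = np.random.default_rng(9)
        u = rng.uniform(size=120_000)
        lo, hi = 1.0, 3.0
        r = np.sqrt(lo**2 + u * (hi**2 - lo**2))
        s = synthetic_samples(r, seed=9, dimension=2)
        p = histogram_pmf(s, bins=np.linspace(lo, hi, 21))
        ref = -np.log(p.grid)
        ref = ref - ref[np.max(np.nonzero(p.mask))]
        dev, err = _finite_dev(p, ref)
        # floor absorbs the ~25% spread of 10-block bootstrap sigma estimates
        assert np.all(np.abs(dev) <= np.maximum(3 * err, 0.04))
        q = jacobian_correct(p)
        assert np.all(np.abs(q.values[q.mask]) <= np.maximum(3 * q.errors[q.mask], 0.04))

    def test_idempotence_error(self):
        rng = np.random.default_rng(10)
        s = synthetic_samples(rng.uniform(1, 3, 5000), seed=10, dimension=3)
        q = jacobian_correct(histogram_pmf(s, bins=np.linspace(1, 3, 10)))
        with pytest.raises(ValueError):
            jacobian_correct(q)


class TestSubtract:
    def _profile(self, vals, grid=None):
        vals = np.asarray(vals, dtype=float)
        g = np.arange(len(vals), dtype=float) if grid is None else grid
        return PMFProfile(
            grid=g, values=vals, errors=np.full(len(vals), 0.1),
            n_samples=np.full(len(vals), 100), anchor="raw", dimension=3,
        )

    def test_self_subtraction_zero(self):
        p = self._profile([3.0, 2.0, 1.0, 0.5])
        d = subtract(p, p)
        assert np.allclose(d.values, 0.0)
        assert np.allclose(d.errors, 0.1 * np.sqrt(2))

    def test_constant_offset_reanchored(self):
        p = self._profile([3.0, 2.0, 1.0, 0.5])
        flat = self._profile([7.0, 7.0, 7.0, 7.0])
        d = subtract(p, flat)
        assert np.allclose(d.values, p.values - 0.5)

    def test_grid_mismatch_raises(self):
        p = self._profile([1.0, 2.0])
        q = self._profile([1.0, 2.0], grid=np.array([0.0, 1.5]))
        with pytest.raises(ValueError):
            subtract(p, q)

    def test_anchoring_invariance_of_differences(self):
        # adding any constant to either input leaves the difference unchanged
        rng = np.random.default_rng(11)
        v1, v2 = rng.normal(size=8), rng.normal(size=8)
        p1, p2 = self._profile(v1), self._profile(v2)
        base = subtract(p1, p2)
        shifted = subtract(self._profile(v1 + 5.3), self._profile(v2 - 2.1))
        assert np.allclose(base.values, shifted.values, atol=1e-12)


class TestBlockError:
    def test_iid_gaussian(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0.0, 2.0, 40_000)
        se = block_error(x, block_len=100)
        expected = 2.0 / np.sqrt(40_000)
        assert se == pytest.approx(expected, rel=0.2)

    def test_ar1_matches_closed_form(self):
        # AR(1) with coefficient phi: var(mean) = s^2 (1+phi)/(1-phi) / n
        rng = np.random.default_rng(13)
        phi, n = 0.9, 400_000
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        s2 = 1.0 / (1.0 - phi**2)
        expected = np.sqrt(s2 * (1 + phi) / (1 - phi) / n)
        se = block_error(x, block_len=4000)  # blocks >> correlation time
        assert se == pytest.approx(expected, rel=0.25)

    def test_constant_series(self):
        assert block_error(np.full(5000, 3.7), block_len=100) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_blocks(self):
        with pytest.raises(ValueError):
            block_error(np.arange(100), block_len=50)
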