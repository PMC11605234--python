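"""Potential-of-mean-force estimation from (biased) sample sets.

Implements binned histogram PMFs, the self-consistent weighted histogram
analysis method (WHAM) for combining harmonic umbrella windows, the
radial-Jacobian correction, profile subtraction, and block-averaged error
estimates.  All free energies are in kT; profiles are anchored to zero at the
largest sampled CV value (every solvent-induced interaction studied here
vanishes at large separation, so differences of anchored profiles are the
physically meaningful quantities).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "PMFProfile",
    "CoverageError",
    "ConvergenceError",
    "DegenerateProfileError",
    "histogram_pmf",
    "wham",
    "jacobian_correct",
    "subtract",
    "block_error",
    "MIN_BIN_COUNT",
]

MIN_BIN_COUNT = 10  # bins with fewer total counts are masked, not extrapolated


class CoverageError(ValueError):
    """Umbrella windows do not overlap: the profile cannot be stitched."""


class ConvergenceError(RuntimeError):
    """WHAM iteration hit max_iter before reaching the tolerance."""


class DegenerateProfileError(ValueError):
    """All samples fell into a single bin; no profile can be resolved."""


@dataclass
class PMFProfile:
    """Free energy versus collective variable on a fixed grid (kT units).

    Masked (undersampled) bins carry NaN in ``values`` and ``errors``.
    """

    grid: np.ndarray  # bin centers, strictly increasing
    values: np.ndarray  # kT
    errors: np.ndarray  # per-bin standard error, kT
    n_samples: np.ndarray  # counts contributing per bin
    anchor: str = "zero_at_rmax"  # or "raw"
    jacobian_corrected: bool = False
    dimension: int = 3

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        self.n_samples = np.asarray(self.n_samples)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("profile grid must be strictly increasing")
        if not (self.grid.shape == self.values.shape == self.errors.shape):
            raise ValueError("grid/values/errors shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.any(self.errors < 0):
                raise ValueError("errors must be nonnegative")

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is defined (finite value)."""
        return np.isfinite(self.values)

    def anchored(self) -> "PMFProfile":
        """Return a copy anchored to zero at the largest defined bin."""
        m = self.mask
        if not np.any(m):
            raise DegenerateProfileError("no defined bins to anchor")
        ref = self.values[np.max(np.nonzero(m))]
        return replace(
            self, values=self.values - ref, errors=self.errors.copy(), anchor="zero_at_rmax"
        )

    def copy(self) -> "PMFProfile":
        return replace(
            self,
            grid=self.grid.copy(),
            values=self.values.copy(),
            errors=self.errors.copy(),
            n_samples=self.n_samples.copy(),
        )


# ---------------------------------------------------------------------------
# helpers


def _bin_edges(bins, samples_list: Sequence[np.ndarray]) -> np.ndarray:
    if np.ndim(bins) == 1 and np.size(bins) > 1:
        edges = np.asarray(bins, dtype=float)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        return edges
    n = int(bins)
    lo = min(float(np.min(s)) for s in samples_list)
    hi = max(float(np.max(s)) for s in samples_list)
    if hi <= lo:
        raise DegenerateProfileError("zero sample range: cannot bin")
    return np.linspace(lo, hi * (1 + 1e-12), n + 1)


def _counts(cv: np.ndarray, edges: np.ndarray) -> np.ndarray:
    c, _ = np.histogram(cv, bins=edges)
    return c.astype(float)


def _profile_from_counts(counts: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    with np.errstate(divide="ignore"):
        vals = -np.log(counts / total)
    vals[counts < MIN_BIN_COUNT] = np.nan
    return centers, vals


def _block_indices(n: int, block_len: int) -> list[np.ndarray]:
    nb = n // block_len
    return [np.arange(k * block_len, (k + 1) * block_len) for k in range(nb)]


# ---------------------------------------------------------------------------
# estimators


def histogram_pmf(samples, bins=60, block_len: int | None = None) -> PMFProfile:
    """PMF from an unbiased sample set: F_i = -ln(count_i / total), in kT.

    Per-bin standard errors come from a block bootstrap of the (correlated)
    CV series; bins with fewer than MIN_BIN_COUNT samples are masked.
    """
    if samples.bias is not None and samples.bias.kind != "none":
        raise ValueError("histogram_pmf requires unbiased samples; use wham for windows")
    cv = np.asarray(samples.cv_samples, dtype=float)
    edges = _bin_edges(bins, [cv])
    counts = _counts(cv, edges)
    if np.sum(counts > 0) <= 1:
        raise DegenerateProfileError("all samples fell into one bin")
    centers, vals = _profile_from_counts(counts, edges)

    # block bootstrap errors
    n = cv.size
    if block_len is None:
        block_len = max(1, n // 10)
    blocks = _block_indices(n, block_len)
    rng = np.random.default_rng((int(samples.seed) * 2654435761 + 101) % (2**31))
    boots = []
    anchor_idx = int(np.max(np.nonzero(np.isfinite(vals))))
    for _ in range(50):
        pick = rng.integers(0, len(blocks), size=len(blocks))
        sel = np.concatenate([blocks[k] for k in pick])
        c_b = _counts(cv[sel], edges)
        with np.errstate(divide="ignore"):
            v_b = -np.log(c_b / c_b.sum())
        v_b[c_b == 0] = np.nan
        ref = v_b[anchor_idx]
        boots.append(v_b - ref)
    boots = np.asarray(boots)
    boots[~np.isfinite(boots)] = np.nan
    n_finite = np.sum(np.isfinite(boots), axis=0)
    err = np.full(vals.size, np.nan)
    cols = n_finite >= 2
    err[cols] = np.nanstd(boots[:, cols], axis=0, ddof=1)
    vals[n_finite < 25] = np.nan
    err[~np.isfinite(vals)] = np.nan

    prof = PMFProfile(
        grid=centers,
        values=vals,
        errors=err,
        n_samples=counts.astype(int),
        anchor="raw",
        jacobian_corrected=False,
        dimension=samples_dimension(samples),
    )
    return prof.anchored()


def samples_dimension(samples) -> int:
    return int(getattr(samples, "dimension", 3))


def _wham_solve(
    n_ik: np.ndarray,  # (n_bins, n_windows) counts
    b_ik: np.ndarray,  # (n_bins, n_windows) -beta * w_k(x_i)
    tol: float,
    max_iter: int,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Self-consistent WHAM iteration; returns (ln_rho, f, iters, residual)."""
    n_bins, n_win = n_ik.shape
    N_k = n_ik.sum(axis=0)
    M_i = n_ik.sum(axis=1)
    with np.errstate(divide="ignore"):
        ln_M = np.log(M_i)
        ln_N = np.log(N_k)
    f = np.zeros(n_win) if f_init is None else f_init.copy()
    occupied = M_i > 0
    resid = np.inf
    it = 0
    for it in range(1, int(max_iter) + 1):
        # ln rho_i = ln M_i - logsumexp_k(ln N_k + f_k + b_ik)
        den = logsumexp(ln_N[None, :] + f[None, :] + b_ik, axis=1)
        ln_rho = np.where(occupied, ln_M - den, -np.inf)
        f_new = -logsumexp(ln_rho[:, None] + b_ik, axis=0)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f) / np.maximum(1.0, np.abs(f_new))))
        f = f_new
        if resid < tol:
            break
    return ln_rho, f, it, resid


def wham(
    window_sets: Sequence,
    bins=60,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    n_bootstrap: int = 50,
    block_len: int | None = None,
) -> PMFProfile:
    """Combine harmonically biased umbrella windows into one PMF (kT units).

    Standard binned self-consistent WHAM.  A single unbiased window reduces
    exactly to :func:`histogram_pmf`.  Per-bin errors come from a per-window
    block bootstrap (>= ``n_bootstrap`` resamples), re-solving the WHAM
    equations hot-started from the converged window free energies.
    """
    if len(window_sets) == 0:
        raise ValueError("wham requires at least one window")
    temps = {float(w.temperature) for w in window_sets}
    if len(temps) != 1:
        raise ValueError("all windows must share one temperature")
    beta = 1.0 / temps.pop()
    cvs = [np.asarray(w.cv_samples, dtype=float) for w in window_sets]
    edges = _bin_edges(bins, cvs)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = centers.size

    def bias_log_weight(w) -> np.ndarray:
        if w.bias is None or w.bias.kind == "none":
            return np.zeros(n_bins)
        return -beta * 0.5 * w.bias.k_umb * (centers - w.bias.r0) ** 2

    n_ik = np.stack([_counts(cv, edges) for cv in cvs], axis=1)
    b_ik = np.stack([bias_log_weight(w) for w in window_sets], axis=1)

    # coverage: windows must form one connected component through occupied bins
    occ = n_ik > 0
    n_win = len(window_sets)
    adj = [(occ[:, a] & occ[:, b]).any() for a in range(n_win) for b in range(n_win)]
    adj = np.asarray(adj).reshape(n_win, n_win)
    seen = {0}
    frontier = [0]
    while frontier:
        k = frontier.pop()
        for m in range(n_win):
            if adj[k, m] and m not in seen:
                seen.add(m)
                frontier.append(m)
    if len(seen) != n_win:
        missing = sorted(set(range(n_win)) - seen)
        raise CoverageError(f"windows {missing} share no occupied bin with window 0")

    ln_rho, f, iters, resid = _wham_solve(n_ik, b_ik, tol, max_iter)
    if resid >= tol:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {resid:.3e})"
        )

    M_i = n_ik.sum(axis=1)
    vals = -ln_rho
    vals[M_i < MIN_BIN_COUNT] = np.nan
    if np.sum(np.isfinite(vals)) <= 1:
        raise DegenerateProfileError("all samples fell into one bin")
    anchor_idx = int(np.max(np.nonzero(np.isfinite(vals))))
    vals = vals - vals[anchor_idx]

    # block-bootstrap errors
    seeds = sum(int(getattr(w, "seed", 0)) for w in window_sets)
    rng = np.random.default_rng((seeds * 2654435761 + 977) % (2**31))
    boots = []
    blocks_per_win = []
    for cv in cvs:
        bl = block_len if block_len is not None else max(1, cv.size // 10)
        blocks_per_win.append(_block_indices(cv.size, bl))
    for _ in range(n_bootstrap):
        cols = []
        for cv, blocks in zip(cvs, blocks_per_win):
            pick = rng.integers(0, len(blocks), size=len(blocks))
            sel = np.concatenate([blocks[k] for k in pick])
            cols.append(_counts(cv[sel], edges))
        n_b = np.stack(cols, axis=1)
        ln_rho_b, _, _, _ = _wham_solve(n_b, b_ik, max(tol, 1e-7), 5000, f_init=f)
        v_b = -ln_rho_b
        v_b = v_b - v_b[anchor_idx] if np.isfinite(v_b[anchor_idx]) else v_b * np.nan
        boots.append(v_b)
    boots = np.asarray(boots)
    boots[:, ~np.isfinite(vals)] = np.nan
    boots[~np.isfinite(boots)] = np.nan
    n_finite = np.sum(np.isfinite(boots), axis=0)
    err = np.full(vals.size, np.nan)
    cols = n_finite >= 2
    err[cols] = np.nanstd(boots[:, cols], axis=0, ddof=1)
    # bins the bootstrap cannot resolve are masked rather than reported with
    # an unreliable error bar
    unstable = n_finite < max(10, n_bootstrap // 2)
    vals[unstable] = np.nan
    err[~np.isfinite(vals)] = np.nan
    if not np.any(np.isfinite(vals)):
        raise DegenerateProfileError("no bin survived the bootstrap stability filter")
    vals = vals - vals[np.max(np.nonzero(np.isfinite(vals)))]

    dim = samples_dimension(window_sets[0])
    return PMFProfile(
        grid=centers,
        values=vals,
        errors=err,
        n_samples=M_i.astype(int),
        anchor="zero_at_rmax",
        jacobian_corrected=False,
        dimension=dim,
    )


# ---------------------------------------------------------------------------
# profile arithmetic


def jacobian_correct(p: PMFProfile) -> PMFProfile:
    """Remove the radial shell-volume term: F_corr = F_raw + (d-1) ln r.

    The raw -ln P(r) of a distance CV in d dimensions contains a
    -(d-1) ln r entropy term from the volume of the spherical shell; removing
    it yields the orientation-fixed profile comparable with quadrature.  In
    1D the correction is the identity.
    """
    if p.jacobian_corrected:
        raise ValueError("profile is already Jacobian-corrected")
    if np.any(p.grid <= 0):
        raise ValueError("Jacobian correction requires a strictly positive distance grid")
    corr = (p.dimension - 1) * np.log(p.grid)
    out = replace(p, values=p.values + corr, jacobian_corrected=True)
    return out.anchored() if p.anchor == "zero_at_rmax" else out


def subtract(p1: PMFProfile, p2: PMFProfile) -> PMFProfile:
    """p1 - p2 bin-wise; errors in quadrature; re-anchored at the largest bin.

    Grids must be identical (no silent interpolation) and both profiles must
    carry the same Jacobian convention (the correction cancels in differences
    only when it is the same on both sides).
    """
    if p1.grid.shape != p2.grid.shape or not np.allclose(p1.grid, p2.grid, rtol=0, atol=1e-12):
        raise ValueError("profile grids differ; refusing to interpolate")
    if p1.jacobian_corrected != p2.jacobian_corrected:
        raise ValueError("profiles carry different Jacobian conventions")
    vals = p1.values - p2.values
    errs = np.sqrt(p1.errors**2 + p2.errors**2)
    out = PMFProfile(
        grid=p1.grid.copy(),
        values=vals,
        errors=errs,
        n_samples=np.minimum(p1.n_samples, p2.n_samples),
        anchor="raw",
        jacobian_corrected=p1.jacobian_corrected,
        dimension=p1.dimension,
    )
    return out.anchored()


def block_error(samples, block_len: int) -> float:
    """Standard error of the mean from block averaging.

    Requires at least 10 blocks; for correlated series the estimate grows
    with block_len until blocks exceed the correlation time.
    """
    x = np.asarray(samples, dtype=float)
    nb = x.size // int(block_len)
    if nb < 10:
        raise ValueError(f"only {nb} blocks of length {block_len}; need >= 10")
    means = x[: nb * block_len].reshape(nb, block_len).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(nb))
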