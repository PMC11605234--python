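# Methods

## The decomposition

The net interaction between two solutes A and B in a solvent V, as a
function of a collective variable R (here the A–B center-of-mass or
site–site distance), contains the direct potential plus solvent-mediated
contributions.  This package computes the pieces of that interaction by
simulating four *couplings* of the same species — the physical system and
three partially connected reference systems — and differencing their free
energy profiles:

| scheme   | species           | couplings switched on                  |
|----------|-------------------|----------------------------------------|
| FULL     | A, B, V           | (A,B), (A,V), (B,V)                    |
| GAS      | A, B              | (A,B)                                  |
| CAVITY   | A, B, V           | (A,V), (B,V) — solutes do not interact |
| DISJOINT | A, B, W_A, W_B    | (A,B), (A,W_A), (B,W_B)                |

Here W_A and W_B are two instances of the solvent placed in the *same* box;
since their mutual coupling is off they interpenetrate freely, and each
solute carries its own solvation environment while the solutes still
interact directly.  From the anchored profiles F_scheme(R):

* **SII** (total solvent-induced interaction) = F_full − F_gas.
* **JSI** (joint solvation interaction)       = F_full − F_disjoint:
  the thermodynamic effect of the solvent accommodating both solutes
  *simultaneously*, isolated from solvation-induced conformational effects.
* **cavity interaction** = the anchored CAVITY profile, −kT ln y(R) up to a
  constant, where y is the indirect correlation function.
* **conformational component** = SII − JSI (bin-wise algebra; exact by
  construction in the pipeline).

All these quantities are defined up to additive constants; every profile is
anchored to zero at the largest sampled separation, where all the
interactions above vanish, so differences of anchored profiles are the
meaningful objects and any constant offset cancels (a property the test
suite asserts).

Exact relations the implementation is validated against:

* spherical solutes: F_disjoint = F_gas + const, hence JSI = SII;
* rigid solutes: the same equivalence (solvating a rigid molecule
  contributes only a constant, because the solvent integral factors out of
  the orientation/COM integral);
* spherical closure: F_full = F_cavity + u(R) + const (g = y·e^(−βu));
* the cluster-cumulant decomposition of the JSI (below);
* SII ≡ JSI + conformational.

## Coupling model

Interactions are strictly pairwise site–site: truncated, unshifted
Lennard-Jones with Lorentz–Berthelot combination, plus an optional plain
Coulomb term permitted only in nonperiodic boxes (no Ewald machinery; the
validation systems need only short-ranged potentials, and truncation
constants cancel in anchored differences).  A symmetric species-pair matrix
λ(A,B) ∈ [0,1] scales every site pair between two species; λ = 0 removes
the interaction entirely, which is what makes the unphysical reference
couplings ordinary simulations.  Intra-species interactions are always
fully on; sites joined by a bond within one molecule are excluded from the
nonbonded sum (1–2 exclusion).

Reduced units throughout: lengths in σ, energies in kT (temperature enters
only as β = 1/kT).  There are no masses — every free energy here is a
configurational integral, so center-of-mass coordinates use unweighted site
means.

## Sampling

Metropolis Monte Carlo with single-molecule moves: whole-molecule
translations, rigid-body rotations (axis–angle with the angle uniform in
±max, symmetric under inversion), and single-site displacements for
flexible molecules.  An optional harmonic umbrella restraint
½·k_umb·(s − r₀)² acts on the collective variable.  Move amplitudes adapt
toward a 40% acceptance rate **per species** during equilibration and are
frozen for production, so the production chain satisfies detailed balance.
Per-species adaptation matters: a free (e.g. ideal-gas) solvent drives a
shared step size to box scale, which freezes a restrained solute; with
per-species steps each species finds its own scale.

Energies are tracked incrementally per move and resynchronized against a
full recomputation every 4000 steps.  Every run is reproducible bit-for-bit
from its seed; sample sets are stamped with the seed and a content hash of
the system definition.

## Free-energy estimation

Umbrella windows are combined by standard binned self-consistent WHAM
(relative tolerance 1e-8, iteration cap 1e5); a single unbiased window
reduces exactly to the histogram estimator −ln(nᵢ/N).  Bins with fewer than
10 total counts are masked, never extrapolated.  Per-bin standard errors
come from a per-window block bootstrap (50 resamples, blocks of 1/10 of
each window's samples — the largest block size that leaves ten blocks, since
block-length scans on the solvated fixtures show the standard error still
rising at smaller blocks — with WHAM re-solved hot-started from the
converged window free energies); bins that fewer than half the resamples
can resolve are masked as well.  For strongly correlated chains the
bootstrap can still underestimate errors somewhat; the honest remedy is a
longer run, not a smaller block.

A distance CV in d dimensions carries a shell-volume term: the raw
−kT ln P(R) equals the orientation-fixed profile minus (d−1)·kT·ln R.
`jacobian_correct` adds that term back.  Both conventions are exposed;
every decomposition output is a difference in which the choice cancels, and
a test asserts that JSI from raw profiles equals JSI from corrected ones.

Umbrella windows are placed so that their centers span the full binned
range (lowest window at the lowest bin edge); windows that do not reach the
repulsive wall leave the wall bins sampled only by restraint tails, with
unreliable bootstrap errors.

## Quadrature oracles

Every estimator is validated against dense trapezoid-grid quadrature of
micro-systems (≤4 mobile single-site particles, 1D/2D, ≤10⁷ nodes):

* `brute_logZ` — ln ∫ e^(−βV) over all particle coordinates for an
  arbitrary subset of coupling edges; periodic grids use the uniform-weight
  (rectangle) rule, open boxes the trapezoid rule.
* `brute_pmf` — the constrained profile with solutes held fixed (A at a
  grid-snapped box center, B at separation r along x), i.e. the
  orientation-fixed, Jacobian-corrected profile.
* `cv_density` — the *exact expectation of a binned, sampled histogram*:
  per bin, ∫ r^(d−1) e^(−βF(r)) dr.  Analytic references for binned
  estimators are always integrated over the bin; evaluating a steep
  function at the bin center adds O(Δr²) systematic error that has nothing
  to do with the estimator under test.
* `mixing_free_energy` — second/third-order mixing free energies
  (F_A⊕B − F_A − F_B and the alternating third-order combination).
* `ccf` — the cluster cumulant function of a diagram, *defined* by Möbius
  inversion over the Boolean lattice of its coupling edges:
  K[G] = Σ_{S⊆edges} (−1)^(|edges|−|S|) ln Z(S).  A single edge reproduces
  −βF⁽²⁾; the three spanning trees plus the triangle of a complete
  3-diagram sum to −βF⁽³⁾; edge sets that split into separate components
  telescope to zero by factorization.  Diagrams with two "white" circles
  hold those species fixed at separation r and are r-dependent.

Two identity checks tie the decomposition to the cumulant expansion:

* `verify_jsi_ccf_identity`: −βF_JSI(r) computed directly as
  ln Q_full(r) − ln Q_disjoint(r) equals K⁽³⁾[D3](r) − K⁽³⁾[D4](r) +
  K⁽²⁾[D3](r) up to an r-independent constant (−ln Q_V), where D3 is the
  fully coupled 3-diagram, D4 the duplicated-solvent disjoint 4-diagram,
  and K⁽²⁾[D3] the solvent-bridged (cavity) path.  The equality is exact at
  any solvent count on a fixed grid: the single-edge and articulation terms
  cancel pairwise and the disjoint cross term vanishes by factorization.
* `delta_line_collapse_check`: duplicating a species into two
  coordinate-identified copies and partitioning its interaction potential
  arbitrarily between the copies (all-on-one, a 35/65 linear split, a
  repulsive/attractive WCA split) leaves ln Z unchanged.

## Numerical choices

* Cutoff comparisons use r ≤ r_c + 1e-9: a distance landing on the cutoff
  up to rounding is treated identically under 1-ulp perturbations, which
  keeps lattice-translation symmetry of grid sums exact (the truncated
  potential is discontinuous at r_c, so a knife-edge comparison converts
  rounding noise into ~1e-4 integral changes).
* Grid-exact identities (factorization, disjoint/gas reduction) are
  asserted at grid-commensurate solute separations, where the quadrature
  bias is bitwise-identical on both sides.
* The grid-refinement report (`brute_logZ(..., return_refinement=True)`)
  reaches the 1e-6 kT level from h = σ/20 for the 1D LJ pair at kT = 1;
  h = σ/10 (the tractability bound for 3-mobile-particle systems) carries
  ~2e-4 kT of resolvable grid bias, which cancels in the identity checks.
* WHAM bias weights are evaluated at bin centers; with the default bin
  widths (≲0.08 σ) the within-bin bias variation is ≪ the statistical
  errors.
* Random placement rejects coupled site pairs closer than 0.7 σ and leaves
  decoupled species free to interpenetrate; umbrella windows start from the
  solutes placed deterministically at the window center.

## Study conditions (fixtures)

The fixture state points were fixed once, as representative desk-scale
conditions:

* `sph2d` / `flexdimer2d`: 2D LJ solvent, reduced density 0.4, kT = 1,
  cutoff 3σ, N_V = 30 (box ≈ 8.66σ from the density); 9 umbrella windows on
  [0.8, 3.6], k_umb = 25 kT/σ², 60k steps per window; 40 bins on
  [0.8, 3.7].
* `dumbbell3d`: rigid two-site dumbbells (bond 0.5σ) in a 3D LJ solvent at
  density 0.3, kT = 1, cutoff 2.2σ, N_V = 30 (box ≈ 4.64σ; the box must
  exceed twice the cutoff for minimum image, which caps the cutoff at this
  size); 8 windows on [0.85, 2.05], k_umb = 40 kT/σ².
* `tiny1d` (L = 10σ) and `tiny2d` (L = 5σ): oracle-tractable
  micro-systems, grid h = 0.1σ.
* DISJOINT boxes are sized from a *single* solvent copy's density: the
  copies do not interact, so their summed density is not physical.  Both
  copies carry the same N_V as the FULL scheme.
* The solvent-count convergence check (`nv_convergence_check`) recomputes
  the JSI at N_V and 2·N_V with the box rescaled at fixed density, and
  reports per-bin |Δ| against max(tol, 3σ); deltas hidden by statistical
  error larger than tol are flagged "inconclusive", distinct from "fail".

Problem sizes (N_V = 30, 10⁴–10⁵ samples per window) were chosen so the
full validation suite runs on a single CPU at desk scale; every statistical
acceptance threshold is 3 combined standard errors per bin, which is
self-calibrating with respect to the sampling budget.

## What the fixtures do and do not emulate

The generators produce neutral Lennard-Jones fluids in small periodic
boxes.  They exercise excluded volume, dispersion attraction, duplicated
and partially coupled solvents, rigid-body orientation sampling, and
flexible-bond conformational coupling — the ingredients the decomposition's
identities depend on.  They do not emulate hydrogen-bond networks,
electrostatics under periodic boundaries, molecular solvents, or
protein-scale conformational ensembles; passing tests show the estimators
and identities are implemented correctly, not that the JSI of a real
aqueous protein system is converged at these box sizes.

## Known limitations

* 1D fixtures are non-ergodic under local moves (LJ cores preserve particle
  order on the ring), so 1D systems are used only for quadrature
  identities; sampler-versus-oracle ensemble checks run in 2D.
* The cavity scheme's overlap region (R < σ_AB) is finite and sampled, but
  the default window sets target the physically shared range of all four
  schemes; dedicated overlap windows would be needed for a converged cavity
  profile at R → 0.
* Ideal-gas (ε = 0) solvents are supported as a degenerate limit; they
  decouple energetically and serve as a null control.
* WHAM error bars at barely-sampled wall bins are block-bootstrap
  estimates; bins not resolvable by at least half the resamples are masked
  rather than reported with unstable errors.
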