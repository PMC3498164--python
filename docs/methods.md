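# Methods

## Model

A protein of N residues is a chain of unit cubes on a periodic cubic
lattice of edge L (default 64).  Each cube occupies eight lattice sites
and is addressed by one corner; two cubes overlap exactly when their
corners are within Chebyshev distance 1 (minimum image), which makes the
excluded-volume test an O(27) neighborhood lookup.  Consecutive residues
are joined by a bond vector from a finite set.

**Bond set.**  The default `classic` set is the standard three-dimensional
bond-fluctuation set: all sign/permutation images of (2,0,0), (2,1,0),
(2,1,1), (2,2,1), (3,0,0), (3,1,0) — 108 vectors with squared lengths
{4, 5, 6, 9, 10}.  Excluding the (2,2,0) class (length √8) is what makes
single-site moves provably unable to cross two chains or a chain through
itself.  Because the literature on this model family states only the bond
length *range* 2…√10, an `inclusive` set containing (2,2,0) is provided
for sensitivity checks; all production defaults use `classic`.

**Contact energies.**  Residue specificity enters through a symmetric
20×20 table ε_ij in reduced energy units, indexed by the hydropathy
ordering I V L F C M A G T S W Y P H Q N D E K R.  The 210 independent
entries linearize row-major along the upper triangle (ε₁₁ … ε₁,₂₀,
ε₂₂ … ε₂₀,₂₀).  Published knowledge-based tables (MJ, BT, BFKV families)
are treated strictly as user-supplied data files — they are not
redistributed, and none of the tests depend on them.  Loaders accept a
labeled 20×20 table (any label permutation; reindexed) or a 210-row
(index, value) triangle listing; a full table with |ε_ij − ε_ji| > 1e−9
is rejected rather than silently averaged, since asymmetry at that level
indicates a transcription error.

**Pair potential.**  Residues within r_c = √8 of each other (corner-to-
corner, minimum image) contribute

    U_ij(r) = |ε_ij| (σ/r)¹² + ε_ij (σ/r)⁶ ,   σ = 1 ,

and exactly zero beyond the cutoff; pairs at r² = 8 do interact (the
cutoff is inclusive).  This "generalized Lennard-Jones" convention — a
repulsive core that is always positive, with the matrix sign carried by
the r⁻⁶ term — is the one used across this model family; it guarantees
that attractive matrix entries are attractive at every accessible
separation.  It is a reconstruction from the model family's conventions,
not a transcription of a specific printed equation, and it is isolated in
one function: `potential_form="lj"` switches to the textbook
ε[(σ/r)¹² − (σ/r)⁶] form.  On the lattice only r² ∈ {4, 5, 6, 8} occur
between distinct residues (7 is not a sum of three squares; smaller values
violate excluded volume), so the kernel uses a (20, 20, 9) lookup table.

Bonded neighbors feel the contact potential too (`include_bonded=True` by
default): bonds of squared length 9 or 10 are beyond the cutoff anyway,
and exempting the shorter bonds would only shift absolute energies without
changing the transition phenomenology.  The flag exists because both
conventions appear in the literature.

**Dynamics.**  Metropolis single-site moves: pick a residue uniformly at
random, pick one of the six axial unit directions uniformly, reject if the
move violates excluded volume or bond constraints (geometric rejections
consume an attempt — this matters for mobility normalization), otherwise
accept with probability min(1, exp(−ΔE/T)), with T > 0 in reduced units
(k_B = 1).  One MCS = N attempts.  The default `random` schedule draws N
independent residues per MCS; `permuted` uses a fresh random permutation
(every residue attempted exactly once per MCS).  ΔE is computed locally
from the ≤66 lattice offsets within the cutoff; an audit comparing the
accumulated ΔE against full recomputes holds to <1e−10 over 10⁴ moves.

**Initialization.**  Seeded self-avoiding growth: bonds are drawn in
random order until one places a non-overlapping cube; a dead end restarts
the whole growth from a fresh sub-seed (cap 500).  Growth is mildly biased
toward compact states relative to the equilibrium ensemble, which is why
steady-state averages discard an equilibration window (default: the first
half of the run; the athermal 64-mer needs ≳10⁵ MCS to forget its initial
size).

**Kernel.**  The production path is a numba-compiled kernel
(~3×10⁶ attempts/s on one core) maintaining wrapped corner coordinates,
an occupancy grid, and unwrapped coordinates for observables.  A pure
Python reference step built on the lattice/energetics modules is the
oracle: the test suite checks that kernel frames satisfy all geometric
invariants, that kernel per-residue energies equal the Python energetics
on every recorded frame, and that steady-state means agree statistically
between the two paths.  Trajectories are bit-reproducible from the master
seed, which spawns separate sub-seeds for growth and dynamics.

## Observables

* **R_g** — RMS distance of residues from their centroid, on unwrapped
  coordinates (periodic folding would corrupt it).  Satisfies the pairwise
  identity R_g² = (1/2N²) Σ r_ij².
* **R_c(t)** — RMS displacement of the center of mass over samples,
  √⟨|COM(t) − COM(0)|²⟩, unwrapped.  The exponent k of R_c ∝ t^k is the
  log–log slope over the last decade of recorded times; a chain that never
  moved is reported as k = 0 with a `frozen` flag instead of a fit.
* **S(q)** — spherically averaged structure factor
  (1/N)⟨|Σ_j exp(iq·r_j)|²⟩.  The default evaluation is the exact Debye
  closed form S(q) = (1/N) Σ_ij sinc(q r_ij) (O(N²) per conformation);
  random-direction averaging is available but needs thousands of
  directions to converge for rigid anisotropic objects (a rod's window fit
  drifts from ~0.35 to ~0.92 between 200 and 2000 directions; the exact
  average gives 0.992).  The q grid is continuous (default geomspace
  0.2–1.2, 30 points), not lattice-commensurate.
* **Effective dimension** — least squares of log S on log q over
  q ∈ [0.35, 0.75] (configurable) gives slope −1/ν and D_e = 1/ν = −slope,
  with the regression standard error.  The default window probes length
  scales 2π/q ≈ 8–18, i.e. the R_g ≈ 10–26 range a 136-residue chain
  spans between globule and coil.
* **Contact map** — pairs (i≠j) with minimum-image r² ≤ 8; symmetric,
  empty diagonal.
* **Profiles** — per-residue mean energy and mobility
  (accepted/attempted fraction, geometric rejections included) over the
  post-equilibration window.

## Sweeps and detectors

A sweep runs n_samples independent seeds per temperature (seed derived
deterministically from the master seed and the cell indices), averages
steady-state R_g with its standard error of the mean over samples, and
optionally fits k and D_e (the latter from steady-state frames pooled
across samples).  Per-run summaries are cached on disk keyed by a SHA-256
hash of the full configuration + sequence + matrix, so re-running an
identical sweep is a pure cache read.  A failed cell is logged and
skipped.

**Transition range.**  The coil–globule transition window is usually read
off a plot; the formalization here is: smooth R_g(T) with a 3-point moving
average, take dR_g/dT, and report the lowest/highest temperatures where
the slope exceeds 10% (configurable) of its maximum.  The detection is
flagged inconclusive when the total rise is within noise (<4 median SE) or
when the super-threshold region touches a grid endpoint (no plateau on
that side) — a monotone ramp or a flat curve yields a flag, not a number.
The grid step is reported as the uncertainty.

**Anomaly.**  Intervals where R_g *decreases* with rising T are reported
when at least two consecutive grid steps each drop by more than 2 combined
standard errors.  The two-consecutive-steps requirement controls the
look-elsewhere effect: on a ~25-point grid a single 2-SE step is expected
from noise alone (measured 33/100 false positives without the rule, 0/100
with it), while a genuine dip spanning ≥2 grid intervals is still
recovered grid-exactly.  Anomalies narrower than two grid steps require a
finer temperature grid.

## Synthetic fixtures and what they do (not) show

* **Matrices** — `zero` (athermal homopolymer: every temperature
  equivalent, energies identically zero), `uniform` (homopolymer with
  tunable attraction/repulsion), `random-symmetric` (210 iid U[−1,1]
  entries).  They exercise every code path but carry none of the
  hydropathy structure of real knowledge-based tables, so sequence-
  specific phenomenology (distinct transition windows per matrix, the
  R_g-decreasing anomaly) is *not* demonstrated by the bundled tests —
  it requires the user-supplied tables.
* **Rod / serpentine globule** — lattice-valid reference conformations
  (collinear (3,0,0) bonds; boustrophedon (2,0,0) serpentine filling the
  smallest cube).  The rod is the D_e ≈ 1 scatterer oracle.  The
  serpentine is deliberately *not* used as the D_e ≈ 3 oracle: a rigid
  uniform object with a sharp surface scatters in the Porod regime over
  the default window (measured slope ≈ −5 for the 136-residue serpentine),
  which measures its surface, not its mass scaling.
* **Coil and crumpled ensembles** — the ideal-coil ensemble is
  non-self-avoiding random walks over the allowed bond set (self-avoidance
  deliberately off to realize ν = 1/2, D_e ≈ 2).  The general-ν oracle is
  an ensemble of fractional-Brownian chains with Hurst exponent H = ν
  (exact internal scaling r(s) ∝ s^ν by construction): ν = 1/3 gives
  crumpled, globule-like statistics with no sharp surface.  For the fit
  window to lie inside the scaling regime [b, bN^ν] at the natural bond
  scale b ≈ 2.7, the ν = 1/3 ensemble uses N = 512, which also puts its
  R_g ≈ 10 at the globule size the window is designed for.  Measured
  D_e: rod 0.99, coil 2.06, crumpled 2.9–3.0.
* **Curves** — sigmoid / dip / flat / linear R_g(T) families with seeded
  Gaussian noise and recorded ground truth (the sigmoid's 10%-slope
  window, the dip's decreasing grid interval) for detector tests.

Passing these tests shows the machinery is correct on ensembles of known
geometry and statistics; it does not by itself validate the biological
realism of any contact matrix.

## Problem sizes

Production ensembles in this model family run 10⁷ MCS with 150–1000
samples per temperature and ~20 temperatures — cluster work.  The test
suite and `scripts/acceptance.py` use desk-scale profiles chosen so each
physical signal is unambiguous (≥3σ) on one core:

| check | size |
| --- | --- |
| diffusive COM exponent | 136-mer, ε≡0, 50 seeds × 10⁵ MCS, k fitted over 2 decades |
| collapse (ε≡−1) | 64-mer, 8 seeds × 4×10⁵ MCS at T = 0.005 and 0.05 |
| SAW exponent | N ∈ {16, 32, 64}, 12 seeds × 2×10⁵ MCS |
| D_e oracles | rod N=64; coil 200×136; crumpled 60×512 |
| ΔE / invariant audits | 10⁴ audited moves; 1.36×10⁵ kernel attempts |

At these sizes the uniform-attraction 64-mer at T = 0.005 is only
*partially* collapsed (R_g ≈ 9.3 vs the coil's 12.1; D_e ≈ 2.1 vs 1.7):
collapse kinetics at contact energies ≈3T are near-glassy, and full
compaction to D_e ≈ 3 needs the production-scale budget.  The collapse
check therefore asserts a >3σ drop in R_g and a >3σ rise of D_e toward 3,
not terminal compaction.

## Known limitations

* Single chain in implicit good/poor solvent via contact energies only —
  no electrostatics, solvent particles, bond-angle or torsion terms.
* The published MJ/BT/BFKV matrices must be transcribed by the user;
  matrix-specific results (transition windows ΔT per potential, the
  BFKV-type anomaly) are reproducible only with that data, and at
  production scale.
* Lattice temperature is in reduced units; mapping to Kelvin requires an
  external calibration that contact potentials do not supply.
* Minimum-image distances assume the chain's extent stays well below L/2;
  at the default L = 64 this holds comfortably for a 136-residue chain
  (R_g ≤ ~26), but results on much smaller lattices should be checked for
  self-image artifacts.
* The kernel's random schedule draws residues with replacement
  (`random`); the `permuted` schedule is provided because the literature
  is ambiguous, and the two agree on all steady-state observables tested.
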