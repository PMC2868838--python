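# Methods

This note documents the models implemented in `coevomech`, the parameters
that matter, the numerical choices, and what the synthetic fixtures do and
do not establish.

## Cα bead model and contact classes

A protein is reduced to one bead per residue at its Cα position. Parsing
(via Biopython's PDB parser) takes one bead per residue in file order,
skips residues without a Cα, includes hetero residues that carry one
(mapped to the nonstandard marker `X` unless they are standard amino
acids), honours insertion codes as distinct residues, and resolves altLoc
duplicates by Biopython's occupancy-based selection (ties go to the first
conformer in the file). Internal indexing is 0-based; author chain labels
and residue numbers are retained for output.

Pairs are split into two classes:

- **covalent**: sequence neighbours (i, i+1) within one chain. Covalency is
  defined by adjacency in the bead chain, not by residue numbering, so a
  numbering gap still yields a covalent pair — the bead-chain abstraction
  has no way to represent a missing segment, and a broken spring there
  would disconnect the network.
- **non-covalent**: every other pair with squared native distance
  ≤ `cutoff_sq` (default 169 Å², i.e. 13 Å; comparison is ≤ on the squared
  distance).

## The elastic network

Every interacting pair contributes a harmonic term ½·k·(s − s⁰)², giving
3×3 Hessian blocks −(k/(s⁰)²)·d dᵀ for native separation vector d — i.e.
spring constant times the outer product of the unit bond vector (the two
formulations are identical; the κ/(s⁰)² scaling with raw d is what the
code implements). Diagonal blocks are the negative row sums, which enforces
translation invariance exactly.

Spring constants: covalent pairs use the uniform weight α (default 82);
non-covalent pairs use the 20×20 contact-energy tables — Miyazawa–Jernigan
magnitudes for same-chain pairs, a Keskin-style table for cross-chain
pairs, optionally the elementwise average of the two. Tables store positive
magnitudes of the published contact energies so every spring is stabilizing;
custom tables are validated for symmetry, labels and positivity.
Nonstandard residues (`X`) fall back to the table's column mean — enough to
keep the Hessian well-defined without inventing chemistry for unknown
residues. The bundled KE file is a clearly-labelled synthetic stand-in on
the MJ scale (its numeric values are not the published Keskin et al.
matrix); analyses that depend on exact KE values should load the published
matrix through the custom-table path.

The eigendecomposition uses the symmetric solver (`numpy.linalg.eigh`),
which coincides with the SVD for this symmetric PSD matrix. The covariance
matrix is the Moore–Penrose pseudo-inverse computed by skipping exactly the
six smallest eigenvalues (rigid translations and rotations). Two warnings
guard the physics: a skipped mode whose eigenvalue exceeds 1e-8·λ_max
(pre-stressed model), and a retained mode below that threshold
(disconnected model). B-factors are (8π²/3)·tr M_ii; the prefactor is one
isolated constant, so relative profiles never depend on it.

**Degenerate geometries.** A collinear bead chain (and, for out-of-plane
motion, any planar structure) has zero-energy transverse displacements:
the six-zero-mode statement holds only for generic 3D geometries. The
fixture generator therefore provides both a collinear `chain` (useful for
distance arithmetic) and a `helix` (Cα-like helix, radius 2.3 Å, rise
1.5 Å, 100° twist, rescaled so consecutive beads sit `spacing` apart),
which is the chain-like fixture used wherever mode counts matter. The
`ring` is puckered (alternating ±0.35·spacing in z) so it is non-planar
while keeping, for even N, all beads symmetry-equivalent. The `dimer` is a
C2-symmetric pair of helices (chain B is chain A rotated 180° about z and
offset 8 Å along x), so the chain swap is an exact isometry — as in real
homo-dimers. The `globule` is self-avoiding random placement (minimum
separation 3.5 Å) inside a sphere, rejected until connected under the
default cutoff. All fixture coordinates are rounded to 3 decimals so PDB
round-trips are lossless; symmetry-based equalities consequently hold to
~1e-3 relative, and tests assert them at that precision.

## Mutual information

Columns are categorical variables over a 22-symbol alphabet (20 amino
acids, gap, nonstandard). Probabilities are relative frequencies; entropies
and MI are in bits (base-2 logs — the convention of the MI-coevolution
literature; the choice only rescales all values). MI is computed by the
direct double sum over the joint table, so the identity
MI = H_i + H_j − H_ij is a genuine cross-check (asserted at 1e-10) rather
than a definition. Gaps are a full symbol by default: a column that is
conserved-as-gap is informative about the family.

The null model estimates the upward bias of the plug-in estimator:
each replicate permutes every column independently (preserving marginals,
destroying inter-column correlation) and the per-pair mean and population
standard deviation over replicates (default 100) are returned. The bias
scales roughly as (effective alphabet − 1)²/(2·ln 2·S), which the tests
verify empirically by deepening the alignment.

## The perturbation protocol

The batch protocol computes the wild-type covariance once, then for each
listed contact removes that single spring, re-solves the network from
scratch (full rebuild and re-decomposition — the honest baseline at the
N ≤ a few hundred this package targets), and records the Frobenius norm of
the covariance difference, optionally restricted to the 3×3 blocks whose
row and column residues both lie in a user-supplied subset. Validation of
the pair list happens before any heavy work. Parallelism (joblib, thread
backend) is a pure throughput device: results are ordered by the input pair
list and are bit-identical for any worker count.

Contact ranking by MI maps alignment columns to residues by position
within the chain (so in a homo-multimer every chain maps onto the same
monomer alignment); a user position map overrides this. Ties in MI are
broken lexicographically by (i, j) — determinism over any deeper rationale.
Quadrant classification min–max normalizes MI and f over the batch
(constant coordinates normalize to 0.5), assigns each point to the nearest
of the four corners, and breaks exact ties toward the higher-MI, then
higher-f corner. Normalization is per-batch, so quadrant labels are
relative to the screened set, not absolute.

## SCPCP

The self-consistent pair contact probability model assigns each
non-covalent contact an occupancy p_ij ∈ [0, 1] that scales its spring
constant; covalent springs are never weighted. Self-consistency closes the
loop through the fluctuations: with M the pseudo-inverse of the weighted
Hessian, the thermal mean-square relative distance fluctuation of a pair is

    σ²_ij = [tr M_ii + tr M_jj − 2 tr M_ij] / β ,

with β the inverse temperature in the (dimensionless) spring-constant
units. The occupancy update treats the relative displacement as the
isotropic Gaussian the harmonic model prescribes and asks for the
probability that it stays within a capture radius R (default 1.0 Å):

    p_ij = P(χ²₃ ≤ 3R²/σ²_ij) ,

the chi-square(3) CDF. This form is in (0, 1] by construction (no clipping
anywhere), tends to 1 in the high-stability limit and to 0 at high
temperature, and is monotone in the fluctuation amplitude. It is one
deliberately replaceable function (`occupancy_probability`): variants in
the literature weight the Boltzmann factor of the contact energy instead;
the fixed-point architecture (probability-weighted springs, pseudo-inverse
covariance, damped iteration) is independent of that choice.

The solver iterates: build the weighted Hessian, pseudo-invert, update
probabilities, mix old and new with damping 0.5 (conservative mixing
avoids the oscillations common in fixed-point schemes), until the maximum
absolute probability change falls below 1e-6 or 200 sweeps elapse.
Initialization is all-formed (p = 1); `max_iter=0` therefore evaluates the
pinned-probability state, which reproduces the plain ANM covariance
exactly. Extra vanishing modes during iteration set a `disconnected` flag
on the state rather than raising — a softened-to-floppy network *is* the
unfolding signal. β scans warm-start each point from the previous state's
probabilities; scanned from high to low β the mean contact probability
drops sigmoidally, and because the fixed point is bistable near the
transition, ascending warm-started scans exhibit hysteresis (cold starts
restore point-wise independence).

With defaults (α = 82, MJ-scale κ, R = 1.0 Å) toy fixtures unfold near
β ≈ 0.5–1; the transition location shifts with R and the spring scale, as
expected for a ratio of thermal amplitude to capture volume.

## What the fixtures do and do not show

The synthetic fixtures give exact, known ground truth: closed-form
eigenvalues (two beads), symmetry-forced equalities (rings, C2 dimers),
planted couplings with MI equal to column entropy, and connected random
globules for the generic-position properties. Problem sizes (N = 5–30
residues, alignments of S = 500, 20 replicate seeds) are chosen so the full
suite solves hundreds of small eigenproblems in seconds while still
exercising every code path at generic positions. What passing them does
*not* show: that the model's B-factors correlate with experiment for real
proteins (that is a claim about the ANM parameterization, tested in the
elastic-network literature, not about this implementation), that MI ranks
biologically validated coevolving pairs first (real alignments carry
phylogenetic correlations the independent-rows generator does not emulate,
and this package deliberately implements no phylogenetic reweighting or
APC-style corrections), or that the synthetic KE stand-in reproduces
published inter-chain analyses.

## Limitations

- Plug-in MI with no bias correction beyond the shuffle null; no
  phylogenetic reweighting (out of scope by design).
- Dense Hessians and full re-decomposition per perturbation: O(N³) per
  break, intended for N up to a few hundred.
- The SCPCP occupancy rule is one defensible choice within a family of
  self-consistent schemes; absolute transition temperatures are not
  comparable across variants, only the qualitative behavior.
- PDB parsing covers ATOM/HETATM Cα extraction only — no biological
  assembly expansion, no mmCIF, no all-atom use.
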