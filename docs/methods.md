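# Methods

## Model overview

The package implements a contact potential over unordered quadruplets of
atom classes. The Delaunay tessellation of a structure's heavy-atom
coordinates is the unique (for points in general position) partition of
their convex hull into tetrahedra whose circumspheres contain no other atom,
so its simplices are an objective, parameter-free definition of four-body
nearest-neighbour contacts. Each retained tetrahedron is mapped to one of
126 quadruplet classes over the alphabet {C, N, O, S, M, X}; observed
quadruplet fractions in a derivation corpus, compared against a multinomial
background, yield log-odds scores interpreted (inverted Boltzmann) as
interaction propensities. Binding affinity is predicted from the difference
in mean tetrahedron score between a complex and its ligand-stripped protein,
rescaled by a fixed empirical linear map.

Assumptions worth keeping in mind:

* **The ligand is small relative to the protein.** The complex tessellation
  keeps all tetrahedra, including ligand-internal ones; the model assumes
  interface tetrahedra dominate the ΔQ signal. For very large ligands
  (peptides, polysaccharides) ligand-internal contacts dilute it.
* **Single conformer.** Only the first MODEL of a multi-model file is used,
  and alternate locations are collapsed (highest occupancy wins, ties go to
  the alphabetically first altloc). The potential was derived from crystal
  structures; ensemble input is outside its scope.
* **Element-level typing only.** No hybridization, charge or aromaticity;
  the alphabet is deliberately coarse so that 126 classes are well populated
  by a corpus of ~1400 structures.

## Parameters

| parameter | default | meaning |
|---|---|---|
| edge cutoff | 8.0 Å | tetrahedra with any longer edge are discarded; retained-at-exactly-8.0, compared untoleranced in double precision |
| missing policy | `zero` | tetrahedra whose quadruplet has an undefined score contribute 0 to the sum but still count in N (so N keeps its meaning of "tetrahedra in the tessellation"); `skip` and `error` are available |
| RT coefficient | 0.592 kcal/mol | used verbatim (not recomputed from R·T = 1.986e-3 × 298 = 0.591828) so tabulated conversions reproduce to all printed digits |
| linear model | ΔG = ΔQ/0.0003 − 10.49 | fixed calibration constants; `evaluate --refit` fits new coefficients on user data but never replaces these |
| metal list | bundled | explicit enumeration of alkali/alkaline-earth/transition/post-transition metals, lanthanides and actinides; metalloids (B, Si, As, Se, Te, Ge) are class X; overridable via a plain-text file |

The cutoff's boundary behaviour (retain at exactly 8.0 Å) and the
whole-tetrahedron semantics of edge removal (a tetrahedron with a discarded
edge is no longer a simplex, so it is dropped and N counts only survivors)
are deliberate choices where conventions in the literature vary; both are
fixed here and tested.

## Numerical choices

* **Scores are base-10 logarithms.** Verified during transcription of the
  reference table: every tabulated score equals log10 of the ratio of
  count-derived observed and composition-derived expected proportions to
  better than 1e-6 (the tabulated 3-significant-figure f and p themselves
  only determine s to ~2e-3).
* **Unrounded composition.** Expected rates use full-precision class
  frequencies; the expected rate of the all-metal quadruplet (~3.86e-14) is
  the fourth power of a frequency of 4.4e-4 and loses a digit per rounding
  step otherwise. Printed 6-decimal frequencies are display only.
* **Undefined scores are a distinct state** (`None`, printed `--`), never 0
  or −∞. A quadruplet with zero expected rate (class absent from the
  derivation corpus) must also have zero count; anything else raises.
* **Deterministic tessellation order.** Retained tetrahedra are sorted by
  vertex indices, so two tessellations with the same simplex set give
  bitwise-identical Q regardless of Qhull's traversal order — a ligand
  placed beyond the cutoff from everything changes nothing and yields
  ΔQ = 0 and ΔG = −10.49 exactly.
* **Degenerate input.** Exactly coplanar or coincident points make the
  triangulation undefined; the default is a hard error naming the
  degeneracy. An opt-in `jitter` retry adds a seeded perturbation ≤ 1e-6 Å
  (far below the 1e-3 Å precision of deposited coordinates) with a logged
  warning, for crystal files whose rounded coordinates are exactly
  degenerate.
* **Standard error** uses the n−2 (regression) denominator; the two
  algebraically equivalent forms (moment form and raw-power-sum form) are
  both implemented and agree to 1e-9 on random input, which guards against
  transcription slips in either.

## Reference potential

The bundled table (126 rows: count, f, p, s per quadruplet, plus the
corpus's class counts) was transcribed from the published derivation over
1417 diverse, low-sequence-identity, high-resolution crystal structures. It
is shipped as TSV with an embedded SHA-256 checksum and validated on load:
exactly 126 keys, total tetrahedron count 34,504,737, Σf ≈ 1. Eleven
quadruplets were never observed and carry undefined scores. Re-deriving this
table requires bulk structure downloads and is supported by
`derive_potential` but not performed here; consequently the published
training/validation correlations (r = 0.79 on hundreds of complexes) are
outside what this repository's tests reproduce.

One transcription-time observation: the published class-frequency table
prints 0.000754 for class X, but its own counts give 4299/5,705,981 =
0.000753 (6 d.p.); the package computes from counts, and the test tolerance
on displayed frequencies is ±1 in the sixth decimal.

## Synthetic fixtures

The generators produce seeded, byte-reproducible point clouds in a cubic
box with a minimum pair separation (default 1.5 Å), with atom classes drawn
from a target composition, emitted as fixed-column PDB text; the complex
variant appends a ligand block (residue name LIG). They emulate only what
the pipeline consumes — finite, well-separated, generally-positioned labelled
points with realistic density and composition — and none of what real
structures add: bonding geometry, secondary structure, packing anisotropy,
solvent shells. Passing tests therefore demonstrate the correctness of the
geometry, counting, scoring and statistics machinery, not predictive
accuracy on real complexes; the latter rests on the published calibration
embodied in the reference table and fixed linear map. Brute-force oracles
(exhaustive empty-circumsphere verification, direct edge scans, independent
tallies) provide the independent checks at test scale (≤ a few hundred
atoms, where exhaustive verification is fast).

## Problem sizes

Tests and examples use corpora of ~5 structures × 150 atoms and single
structures of 50–300 atoms; these sizes populate dozens of quadruplet
classes and thousands of tetrahedra while keeping every brute-force oracle
exhaustive. The acceptance script's quantities are closed-form arithmetic on
the bundled corpus counts and benchmark table and involve no simulation.

## Known limitations

* No residue-level alphabet, pair potentials, or temperature scaling.
* No pose generation, docking, solvation or entropy terms; the model scores
  a given geometry only.
* Ligand identity must be supplied (a residue-name selector); the tool does
  not guess which HETATM groups constitute "the" ligand, since cofactors and
  ions may belong to the protein environment.
* The linear calibration constants (1/0.0003, −10.49) are published values
  with no more digits available; predictions inherit that precision.
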