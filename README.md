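# fourbody

A knowledge-based **four-body atomic statistical potential** derived from
Delaunay tessellation of macromolecular structures, and the topological
scoring model built on it for predicting **protein–ligand binding free
energy**. Intended for structural bioinformaticians and computational
chemists who want a fast, geometry-only scoring function for complexes with
solved coordinates.

## The model

Given the heavy-atom coordinates of a structure (hydrogens and waters
removed), the Delaunay tessellation partitions space into tetrahedra whose
vertices are atoms; each tetrahedron objectively identifies a quadruplet of
nearest-neighbour atoms. Tetrahedra with any edge longer than 8 Å are
discarded. Atoms are typed with a six-letter alphabet — C, N, O, S, M (all
metals), X (all other non-metals) — giving 126 possible unordered quadruplets.

Over a large, diverse corpus of high-resolution crystal structures
(5,705,981 atoms; 34,504,737 retained tetrahedra, bundled with the package)
each quadruplet *ijkl* gets a log-odds score by the inverted Boltzmann
principle:

```
s_ijkl = log10( f_ijkl / p_ijkl )
```

where *f* is the observed fraction of tetrahedra with that quadruplet and
*p* is its multinomial chance rate from the corpus's atom-class frequencies
*a_n*:

```
p_ijkl = 4! / (t_1! … t_6!) · a_1^t_1 … a_6^t_6 ,   Σ t_n = 4 .
```

A structure's **topological score** is the mean tetrahedron score,
`Q = (1/N) Σ s_ijkl`. Scoring a complex twice — once whole, once with the
ligand stripped — gives `ΔQ = Q_complex − Q_protein`, which an empirically
calibrated linear map converts to a binding free energy in kcal/mol:

```
ΔG_calc = ΔQ / 0.0003 − 10.49 .
```

Experimental constants convert via `ΔG_exp = 0.592 · ln(k_d)` (likewise for
k_i), with the lumped RT coefficient at 298 K.

## Worked example

`examples/score_toy_complex.py` builds a seeded synthetic complex
(120 protein atoms + 12 ligand atoms), scores it with the bundled reference
potential, and prints:

```
Q_complex = -0.065500  (N = 470 tetrahedra, 0 undefined)
Q_protein = -0.079226  (N = 381 tetrahedra, 0 undefined)
dQ        = +0.013727
dG_calc   = +35.265 kcal/mol   (= dQ/0.0003 - 10.49)
```

`Q_complex` and `Q_protein` are the mean tetrahedron scores of the two
tessellations (N counts retained tetrahedra; "undefined" counts tetrahedra
whose quadruplet was never seen in the derivation corpus). Their difference
`dQ`, rescaled by the linear model, is the predicted binding energy — here a
nonsensical positive value, because a random point cloud is not a physical
complex; the example demonstrates the mechanics.

The other examples cover the potential arithmetic
(`potential_arithmetic.py`), deriving a potential from your own corpus
(`derive_potential_from_corpus.py`), and the agreement statistics on the
bundled ten-complex benchmark (`evaluate_benchmark.py`), which prints

```
model vs experiment:   r = 0.72, SE = 3.52 kcal/mol, fit y = 1.26x -1.20
x-score vs experiment: r = 0.67  (pk scale; r is invariant under the affine pk -> dG conversion)
```

## Command line

The same workflows are exposed as a thin CLI:

```sh
fourbody score --pdb complex.pdb --ligand "resname:NAG"   # Q, dQ, dG_calc
fourbody convert --pki 6.52                               # -8.887610045 kcal/mol
fourbody derive-potential --corpus manifest.txt -o pot.tsv
fourbody evaluate --input pairs.tsv                       # r, SE, regression
fourbody fixture --n 300 --seed 11 -o toy.pdb             # synthetic structures
fourbody predict --dq 0.003                               # linear model only
```

Defaults reproduce the published settings: 8 Å cutoff, bundled reference
potential, fixed linear-model coefficients. `--missing-policy` controls
tetrahedra with undefined scores (`zero` contributes 0 but counts in N;
`skip`; `error`).

## Scope

The package scores structures you supply and derives potentials from corpora
you assemble; it does not fetch PDB files, curate ligand annotations, dock,
or generate poses. Fixture structures are labelled point clouds with no
claim of chemical realism.
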