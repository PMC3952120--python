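"""Seeded synthetic structures and brute-force geometric oracles.

The generators emit labelled 3D point clouds dressed up as fixed-column PDB
text, so the whole pipeline — parsing, filtering, tessellation, counting,
scoring — can be exercised end to end without any external structure files.
Atoms are placed by rejection sampling inside a cubic box with a minimum pair
separation (default 1.5 A, below typical covalent bond lengths but enough to
keep the triangulation in general position); atom classes are drawn from a
target composition.  The clouds make no claim of chemical realism (no bonds,
no sterics); they exercise geometry and bookkeeping only.

``empty_circumsphere_check`` is an exhaustive, independent verification of the
defining Delaunay property, suitable for point sets up to ~100 atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FixtureError

#: Representative element per atom class, used when writing fixture PDBs.
CLASS_ELEMENTS = {"C": "C", "N": "N", "O": "O", "S": "S", "M": "ZN", "X": "P"}

_MAX_REJECTION_TRIES = 10_000


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of a synthetic point-cloud structure."""

    n_atoms: int = 100
    composition: dict[str, float] = field(
        default_factory=lambda: {"C": 1.0}
    )
    box: float = 30.0              # cubic box edge, Angstrom
    min_separation: float = 1.5    # Angstrom
    seed: int = 0
    n_ligand_atoms: int = 0
    ligand_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise FixtureError(f"composition weights sum to {total}, expected 1")
        if self.min_separation <= 0:
            raise FixtureError("min_separation must be positive")
        if self.n_atoms < 1:
            raise FixtureError("need at least one atom")


def _place_points(rng: np.random.Generator, n: int, box: float,
                  min_sep: float, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Rejection-sample n points in a box keeping all pairs >= min_sep apart."""
    origin = np.asarray(origin, dtype=float)
    points: list[np.ndarray] = []
    tries = 0
    while len(points) < n:
        if tries >= _MAX_REJECTION_TRIES:
            raise FixtureError(
                f"could not place {n} points at separation {min_sep} A in a "
                f"{box} A box after {tries} tries"
            )
        candidate = origin + rng.uniform(0.0, box, size=3)
        tries += 1
        if all(np.linalg.norm(candidate - p) >= min_sep for p in points):
            points.append(candidate)
    return np.array(points)


def _draw_classes(rng: np.random.Generator, n: int, composition: dict[str, float]
                  ) -> list[str]:
    classes = sorted(composition)
    probs = np.array([composition[c] for c in classes], dtype=float)
    return [classes[i] for i in rng.choice(len(classes), size=n, p=probs)]


def _pdb_lines(coords, classes, start_serial=1, start_res=1, resname="MOL",
               lines=None) -> list[str]:
    lines = lines if lines is not None else []
    for i, (xyz, cls) in enumerate(zip(coords, classes)):
        element = CLASS_ELEMENTS[cls]
        name = f"{element}{(i % 99) + 1}"[:4]
        record = "HETATM" if resname == "LIG" else "ATOM  "
        padded = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(
            f"{record}{start_serial + i:>5d} {padded:<4s} {resname:>3s} A"
            f"{start_res + i:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
        )
    return lines


def random_structure(spec: FixtureSpec) -> tuple[str, np.ndarray, list[str]]:
    """Generate a seeded synthetic structure.

    Returns (PDB text, coordinates array, per-atom class labels); the same
    spec always produces byte-identical text.
    """
    rng = np.random.default_rng(spec.seed)
    coords = _place_points(rng, spec.n_atoms, spec.box, spec.min_separation)
    classes = _draw_classes(rng, spec.n_atoms, spec.composition)
    text = "\n".join(_pdb_lines(coords, classes)) + "\nEND\n"
    return text, coords, classes


def toy_complex(spec: FixtureSpec):
    """Generate a synthetic protein + ligand complex.

    The protein block is placed as in :func:`random_structure`; the ligand
    block (residue name LIG, ``spec.n_ligand_atoms`` atoms) is placed in a
    smaller box displaced by ``spec.ligand_offset`` from the protein box
    origin.  Returns (PDB text, LigandSelector, bookkeeping dict with exact
    protein/ligand atom counts and both coordinate blocks).
    """
    from .structure_io import LigandSelector

    if spec.n_ligand_atoms < 1:
        raise FixtureError("toy_complex requires n_ligand_atoms >= 1")
    rng = np.random.default_rng(spec.seed)
    protein = _place_points(rng, spec.n_atoms, spec.box, spec.min_separation)
    protein_classes = _draw_classes(rng, spec.n_atoms, spec.composition)
    ligand_box = max(spec.min_separation * 2.0, spec.box * 0.2)
    ligand = _place_points(
        rng, spec.n_ligand_atoms, ligand_box, spec.min_separation,
        origin=spec.ligand_offset,
    )
    ligand_classes = _draw_classes(rng, spec.n_ligand_atoms, spec.composition)
    lines = _pdb_lines(protein, protein_classes)
    lines = _pdb_lines(
        ligand, ligand_classes,
        start_serial=spec.n_atoms + 1,
        start_res=spec.n_atoms + 1,
        resname="LIG",
        lines=lines,
    )
    text = "\n".join(lines) + "\nEND\n"
    bookkeeping = {
        "n_protein": spec.n_atoms,
        "n_ligand": spec.n_ligand_atoms,
        "protein_coords": protein,
        "ligand_coords": ligand,
        "protein_classes": protein_classes,
        "ligand_classes": ligand_classes,
    }
    return text, LigandSelector(frozenset({"LIG"})), bookkeeping


def scattered_ligand_complex(spec: FixtureSpec, spacing: float = 20.0):
    """Toy complex whose ligand atoms are mutually distant and far away.

    The ligand atoms are placed on a line at ``spacing`` A intervals starting
    well outside the protein box, so no tetrahedron with an edge under the
    8 A cutoff can involve a ligand atom: the complex and isolated-protein
    tessellations retain identical simplex sets and dQ is exactly zero.
    """
    from .structure_io import LigandSelector

    if spec.n_ligand_atoms < 1:
        raise FixtureError("need n_ligand_atoms >= 1")
    rng = np.random.default_rng(spec.seed)
    protein = _place_points(rng, spec.n_atoms, spec.box, spec.min_separation)
    protein_classes = _draw_classes(rng, spec.n_atoms, spec.composition)
    start = spec.box + 100.0
    ligand = np.array(
        [[start + i * spacing, 0.0, 0.0] for i in range(spec.n_ligand_atoms)]
    )
    ligand_classes = _draw_classes(rng, spec.n_ligand_atoms, spec.composition)
    lines = _pdb_lines(protein, protein_classes)
    lines = _pdb_lines(
        ligand, ligand_classes,
        start_serial=spec.n_atoms + 1,
        start_res=spec.n_atoms + 1,
        resname="LIG",
        lines=lines,
    )
    return "\n".join(lines) + "\nEND\n", LigandSelector(frozenset({"LIG"}))


def circumsphere(vertices: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and radius of the sphere through 4 points.

    Solves the linear system equating squared distances to the four vertices;
    raises for (near-)degenerate tetrahedra of zero volume.
    """
    v = np.asarray(vertices, dtype=float)
    a = 2.0 * (v[1:] - v[0])
    b = np.sum(v[1:] ** 2, axis=1) - np.sum(v[0] ** 2)
    try:
        center = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise FixtureError("degenerate (zero-volume) simplex has no circumsphere") from exc
    return center, float(np.linalg.norm(v[0] - center))


def empty_circumsphere_check(coords, simplices, rtol: float = 1e-7):
    """Exhaustively verify the Delaunay empty-circumsphere property.

    For each simplex, checks that no other input point lies strictly inside
    its circumsphere (relative tolerance ``rtol`` on the radius).  Returns
    (ok, violations) where each violation is a (simplex index, point index)
    pair; degenerate simplices are reported with point index -1.
    """
    pts = np.asarray(coords, dtype=float)
    violations: list[tuple[int, int]] = []
    for si, simplex in enumerate(np.asarray(simplices, dtype=int)):
        try:
            center, radius = circumsphere(pts[simplex])
        except FixtureError:
            violations.append((si, -1))
            continue
        inside = np.linalg.norm(pts - center, axis=1) < radius * (1.0 - rtol)
        inside[simplex] = False
        for pi in np.nonzero(inside)[0]:
            violations.append((si, int(pi)))
    return (not violations), violations
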