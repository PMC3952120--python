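"""Reading, filtering and splitting PDB-format coordinate sets.

The tessellation pipeline operates on heavy-atom coordinates only: hydrogen
(and deuterium) atoms and water molecules are removed before any geometry is
computed, and alternate-location duplicates are collapsed to a single copy per
atom so that each physical atom contributes exactly one vertex.  For a bound
complex, the ligand can be stripped out by an explicit selector to produce the
isolated-protein coordinate set that is tessellated alongside the full complex.

Parsing is delegated to :mod:`gemmi`; this module adds strict coordinate-field
validation (fixed-column PDB is unforgiving about silent corruption), the
filtering rules, and a minimal fixed-column writer for auditing filtered output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi

from .errors import FilterError, PDBParseError, SelectionError

logger = logging.getLogger(__name__)

#: Residue names treated as water and removed together with hydrogens.
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record with its resolved chemical element."""

    serial: int
    name: str
    altloc: str            # '' when the record has no alternate location
    residue_name: str
    chain: str
    residue_seq: int
    icode: str             # insertion code, '' if absent
    x: float
    y: float
    z: float
    occupancy: float
    element: str           # upper-case symbol, e.g. 'C', 'ZN'
    is_het: bool

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESIDUES

    @property
    def is_hydrogen(self) -> bool:
        return self.element in _HYDROGEN_ELEMENTS


@dataclass
class Structure:
    """An ordered list of atoms plus bookkeeping about how it was filtered."""

    atoms: list[AtomRecord]
    source_id: str = ""
    filter_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self):
        """Return an (n, 3) float64 array of atomic positions (file order)."""
        import numpy as np

        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


@dataclass(frozen=True)
class LigandSelector:
    """Selects ligand atoms by residue name, optionally narrowed by chain/range.

    ``residue_names`` is matched against the residue-name field; ``chain`` and
    ``residue_range`` (inclusive) narrow the match when given.
    """

    residue_names: frozenset[str]
    chain: str | None = None
    residue_range: tuple[int, int] | None = None

    def matches(self, atom: AtomRecord) -> bool:
        if atom.residue_name not in self.residue_names:
            return False
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not lo <= atom.residue_seq <= hi:
                return False
        return True

    @classmethod
    def from_string(cls, spec: str) -> "LigandSelector":
        """Parse e.g. ``"resname:NAG"`` or ``"resname:LIG,chain:A,resseq:1-14"``."""
        names: set[str] = set()
        chain = None
        rng = None
        for part in spec.split(","):
            key, _, value = part.partition(":")
            key = key.strip().lower()
            value = value.strip()
            if key == "resname" and value:
                names.update(v.strip().upper() for v in value.split("+"))
            elif key == "chain" and value:
                chain = value
            elif key == "resseq" and value:
                lo, _, hi = value.partition("-")
                rng = (int(lo), int(hi or lo))
            else:
                raise ValueError(f"unrecognized selector component: {part!r}")
        if not names:
            raise ValueError(f"selector {spec!r} names no residues")
        return cls(frozenset(names), chain, rng)


def _validate_coordinate_columns(pdb_text: str) -> None:
    """Fail loudly on ATOM/HETATM records whose fixed columns do not parse."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: coordinate record shorter than 54 columns")
        for label, lo, hi in (("x", 30, 38), ("y", 38, 46), ("z", 46, 54)):
            fragment = line[lo:hi]
            try:
                float(fragment)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {label} coordinate field {fragment!r}"
                ) from None


def parse_structure(pdb_text: str, source_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure` (no filtering applied).

    Only the first MODEL of a multi-model file is read.  Elements are taken
    from columns 77-78 when present, otherwise inferred from the atom name.

    Raises
    ------
    PDBParseError
        If the text contains no ATOM/HETATM records, a coordinate field is
        malformed, or an element cannot be resolved.
    """
    _validate_coordinate_columns(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no coordinate records (ATOM/HETATM) found")
    if len(st) > 1:
        logger.info("multi-model file %s: using first model only", source_id or "<string>")

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                element = atom.element.name.upper()
                if element in ("", "X"):
                    # gemmi uses 'X' for unresolvable symbols
                    raise PDBParseError(
                        f"cannot resolve element for atom {atom.serial} "
                        f"({residue.name} {atom.name!r})"
                    )
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        altloc=atom.altloc.replace("\x00", ""),
                        residue_name=residue.name.strip(),
                        chain=chain.name,
                        residue_seq=residue.seqid.num,
                        icode=residue.seqid.icode.strip(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        occupancy=atom.occ,
                        element=element,
                        is_het=residue.het_flag == "H",
                    )
                )
    if not atoms:
        raise PDBParseError("no coordinate records (ATOM/HETATM) found")
    return Structure(atoms=atoms, source_id=source_id)


def filter_structure(s: Structure) -> Structure:
    """Remove hydrogens/deuteriums, waters, and alternate-location duplicates.

    Altloc groups (same chain, residue, atom name) are resolved to the copy
    with the highest occupancy; ties go to the alphabetically first altloc
    identifier.  The returned structure's ``filter_log`` counts atoms removed
    per rule; applying the filter twice is a no-op.

    Raises
    ------
    FilterError
        If no atoms survive filtering.
    """
    log = {"hydrogens": 0, "waters": 0, "altlocs": 0}
    survivors: list[AtomRecord] = []
    for atom in s.atoms:
        if atom.is_hydrogen:
            log["hydrogens"] += 1
        elif atom.is_water:
            log["waters"] += 1
        else:
            survivors.append(atom)

    # Resolve altlocs: keep one atom per (chain, resseq, icode, resname, name).
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in survivors:
        key = (atom.chain, atom.residue_seq, atom.icode, atom.residue_name, atom.name)
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = atom
            order.append(key)
        else:
            log["altlocs"] += 1
            if (-atom.occupancy, atom.altloc) < (-incumbent.occupancy, incumbent.altloc):
                best[key] = atom
    kept = [best[k] for k in order]
    if not kept:
        raise FilterError(
            f"structure {s.source_id or '<unnamed>'} is empty after filtering "
            f"(removed {log['hydrogens']} hydrogens, {log['waters']} water atoms)"
        )
    merged = dict(s.filter_log)
    for rule, n in log.items():
        merged[rule] = merged.get(rule, 0) + n
    return Structure(atoms=kept, source_id=s.source_id, filter_log=merged)


def strip_ligand(s: Structure, selector: LigandSelector) -> tuple[Structure, int]:
    """Split a filtered complex into (protein-only structure, ligand atom count).

    Raises
    ------
    SelectionError
        If the selector matches no atoms, or matches every atom.
    """
    protein = [a for a in s.atoms if not selector.matches(a)]
    n_ligand = len(s.atoms) - len(protein)
    if n_ligand == 0:
        raise SelectionError(f"ligand selector {selector} matches no atoms in {s.source_id!r}")
    if not protein:
        raise SelectionError(f"ligand selector {selector} matches every atom in {s.source_id!r}")
    return replace(s, atoms=protein), n_ligand


def write_pdb(s: Structure) -> str:
    """Serialize a structure back to fixed-column PDB text, keeping serials."""
    lines = []
    for a in s.atoms:
        record = "HETATM" if a.is_het else "ATOM  "
        # name layout follows the PDB convention: 1-2 letter elements start at
        # column 14 unless the name is 4 characters wide
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{a.serial:>5d} {name:<4s}{a.altloc or ' ':1s}"
            f"{a.residue_name:>3s} {a.chain:1s}{a.residue_seq:>4d}{a.icode or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
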