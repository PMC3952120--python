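"""The four-body statistical potential over atomic quadruplets.

Every retained tetrahedron of a tessellated corpus contributes one unordered
quadruplet of atom classes.  With a six-letter alphabet there are exactly 126
distinct quadruplets (multisets of size 4 from 6 letters).  For each quadruplet
the observed proportion f among all retained tetrahedra is compared with the
rate p expected under a multinomial model of the corpus's atom-class
composition, and the log-odds score

    s = log10(f / p)

is, by the inverted Boltzmann principle, proportional to the interaction
energy of that quadruplet.  The 126 scores form the potential.  A quadruplet
never observed in the corpus has an undefined score (stored as None, printed
as '--'), never 0 or -inf; how such quadruplets are treated when scoring a new
structure is a policy of the scoring layer.

A reference potential derived from a large corpus of diverse high-resolution
crystal structures (34,504,737 retained tetrahedra over 5,705,981 atoms) ships
with the package and is checksum-verified on load.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

from .atom_typing import ALPHABET, CompositionVector, composition
from .errors import PotentialError
from .tessellation import Tessellation, tessellate_structure

_REFERENCE_SHA256 = "d52b48806aa1c5ebcc89f88872a50d7b1173a08d34faf7d598f3ca3e0d0c89ae"

_CLASS_RANK = {c: i for i, c in enumerate(ALPHABET)}


def canonical_quadruplet(classes) -> str:
    """Canonical 4-letter key of an unordered atom-class quadruplet.

    All 24 orderings of the same four classes map to one key; letters are
    sorted in the fixed class order C < M < N < O < S < X.
    """
    classes = tuple(classes)
    if len(classes) != 4:
        raise ValueError(f"a quadruplet has exactly 4 classes, got {len(classes)}")
    try:
        return "".join(sorted(classes, key=_CLASS_RANK.__getitem__))
    except KeyError as exc:
        raise ValueError(f"unknown atom class {exc.args[0]!r}") from None


def all_quadruplet_keys() -> list[str]:
    """The 126 canonical quadruplet keys, in lexicographic class order."""
    return ["".join(k) for k in itertools.combinations_with_replacement(ALPHABET, 4)]


def expected_probability(key: str, comp: CompositionVector) -> float:
    """Multinomial chance rate p of a quadruplet given class frequencies a_n.

    p = 4! / (prod t_n!) * prod a_n^t_n, where t_n counts how often class n
    appears in the quadruplet.  Uses the unrounded a_n.
    """
    key = canonical_quadruplet(key)
    if abs(sum(comp.frequencies.values()) - 1.0) > 1e-9:
        raise PotentialError("composition frequencies do not sum to 1")
    multiplicity = Counter(key)
    coeff = math.factorial(4)
    p = 1.0
    for atom_class, t in multiplicity.items():
        coeff //= math.factorial(t)
        p *= comp.frequency(atom_class) ** t
    return coeff * p


def quadruplet_score(f: float, p: float) -> float | None:
    """Log-odds score s = log10(f/p); None (undefined) when f = 0."""
    if p <= 0:
        raise PotentialError(f"expected proportion must be positive, got {p}")
    if f < 0:
        raise PotentialError(f"observed proportion must be non-negative, got {f}")
    if f == 0:
        return None
    return math.log10(f / p)


def count_quadruplets(tessellations) -> tuple[dict[str, int], int]:
    """Tally canonical quadruplet keys over (Tessellation, class labels) pairs.

    Each retained tetrahedron contributes exactly one count.  Class labels
    must cover every vertex index used by the corresponding tessellation.
    """
    counts: Counter[str] = Counter()
    total = 0
    for tess, classes in tessellations:
        for tet in tess.tetrahedra:
            try:
                quad = [classes[i] for i in tet.vertex_indices]
            except IndexError:
                raise PotentialError(
                    f"class labels (n={len(classes)}) do not cover vertex indices "
                    f"{tet.vertex_indices}"
                ) from None
            counts[canonical_quadruplet(quad)] += 1
            total += 1
    return dict(counts), total


@dataclass(frozen=True)
class PotentialEntry:
    key: str
    count: int
    f: float
    p: float
    s: float | None  # None == undefined (never-observed quadruplet)


@dataclass
class PotentialTable:
    """126-entry four-body potential plus the composition that produced it."""

    entries: dict[str, PotentialEntry]
    comp: CompositionVector
    total_tetrahedra: int
    provenance: str = ""
    cutoff: float = 8.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = all_quadruplet_keys()
        if sorted(self.entries) != expected:
            raise PotentialError(
                f"potential table must have exactly the 126 canonical keys, "
                f"got {len(self.entries)}"
            )
        sum_f = sum(e.f for e in self.entries.values())
        if abs(sum_f - 1.0) > 1e-3:
            raise PotentialError(f"observed proportions sum to {sum_f}, expected 1")

    def score(self, key: str) -> float | None:
        return self.entries[canonical_quadruplet(key)].s

    @property
    def undefined_keys(self) -> list[str]:
        return [k for k, e in self.entries.items() if e.s is None]

    def to_tsv(self) -> str:
        """Serialize as TSV (f/p at 6 significant figures, s at 6 decimals)."""
        lines = ["quad\tcount\tf\tp\ts"]
        for key in all_quadruplet_keys():
            e = self.entries[key]
            f_str = "0" if e.f == 0 else f"{e.f:.6G}"
            s_str = "--" if e.s is None else f"{e.s:.6f}"
            lines.append(f"{key}\t{e.count}\t{f_str}\t{e.p:.6G}\t{s_str}")
        return "\n".join(lines) + "\n"


def _table_from_counts(counts: dict[str, int], total: int, comp: CompositionVector,
                       provenance: str, cutoff: float) -> PotentialTable:
    entries = {}
    for key in all_quadruplet_keys():
        n = counts.get(key, 0)
        f = n / total
        p = expected_probability(key, comp)
        if p == 0:
            # a class absent from the corpus: nothing with it can be observed
            if n:
                raise PotentialError(
                    f"quadruplet {key} observed {n} times but its expected rate is 0"
                )
            s = None
        else:
            s = quadruplet_score(f, p)
        entries[key] = PotentialEntry(key=key, count=n, f=f, p=p, s=s)
    return PotentialTable(
        entries=entries,
        comp=comp,
        total_tetrahedra=total,
        provenance=provenance,
        cutoff=cutoff,
    )


def derive_potential(corpus, cutoff: float = 8.0, provenance: str = "derived",
                     jitter: bool = False) -> PotentialTable:
    """Derive a four-body potential from a corpus of filtered structures.

    For each structure: classify atoms, tessellate, apply the edge filter,
    tally quadruplets; then combine the tallies with the corpus-wide
    composition into f, p and s for all 126 keys.

    Raises
    ------
    PotentialError
        Empty corpus, or zero retained tetrahedra overall.
    """
    from .atom_typing import classify_atom  # local to keep import graph flat

    corpus = list(corpus)
    if not corpus:
        raise PotentialError("cannot derive a potential from an empty corpus")
    class_counts: Counter[str] = Counter()
    tallies: list[tuple[Tessellation, list[str]]] = []
    for structure in corpus:
        classes = [classify_atom(e) for e in structure.elements()]
        class_counts.update(classes)
        tallies.append((tessellate_structure(structure, cutoff, jitter=jitter), classes))
    counts, total = count_quadruplets(tallies)
    if total == 0:
        raise PotentialError("corpus yielded zero retained tetrahedra")
    comp = composition(dict(class_counts))
    return _table_from_counts(counts, total, comp, provenance, cutoff)


def _parse_potential_tsv(text: str, comp: CompositionVector, provenance: str,
                         cutoff: float) -> PotentialTable:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[:5] != ["quad", "count", "f", "p", "s"]:
        raise PotentialError(f"unrecognized potential table header: {lines[0]!r}")
    entries = {}
    total = 0
    for ln in lines[1:]:
        key, count, f, p, s = ln.split("\t")
        total += int(count)
        entries[key] = PotentialEntry(
            key=key,
            count=int(count),
            f=float(f),
            p=float(p),
            s=None if s == "--" else float(s),
        )
    table = PotentialTable(
        entries=entries,
        comp=comp,
        total_tetrahedra=total,
        provenance=provenance,
        cutoff=cutoff,
    )
    return table


def load_potential_tsv(path, comp: CompositionVector | None = None,
                       provenance: str | None = None) -> PotentialTable:
    """Load a potential table written by :meth:`PotentialTable.to_tsv`.

    If no composition is supplied, a uniform placeholder is used (the scores
    in the file are what matter for scoring structures).
    """
    with open(path) as fh:
        text = fh.read()
    if comp is None:
        comp = composition({c: 1 for c in ALPHABET})
    return _parse_potential_tsv(text, comp, provenance or str(path), cutoff=8.0)


def load_reference_composition() -> CompositionVector:
    """Atom-class counts of the reference derivation corpus (5,705,981 atoms)."""
    text = resources.files("fourbody.data").joinpath("reference_composition.tsv").read_text()
    counts = {}
    for ln in text.splitlines()[1:]:
        if ln.strip():
            cls, count, _ = ln.split("\t")
            counts[cls] = int(count)
    return composition(counts)


def load_reference_potential() -> PotentialTable:
    """Load the bundled reference four-body potential (checksum-verified)."""
    raw = resources.files("fourbody.data").joinpath("reference_potential.tsv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _REFERENCE_SHA256:
        raise PotentialError(
            f"bundled reference potential is corrupt (sha256 {digest[:12]}..., "
            f"expected {_REFERENCE_SHA256[:12]}...)"
        )
    comp = load_reference_composition()
    table = _parse_potential_tsv(raw.decode(), comp, provenance="reference", cutoff=8.0)
    if table.total_tetrahedra != 34504737:
        raise PotentialError(
            f"reference table total tetrahedron count {table.total_tetrahedra} "
            "does not match the expected 34,504,737"
        )
    return table
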