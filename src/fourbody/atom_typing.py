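"""The six-letter atomic alphabet and corpus composition.

Heavy atoms are coarse-grained to six classes: carbon, nitrogen, oxygen and
sulfur keep their identity, every metal collapses to M, and every remaining
non-metal/metalloid (phosphorus, selenium, halogens, boron, silicon, ...)
collapses to X.  The metal/non-metal boundary ships as an explicit, overridable
element list; metalloids are deliberately on the X side of it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

from .errors import ClassificationError

#: Canonical order of the atom classes; quadruplet keys sort letters this way.
ALPHABET: tuple[str, ...] = ("C", "M", "N", "O", "S", "X")

_SELF_CLASSES = frozenset({"C", "N", "O", "S"})
_HYDROGENS = frozenset({"H", "D"})

# Elements recognized as non-metals/metalloids beyond C/N/O/S; everything in
# the bundled metal list maps to M, everything here maps to X, anything else
# is rejected as unknown.
_NONMETALS = frozenset(
    {
        "B", "SI", "P", "AS", "SB", "TE", "SE", "GE",
        "F", "CL", "BR", "I", "AT",
        "HE", "NE", "AR", "KR", "XE", "RN",
    }
)


def _load_bundled_metals() -> frozenset[str]:
    text = resources.files("fourbody.data").joinpath("metals.txt").read_text()
    metals = set()
    for line in text.splitlines():
        symbol = line.split("#", 1)[0].strip().upper()
        if symbol:
            metals.add(symbol)
    return frozenset(metals)


METALS: frozenset[str] = _load_bundled_metals()


def load_metal_list(path) -> frozenset[str]:
    """Read an override metal list (one element symbol per line, '#' comments)."""
    with open(path) as fh:
        return frozenset(
            s for s in (ln.split("#", 1)[0].strip().upper() for ln in fh) if s
        )


def classify_atom(element: str, metals: frozenset[str] = METALS) -> str:
    """Map an element symbol to its atom class (one of C, N, O, S, M, X).

    Hydrogen/deuterium must have been filtered upstream and are rejected, as
    are symbols that are neither in the metal list nor known non-metals.
    """
    symbol = element.strip().upper()
    if symbol in _HYDROGENS:
        raise ClassificationError(
            "hydrogen/deuterium atoms must be removed before classification"
        )
    if symbol in _SELF_CLASSES:
        return symbol
    if symbol in metals:
        return "M"
    if symbol in _NONMETALS:
        return "X"
    raise ClassificationError(f"unknown element symbol: {element!r}")


@dataclass(frozen=True)
class CompositionVector:
    """Per-class atom counts and relative frequencies a_n over a corpus.

    Frequencies are kept at full double precision; rounding is a display
    concern only (the expected quadruplet rates for rare classes are far more
    sensitive to a_n than the printed six decimals convey).
    """

    counts: dict[str, int]
    total: int

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("composition requires a positive total atom count")
        if sum(self.counts.values()) != self.total:
            raise ValueError("class counts do not sum to the stated total")
        unknown = set(self.counts) - set(ALPHABET)
        if unknown:
            raise ValueError(f"counts contain unknown classes: {sorted(unknown)}")

    def frequency(self, atom_class: str) -> float:
        """Unrounded relative frequency a_n of one class."""
        return self.counts.get(atom_class, 0) / self.total

    @property
    def frequencies(self) -> dict[str, float]:
        return {c: self.frequency(c) for c in ALPHABET}

    def rounded(self, ndigits: int = 6) -> dict[str, float]:
        """Display-precision frequencies (matches 6-decimal reporting style)."""
        return {c: round(self.frequency(c), ndigits) for c in ALPHABET}


def composition(class_counts: dict[str, int]) -> CompositionVector:
    """Build a :class:`CompositionVector` from per-class atom counts."""
    counts = {c: int(class_counts.get(c, 0)) for c in ALPHABET}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot compute a composition from zero atoms")
    return CompositionVector(counts=counts, total=total)


def composition_of_elements(elements, metals: frozenset[str] = METALS) -> CompositionVector:
    """Classify an iterable of element symbols and tally their composition."""
    tally = Counter(classify_atom(e, metals) for e in elements)
    return composition(dict(tally))
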