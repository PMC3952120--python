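"""Topological scores, the binding-energy model, and thermodynamic conversions.

A tessellated structure is scored by looking up each retained tetrahedron's
quadruplet in the four-body potential and averaging:

    Q = (1/N) * sum of tetrahedral scores,   N = number of retained tetrahedra.

For a protein-ligand complex two tessellations are scored — the whole complex
and the isolated protein with the ligand removed — and their difference

    dQ = Q_complex - Q_protein

is the predictor of binding affinity.  dQ values are small and not uniform in
sign, so an empirically calibrated linear map converts them to binding free
energies on the experimental scale:

    dG_calc = dQ / 0.0003 - 10.49   [kcal/mol]

Experimental dissociation/inhibition constants convert to free energies via
dG_exp = 0.592 * ln(k), the lumped RT coefficient at 298 K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .atom_typing import classify_atom
from .errors import PotentialError
from .potential import PotentialTable, canonical_quadruplet
from .structure_io import (
    LigandSelector,
    Structure,
    filter_structure,
    parse_structure,
    strip_ligand,
)
from .tessellation import DEFAULT_CUTOFF, Tessellation, tessellate_structure

logger = logging.getLogger(__name__)

#: Lumped RT at 298 K in kcal/mol, used verbatim (R = 1.986e-3 kcal/K/mol,
#: T = 298 K; the published coefficient 0.592 is kept rather than recomputing
#: 1.986e-3 * 298 = 0.591828, so tabulated conversions reproduce exactly).
RT_KCAL_PER_MOL = 0.592

GAS_CONSTANT_KCAL = 1.986e-3   # kcal K^-1 mol^-1
TEMPERATURE_K = 298.0

#: Coefficients of the empirical linear model dG_calc = dQ / SLOPE + INTERCEPT.
MODEL_DENOMINATOR = 0.0003
MODEL_INTERCEPT = -10.49

MISSING_POLICIES = ("zero", "skip", "error")


@dataclass(frozen=True)
class TopologicalScore:
    """Normalized topological score of one tessellated structure."""

    q: float
    n: int                    # retained tetrahedra (the normalizer)
    n_undefined: int          # tetrahedra whose quadruplet had no score
    structure_id: str = ""
    potential_provenance: str = ""


@dataclass(frozen=True)
class AffinityPrediction:
    """Scores for a complex/protein pair and the derived binding energy."""

    complex_score: TopologicalScore
    protein_score: TopologicalScore
    ligand_atom_count: int

    @property
    def delta_q(self) -> float:
        return self.complex_score.q - self.protein_score.q

    @property
    def dg_calc(self) -> float:
        return predict_binding_energy(self.delta_q)


def topological_score(tess: Tessellation, classes, pot: PotentialTable,
                      missing_policy: str = "zero",
                      structure_id: str = "") -> TopologicalScore:
    """Score a tessellation with a potential table (Q = mean tetrahedron score).

    ``missing_policy`` governs tetrahedra whose quadruplet has an undefined
    potential score (absent from the derivation corpus):

    * ``"zero"`` (default) — contribute 0 to the sum but count in N;
    * ``"skip"`` — excluded from both the sum and N;
    * ``"error"`` — raise, naming the offending quadruplet.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    if tess.n_retained == 0:
        raise PotentialError("cannot score a tessellation with zero retained tetrahedra")
    total = 0.0
    n_undefined = 0
    n_counted = 0
    for tet in tess.tetrahedra:
        key = canonical_quadruplet([classes[i] for i in tet.vertex_indices])
        s = pot.score(key)
        if s is None:
            n_undefined += 1
            if missing_policy == "error":
                raise PotentialError(
                    f"quadruplet {key} has an undefined potential score"
                )
            if missing_policy == "zero":
                n_counted += 1
            continue
        total += s
        n_counted += 1
    if n_undefined:
        logger.warning(
            "%s: %d/%d tetrahedra had undefined potential scores (policy=%s)",
            structure_id or "<structure>", n_undefined, tess.n_retained, missing_policy,
        )
    if n_counted == 0:
        raise PotentialError("all tetrahedra were skipped; Q is undefined")
    return TopologicalScore(
        q=total / n_counted,
        n=n_counted,
        n_undefined=n_undefined,
        structure_id=structure_id,
        potential_provenance=pot.provenance,
    )


def delta_q(q_complex: TopologicalScore, q_protein: TopologicalScore) -> float:
    """Topological score difference dQ = Q_complex - Q_protein.

    Both scores must come from the same potential (provenance check); a dQ
    computed across potentials is meaningless.
    """
    if q_complex.potential_provenance != q_protein.potential_provenance:
        raise PotentialError(
            f"scores come from different potentials "
            f"({q_complex.potential_provenance!r} vs {q_protein.potential_provenance!r})"
        )
    return q_complex.q - q_protein.q


def predict_binding_energy(dq: float) -> float:
    """Binding free energy (kcal/mol) from dQ: dG_calc = dQ/0.0003 - 10.49."""
    if not math.isfinite(dq):
        raise ValueError(f"dQ must be finite, got {dq}")
    return dq / MODEL_DENOMINATOR + MODEL_INTERCEPT


def free_energy_from_constant(k: float) -> float:
    """dG_exp (kcal/mol) from a dissociation or inhibition constant (molar).

    dG = RT ln(k) with the lumped coefficient 0.592 kcal/mol.
    """
    if k <= 0:
        raise ValueError(f"dissociation/inhibition constant must be positive, got {k}")
    return RT_KCAL_PER_MOL * math.log(k)


def pk_to_free_energy(pk: float) -> float:
    """dG_exp (kcal/mol) from pk = -log10(k): dG = -0.592 * ln(10) * pk."""
    if not math.isfinite(pk):
        raise ValueError(f"pk must be finite, got {pk}")
    return -RT_KCAL_PER_MOL * math.log(10.0) * pk


def score_structure(structure: Structure, pot: PotentialTable,
                    cutoff: float = DEFAULT_CUTOFF, missing_policy: str = "zero",
                    jitter: bool = False) -> TopologicalScore:
    """Tessellate a filtered structure and compute its topological score Q."""
    classes = [classify_atom(e) for e in structure.elements()]
    tess = tessellate_structure(structure, cutoff, jitter=jitter)
    return topological_score(
        tess, classes, pot, missing_policy, structure_id=structure.source_id
    )


def score_complex(complex_pdb: str, selector: LigandSelector, pot: PotentialTable,
                  cutoff: float = DEFAULT_CUTOFF, missing_policy: str = "zero",
                  source_id: str = "", jitter: bool = False) -> AffinityPrediction:
    """Full pipeline: complex PDB text -> dQ -> predicted binding energy.

    Parses and filters the complex, scores its tessellation, strips the ligand
    selected by ``selector``, scores the isolated protein, and returns both
    scores with the derived dQ and dG_calc.  The complex tessellation keeps
    all tetrahedra, including ligand-internal ones — the model assumes ligands
    are small enough that interface tetrahedra dominate.
    """
    parsed = parse_structure(complex_pdb, source_id=source_id)
    filtered = filter_structure(parsed)
    complex_score = score_structure(filtered, pot, cutoff, missing_policy, jitter)
    protein, n_ligand = strip_ligand(filtered, selector)
    protein_score = score_structure(protein, pot, cutoff, missing_policy, jitter)
    return AffinityPrediction(
        complex_score=complex_score,
        protein_score=protein_score,
        ligand_atom_count=n_ligand,
    )
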