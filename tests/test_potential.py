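import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fourbody import (
    ALPHABET,
    FixtureSpec,
    all_quadruplet_keys,
    canonical_quadruplet,
    composition,
    count_quadruplets,
    derive_potential,
    expected_probability,
    filter_structure,
    filter_tetrahedra,
    parse_structure,
    quadruplet_score,
    random_structure,
    tessellate,
)
from fourbody.errors import PotentialError
from fourbody.potential import load_potential_tsv
from fourbody.tessellation import Tessellation, Tetrahedron

from test_atom_typing import CORPUS_COUNTS

CORPUS_COMPOSITION = composition(CORPUS_COUNTS)
TOTAL_TETRAHEDRA = 34504737


class TestCanonicalQuadruplet:
    def test_sorts_into_class_order(self):
        assert canonical_quadruplet(["O", "C", "N", "C"]) == "CCNO"

    def test_all_permutations_collapse(self):
        keys = {canonical_quadruplet(p) for p in itertools.permutations("CMSX")}
        assert keys == {"CMSX"}

    def test_idempotent(self):
        assert canonical_quadruplet("CCNO") == "CCNO"

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            canonical_quadruplet(["C", "C", "C"])

    def test_exactly_126_keys(self):
        keys = all_quadruplet_keys()
        assert len(keys) == 126
        assert len(set(keys)) == 126
        assert all(canonical_quadruplet(k) == k for k in keys)


class TestExpectedProbability:
    def test_all_carbon_quadruplet(self):
        assert expected_probability("CCCC", CORPUS_COMPOSITION) == pytest.approx(
            0.160748, abs=1e-6
        )

    def test_three_carbon_one_nitrogen(self):
        assert expected_probability("CCCN", CORPUS_COMPOSITION) == pytest.approx(
            0.172495, abs=2e-6
        )

    def test_all_metal_quadruplet(self):
        assert expected_probability("MMMM", CORPUS_COMPOSITION) == pytest.approx(
            3.86e-14, rel=5e-3
        )

    def test_single_class_alphabet_normalizes(self):
        assert expected_probability("CCCC", composition({"C": 42})) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=10**6), min_size=6, max_size=6))
    def test_multinomial_completeness(self, values):
        comp = composition(dict(zip(ALPHABET, values)))
        total = sum(expected_probability(k, comp) for k in all_quadruplet_keys())
        assert total == pytest.approx(1.0, abs=1e-9)


class TestQuadrupletScore:
    def test_log_odds_is_base_10(self):
        assert quadruplet_score(0.116386, 0.160748) == pytest.approx(-0.140244, abs=1e-5)

    def test_equal_proportions_score_zero(self):
        assert quadruplet_score(0.37, 0.37) == 0.0

    def test_rare_metal_quadruplet(self):
        f = 83 / TOTAL_TETRAHEDRA
        p = expected_probability("MMMM", CORPUS_COMPOSITION)
        assert quadruplet_score(f, p) == pytest.approx(7.794725, abs=1e-4)

    def test_unobserved_quadruplet_is_undefined(self):
        assert quadruplet_score(0.0, 0.5) is None

    def test_nonpositive_expectation_rejected(self):
        with pytest.raises(PotentialError):
            quadruplet_score(0.1, 0.0)


def single_tet_tessellation():
    return Tessellation(
        tetrahedra=[Tetrahedron((0, 1, 2, 3), 1.0)], n_raw=1, cutoff=8.0
    )


class TestCountQuadruplets:
    def test_single_tetrahedron(self):
        counts, total = count_quadruplets([(single_tet_tessellation(), ["C", "C", "C", "C"])])
        assert counts == {"CCCC": 1}
        assert total == 1

    def test_counts_add_across_structures(self):
        pair = [
            (single_tet_tessellation(), ["C", "C", "C", "C"]),
            (single_tet_tessellation(), ["O", "C", "N", "C"]),
        ]
        counts, total = count_quadruplets(pair)
        assert counts == {"CCCC": 1, "CCNO": 1}
        assert total == 2

    def test_label_index_mismatch_rejected(self):
        with pytest.raises(PotentialError):
            count_quadruplets([(single_tet_tessellation(), ["C", "C"])])

    def test_matches_independent_tally_on_seeded_cloud(self):
        text, coords, classes = random_structure(
            FixtureSpec(n_atoms=300,
                        composition={"C": 0.633, "N": 0.17, "O": 0.19,
                                     "S": 0.005, "M": 0.001, "X": 0.001},
                        box=40.0, seed=11)
        )
        tess = filter_tetrahedra(tessellate(coords), coords, cutoff=8.0)
        counts, total = count_quadruplets([(tess, classes)])
        brute = {}
        for tet in tess.tetrahedra:
            key = "".join(sorted(classes[i] for i in tet.vertex_indices))
            brute[key] = brute.get(key, 0) + 1
        assert counts == brute
        assert total == tess.n_retained


def synthetic_corpus(n_structures=5, seed0=100):
    corpus = []
    for i in range(n_structures):
        text, _, _ = random_structure(
            FixtureSpec(n_atoms=150,
                        composition={"C": 0.6, "N": 0.2, "O": 0.15, "S": 0.05},
                        box=24.0, seed=seed0 + i)
        )
        corpus.append(filter_structure(parse_structure(text, source_id=f"synth{i}")))
    return corpus


@pytest.fixture(scope="module")
def derived():
    return derive_potential(synthetic_corpus(), cutoff=8.0)


class TestDerivePotential:
    def test_observed_and_expected_proportions_normalize(self, derived):
        assert sum(e.f for e in derived.entries.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(e.p for e in derived.entries.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unseen_classes_have_zero_counts_and_undefined_scores(self, derived):
        # the corpus has no M or X atoms
        for key, entry in derived.entries.items():
            if "M" in key or "X" in key:
                assert entry.count == 0
                assert entry.s is None

    def test_f_matches_brute_force_ratio(self, derived):
        total = derived.total_tetrahedra
        for entry in derived.entries.values():
            assert entry.f == pytest.approx(entry.count / total, abs=1e-15)

    def test_aggregation_associative(self, derived):
        corpus = synthetic_corpus()
        per_structure = [derive_potential([s], cutoff=8.0) for s in corpus]
        combined_counts = {k: sum(t.entries[k].count for t in per_structure)
                           for k in all_quadruplet_keys()}
        assert combined_counts == {k: e.count for k, e in derived.entries.items()}

    def test_empty_corpus_rejected(self):
        with pytest.raises(PotentialError):
            derive_potential([])

    def test_tsv_roundtrip_preserves_scores(self, derived, tmp_path):
        path = tmp_path / "potential.tsv"
        path.write_text(derived.to_tsv())
        loaded = load_potential_tsv(path)
        for key in all_quadruplet_keys():
            a, b = derived.entries[key], loaded.entries[key]
            assert a.count == b.count
            if a.s is None:
                assert b.s is None
            else:
                assert b.s == pytest.approx(a.s, abs=1e-6)


class TestReferencePotential:
    def test_entry_count_and_total(self, reference_potential):
        assert len(reference_potential.entries) == 126
        assert reference_potential.total_tetrahedra == TOTAL_TETRAHEDRA

    def test_spot_rows(self, reference_potential):
        cccc = reference_potential.entries["CCCC"]
        assert (cccc.count, cccc.s) == (4015872, -0.140244)
        mmmm = reference_potential.entries["MMMM"]
        assert mmmm.count == 83
        assert mmmm.s == pytest.approx(7.794725, abs=1e-6)

    def test_undefined_scores_iff_zero_count(self, reference_potential):
        zero_count = {k for k, e in reference_potential.entries.items() if e.count == 0}
        assert set(reference_potential.undefined_keys) == zero_count
        assert len(zero_count) == 11

    def test_tabulated_scores_reproduce_from_unrounded_counts(self, reference_potential):
        """Every tabulated s equals log10(f/p) with f from the tabulated count
        and p from the unrounded corpus composition (confirms base-10)."""
        comp = reference_potential.comp
        total = reference_potential.total_tetrahedra
        for key, entry in reference_potential.entries.items():
            if entry.s is None:
                continue
            recomputed = math.log10((entry.count / total) / expected_probability(key, comp))
            assert entry.s == pytest.approx(recomputed, abs=1e-4), key

    def test_tabulated_scores_consistent_with_rounded_f_and_p(self, reference_potential):
        # f and p are tabulated at 3 significant figures, which limits the
        # achievable agreement of log10(f/p) to about 2e-3
        for key, entry in reference_potential.entries.items():
            if entry.s is None:
                continue
            assert entry.s == pytest.approx(math.log10(entry.f / entry.p), abs=2.5e-3), key

    def test_composition_matches_tabulated_counts(self, reference_potential):
        assert reference_potential.comp.counts == CORPUS_COUNTS
        assert reference_potential.comp.total == 5705981
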