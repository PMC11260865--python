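"""Druggability and prioritisation scoring against brute-force oracles."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afdrugprior.scoring import (
    antibody_score,
    prioritisation_score,
    rank_targets,
    small_molecule_score,
)
from afdrugprior.types import TargetProfile, Tissue, TractabilityRecord, Trait

POCKET_GRID = [None, 0.0, 0.3, 0.7, 1.0]


def brute_force_sm(druggable_family: bool, pocket) -> int:
    """Independent enumeration of the small-molecule rule: one point for
    family membership, one for a high (>=0.7) or medium (0 < s < 0.7) pocket."""
    points = 0
    if druggable_family:
        points += 1
    if pocket is not None and (pocket >= 0.7 or 0 < pocket < 0.7):
        points += 1
    return points


@pytest.mark.parametrize("family", [False, True])
@pytest.mark.parametrize("pocket", POCKET_GRID)
def test_small_molecule_score_matches_enumeration(family, pocket):
    record = TractabilityRecord(ensembl_id="E", druggable_family=family, pocket_score=pocket)
    assert small_molecule_score(record) == brute_force_sm(family, pocket)


def test_small_molecule_boundary_cases():
    mk = lambda f, p: small_molecule_score(
        TractabilityRecord(ensembl_id="E", druggable_family=f, pocket_score=p)
    )
    assert mk(True, 0.9) == 2
    assert mk(False, None) == 0
    assert mk(True, 0.3) == 2  # medium pocket counts the same single point
    assert mk(True, 0.0) == 1  # a zero score is no usable pocket


def test_pocket_score_outside_unit_interval_rejected():
    record = TractabilityRecord.model_construct(
        ensembl_id="E", druggable_family=False, pocket_score=1.5,
        accessible_uniprot=False, accessible_go=False, accessible_hpa=False,
    )
    with pytest.raises(ValueError, match="pocket_score"):
        small_molecule_score(record)


@pytest.mark.parametrize(
    "flags", list(itertools.product([False, True], repeat=3))
)
def test_antibody_score_counts_each_source_once(flags):
    up, go, hpa = flags
    record = TractabilityRecord(
        ensembl_id="E", accessible_uniprot=up, accessible_go=go, accessible_hpa=hpa
    )
    assert antibody_score(record) == sum(flags)


def test_full_flag_pocket_grid_matches_oracle_including_priority_rule():
    """All 2^4 flag combinations x pocket grid against independent enumeration."""
    for family, up, go, hpa in itertools.product([False, True], repeat=4):
        for pocket in POCKET_GRID:
            t = TractabilityRecord(
                ensembl_id="E", druggable_family=family, pocket_score=pocket,
                accessible_uniprot=up, accessible_go=go, accessible_hpa=hpa,
            )
            sm, ab = small_molecule_score(t), antibody_score(t)
            assert sm == brute_force_sm(family, pocket)
            assert ab == up + go + hpa
            prof = TargetProfile(ensembl_id="E", hgnc_symbol="E")
            scores = prioritisation_score(prof, t)
            assert scores.druggability_priority == (sm > 1 or ab > 1)


trait_sets = st.sets(st.sampled_from([Trait.AF, Trait.PR_INDICES, Trait.LA_INDICES]))
tissue_sets = st.sets(st.sampled_from([Tissue.LA, Tissue.RA, Tissue.LV]))


@settings(deadline=None, max_examples=200)
@given(traits=trait_sets, tissues=tissue_sets, rvas=st.booleans())
def test_prioritisation_matches_set_cardinality_oracle(traits, tissues, rvas):
    profile = TargetProfile(
        ensembl_id="E", hgnc_symbol="E", traits=traits, tissues=tissues, rare_variant=rvas
    )
    scores = prioritisation_score(profile)
    expected = len(traits) + len(tissues) + int(rvas)
    assert scores.prioritisation_score == expected
    assert scores.gene_priority == (expected > 1)
    assert scores.prioritisation_score <= 7


@settings(deadline=None, max_examples=100)
@given(traits=trait_sets, tissues=tissue_sets, rvas=st.booleans(),
       extra=st.sampled_from(list(Trait)[:3] + list(Tissue)[:3]))
def test_adding_evidence_never_decreases_score(traits, tissues, rvas, extra):
    base = prioritisation_score(
        TargetProfile(ensembl_id="E", hgnc_symbol="E", traits=traits,
                      tissues=tissues, rare_variant=rvas)
    )
    bigger_traits = traits | {extra} if isinstance(extra, Trait) else traits
    bigger_tissues = tissues | {extra} if isinstance(extra, Tissue) else tissues
    grown = prioritisation_score(
        TargetProfile(ensembl_id="E", hgnc_symbol="E", traits=bigger_traits,
                      tissues=bigger_tissues, rare_variant=True)
    )
    assert grown.prioritisation_score >= base.prioritisation_score


class TestWorkedExamples:
    """Targets whose printed evidence pins down the score."""

    def test_kcnj5_three_tissues_plus_af_is_priority(self):
        profile = TargetProfile(
            ensembl_id="KCNJ5", hgnc_symbol="KCNJ5",
            traits={Trait.AF}, tissues={Tissue.RA, Tissue.LA, Tissue.LV},
        )
        scores = prioritisation_score(profile)
        assert scores.prioritisation_score >= 4
        assert scores.gene_priority

    def test_adra1a_single_trait_is_not_priority(self):
        profile = TargetProfile(ensembl_id="ADRA1A", hgnc_symbol="ADRA1A", traits={Trait.AF})
        scores = prioritisation_score(profile)
        assert scores.prioritisation_score == 1
        assert not scores.gene_priority

    def test_nr3c1_lv_expression_plus_trait_is_priority(self):
        profile = TargetProfile(
            ensembl_id="NR3C1", hgnc_symbol="NR3C1",
            traits={Trait.AF}, tissues={Tissue.LV},
        )
        scores = prioritisation_score(profile)
        assert scores.prioritisation_score == 2
        assert scores.gene_priority


class TestRanking:
    def _scores(self, spec):
        out = []
        for symbol, total in spec:
            out.append(
                prioritisation_score(
                    TargetProfile(
                        ensembl_id=symbol, hgnc_symbol=symbol,
                        traits=set(list(Trait)[:total]),
                    )
                )
            )
        return out

    def test_descending_by_score(self):
        ranked = rank_targets(self._scores([("A", 3), ("B", 1), ("C", 2)]))
        assert [r.prioritisation_score for r in ranked] == [3, 2, 1]

    def test_ties_break_alphabetically(self):
        ranked = rank_targets(self._scores([("ZZB", 2), ("ZZA", 2)]))
        assert [r.hgnc_symbol for r in ranked] == ["ZZA", "ZZB"]

    @settings(deadline=None, max_examples=20)
    @given(perm=st.permutations(range(5)))
    def test_order_invariant_under_input_permutation(self, perm):
        scores = self._scores([("A", 3), ("B", 1), ("C", 2), ("D", 2), ("E", 0)])
        shuffled = [scores[i] for i in perm]
        assert rank_targets(shuffled) == rank_targets(scores)
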