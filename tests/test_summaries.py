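"""Indication adjacency matrix, action dendrogram, trait partition."""

import numpy as np
import pytest

from afdrugprior.scoring import prioritisation_score
from afdrugprior.summaries import (
    action_dendrogram,
    action_leaf_counts,
    format_trait_partition,
    indication_adjacency,
    partition_by_trait,
    to_newick,
)
from afdrugprior.synth import GeneratorConfig, generate_world
from afdrugprior.types import (
    DrugTargetLink,
    IndicationRecord,
    TargetProfile,
    Tissue,
    Trait,
)
from afdrugprior.xref import decode_indications


def ind(drug, specialty):
    return IndicationRecord(drug_id=drug, ontology_term="T", specialty=specialty)


class TestAdjacency:
    def test_single_drug_single_category(self):
        adj = indication_adjacency([ind("A", "cardiovascular")])
        assert adj.categories == ["cardiovascular"]
        assert adj.matrix == [[1]]

    def test_pairwise_overlap_counted_at_drug_granularity(self):
        rows = [ind("A", "cardio"), ind("B", "cardio"), ind("B", "resp"),
                ind("B", "resp")]  # duplicate indication row must not double count
        adj = indication_adjacency(rows)
        mat, cats = adj.to_array(), adj.categories
        i, j = cats.index("cardio"), cats.index("resp")
        assert mat[i, i] == 2 and mat[j, j] == 1
        assert mat[i, j] == mat[j, i] == 1

    def test_empty_input_gives_zero_dimension(self):
        adj = indication_adjacency([])
        assert adj.categories == [] and adj.matrix == []

    def test_category_order_descending_diagonal_then_alphabetical(self):
        rows = [ind("A", "zeta"), ind("B", "zeta"), ind("C", "alpha"), ind("D", "beta")]
        adj = indication_adjacency(rows)
        assert adj.categories == ["zeta", "alpha", "beta"]

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_diagonal_bound_on_random_bundles(self, seed):
        bundle = generate_world(GeneratorConfig(seed=seed, n_genes=20, n_parent_drugs=15))
        decoded, _ = decode_indications(bundle.indications, bundle.ontology_map)
        adj = indication_adjacency(decoded)
        mat = adj.to_array()
        assert np.array_equal(mat, mat.T)
        diag = np.diag(mat)
        for i in range(len(mat)):
            for j in range(len(mat)):
                if i != j:
                    assert mat[i, j] <= min(diag[i], diag[j])


def make_scores(symbols, priority=True):
    out = {}
    for s in symbols:
        profile = TargetProfile(
            ensembl_id=s, hgnc_symbol=s,
            traits={Trait.AF, Trait.PR_INDICES} if priority else set(),
        )
        out[s] = prioritisation_score(profile)
    return out


class TestDendrogram:
    def test_no_priority_drugs_gives_empty_tree(self):
        links = [DrugTargetLink(drug_id="D1", ensembl_id="E1",
                                action_type="inhibitor", target_class="Enzyme")]
        tree = action_dendrogram(links, make_scores(["E1"], priority=False))
        assert tree.children == []
        assert tree.leaves() == []

    def test_planted_inhibitors_structure(self):
        # 10 inhibitor drugs over 3 ion channels, all priority targets
        channels = ["E1", "E2", "E3"]
        links = [
            DrugTargetLink(drug_id=f"D{i}", ensembl_id=channels[i % 3],
                           action_type="inhibitor", target_class="Ion channel")
            for i in range(10)
        ]
        tree = action_dendrogram(links, make_scores(channels))
        (inhibitor,) = tree.children
        assert inhibitor.name == "inhibitor"
        (klass,) = inhibitor.children
        assert len(klass.children) == 3  # three target nodes
        assert len(tree.leaves()) == 10
        assert action_leaf_counts(tree) == {"inhibitor": 10}

    def test_leaf_multiset_equals_filtered_links(self, bundle):
        from afdrugprior.harmonise import annotate_reports, collapse_reports, resolve_reports
        from afdrugprior.xref import join_targets_to_drugs

        annotated = annotate_reports(bundle.reports, bundle.v2g)
        resolved, _ = resolve_reports(annotated, bundle.registry)
        profiles = collapse_reports(resolved)
        tract = {t.ensembl_id: t for t in bundle.tractability}
        scores = {
            p.ensembl_id: prioritisation_score(p, tract.get(p.ensembl_id))
            for p in profiles
        }
        links, _ = join_targets_to_drugs(bundle.registry, bundle.mechanisms, bundle.drugs)
        tree = action_dendrogram(links, scores)
        expected = [
            l for l in links
            if l.ensembl_id in scores and scores[l.ensembl_id].gene_priority
        ]
        assert len(tree.leaves()) == len(expected)

    def test_newick_serialisation_terminates_properly(self):
        links = [DrugTargetLink(drug_id="D1", ensembl_id="E1",
                                action_type="inhibitor", target_class="Ion channel")]
        text = to_newick(action_dendrogram(links, make_scores(["E1"])))
        assert text.endswith(";") and "inhibitor" in text


class TestTraitPartition:
    def test_all_af_only_gives_one_cell(self):
        profiles = [
            TargetProfile(ensembl_id=f"E{i}", hgnc_symbol=f"G{i}", traits={Trait.AF})
            for i in range(5)
        ]
        counts = partition_by_trait(profiles)
        assert counts == {frozenset({Trait.AF}): 5}

    def test_cells_sum_to_drugged_target_count(self, bundle):
        from afdrugprior.harmonise import annotate_reports, collapse_reports, resolve_reports

        annotated = annotate_reports(bundle.reports, bundle.v2g)
        resolved, _ = resolve_reports(annotated, bundle.registry)
        profiles = collapse_reports(resolved)
        drugged = {m.target_ensembl_id for m in bundle.mechanisms}
        counts = partition_by_trait(profiles, drugged)
        n_counted = len([p for p in profiles if p.ensembl_id in drugged])
        assert sum(counts.values()) == n_counted

    def test_planted_partition_recovered(self):
        bundle = generate_world(GeneratorConfig(seed=21, n_genes=50))
        from afdrugprior.harmonise import annotate_reports, collapse_reports, resolve_reports

        annotated = annotate_reports(bundle.reports, bundle.v2g)
        resolved, _ = resolve_reports(annotated, bundle.registry)
        profiles = collapse_reports(resolved)
        got = {p.ensembl_id: sorted(t.value for t in p.traits) for p in profiles}
        want = {k: v for k, v in bundle.truth.traits.items() if k in got}
        assert got == want

    def test_format_is_stable_and_json_friendly(self):
        counts = {
            frozenset({Trait.AF}): 3,
            frozenset({Trait.AF, Trait.PR_INDICES}): 2,
            frozenset(): 1,
        }
        out = format_trait_partition(counts)
        assert out == {"none": 1, "AF": 3, "AF+PR_INDICES": 2}
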