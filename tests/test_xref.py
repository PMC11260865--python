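"""Drug joins, salt/conjugate deduplication, indication decoding, queries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afdrugprior.synth import GeneratorConfig, generate_world
from afdrugprior.types import (
    DrugRecord,
    EvidenceSource,
    IndicationRecord,
    MechanismRecord,
    ParentDrug,
    TargetRecord,
)
from afdrugprior.xref import (
    DanglingReferenceError,
    build_query_records,
    build_search_queries,
    decode_indications,
    deduplicate_drugs,
    join_targets_to_drugs,
    parent_key,
)

SALTS = ["hydrochloride", "tartrate", "succinate", "sodium", "mesylate"]


class TestJoin:
    def test_fully_crossed_join_counts_pairs(self):
        targets = [TargetRecord(ensembl_id=f"E{i}", hgnc_symbol=f"G{i}") for i in range(3)]
        drugs = [DrugRecord(drug_id=f"D{i}", name=f"drug{i}") for i in range(10)]
        mechanisms = [
            MechanismRecord(drug_id=d.drug_id, action_type="inhibitor",
                            target_ensembl_id=t.ensembl_id)
            for d in drugs for t in targets
        ]
        links, undrugged = join_targets_to_drugs(targets, mechanisms, drugs)
        assert len(links) == 30
        assert undrugged == []

    def test_target_without_mechanisms_reported_undrugged(self):
        targets = [
            TargetRecord(ensembl_id="E1", hgnc_symbol="G1"),
            TargetRecord(ensembl_id="E2", hgnc_symbol="G2"),
        ]
        drugs = [DrugRecord(drug_id="D1", name="drug1")]
        mechanisms = [
            MechanismRecord(drug_id="D1", action_type="agonist", target_ensembl_id="E1")
        ]
        links, undrugged = join_targets_to_drugs(targets, mechanisms, drugs)
        assert len(links) == 1
        assert [t.ensembl_id for t in undrugged] == ["E2"]

    def test_dangling_drug_reference_raises(self):
        targets = [TargetRecord(ensembl_id="E1", hgnc_symbol="G1")]
        mechanisms = [
            MechanismRecord(drug_id="NOPE", action_type="blocker", target_ensembl_id="E1")
        ]
        with pytest.raises(DanglingReferenceError, match="NOPE"):
            join_targets_to_drugs(targets, mechanisms, [])


class TestDeduplication:
    def test_salt_forms_collapse_to_one_parent(self):
        drugs = [
            DrugRecord(drug_id="D1", name="Metoprolol Tartrate"),
            DrugRecord(drug_id="D2", name="Metoprolol Succinate"),
        ]
        (parent,) = deduplicate_drugs(drugs, SALTS)
        assert parent.parent_key == "metoprolol"
        assert parent.member_ids == ["D1", "D2"]

    def test_whitelisted_conjugate_stays_unique(self):
        # an antibody-drug conjugate of two active moieties is not a salt form
        drugs = [
            DrugRecord(drug_id="D1", name="examplemab tartrate"),
            DrugRecord(drug_id="D2", name="examplemab"),
        ]
        parents = deduplicate_drugs(drugs, SALTS, ["examplemab tartrate"])
        assert {p.parent_key for p in parents} == {"examplemab", "examplemab tartrate"}

    def test_repeated_salt_tokens_stripped(self):
        assert parent_key("drugx sodium succinate", SALTS) == "drugx"

    def test_never_strips_a_name_to_nothing(self):
        assert parent_key("sodium", SALTS) == "sodium"

    def test_planted_partition_recovered_exactly(self):
        bundle = generate_world(GeneratorConfig(seed=13, n_parent_drugs=25))
        assert len(bundle.truth.parent_partition) == 25 + bundle.config.n_conjugates
        parents = deduplicate_drugs(
            bundle.drugs, bundle.salt_lexicon, bundle.conjugate_whitelist
        )
        got = {p.parent_key: sorted(p.member_ids) for p in parents}
        want = {k: sorted(v) for k, v in bundle.truth.parent_partition.items()}
        assert got == want

    def test_partition_property_and_idempotence(self, bundle):
        parents = deduplicate_drugs(
            bundle.drugs, bundle.salt_lexicon, bundle.conjugate_whitelist
        )
        members = [m for p in parents for m in p.member_ids]
        assert sorted(members) == sorted(d.drug_id for d in bundle.drugs)
        # feeding back one representative per parent changes nothing
        reps = [DrugRecord(drug_id=p.member_ids[0], name=p.name) for p in parents]
        again = deduplicate_drugs(reps, bundle.salt_lexicon, bundle.conjugate_whitelist)
        assert {p.parent_key for p in again} == {p.parent_key for p in parents}

    @settings(deadline=None, max_examples=15)
    @given(perm=st.permutations(range(6)))
    def test_order_invariance(self, perm):
        drugs = [
            DrugRecord(drug_id=f"D{i}", name=name)
            for i, name in enumerate(
                ["alphaol", "alphaol tartrate", "betaine", "betaine sodium",
                 "gammaide", "gammaide mesylate"]
            )
        ]
        shuffled = [drugs[i] for i in perm]
        base = deduplicate_drugs(drugs, SALTS)
        other = deduplicate_drugs(shuffled, SALTS)
        assert base == other


class TestIndications:
    MAP = {"T:1": ("heart disease", "cardiovascular", ""),
           "T:2": ("asthma", "respiratory", "inflammation")}

    def _rows(self):
        rows = []
        for i in range(12):
            source = EvidenceSource.DAILYMED if i % 3 == 0 else EvidenceSource.TRIAL
            rows.append(
                IndicationRecord(drug_id=f"D{i}", ontology_term="T:1", evidence_source=source)
            )
        return rows

    def test_dailymed_rows_excluded(self):
        decoded, _ = decode_indications(self._rows(), self.MAP)
        assert len(decoded) == 8  # 12 rows, 4 DailyMed
        assert all(r.evidence_source != EvidenceSource.DAILYMED for r in decoded)

    def test_empty_table_gives_empty_output(self):
        decoded, unmapped = decode_indications([], self.MAP)
        assert decoded == [] and unmapped == []

    def test_unmapped_term_retained_and_flagged_never_dropped(self):
        rows = [IndicationRecord(drug_id="D1", ontology_term="T:999")]
        decoded, unmapped = decode_indications(rows, self.MAP)
        assert len(decoded) == 1
        assert decoded[0].specialty == "UNMAPPED"
        assert unmapped == decoded

    def test_decoding_fills_specialty_and_secondary(self):
        rows = [IndicationRecord(drug_id="D1", ontology_term="T:2")]
        (row,), _ = decode_indications(rows, self.MAP)
        assert row.specialty == "respiratory"
        assert row.secondary == "inflammation"


class TestQueries:
    def test_medline_query_template(self):
        medline, registry = build_search_queries("ranolazine")
        assert medline == '"ranolazine" AND "atrial fibrillation"'
        assert registry == ("atrial fibrillation", "ranolazine")

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            build_search_queries("  ")

    def test_two_query_records_per_parent(self):
        parents = [
            ParentDrug(parent_key=f"p{i}", name=f"p{i}", member_ids=[f"D{i}"],
                       member_names=[f"p{i}"])
            for i in range(613)
        ]
        records = build_query_records(parents)
        assert len(records) == 1226
        assert len(records) == 2 * len(parents)
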