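"""Drug-side cross-referencing: target-drug joins, salt/conjugate
deduplication, indication decoding, and literature query construction.

Drug-target links are built from mechanism-of-action rows keyed by Ensembl
id. Salt and ester formulations of the same active moiety are collapsed to
a parent drug by stripping trailing counter-ion tokens from a packaged
lexicon; conjugates of two active compounds (e.g. antibody-drug
conjugates) are whitelisted and kept unique. Indications arrive
ontology-coded and are decoded through a flat term-to-category mapping,
with DailyMed-sourced rows excluded as unreliably coded.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from .types import (
    DrugRecord,
    DrugTargetLink,
    EvidenceSource,
    IndicationRecord,
    MechanismRecord,
    ParentDrug,
    TargetRecord,
)

AF_CONDITION = "atrial fibrillation"
UNMAPPED = "UNMAPPED"


class DanglingReferenceError(ValueError):
    """A row references an id absent from its parent table."""


def join_targets_to_drugs(
    targets: Sequence[TargetRecord],
    mechanisms: Sequence[MechanismRecord],
    drugs: Sequence[DrugRecord],
) -> tuple[list[DrugTargetLink], list[TargetRecord]]:
    """Join targets to drugs through mechanism rows.

    Returns one link per (drug, target) mechanism plus the list of targets
    with zero links — druggable-but-undrugged candidates. A mechanism
    naming an unknown drug id raises :class:`DanglingReferenceError`;
    mechanisms for targets outside the registry are ignored (they belong
    to genes outside the analysis).
    """
    drug_ids = {d.drug_id for d in drugs}
    by_ensembl = {t.ensembl_id: t for t in targets}
    links: list[DrugTargetLink] = []
    linked: set[str] = set()
    for mech in mechanisms:
        if mech.drug_id not in drug_ids:
            raise DanglingReferenceError(
                f"mechanism references unknown drug id {mech.drug_id!r}"
            )
        target = by_ensembl.get(mech.target_ensembl_id)
        if target is None:
            continue
        links.append(
            DrugTargetLink(
                drug_id=mech.drug_id,
                ensembl_id=target.ensembl_id,
                action_type=mech.action_type,
                target_class=target.target_class,
            )
        )
        linked.add(target.ensembl_id)
    undrugged = [t for t in targets if t.ensembl_id not in linked]
    return links, undrugged


def normalise_drug_name(name: str) -> str:
    return " ".join(name.strip().casefold().split())


def parent_key(
    name: str,
    salt_lexicon: Iterable[str],
    conjugate_whitelist: Iterable[str] = (),
) -> str:
    """Parent (active-moiety) key for a drug name.

    Trailing tokens found in the salt lexicon are stripped repeatedly
    after case-folding; multi-word lexicon entries are honoured.
    Whitelisted conjugates keep their full name.
    """
    norm = normalise_drug_name(name)
    if norm in {normalise_drug_name(w) for w in conjugate_whitelist}:
        return norm
    salts = sorted(
        {normalise_drug_name(s) for s in salt_lexicon}, key=len, reverse=True
    )
    changed = True
    while changed:
        changed = False
        for salt in salts:
            suffix = " " + salt
            if norm.endswith(suffix):
                candidate = norm[: -len(suffix)].rstrip()
                if candidate:  # never strip a name down to nothing
                    norm = candidate
                    changed = True
                    break
    return norm


def deduplicate_drugs(
    drugs: Sequence[DrugRecord],
    salt_lexicon: Iterable[str],
    conjugate_whitelist: Iterable[str] = (),
) -> list[ParentDrug]:
    """Collapse salt/ester forms to unique parent drugs with member lists.

    The member lists partition the input exactly; the operation is
    idempotent and order-invariant (parents sorted by key, members by
    drug id).
    """
    salts = list(salt_lexicon)
    whitelist = list(conjugate_whitelist)
    groups: dict[str, list[DrugRecord]] = defaultdict(list)
    for drug in drugs:
        groups[parent_key(drug.name, salts, whitelist)].append(drug)
    parents = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda d: d.drug_id)
        parents.append(
            ParentDrug(
                parent_key=key,
                name=min((m.name for m in members), key=lambda n: (len(n), n)),
                member_ids=[m.drug_id for m in members],
                member_names=[m.name for m in members],
            )
        )
    return parents


def decode_indications(
    indications: Sequence[IndicationRecord],
    ontology_map: Mapping[str, tuple[str, str, str]],
) -> tuple[list[IndicationRecord], list[IndicationRecord]]:
    """Decode ontology-coded indications into specialty categories.

    ``ontology_map`` maps an ontology term id to ``(decoded_label,
    specialty, secondary)``. DailyMed-sourced rows are removed. Unmapped
    terms are retained with specialty ``UNMAPPED`` and returned in the
    second list for logging — never dropped silently.
    """
    decoded: list[IndicationRecord] = []
    unmapped: list[IndicationRecord] = []
    for row in indications:
        if row.evidence_source == EvidenceSource.DAILYMED:
            continue
        entry = ontology_map.get(row.ontology_term)
        if entry is None:
            row = row.model_copy(update={"specialty": UNMAPPED})
            unmapped.append(row)
        else:
            label, specialty, secondary = entry
            row = row.model_copy(
                update={
                    "decoded_label": label,
                    "specialty": specialty,
                    "secondary": secondary,
                }
            )
        decoded.append(row)
    return decoded, unmapped


def build_search_queries(drug_name: str, condition: str = AF_CONDITION) -> tuple[str, tuple[str, str]]:
    """Literature query strings for one drug.

    Returns the MEDLINE boolean query and the trial-registry
    (condition, intervention) field pair.
    """
    name = drug_name.strip()
    if not name:
        raise ValueError("drug name must be non-empty")
    medline = f'"{name}" AND "{condition}"'
    registry = (condition, name)
    return medline, registry


def build_query_records(
    parents: Sequence[ParentDrug], condition: str = AF_CONDITION
) -> list[dict]:
    """One MEDLINE and one registry query record per parent drug.

    Total record count is 2 x the number of parents.
    """
    records = []
    for parent in parents:
        medline, registry = build_search_queries(parent.name, condition)
        records.append(
            {"parent_key": parent.parent_key, "source": "MEDLINE", "query": medline}
        )
        records.append(
            {
                "parent_key": parent.parent_key,
                "source": "REGISTRY",
                "query": f"condition={registry[0]}; intervention={registry[1]}",
            }
        )
    return records
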