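"""Clinical-evidence synthesis per drug.

Curated evidence items are reduced to one summary row per drug: the
maximum level of evidence under the lattice Guideline > Systematic Review
> RCT > Observational, and a single overall effect reconciled among the
items at that maximum level (lower-level contradictions do not dilute the
verdict). Drugs with an AF-guideline indication are labelled existing
treatments regardless of item effects. Harm seen only in observational
data is downgraded to potential harm.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from .types import (
    DESIGN_RANK,
    DesignLevel,
    DrugEvidenceSummary,
    DrugRecord,
    DrugTargetLink,
    Effect,
    EvidenceItem,
    ParentDrug,
    PriorityScores,
)
from .xref import DanglingReferenceError, normalise_drug_name


def max_evidence_level(items: Iterable[EvidenceItem]) -> DesignLevel:
    """Supremum of item design levels; NONE for no items."""
    best = DesignLevel.NONE
    for item in items:
        if DESIGN_RANK[item.design_level] > DESIGN_RANK[best]:
            best = item.design_level
    return best


def overall_effect(
    items: Sequence[EvidenceItem],
    max_level: Optional[DesignLevel] = None,
    guideline_flag: bool = False,
) -> Effect:
    """Reconcile item effects into one overall effect.

    Guideline drugs are existing treatments. Otherwise only items at the
    maximum evidence level vote: opposing directions give MIXED, a
    unanimous direction is kept, harm at observational level only becomes
    POTENTIAL_HARM, and direction-free items give NEUTRAL.
    """
    if guideline_flag:
        return Effect.EXISTING_TREATMENT
    if max_level is None:
        max_level = max_evidence_level(items)
    if max_level == DesignLevel.NONE:
        return Effect.NONE
    top = [i for i in items if i.design_level == max_level]
    effects = {i.effect for i in top}
    if Effect.EXISTING_TREATMENT in effects:
        return Effect.EXISTING_TREATMENT
    benefit = Effect.BENEFICIAL in effects
    harm = bool(effects & {Effect.HARMFUL, Effect.POTENTIAL_HARM})
    if Effect.MIXED in effects or (benefit and harm):
        return Effect.MIXED
    if benefit:
        return Effect.BENEFICIAL
    if harm:
        if max_level == DesignLevel.OBSERVATIONAL:
            return Effect.POTENTIAL_HARM
        return Effect.HARMFUL
    return Effect.NEUTRAL


def assemble_summary(
    parents: Sequence[ParentDrug],
    links: Sequence[DrugTargetLink],
    scores: Mapping[str, PriorityScores],
    items: Sequence[EvidenceItem],
    guideline_list: Iterable[str],
    drugs: Sequence[DrugRecord] = (),
    symbol_of: Optional[Mapping[str, str]] = None,
) -> tuple[list[DrugEvidenceSummary], dict[str, int]]:
    """Build one summary row per parent drug with clinical evidence.

    ``scores`` maps target Ensembl id to its priority scores; a drug is
    high-priority when any linked target has gene priority. ``symbol_of``
    optionally maps Ensembl ids to symbols for the output. Evidence items
    naming a drug outside the parent set raise
    :class:`DanglingReferenceError`. Drugs without items are excluded but
    counted in the returned coverage report.
    """
    by_name = {normalise_drug_name(p.name): p for p in parents}
    by_key = {p.parent_key: p for p in parents}
    items_by_parent: dict[str, list[EvidenceItem]] = defaultdict(list)
    for item in items:
        parent = by_name.get(normalise_drug_name(item.drug_name)) or by_key.get(
            normalise_drug_name(item.drug_name)
        )
        if parent is None:
            raise DanglingReferenceError(
                f"evidence item names unknown drug {item.drug_name!r}"
            )
        items_by_parent[parent.parent_key].append(item)

    guideline_keys = {normalise_drug_name(g) for g in guideline_list}
    member_to_parent = {
        mid: p.parent_key for p in parents for mid in p.member_ids
    }
    targets_by_parent: dict[str, set[str]] = defaultdict(set)
    for link in links:
        pkey = member_to_parent.get(link.drug_id, link.drug_id)
        targets_by_parent[pkey].add(link.ensembl_id)
    drug_by_id = {d.drug_id: d for d in drugs}

    summaries = []
    for parent in parents:
        drug_items = items_by_parent.get(parent.parent_key)
        if not drug_items:
            continue
        level = max_evidence_level(drug_items)
        guideline_flag = normalise_drug_name(parent.name) in guideline_keys
        effect = overall_effect(drug_items, level, guideline_flag)
        if guideline_flag:
            level = DesignLevel.GUIDELINE
        target_ids = sorted(targets_by_parent.get(parent.parent_key, set()))
        high_priority = any(
            tid in scores and scores[tid].gene_priority for tid in target_ids
        )
        members = [drug_by_id[m] for m in parent.member_ids if m in drug_by_id]
        black_box = "; ".join(sorted({m.black_box for m in members if m.black_box}))
        withdrawn = any(m.withdrawn for m in members)
        if symbol_of:
            target_names = sorted(symbol_of.get(t, t) for t in target_ids)
        else:
            target_names = target_ids
        summaries.append(
            DrugEvidenceSummary(
                drug_name=parent.name,
                associated_targets=target_names,
                max_level=level,
                overall_effect=effect,
                black_box=black_box,
                withdrawn=withdrawn,
                high_priority=high_priority,
            )
        )
    coverage = {
        "parents_total": len(parents),
        "parents_with_evidence": len(summaries),
        "parents_without_evidence": len(parents) - len(summaries),
    }
    return summaries, coverage
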