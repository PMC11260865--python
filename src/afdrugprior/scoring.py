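"""Druggability and genetic-prioritisation scoring.

Two druggability domains are scored per target:

* small molecule (0-2): one point for membership in a druggable protein
  family, one point for a usable structural pocket — the pocket score is
  tiered high (>= 0.7) / medium (0 < score < 0.7), and both tiers earn the
  same single point, so any strictly positive assessed score counts;
* antibody (0-3): one point per source (UniProt, GO, HPA) calling a
  high-confidence accessible localisation (plasma membrane, extracellular
  matrix or secreted).

A target is druggability-prioritised when either domain score exceeds 1.

The genetic prioritisation score (0-7) adds one point per trait (AF, PR
indices, LA indices) with association evidence, one per cardiac tissue
(LA, RA, LV) with TWAS or eQTL-colocalization evidence, and one for
rare-variant association support; gene priority requires a total > 1.
Both >1 cut-offs are exposed for sensitivity analyses.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .types import (
    PriorityScores,
    TargetProfile,
    Tissue,
    TractabilityRecord,
    Trait,
)

#: Traits and tissues that can earn prioritisation points.
SCORED_TRAITS = (Trait.AF, Trait.PR_INDICES, Trait.LA_INDICES)
SCORED_TISSUES = (Tissue.LA, Tissue.RA, Tissue.LV)

DEFAULT_PRIORITY_THRESHOLD = 1


def small_molecule_score(t: TractabilityRecord) -> int:
    """Small-molecule druggability score (0-2)."""
    if t.pocket_score is not None and not (0.0 <= t.pocket_score <= 1.0):
        raise ValueError(f"pocket_score {t.pocket_score} outside [0, 1]")
    score = int(t.druggable_family)
    if t.pocket_score is not None and t.pocket_score > 0.0:
        score += 1
    return score


def antibody_score(t: TractabilityRecord) -> int:
    """Antibody tractability score (0-3): one point per accessibility source."""
    return int(t.accessible_uniprot) + int(t.accessible_go) + int(t.accessible_hpa)


def prioritisation_score(
    profile: TargetProfile,
    tractability: Optional[TractabilityRecord] = None,
    *,
    druggability_threshold: int = DEFAULT_PRIORITY_THRESHOLD,
    priority_threshold: int = DEFAULT_PRIORITY_THRESHOLD,
) -> PriorityScores:
    """Score a collapsed evidence profile.

    When no tractability record exists for the target, both druggability
    domain scores are 0 (nothing is known to support tractability).
    """
    tract = tractability or TractabilityRecord(ensembl_id=profile.ensembl_id)
    sm = small_molecule_score(tract)
    ab = antibody_score(tract)
    trait_points = sum(t in profile.traits for t in SCORED_TRAITS)
    tissue_points = sum(t in profile.tissues for t in SCORED_TISSUES)
    rvas_point = int(profile.rare_variant)
    total = trait_points + tissue_points + rvas_point
    return PriorityScores(
        ensembl_id=profile.ensembl_id,
        hgnc_symbol=profile.hgnc_symbol,
        sm_score=sm,
        ab_score=ab,
        druggability_priority=(sm > druggability_threshold or ab > druggability_threshold),
        trait_points=trait_points,
        tissue_points=tissue_points,
        rvas_point=rvas_point,
        prioritisation_score=total,
        gene_priority=total > priority_threshold,
    )


def rank_targets(scores: Iterable[PriorityScores]) -> list[PriorityScores]:
    """Order targets by descending prioritisation score.

    Ties break alphabetically by HGNC symbol (then Ensembl id), so the
    ordering is deterministic and invariant under input permutation.
    """
    return sorted(
        scores,
        key=lambda s: (-s.prioritisation_score, s.hgnc_symbol, s.ensembl_id),
    )
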