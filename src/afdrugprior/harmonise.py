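"""Gene-label harmonisation and variant-to-gene annotation.

Published association studies report gene labels that do not always match
the approved HGNC symbol, and annotate variants by proximity or legacy
conventions. This module resolves reported labels against the target
registry through a fallback chain (exact match, registry synonym, curated
manual map) and applies the variant-to-gene (V2G) precedence rule: a
variant present in the V2G lookup takes its V2G gene; otherwise the
original authors' annotation is kept.

Symbols are normalised before comparison: surrounding whitespace trimmed,
case folded, and a trailing ``.N`` version suffix stripped.
"""

from __future__ import annotations

import re
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from .types import (
    AnalysisClass,
    AnnotationSource,
    GeneReport,
    ResolutionMethod,
    SymbolResolution,
    TargetProfile,
    TargetRecord,
    Tissue,
    Trait,
)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class AmbiguousSymbolError(ValueError):
    """One reported symbol matches synonyms of several registry entries."""

    def __init__(self, reported: str, candidates: Sequence[str]):
        self.reported = reported
        self.candidates = sorted(candidates)
        super().__init__(
            f"symbol {reported!r} is a synonym of multiple registry entries: "
            f"{', '.join(self.candidates)}"
        )


def normalise_symbol(symbol: str) -> str:
    """Canonical form used for symbol comparison."""
    return _VERSION_SUFFIX.sub("", symbol.strip()).casefold()


class RegistryIndex:
    """Symbol and synonym lookup structures over a target registry."""

    def __init__(self, registry: Iterable[TargetRecord]):
        self.by_symbol: dict[str, TargetRecord] = {}
        self.by_synonym: dict[str, list[TargetRecord]] = defaultdict(list)
        self.by_ensembl: dict[str, TargetRecord] = {}
        for rec in registry:
            self.by_symbol[normalise_symbol(rec.hgnc_symbol)] = rec
            self.by_ensembl[rec.ensembl_id] = rec
            for syn in rec.synonyms:
                self.by_synonym[normalise_symbol(syn)].append(rec)


def resolve_symbol(
    reported: str,
    registry: RegistryIndex | Iterable[TargetRecord],
    manual_map: Optional[Mapping[str, str]] = None,
) -> SymbolResolution:
    """Resolve a reported gene label via EXACT → SYNONYM → MANUAL → UNRESOLVED.

    ``manual_map`` maps reported labels to approved symbols (the curated
    web-search stage). A synonym matching two distinct registry entries
    raises :class:`AmbiguousSymbolError` listing the candidates.
    """
    index = registry if isinstance(registry, RegistryIndex) else RegistryIndex(registry)
    manual = {normalise_symbol(k): v for k, v in (manual_map or {}).items()}
    norm = normalise_symbol(reported)

    hit = index.by_symbol.get(norm)
    if hit is not None:
        return SymbolResolution(
            reported_symbol=reported,
            resolved_symbol=hit.hgnc_symbol,
            ensembl_id=hit.ensembl_id,
            method=ResolutionMethod.EXACT,
        )

    syn_hits = {rec.ensembl_id: rec for rec in index.by_synonym.get(norm, [])}
    if len(syn_hits) > 1:
        raise AmbiguousSymbolError(reported, [r.hgnc_symbol for r in syn_hits.values()])
    if len(syn_hits) == 1:
        (rec,) = syn_hits.values()
        return SymbolResolution(
            reported_symbol=reported,
            resolved_symbol=rec.hgnc_symbol,
            ensembl_id=rec.ensembl_id,
            method=ResolutionMethod.SYNONYM,
        )

    if norm in manual:
        target = index.by_symbol.get(normalise_symbol(manual[norm]))
        if target is not None:
            return SymbolResolution(
                reported_symbol=reported,
                resolved_symbol=target.hgnc_symbol,
                ensembl_id=target.ensembl_id,
                method=ResolutionMethod.MANUAL,
            )

    return SymbolResolution(reported_symbol=reported, method=ResolutionMethod.UNRESOLVED)


def annotate_variant(
    variant_id: str,
    v2g: Mapping[str, str],
    author_gene: str,
) -> tuple[str, AnnotationSource]:
    """Gene annotation for a variant with V2G-over-author precedence.

    A variant present in the V2G table with a non-empty gene wins; an
    absent variant (or one mapped to an empty gene) falls back to the
    original authors' annotation.
    """
    gene = v2g.get(variant_id, "")
    if variant_id and gene:
        return gene, AnnotationSource.V2G
    return author_gene, AnnotationSource.AUTHOR


def annotate_reports(
    reports: Iterable[GeneReport], v2g: Mapping[str, str]
) -> list[GeneReport]:
    """Apply the V2G precedence rule to every report's gene annotation."""
    out = []
    for rep in reports:
        gene, source = annotate_variant(rep.variant_id, v2g, rep.reported_symbol)
        out.append(
            rep.model_copy(update={"reported_symbol": gene, "annotation_source": source})
        )
    return out


def resolve_reports(
    reports: Iterable[GeneReport],
    registry: RegistryIndex | Iterable[TargetRecord],
    manual_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[tuple[GeneReport, SymbolResolution]], list[SymbolResolution]]:
    """Resolve every report's symbol; unresolved and ambiguous go to a log.

    Ambiguous synonym hits are excluded (logged as UNRESOLVED with the
    candidate list in the log entry), never guessed.
    """
    index = registry if isinstance(registry, RegistryIndex) else RegistryIndex(registry)
    resolved: list[tuple[GeneReport, SymbolResolution]] = []
    unresolved: list[SymbolResolution] = []
    for rep in reports:
        try:
            res = resolve_symbol(rep.reported_symbol, index, manual_map)
        except AmbiguousSymbolError:
            res = SymbolResolution(
                reported_symbol=rep.reported_symbol, method=ResolutionMethod.UNRESOLVED
            )
        if res.method == ResolutionMethod.UNRESOLVED:
            unresolved.append(res)
        else:
            resolved.append((rep, res))
    return resolved, unresolved


def collapse_reports(
    resolved: Sequence[tuple[GeneReport, SymbolResolution]],
) -> list[TargetProfile]:
    """Collapse study-level reports into one evidence profile per gene.

    A profile stores the set of traits with at least one association
    report, the set of cardiac tissues with at least one TWAS or eQTL
    report (unioned, one per tissue), a rare-variant flag, and
    per-analysis-class report counts. Exactly identical reports are
    counted once, and output order is alphabetical by symbol, so the
    result is invariant under input permutation and duplication.
    """
    profiles: dict[str, TargetProfile] = {}
    seen: set[tuple] = set()
    for rep, res in resolved:
        key_tuple = (tuple(rep.model_dump().items()), res.ensembl_id, res.resolved_symbol)
        if key_tuple in seen:
            continue
        seen.add(key_tuple)
        key = res.ensembl_id or res.resolved_symbol
        prof = profiles.get(key)
        if prof is None:
            prof = TargetProfile(ensembl_id=res.ensembl_id, hgnc_symbol=res.resolved_symbol)
            profiles[key] = prof
        # RVAS reports feed the separate rare-variant scoring domain; their
        # trait is not double-counted into the trait-association domain.
        if rep.trait != Trait.NONE and rep.analysis_class != AnalysisClass.RVAS:
            prof.traits.add(rep.trait)
        if rep.tissue != Tissue.NONE:
            prof.tissues.add(rep.tissue)
        if rep.analysis_class == AnalysisClass.RVAS:
            prof.rare_variant = True
        prof.report_counts[rep.analysis_class] = (
            prof.report_counts.get(rep.analysis_class, 0) + 1
        )
    return sorted(profiles.values(), key=lambda p: (p.hgnc_symbol, p.ensembl_id))
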