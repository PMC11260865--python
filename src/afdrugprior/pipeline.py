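"""End-to-end orchestration: harmonise → score → cross-reference →
synthesise evidence → summarise.

A run consumes a bundle directory (as written by the synthetic generator,
or assembled by hand in the same layout), executes every stage, and
writes each stage's artefact plus a manifest of output checksums and a
machine-readable log of stage counts (reports in, genes resolved, targets
prioritised, parents after dedup, drugs with evidence). Identical inputs
and config produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from . import fixtures, reconstruct
from .evidence import assemble_summary
from .harmonise import annotate_reports, collapse_reports, resolve_reports
from .io import read_table, render_table, write_table
from .scoring import prioritisation_score, rank_targets
from .summaries import (
    action_dendrogram,
    action_leaf_counts,
    format_trait_partition,
    indication_adjacency,
    partition_by_trait,
    to_newick,
)
from .types import (
    DesignLevel,
    DrugRecord,
    EvidenceItem,
    GeneReport,
    IndicationRecord,
    MechanismRecord,
    PriorityScores,
    TargetRecord,
    TractabilityRecord,
)
from .xref import build_query_records, decode_indications, deduplicate_drugs, join_targets_to_drugs

logger = logging.getLogger("afdrugprior")


class RunConfig(BaseModel):
    """Configuration of one pipeline run (YAML-loadable)."""

    input_dir: Path
    output_dir: Path
    druggability_threshold: int = 1
    priority_threshold: int = 1
    salt_lexicon_path: Optional[Path] = None
    conjugate_whitelist_path: Optional[Path] = None
    guideline_list_path: Optional[Path] = None
    manual_map_path: Optional[Path] = None
    seed: Optional[int] = None
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _paths_exist(self) -> "RunConfig":
        if not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir {self.input_dir} does not exist")
        for attr in ("salt_lexicon_path", "conjugate_whitelist_path",
                     "guideline_list_path", "manual_map_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{attr} {p} does not exist")
        return self

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


def _read_two_col(path: Path, skip_header: bool = True) -> dict[str, str]:
    out: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    for line in lines[1:] if skip_header else lines:
        if not line.strip() or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        out[key] = value
    return out


def _read_ontology_map(path: Path) -> dict[str, tuple[str, str, str]]:
    out = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        term, label, specialty, secondary = (line.split("\t") + ["", "", ""])[:4]
        out[term] = (label, specialty, secondary)
    return out


def _read_list(path: Path) -> list[str]:
    return [
        ln.strip()
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages over a bundle directory; returns the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    registry: list[TargetRecord] = read_table(indir / "registry.tsv", TargetRecord)
    tractability = read_table(indir / "tractability.tsv", TractabilityRecord)
    reports: list[GeneReport] = read_table(indir / "gene_reports.tsv", GeneReport)
    drugs: list[DrugRecord] = read_table(indir / "drugs.tsv", DrugRecord)
    mechanisms = read_table(indir / "mechanisms.tsv", MechanismRecord)
    indications = read_table(indir / "indications.tsv", IndicationRecord)
    items: list[EvidenceItem] = read_table(indir / "evidence_items.tsv", EvidenceItem)
    v2g = _read_two_col(indir / "v2g.tsv")
    ontology_map = _read_ontology_map(indir / "ontology_map.tsv")
    salt_lexicon = _read_list(
        Path(config.salt_lexicon_path or indir / "salt_lexicon.txt")
    )
    whitelist_path = Path(config.conjugate_whitelist_path or indir / "conjugate_whitelist.txt")
    conjugates = _read_list(whitelist_path) if whitelist_path.exists() else []
    guideline_path = Path(config.guideline_list_path or indir / "guideline_drugs.txt")
    guidelines = _read_list(guideline_path) if guideline_path.exists() else []
    manual_map = (
        _read_two_col(Path(config.manual_map_path), skip_header=False)
        if config.manual_map_path
        else {}
    )

    counts: dict[str, int] = {"reports_in": len(reports)}

    # Stage 1: harmonise
    annotated = annotate_reports(reports, v2g)
    resolved, unresolved = resolve_reports(annotated, registry, manual_map)
    profiles = collapse_reports(resolved)
    counts["reports_resolved"] = len(resolved)
    counts["reports_unresolved"] = len(unresolved)
    counts["genes_resolved"] = len(profiles)

    # Stage 2: score
    tract_by_id = {t.ensembl_id: t for t in tractability}
    scores = rank_targets(
        prioritisation_score(
            p,
            tract_by_id.get(p.ensembl_id),
            druggability_threshold=config.druggability_threshold,
            priority_threshold=config.priority_threshold,
        )
        for p in profiles
    )
    score_by_id: dict[str, PriorityScores] = {s.ensembl_id: s for s in scores}
    counts["targets_prioritised"] = sum(s.gene_priority for s in scores)

    # Stage 3: cross-reference drugs
    links, undrugged = join_targets_to_drugs(registry, mechanisms, drugs)
    parents = deduplicate_drugs(drugs, salt_lexicon, conjugates)
    member_to_parent = {m: p.parent_key for p in parents for m in p.member_ids}
    links = [l.model_copy(update={"parent_drug_key": member_to_parent.get(l.drug_id, "")}) for l in links]
    decoded, unmapped = decode_indications(indications, ontology_map)
    queries = build_query_records(parents)
    counts["drug_forms_in"] = len(drugs)
    counts["parents_after_dedup"] = len(parents)
    counts["drug_target_links"] = len(links)
    counts["undrugged_targets"] = len(undrugged)
    counts["indications_decoded"] = len(decoded)
    counts["indications_unmapped"] = len(unmapped)
    counts["query_records"] = len(queries)

    # Stage 4: evidence synthesis
    symbol_of = {t.ensembl_id: t.hgnc_symbol for t in registry}
    summaries_rows, coverage = assemble_summary(
        parents, links, score_by_id, items, guidelines, drugs=drugs, symbol_of=symbol_of
    )
    counts["drugs_with_evidence"] = coverage["parents_with_evidence"]

    # Stage 5: summary structures
    adjacency = indication_adjacency(decoded, member_to_parent)
    drug_names = {d.drug_id: d.name for d in drugs}
    tree = action_dendrogram(links, score_by_id, drug_names)
    drugged_ids = {l.ensembl_id for l in links}
    trait_partition = format_trait_partition(partition_by_trait(profiles, drugged_ids))

    # --- write artefacts ----------------------------------------------------
    artefacts: dict[str, Path] = {}

    def emit(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text, encoding="utf-8")
        artefacts[name] = path

    emit("profiles.tsv", render_table(profiles, "TargetProfile"))
    emit("scores.tsv", render_table(scores, "PriorityScores"))
    emit("links.tsv", render_table(links, "DrugTargetLink"))
    emit("parents.tsv", render_table(parents, "ParentDrug"))
    emit("undrugged_targets.tsv", render_table(undrugged, "TargetRecord"))
    emit("indications_decoded.tsv", render_table(decoded, "IndicationRecord"))
    emit(
        "queries.tsv",
        "parent_key\tsource\tquery\n"
        + "".join(f"{q['parent_key']}\t{q['source']}\t{q['query']}\n" for q in queries),
    )
    emit(
        "unresolved_symbols.tsv",
        "reported_symbol\n" + "".join(f"{u.reported_symbol}\n" for u in unresolved),
    )
    emit(
        "summary.tsv",
        "drug_name\tassociated_targets\tmax_level\toverall_effect\tblack_box\twithdrawn\thigh_priority\n"
        + "".join(
            f"{s.drug_name}\t{';'.join(s.associated_targets)}\t{s.max_level.value}\t"
            f"{s.overall_effect.value}\t{s.black_box}\t{str(s.withdrawn).lower()}\t"
            f"{str(s.high_priority).lower()}\n"
            for s in summaries_rows
        ),
    )
    emit(
        "indication_adjacency.json",
        json.dumps(
            {"categories": adjacency.categories, "matrix": adjacency.matrix}, indent=1
        )
        + "\n",
    )
    emit(
        "indication_adjacency.tsv",
        "category\t" + "\t".join(adjacency.categories) + "\n"
        + "".join(
            c + "\t" + "\t".join(str(x) for x in row) + "\n"
            for c, row in zip(adjacency.categories, adjacency.matrix)
        ),
    )
    emit("action_tree.json", tree.model_dump_json(indent=1) + "\n")
    emit("action_tree.nwk", to_newick(tree) + "\n")
    emit(
        "trait_partition.json",
        json.dumps(trait_partition, indent=1) + "\n",
    )
    emit(
        "action_leaf_counts.json",
        json.dumps(action_leaf_counts(tree), indent=1, sort_keys=True) + "\n",
    )
    emit("stage_counts.json", json.dumps(counts, indent=1) + "\n")

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "counts": counts,
        "artefacts": {name: _sha256(path) for name, path in sorted(artefacts.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    for stage, n in counts.items():
        logger.info("%s: %d", stage, n)
    return manifest


def validate_fixtures() -> list[dict]:
    """Assert fixture invariants; returns a list of named checks.

    Each entry has ``name``, ``passed`` and ``detail``. Fixture drift,
    wrong row counts or broken enum domains fail their check.
    """
    checks: list[dict] = []

    def check(name: str, passed: bool, detail: str = "") -> None:
        checks.append({"name": name, "passed": bool(passed), "detail": detail})

    manifest_ok = fixtures.verify_manifest()
    check(
        "manifest_checksums",
        all(manifest_ok.values()),
        ", ".join(f"{k}={'ok' if v else 'FAIL'}" for k, v in manifest_ok.items()),
    )
    try:
        targets = fixtures.load_drugged_targets()
        check("table1_loads", True, f"{len(targets)} rows")
        check("table1_target_count_68", len(targets) == 68, f"found {len(targets)}")
        symbols = [t.hgnc_symbol for t in targets]
        check("table1_symbols_unique", len(set(symbols)) == len(symbols))
    except Exception as exc:  # pragma: no cover - corruption path
        check("table1_loads", False, str(exc))
    try:
        rows = fixtures.load_drug_evidence()
        counts = reconstruct.guideline_level_count(rows)
        check("table2_loads", True, f"{len(rows)} rows")
        check(
            "table2_guideline_rows_21",
            counts.get(DesignLevel.GUIDELINE, 0) == 21,
            f"found {counts.get(DesignLevel.GUIDELINE, 0)}",
        )
        check(
            "table2_observational_rows_15",
            counts.get(DesignLevel.OBSERVATIONAL, 0) == 15,
            f"found {counts.get(DesignLevel.OBSERVATIONAL, 0)}",
        )
    except Exception as exc:  # pragma: no cover - corruption path
        check("table2_loads", False, str(exc))
    bp = fixtures.load_bp_targets()
    check("bp_gene_list_31", len(bp) == 31, f"found {len(bp)}")
    nd = fixtures.load_non_druggable_targets()
    check("non_druggable_list_12", len(nd) == 12, f"found {len(nd)}")
    guidelines = fixtures.load_guideline_drugs()
    check("guideline_list_21", len(guidelines) == 21, f"found {len(guidelines)}")
    return checks
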