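"""Seeded synthetic-world generator.

Builds every input table the pipeline consumes — target registry,
tractability, variant-to-gene lookup, per-study gene reports, drug forms
with planted salt duplicates and conjugates, mechanisms, ontology-coded
indications and curated evidence items — together with a ground-truth
ledger (the planted priority-gene set, the true parent-drug partition,
the true trait/tissue/rare-variant assignments and the variants withheld
from the V2G table). Every stage of the pipeline is therefore testable
for exact parameter recovery without any external download.

The generator emulates the statistical structure of the real corpus:
sparse multi-study gene evidence, tiered tractability annotations, and
many-to-many drug-target links. Gene and drug names come from a
pronounceable-token scheme (``ZZ``-prefixed symbols, invented lowercase
drug stems) disjoint from real HGNC symbols and drug names, so synthetic
worlds can never collide with the packaged fixtures.

Defaults are scaled-down study conditions: 150 genes over 18 studies and
40 parent drugs, a quarter of genes planted as priority, 70% V2G
coverage. Real-world marginal counts (about a thousand genes, six hundred
drugs) are deliberately not matched; they depend on external database
snapshots, and nothing downstream depends on scale.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .io import write_table
from .types import (
    AnalysisClass,
    AnnotationSource,
    DesignLevel,
    DrugRecord,
    Effect,
    EvidenceItem,
    EvidenceSource,
    GeneReport,
    IndicationRecord,
    MechanismRecord,
    TargetRecord,
    Tissue,
    TractabilityRecord,
    Trait,
)

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_ACTION_TYPES = ["inhibitor", "agonist", "antagonist", "blocker", "modulator", "activator"]
_TARGET_CLASSES = [
    "Ion channel",
    "Enzyme",
    "Membrane receptor",
    "Transcription factor",
    "Transporter",
    "Secreted protein",
]
_SPECIALTIES = [
    "cardiovascular",
    "respiratory",
    "oncology",
    "neurology",
    "endocrinology",
    "psychiatry",
    "infectious disease",
    "rheumatology",
]
_SALTS = ["hydrochloride", "tartrate", "succinate", "mesylate", "sodium", "maleate"]


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic world; all probabilities in [0, 1]."""

    seed: int = 0
    n_genes: int = Field(default=150, gt=0)
    n_studies: int = Field(default=18, gt=0)
    trait_probs: dict[Trait, float] = Field(
        default_factory=lambda: {Trait.AF: 0.5, Trait.PR_INDICES: 0.3, Trait.LA_INDICES: 0.1}
    )
    tissue_probs: dict[Tissue, float] = Field(
        default_factory=lambda: {Tissue.LA: 0.25, Tissue.RA: 0.3, Tissue.LV: 0.3}
    )
    rvas_prob: float = Field(default=0.15, ge=0, le=1)
    v2g_coverage: float = Field(default=0.7, ge=0, le=1)
    n_parent_drugs: int = Field(default=40, gt=0)
    salt_multiplicity: dict[int, float] = Field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    n_conjugates: int = Field(default=2, ge=0)
    mechanism_density: float = Field(default=1.8, gt=0)
    specialty_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "cardiovascular": 0.3,
            "oncology": 0.2,
            "respiratory": 0.1,
            "neurology": 0.1,
            "endocrinology": 0.1,
            "psychiatry": 0.08,
            "infectious disease": 0.07,
            "rheumatology": 0.05,
        }
    )
    evidence_prob: float = Field(default=0.5, ge=0, le=1)
    level_probs: dict[DesignLevel, float] = Field(
        default_factory=lambda: {
            DesignLevel.SYSTEMATIC_REVIEW: 0.2,
            DesignLevel.RCT: 0.4,
            DesignLevel.OBSERVATIONAL: 0.4,
        }
    )
    effect_probs: dict[Effect, float] = Field(
        default_factory=lambda: {
            Effect.BENEFICIAL: 0.4,
            Effect.NEUTRAL: 0.35,
            Effect.HARMFUL: 0.25,
        }
    )
    guideline_fraction: float = Field(default=0.1, ge=0, le=1)
    planted_priority_fraction: float = Field(default=0.25, ge=0, le=1)

    @field_validator("trait_probs", "tissue_probs", "salt_multiplicity",
                     "specialty_probs", "level_probs", "effect_probs")
    @classmethod
    def _probs_in_unit(cls, v: dict) -> dict:
        for key, p in v.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {key} outside [0, 1]: {p}")
        return v

    @model_validator(mode="after")
    def _feasible(self) -> "GeneratorConfig":
        if round(self.planted_priority_fraction * self.n_genes) > self.n_genes:
            raise ValueError("more planted priority genes than genes")
        return self


@dataclass
class GroundTruth:
    """Planted facts the pipeline must recover."""

    priority_genes: list[str] = field(default_factory=list)  # ensembl ids
    priority_symbols: list[str] = field(default_factory=list)
    traits: dict[str, list[str]] = field(default_factory=dict)  # ensembl -> trait values
    tissues: dict[str, list[str]] = field(default_factory=dict)
    rvas_genes: list[str] = field(default_factory=list)
    parent_partition: dict[str, list[str]] = field(default_factory=dict)  # key -> drug ids
    withheld_variants: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


@dataclass
class Bundle:
    """A full synthetic input bundle plus its ground-truth ledger."""

    config: GeneratorConfig
    registry: list[TargetRecord]
    tractability: list[TractabilityRecord]
    v2g: dict[str, str]
    reports: list[GeneReport]
    drugs: list[DrugRecord]
    mechanisms: list[MechanismRecord]
    indications: list[IndicationRecord]
    evidence_items: list[EvidenceItem]
    guideline_drugs: list[str]
    salt_lexicon: list[str]
    conjugate_whitelist: list[str]
    ontology_map: dict[str, tuple[str, str, str]]
    truth: GroundTruth

    def write(self, outdir: Path | str) -> dict[str, Path]:
        """Serialise the bundle to a directory of TSV/JSON files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "registry.tsv": (self.registry, TargetRecord),
            "tractability.tsv": (self.tractability, TractabilityRecord),
            "gene_reports.tsv": (self.reports, GeneReport),
            "drugs.tsv": (self.drugs, DrugRecord),
            "mechanisms.tsv": (self.mechanisms, MechanismRecord),
            "indications.tsv": (self.indications, IndicationRecord),
            "evidence_items.tsv": (self.evidence_items, EvidenceItem),
        }
        for name, (records, schema) in tables.items():
            paths[name] = write_table(records, outdir / name, schema)
        (outdir / "v2g.tsv").write_text(
            "variant_id\tgene_id\n"
            + "".join(f"{k}\t{v}\n" for k, v in sorted(self.v2g.items())),
            encoding="utf-8",
        )
        (outdir / "ontology_map.tsv").write_text(
            "term\tlabel\tspecialty\tsecondary\n"
            + "".join(
                f"{t}\t{l}\t{s}\t{sec}\n"
                for t, (l, s, sec) in sorted(self.ontology_map.items())
            ),
            encoding="utf-8",
        )
        for name, lines in [
            ("guideline_drugs.txt", self.guideline_drugs),
            ("salt_lexicon.txt", self.salt_lexicon),
            ("conjugate_whitelist.txt", self.conjugate_whitelist),
        ]:
            (outdir / name).write_text("".join(f"{x}\n" for x in lines), encoding="utf-8")
        (outdir / "ledger.json").write_text(self.truth.to_json() + "\n", encoding="utf-8")
        paths["ledger.json"] = outdir / "ledger.json"
        return paths


def _syllables(rng: np.random.Generator, n: int) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n)
    )


def _gene_symbol(rng: np.random.Generator, i: int) -> str:
    return f"ZZ{_syllables(rng, 2).upper()}{i}"


def _drug_stem(rng: np.random.Generator, i: int) -> str:
    suffix = ["ib", "ol", "ine", "ide", "an", "one"][int(rng.integers(6))]
    return f"{_syllables(rng, 2)}{suffix}{i}"


def _weighted_choice(rng: np.random.Generator, probs: dict) -> object:
    keys = list(probs)
    weights = np.array([probs[k] for k in keys], dtype=float)
    weights = weights / weights.sum()
    return keys[int(rng.choice(len(keys), p=weights))]


def generate_world(config: GeneratorConfig) -> Bundle:
    """Generate a full input bundle with known ground truth.

    Deterministic under a fixed seed: the same config yields a
    byte-identical serialised bundle.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    # --- genes, registry, tractability -------------------------------------
    n_priority = int(round(config.planted_priority_fraction * config.n_genes))
    registry: list[TargetRecord] = []
    tractability: list[TractabilityRecord] = []
    gene_truth: list[dict] = []
    for i in range(config.n_genes):
        symbol = _gene_symbol(rng, i)
        ensembl = f"ENSZ{i:08d}"
        synonyms = [f"{symbol}-ALT", f"zzorf{i}"]
        registry.append(
            TargetRecord(
                ensembl_id=ensembl,
                hgnc_symbol=symbol,
                approved_name=f"synthetic protein {i}",
                biotype="protein_coding",
                synonyms=synonyms,
                subcellular_locations=["Cell membrane"] if rng.random() < 0.5 else ["Cytoplasm"],
                target_class=_TARGET_CLASSES[int(rng.integers(len(_TARGET_CLASSES)))],
            )
        )
        pocket_grid = [None, 0.0, 0.2, 0.5, 0.7, 0.9]
        tractability.append(
            TractabilityRecord(
                ensembl_id=ensembl,
                druggable_family=bool(rng.random() < 0.35),
                pocket_score=pocket_grid[int(rng.integers(len(pocket_grid)))],
                accessible_uniprot=bool(rng.random() < 0.4),
                accessible_go=bool(rng.random() < 0.4),
                accessible_hpa=bool(rng.random() < 0.35),
            )
        )
        planted = i < n_priority
        traits, tissues, rvas = _sample_evidence(rng, config, planted)
        gene_truth.append(
            {"ensembl": ensembl, "symbol": symbol, "traits": traits,
             "tissues": tissues, "rvas": rvas, "planted": planted}
        )
        truth.traits[ensembl] = sorted(t.value for t in traits)
        truth.tissues[ensembl] = sorted(t.value for t in tissues)
        if rvas:
            truth.rvas_genes.append(ensembl)
        if planted:
            truth.priority_genes.append(ensembl)
            truth.priority_symbols.append(symbol)

    # --- study-level gene reports and the V2G table ------------------------
    assoc_classes = [AnalysisClass.GWAS_SNP, AnalysisClass.WGS, AnalysisClass.EXWAS,
                     AnalysisClass.REPLICATION]
    reports: list[GeneReport] = []
    v2g: dict[str, str] = {}
    variant_counter = 0
    for gene in gene_truth:
        for trait in sorted(gene["traits"], key=lambda t: t.value):
            n_rep = 1 + int(rng.poisson(0.7))
            for _ in range(n_rep):
                variant_counter += 1
                variant = f"var{variant_counter:06d}"
                study = f"S{int(rng.integers(config.n_studies)):03d}"
                klass = assoc_classes[int(rng.integers(len(assoc_classes)))]
                covered = rng.random() < config.v2g_coverage
                if covered:
                    v2g[variant] = gene["symbol"]
                else:
                    truth.withheld_variants.append(variant)
                reports.append(
                    GeneReport(
                        study_id=study,
                        analysis_class=klass,
                        trait=trait,
                        variant_id=variant,
                        reported_symbol=gene["symbol"],
                        annotation_source=AnnotationSource.AUTHOR,
                    )
                )
        for tissue in sorted(gene["tissues"], key=lambda t: t.value):
            klass = AnalysisClass.TWAS if rng.random() < 0.5 else AnalysisClass.EQTL_COLOC
            reports.append(
                GeneReport(
                    study_id=f"S{int(rng.integers(config.n_studies)):03d}",
                    analysis_class=klass,
                    trait=Trait.NONE,
                    tissue=tissue,
                    reported_symbol=gene["symbol"],
                )
            )
        if gene["rvas"]:
            reports.append(
                GeneReport(
                    study_id=f"S{int(rng.integers(config.n_studies)):03d}",
                    analysis_class=AnalysisClass.RVAS,
                    trait=Trait.AF,
                    reported_symbol=gene["symbol"],
                )
            )

    # --- drugs: parents, salt forms, conjugates ----------------------------
    drugs: list[DrugRecord] = []
    conjugate_whitelist: list[str] = []
    parent_members: dict[str, list[DrugRecord]] = {}

    def new_form(name: str) -> DrugRecord:
        rec = DrugRecord(
            drug_id=f"DRUG{len(drugs) + 1:04d}",
            name=name,
            drug_type="small molecule",
            max_phase=int(rng.integers(1, 5)),
            approved=bool(rng.random() < 0.6),
            black_box="Cardiotoxicity" if rng.random() < 0.1 else "",
            withdrawn=bool(rng.random() < 0.05),
        )
        drugs.append(rec)
        return rec

    parent_stems = [_drug_stem(rng, i) for i in range(config.n_parent_drugs)]
    for stem in parent_stems:
        multiplicity = int(_weighted_choice(rng, config.salt_multiplicity))
        salt_idx = rng.choice(len(_SALTS), size=max(0, multiplicity - 1), replace=False)
        forms = [stem] + [f"{stem} {_SALTS[int(s)]}" for s in sorted(salt_idx)]
        members = [new_form(name) for name in forms]
        parent_members[stem] = members
        truth.parent_partition[stem] = [m.drug_id for m in members]
    for _ in range(config.n_conjugates):
        a, b = (int(x) for x in rng.choice(config.n_parent_drugs, size=2, replace=False))
        name = f"{parent_stems[a]}mab {parent_stems[b]}tecan"
        conjugate_whitelist.append(name)
        member = new_form(name)
        parent_members[name] = [member]
        truth.parent_partition[name] = [member.drug_id]

    # --- mechanisms: many-to-many drug-target links ------------------------
    mechanisms: list[MechanismRecord] = []
    gene_by_ensembl = {g["ensembl"]: g for g in gene_truth}
    ensembl_ids = [g["ensembl"] for g in gene_truth]
    for parent, members in parent_members.items():
        n_targets = max(1, int(rng.poisson(config.mechanism_density)))
        chosen = rng.choice(len(ensembl_ids), size=min(n_targets, len(ensembl_ids)), replace=False)
        action = _ACTION_TYPES[int(rng.integers(len(_ACTION_TYPES)))]
        for idx in sorted(int(c) for c in chosen):
            gene = gene_by_ensembl[ensembl_ids[idx]]
            for member in members:
                mechanisms.append(
                    MechanismRecord(
                        drug_id=member.drug_id,
                        action_type=action,
                        target_ensembl_id=gene["ensembl"],
                        target_name=gene["symbol"],
                        target_molecule_type="protein",
                    )
                )

    # --- indications with an ontology map ----------------------------------
    ontology_map: dict[str, tuple[str, str, str]] = {}
    for i, spec in enumerate(_SPECIALTIES):
        ontology_map[f"SYNT:{i:04d}"] = (f"{spec} disorder", spec, "")
    term_of = {spec: f"SYNT:{i:04d}" for i, spec in enumerate(_SPECIALTIES)}
    sources = [EvidenceSource.TRIAL, EvidenceSource.ATC, EvidenceSource.FDA_LABEL]
    indications: list[IndicationRecord] = []
    for parent, members in parent_members.items():
        n_ind = 1 + int(rng.integers(3))
        specs = set()
        while len(specs) < n_ind:
            specs.add(str(_weighted_choice(rng, config.specialty_probs)))
        for spec in sorted(specs):
            indications.append(
                IndicationRecord(
                    drug_id=members[0].drug_id,
                    ontology_term=term_of[spec],
                    evidence_source=sources[int(rng.integers(len(sources)))],
                )
            )

    # --- curated evidence items and the guideline list ---------------------
    evidence_items: list[EvidenceItem] = []
    guideline_drugs: list[str] = []
    for parent in sorted(parent_members):
        if rng.random() < config.guideline_fraction:
            guideline_drugs.append(parent)
            evidence_items.append(
                EvidenceItem(
                    drug_name=parent,
                    design_level=DesignLevel.GUIDELINE,
                    effect=Effect.EXISTING_TREATMENT,
                )
            )
            continue
        if rng.random() >= config.evidence_prob:
            continue
        for _ in range(1 + int(rng.integers(3))):
            evidence_items.append(
                EvidenceItem(
                    drug_name=parent,
                    design_level=_weighted_choice(rng, config.level_probs),
                    effect=_weighted_choice(rng, config.effect_probs),
                    population="synthetic cohort",
                )
            )

    return Bundle(
        config=config,
        registry=registry,
        tractability=tractability,
        v2g=v2g,
        reports=reports,
        drugs=drugs,
        mechanisms=mechanisms,
        indications=indications,
        evidence_items=evidence_items,
        guideline_drugs=guideline_drugs,
        salt_lexicon=list(_SALTS),
        conjugate_whitelist=conjugate_whitelist,
        ontology_map=ontology_map,
        truth=truth,
    )


def _sample_evidence(
    rng: np.random.Generator, config: GeneratorConfig, planted: bool
) -> tuple[set[Trait], set[Tissue], bool]:
    """Sample a gene's true trait/tissue/rare-variant evidence.

    Planted priority genes end with a prioritisation score of at least 2;
    all other genes end with a score of at most 1.
    """
    traits = {t for t, p in config.trait_probs.items() if rng.random() < p}
    tissues = {t for t, p in config.tissue_probs.items() if rng.random() < p}
    rvas = rng.random() < config.rvas_prob
    total = len(traits) + len(tissues) + int(rvas)
    if planted:
        while total < 2:
            pool = [t for t in (Trait.AF, Trait.PR_INDICES, Trait.LA_INDICES) if t not in traits]
            tissue_pool = [t for t in (Tissue.LA, Tissue.RA, Tissue.LV) if t not in tissues]
            if pool and (not tissue_pool or rng.random() < 0.5):
                traits.add(pool[int(rng.integers(len(pool)))])
            elif tissue_pool:
                tissues.add(tissue_pool[int(rng.integers(len(tissue_pool)))])
            else:
                rvas = True
            total = len(traits) + len(tissues) + int(rvas)
    else:
        # trim evidence until the score cannot exceed 1
        while total > 1:
            if tissues:
                tissues.pop()
            elif rvas:
                rvas = False
            else:
                traits.pop()
            total = len(traits) + len(tissues) + int(rvas)
    return traits, tissues, rvas


CORRUPT_MODES = ("drop_v2g", "scramble_symbols", "inject_dailymed", "dangling_mechanism")


def corrupt(bundle: Bundle, mode: str) -> Bundle:
    """Apply a targeted perturbation for negative-path testing.

    Modes: ``drop_v2g`` empties the variant-to-gene table (every report
    falls back to the author annotation); ``scramble_symbols`` replaces
    each reported symbol with a registry synonym (resolution must go
    through the SYNONYM stage); ``inject_dailymed`` adds DailyMed-sourced
    indication rows (filtered downstream); ``dangling_mechanism`` appends
    a mechanism naming an unknown drug id (the join must fail loudly).
    """
    if mode not in CORRUPT_MODES:
        raise ValueError(f"unknown corrupt mode {mode!r}; choose from {CORRUPT_MODES}")
    out = copy.deepcopy(bundle)
    if mode == "drop_v2g":
        out.truth.withheld_variants = sorted(
            set(out.truth.withheld_variants) | set(out.v2g)
        )
        out.v2g = {}
    elif mode == "scramble_symbols":
        synonym_of = {r.hgnc_symbol: r.synonyms[0] for r in out.registry if r.synonyms}
        out.reports = [
            rep.model_copy(
                update={"reported_symbol": synonym_of.get(rep.reported_symbol, rep.reported_symbol)}
            )
            for rep in out.reports
        ]
        out.v2g = {k: synonym_of.get(v, v) for k, v in out.v2g.items()}
    elif mode == "inject_dailymed":
        term = next(iter(sorted(out.ontology_map)))
        for drug in out.drugs[: max(1, len(out.drugs) // 10)]:
            out.indications.append(
                IndicationRecord(
                    drug_id=drug.drug_id,
                    ontology_term=term,
                    evidence_source=EvidenceSource.DAILYMED,
                )
            )
    elif mode == "dangling_mechanism":
        out.mechanisms.append(
            MechanismRecord(
                drug_id="DRUG_MISSING",
                action_type="inhibitor",
                target_ensembl_id=out.registry[0].ensembl_id,
            )
        )
    return out
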