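"""Domain types for the AF drug-target prioritisation pipeline.

The pipeline links per-study gene evidence (GWAS and related association
analyses, tissue expression analyses, rare-variant analyses) to drug-side
annotations in an OpenTargets-style export: a target registry, tractability
data, drug / mechanism-of-action / indication tables, and curated clinical
evidence records. Each record class below validates the invariants a row
must satisfy before it enters the analysis.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class AnalysisClass(str, enum.Enum):
    """Kind of genetic analysis a gene report came from."""

    GWAS_SNP = "GWAS_SNP"
    GWAS_CNV = "GWAS_CNV"
    WGS = "WGS"
    EXWAS = "EXWAS"
    RVAS = "RVAS"
    TWAS = "TWAS"
    EQTL_COLOC = "EQTL_COLOC"
    REPLICATION = "REPLICATION"


#: Analysis classes that assert a trait association (as opposed to
#: expression-level evidence, which is tissue-specific).
ASSOCIATION_CLASSES = frozenset(
    {
        AnalysisClass.GWAS_SNP,
        AnalysisClass.GWAS_CNV,
        AnalysisClass.WGS,
        AnalysisClass.EXWAS,
        AnalysisClass.RVAS,
        AnalysisClass.REPLICATION,
    }
)

#: Analysis classes carrying tissue-specific expression evidence.
EXPRESSION_CLASSES = frozenset({AnalysisClass.TWAS, AnalysisClass.EQTL_COLOC})


class Trait(str, enum.Enum):
    """Trait studied: atrial fibrillation or an AF-related trait."""

    AF = "AF"
    PR_INDICES = "PR_INDICES"
    LA_INDICES = "LA_INDICES"
    NONE = "NONE"


class Tissue(str, enum.Enum):
    """Cardiac tissue for expression-level evidence."""

    LA = "LA"
    RA = "RA"
    LV = "LV"
    NONE = "NONE"


class AnnotationSource(str, enum.Enum):
    """Provenance of a variant's gene annotation."""

    V2G = "V2G"
    AUTHOR = "AUTHOR"


class GeneReport(BaseModel):
    """One study-level observation linking a variant/gene to a trait."""

    study_id: str
    analysis_class: AnalysisClass
    trait: Trait = Trait.NONE
    tissue: Tissue = Tissue.NONE
    variant_id: str = ""
    reported_symbol: str
    annotation_source: AnnotationSource = AnnotationSource.AUTHOR

    @model_validator(mode="after")
    def _check_trait_tissue(self) -> "GeneReport":
        has_tissue = self.tissue != Tissue.NONE
        is_expression = self.analysis_class in EXPRESSION_CLASSES
        if has_tissue != is_expression:
            raise ValueError(
                f"tissue={self.tissue.value} is inconsistent with "
                f"analysis_class={self.analysis_class.value}: tissue must be "
                "set exactly for TWAS/EQTL_COLOC reports"
            )
        if self.analysis_class in ASSOCIATION_CLASSES and self.trait == Trait.NONE:
            raise ValueError(
                f"trait must be set for association analysis "
                f"{self.analysis_class.value}"
            )
        return self


class TargetRecord(BaseModel):
    """Registry entry for one gene/protein target."""

    ensembl_id: str
    hgnc_symbol: str
    approved_name: str = ""
    biotype: str = ""
    synonyms: list[str] = Field(default_factory=list)
    subcellular_locations: list[str] = Field(default_factory=list)
    target_class: str = ""

    @field_validator("hgnc_symbol")
    @classmethod
    def _nonempty_symbol(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("hgnc_symbol must be non-empty")
        return v


class TractabilityRecord(BaseModel):
    """Druggability annotations for one target.

    ``pocket_score`` is the structure-based small-molecule pocket score in
    [0, 1]; ``None`` means no structural assessment exists, which is distinct
    from an assessed score of 0.  The three accessibility flags record
    high-confidence plasma-membrane / extracellular / secreted localisation
    calls from UniProt, GO and HPA, the basis of antibody tractability.
    """

    ensembl_id: str
    druggable_family: bool = False
    pocket_score: Optional[float] = None
    accessible_uniprot: bool = False
    accessible_go: bool = False
    accessible_hpa: bool = False

    @field_validator("pocket_score")
    @classmethod
    def _pocket_in_unit_interval(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValueError(f"pocket_score {v} outside [0, 1]")
        return v


class DrugRecord(BaseModel):
    """One drug form (prior to salt/conjugate deduplication)."""

    drug_id: str
    name: str
    drug_type: str = ""
    max_phase: int = 0
    approved: bool = False
    black_box: str = ""
    withdrawn: bool = False
    synonyms: list[str] = Field(default_factory=list)

    @field_validator("max_phase")
    @classmethod
    def _phase_range(cls, v: int) -> int:
        if v not in range(5):
            raise ValueError(f"max_phase {v} outside 0..4")
        return v


class MechanismRecord(BaseModel):
    """Mechanism of action linking a drug to a target."""

    drug_id: str
    action_type: str
    target_ensembl_id: str
    target_name: str = ""
    target_molecule_type: str = ""


class EvidenceSource(str, enum.Enum):
    """Where an indication record was sourced from."""

    TRIAL = "TRIAL"
    ATC = "ATC"
    FDA_LABEL = "FDA_LABEL"
    DAILYMED = "DAILYMED"


class IndicationRecord(BaseModel):
    """Approved/trialled indication for a drug, ontology-coded."""

    drug_id: str
    ontology_term: str
    decoded_label: str = ""
    specialty: str = ""
    secondary: str = ""
    evidence_source: EvidenceSource = EvidenceSource.TRIAL


class DesignLevel(str, enum.Enum):
    """Study-design tier of a clinical evidence item."""

    GUIDELINE = "GUIDELINE"
    SYSTEMATIC_REVIEW = "SYSTEMATIC_REVIEW"
    RCT = "RCT"
    OBSERVATIONAL = "OBSERVATIONAL"
    NONE = "NONE"


#: Rank in the evidence lattice; higher rank = stronger design.
DESIGN_RANK = {
    DesignLevel.NONE: 0,
    DesignLevel.OBSERVATIONAL: 1,
    DesignLevel.RCT: 2,
    DesignLevel.SYSTEMATIC_REVIEW: 3,
    DesignLevel.GUIDELINE: 4,
}


class Effect(str, enum.Enum):
    """Direction of a drug's effect on AF outcomes."""

    BENEFICIAL = "BENEFICIAL"
    HARMFUL = "HARMFUL"
    NEUTRAL = "NEUTRAL"
    MIXED = "MIXED"
    POTENTIAL_HARM = "POTENTIAL_HARM"
    EXISTING_TREATMENT = "EXISTING_TREATMENT"
    NONE = "NONE"


class EvidenceItem(BaseModel):
    """One curated clinical-evidence record for a drug."""

    drug_name: str
    design_level: DesignLevel
    effect: Effect
    comparator: str = ""
    population: str = ""
    estimate_text: str = ""

    @model_validator(mode="after")
    def _levels_set(self) -> "EvidenceItem":
        if self.design_level == DesignLevel.NONE or self.effect == Effect.NONE:
            raise ValueError("design_level and effect must always be set")
        return self


class ResolutionMethod(str, enum.Enum):
    EXACT = "EXACT"
    SYNONYM = "SYNONYM"
    MANUAL = "MANUAL"
    UNRESOLVED = "UNRESOLVED"


class SymbolResolution(BaseModel):
    """Outcome of resolving a reported gene label against the registry."""

    reported_symbol: str
    resolved_symbol: str = ""
    ensembl_id: str = ""
    method: ResolutionMethod

    @model_validator(mode="after")
    def _unresolved_iff_empty(self) -> "SymbolResolution":
        empty = self.resolved_symbol == ""
        if empty != (self.method == ResolutionMethod.UNRESOLVED):
            raise ValueError("method=UNRESOLVED iff resolved_symbol empty")
        return self


class TargetProfile(BaseModel):
    """Per-gene collapsed evidence across all studies."""

    ensembl_id: str
    hgnc_symbol: str
    traits: set[Trait] = Field(default_factory=set)
    tissues: set[Tissue] = Field(default_factory=set)
    rare_variant: bool = False
    report_counts: dict[AnalysisClass, int] = Field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return sum(self.report_counts.values())


class PriorityScores(BaseModel):
    """Druggability domain scores and the multi-domain prioritisation score.

    ``sm_score`` counts small-molecule druggability categories (druggable
    family membership; usable structural pocket).  ``ab_score`` counts the
    three accessibility sources supporting antibody tractability.  The
    prioritisation score adds one point per trait with genetic association
    evidence, one per cardiac tissue with expression-level evidence, and one
    for rare-variant support; priority is flagged when the total exceeds the
    threshold (default 1).
    """

    ensembl_id: str
    hgnc_symbol: str = ""
    sm_score: int = Field(ge=0, le=2)
    ab_score: int = Field(ge=0, le=3)
    druggability_priority: bool
    trait_points: int = Field(ge=0, le=3)
    tissue_points: int = Field(ge=0, le=3)
    rvas_point: int = Field(ge=0, le=1)
    prioritisation_score: int = Field(ge=0, le=7)
    gene_priority: bool

    @model_validator(mode="after")
    def _consistent(self) -> "PriorityScores":
        if self.prioritisation_score != (
            self.trait_points + self.tissue_points + self.rvas_point
        ):
            raise ValueError("prioritisation_score must equal the sum of its parts")
        return self


class DrugTargetLink(BaseModel):
    """One (drug, target) mechanism link."""

    drug_id: str
    parent_drug_key: str = ""
    ensembl_id: str
    action_type: str = ""
    target_class: str = ""


class ParentDrug(BaseModel):
    """Unique active moiety after salt/conjugate deduplication."""

    parent_key: str
    name: str
    member_ids: list[str]
    member_names: list[str]


class DrugEvidenceSummary(BaseModel):
    """Per-drug summary row: max evidence level, overall effect, warnings."""

    drug_name: str
    associated_targets: list[str] = Field(default_factory=list)
    max_level: DesignLevel = DesignLevel.NONE
    overall_effect: Effect = Effect.NONE
    black_box: str = ""
    withdrawn: bool = False
    high_priority: bool = False
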