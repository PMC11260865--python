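"""Loaders for the packaged fixture tables.

Two fixtures transcribe the published evidence tables verbatim: the
drugged-target table (68 genes with subcellular location, target class and
per-tissue TWAS / eQTL-colocalization evidence) and the drug-evidence table
(per-drug maximum level of evidence, overall effect, warnings, and the
bold high-priority flag).  Dashes in the printed tissue columns map to
empty tissue sets.  A manifest of SHA-256 checksums guards against fixture
drift; any edit raises :class:`FixtureCorruptionError`.

Smaller packaged resources loaded here: the printed blood-pressure-
associated and drug-associated-but-not-druggable gene lists, the salt
lexicon and conjugate whitelist used in drug deduplication, the curated
manual symbol map, and the guideline drug list.
"""

from __future__ import annotations

import enum
import hashlib
import json
from importlib import resources
from pathlib import Path

from pydantic import BaseModel, Field

from .io import read_lines, read_mapping, read_table
from .types import DesignLevel, Effect, Tissue

_DATA = resources.files(__package__) / "data"


class FixtureCorruptionError(RuntimeError):
    """A packaged fixture does not match its manifest checksum."""


class FixtureName(str, enum.Enum):
    TABLE1 = "TABLE1"
    TABLE2 = "TABLE2"


class DruggedTargetRow(BaseModel):
    """One row of the drugged-target fixture."""

    hgnc_symbol: str
    approved_name: str
    location: str = ""
    target_class: str = ""
    twas_tissues: set[Tissue] = Field(default_factory=set)
    eqtl_tissues: set[Tissue] = Field(default_factory=set)

    @property
    def tissues(self) -> set[Tissue]:
        """Union of TWAS and eQTL tissue evidence (counted once per tissue)."""
        return self.twas_tissues | self.eqtl_tissues

    @property
    def subcellular_locations(self) -> list[str]:
        return [s.strip() for s in self.location.split(",") if s.strip()]


class DrugEvidenceRow(BaseModel):
    """One row of the drug-evidence fixture (transcribed literally)."""

    drug_name: str
    target_symbols: list[str]
    max_level: DesignLevel
    overall_effect: Effect
    comparator: str = ""
    black_box: str = ""
    withdrawn: bool = False
    high_priority: bool = False


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file (verified against manifest)."""
    path = Path(str(_DATA / name))
    if not path.exists():
        raise FileNotFoundError(f"packaged data file {name!r} not found")
    _verify_checksum(name, path)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest() -> dict[str, str]:
    return json.loads((_DATA / "manifest.json").read_text(encoding="utf-8"))


def _verify_checksum(name: str, path: Path) -> None:
    manifest = _manifest()
    if name not in manifest:
        raise FixtureCorruptionError(f"{name} missing from fixture manifest")
    digest = _sha256(path)
    if digest != manifest[name]:
        raise FixtureCorruptionError(
            f"fixture {name} checksum mismatch: {digest} != {manifest[name]}"
        )


def verify_manifest() -> dict[str, bool]:
    """Check every manifest entry; returns per-file pass/fail."""
    out = {}
    for name, expected in sorted(_manifest().items()):
        path = Path(str(_DATA / name))
        out[name] = path.exists() and _sha256(path) == expected
    return out


def load_fixture(name: FixtureName | str) -> list[BaseModel]:
    """Load a packaged fixture table as validated rows."""
    name = FixtureName(name)
    if name == FixtureName.TABLE1:
        return read_table(data_path("table1.tsv"), DruggedTargetRow)
    return read_table(data_path("table2.tsv"), DrugEvidenceRow)


def load_drugged_targets() -> list[DruggedTargetRow]:
    return load_fixture(FixtureName.TABLE1)  # type: ignore[return-value]


def load_drug_evidence() -> list[DrugEvidenceRow]:
    return load_fixture(FixtureName.TABLE2)  # type: ignore[return-value]


def load_bp_targets() -> list[str]:
    """Printed list of drugged targets also associated with blood pressure."""
    return read_lines(data_path("bp_targets.txt"))


def load_non_druggable_targets() -> list[str]:
    """Printed list of drug-associated targets absent from the druggable genome."""
    return read_lines(data_path("non_druggable_targets.txt"))


def load_salt_lexicon() -> list[str]:
    return read_lines(data_path("salt_lexicon.txt"))


def load_conjugate_whitelist() -> list[str]:
    return read_lines(data_path("conjugate_whitelist.txt"))


def load_manual_symbol_map() -> dict[str, str]:
    return read_mapping(data_path("manual_symbol_map.tsv"))


def load_guideline_drugs() -> dict[str, list[str]]:
    """Guideline drug list; maps drug name to guideline regions."""
    raw = read_mapping(data_path("guidelines.tsv"))
    return {drug: regions.split(";") for drug, regions in raw.items()}
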