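"""Reading and writing the pipeline's tab-separated tables.

Dialect: UTF-8, tab-separated, mandatory header row, ``\n`` line endings.
Missing values are empty strings in text columns; a missing pocket score is
written as the explicit sentinel ``NA`` so that "no structural assessment"
is distinguishable from an assessed score of 0.  List-valued cells join
their elements with ``;``.  Enum cells are matched case-insensitively on
read and written canonical upper-case, so a write → read → write cycle is
byte-identical.
"""

from __future__ import annotations

import csv
import enum
import io as _io
import typing
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence, Type, Union

from pydantic import BaseModel, ValidationError

from .types import (
    AnalysisClass,
    DrugRecord,
    DrugTargetLink,
    EvidenceItem,
    GeneReport,
    IndicationRecord,
    MechanismRecord,
    ParentDrug,
    PriorityScores,
    SymbolResolution,
    TargetProfile,
    TargetRecord,
    TractabilityRecord,
)

MISSING = "NA"
LIST_SEP = ";"

#: Registry of table schemas addressable by name.
SCHEMAS: dict[str, Type[BaseModel]] = {
    "GeneReport": GeneReport,
    "TargetRecord": TargetRecord,
    "TractabilityRecord": TractabilityRecord,
    "DrugRecord": DrugRecord,
    "MechanismRecord": MechanismRecord,
    "IndicationRecord": IndicationRecord,
    "EvidenceItem": EvidenceItem,
    "SymbolResolution": SymbolResolution,
    "TargetProfile": TargetProfile,
    "PriorityScores": PriorityScores,
    "DrugTargetLink": DrugTargetLink,
    "ParentDrug": ParentDrug,
}


class SchemaError(ValueError):
    """The file's header does not match the schema."""


class TableValidationError(ValueError):
    """One or more rows failed the schema's invariants.

    ``row_errors`` maps 1-based data-row numbers to human-readable messages.
    """

    def __init__(self, path: str, row_errors: dict[int, str]):
        self.path = path
        self.row_errors = row_errors
        detail = "; ".join(f"row {r}: {msg}" for r, msg in sorted(row_errors.items()))
        super().__init__(f"{path}: {len(row_errors)} invalid row(s): {detail}")


def _resolve_schema(schema: Union[str, Type[BaseModel]]) -> Type[BaseModel]:
    if isinstance(schema, str):
        try:
            return SCHEMAS[schema]
        except KeyError:
            raise SchemaError(f"unknown schema {schema!r}") from None
    return schema


def _unwrap_optional(tp: Any) -> tuple[Any, bool]:
    origin = typing.get_origin(tp)
    if origin is Union:
        args = [a for a in typing.get_args(tp) if a is not type(None)]
        if len(args) == 1:
            return args[0], True
    return tp, False


def _decode_cell(raw: str, tp: Any) -> Any:
    tp, optional = _unwrap_optional(tp)
    origin = typing.get_origin(tp)
    if optional and raw == MISSING:
        return None
    if origin in (list, set):
        (elem,) = typing.get_args(tp)
        items = [s for s in raw.split(LIST_SEP) if s != ""]
        vals = [_decode_cell(s, elem) for s in items]
        return vals if origin is list else set(vals)
    if origin is dict:
        key_t, val_t = typing.get_args(tp)
        out = {}
        for part in (p for p in raw.split(LIST_SEP) if p):
            k, _, v = part.partition(":")
            out[_decode_cell(k, key_t)] = _decode_cell(v, val_t)
        return out
    if isinstance(tp, type) and issubclass(tp, enum.Enum):
        return tp(raw.strip().upper())
    if tp is bool:
        low = raw.strip().lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no", ""):
            return False
        raise ValueError(f"cannot parse boolean from {raw!r}")
    if tp is int:
        return int(raw)
    if tp is float:
        return float(raw)
    return raw


def _encode_cell(value: Any) -> str:
    if value is None:
        return MISSING
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, "g")
    if isinstance(value, (list, tuple)):
        return LIST_SEP.join(_encode_cell(v) for v in value)
    if isinstance(value, (set, frozenset)):
        return LIST_SEP.join(sorted(_encode_cell(v) for v in value))
    if isinstance(value, dict):
        return LIST_SEP.join(
            f"{_encode_cell(k)}:{_encode_cell(v)}" for k, v in sorted(value.items(), key=lambda kv: _encode_cell(kv[0]))
        )
    return str(value)


def read_table(
    path: Union[str, Path], schema: Union[str, Type[BaseModel]]
) -> list[BaseModel]:
    """Read a TSV file into validated records.

    Raises :class:`SchemaError` if a required column is absent and
    :class:`TableValidationError` listing every invalid row (with its
    1-based data-row number) if any row violates the type's invariants.
    """
    model = _resolve_schema(schema)
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header required") from None
        fields = model.model_fields
        required = [n for n, f in fields.items() if f.is_required()]
        missing_cols = [c for c in required if c not in header]
        if missing_cols:
            raise SchemaError(
                f"{path}: missing required column(s) {missing_cols} "
                f"for schema {model.__name__}"
            )
        known = [c for c in header if c in fields]
        records: list[BaseModel] = []
        row_errors: dict[int, str] = {}
        for rownum, row in enumerate(reader, start=1):
            cells = dict(zip(header, row))
            kwargs = {}
            try:
                for col in known:
                    raw = cells.get(col, "")
                    if raw == "" and not fields[col].is_required():
                        continue
                    kwargs[col] = _decode_cell(raw, fields[col].annotation)
                records.append(model(**kwargs))
            except (ValueError, ValidationError) as exc:
                row_errors[rownum] = _summarise_error(exc)
        if row_errors:
            raise TableValidationError(str(path), row_errors)
    return records


def _summarise_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        parts = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "<model>"
            parts.append(f"{loc}: {err['msg']}")
        return "; ".join(parts)
    return str(exc)


def write_table(
    records: Sequence[BaseModel],
    path: Union[str, Path],
    schema: Optional[Union[str, Type[BaseModel]]] = None,
) -> Path:
    """Write records to a TSV file in canonical column order and encoding."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = render_table(records, schema)
    path.write_text(text, encoding="utf-8")
    return path


def render_table(
    records: Sequence[BaseModel],
    schema: Optional[Union[str, Type[BaseModel]]] = None,
) -> str:
    """Render records as canonical TSV text (field-declaration column order)."""
    if schema is None:
        if not records:
            raise ValueError("schema required to render an empty table")
        model = type(records[0])
    else:
        model = _resolve_schema(schema)
    cols = list(model.model_fields)
    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(cols)
    for rec in records:
        writer.writerow([_encode_cell(getattr(rec, c)) for c in cols])
    return buf.getvalue()


def read_lines(path: Union[str, Path]) -> list[str]:
    """Read a plain one-entry-per-line text file, skipping blanks and '#'."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_mapping(path: Union[str, Path]) -> dict[str, str]:
    """Read a two-column TSV (no header) as an ordered mapping."""
    out: dict[str, str] = {}
    for line in read_lines(path):
        key, _, value = line.partition("\t")
        out[key] = value
    return out
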