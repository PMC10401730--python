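"""Reading and normalizing heterogeneous study data dictionaries.

Two codebook schemas are supported, named after the cohort resources whose
layout they follow:

* ``nacc`` — one row per variable with columns VariableName, Form,
  ShortDescriptor, DataType, AllowableCodes.  The form column holds a short
  code (``a1``) that is resolved to its full name (``Subject Demographics``)
  through a lookup table.
* ``adni`` — one row per variable with columns Phase, FLDNAME, TBLNAME,
  CRFNAME, TEXT, TYPE, LENGTH, CODE, UNITS.  Imaging descriptors with
  concatenated region names (``LeftIsthmusCingulate``) are expanded with
  spaces.

Both are normalized into :class:`DataElementDef` records with a parsed
:class:`CodeSpec` describing the variable's permissible values: a set of
coded categories, a numeric range (optionally with sentinel codes such as
``99 = Unknown``), or unconstrained.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .errors import (
    CodeSpecParseError,
    DuplicateDefinitionError,
    FormLookupError,
    SchemaError,
)

__all__ = [
    "CodeSpec",
    "DataElementDef",
    "parse_code_spec",
    "format_code_spec",
    "expand_concatenated",
    "resolve_form_name",
    "load_form_lookup",
    "default_form_lookup",
    "parse_dictionary",
    "write_normalized",
    "read_normalized",
    "NACC_COLUMNS",
    "ADNI_COLUMNS",
]

CATEGORICAL = "categorical"
NUMERIC_RANGE = "numeric_range"
UNCONSTRAINED = "unconstrained"

NACC_COLUMNS = ("variablename", "form", "shortdescriptor", "datatype", "allowablecodes")
ADNI_COLUMNS = (
    "phase",
    "fldname",
    "tblname",
    "crfname",
    "text",
    "type",
    "length",
    "code",
    "units",
)


@dataclass(frozen=True)
class CodeSpec:
    """Parsed permissible-value specification of one data element.

    ``kind`` is ``categorical`` (coded categories only), ``numeric_range``
    (a [min, max] interval, possibly with out-of-range sentinel codes), or
    ``unconstrained`` (no restriction declared).
    """

    kind: str = UNCONSTRAINED
    categories: tuple[tuple[str, str], ...] = ()
    range: tuple[float, float] | None = None
    special_codes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.kind == CATEGORICAL:
            codes = [c for c, _ in self.categories]
            if len(codes) != len(set(codes)):
                raise ValueError(f"duplicate category codes in {codes}")
        if self.kind == NUMERIC_RANGE:
            if self.range is None:
                raise ValueError("numeric_range spec requires a range")
            lo, hi = self.range
            if lo > hi:
                raise ValueError(f"invalid range [{lo}, {hi}]")

    @property
    def all_codes(self) -> tuple[str, ...]:
        """Category codes plus sentinel codes, in declaration order."""
        return tuple(c for c, _ in self.categories) + tuple(
            c for c, _ in self.special_codes
        )

    def label_for(self, code: str) -> str | None:
        for c, label in (*self.categories, *self.special_codes):
            if c == code:
                return label
        return None


@dataclass(frozen=True)
class DataElementDef:
    """One source variable as declared in a study data dictionary."""

    source: str
    variable_name: str
    group_name: str
    descriptor: str
    data_type: str  # "numeric" | "categorical"
    code_spec: CodeSpec = field(default_factory=CodeSpec)
    units: str = ""
    table_name: str = ""

    def __post_init__(self):
        if not self.variable_name:
            raise ValueError("variable_name must be non-empty")
        if self.data_type not in ("numeric", "categorical"):
            raise ValueError(f"unknown data_type {self.data_type!r}")
        if self.data_type == "categorical" and not self.code_spec.categories:
            raise ValueError(
                f"categorical element {self.variable_name!r} needs >=1 coded category"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.table_name, self.variable_name.casefold())


# --------------------------------------------------------------------------
# code-spec grammar

_RANGE_RE = re.compile(
    r"^(-?\d+(?:\.\d+)?)\s*(?:\.\.|-)\s*(-?\d+(?:\.\d+)?)$"
)


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def parse_code_spec(text: str) -> CodeSpec:
    """Parse an allowable-codes string into a :class:`CodeSpec`.

    Grammar: entries are split on ``;``.  An entry ``<num> - <num>`` or
    ``<num>..<num>`` is a numeric range; ``<code> = <label>`` is a coded
    category (a trailing ``(alias)`` repeating the code, as in ``Yes(1)``,
    is stripped from the label).  A range alongside categories makes the
    categories sentinel codes of a numeric element.  A leading ``-`` binds
    to the code (``-4 = Not available``), never to a range.
    """
    text = (text or "").strip()
    if not text:
        return CodeSpec()
    categories: list[tuple[str, str]] = []
    ranges: list[tuple[float, float]] = []
    for entry in text.split(";"):
        entry = entry.strip()
        if not entry:
            continue
        if "=" in entry:
            code, label = entry.split("=", 1)
            code, label = code.strip(), label.strip()
            if not code:
                raise CodeSpecParseError(entry, text)
            # ADNI-style "Yes(1)": drop a trailing parenthetical echoing the code
            m = re.match(r"^(.*?)\s*\(\s*" + re.escape(code) + r"\s*\)$", label)
            if m:
                label = m.group(1).strip()
            categories.append((code, label))
            continue
        m = _RANGE_RE.match(entry)
        if m:
            lo, hi = float(m.group(1)), float(m.group(2))
            if lo > hi:
                raise CodeSpecParseError(entry, text)
            ranges.append((lo, hi))
            continue
        raise CodeSpecParseError(entry, text)
    if len(ranges) > 1:
        raise CodeSpecParseError(f"{len(ranges)} ranges in one spec", text)
    if ranges:
        return CodeSpec(
            kind=NUMERIC_RANGE,
            range=ranges[0],
            special_codes=tuple(categories),
        )
    return CodeSpec(kind=CATEGORICAL, categories=tuple(categories))


def format_code_spec(spec: CodeSpec) -> str:
    """Canonical printer; ``parse_code_spec(format_code_spec(s)) == s``."""
    if spec.kind == UNCONSTRAINED:
        return ""
    parts: list[str] = []
    if spec.kind == NUMERIC_RANGE:
        lo, hi = spec.range
        parts.append(f"{_format_number(lo)} - {_format_number(hi)}")
        parts.extend(f"{c} = {l}" for c, l in spec.special_codes)
    else:
        parts.extend(f"{c} = {l}" for c, l in spec.categories)
    return "; ".join(parts)


# --------------------------------------------------------------------------
# descriptor and form-name pre-processing

_CAMEL_RE = re.compile(r"(?<=[a-z])(?=[A-Z])")


def expand_concatenated(text: str) -> str:
    """Insert a space at each lower-to-upper boundary inside a word.

    ``LeftIsthmusCingulate`` becomes ``Left Isthmus Cingulate``.  The
    transform is idempotent and leaves already-spaced text unchanged.
    """
    return _CAMEL_RE.sub(" ", text)


def load_form_lookup(path: str | Path) -> dict[str, str]:
    """Read a two-column (short, full) CSV into a lookup table."""
    table: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise SchemaError(f"form lookup row needs 2 columns: {row!r}")
            table[row[0].strip()] = row[1].strip()
    return table


def default_form_lookup() -> dict[str, str]:
    """The lookup table shipped with the package (UDS-style form codes)."""
    text = resources.files("cohortbridge.data").joinpath("form_names.csv").read_text(
        encoding="utf-8"
    )
    table: dict[str, str] = {}
    for row in csv.reader(io.StringIO(text)):
        if row and not row[0].lstrip().startswith("#"):
            table[row[0].strip()] = row[1].strip()
    return table


def resolve_form_name(short: str, lookup: Mapping[str, str]) -> str:
    """Resolve a short form code (``a1``) to its full name, case-insensitively."""
    folded = {k.casefold(): v for k, v in lookup.items()}
    try:
        return folded[short.strip().casefold()]
    except KeyError:
        raise FormLookupError(f"unknown form short name {short!r}") from None


# --------------------------------------------------------------------------
# dictionary parsing

def _normalize_header(name: str) -> str:
    return name.strip().casefold()


def _as_row_dicts(rows) -> list[dict[str, str]]:
    """Accept a DataFrame or an iterable of mappings; normalize headers."""
    if hasattr(rows, "to_dict") and hasattr(rows, "columns"):  # pandas DataFrame
        rows = rows.fillna("").astype(str).to_dict(orient="records")
    out = []
    for row in rows:
        out.append({_normalize_header(k): ("" if v is None else str(v)) for k, v in row.items()})
    return out


def _infer_data_type(spec: CodeSpec) -> str:
    # Both resources mark numeric and coded variables alike ("N", "Numeric"),
    # so the type is inferred from the parsed permissible values.
    return "categorical" if spec.kind == CATEGORICAL and spec.categories else "numeric"


def parse_dictionary(
    rows,
    schema: str,
    *,
    source: str | None = None,
    form_lookup: Mapping[str, str] | None = None,
) -> list[DataElementDef]:
    """Parse data-dictionary rows of the named ``schema`` (``nacc``/``adni``).

    ``rows`` may be a pandas DataFrame or an iterable of header→value
    mappings; headers are matched case-insensitively after trimming.
    """
    schema = schema.lower()
    if schema not in ("nacc", "adni"):
        raise SchemaError(f"unknown dictionary schema {schema!r}")
    records = _as_row_dicts(rows)
    if not records:
        return []
    required = NACC_COLUMNS if schema == "nacc" else ADNI_COLUMNS
    present = set(records[0])
    for col in required:
        if col not in present:
            raise SchemaError(f"missing required column {col!r} for schema {schema!r}")

    if source is None:
        source = schema.upper()
    if form_lookup is None and schema == "nacc":
        form_lookup = default_form_lookup()

    defs: list[DataElementDef] = []
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        if schema == "nacc":
            spec = parse_code_spec(rec["allowablecodes"])
            d = DataElementDef(
                source=source,
                variable_name=rec["variablename"].strip(),
                group_name=resolve_form_name(rec["form"], form_lookup),
                descriptor=rec["shortdescriptor"].strip(),
                data_type=_infer_data_type(spec),
                code_spec=spec,
                units="",
                table_name="",
            )
        else:
            spec = parse_code_spec(rec["code"])
            d = DataElementDef(
                source=source,
                variable_name=rec["fldname"].strip(),
                group_name=rec["crfname"].strip(),
                descriptor=expand_concatenated(rec["text"].strip()),
                data_type=_infer_data_type(spec),
                code_spec=spec,
                units=rec["units"].strip(),
                table_name=rec["tblname"].strip(),
            )
        if d.key in seen:
            raise DuplicateDefinitionError(
                f"duplicate definition of {d.variable_name!r} in "
                f"({d.source!r}, {d.table_name!r})"
            )
        seen.add(d.key)
        defs.append(d)
    return defs


# --------------------------------------------------------------------------
# normalized dictionary round trip (CSV, comma-separated, double-quoted, UTF-8)

_NORMALIZED_HEADER = (
    "source",
    "variable_name",
    "table_name",
    "group_name",
    "descriptor",
    "data_type",
    "code_spec",
    "units",
)


def write_normalized(defs: Sequence[DataElementDef], path: str | Path) -> None:
    """Write the uniform one-row-per-element CSV with canonical code specs."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_ALL)
        w.writerow(_NORMALIZED_HEADER)
        for d in defs:
            w.writerow(
                [
                    d.source,
                    d.variable_name,
                    d.table_name,
                    d.group_name,
                    d.descriptor,
                    d.data_type,
                    format_code_spec(d.code_spec),
                    d.units,
                ]
            )


def read_normalized(path: str | Path) -> list[DataElementDef]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _NORMALIZED_HEADER if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"missing required column {missing[0]!r} in {path}")
        return [
            DataElementDef(
                source=row["source"],
                variable_name=row["variable_name"],
                table_name=row["table_name"],
                group_name=row["group_name"],
                descriptor=row["descriptor"],
                data_type=row["data_type"],
                code_spec=parse_code_spec(row["code_spec"]),
                units=row["units"],
            )
            for row in reader
        ]
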