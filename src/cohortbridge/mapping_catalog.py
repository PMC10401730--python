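"""The harmonization catalog and its value-harmonization operators.

A :class:`Catalog` is the registry tying source data dictionaries to a set
of harmonized common concepts.  On disk it is a directory of five CSV
files:

* ``concepts.csv`` — one row per common concept (id, label, sub-hierarchy
  category, data type, harmonized numeric range, units),
* ``variables.csv`` — the normalized source data elements,
* ``mappings.csv`` — which source variable realizes each concept, plus the
  unit-conversion and numeric-binning rules attached to that mapping,
* ``permissible_values.csv`` — the harmonized value domain of categorical
  concepts and the sentinel codes of numeric ones,
* ``value_harmonization.csv`` — the per-source raw-code → harmonized-code
  recoding table for concepts whose categorical codings disagree.

Harmonization operators implemented here:

* :func:`widen_range` — when two sources declare different numeric ranges
  for the same concept the harmonized range is the interval hull (the
  wider range wins; for partial overlap, the hull).
* :func:`map_value` — recode a raw categorical code to its harmonized
  code and label (identity when the codings already agree).
* :func:`convert_unit` — rescale a measurement into the harmonized unit
  (e.g. mm³ → cc by dividing by 1000).
* :func:`bin_numeric` — discretize a numeric source value into the
  harmonized categorical codes (e.g. packs-per-day 2.5 → "more than two
  packs").
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .dictionary_io import (
    CATEGORICAL,
    NUMERIC_RANGE,
    UNCONSTRAINED,
    CodeSpec,
    DataElementDef,
    format_code_spec,
    parse_code_spec,
    read_normalized,
    write_normalized,
)
from .errors import (
    CatalogValidationError,
    CohortBridgeError,
    UnbinnableValueError,
    UnmappedValueError,
)

__all__ = [
    "CommonConcept",
    "VariableMapping",
    "ValueMappingRow",
    "UnitRule",
    "Bin",
    "BinRule",
    "Catalog",
    "HarmonizationProfile",
    "widen_range",
    "map_value",
    "raw_values_for",
    "convert_unit",
    "inverse_unit_rule",
    "bin_numeric",
    "save_catalog",
    "load_catalog",
    "harmonization_profile",
    "CATALOG_FILES",
]

CATALOG_FILES = (
    "concepts.csv",
    "variables.csv",
    "mappings.csv",
    "permissible_values.csv",
    "value_harmonization.csv",
)


@dataclass(frozen=True)
class CommonConcept:
    """A harmonized concept shared across sources, with its value domain."""

    concept_id: str
    label: str
    category: str
    data_type: str  # "numeric" | "categorical"
    harmonized_domain: CodeSpec
    units: str = ""

    def __post_init__(self):
        if not self.concept_id or not self.label:
            raise ValueError("concept_id and label must be non-empty")

    @property
    def domain_codes(self) -> tuple[str, ...]:
        return self.harmonized_domain.all_codes


@dataclass(frozen=True)
class VariableMapping:
    """concept ↔ source-variable link (at most one variable per source)."""

    concept_id: str
    source: str
    variable_name: str
    table_name: str = ""


@dataclass(frozen=True)
class ValueMappingRow:
    """One raw-code → harmonized-code row (the recode-table shape)."""

    source: str
    concept_id: str
    raw_value: str
    raw_label: str
    harmonized_value: str
    harmonized_label: str


@dataclass(frozen=True)
class UnitRule:
    """Rescale raw values of (concept, source) into the harmonized unit."""

    concept_id: str
    source: str
    factor: float
    direction: str  # "divide" | "multiply"
    raw_unit: str = ""
    harmonized_unit: str = ""

    def __post_init__(self):
        if not self.factor > 0:
            raise ValueError("unit factor must be positive")
        if self.direction not in ("divide", "multiply"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class Bin:
    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool
    code: str

    def contains(self, value: float) -> bool:
        above = value > self.lower or (self.lower_closed and value == self.lower)
        below = value < self.upper or (self.upper_closed and value == self.upper)
        return above and below

    def __str__(self) -> str:
        lo = "[" if self.lower_closed else "("
        hi = "]" if self.upper_closed else ")"
        return f"{lo}{_fmt(self.lower)},{_fmt(self.upper)}{hi}={self.code}"


@dataclass(frozen=True)
class BinRule:
    """Ordered interval table discretizing a numeric source variable."""

    concept_id: str
    source: str
    bins: tuple[Bin, ...]


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


_BIN_RE = re.compile(
    r"^([\[(])\s*(-?\d+(?:\.\d+)?)\s*,\s*(-?\d+(?:\.\d+)?)\s*([\])])=(.+)$"
)


def format_bin_spec(rule: BinRule) -> str:
    return ";".join(str(b) for b in rule.bins)


def parse_bin_spec(concept_id: str, source: str, text: str) -> BinRule:
    bins = []
    for part in text.split(";"):
        m = _BIN_RE.match(part.strip())
        if not m:
            raise CohortBridgeError(f"bad bin spec fragment {part!r}")
        bins.append(
            Bin(
                lower=float(m.group(2)),
                upper=float(m.group(3)),
                lower_closed=m.group(1) == "[",
                upper_closed=m.group(4) == "]",
                code=m.group(5).strip(),
            )
        )
    return BinRule(concept_id=concept_id, source=source, bins=tuple(bins))


# --------------------------------------------------------------------------

@dataclass
class Catalog:
    """The five-part harmonization registry (see module docstring)."""

    concepts: list[CommonConcept] = field(default_factory=list)
    variables: list[DataElementDef] = field(default_factory=list)
    mappings: list[VariableMapping] = field(default_factory=list)
    value_maps: list[ValueMappingRow] = field(default_factory=list)
    unit_rules: list[UnitRule] = field(default_factory=list)
    bin_rules: list[BinRule] = field(default_factory=list)

    # ---- indexes -------------------------------------------------------
    def concept(self, concept_id: str) -> CommonConcept:
        for c in self.concepts:
            if c.concept_id == concept_id:
                return c
        raise KeyError(concept_id)

    def has_concept(self, concept_id: str) -> bool:
        return any(c.concept_id == concept_id for c in self.concepts)

    def mapping_for(self, concept_id: str, source: str) -> VariableMapping | None:
        for m in self.mappings:
            if m.concept_id == concept_id and m.source == source:
                return m
        return None

    def variable_for(self, concept_id: str, source: str) -> DataElementDef | None:
        m = self.mapping_for(concept_id, source)
        if m is None:
            return None
        return self.variable_def(m.source, m.variable_name, m.table_name)

    def variable_def(
        self, source: str, variable_name: str, table_name: str = ""
    ) -> DataElementDef | None:
        for v in self.variables:
            if (
                v.source == source
                and v.variable_name == variable_name
                and (not table_name or v.table_name == table_name)
            ):
                return v
        return None

    def value_map_for(self, source: str, concept_id: str) -> dict[str, ValueMappingRow]:
        return {
            r.raw_value: r
            for r in self.value_maps
            if r.source == source and r.concept_id == concept_id
        }

    def unit_rule_for(self, concept_id: str, source: str) -> UnitRule | None:
        for r in self.unit_rules:
            if r.concept_id == concept_id and r.source == source:
                return r
        return None

    def bin_rule_for(self, concept_id: str, source: str) -> BinRule | None:
        for r in self.bin_rules:
            if r.concept_id == concept_id and r.source == source:
                return r
        return None

    def sources(self) -> list[str]:
        return sorted({m.source for m in self.mappings})

    # ---- validation ----------------------------------------------------
    def validate(self) -> None:
        """Check all referential-integrity invariants; raise listing orphans."""
        problems: list[str] = []
        ids = [c.concept_id for c in self.concepts]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            problems.append(f"duplicate concept ids: {sorted(dup)}")
        id_set = set(ids)
        for c in self.concepts:
            dom = c.harmonized_domain
            if c.data_type == "categorical" and len(dom.categories) < 2:
                problems.append(
                    f"categorical concept {c.concept_id!r} has <2 permissible values"
                )
            if c.data_type == "numeric" and dom.range is None:
                problems.append(f"numeric concept {c.concept_id!r} has no range")

        seen_pairs = set()
        for m in self.mappings:
            if m.concept_id not in id_set:
                problems.append(f"mapping to nonexistent concept {m.concept_id!r}")
            if (m.concept_id, m.source) in seen_pairs:
                problems.append(
                    f"more than one variable for ({m.concept_id!r}, {m.source!r})"
                )
            seen_pairs.add((m.concept_id, m.source))
            if self.variable_def(m.source, m.variable_name, m.table_name) is None:
                problems.append(
                    f"mapping ({m.concept_id!r}, {m.source!r}) to undeclared "
                    f"variable {m.variable_name!r}"
                )

        seen_vals = set()
        for r in self.value_maps:
            if r.concept_id not in id_set:
                problems.append(
                    f"value-map row for nonexistent concept {r.concept_id!r}"
                )
                continue
            key = (r.source, r.concept_id, r.raw_value)
            if key in seen_vals:
                problems.append(f"duplicate value-map key {key}")
            seen_vals.add(key)
            if r.harmonized_value not in self.concept(r.concept_id).domain_codes:
                problems.append(
                    f"harmonized value {r.harmonized_value!r} of "
                    f"({r.source!r}, {r.concept_id!r}) outside the concept domain"
                )

        for u in self.unit_rules:
            if u.concept_id not in id_set:
                problems.append(f"unit rule for nonexistent concept {u.concept_id!r}")
            elif self.mapping_for(u.concept_id, u.source) is None:
                problems.append(
                    f"unit rule for unmapped ({u.concept_id!r}, {u.source!r})"
                )

        for b in self.bin_rules:
            if b.concept_id not in id_set:
                problems.append(f"bin rule for nonexistent concept {b.concept_id!r}")
                continue
            codes = set(self.concept(b.concept_id).domain_codes)
            for bn in b.bins:
                if bn.code not in codes:
                    problems.append(
                        f"bin code {bn.code!r} of {b.concept_id!r} outside domain"
                    )
            for i, x in enumerate(b.bins):
                for y in b.bins[i + 1 :]:
                    if _bins_overlap(x, y):
                        problems.append(
                            f"overlapping bins {x} and {y} in {b.concept_id!r}"
                        )
            var = self.variable_for(b.concept_id, b.source)
            if var is not None and var.code_spec.range is not None:
                lo, hi = var.code_spec.range
                if not (b.bins and b.bins[0].contains(lo) and b.bins[-1].contains(hi)):
                    problems.append(
                        f"bins of {b.concept_id!r} do not cover the declared "
                        f"range [{lo}, {hi}] of {var.variable_name!r}"
                    )
        if problems:
            raise CatalogValidationError(problems)


def _bins_overlap(a: Bin, b: Bin) -> bool:
    lo = max(a.lower, b.lower)
    hi = min(a.upper, b.upper)
    if lo > hi:
        return False
    if lo < hi:
        return True
    # single shared point: overlap only if both sides include it
    return a.contains(lo) and b.contains(lo)


# --------------------------------------------------------------------------
# operators

def widen_range(
    a: tuple[float, float], b: tuple[float, float]
) -> tuple[float, float]:
    """Interval hull of two numeric ranges (the 'keep the wider range' rule)."""
    for r in (a, b):
        if r[0] > r[1]:
            raise CohortBridgeError(f"invalid range {r}")
    return (min(a[0], b[0]), max(a[1], b[1]))


def map_value(
    source: str, concept_id: str, raw_value: str, catalog: Catalog
) -> tuple[str, str]:
    """Harmonize one raw categorical code; returns (code, label).

    Falls back to the identity when the (source, concept) pair has no
    recode row and the raw code already lies in the harmonized domain.
    """
    concept = catalog.concept(concept_id)
    raw_value = str(raw_value).strip()
    vmap = catalog.value_map_for(source, concept_id)
    if raw_value in vmap:
        row = vmap[raw_value]
        return row.harmonized_value, row.harmonized_label
    if raw_value in concept.domain_codes:
        return raw_value, concept.harmonized_domain.label_for(raw_value) or raw_value
    raise UnmappedValueError(source, concept_id, raw_value)


def raw_values_for(
    source: str, concept_id: str, harmonized_value: str, catalog: Catalog
) -> tuple[str, ...]:
    """Inverse of :func:`map_value`: raw codes mapping to a harmonized code.

    Identity when the (source, concept) pair has no recode rows.
    """
    rows = [
        r
        for r in catalog.value_maps
        if r.source == source and r.concept_id == concept_id
    ]
    if not rows:
        return (str(harmonized_value),)
    return tuple(r.raw_value for r in rows if r.harmonized_value == str(harmonized_value))


def convert_unit(value: float, rule: UnitRule) -> float:
    """Apply a unit rule to one measurement (e.g. mm³ / 1000 → cc)."""
    value = float(value)
    if value != value or value in (float("inf"), float("-inf")):
        raise CohortBridgeError(f"non-finite value {value!r}")
    return value / rule.factor if rule.direction == "divide" else value * rule.factor


def inverse_unit_rule(rule: UnitRule) -> UnitRule:
    return UnitRule(
        concept_id=rule.concept_id,
        source=rule.source,
        factor=rule.factor,
        direction="multiply" if rule.direction == "divide" else "divide",
        raw_unit=rule.harmonized_unit,
        harmonized_unit=rule.raw_unit,
    )


def bin_numeric(value: float, rule: BinRule) -> str:
    """Return the code of the unique bin containing ``value``."""
    for b in rule.bins:
        if b.contains(float(value)):
            return b.code
    raise UnbinnableValueError(
        f"value {value!r} outside all bins of {rule.concept_id!r} ({rule.source!r})"
    )


# --------------------------------------------------------------------------
# five-file persistence

def save_catalog(catalog: Catalog, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "concepts.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_ALL)
        w.writerow(
            ["concept_id", "label", "category", "data_type", "range_min", "range_max", "units"]
        )
        for c in catalog.concepts:
            rng = c.harmonized_domain.range
            w.writerow(
                [
                    c.concept_id,
                    c.label,
                    c.category,
                    c.data_type,
                    _fmt(rng[0]) if rng else "",
                    _fmt(rng[1]) if rng else "",
                    c.units,
                ]
            )

    write_normalized(catalog.variables, directory / "variables.csv")

    with open(directory / "mappings.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_ALL)
        w.writerow(
            [
                "concept_id",
                "source",
                "variable_name",
                "table_name",
                "unit_factor",
                "unit_direction",
                "raw_unit",
                "harmonized_unit",
                "bin_spec",
            ]
        )
        for m in catalog.mappings:
            u = catalog.unit_rule_for(m.concept_id, m.source)
            b = catalog.bin_rule_for(m.concept_id, m.source)
            w.writerow(
                [
                    m.concept_id,
                    m.source,
                    m.variable_name,
                    m.table_name,
                    _fmt(u.factor) if u else "",
                    u.direction if u else "",
                    u.raw_unit if u else "",
                    u.harmonized_unit if u else "",
                    format_bin_spec(b) if b else "",
                ]
            )

    with open(
        directory / "permissible_values.csv", "w", newline="", encoding="utf-8"
    ) as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_ALL)
        w.writerow(["concept_id", "code", "label", "is_special"])
        for c in catalog.concepts:
            for code, label in c.harmonized_domain.categories:
                w.writerow([c.concept_id, code, label, "0"])
            for code, label in c.harmonized_domain.special_codes:
                w.writerow([c.concept_id, code, label, "1"])

    with open(
        directory / "value_harmonization.csv", "w", newline="", encoding="utf-8"
    ) as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_ALL)
        w.writerow(
            [
                "source",
                "concept_id",
                "raw_value",
                "raw_label",
                "harmonized_value",
                "harmonized_label",
            ]
        )
        for r in catalog.value_maps:
            w.writerow(
                [
                    r.source,
                    r.concept_id,
                    r.raw_value,
                    r.raw_label,
                    r.harmonized_value,
                    r.harmonized_label,
                ]
            )


def _read_rows(path: Path) -> list[dict[str, str]]:
    if not path.exists():
        raise CohortBridgeError(f"missing catalog file {path.name!r} in {path.parent}")
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def load_catalog(directory: str | Path) -> Catalog:
    """Load and validate a five-file catalog directory."""
    directory = Path(directory)
    pv_rows = _read_rows(directory / "permissible_values.csv")
    by_concept: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for row in pv_rows:
        slot = by_concept.setdefault(row["concept_id"], {"cat": [], "spec": []})
        slot["spec" if row["is_special"] == "1" else "cat"].append(
            (row["code"], row["label"])
        )

    concepts = []
    for row in _read_rows(directory / "concepts.csv"):
        pv = by_concept.get(row["concept_id"], {"cat": [], "spec": []})
        if row["range_min"] != "" and row["range_max"] != "":
            domain = CodeSpec(
                kind=NUMERIC_RANGE,
                range=(float(row["range_min"]), float(row["range_max"])),
                special_codes=tuple(pv["cat"] + pv["spec"]),
            )
        elif pv["cat"] or pv["spec"]:
            domain = CodeSpec(
                kind=CATEGORICAL,
                categories=tuple(pv["cat"]),
                special_codes=tuple(pv["spec"]),
            )
        else:
            domain = CodeSpec()
        concepts.append(
            CommonConcept(
                concept_id=row["concept_id"],
                label=row["label"],
                category=row["category"],
                data_type=row["data_type"],
                harmonized_domain=domain,
                units=row["units"],
            )
        )

    variables = read_normalized(directory / "variables.csv")

    mappings, unit_rules, bin_rules = [], [], []
    for row in _read_rows(directory / "mappings.csv"):
        mappings.append(
            VariableMapping(
                concept_id=row["concept_id"],
                source=row["source"],
                variable_name=row["variable_name"],
                table_name=row["table_name"],
            )
        )
        if row["unit_factor"]:
            unit_rules.append(
                UnitRule(
                    concept_id=row["concept_id"],
                    source=row["source"],
                    factor=float(row["unit_factor"]),
                    direction=row["unit_direction"],
                    raw_unit=row["raw_unit"],
                    harmonized_unit=row["harmonized_unit"],
                )
            )
        if row["bin_spec"]:
            bin_rules.append(
                parse_bin_spec(row["concept_id"], row["source"], row["bin_spec"])
            )

    value_maps = [
        ValueMappingRow(
            source=row["source"],
            concept_id=row["concept_id"],
            raw_value=row["raw_value"],
            raw_label=row["raw_label"],
            harmonized_value=row["harmonized_value"],
            harmonized_label=row["harmonized_label"],
        )
        for row in _read_rows(directory / "value_harmonization.csv")
    ]

    catalog = Catalog(
        concepts=concepts,
        variables=variables,
        mappings=mappings,
        value_maps=value_maps,
        unit_rules=unit_rules,
        bin_rules=bin_rules,
    )
    catalog.validate()
    return catalog


# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonizationProfile:
    numeric: int
    categorical: int
    unit: int

    def __iter__(self):
        return iter((self.numeric, self.categorical, self.unit))


def harmonization_profile(catalog: Catalog) -> HarmonizationProfile:
    """Count concepts needing numeric / categorical / unit harmonization.

    Counting rule (a concept may fall in several groups):

    * numeric — a bin rule applies, or some mapped variable's declared
      range, after applying its unit rule, differs from the harmonized
      range (i.e. range widening was needed);
    * categorical — some recode row is a non-identity raw → harmonized map;
    * unit — a unit rule applies.
    """
    numeric: set[str] = set()
    categorical: set[str] = set()
    unit: set[str] = set()

    for b in catalog.bin_rules:
        numeric.add(b.concept_id)
    for u in catalog.unit_rules:
        unit.add(u.concept_id)
    for r in catalog.value_maps:
        if r.raw_value != r.harmonized_value:
            categorical.add(r.concept_id)
    for m in catalog.mappings:
        if not catalog.has_concept(m.concept_id):
            continue
        concept = catalog.concept(m.concept_id)
        if concept.data_type != "numeric" or concept.harmonized_domain.range is None:
            continue
        var = catalog.variable_def(m.source, m.variable_name, m.table_name)
        if var is None or var.code_spec.range is None:
            continue
        lo, hi = var.code_spec.range
        rule = catalog.unit_rule_for(m.concept_id, m.source)
        if rule is not None:
            lo, hi = convert_unit(lo, rule), convert_unit(hi, rule)
            if lo > hi:
                lo, hi = hi, lo
        if (lo, hi) != concept.harmonized_domain.range:
            numeric.add(m.concept_id)
    return HarmonizationProfile(len(numeric), len(categorical), len(unit))
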