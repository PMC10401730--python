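"""Concept-level query translation, execution and result regrouping.

The pipeline mirrors a mapping-driven federated cohort-count system:

1. A researcher states criteria against *harmonized* concepts
   (:class:`QueryCriteria`, a small JSON-serializable object).
2. :func:`translate` rewrites the criteria into one
   :class:`BackendQuery` per selected dataset, substituting each concept
   with the dataset's raw variable name and each selected harmonized code
   with the dataset's raw code(s) via the inverse recode table.  Numeric
   intervals pass through unchanged because unit and bin harmonization is
   applied once at record import.
3. :func:`execute` runs the per-dataset filters against a
   :class:`RecordStore` holding every visit row of every source in a
   single collection, and collects *distinct* patient identifiers — a
   patient with many qualifying visits is counted once.  The terms of a
   query are a same-record conjunction: one visit row must satisfy all
   predicates simultaneously.
4. :func:`regroup` turns the per-dataset identifier sets into counts and
   a total (identifiers are dataset-scoped, so the total is the sum).

:func:`render_statement` prints the translated query in the document-
database dialect, e.g.::

    db.records_collection.distinct("NACCID",
        {"dataset":"NACC", "EDUC":{"$gte":5, "$lte":15}})
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import (
    ExecutionError,
    QueryValidationError,
    RecordImportError,
    ValueMappingError,
)
from .mapping_catalog import (
    Catalog,
    bin_numeric,
    convert_unit,
    map_value,
    raw_values_for,
)

__all__ = [
    "TermCriterion",
    "QueryCriteria",
    "Filter",
    "BackendQuery",
    "UnmappedTermNotice",
    "RecordStore",
    "DEFAULT_ID_FIELDS",
    "HARMONIZED_SUFFIX",
    "translate",
    "render_statement",
    "execute",
    "regroup",
    "import_records",
    "term_summary",
    "TermDistribution",
    "five_number_summary",
    "search_terms",
    "browse_terms",
]

DEFAULT_ID_FIELDS = {"NACC": "NACCID", "ADNI": "RID"}
HARMONIZED_SUFFIX = "_harmonized"


# --------------------------------------------------------------------------
# criteria

@dataclass(frozen=True)
class TermCriterion:
    concept_id: str
    kind: str  # "categorical" | "numeric"
    values: tuple[str, ...] = ()
    range: tuple[float, float] | None = None


@dataclass(frozen=True)
class QueryCriteria:
    datasets: tuple[str, ...]
    terms: tuple[TermCriterion, ...] = ()

    @classmethod
    def from_json(cls, doc: Mapping | str) -> "QueryCriteria":
        """Build criteria from the published JSON shape.

        ``{"datasets": [...], "terms": [{"concept": id, "values": [...]}
        | {"concept": id, "min": x, "max": y}]}``
        """
        if isinstance(doc, str):
            doc = json.loads(doc)
        if not isinstance(doc, Mapping):
            raise QueryValidationError("criteria document must be a JSON object")
        datasets = doc.get("datasets")
        if not isinstance(datasets, list) or not datasets:
            raise QueryValidationError("'datasets' must be a non-empty list")
        terms = []
        for t in doc.get("terms", []):
            if "concept" not in t:
                raise QueryValidationError(f"term missing 'concept': {t!r}")
            if "values" in t:
                if not isinstance(t["values"], list) or not t["values"]:
                    raise QueryValidationError(
                        f"'values' of {t['concept']!r} must be a non-empty list"
                    )
                terms.append(
                    TermCriterion(
                        concept_id=t["concept"],
                        kind="categorical",
                        values=tuple(str(v) for v in t["values"]),
                    )
                )
            elif "min" in t and "max" in t:
                terms.append(
                    TermCriterion(
                        concept_id=t["concept"],
                        kind="numeric",
                        range=(float(t["min"]), float(t["max"])),
                    )
                )
            else:
                raise QueryValidationError(
                    f"term {t['concept']!r} needs 'values' or 'min'+'max'"
                )
        return cls(datasets=tuple(str(d) for d in datasets), terms=tuple(terms))

    def to_json(self) -> dict:
        terms = []
        for t in self.terms:
            if t.kind == "categorical":
                terms.append({"concept": t.concept_id, "values": list(t.values)})
            else:
                terms.append(
                    {"concept": t.concept_id, "min": t.range[0], "max": t.range[1]}
                )
        return {"datasets": list(self.datasets), "terms": terms}

    def validate(self, catalog: Catalog) -> None:
        if not self.datasets:
            raise QueryValidationError("no dataset selected")
        for t in self.terms:
            if not catalog.has_concept(t.concept_id):
                raise QueryValidationError(f"unknown concept {t.concept_id!r}")
            concept = catalog.concept(t.concept_id)
            if t.kind == "categorical":
                bad = [v for v in t.values if v not in concept.domain_codes]
                if bad:
                    raise QueryValidationError(
                        f"values {bad} outside the harmonized domain of "
                        f"{t.concept_id!r}"
                    )
            else:
                rng = concept.harmonized_domain.range
                if t.range is None or t.range[0] > t.range[1]:
                    raise QueryValidationError(
                        f"invalid range for {t.concept_id!r}: {t.range}"
                    )
                if rng is not None and (t.range[0] < rng[0] or t.range[1] > rng[1]):
                    raise QueryValidationError(
                        f"range {list(t.range)} of {t.concept_id!r} outside the "
                        f"harmonized domain {list(rng)}"
                    )


# --------------------------------------------------------------------------
# backend queries

@dataclass(frozen=True)
class Filter:
    field: str
    op: str  # "in" | "range"
    codes: tuple[str, ...] = ()
    bounds: tuple[float, float] | None = None


@dataclass(frozen=True)
class BackendQuery:
    dataset: str
    patient_id_field: str
    filters: tuple[Filter, ...] = ()


@dataclass(frozen=True)
class UnmappedTermNotice:
    dataset: str
    concept_id: str

    def __str__(self) -> str:
        return (
            f"concept {self.concept_id!r} has no mapped variable in dataset "
            f"{self.dataset!r}; dataset excluded from this query"
        )


def translate(
    criteria: QueryCriteria,
    catalog: Catalog,
    id_fields: Mapping[str, str] | None = None,
) -> tuple[list[BackendQuery], list[UnmappedTermNotice]]:
    """Rewrite harmonized criteria into per-dataset raw-code filters.

    A dataset in which some requested concept has no mapped variable is
    excluded from the returned queries and reported via a notice.
    """
    criteria.validate(catalog)
    id_fields = {**DEFAULT_ID_FIELDS, **(id_fields or {})}
    queries: list[BackendQuery] = []
    notices: list[UnmappedTermNotice] = []
    for dataset in criteria.datasets:
        if dataset not in id_fields:
            raise QueryValidationError(
                f"no patient-id field registered for dataset {dataset!r}"
            )
        filters: list[Filter] = []
        skip = False
        for term in criteria.terms:
            vm = catalog.mapping_for(term.concept_id, dataset)
            if vm is None:
                notices.append(UnmappedTermNotice(dataset, term.concept_id))
                skip = True
                break
            if term.kind == "numeric":
                filters.append(
                    Filter(field=vm.variable_name, op="range", bounds=term.range)
                )
                continue
            if catalog.bin_rule_for(term.concept_id, dataset) is not None:
                # binned numeric source: the harmonized codes live in the
                # added column written at import time
                filters.append(
                    Filter(
                        field=vm.variable_name + HARMONIZED_SUFFIX,
                        op="in",
                        codes=term.values,
                    )
                )
                continue
            raw_codes: list[str] = []
            for hv in term.values:
                raws = raw_values_for(dataset, term.concept_id, hv, catalog)
                if not raws:
                    raise ValueMappingError(
                        f"harmonized code {hv!r} of {term.concept_id!r} has no "
                        f"raw preimage in dataset {dataset!r}"
                    )
                for r in raws:
                    if r not in raw_codes:
                        raw_codes.append(r)
            filters.append(
                Filter(field=vm.variable_name, op="in", codes=tuple(raw_codes))
            )
        if not skip:
            queries.append(
                BackendQuery(
                    dataset=dataset,
                    patient_id_field=id_fields[dataset],
                    filters=tuple(filters),
                )
            )
    return queries, notices


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def render_statement(q: BackendQuery) -> str:
    """Emit the document-database ``distinct`` statement for one dataset."""
    parts = [f'"dataset":"{q.dataset}"']
    for f in q.filters:
        if f.op == "range":
            lo, hi = f.bounds
            parts.append(
                f'"{f.field}":{{"$gte":{_fmt_number(lo)}, "$lte":{_fmt_number(hi)}}}'
            )
        elif len(f.codes) == 1:
            parts.append(f'"{f.field}":"{f.codes[0]}"')
        else:
            inner = ", ".join(f'"{c}"' for c in f.codes)
            parts.append(f'"{f.field}":{{"$in":[{inner}]}}')
    return (
        f'db.records_collection.distinct("{q.patient_id_field}", '
        f'{{{", ".join(parts)}}})'
    )


# --------------------------------------------------------------------------
# record store and execution

class RecordStore:
    """In-memory single-collection store with conjunctive field filters.

    Emulates a document database holding all sources' visit rows in one
    collection, each row tagged with its dataset name.
    """

    def __init__(self):
        self._records: list[dict] = []

    def insert(self, record: dict) -> None:
        self._records.append(record)

    def insert_many(self, records: Iterable[dict]) -> None:
        self._records.extend(records)

    def __len__(self) -> int:
        return len(self._records)

    def known_fields(self, dataset: str) -> set[str]:
        fields: set[str] = set()
        for r in self._records:
            if r.get("dataset") == dataset:
                fields.update(r)
        return fields

    def find(self, query: BackendQuery) -> Iterable[dict]:
        for rec in self._records:
            if rec.get("dataset") != query.dataset:
                continue
            if all(_matches(rec, f) for f in query.filters):
                yield rec

    def distinct(self, field: str, query: BackendQuery) -> set[str]:
        return {rec[field] for rec in self.find(query) if field in rec}

    def values(self, dataset: str, field: str) -> list:
        return [
            r[field] for r in self._records if r.get("dataset") == dataset and field in r
        ]


def _matches(rec: dict, f: Filter) -> bool:
    if f.field not in rec:
        return False
    v = rec[f.field]
    if f.op == "range":
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            return False
        return f.bounds[0] <= v <= f.bounds[1]
    return str(v) in f.codes


def execute(
    queries: Sequence[BackendQuery], store: RecordStore
) -> dict[str, set[str]]:
    """Per dataset, the distinct patient ids with >=1 row matching all filters."""
    results: dict[str, set[str]] = {}
    for q in queries:
        known = store.known_fields(q.dataset)
        if known:
            for f in q.filters:
                aliases = {
                    f.field,
                    f.field + "__special",
                    f.field.removesuffix(HARMONIZED_SUFFIX),
                }
                if not aliases & known:
                    raise ExecutionError(
                        f"field {f.field!r} unknown in dataset {q.dataset!r}"
                    )
        results[q.dataset] = store.distinct(q.patient_id_field, q)
    return results


def regroup(results: Mapping[str, set]) -> tuple[dict[str, int], int]:
    """Set sizes per dataset plus the cross-dataset total (ids are scoped)."""
    counts = {d: len(ids) for d, ids in results.items()}
    return counts, sum(counts.values())


# --------------------------------------------------------------------------
# record import

def import_records(
    rows,
    dataset: str,
    catalog: Catalog,
    store: RecordStore,
    patient_id_field: str | None = None,
    table_name: str = "",
) -> int:
    """Import study rows into the store, applying unit and bin rules.

    ``rows`` is a DataFrame or an iterable of column→text mappings (one
    visit per row).  Numeric fields are parsed to floats; declared
    sentinel codes (9, 99, -4, ...) are moved to a ``<field>__special``
    shadow so they can never satisfy an interval predicate; unit rules
    rescale in place; bin rules append a ``<field>_harmonized`` column
    with the harmonized categorical code.  Returns the row count imported.
    """
    if patient_id_field is None:
        patient_id_field = DEFAULT_ID_FIELDS.get(dataset)
        if patient_id_field is None:
            raise RecordImportError(
                f"no patient-id field known for dataset {dataset!r}"
            )
    if hasattr(rows, "columns"):  # pandas DataFrame
        rows = rows.fillna("").astype(str).to_dict(orient="records")

    # per-column harmonization plan, resolved once
    concept_of: dict[str, "VariableMapping"] = {}
    for m in catalog.mappings:
        if m.source != dataset:
            continue
        if table_name and m.table_name and m.table_name != table_name:
            continue
        concept_of[m.variable_name] = m

    n = 0
    for row in rows:
        if patient_id_field not in row or str(row[patient_id_field]).strip() == "":
            raise RecordImportError(
                f"row without patient identifier {patient_id_field!r} in "
                f"dataset {dataset!r}"
            )
        rec: dict = {"dataset": dataset}
        if table_name:
            rec["table"] = table_name
        for col, value in row.items():
            text = str(value).strip()
            if text == "":
                continue
            var = catalog.variable_def(dataset, col, table_name)
            if var is None or var.data_type == "categorical":
                rec[col] = text
                continue
            if text in (c for c, _ in var.code_spec.special_codes):
                rec[col + "__special"] = text
                continue
            try:
                v = float(text)
            except ValueError:
                raise RecordImportError(
                    f"non-numeric value {text!r} for numeric variable {col!r} "
                    f"in dataset {dataset!r}"
                ) from None
            mapping = concept_of.get(col)
            if mapping is not None:
                rule = catalog.unit_rule_for(mapping.concept_id, dataset)
                if rule is not None:
                    v = convert_unit(v, rule)
                brule = catalog.bin_rule_for(mapping.concept_id, dataset)
                if brule is not None:
                    rec[col + HARMONIZED_SUFFIX] = bin_numeric(v, brule)
            rec[col] = v
        store.insert(rec)
        n += 1
    return n


# --------------------------------------------------------------------------
# term summaries and term discovery

@dataclass(frozen=True)
class TermDistribution:
    concept_id: str
    dataset: str
    kind: str  # "categorical" | "numeric"
    counts: tuple[tuple[str, int], ...] = ()  # harmonized code -> records
    summary: tuple[float, float, float, float, float] | None = None
    n: int = 0

    def to_json(self) -> dict:
        if self.kind == "categorical":
            return {
                "concept": self.concept_id,
                "dataset": self.dataset,
                "kind": self.kind,
                "counts": dict(self.counts),
                "n": self.n,
            }
        return {
            "concept": self.concept_id,
            "dataset": self.dataset,
            "kind": self.kind,
            "summary": list(self.summary) if self.summary else None,
            "n": self.n,
        }


def five_number_summary(values: Sequence[float]) -> tuple[float, ...]:
    """Min, Q1, median, Q3, max with Tukey (median-of-halves) hinges."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 0:
        raise ValueError("empty sample")

    def med(a: Sequence[float]) -> float:
        m = len(a)
        return a[m // 2] if m % 2 else (a[m // 2 - 1] + a[m // 2]) / 2.0

    # Tukey hinges: for odd n the median belongs to both halves
    lower = xs[: (n + 1) // 2]
    upper = xs[n // 2 :]
    return (xs[0], med(lower), med(xs), med(upper), xs[-1])


def term_summary(
    concept_id: str, dataset: str, store: RecordStore, catalog: Catalog
) -> TermDistribution | UnmappedTermNotice:
    """Distribution of a concept's harmonized values in one dataset.

    Categorical concepts yield per-category record counts; numeric ones a
    five-number summary over non-sentinel values.
    """
    vm = catalog.mapping_for(concept_id, dataset)
    if vm is None:
        return UnmappedTermNotice(dataset, concept_id)
    concept = catalog.concept(concept_id)
    if concept.data_type == "categorical":
        if catalog.bin_rule_for(concept_id, dataset) is not None:
            codes = [
                str(v)
                for v in store.values(dataset, vm.variable_name + HARMONIZED_SUFFIX)
            ]
        else:
            codes = [
                map_value(dataset, concept_id, str(v), catalog)[0]
                for v in store.values(dataset, vm.variable_name)
            ]
        counter = Counter(codes)
        ordered = tuple(
            (code, counter[code]) for code in concept.domain_codes if code in counter
        )
        return TermDistribution(
            concept_id=concept_id,
            dataset=dataset,
            kind="categorical",
            counts=ordered,
            n=sum(counter.values()),
        )
    values = [
        v
        for v in store.values(dataset, vm.variable_name)
        if isinstance(v, (int, float)) and not isinstance(v, bool)
    ]
    if not values:
        return TermDistribution(
            concept_id=concept_id, dataset=dataset, kind="numeric", summary=None, n=0
        )
    return TermDistribution(
        concept_id=concept_id,
        dataset=dataset,
        kind="numeric",
        summary=tuple(five_number_summary(values)),
        n=len(values),
    )


def search_terms(text: str, catalog: Catalog) -> list:
    """Case-insensitive substring search over concept labels.

    Exact label matches rank before substring matches; ties break
    alphabetically.
    """
    needle = text.strip().casefold()
    hits = [c for c in catalog.concepts if needle in c.label.casefold()]
    return sorted(hits, key=lambda c: (c.label.casefold() != needle, c.label))


def browse_terms(catalog: Catalog) -> dict[str, list]:
    """Category → concepts tree in deterministic alphabetical order."""
    tree: dict[str, list] = {}
    for c in sorted(catalog.concepts, key=lambda c: (c.category, c.label)):
        tree.setdefault(c.category, []).append(c)
    return dict(sorted(tree.items()))
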