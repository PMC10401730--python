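"""Self-contained two-source synthetic cohorts with known query answers.

The generator emulates the structural heterogeneity of two real AD data
resources without containing any restricted data: source ``NACC`` ships
its visit rows in a single file, source ``ADNI`` splits them across
tables.  The planted concept roster always includes every harmonization
challenge the toolkit must handle:

* ``banked_postmortem_csf`` — inconsistent categorical codings recoded
  through a six-row harmonization table (``ADNI`` 1/2 vs ``NACC``
  0/1/9/-4);
* ``right_hippocampus_volume`` — a mm³-vs-cc unit clash (factor 1000);
* ``packs_per_day`` — numeric in one source, categorical in the other,
  bridged by an interval bin rule;
* ``years_of_education`` — a range clash ([0, 36] vs [0, 20], harmonized
  to the wider range);
* ``game_skill_difficulty`` — offset categorical codes (harmonized
  "Requires assistance" = raw 2 in NACC, raw 4 in ADNI);
* plus cleanly shared concepts (``marital_status``, ``sex``,
  ``mmse_total``).

Every patient's harmonized attribute values are drawn once and repeated
across that patient's visit rows, so distinct-patient counting is
exercised while the per-patient ground truth stays closed-form.
:class:`GroundTruth` answers any :class:`~.query_engine.QueryCriteria`
directly from those attributes; :func:`oracle_count` answers the same
criteria by a brute-force scan of the raw CSV rows.  The two oracles are
independent of the query engine and of each other.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dictionary_io import CATEGORICAL, NUMERIC_RANGE, CodeSpec, parse_dictionary
from .errors import CohortBridgeError
from .mapping_catalog import (
    Bin,
    BinRule,
    Catalog,
    CommonConcept,
    UnitRule,
    ValueMappingRow,
    VariableMapping,
    save_catalog,
)
from .query_engine import DEFAULT_ID_FIELDS, QueryCriteria, TermCriterion

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "CohortBundle",
    "PLANTED_CONCEPTS",
    "generate",
    "oracle_count",
    "random_criteria",
]

SOURCES = ("NACC", "ADNI")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic two-source cohort."""

    seed: int = 0
    n_patients: Mapping[str, int] | int = 2000  # per source
    visits: tuple[int, int] = (1, 4)  # inclusive range per patient
    roster: tuple[str, ...] = ()  # empty = all planted concepts
    missing_rate: float = 0.05
    sentinel_rate: float = 0.05

    def patients(self, source: str) -> int:
        n = (
            self.n_patients
            if isinstance(self.n_patients, int)
            else self.n_patients[source]
        )
        if n <= 0:
            raise CohortBridgeError("n_patients must be positive")
        return n

    def __post_init__(self):
        for r in (self.missing_rate, self.sentinel_rate):
            if not 0.0 <= r <= 1.0:
                raise CohortBridgeError(f"rate {r} outside [0, 1]")
        if self.visits[0] < 1 or self.visits[0] > self.visits[1]:
            raise CohortBridgeError(f"invalid visits range {self.visits}")


# --------------------------------------------------------------------------
# planted concept roster

@dataclass(frozen=True)
class _Planted:
    concept_id: str
    label: str
    category: str
    data_type: str
    domain: CodeSpec
    units: str
    # per-source variable: (variable_name, table, dict-row fields)
    nacc_var: tuple[str, str, str]  # (name, form code, code-spec text)
    adni_var: tuple[str, str, str, str]  # (name, table, code text, units)
    # harmonized-code -> ADNI raw code (None = identity / not categorical)
    adni_recode: tuple[tuple[str, str], ...] | None = None
    nacc_value_rows: tuple[tuple[str, str, str, str], ...] = ()
    # sampling
    cat_probs: tuple[float, ...] = ()
    nacc_sentinels: tuple[str, ...] = ()
    adni_sentinels: tuple[str, ...] = ()


_GAMES_CATS = (
    ("0", "Normal"),
    ("1", "Has difficulty but does by self"),
    ("2", "Requires assistance"),
    ("3", "Dependent"),
)
_PACKS_CATS = (
    ("0", "No reported cigarette use"),
    ("1", "1 cigarette to less than 1/2 pack"),
    ("2", "1/2 pack to less than 1 pack"),
    ("3", "1 pack to 1 1/2 packs"),
    ("4", "1 1/2 packs to 2 packs"),
    ("5", "More than two packs"),
)
_MARITAL_CATS = (
    ("1", "Married"),
    ("2", "Widowed"),
    ("3", "Divorced"),
    ("4", "Separated"),
    ("5", "Never married"),
)

PLANTED_CONCEPTS: tuple[_Planted, ...] = (
    _Planted(
        concept_id="years_of_education",
        label="Years of education",
        category="Demographics",
        data_type="numeric",
        domain=CodeSpec(
            kind=NUMERIC_RANGE, range=(0.0, 36.0), special_codes=(("99", "Unknown"),)
        ),
        units="",
        nacc_var=("EDUC", "a1", "0 - 36; 99 = Unknown"),
        adni_var=("PTEDUCAT", "PTDEMOG", "0..20", ""),
        nacc_sentinels=("99",),
    ),
    _Planted(
        concept_id="marital_status",
        label="Marital status",
        category="Demographics",
        data_type="categorical",
        domain=CodeSpec(
            kind=CATEGORICAL,
            categories=_MARITAL_CATS,
            special_codes=(("9", "Unknown"),),
        ),
        units="",
        nacc_var=(
            "MARISTAT",
            "a1",
            "1 = Married; 2 = Widowed; 3 = Divorced; 4 = Separated; "
            "5 = Never married; 9 = Unknown",
        ),
        adni_var=(
            "PTMARRY",
            "PTDEMOG",
            "1=Married; 2=Widowed; 3=Divorced; 4=Separated; 5=Never married; "
            "9=Unknown",
            "",
        ),
        cat_probs=(0.50, 0.15, 0.15, 0.05, 0.15),
        nacc_sentinels=("9",),
        adni_sentinels=("9",),
    ),
    _Planted(
        concept_id="sex",
        label="Sex",
        category="Demographics",
        data_type="categorical",
        domain=CodeSpec(kind=CATEGORICAL, categories=(("1", "Male"), ("2", "Female"))),
        units="",
        nacc_var=("SEX", "a1", "1 = Male; 2 = Female"),
        adni_var=("PTGENDER", "PTDEMOG", "1=Male(1); 2=Female(2)", ""),
        cat_probs=(0.45, 0.55),
    ),
    _Planted(
        concept_id="mmse_total",
        label="Mini-Mental State Examination (MMSE) total score",
        category="Neuropsychological Battery Scores",
        data_type="numeric",
        domain=CodeSpec(kind=NUMERIC_RANGE, range=(0.0, 30.0)),
        units="",
        nacc_var=("NACCMMSE", "c1", "0 - 30"),
        adni_var=("MMSCORE", "ASSESS", "0..30", ""),
    ),
    _Planted(
        concept_id="banked_postmortem_csf",
        label="Banked postmortem CSF",
        category="Neuropathology",
        data_type="categorical",
        domain=CodeSpec(
            kind=CATEGORICAL,
            categories=(("0", "No"), ("1", "Yes")),
            special_codes=(("9", "Missing/unknown"), ("-4", "Not available")),
        ),
        units="",
        nacc_var=(
            "NPCSFBANK",
            "np",
            "0 = No; 1 = Yes; 9 = Missing/unknown; -4 = Not available",
        ),
        adni_var=("NPCSF", "NPDATA", "1=Yes(1); 2=No(2)", ""),
        # the printed six-row recode table, verbatim shape
        adni_recode=(("1", "1"), ("0", "2")),
        nacc_value_rows=(
            ("0", "No", "0", "No"),
            ("1", "Yes", "1", "Yes"),
            ("9", "Missing/unknown", "9", "Missing/unknown"),
            ("-4", "Not available", "-4", "Not available"),
        ),
        cat_probs=(0.70, 0.30),
        nacc_sentinels=("9", "-4"),
    ),
    _Planted(
        concept_id="game_skill_difficulty",
        label="Difficulty or need help with: Playing a game of skill",
        category="Functional Assessment Scale",
        data_type="categorical",
        domain=CodeSpec(
            kind=CATEGORICAL,
            categories=_GAMES_CATS,
            special_codes=(("8", "Not applicable"), ("9", "Unknown")),
        ),
        units="",
        nacc_var=(
            "GAMES",
            "b7",
            "0 = Normal; 1 = Has difficulty but does by self; "
            "2 = Requires assistance; 3 = Dependent; 8 = Not applicable; "
            "9 = Unknown",
        ),
        adni_var=(
            "FAQGAME",
            "ASSESS",
            "2=Normal; 3=Has difficulty but does by self; 4=Requires assistance; "
            "5=Dependent",
            "",
        ),
        adni_recode=(("0", "2"), ("1", "3"), ("2", "4"), ("3", "5")),
        cat_probs=(0.40, 0.30, 0.20, 0.10),
        nacc_sentinels=("8", "9"),
    ),
    _Planted(
        concept_id="right_hippocampus_volume",
        label="Segmented right hippocampus volume (cc)",
        category="Imaging",
        data_type="numeric",
        domain=CodeSpec(kind=NUMERIC_RANGE, range=(0.0, 10.0)),
        units="cc",
        nacc_var=("HIPPOVOLR", "mri", "0 - 10"),
        adni_var=("ST88SV", "IMGVOL", "0..10000", "mm3"),
    ),
    _Planted(
        concept_id="packs_per_day",
        label="Average number of packs smoked per day",
        category="Medical History",
        data_type="categorical",
        domain=CodeSpec(
            kind=CATEGORICAL,
            categories=_PACKS_CATS,
            special_codes=(
                ("8", "Not applicable"),
                ("9", "Unknown"),
                ("-4", "Not available"),
            ),
        ),
        units="",
        nacc_var=(
            "SMOKEPKS",
            "a5",
            "0 = No reported cigarette use; 1 = 1 cigarette to less than 1/2 pack; "
            "2 = 1/2 pack to less than 1 pack; 3 = 1 pack to 1 1/2 packs; "
            "4 = 1 1/2 packs to 2 packs; 5 = More than two packs; "
            "8 = Not applicable; 9 = Unknown; -4 = Not available",
        ),
        adni_var=("SMOKPKS", "MEDHIST", "0..10", ""),
        cat_probs=(0.55, 0.10, 0.10, 0.10, 0.10, 0.05),
        nacc_sentinels=("8", "9", "-4"),
    ),
)

_PLANTED_BY_ID = {p.concept_id: p for p in PLANTED_CONCEPTS}

PACKS_BINS = (
    Bin(0.0, 0.0, True, True, "0"),
    Bin(0.0, 0.5, False, False, "1"),
    Bin(0.5, 1.0, True, False, "2"),
    Bin(1.0, 1.5, True, False, "3"),
    Bin(1.5, 2.0, True, True, "4"),
    Bin(2.0, 10.0, False, True, "5"),
)


def build_planted_catalog(roster: tuple[str, ...] = ()) -> Catalog:
    """Assemble the Catalog for the planted roster (default: all concepts)."""
    roster = roster or tuple(p.concept_id for p in PLANTED_CONCEPTS)
    unknown = [r for r in roster if r not in _PLANTED_BY_ID]
    if unknown:
        raise CohortBridgeError(f"unknown planted concept(s) {unknown}")
    planted = [_PLANTED_BY_ID[r] for r in roster]

    nacc_dict_rows = [
        {
            "VariableName": p.nacc_var[0],
            "Form": p.nacc_var[1],
            "ShortDescriptor": p.label,
            "DataType": "Numeric",
            "AllowableCodes": p.nacc_var[2],
        }
        for p in planted
    ]
    adni_dict_rows = [
        {
            "Phase": "ADNI1",
            "FLDNAME": p.adni_var[0],
            "TBLNAME": p.adni_var[1],
            "CRFNAME": p.category,
            "TEXT": p.label,
            "TYPE": "N",
            "LENGTH": "8",
            "CODE": p.adni_var[2],
            "UNITS": p.adni_var[3],
        }
        for p in planted
    ]
    variables = parse_dictionary(nacc_dict_rows, "nacc") + parse_dictionary(
        adni_dict_rows, "adni"
    )

    concepts, mappings, value_maps, unit_rules, bin_rules = [], [], [], [], []
    for p in planted:
        concepts.append(
            CommonConcept(
                concept_id=p.concept_id,
                label=p.label,
                category=p.category,
                data_type=p.data_type,
                harmonized_domain=p.domain,
                units=p.units,
            )
        )
        mappings.append(
            VariableMapping(p.concept_id, "NACC", p.nacc_var[0], table_name="")
        )
        mappings.append(
            VariableMapping(p.concept_id, "ADNI", p.adni_var[0], p.adni_var[1])
        )
        for raw, raw_label, hv, hl in p.nacc_value_rows:
            value_maps.append(
                ValueMappingRow("NACC", p.concept_id, raw, raw_label, hv, hl)
            )
        if p.adni_recode:
            for hv, raw in p.adni_recode:
                hl = p.domain.label_for(hv) or hv
                value_maps.append(
                    ValueMappingRow("ADNI", p.concept_id, raw, hl, hv, hl)
                )
        if p.concept_id == "right_hippocampus_volume":
            unit_rules.append(
                UnitRule(
                    concept_id=p.concept_id,
                    source="ADNI",
                    factor=1000.0,
                    direction="divide",
                    raw_unit="mm3",
                    harmonized_unit="cc",
                )
            )
        if p.concept_id == "packs_per_day":
            bin_rules.append(BinRule(p.concept_id, "ADNI", PACKS_BINS))

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
# ground truth

@dataclass
class GroundTruth:
    """Per-patient harmonized attributes and a closed-form query answerer."""

    # dataset -> pid -> concept_id -> harmonized value
    #   str code (categorical), float (numeric), ("special", code), or None
    attributes: dict[str, dict[str, dict]]
    # dataset -> concept_id -> housing table name ("" = single file)
    tables: dict[str, dict[str, str]]

    def answer(self, criteria: QueryCriteria) -> tuple[dict[str, int], int]:
        counts: dict[str, int] = {}
        for dataset in criteria.datasets:
            table_of = self.tables.get(dataset, {})
            if any(t.concept_id not in table_of for t in criteria.terms):
                continue  # unmapped concept: dataset excluded, like translate()
            housing = {table_of[t.concept_id] for t in criteria.terms}
            if len(housing) > 1:
                # terms span tables: no single visit row carries all fields
                counts[dataset] = 0
                continue
            n = 0
            for attrs in self.attributes[dataset].values():
                if all(_satisfies(attrs.get(t.concept_id), t) for t in criteria.terms):
                    n += 1
            counts[dataset] = n
        return counts, sum(counts.values())

    def to_json(self) -> dict:
        enc = {
            d: {
                pid: {
                    c: (["special", v[1]] if isinstance(v, tuple) else v)
                    for c, v in attrs.items()
                }
                for pid, attrs in pats.items()
            }
            for d, pats in self.attributes.items()
        }
        return {"attributes": enc, "tables": self.tables}

    @classmethod
    def from_json(cls, doc: Mapping) -> "GroundTruth":
        attrs = {
            d: {
                pid: {
                    c: (tuple(v) if isinstance(v, list) else v)
                    for c, v in a.items()
                }
                for pid, a in pats.items()
            }
            for d, pats in doc["attributes"].items()
        }
        return cls(attributes=attrs, tables={k: dict(v) for k, v in doc["tables"].items()})


def _satisfies(value, term: TermCriterion) -> bool:
    if value is None or isinstance(value, tuple):  # missing or sentinel
        return False
    if term.kind == "numeric":
        return isinstance(value, (int, float)) and term.range[0] <= value <= term.range[1]
    return isinstance(value, str) and value in term.values


# --------------------------------------------------------------------------
# generation

@dataclass
class CohortBundle:
    spec: CohortSpec
    catalog: Catalog
    nacc_dictionary: list[dict]
    adni_dictionary: list[dict]
    nacc_data: pd.DataFrame
    adni_tables: dict[str, pd.DataFrame]
    ground_truth: GroundTruth

    def raw_tables(self) -> dict[str, dict[str, pd.DataFrame]]:
        """dataset -> table name -> raw rows ('' = the single NACC file)."""
        return {"NACC": {"": self.nacc_data}, "ADNI": dict(self.adni_tables)}

    def write(self, directory: str | Path) -> None:
        """Emit dictionaries, catalog, study CSVs and the ground truth."""
        directory = Path(directory)
        (directory / "dictionaries").mkdir(parents=True, exist_ok=True)
        (directory / "data").mkdir(exist_ok=True)
        _write_csv(
            directory / "dictionaries" / "nacc_dictionary.csv", self.nacc_dictionary
        )
        _write_csv(
            directory / "dictionaries" / "adni_dictionary.csv", self.adni_dictionary
        )
        save_catalog(self.catalog, directory / "catalog")
        self.nacc_data.to_csv(directory / "data" / "nacc.csv", index=False)
        for table, df in sorted(self.adni_tables.items()):
            df.to_csv(directory / "data" / f"adni_{table}.csv", index=False)
        with open(directory / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.ground_truth.to_json(), fh, sort_keys=True, indent=1)


def _write_csv(path: Path, rows: list[dict]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0]), quoting=csv.QUOTE_ALL)
        w.writeheader()
        w.writerows(rows)


def _pick(rng: np.random.Generator, codes: tuple, probs: tuple) -> str:
    return codes[int(rng.choice(len(codes), p=np.asarray(probs) / sum(probs)))]


def _packs_code_from_tenths(k: int) -> str:
    # independent integer arithmetic mirror of the packs/day interval table
    if k == 0:
        return "0"
    if k < 5:
        return "1"
    if k < 10:
        return "2"
    if k < 15:
        return "3"
    if k <= 20:
        return "4"
    return "5"


def generate(spec: CohortSpec) -> CohortBundle:
    """Generate one deterministic synthetic cohort bundle from ``spec``."""
    roster = spec.roster or tuple(p.concept_id for p in PLANTED_CONCEPTS)
    catalog = build_planted_catalog(roster)
    planted = [_PLANTED_BY_ID[r] for r in roster]
    rng = np.random.default_rng(spec.seed)

    attributes: dict[str, dict[str, dict]] = {s: {} for s in SOURCES}
    raw: dict[str, dict[str, dict[str, str]]] = {s: {} for s in SOURCES}

    for source in SOURCES:
        n = spec.patients(source)
        for i in range(n):
            pid = f"N{i + 1:06d}" if source == "NACC" else f"R{i + 1:04d}"
            attrs: dict[str, object] = {}
            cells: dict[str, str] = {}
            for p in planted:
                var = p.nacc_var[0] if source == "NACC" else p.adni_var[0]
                if rng.random() < spec.missing_rate:
                    attrs[p.concept_id] = None
                    cells[var] = ""
                    continue
                sentinels = (
                    p.nacc_sentinels if source == "NACC" else p.adni_sentinels
                )
                if sentinels and rng.random() < spec.sentinel_rate:
                    code = sentinels[int(rng.integers(len(sentinels)))]
                    if p.data_type == "numeric":
                        attrs[p.concept_id] = ("special", code)
                    else:
                        attrs[p.concept_id] = code
                    cells[var] = code
                    continue
                attrs[p.concept_id], cells[var] = _draw(rng, p, source)
            attributes[source][pid] = attrs
            raw[source][pid] = cells

    tables = {
        "NACC": {p.concept_id: "" for p in planted},
        "ADNI": {p.concept_id: p.adni_var[1] for p in planted},
    }
    truth = GroundTruth(attributes=attributes, tables=tables)

    # visit rows repeat each patient's time-invariant values
    nacc_rows = []
    n_visits = {}
    for pid, cells in raw["NACC"].items():
        n_visits[pid] = int(rng.integers(spec.visits[0], spec.visits[1] + 1))
        for v in range(n_visits[pid]):
            nacc_rows.append({"NACCID": pid, "VISITNUM": str(v + 1), **cells})
    nacc_cols = ["NACCID", "VISITNUM"] + [
        p.nacc_var[0] for p in planted
    ]
    nacc_df = pd.DataFrame(nacc_rows, columns=nacc_cols).fillna("")

    adni_tables: dict[str, pd.DataFrame] = {}
    table_vars: dict[str, list[str]] = {}
    for p in planted:
        table_vars.setdefault(p.adni_var[1], []).append(p.adni_var[0])
    adni_visits = {
        pid: int(rng.integers(spec.visits[0], spec.visits[1] + 1))
        for pid in raw["ADNI"]
    }
    for table, vars_ in sorted(table_vars.items()):
        rows = []
        for pid, cells in raw["ADNI"].items():
            for v in range(adni_visits[pid]):
                rows.append(
                    {
                        "RID": pid,
                        "VISCODE": f"m{6 * v:02d}",
                        **{x: cells[x] for x in vars_},
                    }
                )
        adni_tables[table] = pd.DataFrame(rows, columns=["RID", "VISCODE"] + vars_)

    nacc_dict_rows = [
        {
            "VariableName": p.nacc_var[0],
            "Form": p.nacc_var[1],
            "ShortDescriptor": p.label,
            "DataType": "Numeric",
            "AllowableCodes": p.nacc_var[2],
        }
        for p in planted
    ]
    adni_dict_rows = [
        {
            "Phase": "ADNI1",
            "FLDNAME": p.adni_var[0],
            "TBLNAME": p.adni_var[1],
            "CRFNAME": p.category,
            "TEXT": p.label,
            "TYPE": "N",
            "LENGTH": "8",
            "CODE": p.adni_var[2],
            "UNITS": p.adni_var[3],
        }
        for p in planted
    ]

    return CohortBundle(
        spec=spec,
        catalog=catalog,
        nacc_dictionary=nacc_dict_rows,
        adni_dictionary=adni_dict_rows,
        nacc_data=nacc_df,
        adni_tables=adni_tables,
        ground_truth=truth,
    )


def _draw(rng: np.random.Generator, p: _Planted, source: str):
    """Sample one non-missing, non-sentinel (harmonized value, raw cell)."""
    cid = p.concept_id
    if cid == "years_of_education":
        hi = 36 if source == "NACC" else 20
        v = int(rng.integers(0, hi + 1))
        return float(v), str(v)
    if cid == "mmse_total":
        v = int(rng.integers(0, 31))
        return float(v), str(v)
    if cid == "right_hippocampus_volume":
        mm3 = int(rng.integers(0, 10001))
        cc = mm3 / 1000
        return cc, (repr(cc) if source == "NACC" else str(mm3))
    if cid == "packs_per_day" and source == "ADNI":
        k = int(rng.integers(0, 101))  # tenths of a pack, 0.0 .. 10.0
        return _packs_code_from_tenths(k), repr(k / 10)
    # plain categorical draw on the harmonized scale
    codes = tuple(c for c, _ in p.domain.categories)
    hv = _pick(rng, codes, p.cat_probs or (1.0,) * len(codes))
    if source == "ADNI" and p.adni_recode:
        raw = dict(p.adni_recode)[hv]
    else:
        raw = hv
    return hv, raw


# --------------------------------------------------------------------------
# brute-force oracle over the raw CSV rows

def oracle_count(
    criteria: QueryCriteria,
    raw_tables: Mapping[str, Mapping[str, pd.DataFrame]],
    catalog: Catalog,
    id_fields: Mapping[str, str] | None = None,
) -> tuple[dict[str, int], int]:
    """Answer criteria by scanning raw per-dataset rows with raw codes.

    Independent of the query engine: value maps are inverted by hand,
    unit factors applied inline, and bins resolved by a linear scan.
    """
    id_fields = {**DEFAULT_ID_FIELDS, **(id_fields or {})}
    counts: dict[str, int] = {}
    for dataset in criteria.datasets:
        mappings = {
            m.concept_id: m for m in catalog.mappings if m.source == dataset
        }
        if any(t.concept_id not in mappings for t in criteria.terms):
            continue  # dataset excluded: some concept unmapped
        ids: set[str] = set()
        pid_col = id_fields[dataset]
        for table, df in raw_tables[dataset].items():
            rows = df.to_dict("records") if hasattr(df, "to_dict") else list(df)
            for row in rows:
                ok = True
                for term in criteria.terms:
                    m = mappings[term.concept_id]
                    col = m.variable_name
                    if col not in row:
                        ok = False
                        break
                    cell = str(row[col]).strip()
                    if cell in ("", "nan"):
                        ok = False
                        break
                    if not _term_ok(term, cell, dataset, m, catalog):
                        ok = False
                        break
                if ok:
                    ids.add(str(row[pid_col]))
        counts[dataset] = len(ids)
    return counts, sum(counts.values())


def _term_ok(term, cell, dataset, mapping, catalog) -> bool:
    var = catalog.variable_def(dataset, mapping.variable_name, mapping.table_name)
    if term.kind == "numeric":
        if var is not None and cell in (c for c, _ in var.code_spec.special_codes):
            return False
        v = float(cell)
        rule = catalog.unit_rule_for(term.concept_id, dataset)
        if rule is not None:
            v = v / rule.factor if rule.direction == "divide" else v * rule.factor
        return term.range[0] <= v <= term.range[1]
    brule = catalog.bin_rule_for(term.concept_id, dataset)
    if brule is not None:
        v = float(cell)
        code = None
        for b in brule.bins:  # linear scan of the interval table
            lo_ok = v > b.lower or (b.lower_closed and v == b.lower)
            hi_ok = v < b.upper or (b.upper_closed and v == b.upper)
            if lo_ok and hi_ok:
                code = b.code
                break
        return code in term.values
    rows = [
        r
        for r in catalog.value_maps
        if r.source == dataset and r.concept_id == term.concept_id
    ]
    if rows:
        raws = {r.raw_value for r in rows if r.harmonized_value in term.values}
    else:
        raws = set(term.values)
    return cell in raws


# --------------------------------------------------------------------------
# random criteria for property suites

def random_criteria(
    rng: np.random.Generator,
    catalog: Catalog,
    max_terms: int = 3,
) -> QueryCriteria:
    """Draw valid random criteria whose selected codes all have raw preimages
    in every selected dataset (so translation cannot fail)."""
    sources = catalog.sources()
    k = int(rng.integers(1, len(sources) + 1))
    datasets = tuple(
        sources[i] for i in sorted(rng.choice(len(sources), size=k, replace=False))
    )
    n_terms = int(rng.integers(0, max_terms + 1))
    pool = [c for c in catalog.concepts]
    rng.shuffle(pool := list(pool))
    terms: list[TermCriterion] = []
    for concept in pool:
        if len(terms) >= n_terms:
            break
        mapped = [d for d in datasets if catalog.mapping_for(concept.concept_id, d)]
        if concept.data_type == "numeric":
            lo_d, hi_d = concept.harmonized_domain.range
            a = int(rng.integers(int(lo_d), int(hi_d) + 1))
            b = int(rng.integers(int(lo_d), int(hi_d) + 1))
            terms.append(
                TermCriterion(
                    concept_id=concept.concept_id,
                    kind="numeric",
                    range=(float(min(a, b)), float(max(a, b))),
                )
            )
            continue
        safe = []
        for code in concept.domain_codes:
            ok = True
            for d in mapped:
                if catalog.bin_rule_for(concept.concept_id, d) is not None:
                    continue  # bin column holds harmonized codes directly
                rows = [
                    r
                    for r in catalog.value_maps
                    if r.source == d and r.concept_id == concept.concept_id
                ]
                if rows and not any(r.harmonized_value == code for r in rows):
                    ok = False
                    break
            if ok:
                safe.append(code)
        if not safe:
            continue
        m = int(rng.integers(1, len(safe) + 1))
        chosen = sorted(
            safe[i] for i in rng.choice(len(safe), size=m, replace=False)
        )
        terms.append(
            TermCriterion(
                concept_id=concept.concept_id, kind="categorical", values=tuple(chosen)
            )
        )
    return QueryCriteria(datasets=datasets, terms=tuple(terms))
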