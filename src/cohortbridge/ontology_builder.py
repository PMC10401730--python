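"""Compile a harmonization catalog into an OWL ontology of common concepts.

The generated ontology mirrors how ontology-driven cohort-query systems
model a codebook: a single top class, one scaffold class per sub-hierarchy
(Demographics, Neuropathology, ...), one class per common concept under
its sub-hierarchy, and value-domain axioms attached as existential
("some") restrictions:

* a categorical concept class carries one ``hasCategory`` restriction per
  permissible value, whose filler is a named category-value class;
* a numeric concept class carries exactly one ``hasRange`` restriction
  whose filler is an ``xsd:decimal`` datatype interval [min, max].

``hasCategory`` and ``hasRange`` are also declared as named classes under
a ``DataProperty`` scaffold (matching the class-centric presentation such
systems display in an ontology editor) in addition to being used as
properties inside the restrictions.

Serialization is RDF/XML written by a small deterministic emitter (fixed
base IRI, classes in sorted order) so that equal catalogs yield
byte-identical files; parsing goes through :mod:`rdflib`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from xml.sax.saxutils import escape, quoteattr

from rdflib import Graph, Namespace, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import CatalogValidationError, OwlParseError
from .mapping_catalog import Catalog

__all__ = [
    "OntClass",
    "Restriction",
    "OntologyModel",
    "build_ontology",
    "serialize_owl",
    "parse_owl",
    "class_count",
    "BASE_IRI",
    "TOP_CLASS",
]

BASE_IRI = "http://example.org/cohortbridge#"
CB = Namespace(BASE_IRI)

TOP_CLASS = "CommonDataElement"
DATA_PROPERTY = "DataProperty"
HAS_CATEGORY = "hasCategory"
HAS_RANGE = "hasRange"
CATEGORY_VALUE = "CategoryValue"

KIND_SCAFFOLD = "scaffold"
KIND_CONCEPT = "concept"
KIND_CATEGORY_VALUE = "category_value"


@dataclass(frozen=True)
class OntClass:
    name: str  # display name (rdfs:label)
    parent: str | None  # display name of the parent class; None for the top
    kind: str  # scaffold | concept | category_value


@dataclass(frozen=True)
class Restriction:
    on_class: str  # display name of the restricted concept class
    property: str  # hasCategory | hasRange
    filler: str | tuple[float, float]  # category label, or numeric interval


@dataclass(frozen=True)
class OntologyModel:
    classes: tuple[OntClass, ...]
    restrictions: tuple[Restriction, ...]

    def by_kind(self, kind: str) -> list[OntClass]:
        return [c for c in self.classes if c.kind == kind]


def slugify(name: str) -> str:
    slug = re.sub(r"[^0-9A-Za-z]+", "_", name).strip("_")
    return slug or "x"


def build_ontology(catalog: Catalog) -> OntologyModel:
    """Deterministically compile a catalog into an :class:`OntologyModel`."""
    for c in catalog.concepts:
        if not c.category:
            raise CatalogValidationError(
                [f"concept {c.concept_id!r} has an empty category"]
            )

    classes: list[OntClass] = [
        OntClass(TOP_CLASS, None, KIND_SCAFFOLD),
        OntClass(DATA_PROPERTY, TOP_CLASS, KIND_SCAFFOLD),
        OntClass(HAS_CATEGORY, DATA_PROPERTY, KIND_SCAFFOLD),
        OntClass(HAS_RANGE, DATA_PROPERTY, KIND_SCAFFOLD),
        OntClass(CATEGORY_VALUE, DATA_PROPERTY, KIND_SCAFFOLD),
    ]
    for category in sorted({c.category for c in catalog.concepts}):
        classes.append(OntClass(category, TOP_CLASS, KIND_SCAFFOLD))

    restrictions: list[Restriction] = []
    value_labels: set[str] = set()
    for concept in sorted(catalog.concepts, key=lambda c: c.label):
        classes.append(OntClass(concept.label, concept.category, KIND_CONCEPT))
        dom = concept.harmonized_domain
        if concept.data_type == "categorical":
            for _, label in (*dom.categories, *dom.special_codes):
                value_labels.add(label)
                restrictions.append(Restriction(concept.label, HAS_CATEGORY, label))
        else:
            if dom.range is not None:
                restrictions.append(
                    Restriction(concept.label, HAS_RANGE, tuple(dom.range))
                )
    for label in sorted(value_labels):
        classes.append(OntClass(label, CATEGORY_VALUE, KIND_CATEGORY_VALUE))

    names = [c.name for c in classes]
    clash = {n for n in names if names.count(n) > 1}
    if clash:
        raise CatalogValidationError([f"duplicate ontology class names: {sorted(clash)}"])
    return OntologyModel(tuple(classes), tuple(restrictions))


def class_count(model: OntologyModel) -> int:
    """Number of named classes of all kinds (scaffold + concept + value)."""
    return len(model.classes)


# --------------------------------------------------------------------------
# serialization

def _iri(cls: OntClass) -> str:
    prefix = {KIND_CONCEPT: "c_", KIND_CATEGORY_VALUE: "value_"}.get(cls.kind, "")
    return BASE_IRI + prefix + slugify(cls.name)


def _num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def serialize_owl(model: OntologyModel, path: str | Path) -> None:
    """Write the model as deterministic RDF/XML (sorted classes, fixed IRIs)."""
    iri_of = {c.name: _iri(c) for c in model.classes}
    restr_by_class: dict[str, list[Restriction]] = {}
    for r in model.restrictions:
        restr_by_class.setdefault(r.on_class, []).append(r)

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        "<rdf:RDF",
        '    xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"',
        '    xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"',
        '    xmlns:owl="http://www.w3.org/2002/07/owl#"',
        '    xmlns:xsd="http://www.w3.org/2001/XMLSchema#"',
        f'    xmlns:cb="{BASE_IRI}">',
        f'  <owl:Ontology rdf:about="{BASE_IRI.rstrip("#")}"/>',
        f'  <owl:ObjectProperty rdf:about="{BASE_IRI}prop_hasCategory"/>',
        f'  <owl:DatatypeProperty rdf:about="{BASE_IRI}prop_hasRange"/>',
    ]
    for cls in sorted(model.classes, key=lambda c: (c.kind, c.name)):
        lines.append(f"  <owl:Class rdf:about={quoteattr(iri_of[cls.name])}>")
        lines.append(f"    <rdfs:label>{escape(cls.name)}</rdfs:label>")
        lines.append(f"    <cb:kind>{cls.kind}</cb:kind>")
        if cls.parent is not None:
            lines.append(
                f"    <rdfs:subClassOf rdf:resource={quoteattr(iri_of[cls.parent])}/>"
            )
        for r in sorted(
            restr_by_class.get(cls.name, []), key=lambda r: (r.property, str(r.filler))
        ):
            lines.append("    <rdfs:subClassOf>")
            lines.append("      <owl:Restriction>")
            if r.property == HAS_CATEGORY:
                lines.append(
                    f"        <owl:onProperty rdf:resource="
                    f'"{BASE_IRI}prop_hasCategory"/>'
                )
                lines.append(
                    f"        <owl:someValuesFrom rdf:resource="
                    f"{quoteattr(iri_of[str(r.filler)])}/>"
                )
            else:
                lo, hi = r.filler
                lines.append(
                    f"        <owl:onProperty rdf:resource="
                    f'"{BASE_IRI}prop_hasRange"/>'
                )
                lines.append("        <owl:someValuesFrom>")
                lines.append("          <rdfs:Datatype>")
                lines.append(
                    '            <owl:onDatatype rdf:resource='
                    '"http://www.w3.org/2001/XMLSchema#decimal"/>'
                )
                lines.append(
                    '            <owl:withRestrictions rdf:parseType="Collection">'
                )
                lines.append(
                    "              <rdf:Description><xsd:minInclusive "
                    'rdf:datatype="http://www.w3.org/2001/XMLSchema#decimal">'
                    f"{_num(lo)}</xsd:minInclusive></rdf:Description>"
                )
                lines.append(
                    "              <rdf:Description><xsd:maxInclusive "
                    'rdf:datatype="http://www.w3.org/2001/XMLSchema#decimal">'
                    f"{_num(hi)}</xsd:maxInclusive></rdf:Description>"
                )
                lines.append("            </owl:withRestrictions>")
                lines.append("          </rdfs:Datatype>")
                lines.append("        </owl:someValuesFrom>")
            lines.append("      </owl:Restriction>")
            lines.append("    </rdfs:subClassOf>")
        lines.append("  </owl:Class>")
    lines.append("</rdf:RDF>")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# parsing

def parse_owl(path: str | Path) -> OntologyModel:
    """Parse an RDF/XML OWL document back into an :class:`OntologyModel`."""
    g = Graph()
    try:
        g.parse(str(path), format="xml")
    except Exception as exc:  # rdflib raises SAX/parser exceptions
        raise OwlParseError(f"cannot parse OWL file {path}: {exc}") from exc

    kind_pred = URIRef(BASE_IRI + "kind")
    named = [s for s in g.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)]
    label_of: dict[URIRef, str] = {}
    kind_of: dict[URIRef, str] = {}
    for s in named:
        label = g.value(s, RDFS.label)
        label_of[s] = str(label) if label is not None else str(s).rsplit("#", 1)[-1]
        kind = g.value(s, kind_pred)
        kind_of[s] = str(kind) if kind is not None else KIND_CONCEPT

    classes: list[OntClass] = []
    restrictions: list[Restriction] = []
    for s in named:
        parent_name = None
        for parent in g.objects(s, RDFS.subClassOf):
            if isinstance(parent, URIRef) and parent in label_of:
                parent_name = label_of[parent]
            elif (parent, RDF.type, OWL.Restriction) in g:
                restrictions.append(_read_restriction(g, s, parent, label_of))
        classes.append(OntClass(label_of[s], parent_name, kind_of[s]))

    classes.sort(key=lambda c: (c.kind, c.name))
    restrictions.sort(key=lambda r: (r.on_class, r.property, str(r.filler)))
    return OntologyModel(tuple(classes), tuple(restrictions))


def _read_restriction(g: Graph, cls, node, label_of) -> Restriction:
    prop = g.value(node, OWL.onProperty)
    filler = g.value(node, OWL.someValuesFrom)
    prop_name = str(prop).rsplit("#", 1)[-1].replace("prop_", "") if prop else ""
    if prop_name == HAS_RANGE:
        lo = hi = None
        for lst in g.objects(filler, OWL.withRestrictions):
            for item in Collection(g, lst):
                for v in g.objects(item, XSD.minInclusive):
                    lo = float(v)
                for v in g.objects(item, XSD.maxInclusive):
                    hi = float(v)
        if lo is None or hi is None:
            raise OwlParseError(
                f"hasRange restriction on {label_of.get(cls, cls)} lacks min/max facets"
            )
        return Restriction(label_of[cls], HAS_RANGE, (lo, hi))
    if isinstance(filler, URIRef) and filler in label_of:
        target = label_of[filler]
    else:
        target = str(filler)
    return Restriction(label_of[cls], HAS_CATEGORY, target)
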