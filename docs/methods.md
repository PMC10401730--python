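# Methods

## Problem and approach

Multi-site clinical research resources describe their variables in data
dictionaries (codebooks) that disagree on names, codes, units and ranges
even when the underlying measurement is the same. `cohortbridge`
implements the full chain needed to ask *value-level* cohort questions
("how many patients with 5–15 years of education?") across such sources:

1. **Dictionary normalization** — two codebook layouts are parsed into a
   uniform model: a single-file UDS-style layout (variable name, form
   code, short descriptor, data type, allowable codes) and a multi-table
   layout (FLDNAME, TBLNAME, CRFNAME, TEXT, TYPE, CODE, UNITS). Short
   form codes are resolved to full form names through a configurable
   lookup table, and imaging descriptors with concatenated region names
   (`LeftIsthmusCingulate`) get spaces inserted at every lower→upper
   case boundary (an idempotent transform).
2. **Harmonization catalog** — a curated registry linking each *common
   concept* to its per-source variable, together with the rules that
   reconcile value domains. The catalog's external form is five CSV
   files: concepts, variables, variable↔concept mappings, permissible
   values, and the categorical recode table.
3. **Ontology compilation** — the catalog is compiled into an OWL 2
   ontology (RDF/XML): one class per common concept grouped under
   sub-hierarchy classes, with the value domain attached through
   existential restrictions (`hasCategory some <value class>` for each
   permissible value; a single `hasRange some xsd:decimal[min, max]`
   for numeric concepts).
4. **Query engine** — JSON criteria over harmonized concepts are
   translated per dataset into conjunctive filters over *raw* variable
   names and raw codes, executed against a single-collection record
   store, and regrouped into per-dataset distinct-patient counts and a
   total.

## Harmonization rules

* **Range clashes** — when sources declare different numeric ranges the
  harmonized domain is the interval hull (`widen_range`). For the only
  shapes that occur in practice one range contains the other, so the
  hull equals "keep the wider range"; for partial overlap the hull is
  the unique monotone extension.
* **Categorical recoding** — a per-(source, concept) raw→harmonized code
  table (e.g. `Banked postmortem CSF`: raw 2 in the multi-table source
  means "No", harmonized to code 0). When no recode rows exist the map
  is the identity restricted to the harmonized domain; a raw code
  outside both is an error carrying (source, concept, value).
* **Unit clashes** — a positive factor with a direction (e.g. divide by
  1000 to go from mm³ to cc). Applied once at record import.
* **Type clashes** — a numeric variable in one source vs a categorical
  one in the other is bridged by an ordered interval table (`BinRule`).
  The packs-per-day table is: `[0,0]→0`, `(0,0.5)→1`, `[0.5,1)→2`,
  `[1,1.5)→3`, `[1.5,2]→4`, `(2,10]→5`. The category wordings overlap at
  1.5 packs ("1 pack to 1½ packs" / "1½ packs to 2 packs"); bins are
  left-closed/right-open with the final bound closed, and 1.5 is
  assigned to the upper category, which resolves every tie
  deterministically. The binned code is stored as an added
  `<variable>_harmonized` column at import.
* **Sentinel codes** (8 = not applicable, 9/99 = unknown, −4 = not
  available) are labels, not measurements: they are never unit-converted
  or binned. On import into a numeric field they are moved to a
  `<variable>__special` shadow field and the numeric field is left
  absent, so a raw −4 can never satisfy an interval with a negative
  lower bound. Harmonized codes are always stored as text so signed
  sentinels survive round trips.

Unit and bin harmonization happen once at import; categorical recoding
happens at query time through the inverse of the recode table. This
split keeps import cheap (no per-code rewriting of every record) while
intervals still compare against already-harmonized magnitudes.

## Query semantics

* **Same-record conjunction** — a patient qualifies in a dataset iff at
  least one visit row satisfies *all* term predicates simultaneously.
  This is what a single-filter `distinct(<patient id>, {...})` statement
  computes; any-visit-per-term semantics is deliberately not offered.
* **Distinct counting** — replicating a patient's visit rows never
  changes a count.
* **Totals** — patient identifiers are dataset-scoped; the total is the
  sum of per-dataset counts (no cross-dataset linkage is attempted).
* **Unmapped concepts** — a dataset in which some requested concept has
  no mapped variable is excluded from that query and reported via a
  notice rather than silently returning 0.
* **Missing preimages** — selecting a harmonized code that has no raw
  preimage in a dataset's recode table raises an error; the caller can
  drop the dataset or the code explicitly.
* **Multi-table sources** — each table is imported row-wise into the one
  collection under the same dataset tag; no cross-table join is
  performed. Consequently a conjunction over concepts housed in
  different tables of the same source matches no single record and
  returns 0 for that source. This limitation is intrinsic to the
  single-filter statement shape and is covered by tests; callers who
  need cross-table conjunctions should merge tables on their visit key
  before import.
* **Statement dialect** — intervals render as
  `{"$gte":min, "$lte":max}` with integers printed without a decimal
  point; a singleton code set collapses to a scalar equality and larger
  sets render as `{"$in":[...]}`; the dataset tag always comes first and
  terms follow criteria order, so rendering is deterministic.
* **Term summaries** — categorical concepts yield per-harmonized-code
  record counts (records, not patients, matching what a bar chart of the
  stored collection shows); numeric concepts yield the five-number
  summary (min, Q1, median, Q3, max) over non-sentinel values with
  Tukey hinges — for odd n the median belongs to both halves, so
  {1,2,3,4,5} gives (1, 2, 3, 4, 5).
* **Term discovery** — search is case-insensitive substring matching
  over concept labels with exact matches ranked first, then
  alphabetical; browsing returns the category→concept tree in
  alphabetical order.

## Ontology encoding choices

OWL has no canonical way to attach a codebook's value domain to a class;
the encoding here uses existential restrictions with *named* fillers:
one `category_value` class per distinct permissible-value label (so
shared labels like "Yes" are a single class targeted by many
restrictions), and a datatype restriction `xsd:decimal[minInclusive,
maxInclusive]` for ranges. `hasCategory`/`hasRange` additionally appear
as named classes under a `DataProperty` scaffold, mirroring how such
vocabularies are displayed in an ontology editor; the property IRIs used
inside restrictions are distinct (`prop_hasCategory`, `prop_hasRange`)
to keep the RDF clean. `class_count` counts every named class — scaffold,
concept and category-value alike — and a test asserts the rule is
exhaustive. Serialization is a purpose-built deterministic RDF/XML
emitter (fixed base IRI, classes in sorted order) because byte-identical
output for equal catalogs is part of the module contract and stock
graph serializers do not guarantee stable bytes; parsing uses rdflib, so
every emitted file is also independently re-readable. No reasoning or
synonym enrichment is performed.

## Synthetic cohorts

The generator emulates the structural heterogeneity of two AD research
resources — one single-file source, one multi-table source — with every
harmonization challenge planted: the six-row categorical recode table,
the mm³/cc unit clash (factor 1000), the numeric-vs-categorical
packs-per-day clash, the [0,36] vs [0,20] education range clash, the
offset game-difficulty coding (harmonized "Requires assistance" = raw 2
vs raw 4), and cleanly shared concepts (marital status, sex, MMSE).

Defaults: 2000 patients per source, 1–4 visits per patient, 5%
missingness per (patient, concept), 5% sentinel-code rate where the
source declares sentinels. Categorical values are drawn from fixed
per-category probabilities; numeric values uniformly over the source's
declared range (so the two sources genuinely differ on education).
Volumes are generated as integer mm³ and packs-per-day as tenths of a
pack so that unit division and binning are exactly reproducible in
floating point. All visit rows repeat the patient's time-invariant
values, which keeps the per-patient ground truth closed-form while still
exercising distinct counting; it also means per-visit variation (real
longitudinal change, visit-level missingness) is *not* modelled, so
passing tests say nothing about any-visit-versus-same-visit differences
on real data. No attempt is made at clinical realism (disease
progression, correlated biomarkers, realistic marginals).

Correctness is established by triangulation: the query engine, a
brute-force scan of the raw CSVs using hand-inverted raw codes
(`oracle_count`), and the generator's closed-form `GroundTruth.answer`
are three independent routes that must agree — the test suite checks
all three pairwise on hundreds of random criteria, plus monotonicity
(adding a term never increases a count; widening a range never
decreases one), duplicate-visit invariance and total additivity. The
property suite in the acceptance tests runs 200 random criteria on the
full 2 × 2000-patient cohort; the unit suites use a 120-patient cohort
for speed.

## Numerical and degenerate-input conventions

* Ranges are closed intervals; interval predicates use inclusive bounds.
* Numbers that are mathematically integral print without a decimal
  point everywhere (code specs, statements, catalog files).
* An empty allowable-codes string parses to an unconstrained spec; both
  sources mark coded and continuous variables with the same type letter,
  so the numeric/categorical decision comes from the parsed codes
  (categories and no range ⇒ categorical, else numeric).
* `widen_range` on an empty/invalid interval, non-finite unit
  conversion inputs, values outside every bin, and raw codes outside
  both the recode table and the harmonized domain all raise typed
  errors rather than guessing.
* Catalog loading re-validates full referential integrity (orphan
  mappings, duplicate keys, codes outside domains, bins that fail to
  cover the declared source range) and reports every violation at once.

## Known limitations

* Concept↔variable mapping is curation input, not computed; no string
  matching or embedding alignment is attempted.
* No cross-table join for multi-table sources (see query semantics).
* The form-name lookup ships with a small default table; deployments
  with other form codes must extend it.
* The record store is in-memory; it implements the same filter
  semantics as a document database but is not a network service, and no
  adapter to a live database is included.
* Counts only: no record-level data release, no authentication, no UI.
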