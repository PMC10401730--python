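"""Exception hierarchy.

Every error raised by the library derives from :class:`CohortBridgeError`
so callers (notably the CLI) can map failures to exit codes in one place.
"""


class CohortBridgeError(Exception):
    """Base class for all cohortbridge errors."""


class SchemaError(CohortBridgeError):
    """A tabular input does not conform to its declared column schema."""


class DuplicateDefinitionError(CohortBridgeError):
    """Two data elements share the same (source, table, variable) key."""


class CodeSpecParseError(CohortBridgeError):
    """An allowable-codes string contains an unparseable fragment."""

    def __init__(self, fragment: str, text: str = ""):
        self.fragment = fragment
        self.text = text
        super().__init__(
            f"unparseable code-spec fragment {fragment!r}"
            + (f" in {text!r}" if text else "")
        )


class FormLookupError(CohortBridgeError):
    """A short form name is absent from the form-name lookup table."""


class CatalogValidationError(CohortBridgeError):
    """A harmonization catalog violates referential integrity."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "catalog validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


class UnmappedValueError(CohortBridgeError):
    """A raw value has no harmonized image and lies outside the domain."""

    def __init__(self, source, concept_id, raw_value):
        self.source = source
        self.concept_id = concept_id
        self.raw_value = raw_value
        super().__init__(
            f"no harmonized value for raw value {raw_value!r} of concept "
            f"{concept_id!r} in source {source!r}"
        )


class UnbinnableValueError(CohortBridgeError):
    """A numeric value falls outside every bin of a bin rule."""


class ValueMappingError(CohortBridgeError):
    """A harmonized code has no raw preimage in a source's value map."""


class OwlParseError(CohortBridgeError):
    """An OWL document could not be parsed."""


class QueryValidationError(CohortBridgeError):
    """Query criteria are malformed or reference unknown concepts/values."""


class RecordImportError(CohortBridgeError):
    """A study-data row could not be imported into the record store."""


class ExecutionError(CohortBridgeError):
    """A backend query references a field unknown to the store's records."""
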