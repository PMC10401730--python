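"""Catalog persistence and the four value-harmonization operators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cohortbridge.errors import (
    CatalogValidationError,
    CohortBridgeError,
    UnbinnableValueError,
    UnmappedValueError,
)
from cohortbridge.mapping_catalog import (
    Catalog,
    UnitRule,
    VariableMapping,
    bin_numeric,
    convert_unit,
    harmonization_profile,
    inverse_unit_rule,
    load_catalog,
    map_value,
    raw_values_for,
    save_catalog,
    widen_range,
)
from cohortbridge.synthetic_cohort import PACKS_BINS, build_planted_catalog

ranges = st.tuples(
    st.floats(-1e6, 1e6, allow_nan=False), st.floats(-1e6, 1e6, allow_nan=False)
).map(lambda t: (min(t), max(t)))


class TestWidenRange:
    def test_education_example(self):
        assert widen_range((0, 36), (0, 20)) == (0, 36)

    def test_partial_overlap_is_hull(self):
        assert widen_range((0, 20), (5, 36)) == (0, 36)

    def test_invalid_range_rejected(self):
        with pytest.raises(CohortBridgeError):
            widen_range((5, 2), (0, 1))

    @given(ranges, ranges, ranges)
    def test_commutative_associative_idempotent_containing(self, a, b, c):
        assert widen_range(a, b) == widen_range(b, a)
        assert widen_range(a, widen_range(b, c)) == widen_range(widen_range(a, b), c)
        assert widen_range(a, a) == a
        lo, hi = widen_range(a, b)
        assert lo <= a[0] and hi >= a[1] and lo <= b[0] and hi >= b[1]


# The six-row recode table for "Banked postmortem CSF": (source, raw,
# raw label, harmonized, harmonized label)
RECODE_TABLE = [
    ("ADNI", "1", "Yes", "1", "Yes"),
    ("ADNI", "2", "No", "0", "No"),
    ("NACC", "0", "No", "0", "No"),
    ("NACC", "1", "Yes", "1", "Yes"),
    ("NACC", "9", "Missing/unknown", "9", "Missing/unknown"),
    ("NACC", "-4", "Not available", "-4", "Not available"),
]


class TestMapValue:
    @pytest.mark.parametrize("source,raw,_,hv,hl", RECODE_TABLE)
    def test_recode_table_rows(self, planted_catalog, source, raw, _, hv, hl):
        assert map_value(source, "banked_postmortem_csf", raw, planted_catalog) == (
            hv,
            hl,
        )

    def test_identity_when_codings_agree(self, planted_catalog):
        assert map_value("NACC", "sex", "1", planted_catalog) == ("1", "Male")

    def test_unmapped_value_errors_with_context(self, planted_catalog):
        with pytest.raises(UnmappedValueError) as exc:
            map_value("ADNI", "banked_postmortem_csf", "7", planted_catalog)
        assert exc.value.source == "ADNI"
        assert exc.value.raw_value == "7"

    def test_inverse_map(self, planted_catalog):
        assert raw_values_for("ADNI", "banked_postmortem_csf", "0", planted_catalog) == ("2",)
        # identity source: no recode rows
        assert raw_values_for("NACC", "sex", "2", planted_catalog) == ("2",)


class TestConvertUnit:
    RULE = UnitRule("v", "ADNI", 1000.0, "divide", "mm3", "cc")

    def test_cc_per_mm3(self):
        assert convert_unit(1000, self.RULE) == 1.0
        assert convert_unit(0, self.RULE) == 0.0
        assert convert_unit(3215.0, self.RULE) == 3.215

    def test_non_finite_rejected(self):
        with pytest.raises(CohortBridgeError):
            convert_unit(float("nan"), self.RULE)

    @given(st.floats(-1e9, 1e9, allow_nan=False))
    def test_inverse_rule_recovers_input(self, x):
        back = convert_unit(convert_unit(x, self.RULE), inverse_unit_rule(self.RULE))
        assert back == pytest.approx(x, rel=1e-12, abs=1e-300)


class TestBinNumeric:
    @pytest.mark.parametrize(
        "value,code",
        [(0, "0"), (2.5, "5"), (0.75, "2"), (0.25, "1"), (1.0, "3"), (1.5, "4"), (2.0, "4"), (10, "5")],
    )
    def test_packs_rule(self, planted_catalog, value, code):
        rule = planted_catalog.bin_rule_for("packs_per_day", "ADNI")
        assert bin_numeric(value, rule) == code

    def test_outside_all_bins(self, planted_catalog):
        rule = planted_catalog.bin_rule_for("packs_per_day", "ADNI")
        with pytest.raises(UnbinnableValueError):
            bin_numeric(11.0, rule)

    def test_agrees_with_brute_force_scan(self, planted_catalog):
        rule = planted_catalog.bin_rule_for("packs_per_day", "ADNI")
        rng = np.random.default_rng(3)
        for v in rng.uniform(0, 10, size=10_000):
            hits = [
                b.code
                for b in PACKS_BINS
                if (v > b.lower or (b.lower_closed and v == b.lower))
                and (v < b.upper or (b.upper_closed and v == b.upper))
            ]
            assert hits == [bin_numeric(v, rule)]

    def test_value_map_total_over_raw_domains(self, planted_catalog):
        # every declared raw categorical code has a harmonized image
        for m in planted_catalog.mappings:
            var = planted_catalog.variable_def(m.source, m.variable_name, m.table_name)
            if var.data_type != "categorical":
                continue
            for code, _ in var.code_spec.categories:
                hv, _ = map_value(m.source, m.concept_id, code, planted_catalog)
                assert hv in planted_catalog.concept(m.concept_id).domain_codes


class TestPersistence:
    def test_save_load_round_trip(self, planted_catalog, tmp_path):
        save_catalog(planted_catalog, tmp_path)
        again = load_catalog(tmp_path)
        assert again.concepts == planted_catalog.concepts
        assert again.variables == planted_catalog.variables
        assert again.mappings == planted_catalog.mappings
        assert sorted(map(str, again.value_maps)) == sorted(
            map(str, planted_catalog.value_maps)
        )
        assert again.unit_rules == planted_catalog.unit_rules
        assert again.bin_rules == planted_catalog.bin_rules

    def test_missing_file_is_named(self, planted_catalog, tmp_path):
        save_catalog(planted_catalog, tmp_path)
        (tmp_path / "mappings.csv").unlink()
        with pytest.raises(CohortBridgeError, match="mappings.csv"):
            load_catalog(tmp_path)

    def test_planted_orphan_mapping_is_reported(self, planted_catalog, tmp_path):
        broken = Catalog(
            concepts=list(planted_catalog.concepts),
            variables=list(planted_catalog.variables),
            mappings=list(planted_catalog.mappings)
            + [VariableMapping("no_such_concept", "NACC", "EDUC")],
            value_maps=list(planted_catalog.value_maps),
            unit_rules=list(planted_catalog.unit_rules),
            bin_rules=list(planted_catalog.bin_rules),
        )
        with pytest.raises(CatalogValidationError, match="no_such_concept"):
            broken.validate()
        save_catalog(broken, tmp_path)
        with pytest.raises(CatalogValidationError, match="no_such_concept"):
            load_catalog(tmp_path)


class TestHarmonizationProfile:
    def test_empty_catalog(self):
        assert tuple(harmonization_profile(Catalog())) == (0, 0, 0)

    def test_planted_catalog_counts(self, planted_catalog):
        # education (range widening) + packs (bin rule) are numeric-harmonized;
        # CSF banking + game difficulty carry non-identity recodes; the
        # hippocampal volume needs the mm3 -> cc unit rule only.
        assert tuple(harmonization_profile(planted_catalog)) == (2, 2, 1)

    def test_single_unit_rule_counts_once(self, planted_catalog):
        assert harmonization_profile(planted_catalog).unit == 1
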