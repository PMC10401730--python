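"""Query translation, statement rendering, execution and summaries."""

import pytest

from cohortbridge.errors import (
    ExecutionError,
    QueryValidationError,
    ValueMappingError,
)
from cohortbridge.query_engine import (
    BackendQuery,
    Filter,
    QueryCriteria,
    RecordStore,
    TermCriterion,
    UnmappedTermNotice,
    execute,
    five_number_summary,
    import_records,
    regroup,
    render_statement,
    search_terms,
    browse_terms,
    term_summary,
    translate,
)


def education_criteria(datasets=("NACC",), lo=5, hi=15):
    return QueryCriteria(
        datasets=tuple(datasets),
        terms=(
            TermCriterion(
                "years_of_education", "numeric", range=(float(lo), float(hi))
            ),
        ),
    )


class TestTranslate:
    def test_numeric_range_passes_through(self, planted_catalog):
        queries, notices = translate(education_criteria(), planted_catalog)
        assert notices == []
        (q,) = queries
        assert q.patient_id_field == "NACCID"
        assert q.filters == (Filter("EDUC", "range", bounds=(5.0, 15.0)),)

    def test_categorical_maps_to_raw_codes_per_dataset(self, planted_catalog):
        crit = QueryCriteria(
            datasets=("NACC", "ADNI"),
            terms=(
                TermCriterion("game_skill_difficulty", "categorical", values=("2",)),
            ),
        )
        queries, _ = translate(crit, planted_catalog)
        by_ds = {q.dataset: q for q in queries}
        assert by_ds["NACC"].filters[0] == Filter("GAMES", "in", codes=("2",))
        assert by_ds["ADNI"].filters[0] == Filter("FAQGAME", "in", codes=("4",))

    def test_empty_terms_match_all(self, planted_catalog):
        queries, _ = translate(
            QueryCriteria(datasets=("NACC", "ADNI")), planted_catalog
        )
        assert all(q.filters == () for q in queries)

    def test_binned_concept_targets_harmonized_column(self, planted_catalog):
        crit = QueryCriteria(
            datasets=("ADNI",),
            terms=(TermCriterion("packs_per_day", "categorical", values=("5",)),),
        )
        queries, _ = translate(crit, planted_catalog)
        assert queries[0].filters[0].field == "SMOKPKS_harmonized"

    def test_unmapped_concept_excludes_dataset_with_notice(self, planted_catalog):
        import copy

        cat = copy.deepcopy(planted_catalog)
        cat.mappings = [
            m for m in cat.mappings if not (m.concept_id == "sex" and m.source == "ADNI")
        ]
        crit = QueryCriteria(
            datasets=("NACC", "ADNI"),
            terms=(TermCriterion("sex", "categorical", values=("1",)),),
        )
        queries, notices = translate(crit, cat)
        assert [q.dataset for q in queries] == ["NACC"]
        assert notices == [UnmappedTermNotice("ADNI", "sex")]

    def test_code_without_raw_preimage_errors(self, planted_catalog):
        crit = QueryCriteria(
            datasets=("ADNI",),
            terms=(
                TermCriterion("banked_postmortem_csf", "categorical", values=("9",)),
            ),
        )
        with pytest.raises(ValueMappingError):
            translate(crit, planted_catalog)

    def test_invalid_criteria_rejected(self, planted_catalog):
        with pytest.raises(QueryValidationError):
            translate(
                QueryCriteria(
                    datasets=("NACC",),
                    terms=(TermCriterion("no_such", "categorical", values=("1",)),),
                ),
                planted_catalog,
            )
        with pytest.raises(QueryValidationError):
            translate(education_criteria(lo=5, hi=99), planted_catalog)

    def test_criteria_json_round_trip(self, planted_catalog):
        doc = {
            "datasets": ["NACC", "ADNI"],
            "terms": [
                {"concept": "marital_status", "values": ["1"]},
                {"concept": "years_of_education", "min": 5, "max": 15},
            ],
        }
        crit = QueryCriteria.from_json(doc)
        assert crit.to_json() == {
            "datasets": ["NACC", "ADNI"],
            "terms": [
                {"concept": "marital_status", "values": ["1"]},
                {"concept": "years_of_education", "min": 5.0, "max": 15.0},
            ],
        }
        translate(crit, planted_catalog)  # validates


class TestRenderStatement:
    def test_worked_education_statement_byte_for_byte(self, planted_catalog):
        queries, _ = translate(education_criteria(), planted_catalog)
        assert render_statement(queries[0]) == (
            'db.records_collection.distinct("NACCID", '
            '{"dataset":"NACC", "EDUC":{"$gte":5, "$lte":15}})'
        )

    def test_match_all_contains_only_dataset_tag(self):
        q = BackendQuery("NACC", "NACCID", ())
        assert render_statement(q) == (
            'db.records_collection.distinct("NACCID", {"dataset":"NACC"})'
        )

    def test_singleton_code_collapses_to_scalar(self):
        q = BackendQuery(
            "NACC", "NACCID", (Filter("GAMES", "in", codes=("2",)),)
        )
        assert render_statement(q) == (
            'db.records_collection.distinct("NACCID", '
            '{"dataset":"NACC", "GAMES":"2"})'
        )

    def test_multi_code_uses_in_operator(self):
        q = BackendQuery(
            "ADNI", "RID", (Filter("FAQGAME", "in", codes=("4", "5")),)
        )
        assert render_statement(q) == (
            'db.records_collection.distinct("RID", '
            '{"dataset":"ADNI", "FAQGAME":{"$in":["4", "5"]}})'
        )


class TestImportRecords:
    def test_unit_rule_divides_at_import(self, planted_catalog):
        store = RecordStore()
        import_records(
            [{"RID": "R1", "ST88SV": "3215"}],
            "ADNI",
            planted_catalog,
            store,
            table_name="IMGVOL",
        )
        (rec,) = store.find(BackendQuery("ADNI", "RID"))
        assert rec["ST88SV"] == 3.215

    def test_bin_rule_adds_harmonized_column(self, planted_catalog):
        store = RecordStore()
        import_records(
            [{"RID": "R1", "SMOKPKS": "2.5"}],
            "ADNI",
            planted_catalog,
            store,
            table_name="MEDHIST",
        )
        (rec,) = store.find(BackendQuery("ADNI", "RID"))
        assert rec["SMOKPKS_harmonized"] == "5"
        assert rec["SMOKPKS"] == 2.5

    def test_sentinel_shadowed_out_of_numeric_field(self, planted_catalog):
        store = RecordStore()
        import_records(
            [{"NACCID": "N1", "EDUC": "99"}], "NACC", planted_catalog, store
        )
        (rec,) = store.find(BackendQuery("NACC", "NACCID"))
        assert "EDUC" not in rec
        assert rec["EDUC__special"] == "99"
        # a sentinel can never satisfy an interval
        queries, _ = translate(
            education_criteria(lo=0, hi=36), planted_catalog
        )
        assert execute(queries, store) == {"NACC": set()}

    def test_plain_row_stored_verbatim(self, planted_catalog):
        store = RecordStore()
        import_records(
            [{"NACCID": "N1", "MARISTAT": "2"}], "NACC", planted_catalog, store
        )
        (rec,) = store.find(BackendQuery("NACC", "NACCID"))
        assert rec["MARISTAT"] == "2"

    def test_missing_patient_identifier(self, planted_catalog):
        from cohortbridge.errors import RecordImportError

        with pytest.raises(RecordImportError):
            import_records(
                [{"EDUC": "12"}], "NACC", planted_catalog, RecordStore()
            )


class TestExecuteRegroup:
    def test_patient_with_two_qualifying_visits_counted_once(self, planted_catalog):
        store = RecordStore()
        rows = [
            {"NACCID": "N1", "EDUC": "10"},
            {"NACCID": "N1", "EDUC": "10"},
            {"NACCID": "N2", "EDUC": "30"},
        ]
        import_records(rows, "NACC", planted_catalog, store)
        queries, _ = translate(education_criteria(), planted_catalog)
        assert execute(queries, store) == {"NACC": {"N1"}}

    def test_filter_matching_nothing(self, planted_catalog):
        store = RecordStore()
        import_records(
            [{"NACCID": "N1", "EDUC": "30"}], "NACC", planted_catalog, store
        )
        queries, _ = translate(education_criteria(), planted_catalog)
        assert execute(queries, store) == {"NACC": set()}

    def test_unknown_field_raises(self, planted_catalog):
        store = RecordStore()
        import_records(
            [{"NACCID": "N1", "EDUC": "10"}], "NACC", planted_catalog, store
        )
        q = BackendQuery("NACC", "NACCID", (Filter("BOGUS", "in", codes=("1",)),))
        with pytest.raises(ExecutionError, match="BOGUS"):
            execute([q], store)

    def test_regroup_totals(self):
        assert regroup({}) == ({}, 0)
        counts, total = regroup({"A": {"p1", "p2"}, "B": {"q1"}})
        assert counts == {"A": 2, "B": 1}
        assert total == 3


class TestTermSummary:
    def test_five_number_summary_tukey(self):
        assert five_number_summary([1, 2, 3, 4, 5]) == (1, 2, 3, 4, 5)
        assert five_number_summary([5, 1, 4, 2, 3]) == (1, 2, 3, 4, 5)

    def test_categorical_counts_conserved(self, small_bundle, small_store):
        dist = term_summary(
            "banked_postmortem_csf", "NACC", small_store, small_bundle.catalog
        )
        n_records = len(small_store.values("NACC", "NPCSFBANK"))
        assert sum(n for _, n in dist.counts) == n_records == dist.n

    def test_numeric_summary_excludes_sentinels(self, small_bundle, small_store):
        dist = term_summary(
            "years_of_education", "NACC", small_store, small_bundle.catalog
        )
        assert dist.kind == "numeric"
        lo, q1, med, q3, hi = dist.summary
        assert 0 <= lo <= q1 <= med <= q3 <= hi <= 36  # 99s shadowed at import

    def test_empty_dataset_yields_empty_distribution(self, planted_catalog):
        dist = term_summary(
            "years_of_education", "NACC", RecordStore(), planted_catalog
        )
        assert dist.n == 0 and dist.summary is None

    def test_unmapped_concept_notice(self, planted_catalog):
        import copy

        cat = copy.deepcopy(planted_catalog)
        cat.mappings = [m for m in cat.mappings if m.concept_id != "sex"]
        out = term_summary("sex", "NACC", RecordStore(), cat)
        assert isinstance(out, UnmappedTermNotice)


class TestTermDiscovery:
    def test_search_finds_marital_status(self, planted_catalog):
        labels = [c.label for c in search_terms("marital", planted_catalog)]
        assert "Marital status" in labels

    def test_exact_match_ranks_first(self, planted_catalog):
        hits = search_terms("sex", planted_catalog)
        assert hits[0].label == "Sex"

    def test_no_match_is_empty(self, planted_catalog):
        assert search_terms("zzz-nothing", planted_catalog) == []

    def test_browse_partitions_all_concepts(self, planted_catalog):
        tree = browse_terms(planted_catalog)
        seen = [c.concept_id for group in tree.values() for c in group]
        assert sorted(seen) == sorted(c.concept_id for c in planted_catalog.concepts)
        assert list(tree) == sorted(tree)
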