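"""Competency-question queries against a summarized synthetic cohort."""

import datetime as dt

import pytest

from conftest import make_document, make_mention
from oncophen import (compose_record, query_criteria, query_event_interval,
                      run_pipeline, schema_availability, segment_record,
                      stratify, summarize_record, triangulate)
from oncophen.model import CodedValue, DocType, PatientRecord, Polarity
from oncophen.query import QueryError, get_attribute


@pytest.fixture(scope="module")
def cohort(summarized_cohort):
    return [record for record, _ in summarized_cohort]


@pytest.fixture(scope="module")
def truths(summarized_cohort):
    return {record.patient_id: truth for record, truth in summarized_cohort}


class TestCriteria:
    def test_empty_cohort(self):
        assert query_criteria([], "C4194") == set()

    def test_unknown_concept_warns_and_returns_empty(self, cohort, caplog):
        with caplog.at_level("WARNING"):
            result = query_criteria(cohort, "C31337555")
        assert result == set() and "unknown concept" in caplog.text

    def test_recurrence_patients_found_by_ground_truth(self, cohort, truths):
        got = query_criteria(cohort, "C7771", level="mention")
        expected = {pid for pid, t in truths.items()
                    if ["Recurrence", "Diagnostic"] in
                    [list(e) for e in t["episodes"]]}
        assert got == expected and got

    def test_negated_only_patients(self):
        """Negated polarity selects patients whose sole mentions of the
        concept are negated."""
        neg_doc = make_document("d1", dt.date(2020, 1, 1), DocType.other, [])
        neg_doc.mentions = [make_mention("C21243", "d1", 1,
                                         polarity=Polarity.negated)]
        mixed_doc = make_document("d1", dt.date(2020, 1, 1), DocType.other, [],
                                  pid="pt2")
        mixed_doc.mentions = [
            make_mention("C21243", "d1", 1, polarity=Polarity.negated,
                         pid="pt2"),
            make_mention("C21243", "d1", 2, pid="pt2")]
        records = [PatientRecord(patient_id="pt1", documents=[neg_doc]),
                   PatientRecord(patient_id="pt2", documents=[mixed_doc])]
        assert query_criteria(records, "C21243", polarity="negated") == {"pt1"}
        assert query_criteria(records, "C21243", polarity="affirmed") == {"pt2"}

    def test_phenotype_level_subset_of_mention_supported(self, cohort):
        """Cross-level consistency: a phenotype-level hit must trace to at
        least one mention of the same concept via provenance."""
        for code in ["C855", "C456", "C12392"]:
            hits = query_criteria(cohort, code, level="phenotype")
            mention_supported = {
                r.patient_id for r in cohort
                if any(m.concept.code == code and m.polarity is Polarity.affirmed
                       for d in r.documents for m in d.mentions)}
            assert hits <= mention_supported


class TestEventInterval:
    def test_chemo_six_weeks_before_death_included(self):
        docs = [
            make_document("d1", dt.date(2020, 1, 1), DocType.radiology,
                          ["C16818", "C25315"]),
            make_document("d2", dt.date(2020, 1, 8), DocType.pathology,
                          ["C4194"]),
            make_document("d3", dt.date(2020, 2, 1), DocType.progress_note,
                          ["C456"]),  # chemotherapy
            make_document("d4", dt.date(2020, 3, 14), DocType.discharge_summary,
                          ["C28554"]),  # death, 42 days later
        ]
        record = run_pipeline(PatientRecord(patient_id="pt1", documents=docs))
        assert query_event_interval([record], "C456", "C28554", 56) == {"pt1"}
        assert query_event_interval([record], "C456", "C28554", 41) == set()

    def test_zero_gap_excludes_distinct_dates(self):
        docs = [make_document("d1", dt.date(2020, 1, 1), DocType.other,
                              ["C456"]),
                make_document("d2", dt.date(2020, 1, 2), DocType.other,
                              ["C28554"])]
        record = compose_record(PatientRecord(patient_id="pt1",
                                              documents=docs))
        assert query_event_interval([record], "C456", "C28554", 0) == set()

    def test_direction_is_respected(self):
        docs = [make_document("d1", dt.date(2020, 1, 1), DocType.other,
                              ["C28554"]),
                make_document("d2", dt.date(2020, 1, 20), DocType.other,
                              ["C456"])]
        record = compose_record(PatientRecord(patient_id="pt1",
                                              documents=docs))
        assert query_event_interval([record], "C456", "C28554", 56) == set()
        assert query_event_interval([record], "C28554", "C456", 56) == {"pt1"}

    @pytest.mark.parametrize("gap", [0, 30, 56, 365])
    def test_matches_pairwise_date_scan(self, cohort, gap):
        got = query_event_interval(cohort, "C456", "C28554", gap)
        expected = set()
        for record in cohort:  # brute-force O(n^2) oracle over events
            events = record.event_index().values()
            chemo = [e.date for e in events if e.concept.code == "C456"
                     and e.polarity is Polarity.affirmed]
            death = [e.date for e in events if e.concept.code == "C28554"
                     and e.polarity is Polarity.affirmed]
            for a in chemo:
                for b in death:
                    if 0 <= (b - a).days <= gap:
                        expected.add(record.patient_id)
        assert got == expected


class TestStratify:
    def test_two_patient_proportion(self, summarized_cohort):
        treated = [r for r, t in summarized_cohort if t["treatments"]]
        untreated = [r for r, t in summarized_cohort if not t["treatments"]]
        pair = [treated[0], untreated[0]]
        frame = stratify(pair, "cancer_type", "treatment:C456")
        row = frame[(frame["split"] == "carcinoma")
                    & (frame["outcome"] == True)]  # noqa: E712
        assert row["count"].item() == 1
        assert row["proportion"].item() == pytest.approx(0.5)

    def test_planted_split_recovered_exactly(self, cohort, truths):
        frame = stratify(cohort, "manifestation:er_status", "treatment:C855")
        for _, row in frame.iterrows():
            expected = sum(
                1 for pid, t in truths.items()
                if t["tumors"][-1 if t["scenario"] != "treated_with_recurrence"
                               else -2]["manifestations"]
                .get("er_status") == row["split"]
                and ("C855" in t["treatments"]) == row["outcome"])
            # compare against a direct scan of generator ground truth
            truth_counts = 0
            for pid, t in truths.items():
                er = next((tu["manifestations"].get("er_status")
                           for tu in t["tumors"]
                           if tu["episode_type"] == "PrimaryTumor"), None)
                if er == row["split"] and \
                        (("C855" in t["treatments"]) == row["outcome"]):
                    truth_counts += 1
            assert row["count"] == truth_counts == expected

    def test_empty_stratum_rows_retained(self, cohort):
        frame = stratify(cohort, "manifestation:er_status",
                         "treatment:C855")
        combos = set(zip(frame["split"], frame["outcome"]))
        strata = set(frame["split"])
        outcomes = set(frame["outcome"])
        assert combos == {(s, o) for s in strata for o in outcomes}

    def test_absent_attribute_warns_empty(self, cohort, caplog):
        with caplog.at_level("WARNING"):
            frame = stratify(cohort, "manifestation:ca125_status",
                             "treatment:C855")
        assert frame.empty


class TestTriangulate:
    def _records(self):
        progress_only = PatientRecord(patient_id="pt1", documents=[
            make_document("d1", dt.date(2020, 1, 1), DocType.progress_note,
                          ["C855"])])
        both = PatientRecord(patient_id="pt2", documents=[
            make_document("d1", dt.date(2020, 1, 1), DocType.progress_note,
                          ["C855"], pid="pt2"),
            make_document("d2", dt.date(2020, 1, 2), DocType.other,
                          ["C855"], pid="pt2")])
        return [compose_record(r) for r in (progress_only, both)]

    def test_ordered_but_not_administered(self):
        records = self._records()
        assert triangulate(records, "progress_note", "other",
                           "C855") == {"pt1"}

    def test_present_in_both_excluded(self):
        records = self._records()
        assert "pt2" not in triangulate(records, "progress_note", "other",
                                        "C855")

    def test_matches_set_difference_oracle(self, cohort):
        for code in ["C456", "C855", "C4194"]:
            got = triangulate(cohort, "progress_note", "pathology", code)
            expected = set()
            for record in cohort:  # per-doc-type assertion sets
                by_kind: dict[str, set[str]] = {}
                for e in record.event_index().values():
                    if e.polarity is Polarity.affirmed:
                        by_kind.setdefault(e.concept.code, set()).add(
                            e.doc_type.value)
                kinds = by_kind.get(code, set())
                if "progress_note" in kinds and "pathology" not in kinds:
                    expected.add(record.patient_id)
            assert got == expected


class TestSchemaAvailability:
    def test_death_date_for_known_subset(self, cohort, truths):
        got = schema_availability(cohort, "date_of_death")
        expected = {pid for pid, t in truths.items() if t["date_of_death"]}
        assert got == expected

    def test_absent_everywhere(self, cohort):
        only_alive = [r for r in cohort
                      if get_attribute(r, "date_of_death") is None]
        assert schema_availability(only_alive, "date_of_death") == set()

    def test_invalid_value_excluded_and_reported(self, cohort, caplog):
        record = next(r for r in cohort
                      if get_attribute(r, "date_of_death"))
        record = PatientRecord.from_dict(record.to_dict())
        record.summary.patient_attributes["date_of_death"] = "not-a-date"
        with caplog.at_level("WARNING"):
            got = schema_availability([record], "date_of_death")
        assert got == set() and "invalid" in caplog.text

    def test_unknown_attribute_raises(self, cohort):
        with pytest.raises(QueryError):
            schema_availability(cohort, "shoe_size")


def test_queries_are_pure(cohort):
    before = [r.to_dict() for r in cohort]
    query_criteria(cohort, "C7771")
    query_event_interval(cohort, "C456", "C28554", 56)
    stratify(cohort, "manifestation:er_status", "treatment:C855")
    triangulate(cohort, "progress_note", "pathology", "C456")
    schema_availability(cohort, "date_of_death")
    assert [r.to_dict() for r in cohort] == before
    assert query_criteria(cohort, "C7771") == query_criteria(cohort, "C7771")
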