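"""Rule loading, precedence, temporal phenotype change, tumor assignment."""

import datetime as dt
import itertools

import pytest

from conftest import make_document, zero_noise_config
from oncophen import (compose_record, default_ruleset, evaluate_rule,
                      generate, load_rules, run_pipeline, segment_record,
                      summarize_record)
from oncophen.model import (CodedValue, DocType, PatientRecord, Polarity)
from oncophen.rules import RuleError, Ruleset, SummarizationRule, assign_tumors


def _record(docs) -> PatientRecord:
    record = PatientRecord(patient_id="pt1", documents=docs)
    return summarize_record(segment_record(compose_record(record)))


def _workup_docs(*, her2_docs):
    """Diagnostic workup (d1 imaging, d2 dx) plus HER2 assay documents.

    ``her2_docs`` is a list of (day, code, value) for the assay events.
    """
    docs = [
        make_document("d1", dt.date(2020, 1, 1), DocType.radiology,
                      ["C16818", "C25315"]),
        make_document("d2", dt.date(2020, 1, 10), DocType.pathology,
                      ["C4194"]),
    ]
    for i, (day, code, value) in enumerate(her2_docs):
        docs.append(make_document(
            f"dh{i}", dt.date(2020, 1, day), DocType.pathology,
            [(code, CodedValue(code=value))]))
    return docs


def _her2(record) -> str:
    (cancer,) = record.summary.cancers
    (tumor,) = cancer.tumors
    values = {}
    for phen in tumor.phenotypes:
        for a in phen.assertions:
            if a.attribute == "manifestation:her2_status":
                values[phen.valid_period.start] = a.value["code"]
    return values[max(values)]


class TestLoadRules:
    def test_default_ruleset_has_receptor_rules(self):
        ruleset = default_ruleset()
        receptor = [r for r in ruleset
                    if r.action.attribute == "manifestation:her2_status"]
        assert len(receptor) == 2
        fish = next(r for r in receptor if r.condition.method == "FISH")
        ihc = next(r for r in receptor if r.condition.method == "IHC")
        assert fish.priority < ihc.priority

    def test_empty_rule_file(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("rules: []\n", encoding="utf-8")
        assert len(load_rules(path)) == 0

    def test_duplicate_priorities_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("""
rules:
  - id: a
    priority: 5
    scope: cancer
    condition: {concepts: [C4194]}
    action: {attribute: cancer_type, value: {from: constant, value: carcinoma}}
  - id: b
    priority: 5
    scope: cancer
    condition: {concepts: [C4194]}
    action: {attribute: histologic_type, value: {from: constant, value: ductal}}
""", encoding="utf-8")
        with pytest.raises(RuleError, match="duplicate"):
            load_rules(path)

    def test_unknown_attribute_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("""
rules:
  - id: a
    priority: 5
    scope: cancer
    condition: {concepts: [C4194]}
    action: {attribute: foo, value: {from: constant, value: x}}
""", encoding="utf-8")
        with pytest.raises(RuleError, match="foo"):
            load_rules(path)

    def test_unknown_concept_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("""
rules:
  - id: a
    priority: 5
    scope: cancer
    condition: {concepts: [C424242424]}
    action: {attribute: cancer_type, value: {from: constant, value: carcinoma}}
""", encoding="utf-8")
        with pytest.raises(RuleError, match="C424242424"):
            load_rules(path)


class TestAssayPrecedence:
    """The FISH result outranks IHC, whatever the temporal order."""

    def test_same_document_conflict(self):
        record = _record(_workup_docs(her2_docs=[
            (10, "C900212", "positive"), (10, "C900213", "negative")]))
        assert _her2(record) == "negative"

    def test_ihc_then_fish(self):
        record = _record(_workup_docs(her2_docs=[
            (12, "C900212", "positive"), (20, "C900213", "negative")]))
        assert _her2(record) == "negative"

    def test_fish_then_ihc(self):
        record = _record(_workup_docs(her2_docs=[
            (12, "C900213", "negative"), (20, "C900212", "positive")]))
        assert _her2(record) == "negative"
        # and the suppressed IHC result is auditable as a conflict
        (cancer,) = record.summary.cancers
        conflicts = [c for phen in cancer.tumors[0].phenotypes
                     for a in phen.assertions
                     if a.attribute == "manifestation:her2_status"
                     for c in a.conflicts]
        assert any(c["rule_id"] == "her2-by-ihc" for c in conflicts)

    def test_precedence_matches_brute_force_over_rule_orders(self):
        """For same-period competitors the winner is always the rule with
        the smaller priority number, independent of evaluation order."""
        record_docs = _workup_docs(her2_docs=[
            (10, "C900212", "positive"), (10, "C900213", "negative")])
        base = default_ruleset()
        her2_rules = [r for r in base
                      if r.action.attribute == "manifestation:her2_status"]
        other = [r for r in base
                 if r.action.attribute != "manifestation:her2_status"]
        for order in itertools.permutations(her2_rules):
            ruleset = Ruleset([r.model_copy(deep=True)
                               for r in list(order) + other])
            record = PatientRecord(patient_id="pt1",
                                   documents=[d.model_copy(deep=True)
                                              for d in record_docs])
            segment_record(compose_record(record))
            summarize_record(record, ruleset)
            expected_rule = min(her2_rules, key=lambda r: r.priority)
            expected = "negative" if expected_rule.id == "her2-by-fish" \
                else "positive"
            assert _her2(record) == expected


class TestTemporalChange:
    def test_er_change_yields_two_disjoint_phenotype_records(self):
        docs = [
            make_document("d1", dt.date(2020, 1, 1), DocType.radiology,
                          ["C16818", "C25315"]),
            make_document("d2", dt.date(2020, 1, 10), DocType.pathology,
                          ["C4194",
                           ("C900210", CodedValue(code="positive"))]),
            make_document("d3", dt.date(2021, 6, 1), DocType.pathology,
                          [("C900210", CodedValue(code="negative"))]),
        ]
        record = _record(docs)
        (cancer,) = record.summary.cancers
        (tumor,) = cancer.tumors
        er = [(phen.valid_period, a.value["code"])
              for phen in tumor.phenotypes for a in phen.assertions
              if a.attribute == "manifestation:er_status"]
        assert [code for _, code in er] == ["positive", "negative"]
        (p1, _), (p2, _) = er
        assert not p1.overlaps(p2)
        assert p1.end == p2.start == dt.date(2021, 6, 1)


class TestEngineInvariants:
    def test_negated_events_never_assert(self):
        docs = [
            make_document("d1", dt.date(2020, 1, 1), DocType.radiology,
                          ["C16818", "C25315"]),
            make_document("d2", dt.date(2020, 1, 10), DocType.pathology,
                          ["C4194"]),
        ]
        neg = make_document("d3", dt.date(2020, 1, 15), DocType.pathology, [])
        from conftest import make_mention
        neg.mentions = [make_mention("C900210", "d3", 1,
                                     value=CodedValue(code="positive"),
                                     polarity=Polarity.negated)]
        record = _record(docs + [neg])
        (cancer,) = record.summary.cancers
        for phen in cancer.tumors[0].phenotypes:
            assert all(a.attribute != "manifestation:er_status"
                       for a in phen.assertions)

    def test_empty_course_yields_no_cancers(self):
        record = PatientRecord(patient_id="pt1", documents=[])
        summarize_record(segment_record(compose_record(record)))
        assert record.summary.cancers == []

    def test_idempotence(self):
        patient = generate(zero_noise_config(
            1, "treated_with_recurrence", 1, death_rate=1.0))[0]
        record = run_pipeline(patient.record())
        once = record.to_dict()
        summarize_record(record)
        assert record.to_dict() == once

    @pytest.mark.parametrize("seed", [0, 3])
    def test_evaluate_rule_matches_exhaustive_scan(self, seed):
        patient = generate(zero_noise_config(
            seed, "treated_with_recurrence", 1, conflict_rate=1.0))[0]
        record = segment_record(compose_record(patient.record()))
        events = record.event_index()
        ctx_ids = {eid for ep in record.course.leaf_episodes()
                   for eid in ep.events}
        for rule in default_ruleset():
            got = [e.id for e in evaluate_rule(rule, record.course, events)]
            expected = []
            for e in events.values():
                cond = rule.condition
                ok = (e.concept.code in set(cond.concepts)
                      and e.polarity is cond.polarity
                      and (cond.resource_kind is None
                           or e.resource_kind is cond.resource_kind)
                      and (cond.method is None or e.method == cond.method))
                if cond.episode_type is not None:
                    ok = ok and e.id in ctx_ids
                if ok:
                    expected.append(e.id)
            assert sorted(got) == sorted(expected)

    def test_rule_without_match_gives_empty_set(self):
        patient = generate(zero_noise_config(0, "primary_only", 1))[0]
        record = segment_record(compose_record(patient.record()))
        rule = SummarizationRule(
            id="x", priority=99, scope="cancer",
            condition={"concepts": ["C71721"]},  # olaparib: never generated
            action={"attribute": "cancer_type",
                    "value": {"from": "constant", "value": "carcinoma"}})
        assert evaluate_rule(rule, record.course, record.event_index()) == []


class TestAssignTumors:
    def test_worked_example_partition(self, worked_example_record):
        record = segment_record(compose_record(worked_example_record))
        cancer, _, _ = assign_tumors(record.course, record.event_index(),
                                     "pt1")
        kinds = sorted(t.episode_type.value for t in cancer.tumors)
        assert kinds == ["MetastaticTumor", "PrimaryTumor"]

    def test_primary_only_gives_single_tumor(self):
        patient = generate(zero_noise_config(0, "primary_only", 1))[0]
        record = segment_record(compose_record(patient.record()))
        cancer, _, _ = assign_tumors(record.course, record.event_index(),
                                     patient.patient_id)
        assert len(cancer.tumors) == 1
        assert cancer.tumors[0].body_site.code == "C12971"

    @pytest.mark.parametrize("n_sites", [1, 2, 3])
    def test_tumor_count_equals_type_site_pairs(self, n_sites):
        """Counting oracle: one tumor per distinct (episode type, site)."""
        patient = generate(zero_noise_config(
            5, "primary_then_metastasis", 1, n_met_sites=n_sites))[0]
        record = segment_record(compose_record(patient.record()))
        events = record.event_index()
        cancer, _, _ = assign_tumors(record.course, events,
                                     patient.patient_id)
        pairs = set()
        for ep in record.course.leaf_episodes():
            sites = {events[i].concept.code for i in ep.events
                     if events[i].resource_kind.value == "BodySite"} or {None}
            for s in sites:
                pairs.add((ep.episode_type.value, s))
        assert len(cancer.tumors) == len(pairs)
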