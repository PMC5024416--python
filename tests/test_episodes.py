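"""Episode segmentation and the disease-course timeline."""

import datetime as dt

import pytest

from conftest import make_document, zero_noise_config
from oncophen import (compose_record, default_episode_config, generate,
                      segment, segment_record)
from oncophen.episodes import EpisodeConfig, EpisodeConfigError, episode_timeline
from oncophen.model import DocType, EpisodeType, PatientRecord, Phase


class TestWorkedExample:
    def test_two_episodes_with_expected_coverage(self, worked_example_record):
        """Documents 1-3 form the primary diagnostic episode; document 4
        the metastatic one."""
        record = segment_record(compose_record(worked_example_record))
        episodes = list(record.course.all_episodes())
        assert [(e.episode_type, e.phase) for e in episodes] == [
            (EpisodeType.PrimaryTumor, Phase.Diagnostic),
            (EpisodeType.MetastaticTumor, Phase.Diagnostic)]
        primary, metastatic = episodes
        events = record.event_index()
        assert {events[i].document_id for i in primary.events} == {"d1", "d2", "d3"}
        assert {events[i].document_id for i in metastatic.events} == {"d4"}
        assert (primary.start_date, primary.end_date) == (
            dt.date(2011, 3, 1), dt.date(2011, 3, 20))
        assert metastatic.start_date == metastatic.end_date == dt.date(2011, 9, 5)
        # events carry the narrative: all eight workup events in the primary
        assert {events[i].concept.code for i in primary.events} == {
            "C16818", "C25315", "C15361", "C4194", "C48885", "C48884",
            "C48883", "C900220"}
        assert {events[i].concept.code for i in metastatic.events} == {
            "C16809", "C120180", "C36263"}

    def test_timeline_in_document_date_order(self, worked_example_record):
        record = segment_record(compose_record(worked_example_record))
        rows = episode_timeline(record.course)
        assert [(e.episode_type.value, e.phase.value) for e, _, _ in rows] == [
            ("PrimaryTumor", "Diagnostic"), ("MetastaticTumor", "Diagnostic")]


def test_zero_compositions_give_empty_course():
    course, edges = segment([], default_episode_config(), "pt1")
    assert course.episodes == [] and edges == []
    assert course.unclassified == []


def test_boundary_events_recorded(worked_example_record):
    record = segment_record(compose_record(worked_example_record))
    events = record.event_index()
    primary = record.course.episodes[0]
    assert events[primary.start_event].concept.code == "C16818"  # mammogram
    assert events[primary.end_event].concept.code == "C4194"     # the dx


def test_single_episode_timeline_is_singleton():
    patient = generate(zero_noise_config(2, "primary_only", 1,
                                         extra_notes=(0, 0)))[0]
    record = segment_record(compose_record(patient.record()))
    rows = episode_timeline(record.course)
    assert len(rows) == 1
    assert rows[0][0].episode_type is EpisodeType.PrimaryTumor


class TestHierarchy:
    @pytest.fixture
    def treated_record(self) -> PatientRecord:
        patient = generate(zero_noise_config(4, "treated_with_recurrence",
                                             1))[0]
        return segment_record(compose_record(patient.record()))

    def test_parent_wraps_multiple_phases(self, treated_record):
        course = treated_record.course
        parents = [e for e in course.episodes if e.child_episodes]
        assert len(parents) == 1
        parent = parents[0]
        assert parent.episode_type is EpisodeType.PrimaryTumor
        assert parent.phase is None
        assert [c.phase for c in parent.child_episodes] == [
            Phase.Diagnostic, Phase.Treatment]

    def test_children_contained_in_parent(self, treated_record):
        for ep in treated_record.course.episodes:
            for child in ep.child_episodes:
                assert ep.start_date <= child.start_date
                assert child.end_date <= ep.end_date

    def test_timeline_parents_before_children(self, treated_record):
        rows = episode_timeline(treated_record.course)
        index = {ep.id: i for i, (ep, _, _) in enumerate(rows)}
        # brute-force interval-sort oracle: sorted by start, and every
        # parent precedes each of its children
        starts = [s for _, s, _ in rows]
        assert starts == sorted(starts)
        for ep, _, _ in rows:
            for child in ep.child_episodes:
                assert index[ep.id] < index[child.id]

    def test_every_episode_has_events_and_bounds(self, treated_record):
        for ep in treated_record.course.all_episodes():
            assert ep.events
            assert ep.start_date <= ep.end_date


def test_unclassified_bucket_retains_unmatched_events():
    patient = generate(zero_noise_config(6, "primary_only", 1,
                                         extra_notes=(1, 1)))[0]
    record = segment_record(compose_record(patient.record()))
    events = record.event_index()
    codes = {events[i].concept.code for i in record.course.unclassified}
    assert codes & {"C3117", "C26747"}  # the comorbidity note events


def test_determinism():
    patient = generate(zero_noise_config(8, "treated_with_recurrence", 1))[0]
    a = segment_record(compose_record(patient.record()))
    b = segment_record(compose_record(patient.record()))
    assert a.course == b.course


class TestConfigValidation:
    def test_unknown_concept_rejected_at_load(self):
        data = {"episode_types": {"PrimaryTumor": {"phases": {"Diagnostic": {
            "start_triggers": ["C99999999"], "end_triggers": ["C4194"],
            "members": ["C4194"]}}}}}
        with pytest.raises(EpisodeConfigError, match="C99999999"):
            EpisodeConfig(data)

    def test_empty_triggers_rejected(self):
        data = {"episode_types": {"PrimaryTumor": {"phases": {"Diagnostic": {
            "start_triggers": [], "end_triggers": ["C4194"],
            "members": ["C4194"]}}}}}
        with pytest.raises(EpisodeConfigError, match="non-empty"):
            EpisodeConfig(data)

    def test_unknown_phase_rejected(self):
        data = {"episode_types": {"PrimaryTumor": {"phases": {"Staging": {
            "start_triggers": ["C25315"], "end_triggers": ["C4194"],
            "members": ["C4194"]}}}}}
        with pytest.raises(EpisodeConfigError, match="Staging"):
            EpisodeConfig(data)

    def test_default_config_round_trips_through_yaml(self, tmp_path):
        from oncophen import load_episode_config
        from importlib import resources
        text = resources.files("oncophen.data").joinpath(
            "episode_config.yaml").read_text(encoding="utf-8")
        path = tmp_path / "episodes.yaml"
        path.write_text(text, encoding="utf-8")
        config = load_episode_config(path)
        assert set(config.episode_types()) == {
            EpisodeType.MetastaticTumor, EpisodeType.PrimaryTumor,
            EpisodeType.Recurrence}
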