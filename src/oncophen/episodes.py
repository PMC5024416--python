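"""Segmenting event details into typed, phased episodes (Level 2 → 3).

Episode boundaries are declarative: for each (episode type, phase) the
configuration names a start-trigger set, an end-trigger set, and a member
set, as concept codes or lexicon categories. The default configuration
opens a Diagnostic phase at the first affirmed sign/symptom/imaging-finding
trigger and closes it at the first cancer-diagnosis Condition; a Treatment
phase opens at the first therapeutic medication or procedure after
diagnosis and closes at the last such event; FollowUp spans post-treatment
surveillance. A MetastaticTumor episode opens when a metastasis-coded
finding appears.

Temporal anchoring is coarse: an event's time is its document date, and
mentions related BEFORE their document are flagged unbounded-before and
excluded from boundary anchoring (they land in the unclassified bucket).
Episodes of different types may overlap; an event matching two episodes is
assigned to both and flagged multi-assigned. Ties between simultaneous
trigger candidates break on earliest document id, keeping segmentation
deterministic.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import yaml

from .lexicon import Lexicon, LexiconError, default_lexicon
from .model import (Composition, DiseaseCourse, Episode, EpisodeType,
                    EventDetail, PatientRecord, Phase, Polarity)

__all__ = ["EpisodeConfigError", "PhaseConfig", "EpisodeConfig",
           "load_episode_config", "default_episode_config", "segment",
           "segment_record", "episode_timeline"]

_PHASE_ORDER = [Phase.Diagnostic, Phase.Treatment, Phase.FollowUp]


class EpisodeConfigError(ValueError):
    """Raised for invalid episode configuration files."""


class PhaseConfig:
    """Resolved trigger/member concept sets for one (type, phase)."""

    def __init__(self, episode_type: EpisodeType, phase: Phase,
                 raw: dict, lexicon: Lexicon) -> None:
        self.episode_type = episode_type
        self.phase = phase
        try:
            self.start_triggers = frozenset(
                lexicon.expand(raw.get("start_triggers", [])))
            self.end_triggers = frozenset(
                lexicon.expand(raw.get("end_triggers", [])))
            self.members = frozenset(lexicon.expand(raw.get("members", [])))
        except LexiconError as exc:
            raise EpisodeConfigError(
                f"{episode_type.value}/{phase.value}: {exc}") from exc
        if not self.start_triggers or not self.end_triggers:
            raise EpisodeConfigError(
                f"{episode_type.value}/{phase.value}: trigger sets must be "
                f"non-empty")
        self.end_mode = raw.get("end_mode", "first")
        if self.end_mode not in ("first", "last"):
            raise EpisodeConfigError(
                f"{episode_type.value}/{phase.value}: end_mode must be "
                f"'first' or 'last'")
        req = raw.get("requires_phase")
        self.requires_phase = Phase(req) if req else None


class EpisodeConfig:
    """Validated episode-boundary configuration for all episode types."""

    def __init__(self, data: dict, lexicon: Optional[Lexicon] = None) -> None:
        lexicon = lexicon or default_lexicon()
        self.phases: dict[tuple[EpisodeType, Phase], PhaseConfig] = {}
        types = data.get("episode_types")
        if not types:
            raise EpisodeConfigError("configuration defines no episode types")
        for type_name, type_raw in types.items():
            try:
                etype = EpisodeType(type_name)
            except ValueError:
                raise EpisodeConfigError(
                    f"unknown episode type {type_name!r}") from None
            phases = (type_raw or {}).get("phases") or {}
            if not phases:
                raise EpisodeConfigError(
                    f"{type_name}: episode type defines no phases")
            for phase_name, phase_raw in phases.items():
                try:
                    phase = Phase(phase_name)
                except ValueError:
                    raise EpisodeConfigError(
                        f"{type_name}: unknown phase {phase_name!r}") from None
                self.phases[(etype, phase)] = PhaseConfig(
                    etype, phase, phase_raw or {}, lexicon)
        for pc in self.phases.values():
            if (pc.requires_phase
                    and (pc.episode_type, pc.requires_phase) not in self.phases):
                raise EpisodeConfigError(
                    f"{pc.episode_type.value}/{pc.phase.value}: required "
                    f"phase {pc.requires_phase.value} is not configured")

    def episode_types(self) -> list[EpisodeType]:
        return sorted({et for et, _ in self.phases}, key=lambda e: e.value)

    def phases_of(self, etype: EpisodeType) -> list[PhaseConfig]:
        return [self.phases[(etype, p)] for p in _PHASE_ORDER
                if (etype, p) in self.phases]


def load_episode_config(path, lexicon: Optional[Lexicon] = None) -> EpisodeConfig:
    with open(path, encoding="utf-8") as fh:
        return EpisodeConfig(yaml.safe_load(fh) or {}, lexicon)


def default_episode_config(lexicon: Optional[Lexicon] = None) -> EpisodeConfig:
    ref = resources.files("oncophen.data").joinpath("episode_config.yaml")
    with ref.open(encoding="utf-8") as fh:
        return EpisodeConfig(yaml.safe_load(fh), lexicon)


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------

def _event_order(e: EventDetail) -> tuple:
    return (e.date, e.document_id, e.id)


def _build_phase_episode(patient_id: str, pc: PhaseConfig,
                         events: list[EventDetail],
                         not_before) -> Optional[Episode]:
    anchored = [e for e in events if not e.before_document]
    start_candidates = [
        e for e in anchored
        if e.concept.code in pc.start_triggers
        and e.polarity is Polarity.affirmed
        and (not_before is None or e.date >= not_before)]
    if not start_candidates:
        return None
    start_ev = min(start_candidates, key=_event_order)
    end_candidates = [
        e for e in anchored
        if e.concept.code in pc.end_triggers
        and e.polarity is Polarity.affirmed and e.date >= start_ev.date]
    if end_candidates:
        end_ev = (min if pc.end_mode == "first" else max)(
            end_candidates, key=_event_order)
    else:
        # no closing trigger: close at the last member event instead so the
        # episode still carries both boundary dates.
        member_tail = [e for e in anchored
                       if e.concept.code in pc.members
                       and e.date >= start_ev.date]
        end_ev = max(member_tail, key=_event_order) if member_tail else start_ev
    member_events = sorted(
        (e for e in anchored
         if e.concept.code in pc.members
         and start_ev.date <= e.date <= end_ev.date),
        key=_event_order)
    if not member_events:
        return None
    return Episode(
        id=f"epi:{patient_id}:{pc.episode_type.value}:{pc.phase.value}",
        episode_type=pc.episode_type, phase=pc.phase,
        start_date=start_ev.date, end_date=end_ev.date,
        start_event=start_ev.id, end_event=end_ev.id,
        events=[e.id for e in member_events])


def segment(compositions: list[Composition], config: EpisodeConfig,
            patient_id: str) -> tuple[DiseaseCourse, list[tuple[str, str]]]:
    """Classify event details into episodes and order the disease course.

    Returns the course plus ``(episode_id, event_id)`` and
    ``(parent_id, child_id)`` derivation edges. Events matching no episode
    are retained in the course's unclassified bucket; events claimed by
    more than one episode are flagged multi-assigned.
    """
    events = sorted((e for c in compositions for e in c.event_details),
                    key=lambda e: (e.date, e.document_id, e.id))
    top_level: list[Episode] = []
    edges: list[tuple[str, str]] = []
    assignment: dict[str, int] = {}

    for etype in config.episode_types():
        leaves: list[Episode] = []
        for pc in config.phases_of(etype):
            if pc.requires_phase is not None:
                prior = next((ep for ep in leaves
                              if ep.phase is pc.requires_phase), None)
                if prior is None:
                    continue
                not_before = prior.end_date
            else:
                not_before = None
            ep = _build_phase_episode(patient_id, pc, events, not_before)
            if ep is not None:
                leaves.append(ep)
        for ep in leaves:
            for eid in ep.events:
                assignment[eid] = assignment.get(eid, 0) + 1
            edges.extend((ep.id, eid) for eid in ep.events)
        if len(leaves) >= 2:
            leaves.sort(key=lambda e: (e.start_date, e.end_date, e.id))
            parent = Episode(
                id=f"epi:{patient_id}:{etype.value}",
                episode_type=etype, phase=None,
                start_date=leaves[0].start_date,
                end_date=max(e.end_date for e in leaves),
                start_event=leaves[0].start_event,
                end_event=max(leaves, key=lambda e: e.end_date).end_event,
                child_episodes=leaves,
                events=sorted({eid for e in leaves for eid in e.events}))
            edges.extend((parent.id, child.id) for child in leaves)
            top_level.append(parent)
        elif leaves:
            top_level.append(leaves[0])

    top_level.sort(key=lambda e: (e.start_date, e.end_date, e.id))
    course = DiseaseCourse(
        patient_id=patient_id,
        episodes=top_level,
        unclassified=sorted(e.id for e in events if e.id not in assignment),
        multi_assigned=sorted(eid for eid, n in assignment.items() if n > 1))
    return course, edges


def segment_record(record: PatientRecord,
                   config: Optional[EpisodeConfig] = None) -> PatientRecord:
    """Segment a composed record in place, recording provenance edges."""
    if record.compositions is None:
        raise ValueError("record has no compositions; run compose_record first")
    config = config or default_episode_config()
    course, edges = segment(record.compositions, config, record.patient_id)
    for derived, source in edges:
        record.provenance.add_edge(derived, source)
    record.course = course
    return record


def episode_timeline(course: DiseaseCourse) -> list[tuple[Episode, object, object]]:
    """Flatten the course to (episode, start, end), parents before children.

    Sorted by start date then end date; a parent episode always precedes
    its children (depth breaks the tie a child sharing the parent's start
    would otherwise win by its earlier end date).
    """
    rows: list[tuple[int, Episode]] = []

    def _walk(ep: Episode, depth: int) -> None:
        rows.append((depth, ep))
        for child in ep.child_episodes:
            _walk(child, depth + 1)

    for ep in course.episodes:
        _walk(ep, 0)
    rows.sort(key=lambda r: (r[1].start_date, r[0], r[1].end_date, r[1].id))
    return [(ep, ep.start_date, ep.end_date) for _, ep in rows]
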