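"""Prioritized declarative abstraction rules (Level 3 → 4).

A summarization rule pairs a conjunctive condition pattern over event
details (concept codes or lexicon categories, resource kind, polarity,
assay-method qualifier, optional episode context) with an action that
asserts one phenotype attribute or manifestation on a cancer- or
tumor-scoped entity. Rules are forward-applied in priority order (lower
number = higher precedence); there is no arbitrary code in rule files.

Precedence and temporal supersession interact as follows, per (entity,
attribute): a later assertion supersedes the current one — closing its
valid period and opening a new one — only when its priority number is no
worse, so an equal-priority later value records genuine phenotype change
(ER positive acquiring ER negative yields two time-scoped phenotype
records), while a weaker-method result can never displace a stronger one
(an IHC value never overrides a FISH value, in either temporal order).
Same-date conflicts resolve by priority, then by most recent document,
then document id; every suppressed competitor is kept as a conflict
annotation on the winning assertion. Negated events never produce
affirmative assertions.
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources
from typing import Any, Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError

from .lexicon import Lexicon, LexiconError, default_lexicon
from .model import (Assertion, Cancer, CancerPhenotype, CodedValue,
                    ConceptRef, DiseaseCourse, EpisodeType, EventDetail,
                    Manifestation, ManifestationKind, Outcome, PatientRecord,
                    PatientSummary, Period, Phase, Polarity, QuantityValue,
                    ResourceKind, SequenceVariation, Treatment, Tumor,
                    TumorPhenotype, Value, VariationScope)

__all__ = ["RuleError", "RuleCondition", "RuleAction", "SummarizationRule",
           "Ruleset", "load_rules", "default_ruleset", "evaluate_rule",
           "assign_tumors", "summarize", "summarize_record"]

_CANCER_ATTRS = {"cancer_type", "histologic_type", "tumor_extent",
                 "cancer_stage", "t_classification", "n_classification",
                 "m_classification"}
_TUMOR_ATTRS = {"cancer_type", "histologic_type", "tumor_extent"}

_TREATMENT_CATEGORIES = ("therapeutic_procedure", "chemotherapy",
                         "targeted_therapy", "hormonal_therapy",
                         "parp_inhibitor")
#: attribute name of a germline test mapped to its gene symbol; a positive
#: result materializes a germline sequence variation.
_GERMLINE_TESTS = {"brca1_status": "BRCA1", "palb2_status": "PALB2"}


class RuleError(ValueError):
    """Raised for invalid rule files."""


class RuleCondition(BaseModel):
    """Conjunctive pattern over event details."""

    concepts: list[str]
    resource_kind: Optional[ResourceKind] = None
    polarity: Polarity = Polarity.affirmed
    method: Optional[str] = None
    episode_type: Optional[EpisodeType] = None
    phase: Optional[Phase] = None


class RuleAction(BaseModel):
    """Target attribute and value expression."""

    attribute: str
    manifestation_kind: Optional[ManifestationKind] = None
    value: dict[str, Any]


class SummarizationRule(BaseModel):
    id: str
    priority: int
    scope: str  # "cancer" | "tumor"
    condition: RuleCondition
    action: RuleAction


class Ruleset:
    """A validated, priority-sorted collection of summarization rules."""

    def __init__(self, rules: list[SummarizationRule],
                 lexicon: Optional[Lexicon] = None) -> None:
        lexicon = lexicon or default_lexicon()
        priorities = [r.priority for r in rules]
        if len(priorities) != len(set(priorities)):
            dup = sorted({p for p in priorities if priorities.count(p) > 1})
            raise RuleError(f"duplicate rule priorities: {dup}")
        for rule in rules:
            if rule.scope not in ("cancer", "tumor"):
                raise RuleError(f"{rule.id}: scope must be cancer or tumor")
            attr = rule.action.attribute
            if attr.startswith("manifestation:"):
                if rule.action.manifestation_kind is None:
                    raise RuleError(f"{rule.id}: manifestation rules must "
                                    f"declare manifestation_kind")
            else:
                allowed = _CANCER_ATTRS if rule.scope == "cancer" else _TUMOR_ATTRS
                if attr not in allowed:
                    raise RuleError(f"{rule.id}: unknown target attribute "
                                    f"{attr!r} for scope {rule.scope}")
            if rule.action.value.get("from") not in ("event_value", "map",
                                                     "constant"):
                raise RuleError(f"{rule.id}: value expression must be one of "
                                f"event_value/map/constant")
            try:
                rule.condition.concepts = sorted(
                    lexicon.expand(rule.condition.concepts))
            except LexiconError as exc:
                raise RuleError(f"{rule.id}: {exc}") from exc
        self.rules = sorted(rules, key=lambda r: r.priority)
        self.lexicon = lexicon

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


def load_rules(path, lexicon: Optional[Lexicon] = None) -> Ruleset:
    """Load and validate a YAML ruleset (may be empty)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return _parse_rules(data, lexicon)


def _parse_rules(data: dict, lexicon: Optional[Lexicon]) -> Ruleset:
    raw = data.get("rules") or []
    try:
        rules = [SummarizationRule.model_validate(r) for r in raw]
    except ValidationError as exc:
        raise RuleError(str(exc)) from exc
    return Ruleset(rules, lexicon)


def default_ruleset(lexicon: Optional[Lexicon] = None) -> Ruleset:
    """The bundled breast-cancer ruleset (receptor status with FISH>IHC,
    cancer type, histologic type, tumor extent, stage, TNM, manifestations).
    """
    ref = resources.files("oncophen.data").joinpath("rules.yaml")
    with ref.open(encoding="utf-8") as fh:
        return _parse_rules(yaml.safe_load(fh), lexicon)


# --------------------------------------------------------------------------
# Rule evaluation
# --------------------------------------------------------------------------

def _episode_context(course: DiseaseCourse) -> dict[str, list]:
    """event id -> leaf episodes containing it."""
    ctx: dict[str, list] = {}
    for ep in course.leaf_episodes():
        for eid in ep.events:
            ctx.setdefault(eid, []).append(ep)
    return ctx


def evaluate_rule(rule: SummarizationRule, course: DiseaseCourse,
                  events: dict[str, EventDetail]) -> list[EventDetail]:
    """All event-detail bindings satisfying the rule's condition pattern.

    Scans every event detail of the course (episode-assigned and
    unclassified alike) and returns matches in deterministic
    (date, document, id) order.
    """
    ctx = _episode_context(course)
    cond = rule.condition
    concept_set = set(cond.concepts)
    out = []
    for e in events.values():
        if e.concept.code not in concept_set:
            continue
        if cond.resource_kind is not None and e.resource_kind is not cond.resource_kind:
            continue
        if e.polarity is not cond.polarity:
            continue
        if cond.method is not None and e.method != cond.method:
            continue
        if cond.episode_type is not None or cond.phase is not None:
            eps = ctx.get(e.id, [])
            if cond.episode_type is not None:
                eps = [p for p in eps if p.episode_type is cond.episode_type]
            if cond.phase is not None:
                eps = [p for p in eps if p.phase is cond.phase]
            if not eps:
                continue
        out.append(e)
    out.sort(key=lambda e: (e.date, e.document_id, e.id))
    return out


def _resolve_value(rule: SummarizationRule,
                   event: EventDetail) -> Optional[Union[str, Value]]:
    expr = rule.action.value
    src = expr["from"]
    if src == "constant":
        raw: Optional[Union[str, Value]] = expr.get("value")
    elif src == "map":
        mapped = expr.get("map", {}).get(event.concept.code)
        raw = mapped
    else:  # event_value
        raw = event.value
    if raw is None:
        return None
    if rule.action.attribute.startswith("manifestation:"):
        if isinstance(raw, str):
            return CodedValue(code=raw)
        return raw
    # scalar attribute: flatten structured values to a string
    if isinstance(raw, CodedValue):
        return raw.code
    if isinstance(raw, QuantityValue):
        return f"{raw.value:g} {raw.unit}".strip()
    if not isinstance(raw, str):
        return getattr(raw, "text", None)
    return raw


# --------------------------------------------------------------------------
# Tumor assignment
# --------------------------------------------------------------------------

# default body sites when an episode carries no BodySite event: a primary
# or locally recurrent breast tumor sits in the breast.
_DEFAULT_SITES = {EpisodeType.PrimaryTumor: "C12971",
                  EpisodeType.Recurrence: "C12971"}


def assign_tumors(course: DiseaseCourse, events: dict[str, EventDetail],
                  patient_id: str, lexicon: Optional[Lexicon] = None,
                  ) -> tuple[Cancer, dict[str, list[str]],
                             list[tuple[str, str]]]:
    """Partition the course's events into Tumor entities under one Cancer.

    One tumor per (episode type, body site): affirmed BodySite events in an
    episode type's events define its sites (falling back to a configured
    default, breast for the primary); site-specific events attach to their
    site's tumor, all other events of the type to every tumor of that type.
    Returns the cancer, an event-id -> tumor-ids mapping, and provenance
    edges linking tumors to their episodes and the cancer to its tumors.
    """
    lexicon = lexicon or default_lexicon()
    by_type: dict[EpisodeType, list] = {}
    for ep in course.leaf_episodes():
        by_type.setdefault(ep.episode_type, []).append(ep)

    tumors: list[Tumor] = []
    event_tumors: dict[str, list[str]] = {}
    edges: list[tuple[str, str]] = []
    for etype in sorted(by_type, key=lambda t: t.value):
        eps = by_type[etype]
        type_events = sorted({eid for ep in eps for eid in ep.events})
        site_events = [events[eid] for eid in type_events
                       if events[eid].resource_kind.value == "BodySite"
                       and events[eid].polarity is Polarity.affirmed]
        site_codes = sorted({e.concept.code for e in site_events})
        if not site_codes:
            site_codes = [_DEFAULT_SITES.get(etype, "unknown")]
        type_tumor_ids = []
        for code in site_codes:
            concept = lexicon.get(code)
            site = (ConceptRef(code=code, label=concept.label,
                               semantic_class="AnatomicalSite")
                    if concept else None)
            tumor = Tumor(id=f"tum:{patient_id}:{etype.value}:{code}",
                          episode_type=etype, body_site=site)
            tumors.append(tumor)
            type_tumor_ids.append(tumor.id)
            edges.extend((tumor.id, ep.id) for ep in eps)
        for eid in type_events:
            ev = events[eid]
            if (ev.resource_kind.value == "BodySite"
                    and ev.concept.code in site_codes
                    and len(site_codes) > 1):
                owners = [f"tum:{patient_id}:{etype.value}:{ev.concept.code}"]
            else:
                owners = type_tumor_ids
            event_tumors.setdefault(eid, []).extend(owners)

    # events outside every episode (e.g. a receptor panel drawn after the
    # diagnostic episode closed) still carry phenotype evidence: attach
    # them to every tumor — unambiguous with a single tumor, conservative
    # and conflict-visible otherwise.
    all_tumor_ids = [t.id for t in tumors]
    for eid in events:
        if eid not in event_tumors and all_tumor_ids:
            event_tumors[eid] = list(all_tumor_ids)

    cancer = Cancer(id=f"can:{patient_id}:1", tumors=tumors)
    edges.extend((cancer.id, t.id) for t in tumors)
    return cancer, event_tumors, edges


# --------------------------------------------------------------------------
# Summarization
# --------------------------------------------------------------------------

class _Segment:
    """One accepted (value, open period) run for an (entity, attribute)."""

    __slots__ = ("start", "end", "value", "priority", "rule_id", "doc_id",
                 "event_ids", "conflicts", "concept")

    def __init__(self, cand: dict) -> None:
        self.start: _dt.date = cand["date"]
        self.end: Optional[_dt.date] = None
        self.value = cand["value"]
        self.priority: int = cand["priority"]
        self.rule_id: str = cand["rule_id"]
        self.doc_id: str = cand["doc_id"]
        self.event_ids: list[str] = [cand["event_id"]]
        self.conflicts: list[dict] = []
        self.concept: ConceptRef = cand["concept"]

    def suppress(self, cand: dict) -> None:
        self.conflicts.append({"rule_id": cand["rule_id"],
                               "value": _dump_value(cand["value"]),
                               "event_id": cand["event_id"]})

    def take_over(self, cand: dict) -> None:
        self.conflicts.append({"rule_id": self.rule_id,
                               "value": _dump_value(self.value),
                               "event_id": self.event_ids[0]})
        self.value = cand["value"]
        self.priority = cand["priority"]
        self.rule_id = cand["rule_id"]
        self.doc_id = cand["doc_id"]
        self.event_ids.append(cand["event_id"])
        self.concept = cand["concept"]


def _dump_value(v: Any) -> Any:
    return v.model_dump(mode="json") if isinstance(v, BaseModel) else v


def _values_equal(a: Any, b: Any) -> bool:
    return _dump_value(a) == _dump_value(b)


def _build_segments(candidates: list[dict]) -> list[_Segment]:
    """Fold date-ordered candidate assertions into valid-period segments."""
    candidates = sorted(candidates, key=lambda c: (c["date"], c["priority"],
                                                   c["doc_id"], c["event_id"]))
    segments: list[_Segment] = []
    for cand in candidates:
        if not segments:
            segments.append(_Segment(cand))
            continue
        last = segments[-1]
        if _values_equal(last.value, cand["value"]):
            last.priority = min(last.priority, cand["priority"])
            if cand["event_id"] not in last.event_ids:
                last.event_ids.append(cand["event_id"])
            continue
        if cand["date"] == last.start:
            if cand["priority"] < last.priority:
                last.take_over(cand)
            elif (cand["priority"] == last.priority
                  and cand["doc_id"] >= last.doc_id):
                # equal precedence, same date: most recent document wins
                last.take_over(cand)
            else:
                last.suppress(cand)
        elif cand["priority"] <= last.priority:
            # temporal supersession by an equal-or-stronger rule
            last.end = cand["date"]
            segments.append(_Segment(cand))
        else:
            # a weaker-precedence later result never displaces the value
            last.suppress(cand)
    return segments


def summarize(course: DiseaseCourse, ruleset: Ruleset,
              events: dict[str, EventDetail], patient_id: str,
              ) -> tuple[PatientSummary, list[tuple[str, str]]]:
    """Apply the ruleset over a disease course to build the Level-4 summary.

    Returns the patient summary (cancers with time-scoped phenotypes,
    sequence variations, patient-level attributes) and the provenance
    edges linking every asserted value through its matched events.
    """
    lexicon = ruleset.lexicon
    edges: list[tuple[str, str]] = []
    if not events:
        return PatientSummary(), edges

    cancer, event_tumors, tumor_edges = assign_tumors(
        course, events, patient_id, lexicon)
    edges.extend(tumor_edges)

    # -- evaluate rules into per-(entity, attribute) candidates ----------
    candidates: dict[tuple[str, str], list[dict]] = {}
    for rule in ruleset:
        for ev in evaluate_rule(rule, course, events):
            if ev.polarity is not rule.condition.polarity:
                continue  # defensive: the negation barrier is absolute
            value = _resolve_value(rule, ev)
            if value is None:
                continue
            if rule.scope == "cancer":
                targets = [cancer.id]
            else:
                targets = event_tumors.get(ev.id, [])
            for target in targets:
                candidates.setdefault((target, rule.action.attribute), []).append({
                    "date": ev.date, "priority": rule.priority,
                    "doc_id": ev.document_id, "event_id": ev.id,
                    "value": value, "rule_id": rule.id, "concept": ev.concept,
                })

    # -- fold candidates into valid-period segments ----------------------
    by_entity: dict[str, dict[str, list[_Segment]]] = {}
    for (entity, attribute), cands in sorted(candidates.items()):
        segs = _build_segments(cands)
        by_entity.setdefault(entity, {})[attribute] = segs

    rule_kinds = {r.action.attribute: r.action.manifestation_kind
                  for r in ruleset}

    def _build_phenotypes(entity_id: str, cls) -> list:
        attrs = by_entity.get(entity_id, {})
        if not attrs:
            return []
        change_points = sorted({s.start for segs in attrs.values()
                                for s in segs})
        assertion_ids: dict[int, str] = {}
        counter = 0
        records = []
        for i, point in enumerate(change_points):
            nxt = change_points[i + 1] if i + 1 < len(change_points) else None
            record = cls(id=f"phe:p:{entity_id}:{i + 1}",
                         valid_period=Period(start=point, end=nxt))
            covering: list[tuple[str, _Segment]] = []
            for attribute in sorted(attrs):
                for seg in attrs[attribute]:
                    seg_end = seg.end or _dt.date.max
                    if seg.start <= point and point < seg_end:
                        covering.append((attribute, seg))
            for attribute, seg in covering:
                if id(seg) not in assertion_ids:
                    counter += 1
                    aid = f"phe:a:{entity_id}:{counter}"
                    assertion_ids[id(seg)] = aid
                    for eid in seg.event_ids:
                        edges.append((aid, eid))
                aid = assertion_ids[id(seg)]
                record.assertions.append(Assertion(
                    id=aid, attribute=attribute, value=_dump_value(seg.value),
                    rule_id=seg.rule_id, event_ids=list(seg.event_ids),
                    conflicts=list(seg.conflicts)))
                edges.append((record.id, aid))
                if attribute.startswith("manifestation:"):
                    kind = rule_kinds.get(attribute) or ManifestationKind.Clinical
                    record.manifestations.append(Manifestation(
                        id=f"{aid}:m", kind=kind, concept=seg.concept,
                        value=seg.value if isinstance(seg.value, BaseModel)
                        else CodedValue(code=str(seg.value)),
                        valid_period=Period(start=point, end=nxt)))
                else:
                    setattr(record, attribute, seg.value)
            records.append(record)
        return records

    cancer.phenotypes = _build_phenotypes(cancer.id, CancerPhenotype)
    for tumor in cancer.tumors:
        tumor.phenotypes = _build_phenotypes(tumor.id, TumorPhenotype)

    # -- treatments -------------------------------------------------------
    treatment_codes = set()
    for cat in _TREATMENT_CATEGORIES:
        treatment_codes.update(lexicon.category(cat))
    tx_events = sorted((e for e in events.values()
                        if e.concept.code in treatment_codes
                        and e.polarity is Polarity.affirmed),
                       key=lambda e: (e.date, e.document_id, e.id))
    by_code: dict[str, list[EventDetail]] = {}
    for e in tx_events:
        by_code.setdefault(e.concept.code, []).append(e)
    for code in sorted(by_code):
        evs = by_code[code]
        trt = Treatment(id=f"trt:{patient_id}:{code}", concept=evs[0].concept,
                        period=Period(start=min(e.date for e in evs),
                                      end=max(e.date for e in evs)))
        cancer.treatments.append(trt)
        edges.extend((trt.id, e.id) for e in evs)
        owner_tumors = sorted({t for e in evs
                               for t in event_tumors.get(e.id, [])})
        for tumor in cancer.tumors:
            if tumor.id in owner_tumors:
                tumor.treatments.append(trt.model_copy(deep=True))

    # -- outcomes, death, comorbidities -----------------------------------
    summary = PatientSummary(cancers=[cancer])
    death_events = sorted((e for e in events.values()
                           if "death" in (lexicon.get(e.concept.code).categories
                                          if lexicon.get(e.concept.code) else ())
                           and e.polarity is Polarity.affirmed),
                          key=lambda e: (e.date, e.document_id, e.id))
    if death_events:
        ev = death_events[0]
        out = Outcome(id=f"out:{patient_id}:death", concept=ev.concept,
                      period=Period(start=ev.date, end=ev.date))
        cancer.outcomes.append(out)
        edges.append((out.id, ev.id))
        summary.patient_attributes["date_of_death"] = ev.date.isoformat()

    comorbid = sorted({(e.concept.code, e.concept.label)
                       for e in events.values()
                       if e.polarity is Polarity.affirmed
                       and lexicon.get(e.concept.code)
                       and "comorbidity" in lexicon.get(e.concept.code).categories})
    if comorbid:
        # co-morbidities attach at patient level, not to the cancer
        summary.patient_attributes["comorbidities"] = [
            {"code": c, "label": l} for c, l in comorbid]

    # -- sequence variations from positive germline tests ------------------
    for phen in cancer.phenotypes:
        for assertion in phen.assertions:
            name = assertion.attribute.removeprefix("manifestation:")
            gene = _GERMLINE_TESTS.get(name)
            val = assertion.value
            code = val.get("code") if isinstance(val, dict) else val
            if gene and code == "positive":
                vid = f"var:{patient_id}:{gene}"
                if any(v.id == vid for v in summary.sequence_variations):
                    continue
                summary.sequence_variations.append(SequenceVariation(
                    id=vid, scope=VariationScope.germline, gene=gene,
                    description=f"{gene} pathogenic variant carrier "
                                f"(positive mutation analysis)"))
                edges.append((vid, assertion.id))

    if not (cancer.tumors or cancer.phenotypes or cancer.treatments
            or cancer.outcomes):
        summary.cancers = []
    return summary, edges


def summarize_record(record: PatientRecord,
                     ruleset: Optional[Ruleset] = None) -> PatientRecord:
    """Summarize a segmented record in place, recording provenance edges."""
    if record.course is None:
        raise ValueError("record has no disease course; run segment_record first")
    ruleset = ruleset or default_ruleset()
    summary, edges = summarize(record.course, ruleset, record.event_index(),
                               record.patient_id)
    for derived, source in edges:
        record.provenance.add_edge(derived, source)
    record.summary = summary
    return record
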