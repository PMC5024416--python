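"""Competency-question queries over cohorts of summarized records.

Five query categories cover the prototypical questions cancer researchers
ask of a phenotype store:

* **criteria** — which patients carry an assertion of a concept, at the
  mention or the phenotype level, negation-aware;
* **event interval** — which patients experienced two events within a
  bounded number of days (durations are expressed in days; "eight weeks"
  is 56 days, inclusive);
* **stratification** — cross-tabulated counts and proportions of one
  attribute against another (no statistical testing);
* **triangulation** — which patients have a concept asserted in documents
  of one kind but absent from another (e.g. ordered per physician notes
  but never administered per medication records);
* **schema availability** — which patients have a non-null, *valid* value
  for an attribute at all.

Every query is a pure function of the cohort; queries run over summarized
records and delegate mention-level search to the stored Level-1 data.
"""

from __future__ import annotations

import datetime as _dt
import logging
from typing import Any, Iterable, Optional

import pandas as pd

from .lexicon import Lexicon, default_lexicon
from .model import PatientRecord, Polarity

__all__ = ["QueryError", "get_attribute", "query_criteria",
           "query_event_interval", "stratify", "triangulate",
           "schema_availability"]

logger = logging.getLogger(__name__)

Cohort = Iterable[PatientRecord]


class QueryError(KeyError):
    """Raised for queries over attributes the schema does not define."""


# --------------------------------------------------------------------------
# Attribute access
# --------------------------------------------------------------------------

_PHENOTYPE_ATTRS = {"cancer_type", "histologic_type", "tumor_extent",
                    "cancer_stage", "t_classification", "n_classification",
                    "m_classification"}
_PATIENT_ATTRS = {"date_of_death", "comorbidities"}


def _latest_attr(phenotypes: list, attr: str) -> Optional[Any]:
    value = None
    for phen in phenotypes:  # records are time-ordered; keep the last non-null
        v = getattr(phen, attr, None)
        if v is not None:
            value = v
    return value


def _latest_manifestation(phenotypes: list, name: str) -> Optional[Any]:
    target = f"manifestation:{name}"
    value = None
    for phen in phenotypes:
        for a in phen.assertions:
            if a.attribute == target:
                v = a.value
                value = v.get("code", v) if isinstance(v, dict) else v
    return value


def get_attribute(record: PatientRecord, attribute: str) -> Optional[Any]:
    """Resolve a summary attribute on one record, or ``None`` when absent.

    Recognized forms: patient attributes (``date_of_death``,
    ``comorbidities``); cancer-phenotype attributes (``cancer_stage``,
    ``t_classification``, ...), read from the latest phenotype record
    carrying them; ``manifestation:<name>`` (searched on the cancer first,
    then its tumors); ``treatment:<code>`` and ``episode:<type>`` as
    booleans. Anything else raises :class:`QueryError`.
    """
    summary = record.summary
    if attribute in _PATIENT_ATTRS:
        return summary.patient_attributes.get(attribute) if summary else None
    if attribute in _PHENOTYPE_ATTRS:
        if not summary:
            return None
        for cancer in summary.cancers:
            v = _latest_attr(cancer.phenotypes, attribute)
            if v is not None:
                return v
            for tumor in cancer.tumors:
                v = _latest_attr(tumor.phenotypes, attribute)
                if v is not None:
                    return v
        return None
    if attribute.startswith("manifestation:"):
        if not summary:
            return None
        name = attribute.split(":", 1)[1]
        for cancer in summary.cancers:
            v = _latest_manifestation(cancer.phenotypes, name)
            if v is not None:
                return v
            for tumor in cancer.tumors:
                v = _latest_manifestation(tumor.phenotypes, name)
                if v is not None:
                    return v
        return None
    if attribute.startswith("treatment:"):
        code = attribute.split(":", 1)[1]
        if not summary:
            return False
        return any(t.concept.code == code
                   for c in summary.cancers for t in c.treatments)
    if attribute.startswith("episode:"):
        name = attribute.split(":", 1)[1]
        if not record.course:
            return False
        return any(ep.episode_type.value == name
                   for ep in record.course.all_episodes())
    raise QueryError(f"unknown attribute {attribute!r}")


# --------------------------------------------------------------------------
# Queries
# --------------------------------------------------------------------------

def query_criteria(cohort: Cohort, concept: str,
                   polarity: str = "affirmed",
                   level: str = "mention",
                   lexicon: Optional[Lexicon] = None) -> set[str]:
    """Patients with a matching assertion of ``concept`` at a level.

    At mention level, ``polarity="affirmed"`` selects patients with at
    least one affirmed mention of the concept; ``"negated"`` selects
    patients whose mentions of the concept are *all* negated. At phenotype
    level the concept is matched against manifestation, treatment, outcome
    and body-site concepts of the summary (which are affirmative by
    construction, so a negated phenotype-level query is always empty).
    An unknown concept code yields an empty set with a warning.
    """
    lexicon = lexicon or default_lexicon()
    if concept not in lexicon:
        logger.warning("query_criteria: unknown concept code %r", concept)
        return set()
    pol = Polarity(polarity)
    out: set[str] = set()
    for record in cohort:
        if level == "mention":
            mentions = [m for d in record.documents for m in d.mentions
                        if m.concept.code == concept]
            if not mentions:
                continue
            if pol is Polarity.affirmed:
                if any(m.polarity is Polarity.affirmed for m in mentions):
                    out.add(record.patient_id)
            else:
                if all(m.polarity is Polarity.negated for m in mentions):
                    out.add(record.patient_id)
        elif level == "phenotype":
            if pol is Polarity.negated or not record.summary:
                continue
            codes: set[str] = set()
            for cancer in record.summary.cancers:
                codes.update(t.concept.code for t in cancer.treatments)
                codes.update(o.concept.code for o in cancer.outcomes)
                for phen in cancer.phenotypes:
                    codes.update(m.concept.code for m in phen.manifestations)
                for tumor in cancer.tumors:
                    if tumor.body_site:
                        codes.add(tumor.body_site.code)
                    codes.update(t.concept.code for t in tumor.treatments)
                    for phen in tumor.phenotypes:
                        codes.update(m.concept.code
                                     for m in phen.manifestations)
            if concept in codes:
                out.add(record.patient_id)
        else:
            raise QueryError(f"unknown query level {level!r}")
    return out


def query_event_interval(cohort: Cohort, event_a: str, event_b: str,
                         max_gap_days: int) -> set[str]:
    """Patients with an a-event followed by a b-event within the gap.

    The gap is inclusive and directed: the b-event must fall 0 to
    ``max_gap_days`` days *after* the a-event. With a gap of 0 only
    same-day pairs qualify.
    """
    out: set[str] = set()
    for record in cohort:
        events = list(record.event_index().values())
        a_dates = [e.date for e in events
                   if e.concept.code == event_a
                   and e.polarity is Polarity.affirmed and e.date]
        b_dates = [e.date for e in events
                   if e.concept.code == event_b
                   and e.polarity is Polarity.affirmed and e.date]
        if any(0 <= (db - da).days <= max_gap_days
               for da in a_dates for db in b_dates):
            out.add(record.patient_id)
    return out


def stratify(cohort: Cohort, split_attribute: str,
             outcome_attribute: str) -> pd.DataFrame:
    """Cross-tabulate an outcome attribute by a stratifying attribute.

    Returns a tidy frame with columns ``(split, outcome, count,
    proportion)`` where proportions are within-stratum. Patients lacking
    the split attribute are excluded; a missing outcome value appears as
    the ``None`` category. Every (stratum, outcome) combination is
    retained, 0-count rows included. No statistical testing is performed.
    """
    pairs: list[tuple[Any, Any]] = []
    for record in cohort:
        split = get_attribute(record, split_attribute)
        if split is None:
            continue
        pairs.append((split, get_attribute(record, outcome_attribute)))
    if not pairs:
        logger.warning("stratify: attribute %r absent from all patients",
                       split_attribute)
        return pd.DataFrame(columns=["split", "outcome", "count",
                                     "proportion"])
    strata = sorted({s for s, _ in pairs}, key=repr)
    outcomes = sorted({o for _, o in pairs}, key=repr)
    rows = []
    for s in strata:
        total = sum(1 for sp, _ in pairs if sp == s)
        for o in outcomes:
            n = sum(1 for sp, op in pairs if sp == s and op == o)
            rows.append({"split": s, "outcome": o, "count": n,
                         "proportion": n / total if total else 0.0})
    return pd.DataFrame(rows)


def triangulate(cohort: Cohort, doc_kind_a: str, doc_kind_b: str,
                concept: str) -> set[str]:
    """Patients where a concept is asserted in kind-a documents only.

    Uses the doc-type provenance carried on event details: the patient is
    included when an affirmed event of the concept occurs in a document of
    kind ``doc_kind_a`` and no document of kind ``doc_kind_b`` asserts it.
    """
    out: set[str] = set()
    for record in cohort:
        kinds = {e.doc_type.value for e in record.event_index().values()
                 if e.concept.code == concept
                 and e.polarity is Polarity.affirmed}
        if doc_kind_a in kinds and doc_kind_b not in kinds:
            out.add(record.patient_id)
    return out


def _value_is_valid(attribute: str, value: Any,
                    lexicon: Lexicon) -> bool:
    if attribute == "date_of_death":
        try:
            _dt.date.fromisoformat(str(value))
            return True
        except ValueError:
            return False
    if not lexicon.value_allowed(attribute.removeprefix("manifestation:"),
                                 value):
        return False
    return lexicon.pattern_match(attribute, value)


def schema_availability(cohort: Cohort, attribute: str,
                        lexicon: Optional[Lexicon] = None) -> set[str]:
    """Patients whose record carries a non-null, valid attribute value.

    Values failing validation (an unparseable date of death, a stage
    outside the configured value set) are excluded and reported via a
    warning. Unknown attributes raise :class:`QueryError`.
    """
    lexicon = lexicon or default_lexicon()
    out: set[str] = set()
    for record in cohort:
        value = get_attribute(record, attribute)  # raises on unknown attr
        if value is None or value is False:
            continue
        if not _value_is_valid(attribute, value, lexicon):
            logger.warning("schema_availability: patient %s has invalid "
                           "%s value %r", record.patient_id, attribute, value)
            continue
        out.add(record.patient_id)
    return out
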