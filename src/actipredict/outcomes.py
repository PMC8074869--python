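"""Outcome labeling: complication severity grading and the textbook outcome.

Postoperative complications are graded on the Modified Accordion Grading
System (MAGS), a 1-6 severity scale where grade 3 and above is severe
(4 = single organ system failure, 5 = multiorgan failure, 6 = death).

The *textbook outcome* is the composite success label: absence of
postoperative pancreatic fistula, bile leak, post-pancreatectomy hemorrhage,
severe (MAGS >= 3) complication, readmission within the 30-day
post-discharge window, and in-hospital mortality — with one modification:
a distal pancreatectomy patient discharged with a drain still counts as
textbook when the drain is out on or before postoperative day 4.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class ComplicationType(str, enum.Enum):
    PANCREATIC_FISTULA = "pancreatic_fistula"
    BILE_LEAK = "bile_leak"
    POSTPANCREATECTOMY_HEMORRHAGE = "postpancreatectomy_hemorrhage"
    DELAYED_GASTRIC_EMPTYING = "delayed_gastric_emptying"
    ORGAN_SPACE_INFECTION = "organ_space_infection"
    ANASTOMOTIC_LEAK_NONPANCREATIC = "anastomotic_leak_nonpancreatic"
    MYOCARDIAL_INFARCTION = "myocardial_infarction"
    OTHER = "other"


class OperationType(str, enum.Enum):
    PANCREATICODUODENECTOMY = "pancreaticoduodenectomy"
    DISTAL_PANCREATECTOMY = "distal_pancreatectomy"
    TOTAL_PANCREATECTOMY = "total_pancreatectomy"


#: event types whose presence at any grade disqualifies a textbook outcome
#: (they are listed separately from "severe complications" in the definition)
_ALWAYS_DISQUALIFYING = {
    ComplicationType.PANCREATIC_FISTULA: "pancreatic_fistula",
    ComplicationType.BILE_LEAK: "bile_leak",
    ComplicationType.POSTPANCREATECTOMY_HEMORRHAGE: "hemorrhage",
}

SEVERE_GRADE = 3


@dataclass(frozen=True)
class ComplicationEvent:
    """A typed, MAGS-graded postoperative event within 30 days of discharge."""

    type: ComplicationType
    mags_grade: int
    days_post_discharge: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.mags_grade <= 6:
            raise ValueError(f"MAGS grade must be 1-6, got {self.mags_grade}")


@dataclass(frozen=True)
class OutcomeLabel:
    """textbook is True exactly when no criterion failed (reasons empty)."""

    textbook: bool
    reasons: tuple = ()

    def __post_init__(self) -> None:
        assert self.textbook == (len(self.reasons) == 0)


def is_severe(event: ComplicationEvent) -> bool:
    """MAGS grade >= 3 is severe; grades 1-2 are nonsevere."""
    return event.mags_grade >= SEVERE_GRADE


def textbook_outcome(
    events: list[ComplicationEvent],
    readmitted_30d: bool = False,
    in_hospital_death: bool = False,
    op_type: OperationType | str = OperationType.PANCREATICODUODENECTOMY,
    drain_removed_by_day: int | None = None,
    discharged_with_drain: bool = False,
) -> OutcomeLabel:
    """Compute the (modified) textbook outcome label.

    A drain still in place at discharge is tolerated for distal
    pancreatectomy when removed on or before day 4; for any other operation,
    or later removal, it disqualifies.  Grade 1-2 delayed gastric emptying
    and grade 1-2 "other" events are not in the disqualifying set.
    Adding events can only remove the textbook label, never restore it.
    """
    op_type = OperationType(op_type)
    reasons: list[str] = []
    for ev in events:
        tag = _ALWAYS_DISQUALIFYING.get(ev.type)
        if tag is not None and tag not in reasons:
            reasons.append(tag)
        if is_severe(ev) and "severe" not in reasons:
            reasons.append("severe")
    if readmitted_30d:
        reasons.append("readmission")
    if in_hospital_death:
        reasons.append("in_hospital_death")
    if discharged_with_drain:
        allowed = (
            op_type is OperationType.DISTAL_PANCREATECTOMY
            and drain_removed_by_day is not None
            and drain_removed_by_day <= 4
        )
        if not allowed:
            reasons.append("drain_at_discharge")
    return OutcomeLabel(textbook=not reasons, reasons=tuple(reasons))
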