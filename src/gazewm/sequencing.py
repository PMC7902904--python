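"""Partition a display's gaze stream into model-to-model sequences.

A *sequence* is the unit of working-memory use: it opens at a gaze
sample on the Model area and closes at the next qualifying gaze on the
Model.  Everything the participant did in between (searching the
Resource, placing objects in the Workspace) is attributed to one episode
of memory use.  The closing Model visit simultaneously opens the next
sequence, so adjacent sequences share their boundary sample.

Qualification rule: by default a Model re-view closes the open sequence
only if at least one Resource visit occurred since it opened; glances to
the Workspace mid-placement do not split an encoding episode.  A config
switch accepts Workspace visits as qualifying too.  OTHER samples never
terminate or qualify anything; they extend the current state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .ingest import ActionEvent, AoiVisit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QualificationRule:
    """Which AOI visits let a Model re-view close the open sequence."""

    accept_workspace: bool = False

    @property
    def qualifying_aois(self) -> frozenset:
        aois = {"RESOURCE"}
        if self.accept_workspace:
            aois.add("WORKSPACE")
        return frozenset(aois)


@dataclass
class Sequence:
    """One model-view-to-model-view unit."""

    sequence_id: int
    start_time_s: float
    end_time_s: float                  # start of the closing Model visit
    initial_model_dwell_ms: float = 0.0
    action_events: list[ActionEvent] = field(default_factory=list)
    qualifying: bool = True
    truncated: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_time_s - self.start_time_s


def segment_sequences(visits: list[AoiVisit],
                      rule: QualificationRule | None = None,
                      ) -> list[Sequence]:
    """Segment one display's AOI visits into sequences.

    The sequence span convention is half-open on event time,
    ``(start, end]`` with ``end`` the first sample of the closing Model
    visit; the boundary visit's dwell belongs to the *next* sequence.
    Trailing activity without a qualifying closing Model view becomes a
    truncated sequence.
    """
    rule = rule or QualificationRule()
    qualifying = rule.qualifying_aois
    sequences: list[Sequence] = []
    open_start: float | None = None
    seen_qualifier = False
    seen_activity = False      # any visit after the sequence opened
    last_time = None
    for v in visits:
        last_time = v.end_time_s
        if v.aoi == "MODEL":
            if open_start is None:
                open_start = v.start_time_s
            elif seen_qualifier:
                sequences.append(Sequence(
                    sequence_id=len(sequences),
                    start_time_s=open_start, end_time_s=v.start_time_s))
                open_start = v.start_time_s
                seen_qualifier = False
                seen_activity = False
            # a non-qualifying Model re-view merges into the open sequence
        elif open_start is not None:
            seen_activity = True
            if v.aoi in qualifying:
                seen_qualifier = True
        # OTHER (and non-qualifying areas) extend the current state
    if open_start is None:
        log.warning("display has no MODEL visit: zero sequences")
        return []
    if seen_activity:
        # trailing activity never closed by a qualifying Model view
        sequences.append(Sequence(
            sequence_id=len(sequences), start_time_s=open_start,
            end_time_s=last_time, truncated=True))
    _attach_dwells(sequences, visits)
    return sequences


def _attach_dwells(sequences: list[Sequence], visits: list[AoiVisit]) -> None:
    """Initial Model dwell: summed MODEL time from the sequence's opening
    sample until its first RESOURCE visit (Workspace/OTHER interludes do
    not end the initial viewing and are not counted)."""
    for seq in sequences:
        dwell = 0.0
        for v in visits:
            if v.end_time_s <= seq.start_time_s:
                continue
            if v.start_time_s >= seq.end_time_s and not seq.truncated:
                break
            if v.aoi == "RESOURCE" and v.start_time_s >= seq.start_time_s:
                break
            if v.aoi == "MODEL" and v.start_time_s >= seq.start_time_s:
                dwell += v.end_time_s - v.start_time_s
        seq.initial_model_dwell_ms = dwell * 1000.0


def assign_actions(sequences: list[Sequence],
                   events: list[ActionEvent]) -> list[Sequence]:
    """Attach each event to the sequence whose span ``(start, end]``
    contains its timestamp.

    Events before the first sequence opens are assigned to the first
    sequence and flagged; events after the last closed sequence go to the
    truncated tail if one exists, else to the last sequence, flagged.
    """
    if not sequences:
        return sequences
    for ev in events:
        target = None
        flagged = False
        for seq in sequences:
            if seq.start_time_s < ev.time_s <= seq.end_time_s:
                target = seq
                break
            if seq.truncated and ev.time_s > seq.start_time_s:
                target = seq
                break
        if target is None:
            if ev.time_s <= sequences[0].start_time_s:
                target = sequences[0]
            else:
                target = sequences[-1]
            flagged = True
        if flagged:
            ev = ActionEvent(**{**ev.__dict__, "flagged": True})
        target.action_events.append(ev)
    return sequences


def segment_display(visits: list[AoiVisit], events: list[ActionEvent],
                    rule: QualificationRule | None = None) -> list[Sequence]:
    """Segment and attach actions in one call."""
    return assign_actions(segment_sequences(visits, rule), events)
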