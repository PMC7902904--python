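"""Reading, validating and event-ifying frame-by-frame behavioural logs.

The frame-log dialect is a CSV with one row per tracked frame (90 Hz by
default) and the canonical header written by :mod:`gazewm.simulate`.
This module turns the raw stream into two derived representations the
rest of the pipeline consumes:

* run-length encoded AOI visits (:class:`AoiVisit`), and
* discrete pickup/placement events (:class:`ActionEvent`).

AOI labels are taken as given; no fixation detection is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import AOI_LABELS, FRAME_COLUMNS

log = logging.getLogger(__name__)

DISPLAY_KEY = ["participant", "run", "display"]


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class IntegrityError(ValueError):
    """The log violates a frame-log invariant; the message cites the row."""


@dataclass(frozen=True)
class AoiVisit:
    """One maximal run of identical AOI labels."""

    aoi: str
    start_time_s: float
    end_time_s: float          # exclusive: start of the next visit
    n_frames: int
    start_frame: int


@dataclass(frozen=True)
class ActionEvent:
    """A pickup or placement derived from controller events."""

    time_s: float
    kind: str                  # PICKUP | PLACE
    object_id: int
    is_model_object: bool | None = None
    placement_cell: int | None = None
    correct_location: bool | None = None
    is_corrective: bool = False
    flagged: bool = False      # assigned outside any closed sequence span


_DTYPES = {
    "participant": "int32", "session": "int16", "run": "int16",
    "condition_deg": "int16", "display": "int16", "frame": "int64",
    "time_s": "float64",
}


def read_frame_log(path, validate: bool = True) -> pd.DataFrame:
    """Read the frame-log CSV dialect and validate its invariants."""
    df = pd.read_csv(path, keep_default_na=False, na_values=["NA"],
                     low_memory=False, float_precision="round_trip")
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"frame log missing required columns: {missing}")
    for col, dt in _DTYPES.items():
        df[col] = df[col].astype(dt)
    for col in ("gazed_object", "held_object", "placement_cell"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["placement_correct"] = df["placement_correct"].map(
        {"True": True, "False": False, True: True, False: False})
    if validate:
        validate_frame_log(df)
    return df


def validate_frame_log(frames: pd.DataFrame) -> None:
    """Check frame-log invariants; raise :class:`IntegrityError` citing rows."""
    bad_aoi = ~frames["aoi"].isin(AOI_LABELS)
    if bad_aoi.any():
        row = int(np.flatnonzero(bad_aoi.to_numpy())[0])
        raise IntegrityError(
            f"row {row}: unknown AOI label {frames['aoi'].iloc[row]!r}")
    if len(frames) == 0:
        log.warning("frame log is empty")
        return
    for key, block in frames.groupby(DISPLAY_KEY, sort=False):
        t = block["time_s"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            row = int(block.index[np.argmin(np.diff(t) > 0) + 1])
            raise IntegrityError(
                f"display {key}: time not strictly increasing at row {row}")
        ev = block["controller_event"].to_numpy()
        held = block["held_object"].to_numpy()
        held_before = np.concatenate([[np.nan], held[:-1]])
        pick = ev == "PICKUP"
        if np.any(pick & ~np.isnan(held_before)):
            row = int(block.index[np.flatnonzero(pick & ~np.isnan(held_before))[0]])
            raise IntegrityError(
                f"display {key}: PICKUP while holding an object at row {row}")
        rel = ev == "RELEASE"
        if np.any(rel & np.isnan(held_before)):
            row = int(block.index[np.flatnonzero(rel & np.isnan(held_before))[0]])
            raise IntegrityError(
                f"display {key}: RELEASE with no object held at row {row}")


def compress_visits(frames: pd.DataFrame) -> list[AoiVisit]:
    """Run-length encode the AOI column of one display block."""
    if len(frames) == 0:
        log.warning("empty display block: zero visits")
        return []
    aoi = frames["aoi"].to_numpy(dtype=object)
    t = frames["time_s"].to_numpy()
    fr = frames["frame"].to_numpy()
    change = np.flatnonzero(aoi[1:] != aoi[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(aoi)]])
    period = float(np.median(np.diff(t))) if len(t) > 1 else 1.0 / 90.0
    visits = []
    for s, e in zip(starts, ends):
        visits.append(AoiVisit(
            aoi=str(aoi[s]), start_time_s=float(t[s]),
            end_time_s=float(t[e] if e < len(t) else t[-1] + period),
            n_frames=int(e - s), start_frame=int(fr[s])))
    return visits


def derive_events(frames: pd.DataFrame,
                  model_objects: Iterable[int] | None = None,
                  ) -> list[ActionEvent]:
    """Derive ordered pickup/placement events for one display block.

    A RELEASE frame with a placement cell becomes a PLACE; a RELEASE
    without a cell is a dropped object (it re-spawns) and emits no event.
    ``is_corrective`` is set on any PLACE of an object previously placed
    incorrectly, and on re-pickups that undo an incorrect placement.

    ``model_objects`` marks pickups of distractors (identity errors).
    Without a manifest, membership is inferred from which objects are
    eventually placed correctly.
    """
    mask = frames["controller_event"].isin(["PICKUP", "RELEASE"])
    ev_rows = frames[mask].copy()
    # held_object shows the post-event state, so the object a RELEASE
    # refers to is whatever was held on the previous frame
    held_prev = frames["held_object"].shift(1)
    ev_rows["_source_object"] = np.where(
        ev_rows["controller_event"] == "PICKUP",
        ev_rows["held_object"], held_prev[mask])
    if model_objects is None:
        placed = ev_rows[(ev_rows["controller_event"] == "RELEASE")
                         & ev_rows["placement_correct"].eq(True)]
        model_objects = set(int(o) for o in placed["_source_object"].dropna())
        log.debug("inferred %d model objects from correct placements",
                  len(model_objects))
    else:
        model_objects = set(int(o) for o in model_objects)

    events: list[ActionEvent] = []
    misplaced: set[int] = set()    # objects currently placed in a wrong cell
    ever_wrong: set[int] = set()   # objects that have been misplaced before
    for _, row in ev_rows.iterrows():
        obj = row["_source_object"]
        if np.isnan(obj):
            continue  # defensive: malformed event row
        obj = int(obj)
        if row["controller_event"] == "PICKUP":
            corrective = obj in misplaced
            if corrective:
                misplaced.discard(obj)
            events.append(ActionEvent(
                time_s=float(row["time_s"]), kind="PICKUP", object_id=obj,
                is_model_object=obj in model_objects,
                is_corrective=corrective))
        else:
            cell = row["placement_cell"]
            if np.isnan(cell):
                log.debug("dropped object %d at t=%.3f (no placement)",
                          obj, row["time_s"])
                continue
            correct = bool(row["placement_correct"])
            corrective = obj in ever_wrong
            if not correct:
                misplaced.add(obj)
                ever_wrong.add(obj)
            events.append(ActionEvent(
                time_s=float(row["time_s"]), kind="PLACE", object_id=obj,
                is_model_object=obj in model_objects,
                placement_cell=int(cell), correct_location=correct,
                is_corrective=corrective))
    return events


def iter_displays(frames: pd.DataFrame):
    """Yield (key dict, display block) pairs in stable order."""
    for key, block in frames.groupby(DISPLAY_KEY, sort=True):
        meta = dict(zip(DISPLAY_KEY, (int(k) for k in key)))
        meta["condition_deg"] = int(block["condition_deg"].iloc[0])
        meta["session"] = int(block["session"].iloc[0])
        yield meta, block


def events_to_frame(events: list[ActionEvent]) -> pd.DataFrame:
    """Export events as a table (one row per ActionEvent)."""
    return pd.DataFrame([e.__dict__ for e in events])


def model_objects_from_manifest(displays: pd.DataFrame
                                ) -> Mapping[tuple, set]:
    """Map (participant, run, display) -> set of model object ids."""
    out = {}
    for _, row in displays.iterrows():
        key = (int(row["participant"]), int(row["run"]), int(row["display"]))
        out[key] = {int(o) for o in str(row["model_objects"]).split(";")}
    return out
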