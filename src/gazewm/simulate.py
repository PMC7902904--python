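"""Agent-based simulator of an immersive object-copying task.

Generates frame-by-frame gaze/controller logs with the structure the
downstream analysis assumes: a participant repeatedly (1) views a Model
area holding an 8-object arrangement, (2) walks to a Resource area and
picks up objects, (3) places them in a Workspace copy of the arrangement.
The angular separation between Model and Workspace (0/45/90/135 degrees)
manipulates the locomotive cost of re-sampling the Model, so the agent's
policy encodes more object features (identity, location) per Model visit
as the angle grows.

Gaze is emitted directly as area-of-interest (AOI) labels at 90 Hz; no 3D
ray casting is performed.  An optional noise layer can inject spurious
AOI flickers.  Every simulated sequence is recorded in a ground-truth
ledger so the downstream segmentation/scoring pipeline can be validated
against what the agent actually did.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FRAME_COLUMNS = [
    "participant", "session", "run", "condition_deg", "display", "frame",
    "time_s", "aoi", "gazed_object", "controller_event", "held_object",
    "placement_cell", "placement_correct",
]

AOI_LABELS = ("MODEL", "RESOURCE", "WORKSPACE", "OTHER")
_AOI_M, _AOI_R, _AOI_W, _AOI_O = 0, 1, 2, 3

CONDITIONS = (0, 45, 90, 135)
_COND_RANK = {0: 0, 45: 1, 90: 2, 135: 3}

#: Per-condition probability of encoding k features per Model visit.
#: Calibrated to the reported per-condition shares: one-feature use falls
#: from 60% (0 deg) to below 30% (135 deg) while four-feature use rises
#: from ~1% to 10%.
DEFAULT_FEATURES_PMF: Mapping[int, Mapping[int, float]] = {
    0: {1: 0.60, 2: 0.27, 3: 0.12, 4: 0.01},
    45: {1: 0.50, 2: 0.36, 3: 0.12, 4: 0.02},
    90: {1: 0.40, 2: 0.44, 3: 0.11, 4: 0.05},
    135: {1: 0.29, 2: 0.50, 3: 0.11, 4: 0.10},
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class TaskGeometry:
    """Physical layout of the virtual room (centimetres / degrees)."""

    room_side_cm: float = 450.0
    model_angle_deg: int = 0
    model_area_cm: tuple[float, float] = (120.0, 60.0)
    workspace_area_cm: tuple[float, float] = (100.0, 50.0)
    resource_area_cm: tuple[float, float] = (120.0, 75.0)
    object_side_cm: float = 10.0

    def __post_init__(self) -> None:
        if self.model_angle_deg not in CONDITIONS:
            raise ConfigurationError(
                f"model_angle_deg must be one of {CONDITIONS}, "
                f"got {self.model_angle_deg}")
        sizes = (self.room_side_cm, self.object_side_cm,
                 *self.model_area_cm, *self.workspace_area_cm,
                 *self.resource_area_cm)
        if any(s <= 0 for s in sizes):
            raise ConfigurationError("all geometry sizes must be positive")


@dataclass(frozen=True)
class DisplaySpec:
    """One display: which objects to copy, where, and the distractor set."""

    display_id: int
    model_objects: tuple[int, ...]
    distractor_objects: tuple[int, ...]
    cell_assignment: Mapping[int, int]
    pool_size: int = 60

    @property
    def resource_objects(self) -> tuple[int, ...]:
        return self.model_objects + self.distractor_objects

    def __post_init__(self) -> None:
        n = len(self.model_objects)
        if len(set(self.resource_objects)) != n + len(self.distractor_objects):
            raise ConfigurationError("objects repeated within a display")
        cells = sorted(self.cell_assignment[o] for o in self.model_objects)
        if cells != list(range(n)):
            raise ConfigurationError(
                "cell assignment must be a bijection onto the model cells")


@dataclass
class AgentPolicy:
    """Behavioural policy of the simulated participant.

    Time parameters are means of log-normal draws (dispersion
    ``sigma_log`` on the log scale).  ``features_per_visit_pmf`` maps each
    condition (degrees) to the distribution of features encoded per Model
    visit.  Error rates are per-sequence injection probabilities.
    """

    features_per_visit_pmf: Mapping[int, Mapping[int, float]] = field(
        default_factory=lambda: {c: dict(DEFAULT_FEATURES_PMF[c])
                                 for c in CONDITIONS})
    zero_feature_rate: float = 0.05
    encoding_base_s: float = 0.20
    encoding_per_feature_s: float = 0.22
    encoding_condition_gain: float = 0.10
    travel_base_s: float = 0.30
    travel_per_rank_s: float = 0.12
    hop_time_s: float = 0.25
    search_time_s: float = 0.70
    place_time_s: float = 0.60
    glance_time_s: float = 0.30
    zero_visit_time_s: float = 0.50
    correction_pickup_s: float = 0.40
    identity_error_rate: float = 0.018
    location_error_rate: float = 0.029
    sigma_log: float = 0.30

    def __post_init__(self) -> None:
        for cond, pmf in self.features_per_visit_pmf.items():
            total = sum(pmf.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"features pmf for condition {cond} sums to {total}")
            if any(p < 0 for p in pmf.values()):
                raise ConfigurationError("pmf probabilities must be >= 0")
            if any(k < 1 or k != int(k) for k in pmf):
                raise ConfigurationError("pmf support must be integers >= 1")
        for rate in (self.zero_feature_rate, self.identity_error_rate,
                     self.location_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("rates must lie in [0, 1]")
        times = (self.encoding_base_s, self.travel_base_s, self.hop_time_s,
                 self.search_time_s, self.place_time_s, self.glance_time_s,
                 self.zero_visit_time_s, self.correction_pickup_s)
        if any(t <= 0 for t in times):
            raise ConfigurationError("time means must be positive")

    def encoding_mean_s(self, k: int, condition_deg: int) -> float:
        rank = _COND_RANK[condition_deg]
        base = self.encoding_base_s + self.encoding_per_feature_s * k
        return base * (1.0 + self.encoding_condition_gain * rank)

    def travel_mean_s(self, condition_deg: int) -> float:
        return self.travel_base_s + self.travel_per_rank_s * _COND_RANK[condition_deg]


@dataclass(frozen=True)
class SimulationConfig:
    """Scale and timing of a simulated experiment."""

    n_participants: int = 24
    runs_per_participant: int = 8
    displays_per_run: int = 14
    objects_per_display: int = 8
    distractors_per_display: int = 16
    pool_size: int = 60
    display_timeout_s: float = 45.0
    frame_rate_hz: float = 90.0

    def __post_init__(self) -> None:
        if self.runs_per_participant % len(CONDITIONS) != 0:
            raise ConfigurationError(
                "runs_per_participant must be a multiple of the number of "
                "conditions so every condition occurs equally often")
        if self.pool_size < self.objects_per_display + self.distractors_per_display:
            raise ConfigurationError("pool smaller than one display's objects")
        if min(self.n_participants, self.displays_per_run,
               self.objects_per_display) < 1:
            raise ConfigurationError("counts must be positive")


def generate_display(pool_size: int, rng: np.random.Generator,
                     display_id: int = 0, n_model: int = 8,
                     n_distractors: int = 16) -> DisplaySpec:
    """Draw a display: ``n_model`` model objects plus distractors from the pool."""
    if pool_size < n_model + n_distractors:
        raise ConfigurationError(
            f"pool_size must be >= {n_model + n_distractors}, got {pool_size}")
    chosen = rng.choice(pool_size, size=n_model + n_distractors, replace=False)
    model = tuple(int(o) for o in chosen[:n_model])
    distractors = tuple(int(o) for o in chosen[n_model:])
    cells = rng.permutation(n_model)
    assignment = {obj: int(c) for obj, c in zip(model, cells)}
    return DisplaySpec(display_id=display_id, model_objects=model,
                       distractor_objects=distractors,
                       cell_assignment=assignment, pool_size=pool_size)


def _composition_marginal(probs: np.ndarray, ks: np.ndarray,
                          total: int) -> np.ndarray:
    """Pooled part-size marginal of exact-sum compositions drawn by
    rejection from ``probs``, computed exactly by dynamic programming."""
    u = np.zeros(total + 1)
    u[0] = 1.0
    g = np.zeros((len(ks), total + 1))   # E[count_k * 1(hit s)]
    for s in range(1, total + 1):
        for j, k in enumerate(ks):
            if k <= s:
                u[s] += probs[j] * u[s - k]
                g[:, s] += probs[j] * g[:, s - k]
                g[j, s] += probs[j] * u[s - k]
    tot = g[:, total].sum()
    return g[:, total] / tot if tot > 0 else np.full(len(ks), np.nan)


def _tilted_pmf(pmf: Mapping[int, float], total: int,
                tol: float = 1e-12, max_iter: int = 500) -> dict[int, float]:
    """Drawing pmf whose exact-sum compositions realize ``pmf``.

    Conditioning i.i.d. draws on summing exactly to ``total`` length-
    biases the pooled part distribution toward small parts, so drawing
    straight from the target pmf would over-produce one-feature
    sequences.  This solves (fixed point on an exponential tilt) for the
    drawing distribution whose conditional compositions have pooled
    part marginals equal to the target.
    """
    ks = np.array(sorted(pmf), dtype=int)
    target = np.array([pmf[int(k)] for k in ks], dtype=float)
    pos = target > 0
    probs = target.copy()
    for _ in range(max_iter):
        m = _composition_marginal(probs, ks, total)
        if np.any(~np.isfinite(m)):
            return {int(k): float(p) for k, p in zip(ks, target)}
        err = np.max(np.abs(m[pos] - target[pos]))
        if err < tol:
            break
        ratio = np.ones_like(probs)
        ratio[pos] = target[pos] / np.maximum(m[pos], 1e-300)
        probs = probs * ratio
        probs /= probs.sum()
    return {int(k): float(p) for k, p in zip(ks, probs)}


_TILT_CACHE: dict[tuple, dict[int, float]] = {}


def _draw_composition(pmf: Mapping[int, float], total: int,
                      rng: np.random.Generator,
                      max_tries: int = 300) -> tuple[list[int], bool]:
    """Sequence-size composition of ``total`` features.

    Draws i.i.d. from a tilted copy of the policy pmf (see
    :func:`_tilted_pmf`) and accepts only compositions that land exactly
    on ``total``, so the realized per-sequence feature distribution
    matches the configured policy.  If ``total`` is not reachable within
    ``max_tries`` the last draw is truncated and the composition flagged
    as capped.
    """
    key = (tuple(sorted(pmf.items())), total)
    draw_pmf = _TILT_CACHE.get(key)
    if draw_pmf is None:
        draw_pmf = _tilted_pmf(pmf, total)
        _TILT_CACHE[key] = draw_pmf
    ks = np.array(sorted(draw_pmf), dtype=int)
    cum = np.cumsum([draw_pmf[int(k)] for k in ks])
    cum[-1] = 1.0
    parts: list[int] = []
    for _ in range(max_tries):
        parts = []
        s = 0
        while s < total:
            k = int(ks[np.searchsorted(cum, rng.random(), side="right")])
            parts.append(k)
            s += k
        if s == total:
            return parts, False
    # fallback: truncate the final draw
    excess = s - total
    parts[-1] -= excess
    if parts[-1] == 0:
        parts.pop()
    return parts, True


class _DisplayEmitter:
    """Builds the frame arrays and ground-truth ledger for one display."""

    def __init__(self, spec, policy, condition_deg, config, rng, meta):
        self.spec = spec
        self.policy = policy
        self.cond = condition_deg
        self.config = config
        self.rng = rng
        self.meta = meta  # dict with participant/session/run/display
        self.hz = config.frame_rate_hz
        self.segments: list[tuple[int, int]] = []   # (aoi_code, n_frames)
        self.events: list[tuple[int, str, int, object, object]] = []
        self.n_frames = 0
        self.ledger: list[dict] = []
        self.seq_open_frame = 0

    # -- low-level emission -------------------------------------------------
    def _dur_frames(self, mean_s: float, lognormal: bool = True) -> int:
        if lognormal:
            mu = np.log(mean_s) - 0.5 * self.policy.sigma_log ** 2
            d = float(np.exp(self.rng.normal(mu, self.policy.sigma_log)))
        else:
            d = mean_s
        return max(1, int(round(d * self.hz)))

    def _emit(self, aoi: int, n_frames: int, event=None) -> None:
        self.segments.append((aoi, n_frames))
        self.n_frames += n_frames
        if event is not None:
            kind, obj, cell, correct, credit = event
            self.events.append(
                (self.n_frames - 1, kind, obj, cell, correct, credit))

    def _travel(self) -> None:
        self._emit(_AOI_O, self._dur_frames(self.policy.travel_mean_s(self.cond)))

    def _hop(self) -> None:
        self._emit(_AOI_O, self._dur_frames(self.policy.hop_time_s))

    # -- sequence emission ---------------------------------------------------
    def emit_model_view(self, k: int) -> int:
        """Opening Model view encoding the next k features; returns its frame."""
        frame = self.n_frames
        mean = self.policy.encoding_mean_s(k, self.cond)
        self._emit(_AOI_M, self._dur_frames(mean))
        return frame

    def emit_body(self, tokens: list[tuple], identity_error: bool) -> dict:
        """Emit the non-Model body of one sequence.

        ``tokens`` are ('pickup', obj) / ('place', obj) /
        ('corr_pickup', obj) / ('corr_place', obj) actions; an identity
        error inserts a distractor pickup-and-drop at the first
        empty-handed Resource moment.
        """
        stats = {"n_pickups": 0, "n_places": 0, "identity_done": False}
        pending_identity = identity_error
        visited_resource = False
        prev_area = _AOI_M
        for kind, obj in tokens:
            if kind in ("pickup",):
                self._travel() if prev_area == _AOI_M else self._hop()
                if pending_identity:
                    self._inject_identity_error()
                    pending_identity = False
                    stats["identity_done"] = True
                self._emit(_AOI_R, self._dur_frames(self.policy.search_time_s),
                           event=("PICKUP", obj, None, None, True))
                visited_resource = True
                prev_area = _AOI_R
                stats["n_pickups"] += 1
            elif kind == "place":
                if prev_area == _AOI_M:
                    # carrying an object from the previous sequence: the
                    # walk to the Workspace passes the Resource area
                    self._travel()
                    self._emit(_AOI_R, self._dur_frames(self.policy.glance_time_s))
                    visited_resource = True
                else:
                    self._hop()
                cell = self.spec.cell_assignment[obj]
                self._emit(_AOI_W, self._dur_frames(self.policy.place_time_s),
                           event=("RELEASE", obj, cell, True, True))
                prev_area = _AOI_W
                stats["n_places"] += 1
            elif kind == "wrong_place":
                if prev_area == _AOI_M:
                    self._travel()
                    self._emit(_AOI_R, self._dur_frames(self.policy.glance_time_s))
                    visited_resource = True
                else:
                    self._hop()
                good = self.spec.cell_assignment[obj]
                wrong = int(self.rng.choice(
                    [c for c in range(len(self.spec.model_objects)) if c != good]))
                self._emit(_AOI_W, self._dur_frames(self.policy.place_time_s),
                           event=("RELEASE", obj, wrong, False, False))
                prev_area = _AOI_W
            elif kind == "corr_pickup":
                if prev_area == _AOI_M:
                    self._travel()
                else:
                    self._hop()
                self._emit(_AOI_W, self._dur_frames(self.policy.correction_pickup_s),
                           event=("PICKUP", obj, None, None, False))
                prev_area = _AOI_W
            elif kind == "corr_place":
                cell = self.spec.cell_assignment[obj]
                self._emit(_AOI_W, self._dur_frames(self.policy.place_time_s),
                           event=("RELEASE", obj, cell, True, False))
                prev_area = _AOI_W
            else:  # pragma: no cover - defensive
                raise RuntimeError(f"unknown token {kind}")
        if pending_identity:
            # no pickup slot came up empty-handed; err on the way back
            self._travel() if prev_area == _AOI_M else self._hop()
            self._inject_identity_error()
            visited_resource = True
            prev_area = _AOI_R
            stats["identity_done"] = True
        if not visited_resource:
            # guarantee the closing Model view qualifies: the return path
            # passes the Resource area
            self._hop()
            self._emit(_AOI_R, self._dur_frames(self.policy.glance_time_s))
            prev_area = _AOI_R
        self._travel()
        return stats

    def _inject_identity_error(self) -> None:
        """Pick up a distractor at the Resource, notice, and drop it."""
        distractor = int(self.rng.choice(self.spec.distractor_objects))
        self._emit(_AOI_R, self._dur_frames(self.policy.search_time_s),
                   event=("PICKUP", distractor, None, None, False))
        self._emit(_AOI_R, self._dur_frames(0.3),
                   event=("RELEASE", distractor, None, None, False))

    def emit_zero_sequence(self) -> None:
        self._travel()
        self._emit(_AOI_R, self._dur_frames(self.policy.zero_visit_time_s))
        self._travel()


def _plan_tokens(agenda: list[int], holding: int | None,
                 k: int) -> tuple[list[tuple], int | None, list[int]]:
    """Turn a feature budget k into alternating pickup/place tokens."""
    tokens: list[tuple] = []
    idx = 0
    for _ in range(k):
        if holding is None:
            obj = agenda[idx]
            idx += 1                  # a pickup consumes the agenda slot
            tokens.append(("pickup", obj))
            holding = obj
        else:
            tokens.append(("place", holding))
            holding = None
    return tokens, holding, agenda[idx:]


def simulate_display(spec: DisplaySpec, policy: AgentPolicy,
                     geometry: TaskGeometry, config: SimulationConfig,
                     rng: np.random.Generator,
                     meta: Mapping[str, int] | None = None,
                     ) -> tuple[dict, list[dict]]:
    """Simulate one display; returns (frame arrays, sequence ledger rows).

    The frame dict holds numpy columns for this display only.  Ledger rows
    record, per emitted sequence, the credited feature count ``k``, the
    intended count ``k_intended``, injected errors and the drawn initial
    Model dwell.
    """
    meta = dict(meta or {"participant": 1, "session": 1, "run": 1, "display": 1})
    cond = geometry.model_angle_deg
    total_features = 2 * len(spec.model_objects)
    pmf = policy.features_per_visit_pmf[cond]
    parts, capped = _draw_composition(pmf, total_features, rng)

    em = _DisplayEmitter(spec, policy, cond, config, rng, meta)
    agenda = [int(o) for o in rng.permutation(np.array(spec.model_objects))]
    holding: int | None = None
    pending_location = False
    plans: list[dict] = []

    # plan every sequence of the display up front
    queue = list(parts)
    prefix: list[tuple] = []          # corrective tokens carried into next seq
    leftover_budget = 0               # features deferred past a forced correction
    while queue or leftover_budget or prefix:
        if leftover_budget:
            k = leftover_budget
            leftover_budget = 0
            is_part = True
        elif queue:
            if holding is None and not prefix and rng.random() < policy.zero_feature_rate:
                k = 0
                is_part = False
            else:
                k = queue.pop(0)
                is_part = True
        else:
            k = 0
            is_part = False
        identity_err = rng.random() < policy.identity_error_rate
        if is_part and rng.random() < policy.location_error_rate:
            pending_location = True
        tokens, new_holding, new_agenda = _plan_tokens(agenda, holding, k)
        location_err = False
        if pending_location:
            for i, (tk, obj) in enumerate(tokens):
                if tk == "place":
                    location_err = True
                    pending_location = False
                    bad = tokens[: i] + [("wrong_place", obj)]
                    rest = tokens[i + 1:]
                    # remaining credited actions resume after the forced
                    # correction, in the next sequence
                    leftover_budget = len(rest)
                    # reconstruct holding state at the cut point
                    holding = None
                    agenda = new_agenda if not rest else _rewind(new_agenda, rest)
                    plans.append(dict(tokens=prefix + bad, k=i,
                                      k_intended=k, identity=identity_err,
                                      location=True, zero=(k == 0),
                                      capped=False, corrective=bool(prefix)))
                    prefix = [("corr_pickup", obj), ("corr_place", obj)]
                    break
        if location_err:
            continue
        plans.append(dict(tokens=prefix + tokens, k=k, k_intended=k,
                          identity=identity_err, location=False,
                          zero=(k == 0), capped=False,
                          corrective=bool(prefix)))
        prefix = []
        holding = new_holding
        agenda = new_agenda
    if plans and capped:
        plans[-1]["capped"] = True

    # emit frames
    timeout_frame = int(round(config.display_timeout_s * config.frame_rate_hz))
    for i, plan in enumerate(plans):
        dwell_frame = em.emit_model_view(plan["k"])
        stats = em.emit_body(plan["tokens"], plan["identity"])
        em.ledger.append({
            **meta, "condition_deg": cond, "seq_index": i,
            "k": plan["k"], "k_intended": plan["k_intended"],
            "n_pickups": stats["n_pickups"], "n_places": stats["n_places"],
            "has_identity_error": plan["identity"],
            "has_location_error": plan["location"],
            "is_zero": plan["zero"], "capped": plan["capped"],
            "has_corrective": plan["corrective"],
            "open_frame": dwell_frame, "truncated": False,
        })
    # closing verification glance so the final sequence ends at the Model
    em._emit(_AOI_M, em._dur_frames(0.4))

    frames = _segments_to_frames(em, meta, cond, config)
    ledger = em.ledger
    timed_out = em.n_frames > timeout_frame
    if timed_out:
        frames = {k: v[:timeout_frame] for k, v in frames.items()}
        kept = []
        for row in ledger:
            if row["open_frame"] >= timeout_frame:
                continue
            nxt = ledger[row["seq_index"] + 1]["open_frame"] \
                if row["seq_index"] + 1 < len(ledger) else em.n_frames
            if nxt > timeout_frame:
                row["truncated"] = True
                credited = [e for e in em.events
                            if row["open_frame"] <= e[0] < timeout_frame
                            and e[5]]
                row["k"] = len(credited)
                row["n_pickups"] = sum(1 for e in credited
                                       if e[1] == "PICKUP")
                row["n_places"] = sum(1 for e in credited
                                      if e[1] == "RELEASE")
            kept.append(row)
        ledger = kept
    for row in ledger:
        row["display_timed_out"] = timed_out
        row["display_completed"] = not timed_out
    return frames, ledger


def _rewind(agenda_after: list[int], rest: list[tuple]) -> list[int]:
    """Restore the agenda for tokens that were cut by a forced correction."""
    cut_objects = [obj for tk, obj in rest if tk == "pickup"]
    return cut_objects + agenda_after


def _segments_to_frames(em: _DisplayEmitter, meta, cond,
                        config: SimulationConfig) -> dict:
    codes = np.fromiter((a for a, _ in em.segments), dtype=np.int8,
                        count=len(em.segments))
    counts = np.fromiter((n for _, n in em.segments), dtype=np.int64,
                         count=len(em.segments))
    aoi_codes = np.repeat(codes, counts)
    n = len(aoi_codes)
    aoi = np.array(AOI_LABELS, dtype=object)[aoi_codes]
    controller = np.full(n, "NONE", dtype=object)
    gazed = np.full(n, np.nan)
    held = np.full(n, np.nan)
    cell = np.full(n, np.nan)
    correct = np.full(n, np.nan, dtype=object)
    state = np.nan
    last = 0
    for f, kind, obj, c, corr, _credit in em.events:
        held[last:f] = state
        controller[f] = kind
        if kind == "PICKUP":
            state = obj
            gazed[f] = obj
        else:  # RELEASE
            state = np.nan
            if c is not None:
                cell[f] = c
                correct[f] = bool(corr)
        held[f] = state
        last = f + 1
    held[last:] = state
    frames = {
        "participant": np.full(n, meta["participant"], dtype=np.int32),
        "session": np.full(n, meta["session"], dtype=np.int16),
        "run": np.full(n, meta["run"], dtype=np.int16),
        "condition_deg": np.full(n, cond, dtype=np.int16),
        "display": np.full(n, meta["display"], dtype=np.int16),
        "frame": np.arange(n, dtype=np.int64),
        "time_s": np.arange(n, dtype=np.float64) / config.frame_rate_hz,
        "aoi": aoi,
        "gazed_object": gazed,
        "controller_event": controller,
        "held_object": held,
        "placement_cell": cell,
        "placement_correct": correct,
    }
    return frames


def simulate_participant(participant: int, policy: AgentPolicy,
                         config: SimulationConfig,
                         rng: np.random.Generator,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All runs of one participant; returns (frames, ledger, displays)."""
    n_cond = len(CONDITIONS)
    reps = config.runs_per_participant // n_cond
    order = list(CONDITIONS) * reps
    rng.shuffle(order)
    frames_parts: list[dict] = []
    ledger_rows: list[dict] = []
    display_rows: list[dict] = []
    seen_arrangements: set = set()
    runs_in_session = max(1, config.runs_per_participant // 2)
    for run_idx, cond in enumerate(order, start=1):
        session = 1 if run_idx <= runs_in_session else 2
        geometry = TaskGeometry(model_angle_deg=cond)
        for disp_idx in range(1, config.displays_per_run + 1):
            while True:
                spec = generate_display(
                    config.pool_size, rng, display_id=disp_idx,
                    n_model=config.objects_per_display,
                    n_distractors=config.distractors_per_display)
                key = (spec.model_objects,
                       tuple(sorted(spec.cell_assignment.items())))
                if key not in seen_arrangements:
                    seen_arrangements.add(key)
                    break
            meta = {"participant": participant, "session": session,
                    "run": run_idx, "display": disp_idx}
            frames, ledger = simulate_display(
                spec, policy, geometry, config, rng, meta)
            frames_parts.append(frames)
            ledger_rows.extend(ledger)
            display_rows.append({
                **meta, "condition_deg": cond,
                "model_objects": ";".join(str(o) for o in spec.model_objects),
                "distractor_objects": ";".join(
                    str(o) for o in spec.distractor_objects),
                "cells": ";".join(
                    f"{o}:{c}" for o, c in sorted(spec.cell_assignment.items())),
                "timed_out": bool(ledger and ledger[0]["display_timed_out"]),
            })
    frames_df = pd.DataFrame(
        {c: np.concatenate([p[c] for p in frames_parts])
         for c in FRAME_COLUMNS})
    return frames_df, pd.DataFrame(ledger_rows), pd.DataFrame(display_rows)


def simulate_experiment(config: SimulationConfig | None = None,
                        policy: AgentPolicy | None = None,
                        rng_seed: int = 0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full experiment.

    Returns (frame log, sequence ledger, display manifest).  Each
    participant draws from an independent stream spawned from the master
    seed, so adding participants never perturbs earlier ones.
    """
    config = config or SimulationConfig()
    policy = policy or AgentPolicy()
    streams = np.random.SeedSequence(rng_seed).spawn(config.n_participants)
    frames_parts, ledger_parts, display_parts = [], [], []
    for p, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        f, l, d = simulate_participant(p, policy, config, rng)
        frames_parts.append(f)
        ledger_parts.append(l)
        display_parts.append(d)
    return (pd.concat(frames_parts, ignore_index=True),
            pd.concat(ledger_parts, ignore_index=True),
            pd.concat(display_parts, ignore_index=True))


def iter_participants(config: SimulationConfig, policy: AgentPolicy,
                      rng_seed: int):
    """Yield (participant, frames, ledger, displays) one at a time.

    Memory-friendly alternative to :func:`simulate_experiment` for
    experiment-scale runs.
    """
    streams = np.random.SeedSequence(rng_seed).spawn(config.n_participants)
    for p, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        f, l, d = simulate_participant(p, policy, config, rng)
        yield p, f, l, d


def add_gaze_noise(frames: pd.DataFrame, rng: np.random.Generator,
                   flicker_prob: float = 0.0) -> pd.DataFrame:
    """Relabel random single frames to a random AOI (spurious flickers).

    Disabled (prob 0) by default; the analysis consumes AOI labels, so
    this is the only noise channel that matters downstream.
    """
    if flicker_prob <= 0:
        return frames
    out = frames.copy()
    mask = rng.random(len(out)) < flicker_prob
    labels = rng.choice(np.array(AOI_LABELS, dtype=object), size=int(mask.sum()))
    col = out["aoi"].to_numpy(dtype=object, copy=True)
    col[np.flatnonzero(mask)] = labels
    out["aoi"] = col
    return out


# ---------------------------------------------------------------------------
# serialisation

def write_frame_log(frames: pd.DataFrame, path) -> None:
    """Write the frame-log CSV dialect (exact canonical header, NA for missing)."""
    out = frames.loc[:, FRAME_COLUMNS].copy()
    for col in ("gazed_object", "held_object", "placement_cell"):
        out[col] = out[col].astype("Int64")
    out["placement_correct"] = out["placement_correct"].map(
        {True: "True", False: "False"}).astype(object)
    out.to_csv(path, index=False, na_rep="NA")


def write_ledger(ledger: pd.DataFrame, path) -> None:
    ledger.to_csv(path, index=False, na_rep="NA")


def write_manifest(config: SimulationConfig, policy: AgentPolicy,
                   rng_seed: int, path) -> None:
    payload = {
        "config": dataclasses.asdict(config),
        "policy": {
            **{k: v for k, v in dataclasses.asdict(policy).items()
               if k != "features_per_visit_pmf"},
            "features_per_visit_pmf": {
                str(c): {str(k): p for k, p in pmf.items()}
                for c, pmf in policy.features_per_visit_pmf.items()},
        },
        "rng_seed": rng_seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
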