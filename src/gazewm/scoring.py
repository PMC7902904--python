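"""Features-in-memory scoring and per-condition aggregation.

Each sequence's feature count k is the number of object features the
participant *acted on* before re-fixating the Model: every non-corrective
pickup of a model object uses one identity feature, every non-corrective
correct placement uses one location feature.  Corrective actions and
distractor pickups earn nothing but set error flags.  Because each of
the 8 objects carries exactly 2 features, a completed, error-free
display always totals 16 features.

An object picked up in one sequence but placed in the next credits
identity to the first sequence and location to the second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequencing import Sequence

log = logging.getLogger(__name__)

K_BINS = ("0", "1", "2", "3", "4", ">4")


@dataclass(frozen=True)
class FeatureCount:
    sequence_id: int
    k: int
    n_identity: int
    n_location: int
    has_identity_error: bool
    has_location_error: bool
    n_corrective: int

    def __post_init__(self):
        assert self.k == self.n_identity + self.n_location


def count_features(seq: Sequence) -> FeatureCount:
    """Score one sequence from its assigned action events."""
    n_identity = n_location = n_corrective = 0
    identity_error = location_error = False
    for ev in seq.action_events:
        if ev.is_corrective:
            n_corrective += 1
            continue
        if ev.kind == "PICKUP":
            if ev.is_model_object is False:
                identity_error = True     # distractor pickup: no credit
            else:
                n_identity += 1
        elif ev.kind == "PLACE":
            if ev.correct_location:
                n_location += 1
            else:
                location_error = True     # wrong cell: no credit
    return FeatureCount(
        sequence_id=seq.sequence_id, k=n_identity + n_location,
        n_identity=n_identity, n_location=n_location,
        has_identity_error=identity_error, has_location_error=location_error,
        n_corrective=n_corrective)


def score_display(sequences: list[Sequence], meta: dict | None = None,
                  ) -> pd.DataFrame:
    """Score every sequence of one display into a tidy table."""
    rows = []
    for seq in sequences:
        fc = count_features(seq)
        rows.append({
            **(meta or {}),
            "sequence_id": seq.sequence_id,
            "start_s": seq.start_time_s, "end_s": seq.end_time_s,
            "initial_model_dwell_ms": seq.initial_model_dwell_ms,
            "k": fc.k, "n_identity": fc.n_identity,
            "n_location": fc.n_location,
            "n_pickups": sum(1 for e in seq.action_events
                             if e.kind == "PICKUP" and not e.is_corrective),
            "n_places": sum(1 for e in seq.action_events
                            if e.kind == "PLACE" and not e.is_corrective),
            "n_corrective": fc.n_corrective,
            "has_identity_error": fc.has_identity_error,
            "has_location_error": fc.has_location_error,
            "qualifying": seq.qualifying, "truncated": seq.truncated,
        })
    return pd.DataFrame(rows)


def tally_display(scored: pd.DataFrame, expected_total: int = 16,
                  completed: bool = True, error_free: bool | None = None,
                  ) -> tuple[int, bool]:
    """Sum credited features over a display's sequences.

    Returns (total, complete_flag).  For a display marked complete and
    error-free a total different from ``expected_total`` raises, since
    the identity "8 objects x 2 features = 16" must hold whenever no
    credit was lost to errors.
    """
    total = int(scored["k"].sum())
    if error_free is None:
        error_free = not bool(scored["has_identity_error"].any()
                              or scored["has_location_error"].any())
    if completed and error_free and total != expected_total:
        raise AssertionError(
            f"complete error-free display scored {total} features, "
            f"expected {expected_total}")
    return total, completed and total == expected_total


def feature_probabilities(scored: pd.DataFrame,
                          include_zero: bool = False,
                          include_truncated: bool = False,
                          include_errors: bool = False,
                          k_max_bin: int = 4) -> pd.DataFrame:
    """Per participant x condition distribution of feature counts (percent).

    Defaults mirror the reporting conventions of the reference analysis:
    zero-feature sequences are tallied separately, truncated sequences
    are dropped, and error-flagged sequences are dropped because their
    credited k is contaminated by the forced correction.  Counts above
    ``k_max_bin`` are binned as ">4" for reporting but retained exactly
    in ``mean_k``.
    """
    df = scored
    if not include_truncated:
        df = df[~df["truncated"]]
    if not include_errors:
        df = df[~(df["has_identity_error"] | df["has_location_error"])]
    if not include_zero:
        df = df[df["k"] > 0]
    rows = []
    for (p, cond), cell in df.groupby(["participant", "condition_deg"]):
        n = len(cell)
        if n == 0:
            log.warning("participant %s condition %s has no sequences", p, cond)
            continue
        k = cell["k"].to_numpy()
        pmf = {}
        for b in K_BINS:
            if b == ">4":
                pmf[b] = float(np.mean(k > k_max_bin) * 100)
            else:
                pmf[b] = float(np.mean(k == int(b)) * 100)
        rows.append({"participant": p, "condition_deg": cond,
                     "n_sequences": n, "mean_k": float(k.mean()),
                     **{f"pct_{b}": v for b, v in pmf.items()}})
    out = pd.DataFrame(rows)
    return out


def group_mean_probabilities(summary: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean over participants of the per-cell percentages."""
    cols = [c for c in summary.columns if c.startswith("pct_")] + ["mean_k"]
    return summary.groupby("condition_deg")[cols].mean().reset_index()


def error_rates(scored: pd.DataFrame,
                include_truncated: bool = False) -> dict:
    """Percent of sequences flagged with identity / location / any error."""
    df = scored if include_truncated else scored[~scored["truncated"]]
    n = len(df)
    if n == 0:
        return {"identity_pct": np.nan, "location_pct": np.nan,
                "any_pct": np.nan, "n_sequences": 0}
    ident = df["has_identity_error"].mean() * 100
    loc = df["has_location_error"].mean() * 100
    any_err = (df["has_identity_error"] | df["has_location_error"]).mean() * 100
    return {"identity_pct": float(ident), "location_pct": float(loc),
            "any_pct": float(any_err), "n_sequences": int(n)}


def fig2b_report(group_means: pd.DataFrame) -> str:
    """Plain-text table of feature-use probabilities by condition."""
    lines = ["Probability of using k features in memory (percent, group mean)",
             "condition_deg  " + "  ".join(f"{b:>6}" for b in K_BINS)
             + "   mean_k"]
    for _, row in group_means.sort_values("condition_deg").iterrows():
        vals = "  ".join(f"{row[f'pct_{b}']:6.1f}" for b in K_BINS)
        lines.append(f"{int(row['condition_deg']):>13}  {vals}   {row['mean_k']:.2f}")
    return "\n".join(lines)
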