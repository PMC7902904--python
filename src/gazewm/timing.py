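"""Viewing-time and completion-time metrics.

The *initial model viewing time* of a sequence is the summed duration of
Model-AOI gaze from the sequence's opening sample until the first
Resource visit; it proxies encoding duration and is filtered to the
closed interval [50, 2000] ms and to sequences using 1-4 features.
*Display completion time* is the sum of the display's sequence durations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DWELL_MIN_MS = 50.0
DWELL_MAX_MS = 2000.0
K_RANGE = (1, 4)


@dataclass(frozen=True)
class ViewingTime:
    sequence_id: int
    initial_model_dwell_ms: float
    included: bool


def model_viewing_time(seq, k: int | None = None) -> ViewingTime:
    """Viewing time of one (already segmented) sequence.

    The dwell itself is computed during segmentation (Model samples up
    to the first Resource visit, Workspace/OTHER interludes uncounted);
    this applies the inclusion rule.
    """
    dwell = seq.initial_model_dwell_ms
    ok = DWELL_MIN_MS <= dwell <= DWELL_MAX_MS
    if k is not None:
        ok = ok and K_RANGE[0] <= k <= K_RANGE[1]
    return ViewingTime(seq.sequence_id, dwell, bool(ok))


def filter_viewing_times(scored: pd.DataFrame,
                         dwell_bounds: tuple[float, float] = (DWELL_MIN_MS,
                                                              DWELL_MAX_MS),
                         k_range: tuple[int, int] = K_RANGE,
                         ) -> tuple[pd.DataFrame, dict]:
    """Apply the dwell and k filters to a scored sequence table.

    Returns the included subset and an exclusion report.  The dwell
    bounds are closed ("below 50 ms"/"above 2000 ms" excluded); the k
    restriction mirrors the 1-4 feature analysis window.  The excluded
    fraction is reported relative to sequences already in the k window,
    so it corresponds to the "<1% of the data" style statement.
    """
    df = scored[~scored["truncated"]]
    in_k = df[(df["k"] >= k_range[0]) & (df["k"] <= k_range[1])]
    dwell = in_k["initial_model_dwell_ms"]
    kept = in_k[(dwell >= dwell_bounds[0]) & (dwell <= dwell_bounds[1])]
    report = {
        "n_in_k_range": int(len(in_k)),
        "n_included": int(len(kept)),
        "n_excluded_dwell": int(len(in_k) - len(kept)),
        "excluded_fraction": float(1 - len(kept) / len(in_k)) if len(in_k) else 0.0,
    }
    return kept, report


def display_completion_time(scored_display: pd.DataFrame,
                            timeout_s: float = 45.0) -> dict:
    """Completion time and mean feature use of one display.

    ``total_s`` sums sequence durations (equivalently last close minus
    first open, since adjacent sequences share boundaries).  Truncated
    displays are flagged; they are excluded from the completion-time
    analysis by default.
    """
    durations = scored_display["end_s"] - scored_display["start_s"]
    total = float(durations.sum())
    truncated = bool(scored_display["truncated"].any())
    ks = scored_display.loc[scored_display["k"] > 0, "k"]
    return {
        "total_s": total,
        "mean_k_display": float(ks.mean()) if len(ks) else 0.0,
        "n_sequences": int(len(scored_display)),
        "truncated": truncated,
        "within_timeout": total <= timeout_s + 1.0 / 90.0,
    }


def completion_table(scored: pd.DataFrame, timeout_s: float = 45.0,
                     include_truncated: bool = False) -> pd.DataFrame:
    """Per-display completion times for a full scored sequence table."""
    rows = []
    keys = ["participant", "run", "display"]
    for key, block in scored.groupby(keys):
        rec = display_completion_time(block, timeout_s=timeout_s)
        if rec["truncated"] and not include_truncated:
            continue
        rows.append({**dict(zip(keys, key)),
                     "condition_deg": int(block["condition_deg"].iloc[0]),
                     **rec})
    return pd.DataFrame(rows)
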