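import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gazewm as gw
from gazewm.ingest import AoiVisit, model_objects_from_manifest

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Two participants at full per-participant scale, default policy."""
    config = gw.SimulationConfig(n_participants=2)
    frames, ledger, displays = gw.simulate_experiment(config, rng_seed=1)
    mapping = model_objects_from_manifest(displays)
    scored = gw.build_sequence_table(frames, mapping)
    return {"config": config, "frames": frames, "ledger": ledger,
            "displays": displays, "mapping": mapping, "scored": scored}


def make_visits(pattern, dur=1.0):
    """Build AoiVisit lists from compact patterns like "M,R,M".

    An element may carry an explicit duration in ms: "M:300".
    """
    label = {"M": "MODEL", "R": "RESOURCE", "W": "WORKSPACE", "O": "OTHER"}
    visits = []
    t = 0.0
    for i, tok in enumerate(pattern.split(",")):
        if ":" in tok:
            a, ms = tok.split(":")
            d = float(ms) / 1000.0
        else:
            a, d = tok, dur
        visits.append(AoiVisit(aoi=label[a], start_time_s=t,
                               end_time_s=t + d, n_frames=max(1, int(d * 90)),
                               start_frame=int(t * 90)))
        t += d
    return visits


def make_frames(aoi_pattern, events=(), frame_rate=90.0, **meta):
    """Small canonical frame-log block from an AOI pattern and events.

    ``events`` holds (frame_index, kind, object_id, cell, correct).
    """
    label = {"M": "MODEL", "R": "RESOURCE", "W": "WORKSPACE", "O": "OTHER"}
    aoi = [label[c] for c in aoi_pattern.replace(",", "")]
    n = len(aoi)
    meta = {"participant": 1, "session": 1, "run": 1, "condition_deg": 0,
            "display": 1, **meta}
    df = pd.DataFrame({
        **{k: np.full(n, v) for k, v in meta.items()},
        "frame": np.arange(n), "time_s": np.arange(n) / frame_rate,
        "aoi": aoi, "gazed_object": np.nan,
        "controller_event": "NONE", "held_object": np.nan,
        "placement_cell": np.nan,
        "placement_correct": pd.Series([np.nan] * n, dtype=object),
    })
    state = np.nan
    last = 0
    held = np.full(n, np.nan)
    for f, kind, obj, cell, correct in events:
        held[last:f] = state
        df.loc[f, "controller_event"] = kind
        if kind == "PICKUP":
            state = obj
        else:
            state = np.nan
            if cell is not None:
                df.loc[f, "placement_cell"] = cell
                df.loc[f, "placement_correct"] = correct
        held[f] = state
        last = f + 1
    held[last:] = state
    df["held_object"] = held
    df["placement_correct"] = df["placement_correct"].map(
        {1.0: True, 0.0: False, True: True, False: False})
    return df
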