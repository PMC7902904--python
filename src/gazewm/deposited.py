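"""Adapter for externally deposited frame logs.

Published datasets for this task family ship post-processed CSVs whose
column names and codings differ from the canonical frame-log dialect
this package writes.  This module maps such a file onto the canonical
schema via a declarative column mapping, after which the ordinary
pipeline applies unchanged, and exposes convenience entry points that
recompute the headline quantities (feature-use probability table, the
linear-locomotion Poisson GLMM coefficient, and the first planned
pairwise t test) from any frame log in the canonical dialect.

The exact schema of a given deposit must be supplied by the analyst as
a :class:`ColumnMapping`; it cannot be fixed here in advance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import ingest
from .pipeline import PipelineConfig, analyze
from .simulate import FRAME_COLUMNS
from .stats import fit_feature_ladder, paired_tests


@dataclass
class ColumnMapping:
    """Rename/recode recipe from a deposited schema to the canonical one.

    ``columns`` maps canonical name -> deposited name; ``aoi_codes``
    maps deposited gaze labels to MODEL/RESOURCE/WORKSPACE/OTHER;
    ``event_codes`` maps deposited controller codes to
    NONE/PICKUP/RELEASE.  Canonical columns absent from ``columns`` are
    filled with defaults (session 1, NA object ids).
    """

    columns: Mapping[str, str]
    aoi_codes: Mapping[str, str] = field(default_factory=dict)
    event_codes: Mapping[str, str] = field(default_factory=dict)
    condition_levels: Mapping[object, int] = field(default_factory=dict)


_DEFAULTS = {"session": 1, "gazed_object": np.nan, "held_object": np.nan,
             "placement_cell": np.nan, "placement_correct": np.nan,
             "controller_event": "NONE"}


def adapt_frame_log(raw: pd.DataFrame, mapping: ColumnMapping) -> pd.DataFrame:
    """Return a canonical frame log built from a deposited table."""
    out = pd.DataFrame(index=raw.index)
    for canon in FRAME_COLUMNS:
        src = mapping.columns.get(canon)
        if src is not None:
            if src not in raw.columns:
                raise ingest.SchemaError(
                    f"mapped column {src!r} (for {canon!r}) not in input")
            out[canon] = raw[src]
        elif canon in _DEFAULTS:
            out[canon] = _DEFAULTS[canon]
        else:
            raise ingest.SchemaError(f"no mapping for required column {canon!r}")
    if mapping.aoi_codes:
        out["aoi"] = out["aoi"].map(lambda v: mapping.aoi_codes.get(v, v))
    if mapping.event_codes:
        out["controller_event"] = out["controller_event"].map(
            lambda v: mapping.event_codes.get(v, v))
    if mapping.condition_levels:
        out["condition_deg"] = out["condition_deg"].map(
            lambda v: mapping.condition_levels.get(v, v))
    for col, dt in (("participant", "int32"), ("session", "int16"),
                    ("run", "int16"), ("condition_deg", "int16"),
                    ("display", "int16"), ("frame", "int64"),
                    ("time_s", "float64")):
        out[col] = out[col].astype(dt)
    ingest.validate_frame_log(out)
    return out


def recompute_headline_results(frames: pd.DataFrame,
                               model_objects_map=None,
                               config: PipelineConfig | None = None) -> dict:
    """Feature-probability table, linear GLMM coefficient and the first
    planned paired t test, recomputed from a canonical frame log."""
    config = config or PipelineConfig(stats_level="none")
    result = analyze(frames, config, model_objects_map=model_objects_map)
    df = result.scored
    df = df[~df["truncated"]
            & ~(df["has_identity_error"] | df["has_location_error"])]
    fits = fit_feature_ladder(df["k"].to_numpy(),
                              df["condition_deg"].to_numpy(),
                              df["participant"].to_numpy(),
                              models=("linear",), seed=config.seed)
    linear = fits["linear"].fixed_effects.loc["linear"]
    first_t = paired_tests(result.summary, k_levels=(1,),
                           neighbor_pairs=((0, 45),))[0]
    return {
        "probabilities": result.group_means,
        "glmm_linear_beta": float(linear["estimate"]),
        "glmm_linear_se": float(linear["se"]),
        "glmm_linear_z": float(linear["z"]),
        "first_paired_test": first_t,
    }
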