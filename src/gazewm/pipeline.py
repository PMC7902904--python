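"""End-to-end analysis pipeline: frames -> visits -> sequences -> scores
-> timing -> statistics, with a row-count audit at every stage."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ingest, scoring, timing
from .sequencing import QualificationRule, segment_display
from .stats import (LmmSpec, fit_feature_ladder, fit_lmm, lr_ladder,
                    make_predictors, paired_tests, paired_tests_table)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Switches controlling segmentation, filtering and reporting."""

    accept_workspace_qualifier: bool = False
    include_zero_in_probabilities: bool = False
    include_errors_in_probabilities: bool = False
    include_zero_in_glmm: bool = True
    dwell_bounds_ms: tuple[float, float] = (timing.DWELL_MIN_MS,
                                            timing.DWELL_MAX_MS)
    k_range: tuple[int, int] = timing.K_RANGE
    display_timeout_s: float = 45.0
    stats_level: str = "scoring"      # none | scoring | full
    seed: int = 0

    def validate(self) -> None:
        if self.stats_level not in ("none", "scoring", "full"):
            raise ValueError(f"unknown stats_level {self.stats_level!r}")
        lo, hi = self.dwell_bounds_ms
        if not 0 <= lo < hi:
            raise ValueError("dwell bounds must satisfy 0 <= low < high")
        if self.k_range[0] < 0 or self.k_range[0] > self.k_range[1]:
            raise ValueError("invalid k range")


def build_sequence_table(frames: pd.DataFrame,
                         model_objects_map=None,
                         rule: QualificationRule | None = None,
                         counts: dict | None = None) -> pd.DataFrame:
    """Segment and score every display of a frame log."""
    rule = rule or QualificationRule()
    parts = []
    n_visits = n_events = 0
    for meta, block in ingest.iter_displays(frames):
        visits = ingest.compress_visits(block)
        key = (meta["participant"], meta["run"], meta["display"])
        model_objects = (model_objects_map.get(key)
                         if model_objects_map else None)
        events = ingest.derive_events(block, model_objects=model_objects)
        n_visits += len(visits)
        n_events += len(events)
        sequences = segment_display(visits, events, rule)
        parts.append(scoring.score_display(sequences, meta=meta))
    scored = pd.concat([p for p in parts if len(p)], ignore_index=True) \
        if parts else pd.DataFrame()
    if counts is not None:
        counts.update(frames=len(frames), visits=n_visits, events=n_events,
                      sequences=len(scored))
    return scored


@dataclass
class AnalysisResult:
    scored: pd.DataFrame
    summary: pd.DataFrame
    group_means: pd.DataFrame
    error_rates: dict
    viewing: pd.DataFrame
    viewing_report: dict
    completion: pd.DataFrame
    paired: pd.DataFrame | None = None
    ladder: pd.DataFrame | None = None
    ladder_fits: dict = field(default_factory=dict)
    lmm_fits: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def report(self) -> str:
        lines = [scoring.fig2b_report(self.group_means), ""]
        er = self.error_rates
        lines.append(
            f"Error rates over {er['n_sequences']} sequences: "
            f"identity {er['identity_pct']:.1f}%, "
            f"location {er['location_pct']:.1f}%, any {er['any_pct']:.1f}%")
        vr = self.viewing_report
        lines.append(
            f"Viewing-time filter: kept {vr['n_included']} of "
            f"{vr['n_in_k_range']} sequences "
            f"({vr['excluded_fraction'] * 100:.2f}% excluded)")
        lines.append("Stage row counts: " + ", ".join(
            f"{k}={v}" for k, v in self.counts.items()))
        if self.paired is not None:
            lines += ["", "Planned pairwise t tests:",
                      self.paired.to_string(index=False)]
        if self.ladder is not None:
            lines += ["", "Locomotion predictor ladder (Poisson GLMM):",
                      self.ladder.to_string(index=False)]
        for name, fit in self.lmm_fits.items():
            lines += ["", f"{name}:", fit.summary()]
        return "\n".join(lines)


def analyze(frames: pd.DataFrame, config: PipelineConfig | None = None,
            model_objects_map=None, scored: pd.DataFrame | None = None,
            ) -> AnalysisResult:
    """Run the full pipeline on a frame log (or a pre-scored table)."""
    config = config or PipelineConfig()
    config.validate()
    counts: dict = {}
    if scored is None:
        rule = QualificationRule(config.accept_workspace_qualifier)
        scored = build_sequence_table(frames, model_objects_map, rule, counts)
    summary = scoring.feature_probabilities(
        scored, include_zero=config.include_zero_in_probabilities,
        include_errors=config.include_errors_in_probabilities)
    group_means = scoring.group_mean_probabilities(summary)
    errors = scoring.error_rates(scored)
    viewing, vreport = timing.filter_viewing_times(
        scored, dwell_bounds=config.dwell_bounds_ms, k_range=config.k_range)
    counts["viewing_included"] = len(viewing)
    completion = timing.completion_table(
        scored, timeout_s=config.display_timeout_s)
    result = AnalysisResult(scored=scored, summary=summary,
                            group_means=group_means, error_rates=errors,
                            viewing=viewing, viewing_report=vreport,
                            completion=completion, counts=counts)
    if config.stats_level in ("scoring", "full"):
        result.paired = paired_tests_table(paired_tests(summary))
    if config.stats_level == "full":
        _run_full_stats(result, config)
    return result


def _glmm_data(scored: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    df = scored[~scored["truncated"]]
    df = df[~(df["has_identity_error"] | df["has_location_error"])]
    if not config.include_zero_in_glmm:
        df = df[df["k"] > 0]
    return df.reset_index(drop=True)


def _run_full_stats(result: AnalysisResult, config: PipelineConfig) -> None:
    df = _glmm_data(result.scored, config)
    fits = fit_feature_ladder(df["k"].to_numpy(),
                              df["condition_deg"].to_numpy(),
                              df["participant"].to_numpy(),
                              seed=config.seed)
    result.ladder_fits = fits
    result.ladder = lr_ladder(fits)
    result.lmm_fits["viewing time LMM"] = fit_lmm(
        viewing_lmm_spec(result.viewing))
    comp = result.completion[result.completion["within_timeout"]]
    result.lmm_fits["completion time LMM"] = fit_lmm(
        completion_lmm_spec(comp))


def _ortho_quad(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal linear/quadratic columns of x, z-scaled over the design."""
    V = np.column_stack([np.ones_like(x), x, x ** 2])
    Q, _ = np.linalg.qr(V)

    def z(c):
        s = c.std(ddof=0)
        return (c - c.mean()) / s if s > 0 else c - c.mean()

    return z(Q[:, 1]), z(Q[:, 2])


def viewing_lmm_spec(viewing: pd.DataFrame) -> LmmSpec:
    """Model log viewing time by features-in-memory (orthogonal linear +
    quadratic) crossed with locomotion, maximal by-participant structure."""
    df = viewing.copy()
    df["log_dwell"] = np.log(df["initial_model_dwell_ms"].astype(float))
    k_lin, k_quad = _ortho_quad(df["k"].to_numpy(float))
    df["k_lin"], df["k_quad"] = k_lin, k_quad
    df["loco"] = make_predictors(df["condition_deg"].to_numpy())["linear"].to_numpy()
    df["k_lin_x_loco"] = df["k_lin"] * df["loco"]
    df["k_quad_x_loco"] = df["k_quad"] * df["loco"]
    fixed = ["k_lin", "k_quad", "loco", "k_lin_x_loco", "k_quad_x_loco"]
    return LmmSpec(df, "log_dwell", fixed, "participant",
                   random_slopes=list(fixed))


def completion_lmm_spec(completion: pd.DataFrame) -> LmmSpec:
    """Model log display completion time by the display's mean feature
    use (orthogonal linear + quadratic) and locomotion."""
    df = completion.copy()
    df["log_total"] = np.log(df["total_s"].astype(float))
    k_lin, k_quad = _ortho_quad(df["mean_k_display"].to_numpy(float))
    df["k_lin"], df["k_quad"] = k_lin, k_quad
    df["loco"] = make_predictors(df["condition_deg"].to_numpy())["linear"].to_numpy()
    df["k_lin_x_loco"] = df["k_lin"] * df["loco"]
    df["k_quad_x_loco"] = df["k_quad"] * df["loco"]
    fixed = ["k_lin", "k_quad", "loco", "k_lin_x_loco", "k_quad_x_loco"]
    return LmmSpec(df, "log_total", fixed, "participant",
                   random_slopes=list(fixed))


def compare_with_ledger(scored: pd.DataFrame, ledger: pd.DataFrame,
                        include_timed_out: bool = False) -> dict:
    """Scorer-vs-ground-truth agreement on per-sequence feature counts.

    Sequences are matched positionally within each display (the
    simulator's ledger order is emission order, which is time order).
    Timed-out displays are excluded by default; the ledger marks them
    for exclusion because the timeout can cut a sequence mid-action.
    """
    keys = ["participant", "run", "display"]
    if not include_timed_out and "display_timed_out" in ledger.columns:
        ledger = ledger[~ledger["display_timed_out"]]
        good = ledger[keys].drop_duplicates()
        scored = scored.merge(good, on=keys)
    s = scored.sort_values(keys + ["sequence_id"])
    l = ledger.sort_values(keys + ["seq_index"])
    total = agree = count_match = 0
    l_groups = {k: g for k, g in l.groupby(keys)}
    for key, sg in s.groupby(keys):
        lg = l_groups.get(key)
        if lg is None:
            continue
        ks = sg["k"].to_numpy()
        kl = lg["k"].to_numpy()
        m = min(len(ks), len(kl))
        agree += int(np.sum(ks[:m] == kl[:m]))
        total += max(len(ks), len(kl))
        count_match += int(len(ks) == len(kl))
    return {"k_agreement": agree / total if total else np.nan,
            "n_sequences": total,
            "display_count_match": count_match,
            "n_displays": len(l_groups)}
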