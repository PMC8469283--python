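"""Session-level recovery statistics.

Aggregates per-session encoding (MIC over unit-muscle pairs) and decoding
(per-muscle VAF) summaries into a recovery time course, and tests it:
Kruskal-Wallis rank ANOVA for the drop between pre-lesion sessions and the
first post-lesion session (and across all sessions), and the Spearman rank
correlation of each summary against post-lesion day index for the monotonic
recovery trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decoder import DecodingResult
from .preprocess import StepStats


class ParameterError(ValueError):
    pass


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-squared p across groups."""
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ParameterError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # identical values: no evidence of any difference
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def spearman_trend(day_indices: np.ndarray,
                   values: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with two-sided p."""
    day_indices = np.asarray(day_indices, dtype=float)
    values = np.asarray(values, dtype=float)
    if day_indices.size != values.size or day_indices.size < 3:
        raise ParameterError("need >= 3 paired observations")
    if np.all(values == values[0]):
        raise ParameterError("Spearman rho undefined for constant values")
    rho, p = stats.spearmanr(day_indices, values)
    return float(rho), float(p)


@dataclass
class SessionSummary:
    """One row of the recovery time course."""

    session_id: str
    day_index: int
    phase: str
    n_units: int
    muscles: list[str]
    mic_values: dict[str, np.ndarray]     # per muscle: MIC over units
    mic_mean: dict[str, float]
    mic_sd: dict[str, float]
    vaf_mean: dict[str, float]
    vaf_sem: dict[str, float]
    total_steps: int
    mean_consecutive_steps: float


def summarize_session(session_id: str, day_index: int,
                      mic_matrix: np.ndarray, muscles: list[str],
                      decoding: DecodingResult | None,
                      steps: StepStats) -> SessionSummary:
    """Collapse per-(unit, muscle) MIC values and fold VAFs into one record.

    ``mic_matrix`` is (n_units, n_muscles); MIC is summarised as mean +/- SD
    over the unit population, VAF as mean +/- s.e.m. over folds.  The order
    of units does not affect any summary.
    """
    mic_matrix = np.atleast_2d(np.asarray(mic_matrix, dtype=float))
    if mic_matrix.shape[1] != len(muscles):
        raise ParameterError("mic_matrix column count != number of muscles")
    mic_values = {m: mic_matrix[:, j].copy() for j, m in enumerate(muscles)}
    mic_mean = {m: float(v.mean()) for m, v in mic_values.items()}
    mic_sd = {m: float(v.std(ddof=1)) if v.size > 1 else 0.0
              for m, v in mic_values.items()}
    if decoding is not None:
        vaf_summary = decoding.summary()
        vaf_mean = {m: vaf_summary.get(m, (np.nan, np.nan))[0]
                    for m in muscles}
        vaf_sem = {m: vaf_summary.get(m, (np.nan, np.nan))[1]
                   for m in muscles}
    else:
        vaf_mean = {m: np.nan for m in muscles}
        vaf_sem = {m: np.nan for m in muscles}
    return SessionSummary(
        session_id=session_id, day_index=day_index,
        phase="pre" if day_index < 0 else "post",
        n_units=int(mic_matrix.shape[0]), muscles=list(muscles),
        mic_values=mic_values, mic_mean=mic_mean, mic_sd=mic_sd,
        vaf_mean=vaf_mean, vaf_sem=vaf_sem,
        total_steps=steps.total, mean_consecutive_steps=steps.mean)


@dataclass
class RecoveryTimecourse:
    """Ordered session summaries plus the study-level statistics."""

    sessions: list[SessionSummary]
    mic_trend: dict[str, tuple[float, float]] = field(default_factory=dict)
    vaf_trend: dict[str, tuple[float, float]] = field(default_factory=dict)
    kruskal_all_sessions: dict[str, tuple[float, float]] = field(
        default_factory=dict)
    kruskal_pre_vs_first_post: dict[str, tuple[float, float]] = field(
        default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(session, muscle) results table."""
        rows = []
        for s in self.sessions:
            for m in s.muscles:
                rows.append({
                    "session_id": s.session_id,
                    "day_index": s.day_index,
                    "phase": s.phase,
                    "muscle": m,
                    "mic_mean": s.mic_mean[m],
                    "mic_sd": s.mic_sd[m],
                    "vaf_mean": s.vaf_mean[m],
                    "vaf_sem": s.vaf_sem[m],
                    "units": s.n_units,
                    "total_steps": s.total_steps,
                    "mean_consecutive_steps": s.mean_consecutive_steps,
                })
        return pd.DataFrame(rows)


def build_timecourse(summaries: list[SessionSummary]) -> RecoveryTimecourse:
    """Assemble the time course and compute its trend statistics.

    Spearman trends are computed over post-lesion sessions only (MIC means
    and VAF means per muscle against day index).  Kruskal-Wallis is emitted
    in both groupings: across all sessions, and pre-lesion pooled versus the
    first post-lesion session.
    """
    summaries = sorted(summaries, key=lambda s: s.day_index)
    days = [s.day_index for s in summaries]
    if len(set(days)) != len(days):
        raise ParameterError("day indices must be strictly increasing")
    tc = RecoveryTimecourse(sessions=summaries)
    if not summaries:
        return tc
    muscles = summaries[0].muscles
    post = [s for s in summaries if s.phase == "post"]
    pre = [s for s in summaries if s.phase == "pre"]

    for m in muscles:
        if len(post) >= 3:
            post_days = np.array([s.day_index for s in post])
            mic_means = np.array([s.mic_mean[m] for s in post])
            vaf_means = np.array([s.vaf_mean[m] for s in post])
            try:
                tc.mic_trend[m] = spearman_trend(post_days, mic_means)
            except ParameterError:
                pass
            if np.all(np.isfinite(vaf_means)):
                try:
                    tc.vaf_trend[m] = spearman_trend(post_days, vaf_means)
                except ParameterError:
                    pass
        groups = [s.mic_values[m] for s in summaries if s.mic_values[m].size]
        if len(groups) >= 2:
            tc.kruskal_all_sessions[m] = kruskal_wallis(groups)
        if pre and post:
            pre_pool = np.concatenate([s.mic_values[m] for s in pre])
            first_post = post[0].mic_values[m]
            if pre_pool.size and first_post.size:
                tc.kruskal_pre_vs_first_post[m] = kruskal_wallis(
                    [pre_pool, first_post])
    return tc


__all__ = [
    "ParameterError",
    "RecoveryTimecourse",
    "SessionSummary",
    "build_timecourse",
    "kruskal_wallis",
    "spearman_trend",
    "summarize_session",
]
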