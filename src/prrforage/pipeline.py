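"""End-to-end dataset analysis: observed vs. optimal bout lengths.

For every PRR session the pipeline measures the median bout length and the
work tempo, computes the session-specific rate-maximizing bout length from
that tempo and the session's reset delay, and reports the difference as
*excess ratios* — positive values indicate overharvesting (staying in the
depleting patch longer than the rate-maximizing policy).  PR sessions
contribute breakpoint rows for the cross-task trait analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bouts import compute_session_metrics, segment_bouts
from .optimality import OptimalityParams, optimal_bout_length
from .session import EventLog, EventLogError, read_event_log

__all__ = [
    "QCConfig",
    "PipelineResult",
    "InsufficientSubjectsError",
    "analyze_session",
    "analyze_dataset",
    "correlate_across_tasks",
]

SESSION_COLUMNS = [
    "session_id", "subject_id", "sex", "task", "reset_delay_s",
    "observed_bout_length", "press_rate", "n_opt", "excess_ratios",
    "breakpoint", "active_presses", "reset_presses", "pellets",
    "n_bouts_complete", "median_reward_latency_s", "median_work_latency_s",
    "qc_flags",
]


class InsufficientSubjectsError(ValueError):
    """Too few subjects with data in both tasks of a pair."""


@dataclass(frozen=True)
class QCConfig:
    """Quality-control thresholds.

    Sessions with fewer reset presses than ``min_reset_presses`` are
    flagged (mirroring exclusion of subjects that essentially never used
    the reset lever); flagged sessions stay in the output table but are
    excluded from the summary statistics.
    """

    min_reset_presses: int = 1


@dataclass
class PipelineResult:
    """Comparison table, summary statistics and QC log."""

    sessions: pd.DataFrame
    summary: dict
    qc_log: list[str] = field(default_factory=list)


def analyze_session(log: EventLog, handling_time_s: float = 2.0,
                    qc: QCConfig = QCConfig(), rate_mode: str = "ipi") -> dict:
    """One SessionComparison row from a single event log."""
    bouts = segment_bouts(log)
    m = compute_session_metrics(log, bouts, rate_mode=rate_mode)
    flags: list[str] = []
    is_prr = log.meta.task == "PRR"
    if is_prr and m.reset_presses < qc.min_reset_presses:
        flags.append("low_reset_presses")
    if is_prr and m.n_bouts_complete == 0:
        flags.append("no_complete_bouts")

    n_opt: Optional[int] = None
    excess: Optional[float] = None
    if is_prr and m.press_rate is not None:
        n_opt = optimal_bout_length(OptimalityParams(
            press_rate=m.press_rate, reset_delay_s=float(log.meta.reset_delay_s),
            handling_time_s=handling_time_s)).n_opt
        if m.median_bout_length is not None:
            excess = m.median_bout_length - n_opt

    return dict(
        session_id=log.meta.session_id,
        subject_id=log.meta.subject_id,
        sex=log.meta.sex,
        task=log.meta.task,
        reset_delay_s=log.meta.reset_delay_s,
        observed_bout_length=m.median_bout_length,
        press_rate=m.press_rate,
        n_opt=n_opt,
        excess_ratios=excess,
        breakpoint=m.breakpoint,
        active_presses=m.active_presses,
        reset_presses=m.reset_presses,
        pellets=m.pellets,
        n_bouts_complete=m.n_bouts_complete,
        median_reward_latency_s=m.median_reward_latency_s,
        median_work_latency_s=m.median_work_latency_s,
        qc_flags=";".join(flags),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def _summarize(df: pd.DataFrame) -> dict:
    """Summary over QC-clean PRR sessions with measurable bout lengths."""
    prr = df[(df["task"] == "PRR") & (df["qc_flags"] == "")
             & df["observed_bout_length"].notna() & df["n_opt"].notna()]
    summary: dict = {
        "n_sessions": int(len(df)),
        "n_prr_sessions": int((df["task"] == "PRR").sum()),
        "n_prr_sessions_used": int(len(prr)),
    }
    if len(prr) >= 3:
        summary["pearson_r_observed_vs_optimal"] = _pearson(
            prr["observed_bout_length"].to_numpy(float), prr["n_opt"].to_numpy(float))
    by_delay = {}
    for delay, grp in prr.groupby("reset_delay_s"):
        if len(grp) >= 3:
            by_delay[f"{delay:g}"] = _pearson(
                grp["observed_bout_length"].to_numpy(float), grp["n_opt"].to_numpy(float))
    summary["pearson_r_by_delay"] = by_delay
    if len(prr):
        summary["fraction_observed_le_optimal"] = float(
            (prr["observed_bout_length"] <= prr["n_opt"]).mean())
        summary["mean_excess_ratios"] = float(prr["excess_ratios"].mean())
        summary["mean_excess_ratios_by_subject"] = {
            str(k): float(v) for k, v in
            prr.groupby("subject_id")["excess_ratios"].mean().items()}
        summary["mean_excess_ratios_by_sex"] = {
            str(k): float(v) for k, v in
            prr.groupby("sex")["excess_ratios"].mean().items()}
    return summary


def analyze_dataset(
    dataset_dir: str | Path,
    handling_time_s: float = 2.0,
    qc: QCConfig = QCConfig(),
    rate_mode: str = "ipi",
) -> PipelineResult:
    """Analyze a directory of session files (event CSV + metadata sidecar).

    Every readable session contributes one row; unreadable sessions are
    skipped with a QC log entry.  The summary reports the Pearson
    correlation of observed vs. optimal bout length (overall and per reset
    delay), the fraction of sessions at or below the optimum, and mean
    excess ratios overall and by subject and sex.
    """
    dataset_dir = Path(dataset_dir)
    paths = sorted(p for p in dataset_dir.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no session files in {dataset_dir}")
    rows, qc_log = [], []
    for p in paths:
        try:
            log = read_event_log(p)
        except EventLogError as exc:
            qc_log.append(f"SKIP {p.name}: {exc}")
            continue
        rows.append(analyze_session(log, handling_time_s=handling_time_s,
                                    qc=qc, rate_mode=rate_mode))
    if not rows:
        raise FileNotFoundError(f"no readable session files in {dataset_dir}")
    df = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    return PipelineResult(sessions=df, summary=_summarize(df), qc_log=qc_log)


def _task_label(row) -> str:
    if row["task"] == "PR":
        return "PR"
    return f"PRR-{row['reset_delay_s']:g}"


def correlate_across_tasks(sessions: pd.DataFrame, min_subjects: int = 3) -> pd.DataFrame:
    """Pearson correlation of per-subject average bout length between tasks.

    A subject's value per task is the mean of session medians (PRR) or the
    mean breakpoint (PR).  Raises :class:`InsufficientSubjectsError` for
    any task pair with fewer than ``min_subjects`` subjects in common.
    """
    df = sessions.copy()
    df["task_label"] = df.apply(_task_label, axis=1)
    df["value"] = np.where(df["task"] == "PR", df["breakpoint"],
                           df["observed_bout_length"])
    per_subject = (df.dropna(subset=["value"])
                     .groupby(["subject_id", "task_label"])["value"]
                     .mean().unstack("task_label"))
    out = []
    for a, b in combinations(sorted(per_subject.columns), 2):
        both = per_subject[[a, b]].dropna()
        if len(both) < min_subjects:
            raise InsufficientSubjectsError(
                f"task pair ({a}, {b}): {len(both)} subjects < {min_subjects}")
        out.append(dict(task_a=a, task_b=b,
                        r=_pearson(both[a].to_numpy(float), both[b].to_numpy(float)),
                        n_subjects=len(both)))
    return pd.DataFrame(out)
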