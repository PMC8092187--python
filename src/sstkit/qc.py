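"""Participant-level exclusion rules applied before cohort analysis.

Rules, in order:

* ``missing_behavior`` — no usable trial rows (or no estimable category).
* ``implausible_height`` — self-reported height outside configured bounds.
* ``pstop_out_of_range`` — stopping probability (1 - p_respond_signal)
  strictly outside [low, high] in one or more categories; boundary values
  are compliant.  Any violation drops the participant.
* ``race_violation`` — mean signal-respond RT >= mean go RT in a category;
  only that category's SSRT value is rejected, the participant stays.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import QCConfig
from .ssrt_estimator import SSRTEstimate, estimate_cohort

QC_REPORT_COLUMNS = ["participant_id", "missing_behavior", "implausible_height",
                     "pstop_out_of_range", "race_violation", "included"]


@dataclass(frozen=True)
class QCFlags:
    """Exclusion flags for one participant (True = rule violated)."""

    participant_id: str
    pstop_out_of_range: Mapping[str, bool] = field(default_factory=dict)
    race_violation: Mapping[str, bool] = field(default_factory=dict)
    missing_behavior: bool = False
    implausible_height: bool = False

    @property
    def any_pstop(self) -> bool:
        return any(self.pstop_out_of_range.values())

    @property
    def any_race(self) -> bool:
        return any(self.race_violation.values())

    @property
    def included(self) -> bool:
        # Race violations reject the affected per-category values only;
        # they do not exclude the participant.
        return not (self.missing_behavior or self.implausible_height
                    or self.any_pstop)


@dataclass
class QCReport:
    flags: list[QCFlags]
    n_input: int
    n_included: int
    counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "participant_id": f.participant_id,
            "missing_behavior": int(f.missing_behavior),
            "implausible_height": int(f.implausible_height),
            "pstop_out_of_range": int(f.any_pstop),
            "race_violation": int(f.any_race),
            "included": int(f.included),
        } for f in self.flags]
        return pd.DataFrame(rows, columns=QC_REPORT_COLUMNS)

    def summary(self) -> dict:
        return {"n_input": self.n_input, "n_included": self.n_included,
                "n_excluded": self.n_input - self.n_included,
                "counts": dict(self.counts)}

    def save_summary(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass
class CleanCohort:
    """QC-passed slice of a cohort, ready for analysis."""

    participants: pd.DataFrame
    estimates: pd.DataFrame  # race-violating category rows removed
    report: QCReport


def check_pstop(estimate: SSRTEstimate, low: float = 0.25,
                high: float = 0.75) -> bool:
    """True iff the stopping probability falls strictly outside [low, high]."""
    p_stop = 1.0 - estimate.p_respond_signal
    return bool(p_stop < low or p_stop > high)


def check_race_assumption(estimate: SSRTEstimate) -> bool:
    """True iff mean signal-respond RT >= mean go RT (race model violated).

    Without any signal-respond trials the rule is not evaluable; the
    estimate is treated as compliant with a warning.
    """
    if estimate.mean_signal_respond_rt_ms is None:
        warnings.warn(
            f"category {estimate.category!r}: no signal-respond trials; "
            "race assumption not evaluable, treated as compliant",
            stacklevel=2)
        return False
    return bool(estimate.mean_signal_respond_rt_ms >= estimate.mean_go_rt_ms)


def _pstop_flag_row(row: pd.Series, cfg: QCConfig) -> bool:
    p_stop = 1.0 - float(row["p_respond_signal"])
    return bool(p_stop < cfg.pstop_low or p_stop > cfg.pstop_high)


def _race_flag_row(row: pd.Series) -> bool:
    msr = row["mean_signal_respond_rt_ms"]
    if pd.isna(msr):
        return False
    return bool(float(msr) >= float(row["mean_go_rt_ms"]))


def qc_from_estimates(estimates: pd.DataFrame, participants: pd.DataFrame,
                      qc_config: QCConfig | None = None) -> CleanCohort:
    """Apply all exclusion rules given a precomputed estimates table."""
    cfg = qc_config or QCConfig()
    est_pids = set(estimates["participant_id"])
    part_pids = set(participants["participant_id"])
    stray = est_pids - part_pids
    if stray:
        raise KeyError(
            f"estimates reference participants missing from the participant "
            f"table: {sorted(stray)[:5]}")
    flags: list[QCFlags] = []
    for _, prow in participants.sort_values("participant_id").iterrows():
        pid = prow["participant_id"]
        sub = estimates[estimates["participant_id"] == pid]
        # total absence of estimable behavior; a single missing category
        # only loses that category's value downstream
        missing = len(sub) == 0
        height_bad = False
        if "height_cm" in participants.columns and not pd.isna(prow["height_cm"]):
            h = float(prow["height_cm"])
            height_bad = bool(h < cfg.height_min_cm or h > cfg.height_max_cm)
        pstop = {}
        race = {}
        for _, erow in sub.iterrows():
            cat = erow["category"]
            pstop[cat] = _pstop_flag_row(erow, cfg)
            race[cat] = _race_flag_row(erow)
        flags.append(QCFlags(participant_id=pid, pstop_out_of_range=pstop,
                             race_violation=race, missing_behavior=missing,
                             implausible_height=height_bad))

    by_pid = {f.participant_id: f for f in flags}
    included_ids = [f.participant_id for f in flags if f.included]
    kept_parts = participants[participants["participant_id"].isin(included_ids)]
    kept_est = estimates[estimates["participant_id"].isin(included_ids)].copy()
    race_drop = kept_est.apply(
        lambda r: by_pid[r["participant_id"]].race_violation.get(r["category"], False),
        axis=1) if len(kept_est) else pd.Series(dtype=bool)
    n_race_values = int(race_drop.sum()) if len(kept_est) else 0
    kept_est = kept_est[~race_drop] if len(kept_est) else kept_est

    counts = {
        "missing_behavior": sum(f.missing_behavior for f in flags),
        "implausible_height": sum(f.implausible_height for f in flags),
        "pstop_out_of_range": sum(f.any_pstop for f in flags),
        "race_violation_participants": sum(f.any_race for f in flags),
        "race_violation_values_dropped": n_race_values,
    }
    report = QCReport(flags=flags, n_input=len(flags),
                      n_included=len(included_ids), counts=counts)
    return CleanCohort(participants=kept_parts.reset_index(drop=True),
                       estimates=kept_est.reset_index(drop=True),
                       report=report)


def apply_exclusions(trial_log: pd.DataFrame, participants: pd.DataFrame,
                     qc_config: QCConfig | None = None) -> CleanCohort:
    """Estimate per-participant SSRTs from the trial log, then apply QC.

    Raises ``KeyError`` if the trial log references participants absent
    from the participant table.
    """
    log_pids = set(trial_log["participant_id"]) if len(trial_log) else set()
    part_pids = set(participants["participant_id"])
    stray = log_pids - part_pids
    if stray:
        raise KeyError(
            f"trial log references participants missing from the participant "
            f"table: {sorted(stray)[:5]}")
    estimates = estimate_cohort(trial_log)
    return qc_from_estimates(estimates, participants, qc_config)
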