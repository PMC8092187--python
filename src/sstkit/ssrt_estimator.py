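"""Integration-method SSRT estimation with go-omission replacement.

For each stimulus category: take every go-trial RT (choice errors
included), replace each go omission with the participant's maximum
observed go RT, sort ascending, and read off the RT at rank
``ceil(p_respond_signal * n_go)`` (1-based).  SSRT is that quantile minus
the mean SSD over all stop trials of the category.  Estimates with
``p_respond_signal`` of exactly 0 or 1 are flagged invalid.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .race_sim import TrialResult
from .task_design import GO, STOP

ESTIMATE_COLUMNS = ["participant_id", "category", "p_respond_signal",
                    "mean_ssd_ms", "nth_go_rt_ms", "ssrt_ms", "mean_go_rt_ms",
                    "mean_signal_respond_rt_ms", "n_go", "n_stop",
                    "n_go_omissions", "valid"]


class EstimationError(ValueError):
    """The SSRT estimate is undefined for the given trials."""


@dataclass(frozen=True)
class SSRTEstimate:
    category: str
    p_respond_signal: float
    mean_ssd_ms: float
    nth_go_rt_ms: float  # NaN when invalid at p = 0
    ssrt_ms: float
    mean_go_rt_ms: float
    mean_signal_respond_rt_ms: float | None
    n_go: int
    n_stop: int
    n_go_omissions: int
    valid: bool


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    rows = {"trial_type": [], "stimulus_category": [], "ssd_ms": [],
            "responded": [], "rt_ms": []}
    for r in trials:
        if not isinstance(r, TrialResult):
            raise TypeError(f"expected TrialResult or DataFrame, got {type(r)}")
        rows["trial_type"].append(r.spec.trial_type)
        rows["stimulus_category"].append(r.spec.stimulus_category)
        rows["ssd_ms"].append(np.nan if r.ssd_ms is None else r.ssd_ms)
        rows["responded"].append(int(r.responded))
        rows["rt_ms"].append(np.nan if r.rt_ms is None else r.rt_ms)
    return pd.DataFrame(rows)


def p_respond_given_signal(trials, category: str) -> float:
    """Share of the category's stop trials with any response (incl. premature)."""
    df = _as_frame(trials)
    stop = df[(df["trial_type"] == STOP) & (df["stimulus_category"] == category)]
    if len(stop) == 0:
        raise EstimationError(f"no stop trials for category {category!r}")
    return float(stop["responded"].astype(bool).mean())


def go_rt_vector(trials, category: str) -> np.ndarray:
    """Sorted go-RT vector with omissions replaced by the participant's max go RT.

    The replacement value is the maximum observed go RT across the whole
    session (all categories), the standard omission treatment.
    """
    df = _as_frame(trials)
    go_all = df[df["trial_type"] == GO]
    go = go_all[go_all["stimulus_category"] == category]
    if len(go) == 0:
        raise EstimationError(f"no go trials for category {category!r}")
    observed = go.loc[go["responded"].astype(bool), "rt_ms"].to_numpy(float)
    if observed.size == 0:
        raise EstimationError(
            f"all go trials omitted for category {category!r}: distribution undefined")
    any_observed = go_all.loc[go_all["responded"].astype(bool), "rt_ms"].to_numpy(float)
    max_rt = float(np.max(any_observed))
    n_omit = int((~go["responded"].astype(bool)).sum())
    vec = np.concatenate([observed, np.full(n_omit, max_rt)])
    return np.sort(vec)


def integration_ssrt(trials, category: str) -> SSRTEstimate:
    """Integration-method SSRT for one category of one participant's session."""
    df = _as_frame(trials)
    p = p_respond_given_signal(df, category)
    vec = go_rt_vector(df, category)
    n_go = vec.size

    stop = df[(df["trial_type"] == STOP) & (df["stimulus_category"] == category)]
    mean_ssd = float(stop["ssd_ms"].mean())
    responded_stop = stop[stop["responded"].astype(bool)]
    mean_srrt = (float(responded_stop["rt_ms"].mean())
                 if len(responded_stop) else None)

    go = df[(df["trial_type"] == GO) & (df["stimulus_category"] == category)]
    go_obs = go.loc[go["responded"].astype(bool), "rt_ms"]
    mean_go = float(go_obs.mean())
    n_omit = int(len(go) - len(go_obs))

    rank = math.ceil(p * n_go)
    if rank == 0:  # p == 0: quantile undefined
        nth = float("nan")
        ssrt = float("nan")
    else:
        nth = float(vec[rank - 1])
        ssrt = nth - mean_ssd
    return SSRTEstimate(
        category=category,
        p_respond_signal=p,
        mean_ssd_ms=mean_ssd,
        nth_go_rt_ms=nth,
        ssrt_ms=ssrt,
        mean_go_rt_ms=mean_go,
        mean_signal_respond_rt_ms=mean_srrt,
        n_go=n_go,
        n_stop=int(len(stop)),
        n_go_omissions=n_omit,
        valid=bool(0.0 < p < 1.0),
    )


def estimate_session(trials, categories: Sequence[str] | None = None
                     ) -> list[SSRTEstimate]:
    """Per-category estimates for one participant's session."""
    df = _as_frame(trials)
    if categories is None:
        categories = sorted(df["stimulus_category"].dropna().unique())
    return [integration_ssrt(df, c) for c in categories]


def estimate_cohort(trial_log: pd.DataFrame) -> pd.DataFrame:
    """Estimates table over a multi-participant trial log.

    Participants for whom an estimate is undefined in some category (no go
    responses or no stop trials) get no row for that category; downstream
    QC treats missing rows as missing behavioral data.
    """
    records = []
    for pid, sub in trial_log.groupby("participant_id", sort=True):
        for cat in sorted(sub["stimulus_category"].dropna().unique()):
            try:
                est = integration_ssrt(sub, cat)
            except EstimationError:
                continue
            records.append({
                "participant_id": pid,
                "category": est.category,
                "p_respond_signal": est.p_respond_signal,
                "mean_ssd_ms": est.mean_ssd_ms,
                "nth_go_rt_ms": est.nth_go_rt_ms,
                "ssrt_ms": est.ssrt_ms,
                "mean_go_rt_ms": est.mean_go_rt_ms,
                "mean_signal_respond_rt_ms": (
                    np.nan if est.mean_signal_respond_rt_ms is None
                    else est.mean_signal_respond_rt_ms),
                "n_go": est.n_go,
                "n_stop": est.n_stop,
                "n_go_omissions": est.n_go_omissions,
                "valid": int(est.valid),
            })
    return pd.DataFrame(records, columns=ESTIMATE_COLUMNS)
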