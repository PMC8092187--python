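"""Cohort-level statistics on QC-passed estimates.

The mixed model has a random intercept per participant; fixed effects are
the continuous age covariate, the two between-subject factors (condition,
overweight), the within-subject stimulus-category factor, and all factor
interactions, in sum-to-zero coding.  F-tests are Wald tests with
containment denominator degrees of freedom: between-subject terms are
tested against ``n_subjects - 5`` (five between-subject columns including
the intercept), stimulus terms against
``n_obs - n_subjects - 4``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import fit_random_intercept
from .power import (exact_correlation_power, fisher_z_required_n,  # noqa: F401
                    required_n_correlation)

OVERWEIGHT_BMI_THRESHOLD = 25.0

ANALYSIS_COLUMNS = ["participant_id", "group", "overweight", "bmi", "age",
                    "category", "mean_go_rt_ms", "ssrt_ms", "valid"]

_RESPONSE_COLUMNS = {"go_rt": "mean_go_rt_ms", "ssrt": "ssrt_ms"}

#: fixed-effect terms; bool marks within-subject (stimulus) terms
_EFFECTS = [("age", False), ("condition", False), ("overweight", False),
            ("stimulus", True), ("condition:overweight", False),
            ("condition:stimulus", True), ("overweight:stimulus", True),
            ("condition:overweight:stimulus", True)]


class DegenerateDesignError(ValueError):
    """The analysis table cannot support the requested model."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    p: float


def classify_overweight(bmi):
    """True iff BMI >= 25 kg/m^2 (threshold inclusive); scalar or array."""
    arr = np.asarray(bmi, float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("bmi must be positive and finite")
    out = arr >= OVERWEIGHT_BMI_THRESHOLD
    return bool(out) if np.isscalar(bmi) else out


def build_analysis_table(estimates: pd.DataFrame,
                         participants: pd.DataFrame) -> pd.DataFrame:
    """One row per participant x category, merging estimates and covariates."""
    merged = estimates.merge(
        participants[["participant_id", "group", "bmi", "age"]],
        on="participant_id", how="left", validate="many_to_one")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "participant_id"].unique()
        raise KeyError(f"participants missing from covariate table: "
                       f"{sorted(missing)[:5]}")
    merged["overweight"] = classify_overweight(merged["bmi"].to_numpy())
    out = merged[["participant_id", "group", "overweight", "bmi", "age",
                  "category", "mean_go_rt_ms", "ssrt_ms"]].copy()
    out["valid"] = merged["valid"].astype(bool) if "valid" in merged else True
    return out[ANALYSIS_COLUMNS]


def _code_two_level(values: pd.Series, factor: str) -> tuple[np.ndarray, str]:
    levels = sorted(pd.unique(values))
    if len(levels) != 2:
        raise DegenerateDesignError(
            f"factor {factor!r} needs exactly 2 levels, found {levels}")
    # sum coding: first sorted level = +1 (so "gamified" codes positive)
    return np.where(values == levels[0], 1.0, -1.0), str(levels[0])


def fit_mixed_model(table: pd.DataFrame, response: str) -> pd.DataFrame:
    """Wald F table for the random-intercept model of one response.

    Returns a frame with columns effect, estimate, F, df_num, df_den, p.
    ``estimate`` is the sum-coded coefficient: positive means the first
    alphabetical level (gamified / overweight=True via True>False sort
    order, see below) has the larger mean.
    """
    col = _RESPONSE_COLUMNS.get(response)
    if col is None:
        raise ValueError(f"response must be one of {sorted(_RESPONSE_COLUMNS)}")
    df = table.copy()
    df = df[df["valid"].astype(bool) & df[col].notna()]
    if df.empty:
        raise DegenerateDesignError("no valid records")
    y = df[col].to_numpy(float)
    if np.ptp(y) == 0:
        raise DegenerateDesignError("response has zero variance")

    g, _ = _code_two_level(df["group"], "group")
    s, _ = _code_two_level(df["category"], "category")
    # overweight: True coded +1
    ow_levels = sorted(pd.unique(df["overweight"].astype(bool)))
    if len(ow_levels) != 2:
        raise DegenerateDesignError(
            f"factor 'overweight' needs exactly 2 levels, found {ow_levels}")
    o = np.where(df["overweight"].astype(bool), 1.0, -1.0)
    age = df["age"].to_numpy(float)
    age_c = age - age.mean()

    X = np.column_stack([np.ones_like(y), age_c, g, o, s,
                         g * o, g * s, o * s, g * o * s])
    col_of = {"age": 1, "condition": 2, "overweight": 3, "stimulus": 4,
              "condition:overweight": 5, "condition:stimulus": 6,
              "overweight:stimulus": 7, "condition:overweight:stimulus": 8}
    groups = df["participant_id"].to_numpy()
    fit = fit_random_intercept(X, y, groups)

    n_subj = fit.n_groups
    n_obs = fit.n_obs
    df_between = n_subj - 5
    df_within = n_obs - n_subj - 4
    if df_between <= 0:
        raise DegenerateDesignError("too few participants for between-subject tests")

    rows = []
    for effect, is_within in _EFFECTS:
        j = col_of[effect]
        b = fit.beta[j]
        v = fit.cov_beta[j, j]
        F = float(b * b / v)
        dden = df_within if is_within else df_between
        if dden <= 0:
            raise DegenerateDesignError(
                f"no denominator degrees of freedom for {effect!r}")
        rows.append({"effect": effect, "estimate": float(b), "F": F,
                     "df_num": 1, "df_den": int(dden),
                     "p": float(stats.f.sf(F, 1, dden))})
    return pd.DataFrame(rows, columns=["effect", "estimate", "F", "df_num",
                                       "df_den", "p"])


def _pearson_with_ci(x: np.ndarray, y: np.ndarray,
                     ci_level: float = 0.95) -> CorrelationResult:
    n = x.size
    if n < 4:
        raise DegenerateDesignError("need at least 4 records for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDesignError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + ci_level / 2)
    return CorrelationResult(r=float(r), ci_low=float(np.tanh(z - zc * se)),
                             ci_high=float(np.tanh(z + zc * se)),
                             n=int(n), p=float(p))


def bmi_ssrt_correlation(table: pd.DataFrame,
                         ci_level: float = 0.95) -> CorrelationResult:
    """Product-moment correlation of BMI with per-record SSRT (Fisher CI)."""
    df = table[table["valid"].astype(bool) & table["ssrt_ms"].notna()]
    return _pearson_with_ci(df["bmi"].to_numpy(float),
                            df["ssrt_ms"].to_numpy(float), ci_level)


def mad_outlier_rule(threshold: float = 3.0) -> Callable[[np.ndarray], np.ndarray]:
    """Keep-mask factory: values within median +/- threshold * MAD.

    MAD is scaled to be consistent with the normal SD, so threshold 3
    approximates a robust 3-sigma rule.
    """
    def rule(values: np.ndarray) -> np.ndarray:
        med = np.median(values)
        mad = stats.median_abs_deviation(values, scale="normal")
        if mad == 0:
            return np.ones_like(values, dtype=bool)
        return np.abs(values - med) <= threshold * mad
    return rule


def outlier_sensitivity(table: pd.DataFrame,
                        rule: Callable[[np.ndarray], np.ndarray] | None = None,
                        ci_level: float = 0.95) -> CorrelationResult:
    """BMI-SSRT correlation recomputed after removing SSRT outliers."""
    df = table[table["valid"].astype(bool) & table["ssrt_ms"].notna()]
    ssrt = df["ssrt_ms"].to_numpy(float)
    keep = (rule or mad_outlier_rule())(ssrt)
    if not keep.any():
        raise DegenerateDesignError("outlier rule removed every record")
    return _pearson_with_ci(df["bmi"].to_numpy(float)[keep], ssrt[keep], ci_level)
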