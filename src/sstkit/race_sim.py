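"""Synthetic cohorts under the independent race model.

Each simulated participant carries latent generative parameters: an
ex-Gaussian go finishing-time distribution, a truncated-Gaussian stop
latency, and lapse probabilities.  On a stop trial the go and stop
processes race independently: the participant responds iff the sampled
go finishing time beats ``SSD + stop latency``.  Responses emitted before
stop-signal onset (go time < SSD) are therefore failed stops, matching
how premature responses are handled by the staircase.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigurationError, DesignConfig, GroupConfig
from .task_design import (GO, STOP, StaircaseState, TrialSpec,
                          design_from_config, staircase_update)

TRIAL_LOG_COLUMNS = ["participant_id", "group", "trial_index", "trial_type",
                     "stimulus_category", "stimulus_id", "ssd_ms", "responded",
                     "rt_ms", "correct"]
PARTICIPANT_COLUMNS = ["participant_id", "group", "bmi", "age", "gender",
                       "height_cm", "debq_restrained", "debq_emotional",
                       "debq_external", "hunger"]
LATENT_COLUMNS = ["go_mu", "go_sigma", "go_tau", "ssrt_true_mean",
                  "ssrt_true_sd", "p_go_omission", "p_choice_error"]


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent generative parameters plus observed covariates."""

    id: str
    group: str
    bmi: float
    age: float
    gender: str
    height_cm: float
    go_mu: float
    go_sigma: float
    go_tau: float
    ssrt_true_mean: float
    ssrt_true_sd: float
    p_go_omission: float
    p_choice_error: float
    debq_restrained: float
    debq_emotional: float
    debq_external: float
    hunger: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_go_omission <= 1 and 0 <= self.p_choice_error <= 1):
            raise ConfigurationError("lapse probabilities must lie in [0, 1]")
        if min(self.go_sigma, self.go_tau, self.ssrt_true_sd) < 0:
            raise ConfigurationError("scale parameters must be non-negative")
        if self.bmi <= 0:
            raise ConfigurationError("bmi must be positive")


@dataclass(frozen=True)
class TrialResult:
    """Observed outcome of one simulated trial."""

    spec: TrialSpec
    ssd_ms: float | None
    responded: bool
    rt_ms: float | None
    correct: bool

    def __post_init__(self) -> None:
        if self.responded and (self.rt_ms is None or self.rt_ms <= 0):
            raise ValueError("responded trials must carry a positive RT")
        if not self.responded and self.rt_ms is not None:
            raise ValueError("non-responses carry no RT")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float, high: float) -> float:
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))  # pragma: no cover


def sample_cohort_profiles(config: CohortConfig, rng_seed: int
                           ) -> list[ParticipantProfile]:
    """Draw a cohort of participant profiles; deterministic for a fixed seed.

    Overweight membership is assigned exactly (``round(fraction * n)`` per
    group); BMI is drawn from the status-specific truncated normal so the
    flag and the continuous value agree.
    """
    rng = np.random.default_rng(rng_seed)
    profiles: list[ParticipantProfile] = []
    pid = 0
    for group_name in config.groups:
        g: GroupConfig = config.groups[group_name]
        n_ow = round(config.overweight_fraction * g.n)
        ow_flags = np.zeros(g.n, dtype=bool)
        ow_flags[:n_ow] = True
        rng.shuffle(ow_flags)
        for i in range(g.n):
            ow = bool(ow_flags[i])
            if ow:
                bmi = _trunc_normal(rng, g.bmi_overweight_mean,
                                    g.bmi_overweight_sd, 25.0, 60.0)
            else:
                bmi = _trunc_normal(rng, g.bmi_normal_mean, g.bmi_normal_sd,
                                    15.0, 24.999)
            age = _trunc_normal(rng, g.age_mean_years, g.age_sd_years, 18.0, 90.0)
            go_mu = (config.go_mu_ms + g.go_shift_ms
                     + (config.overweight_go_shift_ms if ow else 0.0)
                     + rng.normal(0.0, config.go_mu_between_sd_ms))
            ssrt_mean = (config.ssrt_mean_ms + g.ssrt_shift_ms
                         + (config.overweight_ssrt_shift_ms if ow else 0.0)
                         + config.age_ssrt_slope_ms_per_year
                         * (age - config.age_reference_years)
                         + rng.normal(0.0, config.ssrt_between_sd_ms))
            gender = str(rng.choice(
                ["female", "male", "other"],
                p=[config.p_female,
                   1.0 - config.p_female - config.p_other_gender,
                   config.p_other_gender]))
            profiles.append(ParticipantProfile(
                id=f"p{pid:04d}",
                group=group_name,
                bmi=bmi,
                age=age,
                gender=gender,
                height_cm=_trunc_normal(rng, config.height_mean_cm,
                                        config.height_sd_cm, 150.0, 200.0),
                go_mu=max(go_mu, 100.0),
                go_sigma=config.go_sigma_ms,
                go_tau=config.go_tau_ms,
                ssrt_true_mean=max(ssrt_mean, 50.0),
                ssrt_true_sd=config.ssrt_trial_sd_ms,
                p_go_omission=config.p_go_omission,
                p_choice_error=config.p_choice_error,
                debq_restrained=_trunc_normal(rng, config.debq_restrained_mean,
                                              config.debq_restrained_sd, 10.0, 50.0),
                debq_emotional=_trunc_normal(rng, config.debq_emotional_mean,
                                             config.debq_emotional_sd, 13.0, 65.0),
                debq_external=_trunc_normal(rng, config.debq_external_mean,
                                            config.debq_external_sd, 10.0, 50.0),
                hunger=_trunc_normal(rng, config.hunger_mean, config.hunger_sd,
                                     0.0, 100.0),
            ))
            pid += 1
    return profiles


def _sample_go_time(profile: ParticipantProfile, rng: np.random.Generator) -> float:
    t = rng.normal(profile.go_mu, profile.go_sigma) + rng.exponential(profile.go_tau)
    return max(t, 1.0)


def _sample_stop_latency(profile: ParticipantProfile, rng: np.random.Generator) -> float:
    # Gaussian truncated at zero
    if profile.ssrt_true_sd == 0:
        return max(profile.ssrt_true_mean, 0.0)
    while True:
        t = rng.normal(profile.ssrt_true_mean, profile.ssrt_true_sd)
        if t >= 0:
            return t


def simulate_trial(profile: ParticipantProfile, spec: TrialSpec,
                   state: StaircaseState, rng: np.random.Generator) -> TrialResult:
    """Simulate a single trial (does not advance the staircase)."""
    if spec.trial_type == GO:
        if rng.random() < profile.p_go_omission:
            return TrialResult(spec, None, False, None, False)
        rt = _sample_go_time(profile, rng)
        correct = rng.random() >= profile.p_choice_error
        return TrialResult(spec, None, True, rt, correct)
    ssd = state.ssd_ms[spec.stimulus_category]
    t_go = _sample_go_time(profile, rng)
    t_stop = _sample_stop_latency(profile, rng)
    if t_go < ssd + t_stop:  # go process wins: failed stop
        return TrialResult(spec, ssd, True, t_go, False)
    return TrialResult(spec, ssd, False, None, True)


def simulate_session(profile: ParticipantProfile, design: Sequence[TrialSpec],
                     rng_seed: int,
                     staircase: StaircaseState | None = None,
                     ) -> list[TrialResult]:
    """Simulate a full session, threading the staircase through stop trials."""
    rng = np.random.default_rng(rng_seed)
    if staircase is None:
        cats = sorted({s.stimulus_category for s in design})
        staircase = StaircaseState.initial(cats)
    results: list[TrialResult] = []
    state = staircase
    for spec in design:
        res = simulate_trial(profile, spec, state, rng)
        results.append(res)
        if spec.trial_type == STOP:
            state = staircase_update(state, spec.stimulus_category,
                                     stop_succeeded=not res.responded)
    return results


def session_to_frame(profile: ParticipantProfile,
                     results: Sequence[TrialResult]) -> pd.DataFrame:
    n = len(results)
    return pd.DataFrame({
        "participant_id": [profile.id] * n,
        "group": [profile.group] * n,
        "trial_index": [r.spec.index for r in results],
        "trial_type": [r.spec.trial_type for r in results],
        "stimulus_category": [r.spec.stimulus_category for r in results],
        "stimulus_id": [r.spec.stimulus_id for r in results],
        "ssd_ms": [np.nan if r.ssd_ms is None else r.ssd_ms for r in results],
        "responded": [int(r.responded) for r in results],
        "rt_ms": [np.nan if r.rt_ms is None else r.rt_ms for r in results],
        "correct": [int(r.correct) for r in results],
    }, columns=TRIAL_LOG_COLUMNS)


def participants_to_frame(profiles: Sequence[ParticipantProfile],
                          include_latent: bool = False) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "participant_id": p.id, "group": p.group, "bmi": p.bmi,
            "age": p.age, "gender": p.gender, "height_cm": p.height_cm,
            "debq_restrained": p.debq_restrained,
            "debq_emotional": p.debq_emotional,
            "debq_external": p.debq_external, "hunger": p.hunger,
        }
        if include_latent:
            for col in LATENT_COLUMNS:
                row[col] = getattr(p, col)
        rows.append(row)
    cols = PARTICIPANT_COLUMNS + (LATENT_COLUMNS if include_latent else [])
    return pd.DataFrame(rows, columns=cols)


def simulate_cohort(profiles: Sequence[ParticipantProfile],
                    design_config: DesignConfig, rng_seed: int,
                    ) -> pd.DataFrame:
    """Simulate one session per profile; returns the combined trial log.

    Each participant gets an independently randomized design and session
    stream, all derived from ``rng_seed`` via a seed sequence.
    """
    ss = np.random.SeedSequence(rng_seed)
    frames = []
    for profile, child in zip(profiles, ss.spawn(len(profiles))):
        design_seed, session_seed = child.generate_state(2)
        design = design_from_config(design_config, int(design_seed))
        results = simulate_session(profile, design, int(session_seed),
                                   StaircaseState.from_config(design_config))
        frames.append(session_to_frame(profile, results))
    if not frames:
        return pd.DataFrame(columns=TRIAL_LOG_COLUMNS)
    return pd.concat(frames, ignore_index=True)
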