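"""Session trial sequences and the 1-up/1-down SSD staircase.

A session is a shuffled sequence of :class:`TrialSpec`.  Trial counts are
exact: ``round(p_stop * n_trials)`` stop trials, half the trials per
stimulus category, stop trials split as evenly as possible across
categories.  The stop-signal delay (SSD) is tracked separately per
stimulus category and moves by one fixed step after every stop trial:
up after a successful stop, down after a failed one, clamped to
[floor, ceiling].
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError, DesignConfig

#: stimulus id -> (category, color); colors per the two response keys
STIMULI: dict[str, tuple[str, str]] = {
    "french_fries": ("food", "red"),
    "pizza": ("food", "red"),
    "cake": ("food", "brown"),
    "donut": ("food", "brown"),
    "glove": ("control", "red"),
    "scissors": ("control", "red"),
    "wooden_hammer": ("control", "brown"),
    "chopping_board": ("control", "brown"),
}

DEFAULT_COLOR_KEY_MAP: Mapping[str, str] = {"red": "left", "brown": "right"}

GO, STOP = "go", "stop"

DESIGN_COLUMNS = ["index", "trial_type", "stimulus_id", "stimulus_category",
                  "color", "correct_key"]


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial."""

    index: int
    trial_type: str  # "go" | "stop"
    stimulus_id: str
    stimulus_category: str
    color: str
    correct_key: str


@dataclass(frozen=True)
class StaircaseState:
    """Current SSD per stimulus category plus step and clamp bounds (ms)."""

    ssd_ms: Mapping[str, float]
    step_ms: float = 50.0
    floor_ms: float = 50.0
    ceiling_ms: float = 900.0

    def __post_init__(self) -> None:
        for cat, ssd in self.ssd_ms.items():
            if not self.floor_ms <= ssd <= self.ceiling_ms:
                raise ConfigurationError(
                    f"SSD for {cat!r} ({ssd} ms) outside [{self.floor_ms}, {self.ceiling_ms}]"
                )

    @classmethod
    def initial(cls, categories: Iterable[str], start_ms: float = 200.0,
                step_ms: float = 50.0, floor_ms: float = 50.0,
                ceiling_ms: float = 900.0) -> "StaircaseState":
        return cls(ssd_ms={c: float(start_ms) for c in categories},
                   step_ms=float(step_ms), floor_ms=float(floor_ms),
                   ceiling_ms=float(ceiling_ms))

    @classmethod
    def from_config(cls, cfg: DesignConfig) -> "StaircaseState":
        return cls.initial(cfg.categories, cfg.ssd_start_ms, cfg.ssd_step_ms,
                           cfg.ssd_floor_ms, cfg.ssd_ceiling_ms)


def staircase_update(state: StaircaseState, category: str,
                     stop_succeeded: bool) -> StaircaseState:
    """Return the state after one stop trial of ``category``.

    A successful stop makes the task harder (SSD up one step, clamped at the
    ceiling); a failed stop — including premature responses — makes it
    easier (SSD down one step, clamped at the floor).  Other categories are
    untouched.
    """
    if category not in state.ssd_ms:
        raise KeyError(f"unknown stimulus category: {category!r}")
    cur = state.ssd_ms[category]
    if stop_succeeded:
        new = min(cur + state.step_ms, state.ceiling_ms)
    else:
        new = max(cur - state.step_ms, state.floor_ms)
    ssd = dict(state.ssd_ms)
    ssd[category] = new
    return dataclasses.replace(state, ssd_ms=ssd)


def _category_stimuli(category: str) -> list[tuple[str, str]]:
    out = [(sid, color) for sid, (cat, color) in STIMULI.items() if cat == category]
    if not out:
        raise ConfigurationError(f"no stimuli defined for category {category!r}")
    return out


def generate_design(n_trials: int = 256, p_stop: float = 0.25,
                    categories: Sequence[str] = ("food", "control"),
                    rng_seed: int = 0,
                    color_key_map: Mapping[str, str] | None = None,
                    ) -> list[TrialSpec]:
    """Generate one session's randomized trial sequence.

    Deterministic for a fixed ``rng_seed``.  Categories contribute equally
    many trials; stimulus identities are balanced exactly within category
    (up to divisibility); stop trials are split as evenly as possible
    across categories, any remainder assigned at random.
    """
    categories = tuple(categories)
    if not categories:
        raise ConfigurationError("category set must be non-empty")
    if len(set(categories)) != len(categories):
        raise ConfigurationError("duplicate categories")
    n_stop_f = n_trials * p_stop
    n_stop = round(n_stop_f)
    if abs(n_stop_f - n_stop) > 1e-9 or not 0 < n_stop < n_trials:
        raise ConfigurationError(
            f"n_trials * p_stop = {n_stop_f} is not a positive integer < n_trials"
        )
    if n_trials % len(categories) != 0:
        raise ConfigurationError(
            f"n_trials={n_trials} not divisible by {len(categories)} categories"
        )
    key_map = dict(DEFAULT_COLOR_KEY_MAP if color_key_map is None else color_key_map)

    rng = np.random.default_rng(rng_seed)
    per_cat = n_trials // len(categories)
    base_stop, extra = divmod(n_stop, len(categories))
    lucky = rng.choice(len(categories), size=extra, replace=False) if extra else []
    stops_per_cat = [base_stop + (i in set(np.atleast_1d(lucky))) for i in range(len(categories))]

    trials: list[tuple[str, str, str, str]] = []  # (type, stim, cat, color)
    for ci, cat in enumerate(categories):
        stims = _category_stimuli(cat)
        seq = [stims[i % len(stims)] for i in range(per_cat)]
        types = [STOP] * stops_per_cat[ci] + [GO] * (per_cat - stops_per_cat[ci])
        perm = rng.permutation(per_cat)
        for slot, t in zip(perm, types):
            sid, color = seq[slot]
            trials.append((t, sid, cat, color))
    order = rng.permutation(len(trials))
    specs = []
    for idx, j in enumerate(order):
        t, sid, cat, color = trials[j]
        if color not in key_map:
            raise ConfigurationError(f"color {color!r} missing from color_key_map")
        specs.append(TrialSpec(index=idx, trial_type=t, stimulus_id=sid,
                               stimulus_category=cat, color=color,
                               correct_key=key_map[color]))
    return specs


def design_from_config(cfg: DesignConfig, rng_seed: int = 0) -> list[TrialSpec]:
    return generate_design(cfg.n_trials, cfg.p_stop, cfg.categories, rng_seed,
                           cfg.color_key_map)


def design_to_frame(specs: Sequence[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in specs],
                        columns=DESIGN_COLUMNS)
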