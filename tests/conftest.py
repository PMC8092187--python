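import numpy as np
import pandas as pd
import pytest

from sstkit.config import CohortConfig, DesignConfig
from sstkit.race_sim import (ParticipantProfile, participants_to_frame,
                             sample_cohort_profiles, simulate_cohort)


def make_profile(**overrides) -> ParticipantProfile:
    base = dict(
        id="p0000", group="nongamified", bmi=22.0, age=27.0, gender="female",
        height_cm=170.0, go_mu=426.0, go_sigma=60.0, go_tau=157.0,
        ssrt_true_mean=290.0, ssrt_true_sd=30.0, p_go_omission=0.02,
        p_choice_error=0.03, debq_restrained=17.0, debq_emotional=20.0,
        debq_external=23.0, hunger=40.0,
    )
    base.update(overrides)
    return ParticipantProfile(**base)


def make_session_frame(go_rts_by_cat, stop_by_cat, go_omissions_by_cat=None):
    """Hand-build a single-participant trial log.

    go_rts_by_cat: {category: [rt, ...]}
    stop_by_cat: {category: [(ssd, responded, rt_or_None), ...]}
    go_omissions_by_cat: {category: count}
    """
    rows = []
    idx = 0
    omits = go_omissions_by_cat or {}
    for cat, rts in go_rts_by_cat.items():
        for rt in rts:
            rows.append(dict(participant_id="p0", group="nongamified",
                             trial_index=idx, trial_type="go",
                             stimulus_category=cat, stimulus_id="x",
                             ssd_ms=np.nan, responded=1, rt_ms=float(rt),
                             correct=1))
            idx += 1
        for _ in range(omits.get(cat, 0)):
            rows.append(dict(participant_id="p0", group="nongamified",
                             trial_index=idx, trial_type="go",
                             stimulus_category=cat, stimulus_id="x",
                             ssd_ms=np.nan, responded=0, rt_ms=np.nan,
                             correct=0))
            idx += 1
    for cat, stops in stop_by_cat.items():
        for ssd, responded, rt in stops:
            rows.append(dict(participant_id="p0", group="nongamified",
                             trial_index=idx, trial_type="stop",
                             stimulus_category=cat, stimulus_id="x",
                             ssd_ms=float(ssd), responded=int(responded),
                             rt_ms=np.nan if rt is None else float(rt),
                             correct=int(not responded)))
            idx += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config simulated cohort (n=100), reused across tests."""
    cfg = CohortConfig()
    profiles = sample_cohort_profiles(cfg, rng_seed=20240)
    trials = simulate_cohort(profiles, DesignConfig(), rng_seed=20241)
    participants = participants_to_frame(profiles, include_latent=True)
    return cfg, profiles, trials, participants
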