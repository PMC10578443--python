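"""Shared fixtures: small synthetic cohorts reused across the suite."""

import logging

import pytest

from e4wild import (
    CohortSpec,
    EffectSpec,
    WindowingParams,
    apply_sleep_mask,
    build_feature_table,
    build_windows,
    simulate_cohort,
)

logging.disable(logging.INFO)

#: tiny two-candidate grid keeping nested CV fast in tests
SMALL_GRID = {"lr": [{"C": 1.0}], "rf": [{"n_estimators": 50}]}


def _masks(cohort):
    return {(s.participant_id, s.session_id): apply_sleep_mask(s)
            for s in cohort.sessions}


def make_table(cohort, seed=3):
    masks = _masks(cohort)
    windows = build_windows(cohort.sessions, masks, WindowingParams(seed=seed))
    return build_feature_table(windows, cohort.sessions, masks)


@pytest.fixture(scope="session")
def effect_cohort():
    """4 participants x 2 days x 1.5 h, 2 tags/h, default event signature."""
    return simulate_cohort(CohortSpec(n_participants=4, days=2.0,
                                      hours_per_day=1.5, tag_rate=2.0, seed=1))


@pytest.fixture(scope="session")
def effect_masks(effect_cohort):
    return _masks(effect_cohort)


@pytest.fixture(scope="session")
def effect_table(effect_cohort):
    return make_table(effect_cohort)


@pytest.fixture(scope="session")
def temporal_cohort():
    """3 participants x 8 days x 1 h: enough observation days for
    temporal/personalized splits."""
    return simulate_cohort(CohortSpec(n_participants=3, days=8.0,
                                      hours_per_day=1.0, tag_rate=3.0, seed=5))


@pytest.fixture(scope="session")
def temporal_table(temporal_cohort):
    return make_table(temporal_cohort)


@pytest.fixture(scope="session")
def null_effect():
    return EffectSpec.null()
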