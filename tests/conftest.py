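"""Shared fixtures: small synthetic cohorts computed once per session.

Cohort sizes and record durations here are scaled down from the default
study configuration so the suite stays fast; the statistical structure
(group templates, jitter levels, severity coupling) is the default one.
"""

from __future__ import annotations

import numpy as np
import pytest

from pulsespec.config import default_group_specs
from pulsespec.simulate import (
    GroupEffectSpec,
    JitterSpec,
    radial_template,
    synthesize_cohort,
    synthesize_record,
)
from pulsespec.spectral import attach_metadata, extract_features


@pytest.fixture(scope="session")
def group_specs():
    return default_group_specs()


@pytest.fixture(scope="session")
def zero_jitter_record():
    """Noise-free, jitter-free 60 bpm record (beats exactly 500 samples)."""
    effect = GroupEffectSpec(
        "zero", radial_template(), JitterSpec(), mean_hr_bpm=60.0
    )
    record, ground_truth = synthesize_record(
        effect, duration_s=30.0, fs=500.0, seed=11, subject_id="zero"
    )
    return record, ground_truth


@pytest.fixture(scope="session")
def small_cohort(group_specs):
    """8 AD-like + 8 Control-like subjects, 60 s records."""
    return synthesize_cohort(
        [group_specs["AD"], group_specs["Control"]],
        [8, 8],
        duration_s=60.0,
        fs=500.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_features(small_cohort):
    records, metadata, _ = small_cohort
    features, failures = extract_features(records)
    assert not failures
    return attach_metadata(features, metadata)


@pytest.fixture(scope="session")
def test_cohort_features(group_specs):
    """External test cohorts (SiteA/SiteB/Young), 60 s records."""
    records, metadata, _ = synthesize_cohort(
        [group_specs["SiteA"], group_specs["SiteB"], group_specs["Young"]],
        [6, 6, 4],
        duration_s=60.0,
        fs=500.0,
        seed=99,
    )
    features, failures = extract_features(records)
    assert not failures
    return attach_metadata(features, metadata)


@pytest.fixture(scope="session")
def separable_cohort_features():
    """Two groups separated by a factor-2 high-harmonic boost with tiny
    between-subject spread: linearly separable by construction."""
    low = GroupEffectSpec(
        "Low",
        radial_template(high_harmonic_boost=1.0),
        JitterSpec.uniform(amp_cv=4.0, phase_sd_deg=2.5, h1_amp_cv=1.0, period_cv=3.0),
        mmse_mean=28.0,
        mmse_sd=1.5,
        mean_hr_bpm=70.0,
    )
    high = GroupEffectSpec(
        "High",
        radial_template(high_harmonic_boost=2.0),
        JitterSpec.uniform(amp_cv=4.0, phase_sd_deg=2.5, h1_amp_cv=1.0, period_cv=3.0),
        mmse_mean=28.0,
        mmse_sd=1.5,
        mean_hr_bpm=70.0,
    )
    records, metadata, _ = synthesize_cohort(
        [high, low],
        [15, 15],
        duration_s=60.0,
        fs=500.0,
        seed=7,
        between_subject_sigma=0.02,
        severity_amp_coupling=0.0,
        severity_jitter_coupling=0.0,
    )
    features, failures = extract_features(records)
    assert not failures
    return attach_metadata(features, metadata)
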