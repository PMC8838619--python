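"""Generator contracts: validation, determinism, ground-truth closure."""

import numpy as np
import pandas as pd
import pytest

from pulsespec.config import DEFAULT_N_PER_GROUP, default_cohort
from pulsespec.errors import ValidationError
from pulsespec.simulate import (
    GroupEffectSpec,
    HarmonicTemplate,
    JitterSpec,
    radial_template,
    synthesize_cohort,
    synthesize_record,
)


@pytest.fixture(scope="module")
def template():
    return radial_template()


def zero_jitter_effect(template, hr=70.0):
    return GroupEffectSpec("G", template, JitterSpec(), mean_hr_bpm=hr)


class TestValidation:
    def test_template_requires_ten_harmonics(self):
        with pytest.raises(ValidationError):
            HarmonicTemplate((1.0,) * 9, (0.0,) * 9)

    def test_template_requires_positive_fundamental(self):
        with pytest.raises(ValidationError):
            HarmonicTemplate((0.0,) + (0.1,) * 9, (0.0,) * 10)

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValidationError):
            JitterSpec(amp_cv=(-1.0,) + (0.0,) * 9)
        with pytest.raises(ValidationError):
            JitterSpec(period_cv=-0.1)

    def test_nonfinite_config_rejected(self):
        with pytest.raises(ValidationError):
            JitterSpec(noise_sd=float("nan"))

    def test_mmse_range_enforced(self, template):
        with pytest.raises(ValidationError):
            GroupEffectSpec("G", template, JitterSpec(), mmse_mean=31.0)

    def test_record_preconditions(self, template):
        effect = zero_jitter_effect(template)
        with pytest.raises(ValidationError):
            synthesize_record(effect, duration_s=-1.0)
        with pytest.raises(ValidationError):
            synthesize_record(effect, duration_s=10.0, fs=50.0)

    def test_cohort_preconditions(self, template):
        effect = zero_jitter_effect(template)
        with pytest.raises(ValidationError):
            synthesize_cohort([], [], duration_s=10.0)
        with pytest.raises(ValidationError):
            synthesize_cohort([effect], [1, 2], duration_s=10.0)
        with pytest.raises(ValidationError):
            synthesize_cohort([effect], [0], duration_s=10.0)


class TestRecord:
    def test_determinism(self, template):
        effect = GroupEffectSpec(
            "G",
            template,
            JitterSpec.uniform(amp_cv=5.0, phase_sd_deg=3.0, period_cv=3.0, noise_sd=0.01),
            mean_hr_bpm=72.0,
        )
        rec1, gt1 = synthesize_record(effect, 20.0, 500.0, seed=5)
        rec2, gt2 = synthesize_record(effect, 20.0, 500.0, seed=5)
        assert np.array_equal(rec1.samples, rec2.samples)
        pd.testing.assert_frame_equal(gt1, gt2)
        rec3, _ = synthesize_record(effect, 20.0, 500.0, seed=6)
        assert not np.array_equal(rec1.samples, rec3.samples)

    def test_complete_beat_count_at_70bpm(self, template):
        # 180 s at exactly 60/70 s per beat fits 210 complete beats
        _, gt = synthesize_record(zero_jitter_effect(template, hr=70.0), 180.0, 500.0, seed=0)
        assert gt["beat_index"].nunique() == 210
        assert np.allclose(gt["period_s"], 60.0 / 70.0)

    def test_zero_jitter_beats_identical(self, template):
        record, _ = synthesize_record(zero_jitter_effect(template, hr=60.0), 10.0, 500.0, seed=0)
        beats = record.samples.reshape(10, 500)
        assert np.allclose(beats, beats[0], atol=1e-12)

    def test_amp_cv_closes_on_ground_truth(self, template):
        # 10% amplitude CV on harmonic 2, ~208 beats: sample CV within 10 +/- 2
        jitter = JitterSpec(
            amp_cv=(0.0, 10.0) + (0.0,) * 8,
            phase_sd_deg=(0.0,) * 10,
        )
        effect = GroupEffectSpec("G", template, jitter, mean_hr_bpm=70.0)
        _, gt = synthesize_record(effect, 180.0, 500.0, seed=3)
        a2 = gt.loc[gt["n"] == 2, "amplitude"]
        cv = 100.0 * a2.std(ddof=1) / a2.mean()
        assert cv == pytest.approx(10.0, abs=2.0)

    def test_phase_sd_closes_on_ground_truth(self, template):
        jitter = JitterSpec(
            amp_cv=(0.0,) * 10,
            phase_sd_deg=(0.0, 0.0, 5.0) + (0.0,) * 7,
        )
        effect = GroupEffectSpec("G", template, jitter, mean_hr_bpm=70.0)
        _, gt = synthesize_record(effect, 180.0, 500.0, seed=3)
        p3 = gt.loc[gt["n"] == 3, "phase_deg"]
        assert p3.std(ddof=1) == pytest.approx(5.0, rel=0.2)

    def test_onset_taper_changes_waveform_only(self, template):
        effect = zero_jitter_effect(template)
        plain, gt_plain = synthesize_record(effect, 10.0, 500.0, seed=0)
        tapered, gt_tapered = synthesize_record(effect, 10.0, 500.0, seed=0, onset_taper=True)
        assert not np.array_equal(plain.samples, tapered.samples)
        pd.testing.assert_frame_equal(gt_plain, gt_tapered)


class TestCohort:
    def test_bookkeeping(self, template):
        effects = [
            GroupEffectSpec("A", template, JitterSpec(), mean_hr_bpm=70.0),
            GroupEffectSpec("B", template, JitterSpec(), mean_hr_bpm=70.0),
        ]
        records, metadata, gt = synthesize_cohort(effects, [5, 5], 6.0, 500.0, seed=1)
        assert len(records) == 10
        assert len(metadata) == 10
        assert metadata["subject_id"].is_unique
        assert set(metadata["group"]) == {"A", "B"}
        assert set(gt["subject_id"]) == set(metadata["subject_id"])

    def test_degenerate_mmse_draw(self, template):
        effect = GroupEffectSpec(
            "A", template, JitterSpec(), mmse_mean=21.4, mmse_sd=0.0, mean_hr_bpm=70.0
        )
        _, metadata, _ = synthesize_cohort([effect], [6], 6.0, 500.0, seed=1)
        assert (metadata["mmse"] == 21).all()

    def test_default_study_design_counts(self):
        groups, n_per_group = default_cohort()
        records, metadata, _ = synthesize_cohort(groups, n_per_group, 6.0, 500.0, seed=2)
        assert len(records) == 123
        counts = metadata["group"].value_counts().to_dict()
        assert counts == DEFAULT_N_PER_GROUP

    def test_subject_streams_independent_of_other_counts(self, template):
        effects = [
            GroupEffectSpec("A", template, JitterSpec.uniform(amp_cv=5.0), mean_hr_bpm=70.0),
            GroupEffectSpec("B", template, JitterSpec.uniform(amp_cv=5.0), mean_hr_bpm=70.0),
        ]
        rec_small, _, _ = synthesize_cohort(effects, [3, 2], 6.0, 500.0, seed=9)
        rec_large, _, _ = synthesize_cohort(effects, [3, 5], 6.0, 500.0, seed=9)
        for a, b in zip(rec_small[:3], rec_large[:3]):
            assert a.subject_id == b.subject_id
            assert np.array_equal(a.samples, b.samples)

    def test_mmse_anticorrelated_with_high_harmonic_content(self, small_cohort):
        # severity coupling: lower MMSE -> relatively larger harmonics 6-10
        _, metadata, gt = small_cohort
        high = (
            gt[gt["n"] >= 6]
            .groupby("subject_id")["amplitude"]
            .mean()
        )
        fundamental = (
            gt[gt["n"] == 1]
            .groupby("subject_id")["amplitude"]
            .mean()
        )
        ratio = (high / fundamental).rename("ratio")
        merged = metadata.set_index("subject_id").join(ratio)
        r = np.corrcoef(merged["mmse"], merged["ratio"])[0, 1]
        assert r < 0
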