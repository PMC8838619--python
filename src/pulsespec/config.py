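"""Default study configuration and YAML config loading.

The default cohort mirrors the clinical study design the pipeline targets:
38 Alzheimer's-disease (AD) patients, 38 controls, 39 community subjects at
two sites (20 at the countryside Site A, 19 at the urban Site B) and 8 young
subjects. Group-level MMSE means/SDs and heart rates follow the published
subject characteristics (AD 12.16 +/- 5.52, Site A 21.84 +/- 5.19, Site B
23.95 +/- 4.39; HR 68.8 / 66.35 / 68.42 / 79.36 / 65.75 bpm). Waveform-level
parameters (harmonic boost, jitter levels) are the generator's own choices,
ordered so that AD > Control and Site A > Site B in higher-harmonic content
and beat-to-beat variability, and Young has the most stable phases.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ValidationError
from .simulate import GroupEffectSpec, HarmonicTemplate, JitterSpec, radial_template

__all__ = [
    "DEFAULT_GROUP_ORDER",
    "DEFAULT_N_PER_GROUP",
    "default_group_specs",
    "default_cohort",
    "load_cohort_config",
]

DEFAULT_GROUP_ORDER = ["AD", "Control", "SiteA", "SiteB", "Young"]
DEFAULT_N_PER_GROUP = {"AD": 38, "Control": 38, "SiteA": 20, "SiteB": 19, "Young": 8}

# boost: multiplier on template harmonics 4-10; amp_cv/phase_sd: beat-to-beat
# jitter (percent / degrees) on harmonics 2-10 (harmonic 1 held at 1% CV since
# it is the amplitude-proportion reference); mmse: (mean, sd) score points;
# hr: mean heart rate in bpm.
_GROUP_PARAMS: dict[str, dict] = {
    "AD": dict(boost=1.25, amp_cv=7.0, phase_sd=5.0, period_cv=5.0, mmse=(12.16, 5.52), hr=68.8),
    "Control": dict(boost=1.00, amp_cv=4.0, phase_sd=2.5, period_cv=3.0, mmse=(28.0, 1.5), hr=79.36),
    "SiteA": dict(boost=1.18, amp_cv=6.0, phase_sd=4.0, period_cv=4.0, mmse=(21.84, 5.19), hr=66.35),
    "SiteB": dict(boost=1.08, amp_cv=5.0, phase_sd=3.2, period_cv=3.5, mmse=(23.95, 4.39), hr=68.42),
    "Young": dict(boost=0.95, amp_cv=3.5, phase_sd=1.5, period_cv=3.0, mmse=(29.0, 1.0), hr=65.75),
}

_H1_AMP_CV = 1.0
_NOISE_SD = 0.005
_DRIFT_AMPLITUDE = 0.05


def _spec_from_params(name: str, p: dict) -> GroupEffectSpec:
    return GroupEffectSpec(
        group_name=name,
        template=radial_template(high_harmonic_boost=p["boost"]),
        jitter=JitterSpec.uniform(
            amp_cv=p["amp_cv"],
            phase_sd_deg=p["phase_sd"],
            h1_amp_cv=_H1_AMP_CV,
            period_cv=p["period_cv"],
            noise_sd=_NOISE_SD,
            drift_amplitude=_DRIFT_AMPLITUDE,
        ),
        mmse_mean=p["mmse"][0],
        mmse_sd=p["mmse"][1],
        mean_hr_bpm=p["hr"],
    )


def default_group_specs() -> dict[str, GroupEffectSpec]:
    """The five default group specifications, keyed by group name."""
    return {name: _spec_from_params(name, _GROUP_PARAMS[name]) for name in DEFAULT_GROUP_ORDER}


def default_cohort() -> tuple[list[GroupEffectSpec], list[int]]:
    """Default ``(groups, n_per_group)`` for :func:`simulate.synthesize_cohort`."""
    specs = default_group_specs()
    return (
        [specs[name] for name in DEFAULT_GROUP_ORDER],
        [DEFAULT_N_PER_GROUP[name] for name in DEFAULT_GROUP_ORDER],
    )


# ---------------------------------------------------------------------------
# YAML config


def _jitter_from_mapping(m: dict) -> JitterSpec:
    amp_cv = m.get("amp_cv", 0.0)
    phase_sd = m.get("phase_sd_deg", 0.0)
    kwargs = dict(
        period_cv=m.get("period_cv", 0.0),
        noise_sd=m.get("noise_sd", 0.0),
        drift_amplitude=m.get("drift_amplitude", 0.0),
    )
    if isinstance(amp_cv, (int, float)) and isinstance(phase_sd, (int, float)):
        return JitterSpec.uniform(
            amp_cv=amp_cv,
            phase_sd_deg=phase_sd,
            h1_amp_cv=m.get("h1_amp_cv"),
            **kwargs,
        )
    return JitterSpec(amp_cv=tuple(amp_cv), phase_sd_deg=tuple(phase_sd), **kwargs)


def _group_from_mapping(m: dict) -> tuple[GroupEffectSpec, int]:
    try:
        name = m["name"]
        n = int(m["n"])
    except KeyError as exc:
        raise ValidationError(f"group config missing required key: {exc}") from exc
    if "template" in m:
        t = m["template"]
        template = HarmonicTemplate(
            tuple(t["amplitudes"]), tuple(t["phases_deg"]), t.get("dc_offset", 2.0)
        )
    else:
        template = radial_template(
            high_harmonic_boost=m.get("high_harmonic_boost", 1.0),
            dc_offset=m.get("dc_offset", 2.0),
        )
    mmse = m.get("mmse", {})
    spec = GroupEffectSpec(
        group_name=str(name),
        template=template,
        jitter=_jitter_from_mapping(m.get("jitter", {})),
        mmse_mean=mmse.get("mean", 28.0),
        mmse_sd=mmse.get("sd", 1.5),
        mean_hr_bpm=m.get("mean_hr_bpm", 70.0),
    )
    return spec, n


_COHORT_KWARG_KEYS = (
    "between_subject_sigma",
    "subject_phase_sigma_deg",
    "severity_amp_coupling",
    "severity_jitter_coupling",
    "hr_between_sd_bpm",
    "onset_taper",
)


def load_cohort_config(path: str | Path) -> dict:
    """Parse a YAML cohort configuration.

    Returns a dict with keys ``groups`` (list of GroupEffectSpec),
    ``n_per_group``, ``duration_s``, ``fs`` and ``cohort_kwargs`` (extra
    keyword arguments for :func:`simulate.synthesize_cohort`). A config with
    no ``groups`` section falls back to the default five-group cohort.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("cohort config must be a mapping")
    if "groups" in raw:
        pairs = [_group_from_mapping(g) for g in raw["groups"]]
        groups = [p[0] for p in pairs]
        n_per_group = [p[1] for p in pairs]
    else:
        groups, n_per_group = default_cohort()
    return dict(
        groups=groups,
        n_per_group=n_per_group,
        duration_s=float(raw.get("duration_s", 180.0)),
        fs=float(raw.get("fs", 500.0)),
        cohort_kwargs={k: raw[k] for k in _COHORT_KWARG_KEYS if k in raw},
    )
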