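"""Synthetic cohorts of older adults with repeated stabilometric trials.

The generator plants a known class structure so every downstream stage
(index extraction, classifier, feature selection) is testable without
external data. Each trial is second-order low-pass-filtered Gaussian white
noise per axis, rescaled to a target RMS amplitude — this yields the
1/f-like sway spectra seen in quiet standing with directly controllable
power and bandwidth. For subjects in the at-risk class the per-axis
amplitude and filter cutoff are multiplied by the ``effect_map`` entries,
so e.g. ``{"gain_ap": 2.0}`` doubles AP sway amplitude (quadrupling AP
spectral power) for that class only.

Descriptive variables are drawn per subject from configurable normal
marginals (defaults match a cohort of community-dwelling adults 60+: age
71.3 +/- 6.4 y, height 157.2 +/- 8.1 cm, weight 63.1 +/- 8.4 kg, foot
length 22.6 +/- 1.3 cm, polypharmacy 2.3 +/- 1.6, 78.9% women); BMI is
derived as weight / height_m^2 rather than drawn. ``informative_features``
adds a class shift, in SD units, to named descriptive variables for
at-risk subjects. Trials are i.i.d. given the subject's class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter

from .indices import StabilogramTrial
from .registry import LABEL_FALL_RISK, LABEL_NON_FALL_RISK

__all__ = ["SyntheticCohortConfig", "generate_trial", "generate_cohort"]

#: Default descriptive marginals: (mean, SD) per variable.
DEFAULT_DESCRIPTIVE_PARAMS: dict[str, tuple[float, float]] = {
    "age": (71.3, 6.4),
    "height": (157.2, 8.1),
    "weight": (63.1, 8.4),
    "foot_length": (22.6, 1.3),
    "polypharmacy": (2.3, 1.6),
}

DEFAULT_P_FEMALE = 0.789


@dataclass
class SyntheticCohortConfig:
    """Parameters of a synthetic cohort with planted class structure."""

    n_subjects: int = 76
    p_fall_risk: float = 29 / 76
    trials_per_subject: int = 3
    fs: float = 100.0
    duration: float = 60.0
    #: per-axis baseline sway RMS in mm and filter cutoff in Hz
    rms_ap: float = 4.0
    rms_ml: float = 3.0
    cutoff_hz: float = 1.0
    #: lognormal coefficient of variation of the per-trial sway amplitude,
    #: emulating inter-subject/inter-trial spread; 0 disables it
    rms_cv: float = 0.4
    #: multiplicative class shifts for the at-risk class; recognised keys:
    #: gain_ap, gain_ml (sway amplitude), cutoff_ap, cutoff_ml (bandwidth)
    effect_map: dict[str, float] = field(default_factory=dict)
    #: descriptive variable -> class shift in SD units for at-risk subjects
    informative_features: dict[str, float] = field(default_factory=dict)
    descriptive_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTIVE_PARAMS))
    p_female: float = DEFAULT_P_FEMALE
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 < self.p_fall_risk < 1:
            raise ValueError("p_fall_risk must lie strictly in (0, 1)")
        if self.trials_per_subject < 1:
            raise ValueError("trials_per_subject must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if any(v <= 0 for v in self.effect_map.values()):
            raise ValueError("effect_map shifts must be positive")
        if not 0 <= self.p_female <= 1:
            raise ValueError("p_female must lie in [0, 1]")
        if self.rms_cv < 0:
            raise ValueError("rms_cv must be non-negative")


def _filtered_noise(n: int, fs: float, cutoff: float, rms: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Second-order low-pass filtered white noise, rescaled to target RMS."""
    white = rng.standard_normal(n)
    b, a = butter(2, min(cutoff, 0.45 * fs) / (fs / 2))
    x = lfilter(b, a, white)
    x = x - x.mean()
    scale = x.std()
    if scale > 0:
        x *= rms / scale
    return x


def generate_trial(class_label: str, cfg: SyntheticCohortConfig,
                   rng: np.random.Generator, subject_id: str = "S0",
                   trial_index: int = 0) -> StabilogramTrial:
    """One open-eyes quiet-standing stabilogram for a subject of the given class.

    At-risk trials apply the multiplicative ``effect_map`` shifts to the
    per-axis gain and cutoff; with an empty map the two classes share the
    same generating process.
    """
    cfg.validate()
    n = int(round(cfg.fs * cfg.duration))
    at_risk = class_label == LABEL_FALL_RISK
    eff = cfg.effect_map if at_risk else {}
    if cfg.rms_cv > 0:
        # independent unit-mean lognormal amplitude spread per axis,
        # emulating inter-subject/inter-trial sway variability
        sigma = math.sqrt(math.log1p(cfg.rms_cv**2))
        amp_ml = math.exp(rng.normal(-0.5 * sigma**2, sigma))
        amp_ap = math.exp(rng.normal(-0.5 * sigma**2, sigma))
    else:
        amp_ml = amp_ap = 1.0
    ml = _filtered_noise(n, cfg.fs, cfg.cutoff_hz * eff.get("cutoff_ml", 1.0),
                         amp_ml * cfg.rms_ml * eff.get("gain_ml", 1.0), rng)
    ap = _filtered_noise(n, cfg.fs, cfg.cutoff_hz * eff.get("cutoff_ap", 1.0),
                         amp_ap * cfg.rms_ap * eff.get("gain_ap", 1.0), rng)
    return StabilogramTrial(subject_id=subject_id, trial_index=trial_index,
                            fs=cfg.fs, ml=ml, ap=ap)


def generate_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[pd.DataFrame, list[StabilogramTrial]]:
    """Generate the subject table and all trials of a synthetic cohort.

    The realized number of at-risk subjects is exactly
    ``round(n_subjects * p_fall_risk)``; fall history and the
    high-fall-concern flag are generated consistently with the label rule
    (at least one fall in the last year and/or high concern iff at risk).
    Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_subjects
    n_risk = int(round(n * cfg.p_fall_risk))
    labels = np.array([LABEL_FALL_RISK] * n_risk
                      + [LABEL_NON_FALL_RISK] * (n - n_risk))
    rng.shuffle(labels)

    rows = []
    trials: list[StabilogramTrial] = []
    for i in range(n):
        sid = f"S{i:03d}"
        label = labels[i]
        at_risk = label == LABEL_FALL_RISK
        draw = {}
        for var, (mu, sd) in cfg.descriptive_params.items():
            shift = cfg.informative_features.get(var, 0.0) if at_risk else 0.0
            draw[var] = mu + shift * sd + sd * rng.standard_normal()
        sex = int(rng.random() < cfg.p_female)  # 1 = woman
        age = max(draw.get("age", 71.3), 60.0)  # cohort restricted to 60+
        height = max(draw.get("height", 157.2), 120.0)
        weight = max(draw.get("weight", 63.1), 30.0)
        foot_length = max(draw.get("foot_length", 22.6), 15.0)
        polypharmacy = max(int(round(draw.get("polypharmacy", 2.3))), 0)
        bmi = weight / (height / 100.0) ** 2

        if at_risk:
            # guarantee the label rule: >=1 fall and/or high concern
            falls = rng.poisson(1.5)
            fes_high = bool(rng.random() < 0.5)
            if falls == 0 and not fes_high:
                falls = 1
        else:
            falls, fes_high = 0, False

        rows.append({
            "subject_id": sid, "sex": sex, "age": age, "height": height,
            "weight": weight, "bmi": bmi, "foot_length": foot_length,
            "polypharmacy": polypharmacy, "falls_12mo": falls,
            "fes_high_concern": fes_high, "label": label,
        })
        for t in range(cfg.trials_per_subject):
            trials.append(generate_trial(label, cfg, rng,
                                         subject_id=sid, trial_index=t))

    subjects = pd.DataFrame(rows)
    return subjects, trials
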