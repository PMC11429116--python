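"""Shared fixtures: synthetic feature tables and small cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import swayrisk as sw


def make_feature_table(n_rows: int = 180, n_risk: int = 87,
                       informative: dict[str, float] | None = None,
                       risk_scale: float = 0.35,
                       seed: int = 0) -> pd.DataFrame:
    """Trial-level table with all 47 features as standard-normal noise.

    ``informative`` maps feature name -> additive class shift (in SD units)
    applied to at-risk rows; on those features the at-risk rows also get
    within-class noise scale ``risk_scale``, making the at-risk class a
    compact cluster — the regime the single-class Gaussian score detects.
    """
    rng = np.random.default_rng(seed)
    y = np.array([sw.LABEL_FALL_RISK] * n_risk
                 + [sw.LABEL_NON_FALL_RISK] * (n_rows - n_risk))
    rng.shuffle(y)
    cols = {f: rng.standard_normal(n_rows) for f in sw.ALL_FEATURES}
    risk = y == sw.LABEL_FALL_RISK
    for feat, shift in (informative or {}).items():
        x = cols[feat].copy()
        x[risk] = shift + risk_scale * x[risk]
        cols[feat] = x
    table = pd.DataFrame(cols)
    table.insert(0, "subject_id", [f"S{i:03d}" for i in range(n_rows)])
    table.insert(1, "trial_index", 0)
    table.insert(2, "label", y)
    return table


@pytest.fixture
def feature_table() -> pd.DataFrame:
    return make_feature_table(
        informative={"std_rd": 1.2, "total_power_ap": 1.2, "sex": 1.0,
                     "centroid_freq": 1.0, "freq_dispersion_ap": 1.0})


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort with a planted AP-power effect, 3 trials each."""
    cfg = sw.SyntheticCohortConfig(
        n_subjects=12, p_fall_risk=0.5, trials_per_subject=3,
        duration=10.0, seed=7, effect_map={"gain_ap": 1.8})
    return sw.generate_cohort(cfg)
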