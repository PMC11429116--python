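"""Wrapper feature selection by simulated annealing.

Plants five informative features in an otherwise pure-noise 47-feature
table, then sweeps the annealer over growing subset sizes. The cost of a
candidate subset is mean(AUC) - sd(AUC) over train/test/validation, so the
selector rewards consistent generalization. A reduced schedule (Lk0=10,
Tmin=0.1) keeps this demo quick; the full schedule uses Lk0=30 down to
Tmin=0.0232 (17 temperature levels, ~196k evaluations per dimension).
"""

import warnings

import numpy as np
import pandas as pd

import swayrisk as sw
from swayrisk.annealing import SAConfig, dimension_sweep, search_space_size
from swayrisk.validation import feature_frequency


def noise_table_with_planted_features(planted, n_rows=180, n_risk=87,
                                      seed=0):
    """47 standard-normal features; planted ones get a compact at-risk
    cluster shifted by the given amount (in SD units)."""
    rng = np.random.default_rng(seed)
    y = np.array([sw.LABEL_FALL_RISK] * n_risk
                 + [sw.LABEL_NON_FALL_RISK] * (n_rows - n_risk))
    rng.shuffle(y)
    risk = y == sw.LABEL_FALL_RISK
    cols = {f: rng.standard_normal(n_rows) for f in sw.ALL_FEATURES}
    for feat, shift in planted.items():
        cols[feat][risk] = shift + 0.6 * cols[feat][risk]
    table = pd.DataFrame(cols)
    table.insert(0, "subject_id", [f"S{i:03d}" for i in range(n_rows)])
    table.insert(1, "trial_index", 0)
    table.insert(2, "label", y)
    return table


planted = {"std_rd": 1.0, "total_power_ap": 1.0, "sex": 1.0,
           "centroid_freq": 1.0, "freq_dispersion_ap": 1.0}
table = noise_table_with_planted_features(planted)
split = sw.stratified_split(table, seed=0)
ztable, _ = sw.standardize(table, fit_rows=split.train)

print(f"search space at n=21 over a 42-feature pool: "
      f"{search_space_size(42, 21):,} subsets")

cfg = SAConfig(lk0=10, tmin=0.1, penalty_threshold=0.0, seed=0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    sweep = dimension_sweep(cfg, split, ztable, stop_patience=2, seed=0)

for n, res in sweep.dimensions.items():
    print(f"  n={n:2d}  best cost {res.best_cost:.3f}  "
          f"({res.n_evals} evaluations)")
print("\nmost frequently selected features:")
print(feature_frequency(sweep).head(8).to_string(index=False))
# The planted features should dominate the tally: the annealer keeps
# rediscovering them at every dimension.
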