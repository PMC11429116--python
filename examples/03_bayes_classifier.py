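"""Train and evaluate the Gaussian Bayes fall-risk classifier.

Assembles a labeled feature table from a synthetic cohort, balances the
records (3 trials kept per at-risk subject, 2 per non-risk), standardizes
on the training rows, fits the single-class Gaussian on the at-risk
training rows and reports sensitivity / specificity / AUC per hold-out set.
"""

import warnings

import pandas as pd

import swayrisk as sw

cfg = sw.SyntheticCohortConfig(
    n_subjects=76, p_fall_risk=29 / 76, trials_per_subject=3,
    duration=60.0, seed=1, effect_map={"gain_ap": 1.5, "gain_ml": 1.3})
subjects, trials = sw.generate_cohort(cfg)
rows = []
for tr in trials:
    r = {"subject_id": tr.subject_id, "trial_index": tr.trial_index}
    r.update(sw.compute_all(tr))
    rows.append(r)
table = sw.assemble_feature_table(pd.DataFrame(rows), subjects)
table = sw.balance_records(table, nfr_keep=2, fr_keep=3)
print(f"{len(table)} records "
      f"({(table['label'] == sw.LABEL_FALL_RISK).sum()} at risk)")

split = sw.stratified_split(table, seed=1)
ztable, _ = sw.standardize(table, fit_rows=split.train)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = sw.bayes.fit(ztable.loc[split.train], list(sw.SEED_FEATURES))
    metrics = sw.bayes.evaluate(model, ztable, split)

for name, m in metrics.items():
    print(f"  {name:10s} SE {m['sensitivity']:.2f}  SP {m['specificity']:.2f}"
          f"  AUC {m['auc']:.3f}")
# AUC ~ 0.5 would mean no signal; the planted AP/ML amplitude effect puts
# the 11-feature evidence-based model above chance on the held-out sets.
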