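"""Labeled feature tables: labeling, record balancing, standardization, splits.

A feature table is a trial-level DataFrame with metadata columns
(``subject_id``, ``trial_index``, ``label``) and the 47 predictor columns
(40 CoP indices + 7 descriptive variables). The fall-risk label is assigned
per subject from fall history and fall concern; classes are balanced at the
record level by keeping a different number of repeated trials per class;
features are z-scored with parameters fitted on designated rows (train rows
by default, to avoid leakage into held-out sets); and the stratified
60-20-20 hold-out split allocates per class by largest-remainder rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import (
    ALL_FEATURES,
    LABEL_FALL_RISK,
    LABEL_NON_FALL_RISK,
    META_COLUMNS,
)

__all__ = [
    "StandardizationParams",
    "DataSplit",
    "assign_fall_risk_label",
    "label_subjects",
    "assemble_feature_table",
    "balance_records",
    "standardize",
    "stratified_split",
    "read_feature_table",
    "write_feature_table",
]


def assign_fall_risk_label(falls_12mo, fes_high_concern) -> str:
    """Fall Risk iff >=1 fall in the previous 12 months and/or high fall concern."""
    if falls_12mo is None and fes_high_concern is None:
        raise ValueError("labeling requires fall history and/or the "
                         "high-concern flag")
    falls = 0 if falls_12mo is None else falls_12mo
    concern = bool(fes_high_concern) if fes_high_concern is not None else False
    return LABEL_FALL_RISK if (falls >= 1 or concern) else LABEL_NON_FALL_RISK


def label_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite the ``label`` column of a subject table from the rule."""
    out = subjects.copy()
    out["label"] = [
        assign_fall_risk_label(f, c)
        for f, c in zip(out["falls_12mo"], out["fes_high_concern"])
    ]
    return out


def assemble_feature_table(index_rows: pd.DataFrame,
                           subjects: pd.DataFrame) -> pd.DataFrame:
    """Join per-trial CoP indices with subject descriptive variables + label.

    ``index_rows`` must carry ``subject_id``/``trial_index`` plus the 40 CoP
    indices; ``subjects`` the descriptive variables and ``label``. Rows with
    missing feature values are rejected.
    """
    desc_cols = ["subject_id", "sex", "age", "height", "weight", "bmi",
                 "foot_length", "polypharmacy", "label"]
    table = index_rows.merge(subjects[desc_cols], on="subject_id",
                             validate="many_to_one")
    cols = list(META_COLUMNS) + list(ALL_FEATURES)
    table = table[cols]
    bad = table[list(ALL_FEATURES)].isna().any(axis=1)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} rows with missing features",
                      stacklevel=2)
        table = table.loc[~bad]
    return table.reset_index(drop=True)


def balance_records(table: pd.DataFrame, nfr_keep: int = 1,
                    fr_keep: int = 3) -> pd.DataFrame:
    """Balance classes by keeping the earliest trials per subject.

    At-risk subjects contribute their ``fr_keep`` earliest trials (by
    ``trial_index``), the others ``nfr_keep``. A subject with fewer trials
    than requested keeps all it has, with a warning.
    """
    kept = []
    short = 0
    for (sid, label), grp in table.groupby(["subject_id", "label"], sort=False):
        keep = fr_keep if label == LABEL_FALL_RISK else nfr_keep
        grp = grp.sort_values("trial_index")
        if len(grp) < keep:
            short += 1
        kept.append(grp.head(keep))
    if short:
        warnings.warn(f"{short} subjects have fewer trials than requested; "
                      "keeping all available", stacklevel=2)
    return pd.concat(kept).reset_index(drop=True)


@dataclass
class StandardizationParams:
    """Per-feature location/scale estimated on the fit rows."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.drop(columns=self.dropped, errors="ignore").copy()
        cols = self.mean.index
        out[cols] = (out[cols] - self.mean) / self.sd
        return out


def standardize(
    table: pd.DataFrame,
    fit_rows=None,
    columns=None,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score features using mean/SD estimated from ``fit_rows``.

    ``fit_rows`` defaults to all rows (whole-table mode); pass the train
    index set to avoid leakage into held-out rows. Constant features on the
    fit rows are dropped with a warning. Sample (N-1) SD.
    """
    if columns is None:
        columns = [c for c in ALL_FEATURES if c in table.columns]
    fit = table.loc[fit_rows, columns] if fit_rows is not None \
        else table[columns]
    if len(fit) == 0:
        raise ValueError("fit_rows must be non-empty")
    mean = fit.mean()
    sd = fit.std(ddof=1)
    dropped = list(sd.index[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    keep = [c for c in columns if c not in dropped]
    params = StandardizationParams(mean=mean[keep], sd=sd[keep],
                                   dropped=dropped)
    return params.transform(table), params


@dataclass
class DataSplit:
    """Disjoint train/test/validation row-index sets, stratified by label."""

    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def sets(self) -> dict[str, np.ndarray]:
        return {"train": self.train, "test": self.test,
                "validation": self.validation}


def _largest_remainder(n: int, fractions) -> list[int]:
    quotas = [n * f for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(base)
    remainders = sorted(range(len(fractions)),
                        key=lambda i: (-(quotas[i] - base[i]), i))
    for i in remainders[:leftover]:
        base[i] += 1
    return base


def stratified_split(table: pd.DataFrame,
                     fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0,
                     group_by_subject: bool = False) -> DataSplit:
    """Stratified hold-out split by label with largest-remainder allocation.

    Within each class, rows are shuffled by ``seed`` and dealt to
    train/test/validation in the per-class counts given by
    largest-remainder rounding of ``fractions`` (ties broken toward the
    earlier set), so per-class counts are within 1 of exact proportionality.
    With ``group_by_subject`` the allocation units are subjects, keeping
    all repeated trials of a subject in the same set.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: dict[str, list[np.ndarray]] = {"train": [], "test": [],
                                          "validation": []}
    for label in sorted(table["label"].unique()):
        mask = table["label"] == label
        if group_by_subject:
            units = table.loc[mask, "subject_id"].unique()
        else:
            units = table.index[mask].to_numpy()
        if len(units) < 3 and min(fractions) > 0:
            raise ValueError(f"class {label!r} has fewer than 3 rows")
        units = rng.permutation(units)
        n_tr, n_te, n_va = _largest_remainder(len(units), fractions)
        chunks = (units[:n_tr], units[n_tr:n_tr + n_te], units[n_tr + n_te:])
        for name, chunk in zip(("train", "test", "validation"), chunks):
            if group_by_subject:
                chunk = table.index[
                    mask & table["subject_id"].isin(chunk)].to_numpy()
            parts[name].append(chunk)
    return DataSplit(
        train=np.sort(np.concatenate(parts["train"])),
        test=np.sort(np.concatenate(parts["test"])),
        validation=np.sort(np.concatenate(parts["validation"])),
        fractions=tuple(fractions), seed=seed,
    )


# --- feature-table I/O ------------------------------------------------------

def _validate_schema(columns) -> None:
    allowed = set(META_COLUMNS) | set(ALL_FEATURES)
    unknown = [c for c in columns if c not in allowed]
    if unknown:
        raise ValueError(f"unknown feature-table columns: {unknown}")
    if "label" not in columns:
        raise ValueError("feature table is missing the 'label' column")
    if "subject_id" not in columns:
        raise ValueError("feature table is missing the 'subject_id' column")


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV (12 significant digits, lossless for reads)."""
    _validate_schema(table.columns)
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV, validating columns against the registry."""
    table = pd.read_csv(path)
    _validate_schema(table.columns)
    return table
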