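"""Classifier-based validation of a log-ratio indicator.

Two procedures, mirroring how a focused indicator is benchmarked against the
full feature table:

* ``rf_cv_auc`` — stratified 10-fold cross-validated ROC AUC of a
  500-tree Random Forest, from out-of-fold probability predictions;
* ``compare_classifiers`` — repeated stratified 50:50 splits; on each split
  a forest trained on the full table and one trained on the
  indicator-restricted table classify the test half, and McNemar's test on
  the discordant predictions asks whether the two classifiers differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .mip import IndicatorSpec, LogRatioIndicator

__all__ = [
    "rf_cv_auc",
    "restrict_to_indicator",
    "mcnemar_test",
    "compare_classifiers",
    "ComparisonResult",
]


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(str)
    levels = sorted(np.unique(y))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 classes, got {levels}")
    positive = "deep" if "deep" in levels else levels[1]
    return (y == positive).astype(int)


def rf_cv_auc(
    X,
    labels,
    n_estimators: int = 500,
    n_folds: int = 10,
    seed: int = 0,
):
    """Stratified K-fold ROC AUC of a Random Forest.

    Returns ``(per_fold_auc, mean, sd)``; the AUC of each fold is computed on
    that fold's out-of-fold probability predictions.
    """
    X = np.asarray(X, dtype=float)
    y = _as_binary(labels)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError(f"smallest class ({counts.min()}) has fewer members than n_folds={n_folds}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed + k, n_jobs=1)
        clf.fit(X[tr], y[tr])
        prob = clf.predict_proba(X[te])[:, 1]
        aucs.append(roc_auc_score(y[te], prob))
    aucs = np.asarray(aucs)
    return aucs, float(aucs.mean()), float(aucs.std(ddof=1))


def restrict_to_indicator(
    table: pd.DataFrame,
    taxonomy: pd.Series,
    spec: IndicatorSpec,
    series: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Feature table restricted to the indicator's taxa, with the log-ratio
    appended as an extra column.

    Samples whose log-ratio is dropped (zero on either side) get the column
    minimum imputed and are flagged in the ``log_ratio_imputed`` attribute
    column convention used by callers; the returned frame stores the imputed
    values in ``log_ratio``.
    """
    indicator = LogRatioIndicator(spec).fit(taxonomy)
    if series is None:
        series = indicator.transform(table)
    cols = [
        f
        for f in table.columns
        if f in set(indicator.numerator_features_) | set(indicator.denominator_features_)
    ]
    restricted = table[cols].astype(float).copy()
    lr = series["value"].reindex(table.index)
    if lr.notna().sum() == 0:
        raise ValueError("every sample's log-ratio is dropped")
    fill = float(lr.min())
    restricted["log_ratio"] = lr.fillna(fill)
    restricted.attrs["log_ratio_imputed"] = series["dropped"].reindex(table.index).tolist()
    return restricted


def mcnemar_test(b: int, c: int, mode: str = "auto") -> float:
    """McNemar's test on a discordance pair count.

    ``b``/``c`` are the two off-diagonal cells (one classifier right, the
    other wrong).  ``exact`` = two-sided binomial
    ``min(1, 2 P(X <= min(b,c)))`` with ``X ~ Binomial(b+c, 1/2)``;
    ``cc_chi2`` = continuity-corrected chi-square ``(|b-c|-1)^2/(b+c)``,
    1 df.  ``auto`` uses exact below b+c = 25.  ``b = c = 0`` returns 1.
    """
    if b < 0 or c < 0:
        raise ValueError("b and c must be nonnegative")
    n = b + c
    if n == 0:
        return 1.0
    if mode == "auto":
        mode = "exact" if n < 25 else "cc_chi2"
    if mode == "exact":
        return min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
    if mode == "cc_chi2":
        chi2 = (abs(b - c) - 1) ** 2 / n
        return float(stats.chi2.sf(chi2, df=1))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ComparisonResult:
    """Outcome of the repeated 50:50 full-vs-restricted comparison."""

    auc_full: list[float] = field(default_factory=list)
    auc_restricted: list[float] = field(default_factory=list)
    contingency: list[tuple[int, int]] = field(default_factory=list)  # (b, c) per split
    p_values: list[float] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return int(sum(p < 0.05 for p in self.p_values))

    def summary(self) -> dict:
        af, ar = np.asarray(self.auc_full), np.asarray(self.auc_restricted)
        return {
            "mean_auc_full": float(af.mean()),
            "sd_auc_full": float(af.std(ddof=1)),
            "mean_auc_restricted": float(ar.mean()),
            "sd_auc_restricted": float(ar.std(ddof=1)),
            "n_significant": self.n_significant,
            "n_repeats": len(self.p_values),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "auc_full": self.auc_full,
                "auc_restricted": self.auc_restricted,
                "b": [bc[0] for bc in self.contingency],
                "c": [bc[1] for bc in self.contingency],
                "mcnemar_p": self.p_values,
            }
        )


def compare_classifiers(
    table: pd.DataFrame,
    taxonomy: pd.Series,
    spec: IndicatorSpec,
    labels,
    n_repeats: int = 10,
    split: float = 0.5,
    n_estimators: int = 500,
    seed: int = 0,
) -> ComparisonResult:
    """Repeated stratified 50:50 comparison of the full-table forest against
    the indicator-restricted forest, with a per-split McNemar test.

    On each split both forests are trained on the same train half; test-half
    class calls are made at probability threshold 0.5; the McNemar
    discordance table counts samples one classifier got right and the other
    wrong.  ROC AUCs on the test half are recorded for both arms.
    """
    y = _as_binary(labels)
    X_full = table.to_numpy(dtype=float)
    restricted = restrict_to_indicator(table, taxonomy, spec)
    X_res = restricted.to_numpy(dtype=float)
    sss = StratifiedShuffleSplit(n_splits=n_repeats, test_size=split, random_state=seed)
    result = ComparisonResult()
    for k, (tr, te) in enumerate(sss.split(X_full, y)):
        rf_full = RandomForestClassifier(n_estimators=n_estimators, random_state=seed + k, n_jobs=1)
        rf_res = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed + k, n_jobs=1
        )
        rf_full.fit(X_full[tr], y[tr])
        rf_res.fit(X_res[tr], y[tr])
        prob_full = rf_full.predict_proba(X_full[te])[:, 1]
        prob_res = rf_res.predict_proba(X_res[te])[:, 1]
        pred_full = (prob_full >= 0.5).astype(int)
        pred_res = (prob_res >= 0.5).astype(int)
        correct_full = pred_full == y[te]
        correct_res = pred_res == y[te]
        b = int((correct_full & ~correct_res).sum())
        c = int((~correct_full & correct_res).sum())
        result.auc_full.append(float(roc_auc_score(y[te], prob_full)))
        result.auc_restricted.append(float(roc_auc_score(y[te], prob_res)))
        result.contingency.append((b, c))
        result.p_values.append(mcnemar_test(b, c))
    return result
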