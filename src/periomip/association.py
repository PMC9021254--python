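"""Covariate-adjusted association of the indicator with clinical outcomes.

Participant-level exposure is the mean plaque log-ratio (mean of the shallow
and deep values when both exist).  Outcomes are regressed on the exposure by
OLS adjusting for age, sex, race, BMI and smoking (never vs ever by
default), with listwise deletion of missing rows — the per-model N is
reported.  Quartile analyses fit the outcome on quartile (categorical for
adjusted means, ordinal for the trend p) with a participant random intercept
when participants contribute repeated rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .io import validate_count_table
from .mip import MIP_SPEC, compute_log_ratio, participant_mip, quartile_bins

__all__ = [
    "faiths_pd",
    "ModelResult",
    "adjusted_linear_model",
    "QuartileResult",
    "quartile_trend_model",
    "pearson",
    "run_association_suite",
    "DEFAULT_COVARIATES",
    "PERIODONTAL_OUTCOMES",
    "METABOLIC_OUTCOMES",
]

DEFAULT_COVARIATES = ("age", "sex", "race", "bmi", "smoking")
PERIODONTAL_OUTCOMES = ("attachment_loss_mm", "pocket_depth_mm", "pct_bop", "faith_pd")
METABOLIC_OUTCOMES = ("meansbp", "meandbp", "glucose", "insulin", "homa_ir", "hba1c")


def faiths_pd(table: pd.DataFrame, tree) -> pd.Series:
    """Faith's phylogenetic diversity per sample.

    PD is the total branch length of the minimal subtree connecting a
    sample's nonzero features to the root (root path included).
    """
    table = validate_count_table(table)
    tips = {t.name for t in tree.tips()}
    missing = [f for f in table.columns if f not in tips]
    if missing:
        raise ValueError(f"features absent from tree: {missing[:10]}")
    present = table.to_numpy() > 0
    col_of = {f: i for i, f in enumerate(table.columns)}
    n_samples = present.shape[0]
    pd_vals = np.zeros(n_samples)
    # postorder accumulation: a branch counts when its subtree holds >= 1
    # observed feature of the sample
    has = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = (
                present[:, col_of[node.name]]
                if node.name in col_of
                else np.zeros(n_samples, dtype=bool)
            )
        else:
            vec = np.zeros(n_samples, dtype=bool)
            for child in node.children:
                vec |= has.pop(id(child))
        has[id(node)] = vec
        length = node.length or 0.0
        if node.parent is not None and length > 0:
            pd_vals += length * vec
    return pd.Series(pd_vals, index=table.index, name="faith_pd")


@dataclass
class ModelResult:
    outcome: str
    estimate: float
    std_error: float
    p_value: float
    n: int
    covariates: tuple[str, ...]


def _covariate_terms(data: pd.DataFrame, covariates) -> list[str]:
    terms = []
    for cov in covariates:
        if cov not in data.columns:
            warnings.warn(f"covariate {cov!r} absent; skipped", stacklevel=3)
            continue
        if data[cov].dtype.kind in "biufc":
            terms.append(cov)
        else:
            terms.append(f"C({cov})")
    return terms


def _check_rank(fit, label: str) -> None:
    exog = fit.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = fit.model.exog_names
        raise ValueError(f"{label}: rank-deficient design; check collinearity among {names}")


def adjusted_linear_model(
    data: pd.DataFrame,
    outcome: str,
    exposure: str = "mip",
    covariates=DEFAULT_COVARIATES,
) -> ModelResult:
    """OLS of ``outcome`` on ``exposure`` plus covariates (listwise deletion).

    Returns the exposure coefficient with its SE, two-sided p, and the
    per-model N after deletion of incomplete rows.
    """
    terms = [exposure] + _covariate_terms(data, covariates)
    formula = f"Q('{outcome}') ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data, missing="drop").fit()
    _check_rank(fit, outcome)
    return ModelResult(
        outcome=outcome,
        estimate=float(fit.params[exposure]),
        std_error=float(fit.bse[exposure]),
        p_value=float(fit.pvalues[exposure]),
        n=int(fit.nobs),
        covariates=tuple(covariates),
    )


@dataclass
class QuartileResult:
    outcome: str
    table: pd.DataFrame  # index quartile 1..4: n, adjusted_mean, std_error
    trend_p: float
    model: str  # "mixed" or "ols"


def quartile_trend_model(
    data: pd.DataFrame,
    outcome: str,
    quartile_col: str = "quartile",
    covariates=DEFAULT_COVARIATES,
    cluster: str = "participant_id",
) -> QuartileResult:
    """Adjusted per-quartile means ± SE and an ordinal trend p-value.

    When participants contribute repeated rows, a linear mixed model with a
    participant random intercept absorbs within-person correlation; with one
    row per participant the model reduces to OLS.  Adjusted means are
    marginal predictions (every row set to quartile q, covariates as
    observed) with delta-method standard errors.
    """
    cols = [outcome, quartile_col] + [c for c in covariates if c in data.columns]
    if cluster in data.columns:
        cols.append(cluster)
    sub = data[cols].dropna().copy()
    counts = sub[quartile_col].value_counts()
    quartiles = sorted(sub[quartile_col].unique())
    if len(quartiles) < 4:
        raise ValueError(f"empty quartile(s): populated = {quartiles}")
    terms = _covariate_terms(sub, covariates)
    cat_formula = f"Q('{outcome}') ~ C({quartile_col})" + "".join(f" + {t}" for t in terms)
    ord_formula = f"Q('{outcome}') ~ {quartile_col}" + "".join(f" + {t}" for t in terms)

    repeated = cluster in sub.columns and sub[cluster].duplicated().any()
    if repeated:
        cat_fit = smf.mixedlm(cat_formula, data=sub, groups=sub[cluster]).fit(reml=True)
        ord_fit = smf.mixedlm(ord_formula, data=sub, groups=sub[cluster]).fit(reml=True)
        params = cat_fit.fe_params
        cov = cat_fit.cov_params().loc[params.index, params.index]
        design_info = cat_fit.model.data.design_info
        model_kind = "mixed"
        trend_p = float(ord_fit.pvalues[quartile_col])
    else:
        cat_fit = smf.ols(cat_formula, data=sub).fit()
        _check_rank(cat_fit, outcome)
        ord_fit = smf.ols(ord_formula, data=sub).fit()
        params = cat_fit.params
        cov = cat_fit.cov_params()
        design_info = cat_fit.model.data.design_info
        model_kind = "ols"
        trend_p = float(ord_fit.pvalues[quartile_col])

    from patsy import dmatrix

    rows = []
    for q in quartiles:
        counter = sub.copy()
        counter[quartile_col] = q
        X = np.asarray(dmatrix(design_info, counter, return_type="matrix"))
        g = X.mean(axis=0)
        mean = float(g @ np.asarray(params))
        se = float(np.sqrt(g @ np.asarray(cov) @ g))
        rows.append({"quartile": int(q), "n": int(counts[q]), "adjusted_mean": mean, "std_error": se})
    table = pd.DataFrame(rows).set_index("quartile")
    return QuartileResult(outcome=outcome, table=table, trend_p=trend_p, model=model_kind)


def pearson(x, y):
    """Pearson correlation on pairwise-complete observations.

    Returns ``(r, p)`` with p from the t transform on n − 2 df.
    """
    s = pd.DataFrame({"x": np.asarray(x, dtype=float), "y": np.asarray(y, dtype=float)}).dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 complete pairs")
    if s["x"].std() == 0 or s["y"].std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(s["x"], s["y"])
    return float(r), float(p)


def _participant_frame(series, meta, pd_series=None, collapse_smoking=True) -> pd.DataFrame:
    """Collapse per-sample metadata and MIP to one row per participant."""
    exposure = participant_mip(series, meta)
    keep = [
        c
        for c in meta.columns
        if c not in ("site_class", "pocket_depth_mm")
    ]
    part = meta.groupby("participant_id")[ [c for c in keep if c != "participant_id"] ].first()
    part["pocket_depth_mm"] = meta.groupby("participant_id")["pocket_depth_mm"].mean()
    if pd_series is not None:
        joined = pd_series.to_frame().join(meta[["participant_id"]])
        part["faith_pd"] = joined.groupby("participant_id")["faith_pd"].mean()
    part["mip"] = exposure
    if collapse_smoking and "smoking" in part.columns:
        part["smoking"] = np.where(part["smoking"].astype(str) == "never", "never", "ever")
    return part


def run_association_suite(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    taxonomy: pd.Series,
    tree=None,
    stratum: str = "all",
    covariates=DEFAULT_COVARIATES,
) -> dict[str, pd.DataFrame]:
    """Tables-1-through-6-shaped association reports for one stratum.

    ``stratum``: ``all`` (mean plaque MIP per participant), ``shallow_only``
    (exposure from shallow sites only), ``moderate_severe_only`` (restricted
    to participants with at least one deep site).

    Returns panels ``periodontal`` and ``metabolic`` (linear-model rows) plus
    ``quartiles_periodontal`` / ``quartiles_metabolic`` (quartile trends).
    """
    if stratum not in ("all", "shallow_only", "moderate_severe_only"):
        raise ValueError(f"unknown stratum {stratum!r}")
    # metadata may describe samples the filters removed; align on the table
    common = table.index.intersection(meta.index)
    table = table.loc[common]
    meta = meta.loc[common]
    series = compute_log_ratio(table, taxonomy, MIP_SPEC)
    use_meta = meta
    if stratum == "shallow_only":
        keep = meta["site_class"] == "shallow"
        series = series.loc[keep[series.index]]
        use_meta = meta.loc[keep]
    elif stratum == "moderate_severe_only":
        with_deep = meta.loc[meta["site_class"] == "deep", "participant_id"].unique()
        keep = meta["participant_id"].isin(with_deep)
        series = series.loc[keep[series.index]]
        use_meta = meta.loc[keep]
    if use_meta.empty or series["value"].notna().sum() == 0:
        raise ValueError(f"stratum {stratum!r} is empty")

    pd_series = None
    if tree is not None:
        pd_series = faiths_pd(table.loc[use_meta.index], tree)
    part = _participant_frame(series, use_meta, pd_series)
    part["quartile"] = quartile_bins(part["mip"])

    panels: dict[str, pd.DataFrame] = {}
    for panel_name, outcomes in (
        ("periodontal", PERIODONTAL_OUTCOMES),
        ("metabolic", METABOLIC_OUTCOMES),
    ):
        rows = []
        for outcome in outcomes:
            if outcome not in part.columns:
                continue
            res = adjusted_linear_model(part, outcome, "mip", covariates)
            rows.append(
                {
                    "outcome": outcome,
                    "n": res.n,
                    "estimate": res.estimate,
                    "std_error": res.std_error,
                    "p_value": res.p_value,
                }
            )
        panels[panel_name] = pd.DataFrame(rows).set_index("outcome")

        qrows = []
        for outcome in outcomes:
            if outcome not in part.columns:
                continue
            qres = quartile_trend_model(part, outcome, "quartile", covariates)
            qrows.append({"outcome": outcome, "trend_p": qres.trend_p, "model": qres.model})
        panels[f"quartiles_{panel_name}"] = pd.DataFrame(qrows).set_index("outcome")
    return panels
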