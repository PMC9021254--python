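"""The Microbial Indicator of Periodontitis (MIP) and related log-ratios.

The MIP is the natural-log ratio of summed *Treponema* counts to summed
*Corynebacterium* counts per sample — a reference-frame log-ratio, exactly
invariant to per-sample sequencing depth.  Samples lacking a single read on
either side are flagged ``dropped`` (the log of zero is undefined) and are
never imputed.

Two alternative published indicator ratios are provided as presets:

* ``chen``  — *T. denticola*, *M. timidum*, *Fretibacterium* spp., and
  *T. forsythia* vs. *A. naeslundii* and *S. sanguinis*;
* ``meuric`` — *Eubacterium*, *Campylobacter*, *Treponema*, *Tannerella*
  vs. *Veillonella*, *Neisseria*, *Rothia*, *Corynebacterium*, *Actinomyces*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import validate_count_table

__all__ = [
    "IndicatorSpec",
    "LogRatioIndicator",
    "compute_log_ratio",
    "mip_contrast",
    "quartile_bins",
    "participant_mip",
    "MIP_SPEC",
    "CHEN_SPEC",
    "MEURIC_SPEC",
    "PRESETS",
]


@dataclass(frozen=True)
class IndicatorSpec:
    """Taxon sets defining a log-ratio indicator.

    Patterns are rank-qualified lineage tokens (``g__Treponema``,
    ``s__Treponema_denticola``) matched case-insensitively against the
    semicolon-split lineage of each feature.
    """

    name: str
    numerator_taxa: tuple[str, ...]
    denominator_taxa: tuple[str, ...]

    def __post_init__(self):
        if not self.numerator_taxa or not self.denominator_taxa:
            raise ValueError("numerator and denominator taxa must be non-empty")
        if set(t.lower() for t in self.numerator_taxa) & set(
            t.lower() for t in self.denominator_taxa
        ):
            raise ValueError("numerator and denominator taxa must be disjoint")


MIP_SPEC = IndicatorSpec("mip", ("g__Treponema",), ("g__Corynebacterium",))
CHEN_SPEC = IndicatorSpec(
    "chen",
    (
        "s__Treponema_denticola",
        "s__Mogibacterium_timidum",
        "g__Fretibacterium",
        "s__Tannerella_forsythia",
    ),
    ("s__Actinomyces_naeslundii", "s__Streptococcus_sanguinis"),
)
MEURIC_SPEC = IndicatorSpec(
    "meuric",
    ("g__Eubacterium", "g__Campylobacter", "g__Treponema", "g__Tannerella"),
    ("g__Veillonella", "g__Neisseria", "g__Rothia", "g__Corynebacterium", "g__Actinomyces"),
)
PRESETS = {"mip": MIP_SPEC, "chen": CHEN_SPEC, "meuric": MEURIC_SPEC}


def _lineage_tokens(lineage: str) -> set[str]:
    return {tok.strip().lower() for tok in str(lineage).split(";")}


def match_features(taxonomy: pd.Series, patterns) -> list[str]:
    """Feature ids whose lineage contains any of the rank-qualified patterns."""
    pats = [p.strip().lower() for p in patterns]
    hits = []
    for fid, lineage in taxonomy.items():
        toks = _lineage_tokens(lineage)
        if any(p in toks for p in pats):
            hits.append(fid)
    return hits


class LogRatioIndicator(BaseEstimator):
    """Per-sample log-ratio of two taxon sets, as a fit/transform estimator.

    ``fit(taxonomy)`` resolves the spec's patterns to feature ids;
    ``transform(table)`` returns the per-sample series.

    Attributes (after ``fit``)
    --------------------------
    numerator_features_, denominator_features_ : resolved feature id lists.
    """

    def __init__(self, spec: IndicatorSpec = MIP_SPEC):
        self.spec = spec

    def fit(self, taxonomy: pd.Series, y=None):
        num = match_features(taxonomy, self.spec.numerator_taxa)
        den = match_features(taxonomy, self.spec.denominator_taxa)
        if not num:
            raise ValueError(f"indicator {self.spec.name!r}: no feature matches the numerator taxa")
        if not den:
            raise ValueError(
                f"indicator {self.spec.name!r}: no feature matches the denominator taxa"
            )
        self.numerator_features_ = num
        self.denominator_features_ = den
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Per-sample ``value`` (natural log), ``dropped`` flag, and the two sums.

        ``dropped`` is True iff either side sums to zero; ``value`` is NaN
        for dropped samples and is never imputed.
        """
        table = validate_count_table(table)
        num_cols = [f for f in self.numerator_features_ if f in table.columns]
        den_cols = [f for f in self.denominator_features_ if f in table.columns]
        if not num_cols or not den_cols:
            side = "numerator" if not num_cols else "denominator"
            raise ValueError(f"indicator {self.spec.name!r}: {side} features absent from table")
        num = table[num_cols].sum(axis=1)
        den = table[den_cols].sum(axis=1)
        dropped = (num == 0) | (den == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            value = np.log(num.astype(float) / den.astype(float))
        value[dropped] = np.nan
        return pd.DataFrame(
            {
                "value": value,
                "dropped": dropped,
                "numerator_sum": num.astype(np.int64),
                "denominator_sum": den.astype(np.int64),
            },
            index=table.index,
        )


def compute_log_ratio(table, taxonomy, spec: IndicatorSpec = MIP_SPEC) -> pd.DataFrame:
    """Functional wrapper: fit a :class:`LogRatioIndicator` and transform."""
    return LogRatioIndicator(spec).fit(taxonomy).transform(table)


def mip_contrast(series: pd.DataFrame, meta: pd.DataFrame):
    """Paired deep-vs-shallow contrast of the indicator within participants.

    Pairs are participants with non-dropped values at both sites.  Returns a
    dict with the mean difference (deep − shallow), paired t statistic,
    two-sided p, and the number of pairs.
    """
    df = series.join(meta[["participant_id", "site_class"]])
    ok = df.loc[~df["dropped"]]
    wide = ok.pivot_table(index="participant_id", columns="site_class", values="value")
    if "shallow" not in wide.columns or "deep" not in wide.columns:
        raise ValueError("need both shallow and deep non-dropped samples")
    wide = wide.dropna(subset=["shallow", "deep"])
    if len(wide) < 2:
        raise ValueError("fewer than 2 complete shallow/deep pairs")
    diff = wide["deep"] - wide["shallow"]
    if np.allclose(diff, diff.iloc[0]) and diff.std(ddof=1) == 0:
        # degenerate: identical differences everywhere -> no evidence either way
        t, p = (0.0, 1.0) if diff.iloc[0] == 0 else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(wide["deep"], wide["shallow"])
    return {
        "mean_difference": float(diff.mean()),
        "t_statistic": float(t),
        "p_value": float(p),
        "n_pairs": int(len(wide)),
    }


def quartile_bins(series) -> pd.Series:
    """Empirical quartile bin (1–4) of the non-dropped indicator values.

    Boundary ties go to the lower bin; dropped samples get NaN.  All-equal
    values degenerate to bin 1 with a warning.
    """
    if isinstance(series, pd.DataFrame):
        values = series["value"].where(~series["dropped"])
    else:
        values = pd.Series(series, dtype=float)
    ok = values.dropna()
    if len(ok) < 4:
        raise ValueError("need at least 4 non-dropped values for quartiles")
    q1, q2, q3 = np.quantile(ok.to_numpy(), [0.25, 0.5, 0.75])
    if q1 == q3:
        warnings.warn("degenerate quartiles (all values equal); every sample in bin 1", stacklevel=2)
    bins = pd.Series(np.nan, index=values.index, dtype=float)
    v = values
    bins[v <= q1] = 1
    bins[(v > q1) & (v <= q2)] = 2
    bins[(v > q2) & (v <= q3)] = 3
    bins[v > q3] = 4
    return bins


def participant_mip(series: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Participant-level indicator: the mean of the participant's non-dropped
    site values (mean of shallow and deep when both exist)."""
    df = series.join(meta[["participant_id"]])
    ok = df.loc[~df["dropped"]]
    return ok.groupby("participant_id")["value"].mean().rename("mip")
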