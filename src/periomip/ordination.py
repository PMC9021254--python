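"""Compositional beta-diversity: rclr, robust Aitchison PCA, and tests.

The robust centered log-ratio (rclr) transform takes each sample's counts to
``ln(count) - mean(ln(nonzero counts))``, leaving structural zeros *missing*
rather than imputed.  Robust Aitchison PCA (RPCA) then ordinates samples by
low-rank matrix completion of the rclr matrix over its observed entries,
which makes the resulting distances invariant to per-sample total counts —
the property that motivates this ordination for microbiome data where
microbial load varies over orders of magnitude.

PERMANOVA (Anderson's pseudo-F with a permutation p-value), the four-way
pairwise-distance group comparison (ANOVA + Tukey HSD), and redundancy-
analysis effect sizes (Ezekiel-adjusted R² with permutation p) complete the
beta-diversity toolkit.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import validate_count_table

__all__ = [
    "RclrTransformer",
    "rclr",
    "RobustAitchisonPCA",
    "rpca",
    "matrix_complete",
    "sample_distances",
    "permanova",
    "pairwise_distance_groups",
    "rda_effect_sizes",
    "COVARIATE_CATEGORIES",
]


class RclrTransformer(TransformerMixin, BaseEstimator):
    """Robust centered log-ratio transform (stateless).

    ``transform`` maps a samples × features count table to a real matrix with
    NaN at structural zeros; each row's non-missing entries are centered on
    the natural log of the row's nonzero geometric mean.  Exactly invariant
    to rescaling any sample's counts.
    """

    def fit(self, X, y=None):
        self._validate(X)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    @staticmethod
    def _validate(X):
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D samples x features table")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        nonzero = (arr > 0).sum(axis=1)
        if (nonzero < 2).any():
            bad = np.nonzero(nonzero < 2)[0]
            names = (
                list(np.asarray(X.index)[bad]) if isinstance(X, pd.DataFrame) else bad.tolist()
            )
            raise ValueError(f"samples with < 2 nonzero features: {names[:5]}")
        return arr

    def transform(self, X):
        arr = self._validate(X)
        with np.errstate(divide="ignore"):
            logged = np.log(arr)
        logged[arr == 0] = np.nan
        centered = logged - np.nanmean(logged, axis=1, keepdims=True)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(centered, index=X.index, columns=X.columns)
        return centered


def rclr(table) -> pd.DataFrame:
    """Functional wrapper over :class:`RclrTransformer`."""
    return RclrTransformer().fit_transform(table)


def matrix_complete(M, mask, rank, max_iter=500, tol=1e-8, seed=0, ridge=1e-9):
    """Low-rank completion of ``M`` over ``mask`` by alternating least squares.

    Minimises the squared error on observed entries with a tiny ridge for
    conditioning.  Returns ``(U, V, n_iter, converged)`` with the completed
    matrix ``U @ V.T``.
    """
    M = np.asarray(M, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n, d = M.shape
    if rank >= min(n, d):
        raise ValueError(f"rank {rank} must be < min(n_samples, n_features) = {min(n, d)}")
    rng = np.random.default_rng(seed)
    U = rng.normal(0.0, 1.0, size=(n, rank))
    V = rng.normal(0.0, 1.0, size=(d, rank))
    Mz = np.where(mask, M, 0.0)
    eye = np.eye(rank)
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            Vo = V[mask[i]]
            U[i] = np.linalg.solve(Vo.T @ Vo + ridge * eye, Vo.T @ M[i, mask[i]])
        for j in range(d):
            Uo = U[mask[:, j]]
            V[j] = np.linalg.solve(Uo.T @ Uo + ridge * eye, Uo.T @ M[mask[:, j], j])
        resid = (U @ V.T - Mz)[mask]
        mse = float(resid @ resid) / mask.sum()
        if np.isfinite(prev) and prev - mse <= tol * max(prev, 1e-30):
            converged = True
            break
        prev = mse
    if not converged:
        warnings.warn(f"matrix completion did not converge in {max_iter} iterations", stacklevel=2)
    return U, V, it, converged


class RobustAitchisonPCA(BaseEstimator):
    """Robust Aitchison PCA: rclr + low-rank matrix completion + SVD.

    Parameters
    ----------
    rank : int, default 3
        Number of ordination axes (and completion rank).
    max_iter, tol : ALS stopping rule.
    random_state : seed for the random initialisation; the fit is
        deterministic given the seed.

    Attributes (after ``fit``)
    --------------------------
    sample_scores_ : DataFrame (samples × rank), scaled by singular values.
    feature_loadings_ : DataFrame (features × rank).
    eigenvalues_ : ndarray, nonincreasing.
    proportion_explained_ : ndarray.
    n_iter_, converged_ : ALS diagnostics.
    """

    def __init__(self, rank: int = 3, max_iter: int = 500, tol: float = 1e-8, random_state: int = 0):
        self.rank = rank
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        table = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        r = rclr(table)
        M = r.to_numpy()
        mask = ~np.isnan(M)
        U, V, self.n_iter_, self.converged_ = matrix_complete(
            np.nan_to_num(M), mask, self.rank, self.max_iter, self.tol, self.random_state
        )
        completed = U @ V.T
        # double-center so the SVD reflects sample/feature structure, not offsets
        completed = completed - completed.mean(axis=1, keepdims=True)
        completed = completed - completed.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(completed, full_matrices=False)
        k = self.rank
        self.completed_ = pd.DataFrame(completed, index=table.index, columns=table.columns)
        self.sample_scores_ = pd.DataFrame(
            u[:, :k] * s[:k], index=table.index, columns=[f"PC{i+1}" for i in range(k)]
        )
        self.feature_loadings_ = pd.DataFrame(
            vt[:k].T, index=table.columns, columns=[f"PC{i+1}" for i in range(k)]
        )
        self.eigenvalues_ = s[:k] ** 2
        total = float((s**2).sum())
        self.proportion_explained_ = self.eigenvalues_ / total if total > 0 else self.eigenvalues_
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).sample_scores_


def rpca(table, rank: int = 3, max_iter: int = 500, tol: float = 1e-8, seed: int = 0):
    """Fit :class:`RobustAitchisonPCA` and return the fitted estimator."""
    return RobustAitchisonPCA(rank=rank, max_iter=max_iter, tol=tol, random_state=seed).fit(table)


def sample_distances(ordination: RobustAitchisonPCA | pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between samples in full score space."""
    scores = ordination.sample_scores_ if hasattr(ordination, "sample_scores_") else ordination
    arr = scores.to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    sq = (arr**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * arr @ arr.T
    d = np.sqrt(np.maximum(d2, 0.0))
    np.fill_diagonal(d, 0.0)
    idx = scores.index if isinstance(scores, pd.DataFrame) else pd.RangeIndex(len(arr))
    return pd.DataFrame(d, index=idx, columns=idx)


def _permanova_f(D2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = len(labels)
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for g in groups:
        m = labels == g
        ng = int(m.sum())
        ss_within += D2[np.ix_(m, m)].sum() / (2 * ng)
    a = len(groups)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(d, labels, n_perm: int = 999, seed: int = 0, permutations=None):
    """Anderson's PERMANOVA pseudo-F with a permutation p-value.

    ``p = (1 + #{perm F >= observed F}) / (1 + n_perm)``.  Pass an explicit
    array of label permutations (rows) via ``permutations`` to run, e.g., the
    exhaustive test on tiny designs; then ``p = #{F >= obs}/n`` including the
    identity if present.
    """
    D = d.to_numpy() if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError(f"singleton group(s): {groups[counts < 2].tolist()}")
    D2 = D**2
    f_obs = _permanova_f(D2, labels, groups)
    if permutations is not None:
        perms = np.asarray(permutations)
        fs = np.array([_permanova_f(D2, p, groups) for p in perms])
        p_val = float((fs >= f_obs - 1e-12).mean())
        return f_obs, p_val
    rng = np.random.default_rng(seed)
    n = len(labels)
    # vectorised permutation null: SS_within per permutation from group masks
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_labels = labels[perm_idx]
    ss_total = D2.sum() / (2 * n)
    ss_within = np.zeros(n_perm)
    for g, ng in zip(groups, counts):
        Z = (perm_labels == g).astype(float)
        ss_within += np.einsum("pi,ij,pj->p", Z, D2, Z) / (2 * ng)
    a = len(groups)
    fs = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
    p_val = (1 + int((fs >= f_obs - 1e-12).sum())) / (1 + n_perm)
    return f_obs, p_val


_PAIR_CATEGORIES = (
    "shallow_shallow_between",
    "deep_deep_between",
    "shallow_deep_within",
    "shallow_deep_between",
)


def pairwise_distance_groups(d: pd.DataFrame, meta: pd.DataFrame):
    """Partition sample pairs into the four shallow/deep × within/between
    person categories and compare their RPCA distances.

    Only plaque samples (site_class shallow or deep) present in both the
    distance matrix and the metadata enter.  Returns ``(groups, result)``
    where ``groups`` maps category → ndarray of distances and ``result`` has
    the one-way ANOVA F/p and a Tukey HSD p-value table.  Empty categories
    are reported empty and excluded from the ANOVA with a warning.

    Note: pairs sharing samples are not independent observations; the ANOVA
    treats them as such, which is the conventional (anticonservative)
    presentation for this figure-style analysis.
    """
    ids = [s for s in d.index if s in meta.index and meta.loc[s, "site_class"] in ("shallow", "deep")]
    groups: dict[str, list] = {c: [] for c in _PAIR_CATEGORIES}
    D = d.loc[ids, ids].to_numpy()
    site = meta.loc[ids, "site_class"].to_numpy()
    part = meta.loc[ids, "participant_id"].to_numpy()
    for i, j in combinations(range(len(ids)), 2):
        same_person = part[i] == part[j]
        si, sj = site[i], site[j]
        if si == sj == "shallow":
            cat = None if same_person else "shallow_shallow_between"
        elif si == sj == "deep":
            cat = None if same_person else "deep_deep_between"
        else:
            cat = "shallow_deep_within" if same_person else "shallow_deep_between"
        if cat is None:
            warnings.warn("same-person same-class pair excluded", stacklevel=2)
            continue
        groups[cat].append(D[i, j])
    groups = {c: np.asarray(v) for c, v in groups.items()}
    populated = [c for c in _PAIR_CATEGORIES if len(groups[c]) >= 2]
    if len(populated) < len(_PAIR_CATEGORIES):
        warnings.warn(
            f"empty/singleton categories excluded from ANOVA: "
            f"{sorted(set(_PAIR_CATEGORIES) - set(populated))}",
            stacklevel=2,
        )
    if len(populated) < 2:
        raise ValueError("fewer than 2 populated pair categories")
    f_stat, p = stats.f_oneway(*(groups[c] for c in populated))
    tukey = stats.tukey_hsd(*(groups[c] for c in populated))
    pairs, pvals = [], []
    for i, j in combinations(range(len(populated)), 2):
        pairs.append((populated[i], populated[j]))
        pvals.append(tukey.pvalue[i, j])
    tukey_table = pd.DataFrame(
        {"group_a": [p[0] for p in pairs], "group_b": [p[1] for p in pairs], "p_value": pvals}
    )
    result = {"anova_F": float(f_stat), "anova_p": float(p), "tukey": tukey_table}
    return groups, result


#: Default Fig.-2C-style category assignment for known covariates.
COVARIATE_CATEGORIES = {
    "pocket_depth_mm": "periodontal",
    "site_class": "periodontal",
    "attachment_loss_mm": "periodontal",
    "pct_bop": "periodontal",
    "faith_pd": "periodontal",
    "participant_id": "demographic",
    "age": "demographic",
    "sex": "demographic",
    "race": "demographic",
    "bmi": "metabolic",
    "meansbp": "metabolic",
    "meandbp": "metabolic",
    "glucose": "metabolic",
    "insulin": "metabolic",
    "homa_ir": "metabolic",
    "hba1c": "metabolic",
    "smoking": "lifestyle",
}


def _design_matrix(series: pd.Series) -> np.ndarray:
    if series.dtype.kind in "biufc":
        return series.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(series.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def rda_effect_sizes(
    response: pd.DataFrame,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Marginal redundancy-analysis effect size per covariate.

    For each covariate alone, the multivariate regression of the (row-subset,
    column-centered) response matrix on the dummy-coded covariate gives a
    redundancy R²; the reported effect size is the Ezekiel-adjusted R²
    (clamped at 0), with a permutation p-value from shuffling the covariate.
    Constant covariates are skipped with a warning.

    Returns a DataFrame indexed by covariate with columns
    ``effect_size`` (adjusted R²), ``r2``, ``p_value``, ``n``, ``category``.
    """
    categories = {**COVARIATE_CATEGORIES, **(categories or {})}
    rng = np.random.default_rng(seed)
    rows = []
    for name in covariates.columns:
        col = covariates[name]
        sub = col.dropna()
        common = response.index.intersection(sub.index)
        sub = sub.loc[common]
        if sub.nunique() < 2:
            warnings.warn(f"constant covariate {name!r} skipped", stacklevel=2)
            continue
        Y = response.loc[common].to_numpy(dtype=float)
        Y = Y - Y.mean(axis=0, keepdims=True)
        ss_tot = float((Y**2).sum())
        if ss_tot == 0:
            warnings.warn(f"zero-variance response for covariate {name!r}; skipped", stacklevel=2)
            continue
        X = _design_matrix(sub)
        m = X.shape[1]
        n = X.shape[0]

        def _r2(Xmat):
            Xc = Xmat - Xmat.mean(axis=0, keepdims=True)
            Q, _ = np.linalg.qr(Xc)
            proj = Q.T @ Y
            return float((proj**2).sum()) / ss_tot

        r2 = _r2(X)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _r2(X[perm]) >= r2 - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        rows.append(
            {
                "covariate": name,
                "effect_size": max(adj, 0.0),
                "r2": r2,
                "p_value": p,
                "n": n,
                "category": categories.get(name, "other"),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["effect_size", "r2", "p_value", "n", "category"],
            index=pd.Index([], name="covariate"),
        )
    return pd.DataFrame(rows).set_index("covariate")
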