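"""Genome-wide between-group variance comparison.

Three ingredients: per-gene raw variances with a which-group-is-larger
indicator, an exact binomial sign test on the indicator counts, and
one-sided Levene tests on covariate-adjusted residuals (null: residual
variance in the test group is equal to or less than in the reference
group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import GROUP_COLUMN, ExpressionDataset

__all__ = [
    "group_variances",
    "sign_test",
    "residualize",
    "levene_one_sided",
    "variance_table",
    "CovariateResidualizer",
]


def group_variances(
    data: ExpressionDataset, test_group: str, reference_group: str
) -> pd.DataFrame:
    """Per-gene unbiased variances in each group plus the comparison indicator.

    The indicator is ``var(test) > var(reference)``; exact ties are left as
    missing (excluded from the sign test downstream).
    """
    for g in (test_group, reference_group):
        if g not in data.groups:
            raise ValueError(f"group {g!r} not present in the dataset")
        if (data.samples[GROUP_COLUMN] == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least two samples")
    out = pd.DataFrame(index=data.expression.index)
    values = {}
    for g in (test_group, reference_group):
        mask = (data.samples[GROUP_COLUMN] == g).to_numpy()
        values[g] = data.expression.to_numpy(dtype=float)[:, mask].var(axis=1, ddof=1)
    out[f"var_{test_group}"] = values[test_group]
    out[f"var_{reference_group}"] = values[reference_group]
    tie = values[test_group] == values[reference_group]
    indicator = pd.Series(values[test_group] > values[reference_group], index=out.index)
    out["indicator"] = indicator.mask(tie)
    return out


def sign_test(k: int, n: int) -> float:
    """Exact one-sided binomial tail P(X >= k | n, 1/2).

    ``k`` is the number of informative genes favouring the test group and
    ``n`` the number of informative (untied) genes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)


def _design_matrix(samples: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Intercept + numeric covariates + dummy-coded categoricals."""
    pieces = [pd.Series(1.0, index=samples.index, name="intercept")]
    for c in covariates:
        if c not in samples.columns:
            raise ValueError(f"covariate {c!r} absent from sample metadata")
        col = samples[c]
        if pd.api.types.is_numeric_dtype(col):
            pieces.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            pieces.append(dummies)
    X = pd.concat(pieces, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        redundant = []
        cols = X.columns.tolist()
        for j in range(X.shape[1]):
            keep = [i for i in range(X.shape[1]) if i != j and cols[i] not in redundant]
            if np.linalg.matrix_rank(X.iloc[:, keep].to_numpy()) == rank:
                redundant.append(cols[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {redundant}")
    return X


def residualize(data: ExpressionDataset, covariates: list[str] | None = None) -> pd.DataFrame:
    """Per-gene least-squares residuals after the covariate model (pooled samples).

    Residuals have mean zero per gene and are orthogonal to every design
    column.  Covariates default to all metadata columns except the group
    label; categoricals are dummy-coded.
    """
    if covariates is None:
        covariates = data.covariate_names
    X = _design_matrix(data.samples, list(covariates)).to_numpy()
    Y = data.expression.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid.T, index=data.expression.index, columns=data.expression.columns)


@dataclass
class _LeveneResult:
    p: float
    statistic: float
    degenerate: bool = False


def levene_one_sided(values_a: np.ndarray, values_b: np.ndarray):
    """One-sided Levene test of H1: var(A) > var(B), mean-centred deviations.

    For two groups Levene's statistic is the pooled two-sample t statistic on
    the absolute deviations from the group means (its square is the classic
    ANOVA F form), which gives the one-sided alternative a well-defined
    sign.  Accepts 1-D arrays (returns a scalar p) or 2-D genes-by-samples
    arrays (returns a vector of p-values).  Swapping the groups maps the
    statistic t to -t, i.e. p to 1 - p.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    na, nb = A.shape[1], B.shape[1]
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least three samples")
    da = np.abs(A - A.mean(axis=1, keepdims=True))
    db = np.abs(B - B.mean(axis=1, keepdims=True))
    ma, mb = da.mean(axis=1), db.mean(axis=1)
    ssa = ((da - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((db - mb[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    pooled = (ssa + ssb) / df
    scale = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    degenerate = scale == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, (ma - mb) / np.where(degenerate, 1.0, scale))
    p = stats.t.sf(t, df)
    p = np.where(degenerate, 1.0, p)
    if np.asarray(values_a).ndim == 1:
        return _LeveneResult(float(p[0]), float(t[0]), bool(degenerate[0]))
    return p


def variance_table(
    data: ExpressionDataset,
    test_group: str,
    reference_group: str,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Full per-gene table: group variances, indicator, residual Levene p."""
    table = group_variances(data, test_group, reference_group)
    resid = residualize(data, covariates) if (covariates is None or covariates) else None
    if resid is None or resid.shape[0] == 0:
        return table
    mask_a = (data.samples[GROUP_COLUMN] == test_group).to_numpy()
    mask_b = (data.samples[GROUP_COLUMN] == reference_group).to_numpy()
    R = resid.to_numpy()
    table["levene_p"] = levene_one_sided(R[:, mask_a], R[:, mask_b])
    return table


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """Transformer wrapper over :func:`residualize` (fit learns the OLS betas).

    Operates on samples-by-genes matrices to match scikit-learn orientation.
    """

    def __init__(self, covariates: list[str] | None = None):
        self.covariates = covariates

    def fit(self, X: np.ndarray, y=None, samples: pd.DataFrame | None = None):
        if samples is None:
            raise ValueError("pass the sample metadata via fit(..., samples=...)")
        covs = self.covariates if self.covariates is not None else [
            c for c in samples.columns if c != GROUP_COLUMN
        ]
        design = _design_matrix(samples, list(covs))
        self.design_columns_ = list(design.columns)
        self._X_design = design.to_numpy()
        beta, *_ = np.linalg.lstsq(self._X_design, np.asarray(X, dtype=float), rcond=None)
        self.coef_ = beta
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise ValueError("CovariateResidualizer is not fitted")
        return np.asarray(X, dtype=float) - self._X_design @ self.coef_
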