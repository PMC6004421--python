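"""Disease-status modeling from pathway-gene covariance structure.

Principal components of covariate-adjusted residuals over the selected
pathway genes (components individually explaining at least a threshold
fraction of variance) feed a logistic regression with disease status as the
outcome; fit quality is summarised by the concordance index (area under the
ROC curve) and a pseudo-R-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA

__all__ = [
    "ClassificationReport",
    "pca_select",
    "logistic_status_fit",
    "c_index",
    "PCLogistic",
]


@dataclass
class ClassificationReport:
    n_components: int
    explained_variance_ratio: np.ndarray
    coefficients: np.ndarray
    coefficient_pvalues: np.ndarray
    c_index: float
    pseudo_r2: float
    pseudo_r2_method: str
    mcfadden_r2: float
    perfect_separation: bool = False


def pca_select(residuals: pd.DataFrame | np.ndarray, threshold: float = 0.01):
    """Centered (unscaled) PCA; retain components explaining >= threshold variance.

    ``residuals`` is genes-by-samples (matching the residual matrix
    orientation); returns (scores ``n_samples x k``, explained-variance
    fractions of the retained components).
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("need at least two genes and two samples")
    X = R.T  # samples x genes
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("residual matrix is constant; PCA undefined")
    n, p = X.shape
    pca = PCA(n_components=min(n - 1, p), svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    keep = evr >= threshold if threshold > 0 else np.ones(evr.size, dtype=bool)
    return scores[:, keep], evr[keep]


def c_index(scores, labels) -> float:
    """Concordance index: P(score_case > score_control) + 0.5 P(tie).

    Computed by the rank (Mann-Whitney) formula over all case-control pairs;
    equals the area under the ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def logistic_status_fit(components: np.ndarray, labels) -> ClassificationReport:
    """ML logistic fit of disease status on retained component scores."""
    X = np.atleast_2d(np.asarray(components, dtype=float))
    if X.shape[0] == 1 and np.asarray(labels).size != 1:
        X = X.T
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("labels must be binary")
        y = (y == classes[1]).astype(int)
    else:
        y = y.astype(int)
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")

    design = sm.add_constant(X, has_constant="add")
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:  # perfect separation raises in some statsmodels versions
            separated = True
            fit = sm.Logit(y, design).fit_regularized(disp=0, alpha=1e-6, maxiter=500)
    params = np.asarray(fit.params)
    if not separated and np.any(np.abs(params) > 50):
        separated = True
    if separated:
        warnings.warn("possible perfect separation; coefficients reported with caution")
    try:
        pvals = np.asarray(fit.pvalues)
    except Exception:
        pvals = np.full(params.size, np.nan)

    scores = design @ params
    cidx = c_index(scores, y)
    lln = sm.Logit(y, np.ones((y.size, 1))).fit(disp=0).llf
    llf = float(sm.Logit(y, design).loglike(params))
    n = y.size
    cox_snell = 1.0 - np.exp(2.0 * (lln - llf) / n)
    nagelkerke = cox_snell / (1.0 - np.exp(2.0 * lln / n))
    mcfadden = 1.0 - llf / lln
    evr_placeholder = np.array([])
    return ClassificationReport(
        n_components=X.shape[1],
        explained_variance_ratio=evr_placeholder,
        coefficients=params[1:],
        coefficient_pvalues=pvals[1:],
        c_index=cidx,
        pseudo_r2=float(nagelkerke),
        pseudo_r2_method="nagelkerke",
        mcfadden_r2=float(mcfadden),
        perfect_separation=separated,
    )


class PCLogistic(BaseEstimator, ClassifierMixin):
    """PCA-of-residuals -> logistic-regression classifier for disease status.

    Parameters
    ----------
    threshold : minimum individual explained-variance fraction for a
        component to enter the logistic model.

    Fitted attributes: ``n_components_``, ``explained_variance_ratio_``,
    ``report_`` (full :class:`ClassificationReport`), ``c_index_``.
    """

    def __init__(self, threshold: float = 0.01):
        self.threshold = threshold

    def fit(self, X, y):
        """X: samples x genes residual matrix; y: binary status labels."""
        X = np.asarray(X, dtype=float)
        scores, evr = pca_select(X.T, threshold=self.threshold)
        report = logistic_status_fit(scores, y)
        report.explained_variance_ratio = evr
        self.classes_ = np.unique(y)
        self.n_components_ = scores.shape[1]
        self.explained_variance_ratio_ = evr
        self.report_ = report
        self.c_index_ = report.c_index
        self._scores = scores
        return self

    def fit_report(self, X, y) -> ClassificationReport:
        return self.fit(X, y).report_
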