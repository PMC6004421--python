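"""Covariance-structure maximum-likelihood SEM.

The model is the standard linear structural system

    [y, eta] = B [y, eta] + Gamma [x] + zeta,        z = Lambda [eta] + delta,

with observed endogenous/exogenous variables, optional latent variables
(scaled by fixing their disturbance variance to 1 and mean to 0), diagonal
structural and measurement error covariances, and pairwise covariances
between exogenous pathway variables fixed to zero.  Estimation minimises the
ML discrepancy

    F_ML = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

between the model-implied covariance Sigma and the sample covariance S.

Internally the code uses a single all-variable assembly: every variable
(observed gene, latent, covariate) is a row of one path matrix ``A`` and one
error covariance ``Omega``; the implied covariance of the full variable
vector is (I-A)^-1 Omega (I-A)^-T and the observed block is selected from
it.  The public grammar still speaks in terms of B/Gamma/Lambda patterns.

Multigroup fitting minimises sum_g (n_g - 1) F_g with covariate-equation
slopes constrained equal across groups and all structural parameters
group-specific.  Covariates enter with a fixed-x convention: their
variance/covariance block is fixed at the group sample moments and
contributes no misfit.  With per-variable intercepts free the mean structure
is saturated and profiles out, so the fit is covariance-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .datasets import ExpressionDataset
from .networks import ResolvedNetwork

__all__ = [
    "SemModel",
    "FitResult",
    "MultigroupFit",
    "implied_covariance",
    "ml_discrepancy",
    "fit_single_group",
    "fit_multigroup",
    "fit_indices",
    "wald_difference_test",
    "check_identifiability",
    "MultigroupSEM",
]

_EIG_TOL = 1e-8  # relative eigenvalue floor for information-matrix PD checks


# ---------------------------------------------------------------------------
# model definition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SemModel:
    """Structural model over observed genes, optional latents and covariates.

    Parameters
    ----------
    genes : structural observed variables (one per resolved network node).
    latents : latent variable labels; disturbance variance fixed to 1.
    structural_edges : directed paths among genes/latents (entries of B).
    loading_edges : (latent -> indicator gene) measurement loadings (Lambda).
    covariates : observed exogenous covariates; slopes onto every observed
        gene form the covariate equations (Gamma block), shared across groups
        in multigroup fits.
    """

    genes: tuple[str, ...]
    latents: tuple[str, ...] = ()
    structural_edges: tuple[tuple[str, str], ...] = ()
    loading_edges: tuple[tuple[str, str], ...] = ()
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        known = set(self.genes) | set(self.latents)
        for src, dst in self.structural_edges:
            if src not in known or dst not in known:
                raise ValueError(f"structural edge ({src!r}, {dst!r}) uses unknown variable")
            if src == dst:
                raise ValueError(f"self-loop on {src!r} is not allowed")
        for lat, ind in self.loading_edges:
            if lat not in self.latents:
                raise ValueError(f"loading source {lat!r} is not a declared latent")
            if ind not in self.genes:
                raise ValueError(f"loading indicator {ind!r} is not a declared gene")
        overlap = (set(self.genes) | set(self.latents)) & set(self.covariates)
        if overlap:
            raise ValueError(f"covariates overlap model variables: {sorted(overlap)}")

    @classmethod
    def from_resolved(
        cls, resolved: ResolvedNetwork, covariates: Sequence[str] = ()
    ) -> "SemModel":
        """Build a model from a resolved (single-gene-per-node) network."""
        latents = tuple(resolved.latent_nodes)
        genes = tuple(resolved.genes)
        loadings = tuple(
            (lat, ind) for lat, inds in resolved.latent_indicators for ind in inds
        )
        indicator_genes = tuple(g for _, g in loadings if g not in genes)
        return cls(
            genes=genes + indicator_genes,
            latents=latents,
            structural_edges=tuple(resolved.edges),
            loading_edges=loadings,
            covariates=tuple(covariates),
        )

    # -- variable bookkeeping -------------------------------------------
    @property
    def observed(self) -> tuple[str, ...]:
        """Observed variables entering the covariance structure (genes + covariates)."""
        return self.genes + self.covariates

    @property
    def all_vars(self) -> tuple[str, ...]:
        return self.genes + self.latents + self.covariates

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {dst for _, dst in self.structural_edges}
        targets |= {ind for _, ind in self.loading_edges}
        if self.covariates:
            targets |= set(self.genes)  # covariate equations make every gene endogenous
        return tuple(v for v in self.genes + self.latents if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        endo = set(self.endogenous)
        return tuple(v for v in self.all_vars if v not in endo)

    # -- pattern matrices (public grammar) ------------------------------
    def pattern_B(self) -> pd.DataFrame:
        """Free/fixed pattern of endogenous->endogenous paths (True = free)."""
        varlist = list(self.genes + self.latents)
        pat = pd.DataFrame(False, index=varlist, columns=varlist)
        for src, dst in self.structural_edges:
            pat.loc[dst, src] = True
        return pat

    def pattern_Lambda(self) -> pd.DataFrame:
        pat = pd.DataFrame(False, index=list(self.genes), columns=list(self.latents))
        for lat, ind in self.loading_edges:
            pat.loc[ind, lat] = True
        return pat

    def pattern_Gamma(self) -> pd.DataFrame:
        pat = pd.DataFrame(False, index=list(self.genes), columns=list(self.covariates))
        if self.covariates:
            pat.loc[:, :] = True
        return pat

    def baseline(self) -> "SemModel":
        """Independence baseline: free variances and covariate slopes only."""
        return SemModel(genes=self.genes, covariates=self.covariates)


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------


@dataclass
class _Layout:
    """Index bookkeeping for one multigroup parameter vector.

    Vector order: [shared slopes] + per group ([edge coefficients] + [gene
    (residual) variances]).  Variances are log-transformed during
    optimisation and natural-scale for standard errors.
    """

    model: SemModel
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        m = self.model
        self.var_index = {v: i for i, v in enumerate(m.all_vars)}
        self.n_all = len(m.all_vars)
        self.obs_idx = np.array([self.var_index[v] for v in m.observed], dtype=int)
        self.gene_idx = np.array([self.var_index[g] for g in m.genes], dtype=int)
        self.latent_idx = np.array([self.var_index[l] for l in m.latents], dtype=int)
        self.cov_idx = np.array([self.var_index[c] for c in m.covariates], dtype=int)

        self.slopes = [(g, c) for g in m.genes for c in m.covariates]
        self.edges = list(m.structural_edges) + list(m.loading_edges)
        self.psis = list(m.genes)

        self.slope_rc = (
            np.array([self.var_index[g] for g, _ in self.slopes], dtype=int),
            np.array([self.var_index[c] for _, c in self.slopes], dtype=int),
        )
        self.edge_rc = (
            np.array([self.var_index[d] for _, d in self.edges], dtype=int),
            np.array([self.var_index[s] for s, _ in self.edges], dtype=int),
        )

        self.n_shared = len(self.slopes)
        self.n_edges = len(self.edges)
        self.n_psi = len(self.psis)
        self.per_group = self.n_edges + self.n_psi
        self.n_params = self.n_shared + len(self.groups) * self.per_group

    def split(self, theta: np.ndarray):
        shared = theta[: self.n_shared]
        out = {}
        off = self.n_shared
        for g in self.groups:
            out[g] = (theta[off : off + self.n_edges], theta[off + self.n_edges : off + self.per_group])
            off += self.per_group
        return shared, out

    def names(self) -> list[str]:
        names = [f"slope:{g}~{c}" for g, c in self.slopes]
        for g in self.groups:
            names += [f"beta:{s}->{d}@{g}" for s, d in self.edges]
            names += [f"psi:{v}@{g}" for v in self.psis]
        return names


# ---------------------------------------------------------------------------
# covariance assembly and discrepancy
# ---------------------------------------------------------------------------


def _assemble(layout: _Layout, edge_vals, psi_vals, slope_vals, cov_block):
    """Return (A, Omega) for one group on the all-variable space."""
    m = layout.n_all
    A = np.zeros((m, m))
    if layout.n_edges:
        A[layout.edge_rc] = edge_vals
    if layout.n_shared:
        A[layout.slope_rc] = slope_vals
    Omega = np.zeros((m, m))
    Omega[layout.gene_idx, layout.gene_idx] = psi_vals
    if len(layout.latent_idx):
        Omega[layout.latent_idx, layout.latent_idx] = 1.0
    if len(layout.cov_idx):
        Omega[np.ix_(layout.cov_idx, layout.cov_idx)] = cov_block
    return A, Omega


def _sigma_of(A, Omega, obs_idx):
    m = A.shape[0]
    T = linalg.solve(np.eye(m) - A, np.eye(m))
    M = T[obs_idx, :]
    return M @ Omega @ M.T, T, M


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """ML discrepancy F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p.

    Both matrices must be symmetric positive definite of equal dimension.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S and Sigma must be square matrices of equal dimension")
    p = S.shape[0]
    for name, mat in (("S", S), ("Sigma", Sigma)):
        try:
            linalg.cholesky(mat, lower=True)
        except linalg.LinAlgError as exc:
            cond = np.linalg.cond(mat)
            raise linalg.LinAlgError(
                f"{name} is not positive definite (condition number {cond:.3g})"
            ) from exc
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    return float(logdet_m + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


def implied_covariance(
    model: SemModel,
    paths: Mapping[tuple[str, str], float],
    variances: Mapping[str, float],
    slopes: Mapping[tuple[str, str], float] | None = None,
    covariate_cov: np.ndarray | None = None,
) -> pd.DataFrame:
    """Model-implied covariance of the observed variables at given parameters.

    Parameters
    ----------
    paths : coefficient per structural/loading edge ``(src, dst)``.
    variances : (residual) variance per observed gene.
    slopes : covariate-equation coefficient per ``(gene, covariate)``.
    covariate_cov : fixed covariate covariance block (defaults to identity).
    """
    layout = _Layout(model, groups=("g",))
    missing = [e for e in layout.edges if tuple(e) not in {tuple(k) for k in paths}]
    if missing:
        raise ValueError(f"missing path coefficients for edges: {missing}")
    edge_vals = np.array([paths[(s, d)] for s, d in layout.edges])
    psi_vals = np.array([float(variances[g]) for g in layout.psis])
    if np.any(psi_vals < 0):
        raise ValueError("variances must be non-negative")
    slope_vals = np.array(
        [0.0 if slopes is None else float(slopes.get((g, c), 0.0)) for g, c in layout.slopes]
    )
    q = len(model.covariates)
    block = np.eye(q) if covariate_cov is None else np.asarray(covariate_cov, dtype=float)
    A, Omega = _assemble(layout, edge_vals, psi_vals, slope_vals, block)
    m = layout.n_all
    IA = np.eye(m) - A
    if abs(np.linalg.det(IA)) < 1e-12:
        raise linalg.LinAlgError("I - B is singular at the supplied coefficients")
    Sigma, _, _ = _sigma_of(A, Omega, layout.obs_idx)
    obs = list(model.observed)
    return pd.DataFrame(Sigma, index=obs, columns=obs)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Single-group estimates with their uncertainty and fit summary."""

    group: str
    estimates: pd.Series
    se: pd.Series | None
    sample_cov: pd.DataFrame
    implied_cov: pd.DataFrame
    f_ml: float
    loglik: float
    n: int
    p: int
    chi2: float
    df: int
    aic: float
    bic: float
    converged: bool
    identifiable: bool
    diagnostics: list[str] = field(default_factory=list)
    baseline_chi2: float | None = None
    baseline_df: int | None = None


@dataclass
class MultigroupFit:
    """Joint multigroup solution with equality-constrained covariate slopes."""

    model: SemModel
    groups: tuple[str, ...]
    group_fits: dict[str, FitResult]
    shared_estimates: pd.Series
    shared_se: pd.Series | None
    chi2: float
    df: int
    baseline_chi2: float
    baseline_df: int
    n_total: int
    converged: bool
    identifiable: bool
    diagnostics: list[str]
    wald_table: pd.DataFrame

    @property
    def rmsea(self) -> float:
        return fit_indices(self)["RMSEA"]

    @property
    def cfi(self) -> float:
        return fit_indices(self)["CFI"]


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


class _GroupData:
    """Per-group sufficient statistics for the covariance-structure fit."""

    def __init__(self, name: str, n: int, S: np.ndarray, q: int):
        self.name = name
        self.n = n
        self.S = S
        self.w = float(n - 1)
        self.q = q
        self.cov_block = S[S.shape[0] - q :, S.shape[0] - q :] if q else np.zeros((0, 0))
        eigs = np.linalg.eigvalsh(S)
        self.singular = eigs[0] < _EIG_TOL * max(eigs[-1], 1.0)
        if not self.singular:
            _, self.logdet_s = np.linalg.slogdet(S)
        else:
            self.logdet_s = np.nan


def _prepare_groups(
    model: SemModel, data_by_group: Mapping[str, ExpressionDataset]
) -> list[_GroupData]:
    groups = []
    p_obs = len(model.observed)
    for name, ds in data_by_group.items():
        X = ds.values_for(list(model.genes))
        if model.covariates:
            C = ds.covariate_matrix(list(model.covariates))
            X = np.column_stack([X, C])
        n = X.shape[0]
        if n <= p_obs:
            raise ValueError(
                f"group {name!r}: n={n} must exceed the number of observed variables p={p_obs}"
            )
        if np.isnan(X).any():
            raise ValueError(f"group {name!r}: missing values are not supported")
        S = np.cov(X, rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        groups.append(_GroupData(name, n, S, len(model.covariates)))
    return groups


def _objective_and_grad(theta, layout: _Layout, groups: list[_GroupData], log_psi: bool):
    """Weighted discrepancy sum_g (n_g-1) F_g and its gradient."""
    shared, per_group = layout.split(theta)
    total = 0.0
    grad = np.zeros_like(theta)
    off = layout.n_shared
    for gd in groups:
        edge_vals, psi_raw = per_group[gd.name]
        psi_vals = np.exp(psi_raw) if log_psi else psi_raw
        A, Omega = _assemble(layout, edge_vals, psi_vals, shared, gd.cov_block)
        m = layout.n_all
        try:
            Sigma, T, M = _sigma_of(A, Omega, layout.obs_idx)
            L = linalg.cholesky(Sigma, lower=True)
        except (linalg.LinAlgError, ValueError):
            return 1e12, np.zeros_like(theta)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Sinv = linalg.cho_solve((L, True), np.eye(Sigma.shape[0]))
        F = logdet + float(np.sum(Sinv * gd.S)) - gd.logdet_s - Sigma.shape[0]
        total += gd.w * F

        W = Sinv - Sinv @ gd.S @ Sinv
        P = W @ M  # p x m
        U = M.T @ P  # m x m
        D = T @ Omega @ U  # m x m
        gA = 2.0 * D.T  # gradient wrt A entries
        # shared slopes
        if layout.n_shared:
            grad[: layout.n_shared] += gd.w * gA[layout.slope_rc]
        # per-group edges
        if layout.n_edges:
            grad[off : off + layout.n_edges] += gd.w * gA[layout.edge_rc]
        # per-group variances
        g_psi = np.diag(U)[layout.gene_idx]
        if log_psi:
            g_psi = g_psi * psi_vals
        grad[off + layout.n_edges : off + layout.per_group] += gd.w * g_psi
        off += layout.per_group
    return total, grad


def _natural_gradient(theta_nat, layout, groups):
    _, g = _objective_and_grad(theta_nat, layout, groups, log_psi=False)
    return g


def _hessian_natural(theta_nat, layout, groups) -> np.ndarray:
    """Observed information (times 2) by central differences of the gradient."""
    k = theta_nat.size
    H = np.zeros((k, k))
    for i in range(k):
        h = 1e-5 * max(abs(theta_nat[i]), 1.0)
        up = theta_nat.copy()
        dn = theta_nat.copy()
        up[i] += h
        dn[i] -= h
        H[:, i] = (_natural_gradient(up, layout, groups) - _natural_gradient(dn, layout, groups)) / (
            2 * h
        )
    return 0.5 * (H + H.T)


def _start_values(layout: _Layout, groups: list[_GroupData], log_psi=True) -> np.ndarray:
    theta = np.zeros(layout.n_params)
    off = layout.n_shared
    gene_pos = {g: i for i, g in enumerate(layout.model.genes)}
    for gd in groups:
        edge_start = np.array(
            [1.0 if (s, d) in layout.model.loading_edges else 0.1 for s, d in layout.edges]
        )
        diag = np.diag(gd.S)
        psi_start = np.array([0.5 * max(diag[gene_pos[g]], 1e-3) for g in layout.psis])
        theta[off : off + layout.n_edges] = edge_start
        theta[off + layout.n_edges : off + layout.per_group] = (
            np.log(psi_start) if log_psi else psi_start
        )
        off += layout.per_group
    return theta


def _count_df(model: SemModel, n_groups: int, n_params: int) -> int:
    p = len(model.observed)
    q = len(model.covariates)
    moments = n_groups * (p * (p + 1) // 2 - q * (q + 1) // 2)
    return moments - n_params


def _fit_core(model: SemModel, groups: list[_GroupData], compute_se: bool = True):
    """Minimise the joint discrepancy; return layout, theta-hat, details."""
    layout = _Layout(model, groups=tuple(gd.name for gd in groups))
    diagnostics: list[str] = []
    degenerate = [gd.name for gd in groups if gd.singular]
    if degenerate:
        diagnostics.append(f"sample covariance singular in group(s) {degenerate}")
        theta0 = _start_values(layout, groups, log_psi=False)
        return layout, theta0, None, False, False, diagnostics

    theta0 = _start_values(layout, groups, log_psi=True)
    total_w = sum(gd.w for gd in groups)

    def scaled(theta):
        f, g = _objective_and_grad(theta, layout, groups, True)
        return f / total_w, g / total_w

    res = optimize.minimize(
        scaled,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or gnorm < 1e-6)
    if not converged:
        diagnostics.append(f"optimizer did not converge (max |grad| = {gnorm:.3g})")
    # natural-scale parameters
    theta_nat = res.x.copy()
    off = layout.n_shared
    for _ in groups:
        sl = slice(off + layout.n_edges, off + layout.per_group)
        theta_nat[sl] = np.exp(theta_nat[sl])
        off += layout.per_group

    if not compute_se:
        return layout, theta_nat, None, converged, converged, diagnostics

    H = _hessian_natural(theta_nat, layout, groups)
    info = 0.5 * H  # observed information of sum_g ((n_g-1)/2) F_g
    eigs = np.linalg.eigvalsh(info)
    info_pd = eigs[0] > _EIG_TOL * max(eigs[-1], 1.0)
    se = None
    identifiable = converged and info_pd
    if not info_pd:
        diagnostics.append(
            f"information matrix not positive definite (min/max eig = {eigs[0]:.3g}/{eigs[-1]:.3g})"
        )
    else:
        cov = np.linalg.inv(info)
        dvar = np.diag(cov)
        if np.any(dvar < 0):
            identifiable = False
            diagnostics.append("negative variance on information inverse diagonal")
            se = None
        else:
            se = np.sqrt(dvar)
            explode = (se > 20 * np.abs(theta_nat)) & (se > 10)
            if np.any(explode):
                identifiable = False
                bad = [layout.names()[i] for i in np.where(explode)[0]]
                diagnostics.append(f"exploding standard errors for {bad}")
    return layout, theta_nat, se, converged, identifiable, diagnostics


def _group_result(
    model: SemModel,
    layout: _Layout,
    gd: _GroupData,
    theta_nat,
    se,
    converged,
    identifiable,
    diagnostics,
    k_g: float,
    group_df: int,
) -> FitResult:
    shared, per_group = layout.split(theta_nat)
    edge_vals, psi_vals = per_group[gd.name]
    A, Omega = _assemble(layout, edge_vals, psi_vals, shared, gd.cov_block)
    Sigma, _, _ = _sigma_of(A, Omega, layout.obs_idx)
    obs = list(model.observed)
    p = len(obs)
    if gd.singular:
        f_val = np.nan
        loglik = np.nan
    else:
        L = linalg.cholesky(Sigma, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Sinv = linalg.cho_solve((L, True), np.eye(p))
        f_val = float(logdet + np.sum(Sinv * gd.S) - gd.logdet_s - p)
        loglik = -0.5 * gd.w * (p * np.log(2 * np.pi) + logdet + float(np.sum(Sinv * gd.S)))
    names = layout.names()
    own = [i for i, nm in enumerate(names) if nm.endswith(f"@{gd.name}") or nm.startswith("slope:")]
    est = pd.Series(theta_nat[own], index=[names[i] for i in own])
    se_s = pd.Series(se[own], index=est.index) if se is not None else None
    chi2_g = gd.w * f_val if np.isfinite(f_val) else np.nan
    return FitResult(
        group=gd.name,
        estimates=est,
        se=se_s,
        sample_cov=pd.DataFrame(gd.S, index=obs, columns=obs),
        implied_cov=pd.DataFrame(Sigma, index=obs, columns=obs),
        f_ml=f_val,
        loglik=loglik,
        n=gd.n,
        p=p,
        chi2=chi2_g,
        df=group_df,
        aic=-2 * loglik + 2 * k_g,
        bic=-2 * loglik + k_g * np.log(gd.n),
        converged=converged,
        identifiable=identifiable,
        diagnostics=list(diagnostics),
    )


def _baseline_chi2(model: SemModel, groups: list[_GroupData]) -> tuple[float, int]:
    base = model.baseline()
    layout, theta_nat, _, _, _, _ = _fit_core(base, groups, compute_se=False)
    val, _ = _objective_and_grad(theta_nat, layout, groups, log_psi=False)
    df = _count_df(base, len(groups), layout.n_params)
    return float(val), df


def fit_multigroup(
    model: SemModel,
    data_by_group: Mapping[str, ExpressionDataset],
    covariates: Sequence[str] | None = None,
) -> MultigroupFit:
    """Joint ML fit across groups with covariate slopes constrained equal.

    Parameters
    ----------
    model : the structural model.  If ``covariates`` is given it overrides
        the model's covariate list.
    data_by_group : mapping group label -> dataset; all datasets must carry
        the model's genes and covariate columns.
    """
    if covariates is not None and tuple(covariates) != model.covariates:
        model = SemModel(
            model.genes, model.latents, model.structural_edges, model.loading_edges,
            tuple(covariates),
        )
    if len(data_by_group) < 2:
        raise ValueError("multigroup fit needs at least two groups")
    groups = _prepare_groups(model, data_by_group)
    layout, theta_nat, se, converged, identifiable, diagnostics = _fit_core(model, groups)

    chi2, _ = _objective_and_grad(theta_nat, layout, groups, log_psi=False)
    df = _count_df(model, len(groups), layout.n_params)
    base_chi2, base_df = _baseline_chi2(model, groups)

    names = layout.names()
    n_groups = len(groups)
    k_shared = layout.n_shared / n_groups
    group_fits = {}
    for gd in groups:
        group_fits[gd.name] = _group_result(
            model, layout, gd, theta_nat, se, converged, identifiable, diagnostics,
            k_g=layout.per_group + k_shared, group_df=df // n_groups if n_groups else df,
        )
    shared_est = pd.Series(theta_nat[: layout.n_shared], index=names[: layout.n_shared])
    shared_se = (
        pd.Series(se[: layout.n_shared], index=names[: layout.n_shared])
        if se is not None
        else None
    )
    mfit = MultigroupFit(
        model=model,
        groups=tuple(gd.name for gd in groups),
        group_fits=group_fits,
        shared_estimates=shared_est,
        shared_se=shared_se,
        chi2=float(chi2),
        df=df,
        baseline_chi2=base_chi2,
        baseline_df=base_df,
        n_total=sum(gd.n for gd in groups),
        converged=converged,
        identifiable=identifiable,
        diagnostics=diagnostics,
        wald_table=pd.DataFrame(),
    )
    mfit.wald_table = _build_wald_table(mfit)
    return mfit


def _build_wald_table(mfit: MultigroupFit) -> pd.DataFrame:
    """Per-edge between-group Wald tests plus per-group significance."""
    model = mfit.model
    rows = []
    g1, g2 = mfit.groups[0], mfit.groups[-1]
    edges = list(model.structural_edges) + list(model.loading_edges)
    for src, dst in edges:
        row: dict = {"edge": f"{src}->{dst}", "src": src, "dst": dst}
        for g in mfit.groups:
            fr = mfit.group_fits[g]
            key = f"beta:{src}->{dst}@{g}"
            est = fr.estimates.get(key, np.nan)
            se = fr.se.get(key, np.nan) if fr.se is not None else np.nan
            row[f"est_{g}"] = est
            row[f"se_{g}"] = se
            if np.isfinite(se) and se > 0:
                zg = est / se
                row[f"p_{g}"] = 2 * stats.norm.sf(abs(zg))
            else:
                row[f"p_{g}"] = np.nan
        se1, se2 = row[f"se_{g1}"], row[f"se_{g2}"]
        if np.isfinite(se1) and np.isfinite(se2):
            denom = np.sqrt(se1**2 + se2**2)
            z = (row[f"est_{g1}"] - row[f"est_{g2}"]) / denom if denom > 0 else np.nan
            row["z_diff"] = z
            row["p_diff"] = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        else:
            row["z_diff"] = np.nan
            row["p_diff"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def fit_single_group(model: SemModel, data: ExpressionDataset, group: str = "all") -> FitResult:
    """ML fit of one group (no equality constraints)."""
    groups = _prepare_groups(model, {group: data})
    layout, theta_nat, se, converged, identifiable, diagnostics = _fit_core(model, groups)
    chi2, _ = _objective_and_grad(theta_nat, layout, groups, log_psi=False)
    df = _count_df(model, 1, layout.n_params)
    result = _group_result(
        model, layout, groups[0], theta_nat, se, converged, identifiable, diagnostics,
        k_g=layout.n_params, group_df=df,
    )
    result.chi2 = float(chi2)
    result.df = df
    if not groups[0].singular:
        base_chi2, base_df = _baseline_chi2(model, groups)
        result.baseline_chi2 = base_chi2
        result.baseline_df = base_df
    return result


# ---------------------------------------------------------------------------
# fit indices and tests
# ---------------------------------------------------------------------------


def fit_indices(fit: MultigroupFit | FitResult) -> dict:
    """RMSEA, CFI, AIC, BIC, chi-square and df for a converged fit.

    RMSEA uses the multigroup convention sqrt(G) * sqrt(max(chi2-df,0) /
    (df*(N-G))); CFI is measured against the independence baseline (free
    variances and covariate slopes) and clamped to [0, 1].
    """
    if isinstance(fit, MultigroupFit):
        chi2, df = fit.chi2, fit.df
        base_chi2, base_df = fit.baseline_chi2, fit.baseline_df
        n_groups = len(fit.groups)
        n_total = fit.n_total
        aic = sum(fr.aic for fr in fit.group_fits.values())
        bic = sum(fr.bic for fr in fit.group_fits.values())
    else:
        chi2, df = fit.chi2, fit.df
        base_chi2, base_df = fit.baseline_chi2, fit.baseline_df
        n_groups, n_total = 1, fit.n
        aic, bic = fit.aic, fit.bic

    if df <= 0:
        if df < 0:
            warnings.warn("negative degrees of freedom; model is over-parameterised")
        else:
            warnings.warn("df = 0: RMSEA undefined, reported as 0")
        rmsea = 0.0
    else:
        rmsea = np.sqrt(n_groups) * np.sqrt(max(chi2 - df, 0.0) / (df * (n_total - n_groups)))
    if base_chi2 is None or base_df is None:
        cfi = np.nan
    else:
        denom = max(base_chi2 - base_df, chi2 - df, 0.0)
        cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
        cfi = float(np.clip(cfi, 0.0, 1.0))
    return {
        "RMSEA": float(rmsea),
        "CFI": cfi,
        "AIC": float(aic),
        "BIC": float(bic),
        "chi2": float(chi2),
        "df": int(df),
    }


def wald_difference_test(fit: MultigroupFit, edge: tuple[str, str]) -> dict:
    """Between-group Wald test of one path coefficient.

    z = (theta_1 - theta_2) / sqrt(SE_1^2 + SE_2^2), two-sided normal p.
    Returns ``{"z": nan, "p": nan, "testable": False}`` when a standard
    error is unavailable.
    """
    src, dst = edge
    table = fit.wald_table
    row = table[(table["src"] == src) & (table["dst"] == dst)]
    if row.empty:
        raise KeyError(f"edge {edge!r} is not in the model")
    z = float(row["z_diff"].iloc[0])
    p = float(row["p_diff"].iloc[0])
    return {"z": z, "p": p, "testable": bool(np.isfinite(z))}


def check_identifiability(fit: MultigroupFit | FitResult) -> tuple[bool, list[str]]:
    """Empirical identifiability verdict with the triggering diagnostics."""
    return bool(fit.identifiable), list(fit.diagnostics)


# ---------------------------------------------------------------------------
# sklearn-style wrapper
# ---------------------------------------------------------------------------


class MultigroupSEM:
    """Estimator-style interface over :func:`fit_multigroup`.

    Parameters mirror scikit-learn conventions: construct with the model
    specification, call :meth:`fit` with the grouped data, read fitted
    attributes with trailing underscores.
    """

    def __init__(self, model: SemModel, covariates: Sequence[str] | None = None):
        self.model = model
        self.covariates = covariates

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "covariates": self.covariates}

    def set_params(self, **params) -> "MultigroupSEM":
        for k, v in params.items():
            if k not in ("model", "covariates"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, data_by_group: Mapping[str, ExpressionDataset]) -> "MultigroupSEM":
        result = fit_multigroup(self.model, data_by_group, self.covariates)
        self.result_ = result
        self.wald_table_ = result.wald_table
        self.indices_ = fit_indices(result)
        self.identifiable_ = result.identifiable
        return self
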