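"""Alternative-model search over a pathway network.

Every single-gene-per-node resolution of the network is fitted by multigroup
SEM; empirically non-identifiable fits are discarded, the remainder filtered
on the number of non-significant control-group paths and on RMSEA, and the
best model is the surviving fit with the highest CFI (ties broken by lower
RMSEA, then enumeration order).  The selected model's between-group Wald
table reports which gene-gene relationships differ between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .networks import DEFAULT_ALTERNATIVE_CAP, PathwayNetwork, ResolvedNetwork, enumerate_alternatives
from .sem import MultigroupFit, SemModel, fit_indices, fit_multigroup

__all__ = [
    "SearchCriteria",
    "BestModelReport",
    "search_best_model",
    "group_information_comparison",
    "star_annotation",
]

_CFI_TIE_TOL = 1e-6


@dataclass
class SearchCriteria:
    """Screening thresholds for admissible alternative models."""

    max_nonsignificant_paths: int = 3
    rmsea_ceiling: float = 0.2
    alpha: float = 0.05
    alternative_cap: int = DEFAULT_ALTERNATIVE_CAP

    def __post_init__(self) -> None:
        if self.rmsea_ceiling < 0:
            raise ValueError("RMSEA ceiling must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class BestModelReport:
    pathway: str
    n_generated: int
    n_identifiable: int
    n_surviving: int
    selected: ResolvedNetwork | None
    selected_fit: MultigroupFit | None
    indices: dict | None
    group_aic: dict[str, float]
    group_bic: dict[str, float]
    wald_table: pd.DataFrame | None
    control_group: str = "control"
    failure_log: list[dict] = field(default_factory=list)

    @property
    def has_selection(self) -> bool:
        return self.selected is not None

    def starred_wald_table(self) -> pd.DataFrame:
        if self.wald_table is None:
            raise ValueError("no admissible model was selected")
        table = self.wald_table.copy()
        table["stars"] = [
            star_annotation(p) if np.isfinite(p) else "ns" for p in table["p_diff"]
        ]
        return table


def star_annotation(p: float) -> str:
    """Significance stars: ns (p >= 0.05), * (<0.05), ** (<0.01), *** (<0.001)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _count_nonsignificant_control(fit: MultigroupFit, control_group: str, alpha: float) -> int:
    col = f"p_{control_group}"
    ps = fit.wald_table[col].to_numpy(dtype=float)
    return int(np.sum(~np.isfinite(ps) | (ps >= alpha)))


def search_best_model(
    network: PathwayNetwork,
    data_by_group: Mapping[str, ExpressionDataset],
    covariates: Sequence[str] = (),
    criteria: SearchCriteria | None = None,
    control_group: str = "control",
) -> BestModelReport:
    """Fit every alternative resolved network and select the best admissible one.

    Filters, in order: empirical identifiability; at most
    ``criteria.max_nonsignificant_paths`` control-group paths with Wald
    p >= alpha; RMSEA strictly below the ceiling.  Among survivors the
    highest CFI wins (ties: lower RMSEA, then enumeration order).  Failed
    fits never abort the search; they are logged with diagnostics.
    """
    criteria = criteria or SearchCriteria()
    network.validate_for_sem()
    if control_group not in data_by_group:
        raise ValueError(f"control group {control_group!r} missing from data")
    if len(data_by_group) < 2:
        raise ValueError("need at least two groups")

    candidates = []
    failure_log: list[dict] = []
    n_generated = 0
    n_identifiable = 0
    for order, resolved in enumerate(
        enumerate_alternatives(network, cap=criteria.alternative_cap)
    ):
        n_generated += 1
        model = SemModel.from_resolved(resolved, covariates=covariates)
        try:
            fit = fit_multigroup(model, data_by_group)
        except Exception as exc:  # data-level failure for this alternative only
            failure_log.append(
                {"alternative": order, "status": "error", "detail": str(exc)}
            )
            continue
        if not fit.identifiable:
            failure_log.append(
                {
                    "alternative": order,
                    "status": "non-identifiable",
                    "detail": "; ".join(fit.diagnostics),
                }
            )
            continue
        n_identifiable += 1
        idx = fit_indices(fit)
        n_ns = _count_nonsignificant_control(fit, control_group, criteria.alpha)
        if n_ns > criteria.max_nonsignificant_paths:
            failure_log.append(
                {
                    "alternative": order,
                    "status": "filtered",
                    "detail": f"{n_ns} non-significant control-group paths",
                }
            )
            continue
        if not idx["RMSEA"] < criteria.rmsea_ceiling:
            failure_log.append(
                {
                    "alternative": order,
                    "status": "filtered",
                    "detail": f"RMSEA {idx['RMSEA']:.4f} >= {criteria.rmsea_ceiling}",
                }
            )
            continue
        candidates.append((order, resolved, fit, idx))

    if not candidates:
        return BestModelReport(
            pathway=network.name,
            n_generated=n_generated,
            n_identifiable=n_identifiable,
            n_surviving=0,
            selected=None,
            selected_fit=None,
            indices=None,
            group_aic={},
            group_bic={},
            wald_table=None,
            control_group=control_group,
            failure_log=failure_log,
        )

    # argmax CFI; ties (within tolerance) -> lower RMSEA -> enumeration order
    def sort_key(item):
        order, _, _, idx = item
        return (-round(idx["CFI"] / _CFI_TIE_TOL), idx["RMSEA"], order)

    candidates.sort(key=sort_key)
    order, resolved, fit, idx = candidates[0]
    return BestModelReport(
        pathway=network.name,
        n_generated=n_generated,
        n_identifiable=n_identifiable,
        n_surviving=len(candidates),
        selected=resolved,
        selected_fit=fit,
        indices=idx,
        group_aic={g: fr.aic for g, fr in fit.group_fits.items()},
        group_bic={g: fr.bic for g, fr in fit.group_fits.items()},
        wald_table=fit.wald_table,
        control_group=control_group,
        failure_log=failure_log,
    )


def group_information_comparison(report: BestModelReport) -> dict:
    """Which group the selected model explains better, by AIC and by BIC.

    Lower information-criterion values indicate the better-explained group.
    """
    if not report.has_selection:
        raise ValueError("no admissible model was selected")
    best_aic = min(report.group_aic, key=report.group_aic.get)
    best_bic = min(report.group_bic, key=report.group_bic.get)
    return {
        "aic": dict(report.group_aic),
        "bic": dict(report.group_bic),
        "better_by_aic": best_aic,
        "better_by_bic": best_bic,
    }
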