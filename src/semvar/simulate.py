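"""Truth-known synthetic two-group expression data.

The generator is the sampling counterpart of the structural model fitted by
:mod:`semvar.sem`: for each group, pathway genes are draws from the linear
structural system with group-specific path coefficients, shared covariate
effects (age, sex, batch, two expression PCs) and Gaussian structural /
measurement errors.  A genome-wide background of independent Gaussian genes
can be added, in which a configurable fraction has its variance inflated in
one target group — emulating the genome-wide variance-comparison setting.

Default sample sizes follow the study design this emulates: 144 affected
("SCZ") and 111 unaffected ("control") individuals, 23,920 background genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, concat_genes
from .networks import PathwayNetwork

__all__ = [
    "BackgroundConfig",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_pathway_expression",
    "simulate_background_genes",
    "simulate_study",
]

#: (name, population variance, sampler) for the five shared covariates.
_COVARIATE_SPECS = (
    ("age", (48.0**2 - 1) / 12.0, lambda rng, n: rng.integers(18, 66, size=n).astype(float)),
    ("sex", 0.25, lambda rng, n: rng.integers(0, 2, size=n).astype(float)),
    ("batch", 0.25, lambda rng, n: rng.integers(0, 2, size=n).astype(float)),
    ("PC1", 1.0, lambda rng, n: rng.standard_normal(n)),
    ("PC2", 1.0, lambda rng, n: rng.standard_normal(n)),
)

COVARIATE_NAMES = tuple(name for name, _, _ in _COVARIATE_SPECS)


@dataclass
class BackgroundConfig:
    """Independent background genes with variance inflation in one group."""

    n_genes: int = 23_920
    fraction_inflated: float = 0.3
    inflation_factor: float = 2.0
    target_group: str = "SCZ"
    base_variance: float = 1.0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("background n_genes must be >= 1")
        if not 0.0 <= self.fraction_inflated <= 1.0:
            raise ValueError("fraction_inflated must lie in [0, 1]")
        if self.inflation_factor < 1.0:
            raise ValueError("inflation_factor must be >= 1")


@dataclass
class SimulationConfig:
    """Generating parameters for one two-group pathway simulation.

    ``coefficients_by_group`` maps group label -> {(src node, dst node) ->
    coefficient}; every keyed edge must exist in the network.  Covariate
    effects are shared across groups by construction.  ``resolution`` picks
    the causally active gene for each complex node (default: first member).
    """

    network: PathwayNetwork
    coefficients_by_group: dict[str, dict[tuple[str, str], float]]
    error_variances: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=lambda: {"SCZ": 144, "control": 111})
    resolution: dict[str, str] | None = None
    latent_loadings: dict[tuple[str, str], float] = field(default_factory=dict)
    background: BackgroundConfig | None = None
    decoy_variance: float = 1.0  # variance of unchosen complex-node member genes
    seed: int = 0

    def validate(self) -> None:
        if len(self.coefficients_by_group) < 2:
            raise ValueError("need coefficients for at least two groups")
        if set(self.coefficients_by_group) != set(self.n_per_group):
            raise ValueError("groups in coefficients_by_group and n_per_group disagree")
        edge_set = set(self.network.edges)
        for group, coefs in self.coefficients_by_group.items():
            bad = [e for e in coefs if tuple(e) not in edge_set]
            if bad:
                raise ValueError(f"group {group!r} has coefficients for non-edges: {bad}")
        for var, v in self.error_variances.items():
            if v <= 0:
                raise ValueError(f"error variance for {var!r} must be positive, got {v}")
        for group, n in self.n_per_group.items():
            if n < 3:
                raise ValueError(f"group {group!r} needs n >= 3, got {n}")
        if self.background is not None:
            self.background.validate()

    def resolved_gene(self, node_id: str) -> str:
        node = self.network.node(node_id)
        if node.latent:
            return node.id
        if self.resolution and node_id in self.resolution:
            gene = self.resolution[node_id]
            if gene not in node.members:
                raise ValueError(f"resolution gene {gene!r} is not a member of node {node_id!r}")
            return gene
        return node.members[0]


@dataclass
class SimulationTruth:
    """Exact generating parameters and their implied moments."""

    implied_cov: dict[str, pd.DataFrame]  # per group, over observed pathway genes
    differing_edges: list[tuple[str, str]]  # node-level edges with unequal coefficients
    resolution: dict[str, str]
    inflated_genes: pd.Series | None = None  # boolean indicator over background genes


def _assemble_generating(config: SimulationConfig, group: str):
    """Full-variable (I-A, Omega-diag, var order) assembly for one group."""
    net = config.network
    gene_of = {n.id: config.resolved_gene(n.id) for n in net.nodes}
    struct_vars = [gene_of[n.id] for n in net.nodes]  # gene or latent-node label
    latents = [n.id for n in net.nodes if n.latent]
    indicator_genes = [g for n in net.nodes if n.latent for g in n.members]
    observed = [v for v in struct_vars if v not in latents] + indicator_genes

    all_vars = list(dict.fromkeys(struct_vars + indicator_genes)) + list(COVARIATE_NAMES)
    idx = {v: i for i, v in enumerate(all_vars)}
    m = len(all_vars)
    A = np.zeros((m, m))
    coefs = config.coefficients_by_group[group]
    for (src, dst), val in coefs.items():
        A[idx[gene_of[dst]], idx[gene_of[src]]] = val
    for n in net.nodes:
        if n.latent:
            for g in n.members:
                A[idx[g], idx[n.id]] = config.latent_loadings.get((n.id, g), 1.0)
    for (var, cov), val in config.covariate_effects.items():
        var = gene_of.get(var, var)
        if var not in idx or cov not in COVARIATE_NAMES:
            raise ValueError(f"unknown covariate effect target ({var!r}, {cov!r})")
        A[idx[var], idx[cov]] = val

    omega = np.ones(m)
    for v in all_vars:
        if v in latents:
            omega[idx[v]] = 1.0
        elif v in config.error_variances:
            omega[idx[v]] = config.error_variances[v]
    for name, var, _ in _COVARIATE_SPECS:
        omega[idx[name]] = var

    IA = np.eye(m) - A
    if abs(np.linalg.det(IA)) < 1e-12:
        raise np.linalg.LinAlgError(
            f"I - B is singular for group {group!r}: the structural system has no "
            "unique reduced form at the supplied coefficients"
        )
    obs_rows = np.array([idx[v] for v in observed], dtype=int)
    return IA, omega, all_vars, observed, obs_rows, idx


def simulate_pathway_expression(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Draw two-group expression for a pathway's genes from the structural system.

    The returned dataset contains every member gene of the network: the
    resolved (causally active) gene per node follows the structural system,
    while unchosen members of complex nodes are independent Gaussian decoys,
    so that every alternative single-gene model can be fitted to the data.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    cov_seed, path_seed, decoy_seed = root.spawn(3)
    rng_cov = np.random.default_rng(cov_seed)
    rng_path = np.random.default_rng(path_seed)
    rng_decoy = np.random.default_rng(decoy_seed)

    groups = sorted(config.n_per_group)  # deterministic group order
    frames, metas = [], []
    implied: dict[str, pd.DataFrame] = {}
    resolution = {
        n.id: config.resolved_gene(n.id) for n in config.network.nodes if not n.latent
    }
    chosen = set(resolution.values())
    decoys = sorted(
        g
        for n in config.network.nodes
        if not n.latent
        for g in n.members
        if g not in chosen
    )

    for group in groups:
        n = config.n_per_group[group]
        IA, omega, all_vars, observed, obs_rows, idx = _assemble_generating(config, group)
        m = len(all_vars)
        shocks = np.zeros((m, n))
        for name, _, sampler in _COVARIATE_SPECS:
            shocks[idx[name]] = sampler(rng_cov, n)
        noise_rows = [i for i, v in enumerate(all_vars) if v not in COVARIATE_NAMES]
        sd = np.sqrt(omega[noise_rows])
        shocks[noise_rows] = rng_path.standard_normal((len(noise_rows), n)) * sd[:, None]
        values = np.linalg.solve(IA, shocks)

        expr = pd.DataFrame(values[obs_rows], index=observed)
        if decoys:
            decoy_vals = rng_decoy.standard_normal((len(decoys), n)) * np.sqrt(
                config.decoy_variance
            )
            expr = pd.concat([expr, pd.DataFrame(decoy_vals, index=decoys)])
        meta = pd.DataFrame(
            {name: shocks[idx[name]] for name, _, _ in _COVARIATE_SPECS}
        )
        meta.insert(0, "group", group)
        frames.append(expr)
        metas.append(meta)

        # analytic implied covariance over the observed structural genes
        full_cov = np.linalg.solve(IA, np.diag(omega)) @ np.linalg.inv(IA).T
        implied[group] = pd.DataFrame(
            full_cov[np.ix_(obs_rows, obs_rows)], index=observed, columns=observed
        )

    sample_ids = [f"{g}_{i:04d}" for g, meta in zip(groups, metas) for i in range(len(meta))]
    expression = pd.concat(frames, axis=1)
    expression.columns = sample_ids
    samples = pd.concat(metas, ignore_index=True)
    samples.index = pd.Index(sample_ids, name="sample_id")

    differing = sorted(
        {
            e
            for g1 in groups
            for g2 in groups
            for e in set(config.coefficients_by_group[g1]) | set(config.coefficients_by_group[g2])
            if config.coefficients_by_group[g1].get(e, 0.0)
            != config.coefficients_by_group[g2].get(e, 0.0)
        }
    )
    truth = SimulationTruth(implied_cov=implied, differing_edges=differing, resolution=resolution)
    return ExpressionDataset(expression, samples), truth


def simulate_background_genes(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, pd.Series]:
    """Independent Gaussian background genes with group-targeted variance inflation.

    Returns the dataset and the boolean truth indicator of inflated genes.
    """
    bg = config.background
    if bg is None:
        raise ValueError("config.background is not set")
    bg.validate()
    for group, n in config.n_per_group.items():
        if n < 3:
            raise ValueError(f"group {group!r} needs n >= 3, got {n}")
    if bg.target_group not in config.n_per_group:
        raise ValueError(f"target group {bg.target_group!r} not among simulated groups")

    root = np.random.SeedSequence(config.seed)
    (bg_seed,) = root.spawn(4)[3:]
    rng = np.random.default_rng(bg_seed)

    genes = [f"BG{i:05d}" for i in range(bg.n_genes)]
    n_inflated = int(round(bg.fraction_inflated * bg.n_genes))
    inflated = np.zeros(bg.n_genes, dtype=bool)
    inflated[rng.choice(bg.n_genes, size=n_inflated, replace=False)] = True

    groups = sorted(config.n_per_group)
    blocks, metas, sample_ids = [], [], []
    for group in groups:
        n = config.n_per_group[group]
        sd = np.full(bg.n_genes, np.sqrt(bg.base_variance))
        if group == bg.target_group:
            sd[inflated] *= np.sqrt(bg.inflation_factor)
        blocks.append(rng.standard_normal((bg.n_genes, n)) * sd[:, None])
        metas.append(pd.DataFrame({"group": [group] * n}))
        sample_ids += [f"{group}_{i:04d}" for i in range(n)]

    expression = pd.DataFrame(np.concatenate(blocks, axis=1), index=genes, columns=sample_ids)
    samples = pd.concat(metas, ignore_index=True)
    samples.index = pd.Index(sample_ids, name="sample_id")
    indicator = pd.Series(inflated, index=genes, name="inflated")
    return ExpressionDataset(expression, samples), indicator


def simulate_study(config: SimulationConfig) -> tuple[ExpressionDataset, SimulationTruth]:
    """Pathway plus background in one dataset (shared samples and covariates)."""
    pathway_ds, truth = simulate_pathway_expression(config)
    if config.background is None:
        return pathway_ds, truth
    bg_ds, indicator = simulate_background_genes(config)
    bg_expr = bg_ds.expression
    bg_expr.columns = pathway_ds.expression.columns  # same group layout by construction
    combined = concat_genes(
        [pathway_ds, ExpressionDataset(bg_expr, pathway_ds.samples.copy())]
    )
    truth.inflated_genes = indicator
    return combined, truth
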