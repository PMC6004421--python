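"""Pathway-level enrichment of differential-variance signal.

Four procedures over a genome-wide variance comparison:

* ``ease_ora`` — conservative one-tailed Fisher exact over-representation
  p-value with the hit cell reduced by one (the EASE penalisation).
* ``node_ora`` — node-based over-representation: the score of a pathway is
  the number of nodes containing at least one flagged gene, with a
  Monte-Carlo permutation null over the gene universe.
* ``gsea_preranked`` — classic weighted Kolmogorov-Smirnov running-sum
  enrichment statistic on a ranked gene list, gene-label permutation null.
* ``node_gsa_fisher`` — two-stage Fisher's-method aggregation of per-gene
  p-values: genes -> node, then nodes -> pathway.

plus Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .networks import PathwayNetwork

__all__ = [
    "EnrichmentResult",
    "ease_ora",
    "node_ora",
    "gsea_preranked",
    "node_gsa_fisher",
    "bh_fdr",
    "enrich_pathways",
]

_MIN_P = np.finfo(float).tiny


@dataclass
class EnrichmentResult:
    pathway: str
    method: str
    score: float
    p: float
    fdr: float | None = None
    n_trials: int | None = None
    seed: int | None = None


def ease_ora(hits_in_set: int, set_size: int, hits_universe: int, universe_size: int) -> float:
    """EASE score: upper-tail Fisher exact p after removing one hit from the set.

    With the overlap cell reduced to ``max(hits_in_set - 1, 0)`` the p-value
    is the hypergeometric tail P(X >= hits_in_set - 1) for X ~
    Hypergeom(universe, hits_universe, set_size).
    """
    if not (0 <= hits_in_set <= set_size <= universe_size):
        raise ValueError("inconsistent contingency counts (set side)")
    if not (hits_in_set <= hits_universe <= universe_size):
        raise ValueError("inconsistent contingency counts (universe side)")
    if set_size - hits_in_set > universe_size - hits_universe:
        raise ValueError("more non-hits in set than exist in the universe")
    penalized = max(hits_in_set - 1, 0)
    if penalized == 0:
        return 1.0
    return float(stats.hypergeom.sf(penalized - 1, universe_size, hits_universe, set_size))


def node_ora(
    network: PathwayNetwork,
    indicator: pd.Series,
    n_trials: int = 1_000_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Node-based over-representation with a Monte-Carlo permutation null.

    The observed score is the number of nodes with at least one flagged
    member gene.  Under the null the flags are permuted across the universe
    (all genes in ``indicator``); equivalently, for the pathway's member
    genes the flag pattern follows the multivariate hypergeometric law,
    which is what is sampled.  p = (1 + #{null score >= observed}) /
    (1 + n_trials) — the add-one smoothing keeps p strictly positive.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    indicator = indicator.astype(bool)
    members = sorted(network.member_genes)
    missing = [g for g in members if g not in indicator.index]
    if missing:
        raise KeyError(f"member genes absent from the indicator universe: {missing}")
    universe = len(indicator)
    n_flagged = int(indicator.sum())

    member_pos = {g: i for i, g in enumerate(members)}
    node_members = [np.array([member_pos[g] for g in n.members]) for n in network.nodes]
    flags_obs = indicator.loc[members].to_numpy()
    score_obs = int(sum(flags_obs[mi].any() for mi in node_members))

    rng = np.random.default_rng(seed)
    m = len(members)
    exceed = 0
    chunk = 100_000
    for start in range(0, n_trials, chunk):
        size = min(chunk, n_trials - start)
        # how many of the m member genes are flagged in each trial
        k_m = rng.hypergeometric(n_flagged, universe - n_flagged, m, size=size)
        # which members: a uniformly random k_m-subset via random-key ranking
        keys = rng.random((size, m))
        order = np.argsort(keys, axis=1)
        ranks = np.empty_like(order)
        rows = np.arange(size)[:, None]
        ranks[rows, order] = np.arange(m)[None, :]
        flags_null = ranks < k_m[:, None]
        scores_null = np.zeros(size, dtype=np.int32)
        for mi in node_members:
            scores_null += flags_null[:, mi].any(axis=1)
        exceed += int(np.sum(scores_null >= score_obs))
    p = (1 + exceed) / (1 + n_trials)
    return EnrichmentResult(
        pathway=network.name, method="node-ORA", score=float(score_obs), p=float(p),
        n_trials=n_trials, seed=seed,
    )


def _running_es(scores: np.ndarray, in_set: np.ndarray) -> float:
    """Signed enrichment statistic (weight exponent 1) for one ordering."""
    nh = int(in_set.sum())
    n = scores.size
    if nh == 0 or nh == n:
        raise ValueError("gene set must be a proper nonempty subset of the ranked list")
    weights = np.abs(scores)
    nr = weights[in_set].sum()
    if nr == 0:
        # all in-set scores zero: fall back to equal hit increments
        inc = np.where(in_set, 1.0 / nh, -1.0 / (n - nh))
    else:
        inc = np.where(in_set, weights / nr, -1.0 / (n - nh))
    running = np.cumsum(inc)
    i_max = np.argmax(np.abs(running))
    return float(running[i_max])


def gsea_preranked(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_set: set[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Classic preranked enrichment score with a gene-label permutation null.

    ``ranked_genes``/``scores`` must already be ordered (best first); the
    running sum steps up by |score|/sum(in-set |score|) at set members and
    down by 1/(N - set size) elsewhere.  The p-value is the tail of the
    permutation null on the same side as the observed statistic's sign.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    in_set = np.array([g in gene_set for g in ranked_genes])
    if not in_set.any():
        return EnrichmentResult("", "GSEA", np.nan, np.nan)  # not testable
    if in_set.all():
        raise ValueError("gene set covers the whole ranked list")
    es = _running_es(scores, in_set)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _running_es(scores, rng.permutation(in_set))
    # standard signed convention: compare against the same-sign half of the null
    same_sign = null >= 0 if es >= 0 else null < 0
    p = (1 + int(np.sum(np.abs(null[same_sign]) >= abs(es)))) / (1 + int(same_sign.sum()))
    return EnrichmentResult(
        pathway="", method="GSEA", score=es, p=float(p), n_trials=n_permutations, seed=seed
    )


def _fisher_combine(pvals: np.ndarray) -> float:
    pvals = np.clip(np.asarray(pvals, dtype=float), _MIN_P, 1.0)
    statistic = -2.0 * np.log(pvals).sum()
    return float(stats.chi2.sf(statistic, 2 * pvals.size))


def node_gsa_fisher(network: PathwayNetwork, gene_pvalues: pd.Series) -> EnrichmentResult:
    """Two-stage Fisher aggregation: member p-values -> node p, node ps -> pathway p."""
    missing = [g for g in network.member_genes if g not in gene_pvalues.index]
    if missing:
        raise KeyError(f"member genes lack p-values: {missing}")
    if (gene_pvalues.loc[sorted(network.member_genes)] <= 0).any():
        import warnings

        warnings.warn("p-values of 0 clamped to the smallest positive float")
    node_ps = np.array(
        [_fisher_combine(gene_pvalues.loc[list(n.members)].to_numpy()) for n in network.nodes]
    )
    p = _fisher_combine(node_ps)
    return EnrichmentResult(
        pathway=network.name, method="node-GSA-Fisher", score=float(-2 * np.log(np.clip(node_ps, _MIN_P, 1)).sum()), p=p
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def enrich_pathways(
    networks: list[PathwayNetwork],
    indicator: pd.Series,
    gene_pvalues: pd.Series,
    n_trials: int = 1_000_000,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run all four enrichment methods over a set of pathways; BH-adjust per method.

    ``indicator`` flags increased-variance genes over the analysis universe;
    ``gene_pvalues`` are the per-gene one-sided Levene p-values over the same
    universe (used for EASE hits via the indicator, for ranking in GSEA and
    for Fisher aggregation).
    """
    universe = indicator.index
    order = gene_pvalues.loc[universe].sort_values(kind="mergesort")
    ranked = list(order.index)
    ranking_scores = -np.log10(np.clip(order.to_numpy(), _MIN_P, 1.0))
    rows = []
    for i, net in enumerate(networks):
        members = sorted(net.member_genes & set(universe))
        if len(members) < len(net.member_genes):
            missing = sorted(net.member_genes - set(universe))
            raise KeyError(f"pathway {net.name!r}: genes missing from universe: {missing}")
        hits_in_set = int(indicator.loc[members].sum())
        res_ease = ease_ora(hits_in_set, len(members), int(indicator.sum()), len(universe))
        rows.append((net.name, "EASE-ORA", float(hits_in_set), res_ease))
        res_node = node_ora(net, indicator, n_trials=n_trials, seed=seed + i)
        rows.append((net.name, "node-ORA", res_node.score, res_node.p))
        res_gsea = gsea_preranked(
            ranked, ranking_scores, set(members), n_permutations=n_permutations, seed=seed + i
        )
        rows.append((net.name, "GSEA", res_gsea.score, res_gsea.p))
        res_fisher = node_gsa_fisher(net, gene_pvalues)
        rows.append((net.name, "node-GSA-Fisher", res_fisher.score, res_fisher.p))
    table = pd.DataFrame(rows, columns=["pathway", "method", "score", "p"])
    table["fdr"] = np.nan
    for method in table["method"].unique():
        mask = table["method"] == method
        valid = mask & table["p"].notna()
        if valid.any():
            table.loc[valid, "fdr"] = bh_fdr(table.loc[valid, "p"].to_numpy())
    return table
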