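"""Enrichment statistics: EASE, node-based ORA, preranked GSEA, Fisher, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import semvar as sv
from semvar.networks import PathwayNetwork, PathwayNode


def toy_network(node_members, name="toy", edges=()):
    nodes = [PathwayNode(nid, tuple(m)) for nid, m in node_members]
    return PathwayNetwork(name, nodes, list(edges))


# ---------------------------------------------------------------------------
# EASE
# ---------------------------------------------------------------------------


def test_ease_zero_or_one_hit_gives_p_one():
    assert sv.ease_ora(0, 10, 50, 200) == 1.0
    assert sv.ease_ora(1, 10, 50, 200) == 1.0


def test_ease_matches_hypergeometric_with_decremented_cell():
    p = sv.ease_ora(8, 10, 50, 200)
    oracle = float(stats.hypergeom.sf(6, 200, 50, 10))  # P(X >= 7)
    assert p == pytest.approx(oracle, rel=1e-12)


def test_ease_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        sv.ease_ora(11, 10, 50, 200)
    with pytest.raises(ValueError):
        sv.ease_ora(5, 10, 4, 200)


# ---------------------------------------------------------------------------
# node-based ORA
# ---------------------------------------------------------------------------


def _exact_node_ora_p(network, universe_genes, n_flagged, score_obs):
    """Exhaustive permutation oracle: enumerate all flag placements."""
    members = sorted(network.member_genes)
    more_extreme = 0
    total = 0
    for flagged in itertools.combinations(universe_genes, n_flagged):
        flags = set(flagged)
        score = sum(any(g in flags for g in node.members) for node in network.nodes)
        total += 1
        more_extreme += score >= score_obs
    return more_extreme / total


def test_node_ora_saturated_and_empty_cases():
    net = toy_network([("A", ["a"]), ("B", ["b"])])
    universe = pd.Series(True, index=["a", "b", "c", "d"])
    res = sv.node_ora(net, universe, n_trials=1000, seed=0)
    assert res.score == 2 and res.p == 1.0
    res0 = sv.node_ora(net, universe & False, n_trials=1000, seed=0)
    assert res0.score == 0 and res0.p == 1.0


def test_node_ora_monte_carlo_matches_exhaustive_oracle():
    """10-gene universe, 4 flags: MC p within 3 binomial SE of the exact p."""
    net = toy_network([("A", ["g0", "g1"]), ("B", ["g2"]), ("C", ["g3", "g4", "g5"])])
    genes = [f"g{i}" for i in range(10)]
    indicator = pd.Series([True, False, True, False, True, False, False, True, False, False],
                          index=genes)
    score_obs = sum(
        any(indicator[g] for g in node.members) for node in net.nodes
    )
    exact = _exact_node_ora_p(net, genes, int(indicator.sum()), score_obs)
    n_trials = 200_000
    res = sv.node_ora(net, indicator, n_trials=n_trials, seed=1)
    se = np.sqrt(exact * (1 - exact) / n_trials)
    assert res.score == score_obs
    assert abs(res.p - exact) < 3 * se + 2 / n_trials  # add-one smoothing slack


def test_node_ora_reproducible_given_seed():
    net = toy_network([("A", ["g0", "g1"]), ("B", ["g2"])])
    indicator = pd.Series([True, False, True, False, False], index=[f"g{i}" for i in range(5)])
    p1 = sv.node_ora(net, indicator, n_trials=50_000, seed=7).p
    p2 = sv.node_ora(net, indicator, n_trials=50_000, seed=7).p
    assert p1 == p2


def test_node_ora_missing_members_reported():
    net = toy_network([("A", ["gX"])])
    indicator = pd.Series([True], index=["g0"])
    with pytest.raises(KeyError, match="gX"):
        sv.node_ora(net, indicator, n_trials=10, seed=0)


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


def test_gsea_single_head_gene_hand_formula():
    """Set = first gene of 10: running sum hits 1 at position one, so ES = 1."""
    genes = [f"g{i}" for i in range(10)]
    scores = np.linspace(5, 0.5, 10)
    res = sv.gsea_preranked(genes, scores, {"g0"}, n_permutations=200, seed=0)
    assert res.score == pytest.approx(1.0)


def test_gsea_top_k_set_is_maximal():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(40)]
    scores = np.sort(rng.random(40))[::-1] + 0.1
    top5 = set(genes[:5])
    es_top = sv.gsea_preranked(genes, scores, top5, n_permutations=50, seed=0).score
    for _ in range(30):
        other = set(rng.choice(genes, size=5, replace=False))
        es = sv.gsea_preranked(genes, scores, other, n_permutations=1, seed=0).score
        assert es <= es_top + 1e-12


def test_gsea_null_pvalues_roughly_uniform():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(60)]
    ps = []
    for rep in range(200):
        scores = rng.random(60) + 0.05
        gene_set = set(rng.choice(genes, size=8, replace=False))
        ps.append(sv.gsea_preranked(genes, scores, gene_set, n_permutations=99, seed=rep).p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_gsea_empty_intersection_not_testable():
    res = sv.gsea_preranked(["g0", "g1"], np.array([1.0, 0.5]), {"absent"}, 10, 0)
    assert np.isnan(res.p)


# ---------------------------------------------------------------------------
# Fisher node-based GSA
# ---------------------------------------------------------------------------


def test_fisher_all_ones_stays_one():
    net = toy_network([("A", ["a"]), ("B", ["b"])])
    pvals = pd.Series(1.0, index=["a", "b"])
    assert sv.node_gsa_fisher(net, pvals).p == pytest.approx(1.0)


def test_fisher_single_gene_single_node_is_identity():
    net = toy_network([("A", ["a"])])
    for p in (0.001, 0.2, 0.77):
        # one gene: chi2(2) tail of -2 ln p equals p; applied twice stays p
        assert sv.node_gsa_fisher(net, pd.Series({"a": p})).p == pytest.approx(p, rel=1e-9)


def test_fisher_hand_computation_two_nodes():
    """-2(ln 0.01 + ln 0.04) = 15.648, chi2(4) upper tail = 0.00353."""
    statistic = -2 * (np.log(0.01) + np.log(0.04))
    assert statistic == pytest.approx(15.648092, abs=1e-5)
    assert stats.chi2.sf(statistic, 4) == pytest.approx(0.0035296184, abs=1e-9)
    # the pathway stage combines the two node p-values exactly this way
    net = toy_network([("A", ["a"]), ("B", ["b"])])
    node_a = stats.chi2.sf(-2 * np.log(0.01), 2)  # = 0.01
    node_b = stats.chi2.sf(-2 * np.log(0.04), 2)  # = 0.04
    expected = stats.chi2.sf(-2 * (np.log(node_a) + np.log(node_b)), 4)
    got = sv.node_gsa_fisher(net, pd.Series({"a": 0.01, "b": 0.04}))
    assert got.p == pytest.approx(expected, rel=1e-9)


def test_fisher_zero_pvalue_clamped_with_warning():
    net = toy_network([("A", ["a"])])
    with pytest.warns(UserWarning, match="clamped"):
        res = sv.node_gsa_fisher(net, pd.Series({"a": 0.0}))
    assert 0 < res.p < 1e-100


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------


def test_bh_single_p_unchanged():
    assert sv.bh_fdr([0.3])[0] == pytest.approx(0.3)


def test_bh_hand_stepup():
    adjusted = sv.bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])


def test_bh_monotone_after_sorting():
    rng = np.random.default_rng(3)
    p = rng.random(50)
    adj = sv.bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_bh_null_fdr_control():
    """Global null: fraction of pathways at FDR < 0.01 stays near zero."""
    rng = np.random.default_rng(4)
    hits = 0
    n_rep, n_path = 200, 20
    for _ in range(n_rep):
        adj = sv.bh_fdr(rng.random(n_path))
        hits += (adj < 0.01).sum()
    rate = hits / (n_rep * n_path)
    assert rate <= 0.01 + 3 * np.sqrt(0.01 / (n_rep * n_path))


# ---------------------------------------------------------------------------
# combined table
# ---------------------------------------------------------------------------


def test_enrich_pathways_runs_all_methods_and_adjusts():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(30)]
    net = toy_network([("A", ["g0", "g1"]), ("B", ["g2"])], name="p1")
    indicator = pd.Series(rng.random(30) < 0.3, index=genes)
    pvals = pd.Series(rng.random(30), index=genes)
    table = sv.enrich_pathways([net], indicator, pvals, n_trials=2000, n_permutations=99, seed=0)
    assert set(table["method"]) == {"EASE-ORA", "node-ORA", "GSEA", "node-GSA-Fisher"}
    assert ((table["fdr"] > 0) & (table["fdr"] <= 1)).all()
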