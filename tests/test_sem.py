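"""SEM core: implied covariance, ML discrepancy, fitting, indices, Wald tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import semvar as sv
from semvar.sem import _Layout, _objective_and_grad, _prepare_groups, _start_values

from conftest import chain_config, make_dataset


# ---------------------------------------------------------------------------
# implied covariance
# ---------------------------------------------------------------------------


def test_implied_covariance_independence_case():
    model = sv.SemModel(genes=("a", "b", "c"))
    sigma = sv.implied_covariance(model, paths={}, variances={"a": 1.0, "b": 2.0, "c": 3.0})
    assert np.allclose(sigma.to_numpy(), np.diag([1.0, 2.0, 3.0]))


def test_implied_covariance_hand_algebra():
    """x -> y with path b: Sigma = [[1, b], [b, b^2 + psi]]."""
    model = sv.SemModel(genes=("x", "y"), structural_edges=(("x", "y"),))
    sigma = sv.implied_covariance(model, paths={("x", "y"): 0.8}, variances={"x": 1.0, "y": 0.5})
    assert np.allclose(sigma.to_numpy(), [[1.0, 0.8], [0.8, 0.8**2 + 0.5]])


def test_implied_covariance_matches_simulation_two_parent_node():
    """4-gene network with two upstream paths into one node vs Monte Carlo."""
    from semvar.networks import PathwayNetwork, PathwayNode

    net = PathwayNetwork(
        "diamond",
        [PathwayNode(g, (g,)) for g in ("a", "b", "c", "d")],
        [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")],
    )
    coef = {("a", "b"): 0.8, ("a", "c"): -0.5, ("b", "d"): 0.6, ("c", "d"): 0.4}
    cfg = sv.SimulationConfig(
        network=net,
        coefficients_by_group={"control": coef, "SCZ": coef},
        n_per_group={"SCZ": 3, "control": 200_000},
        seed=11,
    )
    ds, _ = sv.simulate_pathway_expression(cfg)
    model = sv.SemModel(genes=("a", "b", "c", "d"), structural_edges=tuple(coef))
    sigma = sv.implied_covariance(model, paths=coef, variances={g: 1.0 for g in "abcd"})
    emp = np.cov(ds.subset_group("control").expression.loc[["a", "b", "c", "d"]].to_numpy())
    # elementwise MC-SE of covariance entries is about sqrt(2)*var/sqrt(n) < 0.01
    assert np.max(np.abs(sigma.to_numpy() - emp)) < 3 * 0.01


def test_implied_covariance_singular_system_raises():
    model = sv.SemModel(genes=("a", "b"), structural_edges=(("a", "b"), ("b", "a")))
    with pytest.raises(Exception, match="singular"):
        sv.implied_covariance(
            model, paths={("a", "b"): 1.0, ("b", "a"): 1.0}, variances={"a": 1.0, "b": 1.0}
        )


# ---------------------------------------------------------------------------
# ML discrepancy
# ---------------------------------------------------------------------------


def test_ml_discrepancy_perfect_fit_is_zero():
    S = np.array([[2.0, 0.5], [0.5, 1.0]])
    assert sv.ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)


def test_ml_discrepancy_hand_value():
    S = np.array([[2.0, 1.0], [1.0, 2.0]])
    assert sv.ml_discrepancy(S, np.eye(2)) == pytest.approx(2 - np.log(3), abs=1e-12)


def test_ml_discrepancy_nonnegative_on_random_pd_pairs():
    """F_ML is a KL-type divergence: nonnegative for any PD pair."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        p = rng.integers(2, 6)
        a = rng.standard_normal((p, p + 3))
        b = rng.standard_normal((p, p + 3))
        S = a @ a.T / (p + 3)
        Sigma = b @ b.T / (p + 3)
        assert sv.ml_discrepancy(S, Sigma) >= -1e-10


def test_ml_discrepancy_rejects_non_pd():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
    with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
        sv.ml_discrepancy(bad, np.eye(2))


# ---------------------------------------------------------------------------
# analytic gradient
# ---------------------------------------------------------------------------


def test_analytic_gradient_matches_finite_differences(chain_model):
    cfg = chain_config({("x", "y"): 0.8, ("y", "z"): 0.5}, n=200, seed=13)
    ds, _ = sv.simulate_pathway_expression(cfg)
    model = sv.SemModel(
        genes=("x", "y", "z"),
        structural_edges=(("x", "y"), ("y", "z")),
        covariates=("age", "PC1"),
    )
    groups = _prepare_groups(model, ds.by_group())
    layout = _Layout(model, tuple(g.name for g in groups))
    theta = _start_values(layout, groups)
    _, grad = _objective_and_grad(theta, layout, groups, True)
    num = np.zeros_like(theta)
    for i in range(theta.size):
        e = np.zeros_like(theta)
        e[i] = 1e-6
        num[i] = (
            _objective_and_grad(theta + e, layout, groups, True)[0]
            - _objective_and_grad(theta - e, layout, groups, True)[0]
        ) / 2e-6
    assert np.max(np.abs(grad - num) / np.maximum(np.abs(num), 1.0)) < 1e-6


# ---------------------------------------------------------------------------
# single-group fitting
# ---------------------------------------------------------------------------


def test_single_group_parameter_recovery_within_3se(chain_model):
    """Estimates fall within 3 SE of truth for the large majority of replicates."""
    truth = {("x", "y"): 0.8, ("y", "z"): 0.5}
    hits, total = 0, 0
    for rep in range(30):
        cfg = chain_config(truth, n=5000, seed=100 + rep)
        ds, _ = sv.simulate_pathway_expression(cfg)
        fr = sv.fit_single_group(chain_model, ds.subset_group("control"))
        assert fr.converged and fr.identifiable
        for (s, d), v in truth.items():
            est = fr.estimates[f"beta:{s}->{d}@all"]
            se = fr.se[f"beta:{s}->{d}@all"]
            total += 1
            hits += abs(est - v) <= 3 * se
    assert hits / total >= 0.95


def test_saturated_model_reaches_zero_discrepancy():
    rng = np.random.default_rng(5)
    X = rng.multivariate_normal([0, 0, 0], [[2, 1, 0.5], [1, 2, 0.3], [0.5, 0.3, 1]], size=300)
    ds = make_dataset(X.T, ("a", "b", "c"), ["g"] * 300)
    saturated = sv.SemModel(
        genes=("a", "b", "c"), structural_edges=(("a", "b"), ("a", "c"), ("b", "c"))
    )
    fr = sv.fit_single_group(saturated, ds)
    assert abs(fr.f_ml) < 1e-8
    assert fr.df == 0


def test_constant_variable_flagged_unidentifiable():
    rng = np.random.default_rng(6)
    vals = rng.standard_normal((2, 50))
    vals = np.vstack([vals, np.ones(50)])  # constant third gene
    ds = make_dataset(vals, ("a", "b", "c"), ["g"] * 50)
    model = sv.SemModel(genes=("a", "b", "c"), structural_edges=(("a", "b"),))
    fr = sv.fit_single_group(model, ds)
    ok, diags = sv.check_identifiability(fr)
    assert not ok
    assert any("singular" in d for d in diags)


def test_collinear_variables_flagged_unidentifiable():
    rng = np.random.default_rng(7)
    a = rng.standard_normal(80)
    ds = make_dataset(np.vstack([a, 2 * a]), ("a", "b"), ["g"] * 80)
    model = sv.SemModel(genes=("a", "b"), structural_edges=(("a", "b"),))
    fr = sv.fit_single_group(model, ds)
    assert not sv.check_identifiability(fr)[0]


def test_duplicated_free_path_flagged_unidentifiable():
    cfg = chain_config({("x", "y"): 0.8, ("y", "z"): 0.5}, n=300, seed=14)
    ds, _ = sv.simulate_pathway_expression(cfg)
    model = sv.SemModel(
        genes=("x", "y", "z"),
        structural_edges=(("x", "y"), ("x", "y"), ("y", "z")),  # same edge twice
    )
    fr = sv.fit_single_group(model, ds.subset_group("control"))
    assert not sv.check_identifiability(fr)[0]


def test_n_not_larger_than_p_rejected():
    rng = np.random.default_rng(8)
    ds = make_dataset(rng.standard_normal((3, 3)), ("a", "b", "c"), ["g"] * 3)
    model = sv.SemModel(genes=("a", "b", "c"))
    with pytest.raises(ValueError, match="exceed"):
        sv.fit_single_group(model, ds)


def test_estimates_invariant_to_sample_order():
    cfg = chain_config({("x", "y"): 0.8, ("y", "z"): 0.5}, n=300, seed=15)
    ds, _ = sv.simulate_pathway_expression(cfg)
    sub = ds.subset_group("control")
    rng = np.random.default_rng(0)
    perm = rng.permutation(sub.n_samples)
    shuffled = sv.ExpressionDataset(sub.expression.iloc[:, perm], sub.samples.iloc[perm])
    model = sv.SemModel(genes=("x", "y", "z"), structural_edges=(("x", "y"), ("y", "z")))
    f1 = sv.fit_single_group(model, sub)
    f2 = sv.fit_single_group(model, shuffled)
    pd.testing.assert_series_equal(f1.estimates, f2.estimates, atol=1e-6, rtol=0)


# ---------------------------------------------------------------------------
# multigroup fitting
# ---------------------------------------------------------------------------


def test_multigroup_without_constraints_reduces_to_separate_fits(chain_model):
    """With no covariates there are no shared parameters: the joint fit must
    reproduce the two independent single-group solutions."""
    cfg = chain_config(
        {("x", "y"): 0.8, ("y", "z"): 0.5},
        coef_test={("x", "y"): 0.3, ("y", "z"): 0.9},
        n=400,
        seed=16,
    )
    ds, _ = sv.simulate_pathway_expression(cfg)
    mf = sv.fit_multigroup(chain_model, ds.by_group())
    for group, sub in ds.by_group().items():
        single = sv.fit_single_group(chain_model, sub, group=group)
        for name, value in single.estimates.items():
            joint_name = name  # identical naming convention per group
            assert mf.group_fits[group].estimates[joint_name] == pytest.approx(
                value, abs=1e-6
            )


def test_multigroup_shared_slopes_are_exactly_equal():
    cfg = chain_config(
        {("x", "y"): 0.8, ("y", "z"): 0.5},
        n=300,
        seed=17,
        covariate_effects={("x", "age"): 0.02, ("z", "PC1"): 0.4},
    )
    ds, _ = sv.simulate_pathway_expression(cfg)
    model = sv.SemModel(
        genes=("x", "y", "z"),
        structural_edges=(("x", "y"), ("y", "z")),
        covariates=("age", "sex", "batch", "PC1", "PC2"),
    )
    mf = sv.fit_multigroup(model, ds.by_group())
    # the shared slope parameters appear identically in every group's estimates
    for name, value in mf.shared_estimates.items():
        for group in mf.groups:
            assert mf.group_fits[group].estimates[name] == value
    # generating effects are recovered
    assert mf.shared_estimates["slope:x~age"] == pytest.approx(0.02, abs=0.02)
    assert mf.shared_estimates["slope:z~PC1"] == pytest.approx(0.4, abs=0.1)


def test_multigroup_needs_two_groups(chain_model):
    cfg = chain_config({("x", "y"): 0.8, ("y", "z"): 0.5}, n=100, seed=18)
    ds, _ = sv.simulate_pathway_expression(cfg)
    with pytest.raises(ValueError, match="two groups"):
        sv.fit_multigroup(chain_model, {"only": ds.subset_group("control")})


def test_planted_difference_detected_null_paths_calibrated(chain_model):
    """One path differing by 0.7 at n=500/group is flagged; the null path is not."""
    flagged, null_flagged = 0, 0
    reps = 40
    for rep in range(reps):
        cfg = chain_config(
            {("x", "y"): 0.8, ("y", "z"): 0.5},
            coef_test={("x", "y"): 0.8, ("y", "z"): 1.2},
            n=500,
            seed=300 + rep,
        )
        ds, _ = sv.simulate_pathway_expression(cfg)
        mf = sv.fit_multigroup(chain_model, ds.by_group())
        flagged += sv.wald_difference_test(mf, ("y", "z"))["p"] < 0.05
        null_flagged += sv.wald_difference_test(mf, ("x", "y"))["p"] < 0.05
    assert flagged / reps >= 0.9
    assert null_flagged / reps <= 0.2


def test_wald_difference_hand_computation():
    """z = (0.5 - 0.1)/sqrt(0.1^2 + 0.1^2) = 2.828, p = 0.0047."""
    z = (0.5 - 0.1) / np.sqrt(0.1**2 + 0.1**2)
    assert z == pytest.approx(2.8284271, abs=1e-6)
    assert 2 * stats.norm.sf(z) == pytest.approx(0.0046777, abs=1e-6)


def test_wald_antisymmetry_under_group_relabeling(chain_model):
    cfg = chain_config(
        {("x", "y"): 0.8, ("y", "z"): 0.5},
        coef_test={("x", "y"): 0.8, ("y", "z"): 1.0},
        n=300,
        seed=19,
    )
    ds, _ = sv.simulate_pathway_expression(cfg)
    groups = ds.by_group()
    mf_ab = sv.fit_multigroup(chain_model, dict(sorted(groups.items())))
    mf_ba = sv.fit_multigroup(chain_model, dict(sorted(groups.items(), reverse=True)))
    t_ab = sv.wald_difference_test(mf_ab, ("y", "z"))
    t_ba = sv.wald_difference_test(mf_ba, ("y", "z"))
    assert t_ab["z"] == pytest.approx(-t_ba["z"], abs=1e-4)
    assert t_ab["p"] == pytest.approx(t_ba["p"], abs=1e-6)


def test_identical_group_data_gives_z_zero_p_one(chain_model):
    """Fitting the same sample as both groups forces equal estimates: z=0, p=1."""
    cfg = chain_config({("x", "y"): 0.8, ("y", "z"): 0.5}, n=300, seed=20)
    ds, _ = sv.simulate_pathway_expression(cfg)
    sub = ds.subset_group("control")
    twin = sv.ExpressionDataset(sub.expression.copy(), sub.samples.copy())
    mf = sv.fit_multigroup(chain_model, {"g1": sub, "g2": twin})
    res = sv.wald_difference_test(mf, ("x", "y"))
    assert res["z"] == pytest.approx(0.0, abs=1e-4)
    assert res["p"] == pytest.approx(1.0, abs=1e-3)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


def test_saturated_model_has_cfi_one_rmsea_zero():
    rng = np.random.default_rng(9)
    X = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=300)
    ds = make_dataset(X.T, ("a", "b"), ["g"] * 300)
    saturated = sv.SemModel(genes=("a", "b"), structural_edges=(("a", "b"),))
    fr = sv.fit_single_group(saturated, ds)
    with pytest.warns(UserWarning, match="df = 0"):
        idx = sv.fit_indices(fr)
    assert idx["RMSEA"] == 0.0
    assert idx["CFI"] == 1.0


def test_baseline_model_scores_cfi_zero():
    """Evaluating the independence baseline as the fitted model gives CFI 0."""
    rng = np.random.default_rng(10)
    X = rng.multivariate_normal([0, 0, 0], [[1, 0.7, 0.5], [0.7, 1, 0.6], [0.5, 0.6, 1]], size=500)
    ds = make_dataset(X.T, ("a", "b", "c"), ["g"] * 500)
    independence = sv.SemModel(genes=("a", "b", "c"))
    fr = sv.fit_single_group(independence, ds)
    idx = sv.fit_indices(fr)
    assert idx["CFI"] == pytest.approx(0.0, abs=1e-9)
    assert idx["chi2"] == pytest.approx(fr.baseline_chi2, rel=1e-6)


def test_misspecified_model_shows_large_rmsea():
    """Fitting independence to strongly chained data yields RMSEA > 0.2."""
    hits = 0
    reps = 20
    independence = sv.SemModel(genes=("x", "y", "z"))
    for rep in range(reps):
        cfg = chain_config({("x", "y"): 0.9, ("y", "z"): 0.9}, n=1000, seed=400 + rep)
        ds, _ = sv.simulate_pathway_expression(cfg)
        fr = sv.fit_single_group(independence, ds.subset_group("control"))
        hits += sv.fit_indices(fr)["RMSEA"] > 0.2
    assert hits / reps >= 0.95


def test_latent_variable_model_fits():
    """A latent node with three indicators: loadings recovered, fit converges."""
    from semvar.networks import PathwayNetwork, PathwayNode

    net = PathwayNetwork(
        "lat",
        [
            PathwayNode("F", ("i1", "i2", "i3"), latent=True),
            PathwayNode("G", ("g",)),
        ],
        [("G", "F")],
    )
    cfg = sv.SimulationConfig(
        network=net,
        coefficients_by_group={"control": {("G", "F"): 0.6}, "SCZ": {("G", "F"): 0.6}},
        latent_loadings={("F", "i1"): 1.0, ("F", "i2"): 0.8, ("F", "i3"): 0.6},
        n_per_group={"SCZ": 1500, "control": 1500},
        seed=21,
    )
    ds, _ = sv.simulate_pathway_expression(cfg)
    resolved = next(
        iter(
            sv.enumerate_alternatives(net)
        )
    )
    model = sv.SemModel.from_resolved(resolved)
    fr = sv.fit_single_group(model, ds.subset_group("control"))
    assert fr.converged and fr.identifiable
    assert fr.estimates["beta:F->i2@all"] == pytest.approx(0.8, abs=0.1)
    assert fr.estimates["beta:g->F@all"] == pytest.approx(0.6, abs=0.1)
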