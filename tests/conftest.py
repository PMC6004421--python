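"""Shared builders for small synthetic networks and datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from semvar import ExpressionDataset, SemModel, SimulationConfig
from semvar.networks import PathwayNetwork, PathwayNode


def make_chain_network(genes=("x", "y", "z"), name="chain") -> PathwayNetwork:
    nodes = [PathwayNode(g, (g,)) for g in genes]
    edges = [(genes[i], genes[i + 1]) for i in range(len(genes) - 1)]
    return PathwayNetwork(name, nodes, edges)


def make_dataset(values: np.ndarray, genes, groups, covariates=None) -> ExpressionDataset:
    """values: genes x samples array; groups: per-sample labels."""
    cols = [f"s{i}" for i in range(values.shape[1])]
    expr = pd.DataFrame(values, index=list(genes), columns=cols)
    meta = pd.DataFrame({"group": list(groups)}, index=cols)
    if covariates is not None:
        for name, vals in covariates.items():
            meta[name] = vals
    return ExpressionDataset(expr, meta)


@pytest.fixture
def chain_network():
    return make_chain_network()


@pytest.fixture
def chain_model():
    return SemModel(genes=("x", "y", "z"), structural_edges=(("x", "y"), ("y", "z")))


def chain_config(coef_control, coef_test=None, n=500, seed=0, **kwargs) -> SimulationConfig:
    net = make_chain_network()
    coef_test = coef_test or dict(coef_control)
    return SimulationConfig(
        network=net,
        coefficients_by_group={"control": dict(coef_control), "SCZ": dict(coef_test)},
        n_per_group={"SCZ": n, "control": n},
        seed=seed,
        **kwargs,
    )
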