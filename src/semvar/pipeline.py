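"""End-to-end orchestration: variance -> enrichment -> classifier -> model search.

The pipeline consumes an expression TSV (genes x samples), a sample metadata
TSV (group label + covariates) and a set of pathway network JSON files, and
writes per-stage tables plus a machine-readable run summary.  Pathways
significantly enriched for increased-variance genes by either node-based
method (FDR below the configured threshold) are merged into one selected
set; their member genes feed the PCA-logistic disease-status model, and each
selected pathway is then searched for its best alternative structural model.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import PCLogistic
from .datasets import ExpressionDataset
from .networks import PathwayNetwork, load_network, unique_genes
from .enrichment import enrich_pathways
from .search import BestModelReport, SearchCriteria, search_best_model
from .variance import residualize, sign_test, variance_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "export_path_diagram", "demo_inputs"]

#: Node-based enrichment methods whose significant pathways are merged.
_SELECTION_METHODS = ("node-ORA", "node-GSA-Fisher")


class PipelineError(RuntimeError):
    """Stage failure; carries the failing stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    expression_tsv: str
    metadata_tsv: str
    network_jsons: list[str]
    out_dir: str
    seed: int = 0
    test_group: str = "SCZ"
    control_group: str = "control"
    covariates: list[str] | None = None  # None -> all metadata columns except group
    enrichment_fdr: float = 0.01
    pc_threshold: float = 0.01
    n_trials: int = 1_000_000
    n_permutations: int = 1000
    criteria: SearchCriteria = field(default_factory=SearchCriteria)

    def validate(self) -> None:
        for path in [self.expression_tsv, self.metadata_tsv, *self.network_jsons]:
            if not Path(path).exists():
                raise FileNotFoundError(path)
        if not 0 < self.enrichment_fdr < 1:
            raise ValueError("enrichment_fdr must lie in (0, 1)")
        if not 0 <= self.pc_threshold < 1:
            raise ValueError("pc_threshold must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        crit = raw.pop("criteria", None)
        cfg = cls(**raw)
        if crit:
            cfg.criteria = SearchCriteria(**crit)
        return cfg

    def content_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def export_path_diagram(report: BestModelReport, path: str | Path) -> None:
    """Write the selected model as a DOT digraph.

    Each edge label carries three lines: control estimate (SE), test-group
    estimate, and the significance stars for the between-group difference.
    """
    if not report.has_selection:
        raise ValueError("no admissible model was selected")
    table = report.starred_wald_table()
    fit = report.selected_fit
    groups = list(fit.groups)
    control = report.control_group if report.control_group in groups else groups[-1]
    test = next(g for g in groups if g != control)
    lines = [f'digraph "{report.pathway}" {{', "  rankdir=LR;"]
    for node in dict.fromkeys(
        [v for pair in zip(table["src"], table["dst"]) for v in pair]
        + list(fit.model.genes)
    ):
        lines.append(f'  "{node}";')
    for _, row in table.iterrows():
        est_c, se_c = row.get(f"est_{control}", np.nan), row.get(f"se_{control}", np.nan)
        est_t = row.get(f"est_{test}", np.nan)
        label = f"{est_c:.2f} ({se_c:.2f})\\n{est_t:.2f}\\n{row['stars']}"
        lines.append(f'  "{row["src"]}" -> "{row["dst"]}" [label="{label}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Partial outputs are preserved on failure; a :class:`PipelineError`
    naming the failing stage is raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {"semvar": __version__, "python": platform.python_version()},
        "stages": {},
    }

    # -- load ------------------------------------------------------------
    stage = "load"
    try:
        data = ExpressionDataset.from_tsv(config.expression_tsv, config.metadata_tsv)
        covariates = (
            config.covariates if config.covariates is not None else data.covariate_names
        )
        missing = [c for c in covariates if c not in data.samples.columns]
        if missing:
            raise ValueError(f"metadata lacks covariate column(s): {missing}")
        for g in (config.test_group, config.control_group):
            if g not in data.groups:
                raise ValueError(f"group {g!r} absent from metadata")
        networks = [load_network(p) for p in config.network_jsons]
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- variance --------------------------------------------------------
    stage = "variance"
    try:
        vtable = variance_table(data, config.test_group, config.control_group, covariates)
        vtable.to_csv(out / "variance_table.tsv", sep="\t", index_label="gene")
        informative = vtable["indicator"].dropna()
        k = int(informative.sum())
        n_inf = int(informative.size)
        p_sign = sign_test(k, n_inf) if n_inf else np.nan
        summary["stages"]["variance"] = {
            "n_genes": int(vtable.shape[0]),
            "n_informative": n_inf,
            "n_test_greater": k,
            "sign_test_p": p_sign,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- enrichment ------------------------------------------------------
    stage = "enrichment"
    try:
        indicator = vtable["indicator"].fillna(False).astype(bool)
        gene_p = vtable["levene_p"] if "levene_p" in vtable else pd.Series(
            1.0, index=vtable.index
        )
        etable = enrich_pathways(
            networks,
            indicator,
            gene_p,
            n_trials=config.n_trials,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        etable.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        selected = sorted(
            set(
                etable.loc[
                    etable["method"].isin(_SELECTION_METHODS)
                    & (etable["fdr"] < config.enrichment_fdr),
                    "pathway",
                ]
            )
        )
        summary["stages"]["enrichment"] = {
            "selected_pathways": selected,
            "fdr_threshold": config.enrichment_fdr,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    selected_networks = [n for n in networks if n.name in selected]

    # -- classifier ------------------------------------------------------
    stage = "classifier"
    try:
        if selected_networks:
            genes = sorted(unique_genes(selected_networks))
            resid = residualize(data, covariates).loc[genes]
            clf = PCLogistic(threshold=config.pc_threshold)
            clf.fit(resid.to_numpy().T, (data.samples["group"] == config.test_group).to_numpy())
            rep = clf.report_
            summary["stages"]["classifier"] = {
                "n_pathway_genes": len(genes),
                "n_components": rep.n_components,
                "explained_variance_ratio": rep.explained_variance_ratio.tolist(),
                "c_index": rep.c_index,
                "pseudo_r2_nagelkerke": rep.pseudo_r2,
                "pseudo_r2_mcfadden": rep.mcfadden_r2,
                "coefficient_pvalues": rep.coefficient_pvalues.tolist(),
            }
        else:
            summary["stages"]["classifier"] = {"skipped": "no pathway selected"}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- model search ----------------------------------------------------
    stage = "model_search"
    try:
        data_by_group = {
            config.control_group: data.subset_group(config.control_group),
            config.test_group: data.subset_group(config.test_group),
        }
        search_summaries = {}
        for net in selected_networks:
            report = search_best_model(
                net,
                data_by_group,
                covariates=covariates,
                criteria=config.criteria,
                control_group=config.control_group,
            )
            entry = {
                "generated": report.n_generated,
                "identifiable": report.n_identifiable,
                "surviving": report.n_surviving,
            }
            if report.has_selection:
                entry["selected_assignment"] = dict(report.selected.assignment)
                entry["indices"] = report.indices
                entry["group_aic"] = report.group_aic
                entry["group_bic"] = report.group_bic
                table = report.starred_wald_table()
                table.to_csv(out / f"search_{net.name}_wald.tsv", sep="\t", index=False)
                export_path_diagram(report, out / f"search_{net.name}.dot")
                entry["significant_differences"] = [
                    {"edge": row["edge"], "p": row["p_diff"], "stars": row["stars"]}
                    for _, row in table.iterrows()
                    if np.isfinite(row["p_diff"]) and row["p_diff"] < 0.05
                ]
            else:
                entry["failure_log"] = report.failure_log
            search_summaries[net.name] = entry
        summary["stages"]["model_search"] = search_summaries
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=_json_default) + "\n"
    )
    return out


# ---------------------------------------------------------------------------
# bundled synthetic demo
# ---------------------------------------------------------------------------


def demo_inputs(directory: str | Path, seed: int = 0) -> RunConfig:
    """Generate the bundled synthetic demo inputs and return a ready RunConfig.

    The demo simulates a five-gene chain pathway whose downstream edge is
    stronger in the test group (inflating downstream variance), a modest
    independent background with partial variance inflation, and two decoy
    pathways drawn from background genes.
    """
    from .fixtures import serine_biosynthesis
    from .networks import PathwayNode
    from .simulate import BackgroundConfig, SimulationConfig, simulate_study

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    net = serine_biosynthesis()
    coef_control = {
        ("PHGDH", "PSAT1"): 0.7,
        ("PSAT1", "PSPH"): 0.7,
        ("PSPH", "SHMT1"): 0.5,
        ("PSPH", "SHMT2"): 0.3,
    }
    coef_test = dict(coef_control)
    coef_test[("PSPH", "SHMT2")] = 1.4  # group-different edge, inflates SHMT2 variance
    coef_test[("PHGDH", "PSAT1")] = 1.3
    config = SimulationConfig(
        network=net,
        coefficients_by_group={"control": coef_control, "SCZ": coef_test},
        covariate_effects={("PHGDH", "age"): 0.01, ("PSPH", "PC1"): 0.2},
        n_per_group={"SCZ": 144, "control": 111},
        background=BackgroundConfig(
            n_genes=400, fraction_inflated=0.2, inflation_factor=2.5, target_group="SCZ"
        ),
        seed=seed,
    )
    data, truth = simulate_study(config)
    data.to_tsv(directory / "expression.tsv", directory / "metadata.tsv")

    network_paths = []
    net_path = directory / "serine_biosynthesis.json"
    net.save(net_path)
    network_paths.append(str(net_path))
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    bg_genes = [g for g in data.genes if g.startswith("BG")]
    for d in range(2):
        picks = rng.choice(len(bg_genes), size=8, replace=False)
        genes = [bg_genes[i] for i in sorted(picks)]
        nodes = [PathwayNode(g, (g,)) for g in genes]
        edges = [(genes[i], genes[i + 1]) for i in range(len(genes) - 1)]
        decoy = PathwayNetwork(f"decoy_{d}", nodes, edges)
        p = directory / f"decoy_{d}.json"
        decoy.save(p)
        network_paths.append(str(p))

    cfg = RunConfig(
        expression_tsv=str(directory / "expression.tsv"),
        metadata_tsv=str(directory / "metadata.tsv"),
        network_jsons=network_paths,
        out_dir=str(directory / "results"),
        seed=seed,
        n_trials=20_000,
        n_permutations=200,
    )
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return cfg
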