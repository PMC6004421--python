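"""Pathway network representation and alternative-model enumeration.

A pathway network is a small directed graph whose nodes each carry one or
more member genes.  Nodes with two or more members ("complex nodes": protein
complexes or paralog families) are ambiguous — the data-level model requires
exactly one gene per node, so every assignment of one member gene to each
node yields one *alternative* resolved network.  Enumeration of these
alternatives is the combinatorial core of the model-search stage.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import networkx as nx

#: Networks larger than this are not identifiable in practice for the SEM stage.
MAX_SEM_NODES = 14

#: Default ceiling on the number of alternatives materialised by enumeration.
DEFAULT_ALTERNATIVE_CAP = 10_000


class NetworkSchemaError(ValueError):
    """Raised when a network file or structure violates the schema."""


@dataclass(frozen=True)
class PathwayNode:
    id: str
    members: tuple[str, ...]
    latent: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise NetworkSchemaError(f"node {self.id!r} has an empty member list")

    @property
    def is_complex(self) -> bool:
        return len(self.members) >= 2


@dataclass
class PathwayNetwork:
    """Directed pathway graph with gene-annotated nodes."""

    name: str
    nodes: list[PathwayNode]
    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise NetworkSchemaError(f"duplicate node id {i!r} in network {self.name!r}")
            seen.add(i)
        self.edges = [tuple(e) for e in self.edges]
        for src, dst in self.edges:
            for endpoint in (src, dst):
                if endpoint not in seen:
                    raise NetworkSchemaError(
                        f"edge ({src!r} -> {dst!r}) references undeclared node {endpoint!r}"
                    )

    # -- accessors -------------------------------------------------------
    def node(self, node_id: str) -> PathwayNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    @property
    def complex_nodes(self) -> list[PathwayNode]:
        return [n for n in self.nodes if n.is_complex]

    @property
    def member_genes(self) -> set[str]:
        return {g for n in self.nodes for g in n.members}

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g

    def validate_for_sem(self) -> None:
        if len(self.nodes) > MAX_SEM_NODES:
            raise ValueError(
                f"network {self.name!r} has {len(self.nodes)} nodes; SEM fitting is "
                f"limited to {MAX_SEM_NODES} nodes"
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nodes": [
                {"id": n.id, "members": list(n.members), "latent": n.latent} for n in self.nodes
            ],
            "edges": [list(e) for e in self.edges],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


@dataclass(frozen=True)
class ResolvedNetwork:
    """A single-gene-per-node substitution of a :class:`PathwayNetwork`."""

    parent: str
    assignment: tuple[tuple[str, str], ...]  # (node id, chosen variable), in node order
    edges: tuple[tuple[str, str], ...]  # variable-level directed edges
    latent_nodes: tuple[str, ...] = ()  # node ids flagged latent (variable == node id)
    latent_indicators: tuple[tuple[str, tuple[str, ...]], ...] = ()  # (latent id, indicator genes)

    @property
    def gene_of(self) -> dict[str, str]:
        return dict(self.assignment)

    @property
    def genes(self) -> list[str]:
        """Observed structural genes, in node order (latent labels excluded)."""
        latent = set(self.latent_nodes)
        return [g for node, g in self.assignment if node not in latent]


def load_network(path: str | Path) -> PathwayNetwork:
    """Read and validate a network JSON file.

    Schema: ``{"name", "nodes": [{"id", "members": [...], "latent": false}],
    "edges": [["src", "dst"], ...]}``.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise NetworkSchemaError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("name", "nodes", "edges"):
        if key not in raw:
            raise NetworkSchemaError(f"{path}: missing top-level key {key!r}")
    nodes = []
    for entry in raw["nodes"]:
        if "id" not in entry or "members" not in entry:
            raise NetworkSchemaError(f"{path}: node entry {entry!r} lacks id/members")
        nodes.append(
            PathwayNode(entry["id"], tuple(entry["members"]), bool(entry.get("latent", False)))
        )
    return PathwayNetwork(raw["name"], nodes, [tuple(e) for e in raw["edges"]])


def count_alternatives(network: PathwayNetwork) -> int:
    """Number of single-gene substitution models: product of node member counts.

    Latent nodes are not substituted — their members act as simultaneous
    indicators of the latent variable — so they contribute a factor of one.
    """
    count = 1
    for n in network.nodes:
        if not n.latent:
            count *= len(n.members)
    return count


def enumerate_alternatives(
    network: PathwayNetwork, cap: int = DEFAULT_ALTERNATIVE_CAP
) -> Iterator[ResolvedNetwork]:
    """Lazily yield every resolved network.

    Order is deterministic: the Cartesian product over nodes in declaration
    order, each node's members in declared order (last node varies fastest).
    """
    total = count_alternatives(network)
    if total > cap:
        raise ValueError(
            f"network {network.name!r} has {total} alternatives, exceeding the cap of "
            f"{cap}; pass a larger `cap` to override"
        )
    latent_ids = tuple(n.id for n in network.nodes if n.latent)
    # Latent nodes keep their id as the variable label; their members are
    # measurement indicators, not substitution candidates.
    member_lists = [(n.id,) if n.latent else n.members for n in network.nodes]
    ids = network.node_ids
    indicators = tuple((n.id, n.members) for n in network.nodes if n.latent)
    for combo in itertools.product(*member_lists):
        gene_of = dict(zip(ids, combo))
        edges = tuple((gene_of[s], gene_of[d]) for s, d in network.edges)
        yield ResolvedNetwork(
            network.name, tuple(zip(ids, combo)), edges, latent_ids, indicators
        )


def unique_genes(networks: list[PathwayNetwork]) -> set[str]:
    """Union of member gene symbols over a collection of networks."""
    if not networks:
        raise ValueError("need at least one network")
    out: set[str] = set()
    for net in networks:
        out |= net.member_genes
    return out


# -- gene sets (GMT) -----------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: tab-separated name, description, genes..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise NetworkSchemaError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [f"{name}\t{name}\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")
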