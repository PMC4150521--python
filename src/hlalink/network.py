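"""Seed-expanded protein-interaction subnetworks and intermediate-node scoring.

The background is an undirected simple graph of experimentally reported
protein-protein interactions, each edge annotated with the literature
references supporting it.  Hub references (those supporting many edges,
typically high-throughput screens) can be filtered out.  Starting from a
seed protein set, the subnetwork keeps seed-seed edges plus every
non-seed node adjacent to at least two distinct seeds (a path of length
two between seeds) with its seed-incident edges only.  Each such
intermediate node is scored with a binomial-proportions z comparing its
seed-link fraction k/n against the global ratio p0 = subnetwork links /
background links; large z means the node links to seeds far more often
than a random edge endpoint would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import sqrt
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundNetwork",
    "Subnetwork",
    "IntermediateScore",
    "load_background",
    "filter_by_reference",
    "expand_subnetwork",
    "intermediate_z",
    "score_intermediates",
    "write_sif",
    "write_scores",
]


@dataclass
class BackgroundNetwork:
    """Undirected simple graph with per-edge reference-id sets."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def total_links(self) -> int:
        return self.graph.number_of_edges()

    def references(self, a: str, b: str) -> frozenset[str]:
        return self.graph.edges[a, b]["references"]

    def degree(self, node: str) -> int:
        return self.graph.degree[node]


@dataclass(frozen=True)
class Subnetwork:
    seeds: frozenset[str]
    intermediates: frozenset[str]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.seeds & self.intermediates:
            raise ValueError("a node cannot be both seed and intermediate")

    @property
    def total_links(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class IntermediateScore:
    node_id: str
    n_links: int
    k_seed_links: int
    z: float
    significant: bool


def _add_edge(g: nx.Graph, a: str, b: str, refs: Iterable[str]) -> None:
    refs = frozenset(refs)
    if g.has_edge(a, b):
        g.edges[a, b]["references"] = g.edges[a, b]["references"] | refs
    else:
        g.add_edge(a, b, references=refs)


def load_background(source: str | Path | Iterable[str], fmt: str = "tsv") -> BackgroundNetwork:
    """Load an edge list into a background network.

    ``fmt='tsv'``: lines "node_a<TAB>node_b[<TAB>ref1,ref2,...]" (any
    whitespace accepted as separator; the reference column is optional).
    ``fmt='sif'``: "node_a interaction node_b" with the middle token
    ignored.  Duplicate edges are merged with unioned references;
    self-loops are dropped with a warning.  '#' lines are comments.
    """
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {fmt!r}")
    if isinstance(source, (str, Path)):
        with Path(source).open() as fh:
            return load_background(list(fh), fmt=fmt)
    g: nx.Graph = nx.Graph()
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if fmt == "sif":
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: SIF line needs 'node interaction node', got {line!r}")
            a, _, b = parts
            refs: frozenset[str] = frozenset()
        else:
            if len(parts) not in (2, 3):
                raise ValueError(f"line {lineno}: expected 'node_a node_b [refs]', got {line!r}")
            a, b = parts[0], parts[1]
            refs = frozenset(r for r in parts[2].split(",") if r) if len(parts) == 3 else frozenset()
        if a == b:
            logger.warning("line %d: dropping self-loop on %r", lineno, a)
            g.add_node(a)
            continue
        _add_edge(g, a, b, refs)
    return BackgroundNetwork(graph=g)


def filter_by_reference(
    net: BackgroundNetwork,
    max_links_per_reference: int = 4,
    min_references: int = 0,
) -> BackgroundNetwork:
    """Drop edges supported only by hub-like references.

    A reference is hub-like when it supports more than
    ``max_links_per_reference`` edges of the input network.  An edge is
    kept iff it has at least one non-hub reference (edges without any
    reference annotation are kept: nothing implicates them) and carries
    at least ``min_references`` references.
    """
    if max_links_per_reference < 1:
        raise ValueError("max_links_per_reference must be >= 1")
    if min_references < 0:
        raise ValueError("min_references must be >= 0")
    support: dict[str, int] = {}
    for _, _, refs in net.graph.edges(data="references"):
        for r in refs:
            support[r] = support.get(r, 0) + 1
    hubs = {r for r, n in support.items() if n > max_links_per_reference}
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for a, b, refs in net.graph.edges(data="references"):
        if len(refs) < min_references:
            continue
        if refs and not (refs - hubs):
            continue
        g.add_edge(a, b, references=refs)
    return BackgroundNetwork(graph=g)


def expand_subnetwork(net: BackgroundNetwork, seeds: Iterable[str], max_path_length: int = 2) -> Subnetwork:
    """Expand a seed set to its length-2 subnetwork.

    Keeps seed-seed edges and every non-seed node adjacent to >= 2
    distinct seeds together with its seed-incident edges only, so the
    subnetwork's link total is the number of seed-seed edges plus the
    sum of per-intermediate seed links.
    """
    if max_path_length != 2:
        raise ValueError("only a maximum path length of 2 is supported")
    seeds = set(seeds)
    present = seeds & net.nodes
    if len(present) < 2:
        missing = sorted(seeds - net.nodes)
        raise ValueError(
            f"need >= 2 seeds in the network, found {len(present)}; missing seeds: {missing}"
        )
    edges: list[tuple[str, str]] = []
    for a, b in net.graph.edges():
        if a in present and b in present:
            edges.append(tuple(sorted((a, b))))
    intermediates = set()
    for node in net.nodes - seeds:
        seed_neighbors = sorted(n for n in net.graph.neighbors(node) if n in present)
        if len(seed_neighbors) >= 2:
            intermediates.add(node)
            edges.extend(tuple(sorted((node, s))) for s in seed_neighbors)
    return Subnetwork(
        seeds=frozenset(present),
        intermediates=frozenset(intermediates),
        edges=tuple(sorted(edges)),
    )


def intermediate_z(n_links: int, k_seed_links: int, sub_links: int, bg_links: int) -> float:
    """Binomial-proportions z: (k/n - p0) / sqrt(p0 (1-p0) / n), p0 = sub/bg."""
    if n_links < 1:
        raise ValueError("n_links must be >= 1")
    if not 0 <= k_seed_links <= n_links:
        raise ValueError("k_seed_links must satisfy 0 <= k <= n_links")
    if bg_links < 1 or not 1 <= sub_links <= bg_links:
        raise ValueError("need 1 <= sub_links <= bg_links")
    p0 = sub_links / bg_links
    if p0 >= 1:
        raise ValueError("sub_links must be smaller than bg_links for a finite z")
    return (k_seed_links / n_links - p0) / sqrt(p0 * (1 - p0) / n_links)


def score_intermediates(
    net: BackgroundNetwork,
    sub: Subnetwork,
    z_cutoff: float = 2.5,
) -> list[IntermediateScore]:
    """Score every intermediate of ``sub`` against the background ``net``.

    n is the node's background degree, k its number of seed links; the
    one-sided significance flag is z >= z_cutoff.  Output sorted by
    decreasing z, ties broken by node id.
    """
    scores = []
    for node in sub.intermediates:
        n = net.degree(node)
        k = sum(1 for nb in net.graph.neighbors(node) if nb in sub.seeds)
        z = intermediate_z(n, k, sub.total_links, net.total_links)
        scores.append(IntermediateScore(node_id=node, n_links=n, k_seed_links=k, z=z, significant=z >= z_cutoff))
    scores.sort(key=lambda s: (-s.z, s.node_id))
    return scores


def write_sif(sub: Subnetwork, path: str | Path, interaction: str = "pp") -> None:
    """Export subnetwork edges as SIF for graph viewers."""
    with Path(path).open("w") as fh:
        for a, b in sub.edges:
            fh.write(f"{a}\t{interaction}\t{b}\n")


def write_scores(scores: Sequence[IntermediateScore], path: str | Path, sub_links: int, bg_links: int) -> None:
    with Path(path).open("w") as fh:
        fh.write("node\tlinks\tlinks_in_background\tlinks_to_seed\tlinks_in_subnetwork\tz\tsignificant\n")
        for s in scores:
            fh.write(
                f"{s.node_id}\t{s.n_links}\t{bg_links}\t{s.k_seed_links}\t{sub_links}"
                f"\t{s.z:.6g}\t{int(s.significant)}\n"
            )
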