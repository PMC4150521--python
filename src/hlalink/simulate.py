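"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Three generators: case-control 2x2 study tables with a common (or
normally dispersed) true log odds ratio; document-concept co-occurrence
corpora with optionally planted gene/query co-mentions; and Erdos-Renyi
interaction backgrounds with planted connector nodes wired to a seed
set.  All generators are deterministic for a fixed seed and emit files
the corresponding readers parse unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .meta import StudyRecord, write_study_table
from .network import BackgroundNetwork
from .profiles import Corpus, write_corpus

__all__ = [
    "StudySimSpec",
    "CorpusSimSpec",
    "NetworkSimSpec",
    "gen_studies",
    "gen_corpus",
    "gen_network",
    "rewire_background",
    "write_network",
    "QUERY_A",
    "QUERY_B",
]

QUERY_A = "QUERY_A"
QUERY_B = "QUERY_B"

#: Case/control totals of the 19 studies in the carriage meta-analysis,
#: in publication order (also shipped as the table1_studies.tsv fixture).
TABLE1_CASES = (34, 32, 18, 14, 38, 44, 52, 124, 122, 36, 54, 95, 479, 178, 55, 451, 460, 160, 173)
TABLE1_CONTROLS = (239, 35, 342, 64, 301, 100, 305, 458, 66, 25, 263, 45, 233, 161, 73, 477, 266, 167, 258)


@dataclass(frozen=True)
class StudySimSpec:
    """Study-table generator settings.

    Defaults emulate the meta-analysis study base: 19 studies at the
    published case/control totals, a 40% carrier frequency in controls
    (typical of HLA-A2 in European-ancestry populations), a mild true
    odds ratio of 1.1 and no between-study dispersion.
    """

    n_studies: int = 19
    cases_sizes: Sequence[int] = TABLE1_CASES
    controls_sizes: Sequence[int] = TABLE1_CONTROLS
    control_carrier_freq: float = 0.4
    true_or: float = 1.1
    between_study_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cases_sizes) != self.n_studies or len(self.controls_sizes) != self.n_studies:
            raise ValueError("cases_sizes and controls_sizes must have length n_studies")
        if any(n <= 0 for n in self.cases_sizes) or any(n <= 0 for n in self.controls_sizes):
            raise ValueError("sample sizes must be positive")
        if not 0 < self.control_carrier_freq < 1:
            raise ValueError("control_carrier_freq must be in (0,1)")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if self.between_study_sd < 0:
            raise ValueError("between_study_sd must be >= 0")


@dataclass(frozen=True)
class CorpusSimSpec:
    """Corpus generator settings.

    Two query concepts plus ``n_genes`` gene concepts occur independently
    per document with probability ``baseline_occurrence``; each planted
    gene's occurrence is redrawn with probability ``planted_cooccurrence``
    in documents where a query concept occurs, so setting the planted
    rate to the baseline plants no signal at all.
    """

    n_docs: int = 300
    n_genes: int = 30
    baseline_occurrence: float = 0.15
    planted_genes: frozenset[str] = frozenset()
    planted_cooccurrence: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.baseline_occurrence, self.planted_cooccurrence):
            if not 0 < p < 1:
                raise ValueError("probabilities must be in (0,1)")
        genes = set(self.gene_ids())
        if not set(self.planted_genes) <= genes:
            raise ValueError("planted_genes must be a subset of the gene identifiers")

    def gene_ids(self) -> list[str]:
        return [f"G{i:03d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class NetworkSimSpec:
    """Background-network generator settings: an Erdos-Renyi graph with
    designated seed nodes and planted connectors wired to several seeds."""

    n_nodes: int = 500
    mean_degree: float = 4.0
    n_seeds: int = 10
    n_planted_connectors: int = 3
    connector_seed_links: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < self.n_seeds + self.n_planted_connectors:
            raise ValueError("n_nodes too small for the requested seeds and connectors")
        if self.connector_seed_links < 2:
            raise ValueError("connector_seed_links must be >= 2")
        if self.connector_seed_links > self.n_seeds:
            raise ValueError("connector_seed_links cannot exceed n_seeds")
        if self.mean_degree <= 0:
            raise ValueError("mean_degree must be positive")


def gen_studies(spec: StudySimSpec) -> list[StudyRecord]:
    """Simulate per-study 2x2 carriage tables.

    Per study, a true log OR is drawn from Normal(ln(true_or),
    between_study_sd^2); control carriers are Binomial(n_controls, p_c)
    and case carriers Binomial(n_cases, p_case) with the case carrier
    probability obtained from p_c and the study OR by the odds
    transform p_case = OR*odds_c / (1 + OR*odds_c).
    """
    rng = np.random.default_rng(spec.seed)
    odds_c = spec.control_carrier_freq / (1 - spec.control_carrier_freq)
    studies = []
    for i in range(spec.n_studies):
        log_or = rng.normal(np.log(spec.true_or), spec.between_study_sd)
        odds_case = np.exp(log_or) * odds_c
        p_case = odds_case / (1 + odds_case)
        n_cases = int(spec.cases_sizes[i])
        n_controls = int(spec.controls_sizes[i])
        a = int(rng.binomial(n_cases, p_case))
        c = int(rng.binomial(n_controls, spec.control_carrier_freq))
        studies.append(
            StudyRecord(
                label=f"sim{i + 1:02d}",
                population="synthetic",
                typing_method="simulated",
                a=a,
                b=n_cases - a,
                c=c,
                d=n_controls - c,
            )
        )
    return studies


def gen_corpus(spec: CorpusSimSpec) -> Corpus:
    """Simulate a document-concept co-occurrence corpus.

    Documents that draw no concept at all receive the neutral marker
    concept ``BACKGROUND`` so that exactly ``n_docs`` documents are
    emitted and every document has a non-empty concept set.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    records = []
    for i in range(spec.n_docs):
        concepts = set()
        query_present = False
        for q in (QUERY_A, QUERY_B):
            if rng.random() < spec.baseline_occurrence:
                concepts.add(q)
                query_present = True
        for g in genes:
            p = spec.planted_cooccurrence if (query_present and g in spec.planted_genes) else spec.baseline_occurrence
            if rng.random() < p:
                concepts.add(g)
        if not concepts:
            concepts.add("BACKGROUND")
        records.append((f"doc{i:05d}", concepts))
    return Corpus.from_records(records)


def _node_name(i: int) -> str:
    return f"N{i:04d}"


def gen_network(spec: NetworkSimSpec) -> tuple[BackgroundNetwork, set[str], set[str]]:
    """Simulate a background network with planted connectors.

    Returns (network, seed node set, planted connector set).  Seeds are
    the first ``n_seeds`` nodes; each planted connector gets edges to
    ``connector_seed_links`` distinct seeds on top of its Erdos-Renyi
    wiring.  Every edge carries a unique synthetic reference id.
    """
    rng = np.random.default_rng(spec.seed)
    p = min(1.0, spec.mean_degree / (spec.n_nodes - 1))
    er = nx.fast_gnp_random_graph(spec.n_nodes, p, seed=int(rng.integers(2 ** 31)))
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(_node_name(i) for i in range(spec.n_nodes))
    for u, v in er.edges():
        g.add_edge(_node_name(u), _node_name(v))
    seeds = {_node_name(i) for i in range(spec.n_seeds)}
    connectors = {_node_name(spec.n_seeds + j) for j in range(spec.n_planted_connectors)}
    seed_list = sorted(seeds)
    for node in sorted(connectors):
        chosen = rng.choice(len(seed_list), size=spec.connector_seed_links, replace=False)
        for idx in chosen:
            g.add_edge(node, seed_list[idx])
    for n_ref, (u, v) in enumerate(sorted(map(lambda e: tuple(sorted(e)), g.edges()))):
        g.edges[u, v]["references"] = frozenset({f"R{n_ref:06d}"})
    return BackgroundNetwork(graph=g), seeds, connectors


def rewire_background(net: BackgroundNetwork, seed: int, n_swaps: int | None = None) -> BackgroundNetwork:
    """Degree-preserving rewiring (double edge swaps) for null comparisons.

    References are reassigned as fresh unique ids since the literature
    annotation of a rewired edge is meaningless.
    """
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from(net.graph.edges())
    m = g.number_of_edges()
    if n_swaps is None:
        n_swaps = 4 * m
    nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
    for n_ref, (u, v) in enumerate(sorted(map(lambda e: tuple(sorted(e)), g.edges()))):
        g.edges[u, v]["references"] = frozenset({f"R{n_ref:06d}"})
    return BackgroundNetwork(graph=g)


def write_network(net: BackgroundNetwork, path: str | Path, header_comment: str = "") -> None:
    """Write a background network as a TSV edge list with reference column."""
    with Path(path).open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for u, v in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges())):
            refs = ",".join(sorted(net.graph.edges[u, v].get("references", frozenset())))
            fh.write(f"{u}\t{v}\t{refs}\n" if refs else f"{u}\t{v}\n")


def provenance_comment(spec) -> str:
    """One-line key=value provenance string for generator output headers."""
    items = []
    for key, value in vars(spec).items():
        if isinstance(value, (frozenset, set)):
            value = ",".join(sorted(value)) or "-"
        elif isinstance(value, (tuple, list)):
            value = ",".join(str(v) for v in value)
        items.append(f"{key}={value}")
    return " ".join(items)


def write_studies(studies: Sequence[StudyRecord], path: str | Path, spec: StudySimSpec) -> None:
    write_study_table(studies, path, header_comment=f"simulated studies: {provenance_comment(spec)}")
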