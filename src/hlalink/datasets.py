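"""Published data tables shipped with the package, and helpers built on them.

Three small TSV fixtures accompany the pipeline: the 19-study
case-control table (labels, populations, typing techniques and sample
totals; the per-study 2x2 cells were never published), the 21-gene
contribution table of the disease/gene concept-profile comparison, and
the 13 intermediate nodes of the seed-expanded interaction subnetwork.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .network import BackgroundNetwork, load_background

__all__ = [
    "load_table1",
    "load_table2",
    "load_table3",
    "seed_genes",
    "implied_cohesion",
    "reconstruct_intermediate_network",
]

#: Proteins retained as seed nodes in the interaction analysis (10 of the
#: 21 genes above the 0.1% contribution threshold).
SEED_GENES = ("APP", "ICAM1", "ITGB2", "ITGAL", "SELP", "SELL", "IL2", "IL1B", "CD4", "CD8A")


def _read(name: str) -> pd.DataFrame:
    with resources.files("hlalink.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_table1() -> pd.DataFrame:
    """The 19 case-control studies: label, population, typing_method, totals."""
    df = _read("table1_studies.tsv")
    return df


def load_table2() -> pd.DataFrame:
    """Genes above the 0.1% contribution threshold with printed weights."""
    return _read("table2_weights.tsv")


def load_table3() -> pd.DataFrame:
    """The 13 intermediate nodes with degrees, seed links and printed z."""
    return _read("table3_intermediates.tsv")


def seed_genes() -> list[str]:
    return list(SEED_GENES)


def implied_cohesion(table2: pd.DataFrame | None = None) -> tuple[float, pd.DataFrame]:
    """Cohesion score implied by the printed per-gene weights and percentages.

    The printed table covers only genes contributing > 0.1%, so the full
    cohesion score (the denominator of the percentages) is not printed.
    It is recovered as sum(products) / (sum(printed percentages)/100),
    and each gene's contribution is recomputed as product / CS * 100.
    Returns (implied CS, table with 'product' and 'recomputed_percent'
    columns added).
    """
    df = (table2 if table2 is not None else load_table2()).copy()
    df["product"] = df["weight_in_AD"] * df["weight_in_HLA_A"]
    cs = float(df["product"].sum() / (df["percentage"].sum() / 100.0))
    df["recomputed_percent"] = 100.0 * df["product"] / cs
    return cs, df


def reconstruct_intermediate_network(
    table3: pd.DataFrame | None = None,
) -> tuple[BackgroundNetwork, set[str]]:
    """Rebuild a background network with the published subnetwork structure.

    The published analysis reports, per intermediate node, its background
    degree and its number of links to seed proteins, together with the
    global constants (29 subnetwork links, 11429 background links).  This
    helper materialises one concrete background graph consistent with all
    of those numbers: each intermediate is wired to the stated number of
    distinct seeds (round-robin over the 10 seed proteins) and padded
    with degree-filler neighbours up to its background degree; a chain of
    filler edges brings the edge total to exactly 11429.  Every edge
    carries a unique reference id, so the hub-reference filter leaves the
    graph unchanged.  Expanding the seed set on this graph and scoring
    its intermediates recomputes the published z-scores end to end.
    """
    df = table3 if table3 is not None else load_table3()
    lines = []
    ref = 0

    def edge(a: str, b: str) -> str:
        nonlocal ref
        ref += 1
        return f"{a}\t{b}\tR{ref:06d}"

    seed_cycle = 0
    for _, row in df.iterrows():
        node, n, k = str(row["node"]), int(row["links"]), int(row["links_to_seed"])
        chosen = [SEED_GENES[(seed_cycle + j) % len(SEED_GENES)] for j in range(k)]
        seed_cycle = (seed_cycle + k) % len(SEED_GENES)
        for s in chosen:
            lines.append(edge(node, s))
        for j in range(n - k):
            lines.append(edge(node, f"X_{node}_{j}"))
    bg_total = int(df["links_in_background"].iloc[0])
    n_filler = bg_total - len(lines)
    if n_filler < 0:
        raise ValueError("table implies more structural edges than background links")
    for j in range(n_filler):
        lines.append(edge(f"F{j}", f"F{j + 1}"))
    net = load_background(lines, fmt="tsv")
    assert net.total_links == bg_total
    return net, set(SEED_GENES)
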