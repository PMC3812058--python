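"""Graph analyses of pocket space: representative (dominating) sets, strongly
connected components, growth curves, and per-ligand subspace coverage.

Pocket similarity relations form a directed graph: an edge A -> B means the
alignment with B as the query (score normalized by B's length) passes both
the PS-score and the P-value threshold.  Two pockets are *matched* when they
are connected in both directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass
class PocketGraph:
    g: nx.DiGraph
    ps_min: float
    p_max: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.g.nodes)

    def n_edges(self) -> int:
        return self.g.number_of_edges()


@dataclass
class DominatingSetResult:
    selected: list[str]  # in selection order
    N: int
    coverage: float


def build_graph(results: pd.DataFrame, ps_min: float, p_max: float,
                nodes: list[str] | None = None) -> PocketGraph:
    """Threshold a pairwise alignment table into a directed pocket graph.

    ``results`` columns: template_id, query_id, ps_score, p_value.  The edge
    template -> query is added when ps_score >= ps_min and p_value < p_max.
    Self rows are ignored.
    """
    g = nx.DiGraph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    else:
        g.add_nodes_from(pd.unique(results[["template_id", "query_id"]].values.ravel()))
    ok = (
        (results["ps_score"] >= ps_min)
        & (results["p_value"] < p_max)
        & (results["template_id"] != results["query_id"])
    )
    for row in results.loc[ok].itertuples(index=False):
        g.add_edge(row.template_id, row.query_id,
                   ps_score=row.ps_score, p_value=row.p_value)
    return PocketGraph(g, ps_min, p_max)


def greedy_dominating_set(graph: PocketGraph) -> DominatingSetResult:
    """Greedy estimate of the domination number N.

    Repeatedly select the node matching the most still-unmatched nodes
    (a node matches itself and every bidirectional neighbour); ties break
    lexicographically by node id.  Iterates until every node is matched.
    """
    g = graph.g
    matched: dict[str, set[str]] = {}
    for v in g.nodes:
        partners = {u for u in g.successors(v) if g.has_edge(u, v)}
        partners.add(v)
        matched[v] = partners
    unmatched = set(g.nodes)
    selected: list[str] = []
    total = g.number_of_nodes()
    while unmatched:
        best = min(matched, key=lambda v: (-len(matched[v] & unmatched), v))
        selected.append(best)
        unmatched -= matched[best]
    coverage = 1.0 if total == 0 else (total - len(unmatched)) / total
    return DominatingSetResult(selected, len(selected), coverage)


def strongly_connected_components(graph: PocketGraph) -> list[list[str]]:
    """SCCs sorted largest first (ties by smallest member id); LSCC is first."""
    comps = [sorted(c) for c in nx.strongly_connected_components(graph.g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def lscc_fraction(graph: PocketGraph) -> float:
    n = graph.g.number_of_nodes()
    if n == 0:
        return 0.0
    return len(strongly_connected_components(graph)[0]) / n


def growth_by_year(pockets, results: pd.DataFrame, ps_min: float,
                   p_max: float) -> pd.DataFrame:
    """Cumulative growth: per year, total pockets and the greedy N among them."""
    dated = []
    for p in pockets:
        if p.year is None:
            warnings.warn(f"pocket {p.pocket_id} has no deposition year; excluded")
        else:
            dated.append(p)
    years = sorted({p.year for p in dated})
    rows = []
    for y in years:
        ids = {p.pocket_id for p in dated if p.year <= y}
        sub = results[
            results["template_id"].isin(ids) & results["query_id"].isin(ids)
        ]
        graph = build_graph(sub, ps_min, p_max, nodes=sorted(ids))
        rows.append(
            {"year": y, "n_pockets": len(ids),
             "n_representatives": greedy_dominating_set(graph).N}
        )
    return pd.DataFrame(rows)


def ligand_subspace_coverage(pockets, results: pd.DataFrame, p_max: float,
                             min_pockets: int = 30,
                             ps_min: float = 0.0) -> pd.DataFrame:
    """Per-ligand LSCC coverage of its pocket subspace.

    For each HET code with more than ``min_pockets`` pockets, build the
    subspace graph at the given thresholds and report the LSCC size divided
    by the subspace size.
    """
    by_het: dict[str, list] = {}
    for p in pockets:
        by_het.setdefault(p.het_code, []).append(p)
    rows = []
    for het in sorted(by_het):
        group = by_het[het]
        if len(group) <= min_pockets:
            continue
        ids = {p.pocket_id for p in group}
        sub = results[
            results["template_id"].isin(ids) & results["query_id"].isin(ids)
        ]
        graph = build_graph(sub, ps_min, p_max, nodes=sorted(ids))
        lscc = len(strongly_connected_components(graph)[0])
        rows.append(
            {"het_code": het, "n_pockets": len(ids), "lscc_size": lscc,
             "coverage": lscc / len(ids)}
        )
    return pd.DataFrame(rows, columns=["het_code", "n_pockets", "lscc_size", "coverage"])


def write_edge_list(graph: PocketGraph, path: str) -> None:
    rows = [
        {"source": u, "target": v, **d} for u, v, d in graph.g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "ps_score", "p_value"]).to_csv(
        path, sep="\t", index=False
    )
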