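"""Weighted variability-correlation networks: layout, centralities, export.

Nodes are biomarker variabilities (LCVs); every pair is joined by an edge
weighted by its correlation coefficient, sign preserved and no threshold
applied.  Path-based centralities use the common weighted-network
convention that an edge of absolute weight |r| has length 1/|r|, so
strongly correlated regulatory systems are "close".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from dysreg.association import CorrelationMatrix

__all__ = ["PhysioNetwork", "build_graph", "fr_layout", "centralities"]


@dataclass
class PhysioNetwork:
    """A complete weighted graph over variability nodes plus derived artifacts."""

    graph: nx.Graph
    layout: dict | None = None
    layout_seed: int | None = None
    centrality: pd.DataFrame | None = None

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def write(self, outdir: str | Path, stem: str = "network") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(self.graph, outdir / f"{stem}.graphml")
        self.edge_table().to_csv(outdir / "edges.csv", index=False)
        if self.layout is not None:
            pd.DataFrame(
                [(n, x, y) for n, (x, y) in self.layout.items()],
                columns=["node", "x", "y"],
            ).to_csv(outdir / "layout.csv", index=False)
        if self.centrality is not None:
            self.centrality.to_csv(outdir / "centrality.csv")


def build_graph(corr: CorrelationMatrix, subset: Sequence[str] | None = None) -> PhysioNetwork:
    """Complete weighted graph whose edge weights are the pairwise correlations.

    Negative correlations are retained with their sign; no edge is
    thresholded away (a display cutoff, if any, is a rendering concern).
    """
    variables = list(subset) if subset is not None else corr.variables
    unknown = set(variables) - set(corr.variables)
    if unknown:
        raise ValueError(f"subset contains unknown variables: {sorted(unknown)}")
    if len(variables) < 2:
        raise ValueError(f"need >= 2 nodes to build a network, got {len(variables)}")
    g = nx.Graph()
    g.add_nodes_from(variables)
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            w = float(corr.r.loc[a, b])
            g.add_edge(a, b, weight=w, absweight=abs(w))
    return PhysioNetwork(graph=g)


def fr_layout(
    network: PhysioNetwork, seed: int = 42, iterations: int = 200
) -> Mapping[str, np.ndarray]:
    """Fruchterman-Reingold force-directed layout, attraction scaled by |r|.

    Deterministic for a fixed seed; coordinates are stored on the network.
    """
    if network.graph.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes for a layout")
    pos = nx.spring_layout(
        network.graph, weight="absweight", seed=seed, iterations=iterations
    )
    network.layout = {n: np.asarray(p, dtype=float) for n, p in pos.items()}
    network.layout_seed = seed
    return network.layout


def centralities(network: PhysioNetwork) -> pd.DataFrame:
    """Node strength, closeness, and betweenness of the weighted network.

    strength(i)   = sum of |w| over incident edges;
    closeness(i)  = 1 / sum_j d(i, j) with edge length 1/|w|
                    (undefined, reported as NaN, for a node with only
                    zero-weight edges);
    betweenness   = shortest-path betweenness on the same lengths,
                    normalized to [0, 1].
    """
    g = network.graph
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        aw = abs(d["weight"])
        if aw > 0:
            h.add_edge(u, v, dist=1.0 / aw)
    strength = {n: 0.0 for n in g.nodes}
    for u, v, d in g.edges(data=True):
        strength[u] += abs(d["weight"])
        strength[v] += abs(d["weight"])
    closeness = {}
    for n in g.nodes:
        if h.degree(n) == 0:
            closeness[n] = float("nan")
            continue
        dists = nx.single_source_dijkstra_path_length(h, n, weight="dist")
        total = sum(v for k, v in dists.items() if k != n)
        closeness[n] = 1.0 / total if total > 0 else float("nan")
    betweenness = nx.betweenness_centrality(h, weight="dist", normalized=True)
    out = pd.DataFrame(
        {
            "strength": pd.Series(strength),
            "closeness": pd.Series(closeness),
            "betweenness": pd.Series({n: betweenness.get(n, 0.0) for n in g.nodes}),
        }
    )
    out.index.name = "node"
    network.centrality = out
    return out
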