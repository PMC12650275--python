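"""Signed co-occurrence network container and plain-text graph I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class SignedNetwork:
    """Undirected ASV co-occurrence graph with signed weighted edges.

    Edge attributes: ``weight`` (the signed correlation), ``abs_weight``
    and ``sign`` (+1/-1). ``threshold`` records the similarity cutoff the
    network was built at.
    """

    graph: nx.Graph
    threshold: float

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:3]}")
        for u, v, data in self.graph.edges(data=True):
            if abs(data["weight"]) < self.threshold - 1e-12:
                raise ValueError(f"edge ({u},{v}) below threshold {self.threshold}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_edge_tsv(self, path) -> None:
        rows = [
            {"node_a": u, "node_b": v, "weight": d["weight"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "sign"]).to_csv(
            path, sep="\t", index=False
        )

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, Path(path))

    @classmethod
    def from_edge_tsv(cls, path, threshold: float) -> "SignedNetwork":
        frame = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in frame.itertuples(index=False):
            g.add_edge(
                row.node_a,
                row.node_b,
                weight=float(row.weight),
                abs_weight=abs(float(row.weight)),
                sign=int(row.sign),
            )
        return cls(g, threshold)


def from_correlation(
    corr: pd.DataFrame, threshold: float, nodes: list[str] | None = None
) -> SignedNetwork:
    """Threshold a symmetric correlation matrix into a signed network.

    An edge (i, j) exists iff |corr_ij| >= threshold; isolated nodes are
    kept so topology denominators stay honest.
    """
    g = nx.Graph()
    labels = list(corr.index) if nodes is None else list(nodes)
    g.add_nodes_from(labels)
    mat = corr.to_numpy()
    idx = list(corr.index)
    iu = np.triu_indices(len(idx), 1)
    sel = np.abs(mat[iu]) >= threshold - 1e-12  # tolerate fp round-off at rho = +-1
    for i, j in zip(iu[0][sel], iu[1][sel]):
        r = float(mat[i, j])
        g.add_edge(idx[i], idx[j], weight=r, abs_weight=abs(r), sign=1 if r >= 0 else -1)
    return SignedNetwork(g, threshold)
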