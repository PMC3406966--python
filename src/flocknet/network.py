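"""Animal-exchange networks: construction, average degree, shortest paths.

Herds are vertices; one undirected edge joins two herds as soon as one or
more exchanges were reported between them (direction is recorded but
ignored by every metric).  The average degree AD = 2e/n is the study's
connectivity measure; the shortest-path-length (SPL) matrix is the
network distance fed to the Mantel correlation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genio import ExchangeRecord
from .differentiation import PairwiseHerdMatrix

__all__ = [
    "HerdGraph",
    "SplMatrix",
    "SplStratumMetrics",
    "build_graph",
    "average_degree",
    "shortest_path_lengths",
    "geodesic_counts",
    "spl_stratified_metrics",
]


@dataclass
class HerdGraph:
    """Undirected analysis view of an exchange network.

    The original (possibly directed) records are retained for reporting.
    """

    graph: nx.Graph
    directed_records: list[ExchangeRecord]

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def e(self) -> int:
        return self.graph.number_of_edges()

    def vertices(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def adjacency_matrix(self) -> tuple[list[str], np.ndarray]:
        herds = self.vertices()
        m = nx.to_numpy_array(self.graph, nodelist=herds, dtype=int)
        return herds, m


@dataclass
class SplMatrix:
    """Symmetric matrix of geodesic edge counts; inf marks unreachable pairs."""

    herds: list[str]
    values: np.ndarray  # float, integer-valued where finite

    def as_pairwise(self) -> PairwiseHerdMatrix:
        return PairwiseHerdMatrix(list(self.herds), self.values.copy(), "spl")


@dataclass
class SplStratumMetrics:
    spl: int
    mean_geodesic_count: float
    mean_genetic_distance: float | None
    n_exchanges: int
    n_herds: int
    average_degree: float
    herds: list[str]
    edges: list[tuple[str, str]]


def build_graph(
    records: Iterable[ExchangeRecord],
    restrict_to: Iterable[str] | None = None,
) -> HerdGraph:
    """Collapse exchange records into an undirected herd graph.

    Multiple records between the same pair collapse to one edge.  With
    *restrict_to*, only the listed herds (as isolated vertices if need be)
    and edges between them are kept.
    """
    records = list(records)
    g = nx.Graph()
    if restrict_to is not None:
        keep = set(restrict_to)
        g.add_nodes_from(keep)
    for r in records:
        if restrict_to is not None and (
            r.source_herd not in keep or r.dest_herd not in keep
        ):
            continue
        g.add_edge(r.source_herd, r.dest_herd)
    return HerdGraph(g, records)


def average_degree(g: HerdGraph) -> float:
    """AD = 2e/n, the mean number of exchange partners per herd."""
    if g.n == 0:
        raise ValueError("average degree undefined for an empty vertex set")
    return 2.0 * g.e / g.n


def shortest_path_lengths(g: HerdGraph) -> SplMatrix:
    """All-pairs geodesic edge counts by breadth-first search."""
    herds = g.vertices()
    idx = {h: i for i, h in enumerate(herds)}
    n = len(herds)
    vals = np.full((n, n), np.inf)
    np.fill_diagonal(vals, 0.0)
    for src, dists in nx.all_pairs_shortest_path_length(g.graph):
        for dst, d in dists.items():
            vals[idx[src], idx[dst]] = float(d)
    return SplMatrix(herds, vals)


def geodesic_counts(g: HerdGraph) -> tuple[list[str], np.ndarray]:
    """Number of distinct shortest paths for every herd pair.

    BFS path-counting recurrence: sigma(s, v) = sum of sigma(s, u) over
    geodesic predecessors u of v.  Unreachable pairs count 0; the diagonal
    is 1 (the empty path).
    """
    herds = g.vertices()
    idx = {h: i for i, h in enumerate(herds)}
    n = len(herds)
    counts = np.zeros((n, n), dtype=np.int64)
    for s in herds:
        si = idx[s]
        dist = {s: 0}
        sigma = {s: 1}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in g.graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    q.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        for v, c in sigma.items():
            counts[si, idx[v]] = c
    return herds, counts


def spl_stratified_metrics(
    g: HerdGraph,
    spl: SplMatrix | None = None,
    counts: np.ndarray | None = None,
    gen: PairwiseHerdMatrix | None = None,
) -> list[SplStratumMetrics]:
    """Per-SPL network metrics (one row per observed SPL value >= 1).

    The stratum for SPL = d is built from the pair set P_d = {pairs at
    geodesic distance d}: its vertex set is every herd appearing in at
    least one pair of P_d, its edge set the edges of *g* induced on that
    vertex set, and AD = 2e/n on that subgraph.  The mean geodesic count
    and (when *gen* is given, aligned on the same herds) the mean genetic
    distance are averaged over P_d.
    """
    if spl is None:
        spl = shortest_path_lengths(g)
    if counts is None:
        _, counts = geodesic_counts(g)
    herds = spl.herds
    if gen is not None and gen.herds != herds:
        gen = gen.reorder(herds)
    n = len(herds)
    iu = np.triu_indices(n, k=1)
    dvals = spl.values[iu]
    finite = np.isfinite(dvals) & (dvals >= 1)
    out = []
    for d in sorted(set(int(x) for x in dvals[finite])):
        mask = finite & (dvals == d)
        rows, cols = iu[0][mask], iu[1][mask]
        verts = sorted({herds[i] for i in rows} | {herds[i] for i in cols})
        sub = g.graph.subgraph(verts)
        mean_gen = None
        if gen is not None:
            pair_vals = gen.values[rows, cols]
            pair_vals = pair_vals[~np.isnan(pair_vals)]
            if pair_vals.size:
                mean_gen = float(pair_vals.mean())
        out.append(
            SplStratumMetrics(
                spl=d,
                mean_geodesic_count=float(counts[rows, cols].mean()),
                mean_genetic_distance=mean_gen,
                n_exchanges=sub.number_of_edges(),
                n_herds=sub.number_of_nodes(),
                average_degree=2.0 * sub.number_of_edges() / sub.number_of_nodes(),
                herds=list(verts),
                edges=sorted(tuple(sorted(e)) for e in sub.edges),
            )
        )
    return out


def strata_to_frame(strata: Sequence[SplStratumMetrics]) -> pd.DataFrame:
    """Tabular view of SPL-stratified metrics."""
    return pd.DataFrame(
        [
            {
                "spl": s.spl,
                "mean_n_shortest_paths": s.mean_geodesic_count,
                "mean_genetic_distance": s.mean_genetic_distance,
                "n_exchanges": s.n_exchanges,
                "n_herds": s.n_herds,
                "average_degree": s.average_degree,
            }
            for s in strata
        ]
    )
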