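"""Mantel correlation between genetic and network distances.

Aligns the Reynolds-distance and shortest-path-length matrices on the
herds that qualify for analysis (enough genotyped animals, connected in
the exchange network) and tests their association by joint row/column
permutation of one matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .genio import GenotypeTable
from .differentiation import PairwiseHerdMatrix
from .network import HerdGraph

__all__ = ["MantelResult", "select_analysis_herds", "mantel_test"]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n_herds: int
    tail: str
    seed: int | None = None


def select_analysis_herds(
    gt: GenotypeTable, g: HerdGraph, min_animals: int = 5
) -> tuple[list[str], dict[str, str]]:
    """Herds admissible for the genetic-vs-network correlation.

    A herd qualifies when it has at least *min_animals* genotyped animals
    AND lies in the largest connected component of the exchange graph
    restricted to qualifying herds — isolated islets would contribute
    infinite network distances.  Returns (selected, exclusions) where
    exclusions maps each dropped herd to its reason.
    """
    members = gt.herd_members()
    exclusions: dict[str, str] = {}
    enough = []
    for h in sorted(set(members) | set(g.graph.nodes)):
        n_gen = len(members.get(h, []))
        if n_gen < min_animals:
            exclusions[h] = f"below threshold ({n_gen} < {min_animals} genotyped)"
        elif h not in g.graph:
            exclusions[h] = "no exchange information"
        else:
            enough.append(h)
    sub = g.graph.subgraph(enough)
    comps = sorted(nx.connected_components(sub), key=len, reverse=True)
    if not comps:
        raise ValueError("no herds qualify for the Mantel analysis")
    main = comps[0]
    selected = [h for h in enough if h in main]
    for h in enough:
        if h not in main:
            exclusions[h] = "isolated network (outside the main component)"
    if len(selected) < 3:
        raise ValueError(
            f"only {len(selected)} herds survive selection; Mantel needs >= 3"
        )
    return selected, exclusions


def _tri(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_test(
    m1: PairwiseHerdMatrix,
    m2: PairwiseHerdMatrix,
    n_perm: int = 100_000,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two aligned herd distance matrices.

    r is the Pearson correlation over the strict upper triangle.  The null
    distribution permutes rows and columns of *m2* simultaneously;
    p = (#{statistic as or more extreme} + 1) / (n_perm + 1), so p is
    never 0.  *tail* is ``"greater"`` (positive association, the default
    directional hypothesis) or ``"two-sided"``.
    """
    if m1.herds != m2.herds:
        raise ValueError("matrices are not aligned on the same herd ordering")
    if tail not in ("greater", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    a, b = np.asarray(m1.values, float), np.asarray(m2.values, float)
    n = a.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 herds")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("matrices contain non-finite entries")
    v1, v2 = _tri(a), _tri(b)
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    z1 = (v1 - v1.mean()) / v1.std()
    r_obs = float((z1 * ((v2 - v2.mean()) / v2.std())).mean())

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = b[np.ix_(perm, perm)][iu]
        r_p = float((z1 * ((vp - vp.mean()) / vp.std())).mean())
        if tail == "greater":
            if r_p >= r_obs:
                hits += 1
        else:
            if abs(r_p) >= abs(r_obs):
                hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, n, tail, seed)
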