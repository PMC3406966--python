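"""Forward-time drift-on-network simulator.

Generates the statistical structure the analysis pipeline assumes: herds
of diploid animals drifting from founder allele-frequency pools at ~19
microsatellite-like loci, with gene flow confined to the edges of a known
exchange network.  Each generation every herd's gene pool is resampled
Wright–Fisher style (2N genes) after a *migration_rate* fraction is
replaced by the pool of one uniformly chosen network neighbour.  The
final generation is sampled into diploid genotypes (5–15 per herd by
default), and the network edges double as the matching exchange-record
table.  A truth object (herd -> group, frequency trajectories) is kept
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genio import (
    ExchangeRecord,
    GenotypeTable,
    PedigreeRecord,
)

__all__ = ["SimConfig", "SimResult", "random_connected_network", "simulate_scenario"]


@dataclass
class SimConfig:
    """Scenario parameters; every random choice flows from the single seed."""

    n_herds: int = 12
    herd_size: int = 20  # diploid breeding individuals per herd (N)
    n_loci: int = 19
    founder_alleles_per_locus: int = 8
    target_avg_degree: float = 3.0
    migration_rate: float = 0.05
    generations: int = 30
    sample_per_herd: tuple[int, int] = (5, 15)  # uniform inclusive range
    n_groups: int = 1  # independent founder pools; herds split into blocks
    islet_herds: int = 0  # extra herds forming a disconnected component
    n_pedigree_only: int = 0  # non-genotyped offspring of sampled parents
    breed_label: str = "SYN"
    store_trajectories: bool = False
    seed: int = 0


@dataclass
class SimResult:
    genotypes: GenotypeTable
    exchanges: list[ExchangeRecord]
    pedigree: list[PedigreeRecord]
    truth: dict = field(default_factory=dict)


def random_connected_network(
    n: int, target_avg_degree: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Random connected graph: uniform spanning-tree skeleton plus random
    extra edges until e = round(AD* n / 2)."""
    if n < 2:
        raise ValueError("need at least 2 herds for a network")
    e_target = int(round(target_avg_degree * n / 2.0))
    e_min, e_max = n - 1, n * (n - 1) // 2
    if not e_min <= e_target <= e_max:
        lo, hi = 2.0 * e_min / n, 2.0 * e_max / n
        raise ValueError(
            f"target average degree {target_avg_degree} infeasible for {n} herds "
            f"(feasible range {lo:.2f}..{hi:.2f})"
        )
    order = rng.permutation(n)
    edges = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        a, b = int(order[i]), int(order[j])
        edges.add((min(a, b), max(a, b)))
    while len(edges) < e_target:
        a, b = rng.integers(0, n, size=2)
        if a == b:
            continue
        edges.add((min(int(a), int(b)), max(int(a), int(b))))
    return sorted(edges)


def _herd_id(i: int) -> str:
    return f"H{i + 1:02d}"


def simulate_scenario(cfg: SimConfig) -> SimResult:
    """Run the scenario and emit analysis-ready tables.

    Determinism contract: the same config (including seed) produces
    bit-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_herds + cfg.islet_herds
    if cfg.n_groups < 1 or cfg.n_groups > cfg.n_herds:
        raise ValueError("n_groups must be between 1 and n_herds")

    # --- network ---------------------------------------------------------
    if cfg.n_herds == 1:
        edges: list[tuple[int, int]] = []
    else:
        edges = random_connected_network(cfg.n_herds, cfg.target_avg_degree, rng)
    if cfg.islet_herds >= 2:
        base = cfg.n_herds
        edges += [(base + i, base + i + 1) for i in range(cfg.islet_herds - 1)]
    elif cfg.islet_herds == 1:
        raise ValueError("an islet needs >= 2 herds to carry an exchange")
    neighbours: dict[int, list[int]] = {i: [] for i in range(n_total)}
    for a, b in edges:
        neighbours[a].append(b)
        neighbours[b].append(a)

    # --- founder pools ---------------------------------------------------
    A = cfg.founder_alleles_per_locus
    group_of_herd = np.minimum(
        np.arange(cfg.n_herds) * cfg.n_groups // cfg.n_herds, cfg.n_groups - 1
    )
    # islet herds drift from the first group's pool
    group_of_herd = np.concatenate(
        [group_of_herd, np.zeros(cfg.islet_herds, dtype=group_of_herd.dtype)]
    )
    founder = rng.dirichlet(np.ones(A), size=(cfg.n_groups, cfg.n_loci))

    # --- drift with migration along edges --------------------------------
    freqs = founder[group_of_herd].copy()  # (n_total, L, A)
    two_n = 2 * cfg.herd_size
    traj = [freqs.copy()] if cfg.store_trajectories else None
    for _ in range(cfg.generations):
        pools = freqs.copy()
        if cfg.migration_rate > 0:
            for h in range(n_total):
                nb = neighbours[h]
                if nb:
                    src = nb[int(rng.integers(0, len(nb)))]
                    pools[h] = (
                        (1.0 - cfg.migration_rate) * freqs[h]
                        + cfg.migration_rate * freqs[src]
                    )
        for h in range(n_total):
            for l in range(cfg.n_loci):
                freqs[h, l] = rng.multinomial(two_n, pools[h, l]) / two_n
        if traj is not None:
            traj.append(freqs.copy())

    # --- sample diploid genotypes ----------------------------------------
    lo, hi = cfg.sample_per_herd
    individuals: list[str] = []
    calls_rows: list[np.ndarray] = []
    herd_of: dict[str, str | None] = {}
    breed: dict[str, str] = {}
    herd_samples: dict[str, list[str]] = {}
    for h in range(n_total):
        hid = _herd_id(h)
        s = int(rng.integers(lo, hi + 1))
        herd_samples[hid] = []
        for k in range(s):
            aid = f"{hid}_A{k + 1:02d}"
            geno = np.empty((cfg.n_loci, 2), dtype=np.int64)
            for l in range(cfg.n_loci):
                geno[l] = rng.choice(A, size=2, p=freqs[h, l]) + 1
            individuals.append(aid)
            calls_rows.append(geno)
            herd_of[aid] = hid
            breed[aid] = cfg.breed_label
            herd_samples[hid].append(aid)
    gt = GenotypeTable(
        individuals, [f"L{l + 1:02d}" for l in range(cfg.n_loci)],
        np.stack(calls_rows), herd_of, breed,
    )

    # --- exchange records (one per direction used) -----------------------
    records = []
    for a, b in edges:
        if rng.random() < 0.5:
            a, b = b, a
        records.append(ExchangeRecord(_herd_id(a), _herd_id(b), True))

    # --- pedigree: sampled animals founders; optional extra offspring ----
    pedigree = [PedigreeRecord(aid) for aid in individuals]
    offspring = []
    for k in range(cfg.n_pedigree_only):
        h = _herd_id(int(rng.integers(0, n_total)))
        pool = herd_samples[h]
        if len(pool) < 2:
            continue
        sire, dam = rng.choice(len(pool), size=2, replace=False)
        oid = f"{h}_X{k + 1:02d}"
        pedigree.append(PedigreeRecord(oid, pool[int(sire)], pool[int(dam)]))
        offspring.append(oid)

    truth = {
        "group_of_herd": {
            _herd_id(h): int(group_of_herd[h]) for h in range(n_total)
        },
        "founder_freqs": founder,
        "final_freqs": freqs,
        "edges": [(_herd_id(a), _herd_id(b)) for a, b in edges],
        "pedigree_only": offspring,
        "config": cfg,
    }
    if traj is not None:
        truth["trajectories"] = np.stack(traj)
    return SimResult(gt, records, pedigree, truth)
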