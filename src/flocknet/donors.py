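"""Tiered characterization of cryobank donor candidates.

Evidence quality orders the tiers: tier 1 animals carry their own
genotype (assigned to a genetic group when their individual membership
coefficient reaches the threshold, kept as tier 1 even when unassigned);
tier 2 animals are ungenotyped but have genotyped parents (preferred) or
grandparents whose common group is inherited putatively; tier 3 animals
are characterized from the exchange network alone — their natal herd's
group, or failing that the majority group among the herd's direct
exchange partners.  Within a tier the ranking round-robins across
genetic groups so every group is represented early.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genio import GenotypeTable, PedigreeRecord
from .clustering import UNASSIGNED, GroupAssignment, MembershipMatrix
from .network import HerdGraph

__all__ = ["DonorCandidate", "rank_donors", "UNKNOWN_GROUP"]

#: Group label for candidates with no usable evidence at all.
UNKNOWN_GROUP = "UNKNOWN"


@dataclass
class DonorCandidate:
    animal: str
    herd: str | None
    genotyped: bool
    group_evidence: str  # direct | pedigree | network | none
    assigned_group: int | str  # cluster index, UNASSIGNED or UNKNOWN
    tier: int | None  # 1 | 2 | 3 | None (uncharacterizable)
    provenance_notes: str = ""


def _individual_group(
    animal: str, memberships: MembershipMatrix, threshold: float
) -> int | str:
    i = memberships.individuals.index(animal)
    q = memberships.q[i]
    return int(q.argmax()) if float(q.max()) >= threshold else UNASSIGNED


def _common_group(groups: Sequence[int | str]) -> int | str:
    real = [g for g in groups if g != UNASSIGNED]
    if not real:
        return UNASSIGNED
    if all(g == real[0] for g in real) and len(real) == len(groups):
        return real[0]
    return UNASSIGNED


def rank_donors(
    candidates: Sequence[str],
    gt: GenotypeTable,
    assignments: Sequence[GroupAssignment],
    memberships: MembershipMatrix,
    ped: Sequence[PedigreeRecord],
    g: HerdGraph,
    threshold: float = 0.7,
    herd_of: Mapping[str, str] | None = None,
) -> list[DonorCandidate]:
    """Characterize and rank donor candidates by evidence tier.

    *herd_of* supplies natal herds for animals absent from the genotype
    table (defaults to the table's own herd map).  Every input candidate
    appears exactly once in the output; candidates absent from all
    evidence sources come back with ``tier=None`` rather than being
    dropped.
    """
    herd_group = {a.herd: a.group for a in assignments}
    ped_by_animal = {r.animal: r for r in ped}
    genotyped = set(gt.individuals)

    def natal_herd(animal: str) -> str | None:
        if herd_of is not None and animal in herd_of:
            return herd_of[animal]
        return gt.herd_of_birth.get(animal)

    out: list[DonorCandidate] = []
    for animal in candidates:
        herd = natal_herd(animal)
        if animal in genotyped:
            grp = _individual_group(animal, memberships, threshold)
            out.append(
                DonorCandidate(
                    animal, herd, True, "direct", grp, 1,
                    "own genotype; individual q rule",
                )
            )
            continue
        rec = ped_by_animal.get(animal)
        parent_evidence: list[str] | None = None
        note = ""
        if rec is not None:
            parents = [p for p in (rec.sire, rec.dam) if p is not None]
            gen_parents = [p for p in parents if p in genotyped]
            if gen_parents:
                parent_evidence = gen_parents
                note = f"genotyped parents: {', '.join(gen_parents)}"
            else:
                gps: list[str] = []
                for p in parents:
                    pr = ped_by_animal.get(p)
                    if pr is not None:
                        gps.extend(
                            x for x in (pr.sire, pr.dam)
                            if x is not None and x in genotyped
                        )
                if gps:
                    parent_evidence = gps
                    note = f"genotyped grandparents: {', '.join(gps)}"
        if parent_evidence:
            groups = [
                _individual_group(p, memberships, threshold) for p in parent_evidence
            ]
            out.append(
                DonorCandidate(
                    animal, herd, False, "pedigree",
                    _common_group(groups), 2, note,
                )
            )
            continue
        # network-only presumption
        if herd is not None and (herd in herd_group or herd in g.graph):
            grp = herd_group.get(herd, UNASSIGNED)
            note = f"natal herd {herd} group"
            if grp == UNASSIGNED and herd in g.graph:
                votes: dict[int | str, int] = {}
                for nb in g.graph.neighbors(herd):
                    nb_grp = herd_group.get(nb, UNASSIGNED)
                    if nb_grp != UNASSIGNED:
                        votes[nb_grp] = votes.get(nb_grp, 0) + 1
                if votes:
                    best = max(votes.values())
                    winners = [k for k, v in votes.items() if v == best]
                    grp = winners[0] if len(winners) == 1 else UNASSIGNED
                    note = f"majority group among exchange partners of {herd}"
            out.append(DonorCandidate(animal, herd, False, "network", grp, 3, note))
            continue
        out.append(
            DonorCandidate(
                animal, herd, False, "none", UNKNOWN_GROUP, None,
                "uncharacterizable: no genotype, pedigree or network evidence",
            )
        )

    return _round_robin_rank(out)


def _round_robin_rank(cands: list[DonorCandidate]) -> list[DonorCandidate]:
    """Tier-ascending order; within a tier, cycle over genetic groups so
    per-group counts never differ by more than one."""
    ranked: list[DonorCandidate] = []
    for tier in (1, 2, 3):
        pool = [c for c in cands if c.tier == tier]
        by_group: dict[int | str, list[DonorCandidate]] = {}
        for c in pool:
            by_group.setdefault(c.assigned_group, []).append(c)
        # real groups first (stable by group index), UNASSIGNED last
        keys = sorted(
            by_group, key=lambda k: (isinstance(k, str), k if isinstance(k, int) else 0)
        )
        queues = [by_group[k] for k in keys]
        while any(queues):
            for qx in queues:
                if qx:
                    ranked.append(qx.pop(0))
    ranked.extend(c for c in cands if c.tier is None)
    return ranked


def tier_summary(ranked: Sequence[DonorCandidate]) -> dict:
    """Per-tier / per-group counts for reporting."""
    out: dict = {"tiers": {}, "groups": {}}
    for c in ranked:
        t = str(c.tier) if c.tier is not None else "uncharacterizable"
        out["tiers"][t] = out["tiers"].get(t, 0) + 1
        gkey = str(c.assigned_group)
        out["groups"][gkey] = out["groups"].get(gkey, 0) + 1
    return out
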