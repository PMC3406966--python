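"""Per-locus and per-population microsatellite diversity statistics.

Covers the classical within-population toolbox: observed and unbiased
expected heterozygosity, the Weir–Cockerham small-sample inbreeding
coefficient f (Fis), rarefied allelic richness, the Guo–Thompson
Markov-chain exact test for Hardy–Weinberg equilibrium, Bonferroni
correction, and a homozygote-excess null-allele screen (Brookfield
estimator 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genio import MISSING, GenotypeTable

__all__ = [
    "AlleleFreqs",
    "LocusStats",
    "RichnessResult",
    "HweResult",
    "resolve_partition",
    "allele_frequencies",
    "per_locus_stats",
    "unit_summary",
    "allelic_richness",
    "hwe_exact_test",
    "bonferroni_adjust",
    "null_allele_estimate",
]


@dataclass
class AlleleFreqs:
    """Allele counts at one locus in one unit."""

    counts: dict[int, int]  # allele code -> gene count
    n_genes: int

    @property
    def freqs(self) -> dict[int, float]:
        return {a: c / self.n_genes for a, c in self.counts.items()}


@dataclass
class LocusStats:
    locus: str
    n_ind: int
    n_alleles: int
    Ho: float
    He: float
    Fis: float | None
    hwe_p: float | None = None


@dataclass
class RichnessResult:
    unit: str
    g: int
    AR_value: float
    per_locus: dict[str, float]


@dataclass
class HweResult:
    p: float | None
    se: float | None
    reason: str | None = None


def resolve_partition(
    gt: GenotypeTable, partition: str | Mapping[str, str]
) -> dict[str, list[int]]:
    """Resolve a partition spec into unit -> row indices.

    *partition* is ``"herd"`` (birth herd; unknown-birth animals dropped),
    ``"breed"``, or an explicit animal -> unit mapping (animals absent
    from the mapping are dropped).
    """
    out: dict[str, list[int]] = {}
    if partition == "herd":
        return gt.herd_members()
    if partition == "breed":
        for i, ind in enumerate(gt.individuals):
            out.setdefault(gt.breed[ind], []).append(i)
        return out
    for i, ind in enumerate(gt.individuals):
        u = partition.get(ind)
        if u is not None:
            out.setdefault(u, []).append(i)
    return out


def allele_frequencies(
    gt: GenotypeTable, partition: str | Mapping[str, str]
) -> dict[str, dict[str, AlleleFreqs | None]]:
    """Allele counts/frequencies per unit per locus.

    A unit with zero typed individuals at a locus yields ``None`` (NA),
    never a zero-frequency table.
    """
    units = resolve_partition(gt, partition)
    out: dict[str, dict[str, AlleleFreqs | None]] = {}
    for unit, rows in units.items():
        sub = gt.calls[rows]  # (n, L, 2)
        per_locus: dict[str, AlleleFreqs | None] = {}
        for j, loc in enumerate(gt.loci):
            genes = sub[:, j, :].ravel()
            genes = genes[genes != MISSING]
            if genes.size == 0:
                per_locus[loc] = None
                continue
            vals, cnts = np.unique(genes, return_counts=True)
            per_locus[loc] = AlleleFreqs(
                {int(a): int(c) for a, c in zip(vals, cnts)}, int(genes.size)
            )
        out[unit] = per_locus
    return out


def _locus_genotypes(gt: GenotypeTable, rows: Sequence[int], j: int) -> np.ndarray:
    """Fully typed genotype pairs (n, 2) at locus column j."""
    sub = gt.calls[list(rows)][:, j, :]
    ok = (sub != MISSING).all(axis=1)
    return sub[ok]


def _wc_f_components(pairs: np.ndarray) -> tuple[float, float]:
    """Weir–Cockerham within-population variance components (sum_b, sum_c)
    over alleles at one locus.  f = 1 - sum_c / (sum_b + sum_c)."""
    n = pairs.shape[0]
    alleles = np.unique(pairs)
    sum_b = sum_c = 0.0
    for a in alleles:
        is_a = pairs == a
        p = is_a.mean()
        het = float(((is_a.sum(axis=1) == 1)).mean())  # heterozygous for a
        b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * het)
        c = het / 2.0
        sum_b += b
        sum_c += c
    return sum_b, sum_c


def per_locus_stats(
    gt: GenotypeTable,
    partition: str | Mapping[str, str],
    fis_method: str = "weir-cockerham",
) -> dict[str, list[LocusStats]]:
    """Ho, unbiased He and Fis per locus for each unit.

    He is Nei's unbiased estimator ``(2n/(2n-1)) * (1 - sum p_i^2)``.
    Fis defaults to the Weir–Cockerham small-sample f; ``fis_method="naive"``
    gives 1 - Ho/He for cross-checking.  Monomorphic loci report
    Ho = He = 0 and Fis = None.
    """
    if fis_method not in ("weir-cockerham", "naive"):
        raise ValueError(f"unknown fis_method {fis_method!r}")
    units = resolve_partition(gt, partition)
    out: dict[str, list[LocusStats]] = {}
    for unit, rows in units.items():
        stats = []
        for j, loc in enumerate(gt.loci):
            pairs = _locus_genotypes(gt, rows, j)
            n = pairs.shape[0]
            if n == 0:
                stats.append(LocusStats(loc, 0, 0, math.nan, math.nan, None))
                continue
            alleles, counts = np.unique(pairs, return_counts=True)
            k = alleles.size
            if k == 1:
                stats.append(LocusStats(loc, n, 1, 0.0, 0.0, None))
                continue
            ho = float((pairs[:, 0] != pairs[:, 1]).mean())
            p = counts / (2.0 * n)
            he = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - float(np.sum(p**2)))
            if fis_method == "naive":
                fis = 1.0 - ho / he if he > 0 else None
            else:
                sum_b, sum_c = _wc_f_components(pairs)
                denom = sum_b + sum_c
                fis = 1.0 - sum_c / denom if denom > 0 else None
            stats.append(LocusStats(loc, n, k, ho, he, fis))
        out[unit] = stats
    return out


def unit_summary(stats: Sequence[LocusStats]) -> dict[str, float]:
    """Multi-locus summary: unweighted means over polymorphic loci."""
    poly = [s for s in stats if s.n_alleles >= 2]
    if not poly:
        return {"Ho": 0.0, "He": 0.0, "mean_alleles": 1.0, "n_loci": 0}
    return {
        "Ho": float(np.mean([s.Ho for s in poly])),
        "He": float(np.mean([s.He for s in poly])),
        "mean_alleles": float(np.mean([s.n_alleles for s in stats if s.n_ind > 0])),
        "n_loci": len(poly),
    }


# ---------------------------------------------------------------------------
# Allelic richness (rarefaction)
# ---------------------------------------------------------------------------

def _rarefied_alleles(counts: np.ndarray, g: int) -> float:
    """Expected distinct alleles in a random g-gene subsample (hypergeometric)."""
    total = int(counts.sum())
    if g > total:
        raise ValueError(f"rarefaction size g={g} exceeds gene count {total}")
    # 1 - C(total - Na, g) / C(total, g) per allele, in log space for stability
    out = 0.0
    log_denom = math.lgamma(total + 1) - math.lgamma(g + 1) - math.lgamma(total - g + 1)
    for na in counts:
        rem = total - int(na)
        if rem < g:
            out += 1.0
        else:
            log_num = (
                math.lgamma(rem + 1) - math.lgamma(g + 1) - math.lgamma(rem - g + 1)
            )
            out += 1.0 - math.exp(log_num - log_denom)
    return out


def allelic_richness(
    gt: GenotypeTable,
    partition: str | Mapping[str, str],
    g: int | None = None,
) -> list[RichnessResult]:
    """Mean rarefied allele count per locus for each unit.

    *g* is the rarefaction size in genes; by default the smallest gene
    count over all (unit, locus) cells with data — the convention that
    makes richness comparable across unequal sample sizes.
    """
    freqs = allele_frequencies(gt, partition)
    gene_counts = [
        af.n_genes for per_locus in freqs.values() for af in per_locus.values()
        if af is not None
    ]
    if not gene_counts:
        raise ValueError("no typed data in any unit")
    if g is None:
        g = min(gene_counts)
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    results = []
    for unit, per_locus in freqs.items():
        vals: dict[str, float] = {}
        for loc, af in per_locus.items():
            if af is None or af.n_genes < g:
                continue
            vals[loc] = _rarefied_alleles(
                np.array(list(af.counts.values()), dtype=np.int64), g
            )
        if vals:
            results.append(
                RichnessResult(unit, g, float(np.mean(list(vals.values()))), vals)
            )
    return results


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (Guo & Thompson Markov chain)
# ---------------------------------------------------------------------------

def _log_table_weight(geno_counts: np.ndarray) -> float:
    """log of the non-constant part of P(genotype table | allele counts):
    H*log2 - sum log(n_ab!) over unordered genotype cells."""
    a_idx, b_idx = np.nonzero(np.triu(geno_counts + geno_counts.T))
    w = 0.0
    for a, b in zip(a_idx, b_idx):
        nab = geno_counts[a, b] + (geno_counts[b, a] if a != b else 0)
        if a != b:
            w += nab * math.log(2.0) - math.lgamma(nab + 1)
        else:
            w += -math.lgamma(nab + 1)
    return w


def hwe_exact_test(
    gt: GenotypeTable,
    partition: str | Mapping[str, str],
    unit: str,
    locus: str,
    batches: int = 100,
    iters_per_batch: int = 5000,
    dememorization: int = 10000,
    seed: int | None = None,
) -> HweResult:
    """Markov-chain estimate of the exact probability test for HWE.

    Runs the Guo–Thompson allele-swapping chain over genotype tables with
    the observed allele counts.  The p-value is the stationary probability
    of tables no more probable than the observed one; its Monte-Carlo
    standard error is estimated across batches.  Fully seeded.
    """
    units = resolve_partition(gt, partition)
    if unit not in units:
        raise ValueError(f"unknown unit {unit!r}")
    j = gt.loci.index(locus)
    pairs = _locus_genotypes(gt, units[unit], j)
    n = pairs.shape[0]
    if n < 2:
        return HweResult(None, None, "fewer than 2 typed individuals")
    alleles = np.unique(pairs)
    if alleles.size < 2:
        return HweResult(None, None, "monomorphic locus")
    recode = {int(a): i for i, a in enumerate(alleles)}
    genos = np.array([[recode[int(a)] for a in row] for row in pairs], dtype=np.int64)

    rng = np.random.default_rng(seed)
    A = alleles.size
    counts = np.zeros((A, A), dtype=np.int64)
    for a, b in genos:
        counts[min(a, b), max(a, b)] += 1
    log_obs = _log_table_weight(counts)

    # Chain state: the arrangement of the 2N genes into N slot pairs, plus
    # cell counts and a running log table weight.  Given the allele counts,
    # HWE makes every gene arrangement equally likely, so the target on
    # this state space is uniform: every proposed cross-individual swap is
    # accepted, and the walk's table marginal is the exact conditional
    # distribution.  The table weight (with its count factorials) is only
    # used to compare visited tables against the observed one.
    cur = genos.copy()
    cur_counts = counts.copy()
    log_cur = log_obs
    log2 = math.log(2.0)

    def cell(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a <= b else (b, a)

    def remove_weight(a: int, b: int) -> float:
        # change in log table weight from removing one (a,b) genotype
        ca, cb = cell(a, b)
        nab = cur_counts[ca, cb]
        d = math.log(nab)
        if a != b:
            d -= log2
        cur_counts[ca, cb] -= 1
        return d

    def add_weight(a: int, b: int) -> float:
        ca, cb = cell(a, b)
        cur_counts[ca, cb] += 1
        nab = cur_counts[ca, cb]
        d = -math.log(nab)
        if a != b:
            d += log2
        return d

    def step() -> None:
        nonlocal log_cur
        i1, i2 = rng.integers(0, n), rng.integers(0, n)
        if i1 == i2:
            return
        s1, s2 = rng.integers(0, 2), rng.integers(0, 2)
        a_keep, a_swap = cur[i1, 1 - s1], cur[i1, s1]
        b_keep, b_swap = cur[i2, 1 - s2], cur[i2, s2]
        if a_swap == b_swap:
            return
        d = 0.0
        d += remove_weight(cur[i1, 0], cur[i1, 1])
        d += remove_weight(cur[i2, 0], cur[i2, 1])
        d += add_weight(a_keep, b_swap)
        d += add_weight(b_keep, a_swap)
        cur[i1, s1] = b_swap
        cur[i2, s2] = a_swap
        log_cur += d

    for _ in range(dememorization):
        step()
    tol = 1e-9
    batch_means = np.empty(batches)
    for b in range(batches):
        hits = 0
        for _ in range(iters_per_batch):
            step()
            if log_cur <= log_obs + tol:
                hits += 1
        batch_means[b] = hits / iters_per_batch
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(batches)) if batches > 1 else None
    return HweResult(max(p, 1.0 / (batches * iters_per_batch)), se, None)


def bonferroni_adjust(pvalues: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Flag test i significant iff p_i <= alpha / m (m = number of tests)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = len(pvalues)
    if m == 0:
        return []
    return [p <= alpha / m for p in pvalues]


def null_allele_estimate(
    gt: GenotypeTable,
    partition: str | Mapping[str, str],
    unit: str,
    locus: str,
    threshold: float = 0.05,
) -> tuple[float | None, bool]:
    """Brookfield estimator 1 of null-allele frequency, r = (He-Ho)/(1+He).

    Returns (r, suspected); a locus is suspected when r exceeds *threshold*
    and Ho < He.  Monomorphic loci return (None, False).
    """
    stats = per_locus_stats(gt, partition)[unit]
    s = next(x for x in stats if x.locus == locus)
    if s.n_alleles < 2:
        return None, False
    r = (s.He - s.Ho) / (1.0 + s.He)
    return r, bool(r > threshold and s.Ho < s.He)
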