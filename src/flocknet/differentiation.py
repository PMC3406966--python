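"""Genetic differentiation: Weir–Cockerham Fst and Reynolds coancestry distances.

The multilocus Fst is the Weir–Cockerham (1984) variance-component theta,
with a leave-one-locus-out jackknife for its standard deviation.  Pairwise
herd distances are coancestry estimates in the Reynolds (1983) family,
reported as D_r = -ln(1 - theta_hat), the form linear in drift time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genio import MISSING, GenotypeTable
from .diversity import resolve_partition

__all__ = [
    "FstResult",
    "PairwiseHerdMatrix",
    "wc_fst",
    "fst_jackknife",
    "reynolds_theta",
    "reynolds_matrix",
]


@dataclass
class FstResult:
    units: list[str]
    theta: float
    sd_jackknife: float | None
    per_locus: dict[str, float | None]
    # per-locus summed variance components (a, a+b+c), for jackknifing
    components: dict[str, tuple[float, float]]


@dataclass
class PairwiseHerdMatrix:
    """Symmetric herd x herd matrix with aligned ordering.

    *kind* is ``"reynolds"`` (genetic distance), ``"theta"`` (raw
    coancestry) or ``"spl"`` (shortest path length).
    """

    herds: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.herds)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match herd list")

    def reorder(self, herds: Sequence[str]) -> "PairwiseHerdMatrix":
        idx = [self.herds.index(h) for h in herds]
        return PairwiseHerdMatrix(
            list(herds), self.values[np.ix_(idx, idx)].copy(), self.kind
        )


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------

def _locus_components(
    calls: np.ndarray, unit_rows: Sequence[Sequence[int]], j: int
) -> tuple[float, float] | None:
    """Summed (a, a+b+c) variance components over alleles at locus column j.

    Returns None when fewer than two units have typed individuals or the
    locus is monomorphic across units.
    """
    pops = []
    for rows in unit_rows:
        sub = calls[list(rows)][:, j, :]
        ok = (sub != MISSING).all(axis=1)
        if ok.sum() > 0:
            pops.append(sub[ok])
    r = len(pops)
    if r < 2:
        return None
    alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
    if alleles.size < 2:
        return None
    n_i = np.array([p.shape[0] for p in pops], dtype=float)
    n_sum = n_i.sum()
    n_bar = n_sum / r
    n_c = (n_sum - (n_i**2).sum() / n_sum) / (r - 1.0)
    sum_a = sum_abc = 0.0
    for al in alleles:
        p_i = np.array([(p == al).mean() for p in pops])
        h_i = np.array([((p == al).sum(axis=1) == 1).mean() for p in pops])
        p_bar = float((n_i * p_i).sum() / n_sum)
        s2 = float((n_i * (p_i - p_bar) ** 2).sum() / ((r - 1.0) * n_bar))
        h_bar = float((n_i * h_i).sum() / n_sum)
        if n_bar <= 1:
            return None
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
        sum_a += a
        sum_abc += a + b + c
    return sum_a, sum_abc


def wc_fst(gt: GenotypeTable, partition: str | Mapping[str, str]) -> FstResult:
    """Multilocus Weir–Cockerham theta over the given partition.

    Per-locus variance components are summed over alleles; the multilocus
    estimate is sum(a) / sum(a+b+c) over loci and alleles.  Loci that are
    monomorphic across all units contribute nothing (skipped).
    """
    units = resolve_partition(gt, partition)
    if len(units) < 2:
        raise ValueError("Fst needs at least two units")
    unit_rows = list(units.values())
    per_locus: dict[str, float | None] = {}
    components: dict[str, tuple[float, float]] = {}
    num = den = 0.0
    for j, loc in enumerate(gt.loci):
        comp = _locus_components(gt.calls, unit_rows, j)
        if comp is None:
            per_locus[loc] = None
            continue
        a, abc = comp
        components[loc] = comp
        per_locus[loc] = a / abc if abc != 0 else None
        num += a
        den += abc
    if den == 0:
        raise ValueError("no informative loci for Fst")
    return FstResult(list(units), num / den, None, per_locus, components)


def fst_jackknife(gt: GenotypeTable, partition: str | Mapping[str, str]) -> FstResult:
    """Weir–Cockerham theta with delete-one-locus jackknife standard deviation.

    sd = sqrt( (L-1)/L * sum (theta_(-i) - mean theta_(-.))^2 ) over the L
    informative loci.  Requires at least three such loci.
    """
    res = wc_fst(gt, partition)
    comps = list(res.components.values())
    L = len(comps)
    if L < 3:
        raise ValueError("jackknife needs at least 3 informative loci")
    tot_a = sum(a for a, _ in comps)
    tot_abc = sum(abc for _, abc in comps)
    leave_out = np.array(
        [(tot_a - a) / (tot_abc - abc) for a, abc in comps if tot_abc - abc != 0]
    )
    mean_lo = leave_out.mean()
    sd = math.sqrt((L - 1.0) / L * float(((leave_out - mean_lo) ** 2).sum()))
    res.sd_jackknife = sd
    return res


# ---------------------------------------------------------------------------
# Reynolds coancestry distance
# ---------------------------------------------------------------------------

def _pair_locus_terms(p1: np.ndarray, p2: np.ndarray) -> tuple[float, float] | None:
    """Per-locus (numerator, denominator) of the coancestry moment estimator
    for one pair of herds; p_i are fully typed genotype arrays (n_i, 2)."""
    n1, n2 = p1.shape[0], p2.shape[0]
    if n1 == 0 or n2 == 0:
        return None
    alleles = np.unique(np.concatenate([p1.ravel(), p2.ravel()]))
    if alleles.size < 2:
        return None
    f1 = np.array([(p1 == a).mean() for a in alleles])
    f2 = np.array([(p2 == a).mean() for a in alleles])
    ssq = float(((f1 - f2) ** 2).sum())
    # unbiased gene diversity per herd: (2n/(2n-1)) (1 - sum p^2)
    g1 = (2 * n1 / (2 * n1 - 1.0)) * (1.0 - float((f1**2).sum()))
    g2 = (2 * n2 / (2 * n2 - 1.0)) * (1.0 - float((f2**2).sum()))
    num = 0.5 * (ssq - g1 / (2.0 * n1) - g2 / (2.0 * n2))
    den = num + 0.5 * (g1 + g2)
    return num, den


def reynolds_theta(
    gt: GenotypeTable, rows_a: Sequence[int], rows_b: Sequence[int]
) -> float | None:
    """Multilocus coancestry theta_hat for two sets of individuals.

    Moment estimator in the Reynolds–Weir–Cockerham family: per locus,
    numerator = (1/2)[sum_u (p1u - p2u)^2 - h1/(2 n1) - h2/(2 n2)] and
    denominator = numerator + (h1 + h2)/2, with h the unbiased gene
    diversity; loci combined by summing numerators and denominators.
    Returns None when no shared polymorphic locus exists.
    """
    num = den = 0.0
    any_locus = False
    for j in range(gt.n_loci):
        pa = gt.calls[list(rows_a)][:, j, :]
        pb = gt.calls[list(rows_b)][:, j, :]
        pa = pa[(pa != MISSING).all(axis=1)]
        pb = pb[(pb != MISSING).all(axis=1)]
        terms = _pair_locus_terms(pa, pb)
        if terms is None:
            continue
        any_locus = True
        num += terms[0]
        den += terms[1]
    if not any_locus or den == 0:
        return None
    return num / den


def reynolds_matrix(
    gt: GenotypeTable,
    herds: Sequence[str] | None = None,
    min_animals: int = 5,
    kind: str = "reynolds",
) -> PairwiseHerdMatrix:
    """Pairwise herd matrix of Reynolds distances D_r = -ln(1 - theta_hat).

    Only herds with at least *min_animals* genotyped animals are included
    (pass ``min_animals=1`` to disable).  Negative theta_hat is truncated
    to 0 before the log transform; ``kind="theta"`` returns the truncated
    theta_hat itself.  Pairs sharing no typed polymorphic locus are NaN.
    """
    if kind not in ("reynolds", "theta"):
        raise ValueError(f"unknown kind {kind!r}")
    members = gt.herd_members()
    if herds is None:
        herds = [h for h in gt.herds() if len(members[h]) >= min_animals]
    else:
        for h in herds:
            if h not in members:
                raise ValueError(f"herd {h!r} has no genotyped animals")
            if len(members[h]) < min_animals:
                raise ValueError(
                    f"herd {h!r} has {len(members[h])} genotyped animals, "
                    f"fewer than min_animals={min_animals}"
                )
    herds = list(herds)
    n = len(herds)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            th = reynolds_theta(gt, members[herds[i]], members[herds[j]])
            if th is None:
                v = math.nan
            else:
                th = min(max(th, 0.0), 1.0 - 1e-12)
                v = th if kind == "theta" else -math.log(1.0 - th)
            vals[i, j] = vals[j, i] = v
    return PairwiseHerdMatrix(herds, vals, kind)
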