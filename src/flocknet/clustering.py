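"""Bayesian admixture clustering of multilocus genotypes.

A Gibbs sampler over the admixture model with independent allele
frequencies: each cluster k carries its own allele-frequency vector per
locus (Dirichlet(lambda) prior), each individual a membership vector q
over the K clusters (Dirichlet(alpha) prior, alpha updated by a
Metropolis step with a uniform prior on (0, 10]), and every allele copy
an unobserved cluster of origin sampled conditionally.  The reported q
is the posterior mean over post-burn-in sweeps; the model log-probability
lnP uses the conventional mean(lnL) - var(lnL)/2 estimator.

Model-order selection follows the second-difference criterion
Delta K = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)) over
replicate runs; herds are assigned to genetic groups when their mean
membership to one cluster reaches the 0.7 threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeTable

__all__ = [
    "MembershipMatrix",
    "RunResult",
    "GroupAssignment",
    "UNASSIGNED",
    "admixture_gibbs",
    "run_k_range",
    "align_runs",
    "mean_membership",
    "evanno_delta_k",
    "herd_membership",
    "assign_groups",
]

#: Sentinel group for herds/animals whose best membership stays below threshold.
UNASSIGNED = "UNASSIGNED"


@dataclass
class MembershipMatrix:
    individuals: list[str]
    K: int
    q: np.ndarray  # (n, K), rows on the simplex

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.individuals), self.K):
            raise ValueError("q shape mismatch")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("q rows must sum to 1")
        if (self.q < -1e-12).any():
            raise ValueError("q must be non-negative")


@dataclass
class RunResult:
    K: int
    seed: int
    lnP: float
    membership: MembershipMatrix
    alpha: float


@dataclass
class GroupAssignment:
    herd: str
    q_bar: np.ndarray
    group: int | str  # cluster index (0-based) or UNASSIGNED


def _recode(gt: GenotypeTable) -> tuple[np.ndarray, list[int]]:
    """Allele codes -> per-locus 0-based indices; MISSING -> -1."""
    idx = np.full_like(gt.calls, -1)
    sizes = []
    for j in range(gt.n_loci):
        col = gt.calls[:, j, :]
        alleles = np.unique(col[col != MISSING])
        sizes.append(len(alleles))
        lut = {int(a): i for i, a in enumerate(alleles)}
        for a, i in lut.items():
            idx[:, j, :][col == a] = i
    return idx, sizes


def _dirichlet_rows(rng: np.random.Generator, conc: np.ndarray) -> np.ndarray:
    g = rng.gamma(conc)
    s = g.sum(axis=-1, keepdims=True)
    # guard against all-zero gamma draws at tiny concentrations
    bad = (s == 0).ravel()
    if bad.any():
        g[bad] = 1.0 / conc.shape[-1]
        s = g.sum(axis=-1, keepdims=True)
    return g / s


def admixture_gibbs(
    gt: GenotypeTable,
    K: int,
    burnin: int = 10_000,
    iters: int = 10_000,
    seed: int | None = None,
    alpha0: float = 1.0,
    lambda_: float = 1.0,
    alpha_prop_sd: float = 0.25,
    alpha_max: float = 10.0,
) -> RunResult:
    """One MCMC run of the admixture model at fixed K.

    No prior population labels are used.  Same seed and parameters give
    bit-identical results.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gt.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    rng = np.random.default_rng(seed)
    calls, allele_counts = _recode(gt)
    n, L = gt.n_individuals, gt.n_loci
    valid = calls >= 0  # (n, L, 2)

    if K == 1:
        # degenerate simplex: q is exactly [1.0]; lnP from the same estimator
        q = np.ones((n, 1))
        lnls = []
        for _ in range(max(iters // 10, 1)):
            lnl = 0.0
            for j in range(L):
                cj = calls[:, j, :][valid[:, j, :]]
                if cj.size == 0:
                    continue
                cnt = np.bincount(cj, minlength=allele_counts[j])
                p = rng.gamma(lambda_ + cnt)
                p /= p.sum()
                lnl += float(np.log(p[cj]).sum())
            lnls.append(lnl)
        lnls = np.array(lnls)
        lnp = float(lnls.mean() - lnls.var(ddof=1) / 2.0) if len(lnls) > 1 else float(lnls.mean())
        return RunResult(1, seed if seed is not None else -1,
                         lnp, MembershipMatrix(list(gt.individuals), 1, q), alpha0)

    # latent origins
    z = rng.integers(0, K, size=(n, L, 2))
    z[~valid] = -1
    alpha = alpha0
    q_sum = np.zeros((n, K))
    lnls: list[float] = []
    n_alpha_reject_stretch = 0

    log_gamma = math.lgamma

    def alpha_logdens(a: float, qmat: np.ndarray) -> float:
        # product of symmetric Dirichlet densities over individuals
        logq = np.log(np.clip(qmat, 1e-300, None)).sum()
        return n * (log_gamma(K * a) - K * log_gamma(a)) + (a - 1.0) * logq

    for sweep in range(burnin + iters):
        # cluster allele frequencies P | Z
        P = []
        for j in range(L):
            vj = valid[:, j, :]
            zj = z[:, j, :][vj]
            aj = calls[:, j, :][vj]
            cnt = np.zeros((K, allele_counts[j]))
            np.add.at(cnt, (zj, aj), 1.0)
            P.append(_dirichlet_rows(rng, lambda_ + cnt))
        # memberships Q | Z
        m = np.zeros((n, K))
        flat_i = np.broadcast_to(np.arange(n)[:, None, None], (n, L, 2))
        zi = z[valid]
        np.add.at(m, (flat_i[valid], zi), 1.0)
        q = _dirichlet_rows(rng, alpha + m)
        # origins Z | P, Q  and complete-data log-likelihood
        lnl = 0.0
        for j in range(L):
            Pj = P[j]
            for c in range(2):
                vj = valid[:, j, c]
                if not vj.any():
                    continue
                a = calls[vj, j, c]
                w = q[vj] * Pj[:, a].T  # (nv, K)
                tot = w.sum(axis=1)
                lnl += float(np.log(tot).sum())
                u = rng.random(w.shape[0]) * tot
                z[vj, j, c] = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
        # alpha | Q (Metropolis, uniform prior on (0, alpha_max])
        prop = alpha + rng.normal(0.0, alpha_prop_sd)
        if 0.0 < prop <= alpha_max:
            logr = alpha_logdens(prop, q) - alpha_logdens(alpha, q)
            if logr >= 0 or math.log(rng.random()) < logr:
                alpha = prop
                n_alpha_reject_stretch = 0
            else:
                n_alpha_reject_stretch += 1
        else:
            n_alpha_reject_stretch += 1
        if n_alpha_reject_stretch == 2000:
            warnings.warn("alpha update rejected 2000 times in a row", stacklevel=2)
        if sweep >= burnin:
            q_sum += q
            lnls.append(lnl)

    q_mean = q_sum / iters
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    arr = np.array(lnls)
    lnp = float(arr.mean() - arr.var(ddof=1) / 2.0) if len(arr) > 1 else float(arr.mean())
    return RunResult(
        K, seed if seed is not None else -1, lnp,
        MembershipMatrix(list(gt.individuals), K, q_mean), alpha,
    )


def run_k_range(
    gt: GenotypeTable,
    k_values: Sequence[int],
    runs_per_k: int = 10,
    burnin: int = 10_000,
    iters: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> list[RunResult]:
    """Replicate runs across a K range; child seeds derive from *seed*."""
    out = []
    for k in k_values:
        for r in range(runs_per_k):
            child = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(k, r)).generate_state(1)[0]
                % (2**31)
            )
            out.append(admixture_gibbs(gt, k, burnin, iters, child, **kwargs))
    return out


def align_runs(runs: Sequence[RunResult]) -> list[np.ndarray]:
    """Align cluster labels across runs at one K.

    Greedy matching on q-column correlation against the first run: the
    highest-correlation (reference column, run column) pair is matched
    first, then the next among the remainder, and so on.
    """
    if not runs:
        return []
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("all runs must share the same K")
    ref = runs[0].membership.q
    out = [ref.copy()]
    for run in runs[1:]:
        q = run.membership.q
        if K == 1:
            out.append(q.copy())
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(ref.T, q.T)[:K, K:]
        corr = np.nan_to_num(corr, nan=-2.0)
        perm = np.full(K, -1)
        used_ref, used_run = set(), set()
        for _ in range(K):
            best, bi, bj = -np.inf, -1, -1
            for i in range(K):
                if i in used_ref:
                    continue
                for jj in range(K):
                    if jj in used_run:
                        continue
                    if corr[i, jj] > best:
                        best, bi, bj = corr[i, jj], i, jj
            perm[bi] = bj
            used_ref.add(bi)
            used_run.add(bj)
        out.append(q[:, perm].copy())
    return out


def mean_membership(runs: Sequence[RunResult]) -> MembershipMatrix:
    """Label-aligned average q over replicate runs at one K."""
    aligned = align_runs(runs)
    q = np.mean(aligned, axis=0)
    q /= q.sum(axis=1, keepdims=True)
    return MembershipMatrix(list(runs[0].membership.individuals), runs[0].K, q)


def evanno_delta_k(runs: Sequence[RunResult]) -> pd.DataFrame:
    """Second-difference model-order criterion over replicate runs.

    Returns a frame with columns K, n_runs, mean_lnP, sd_lnP, delta_k;
    delta_k is NaN at the K-range endpoints and +inf (with a warning)
    when sd(lnP) is zero at an interior K.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.lnP)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range of length >= 3")
    for k, v in by_k.items():
        if len(v) < 2:
            raise ValueError(f"need >= 2 runs at K={k}")
    mean = {k: float(np.mean(v)) for k, v in by_k.items()}
    sd = {k: float(np.std(v, ddof=1)) for k, v in by_k.items()}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            dk = math.nan
        else:
            num = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1])
            if sd[k] == 0:
                warnings.warn(f"sd(lnP)=0 at K={k}; delta K infinite", stacklevel=2)
                dk = math.inf
            else:
                dk = num / sd[k]
        rows.append(
            {"K": k, "n_runs": len(by_k[k]), "mean_lnP": mean[k],
             "sd_lnP": sd[k], "delta_k": dk}
        )
    return pd.DataFrame(rows)


def best_k(delta_table: pd.DataFrame) -> int:
    """argmax Delta K over interior K values (a suggestion, never forced)."""
    interior = delta_table.dropna(subset=["delta_k"])
    return int(interior.loc[interior["delta_k"].idxmax(), "K"])


def herd_membership(
    membership: MembershipMatrix, herd_of_birth: Mapping[str, str | None]
) -> dict[str, np.ndarray]:
    """Unweighted herd means q_bar of member individuals' q vectors."""
    idx: dict[str, list[int]] = {}
    for i, ind in enumerate(membership.individuals):
        h = herd_of_birth.get(ind)
        if h is not None:
            idx.setdefault(h, []).append(i)
    return {h: membership.q[rows].mean(axis=0) for h, rows in idx.items()}


def assign_groups(
    q_bars: Mapping[str, np.ndarray], threshold: float = 0.7
) -> list[GroupAssignment]:
    """Assign herds to genetic groups by the max-q_bar >= threshold rule.

    Herds sharing a winning cluster form one genetic group.  Output is
    ordered by decreasing max q_bar (assigned herds first); exact ties at
    or above threshold resolve to the lowest cluster index.
    """
    out = []
    for herd, qb in q_bars.items():
        qb = np.asarray(qb, float)
        top = float(qb.max())
        group: int | str = int(qb.argmax()) if top >= threshold else UNASSIGNED
        out.append(GroupAssignment(herd, qb, group))
    out.sort(key=lambda a: (a.group == UNASSIGNED, -float(a.q_bar.max())))
    return out
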