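import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from flocknet.differentiation import (
    fst_jackknife,
    reynolds_matrix,
    reynolds_theta,
    wc_fst,
)
from flocknet.synthetic import SimConfig, simulate_scenario
from conftest import make_table, random_table


# --------------------------- Weir–Cockerham Fst ---------------------------

def test_fixed_units_theta_near_one():
    rows = [[(1, 1)] * 3] * 40 + [[(2, 2)] * 3] * 40
    herds = ["A"] * 40 + ["B"] * 40
    gt = make_table(rows, herds=herds)
    assert wc_fst(gt, "herd").theta > 0.98


def test_null_split_theta_near_zero():
    rng = np.random.default_rng(17)
    gt = random_table(rng, n_ind=200, n_loci=8, n_pops=1, n_alleles=5)
    half = {ind: ("A" if i < 100 else "B") for i, ind in enumerate(gt.individuals)}
    assert abs(wc_fst(gt, half).theta) < 0.02


def _wc_oracle(pop_pairs):
    """Independently coded Weir–Cockerham variance components, one locus.

    pop_pairs: list (one per population) of genotype pair lists.
    Returns (sum_a, sum_abc) over alleles.
    """
    r = len(pop_pairs)
    n = [len(p) for p in pop_pairs]
    nsum = sum(n)
    nbar = nsum / r
    nc = (nsum - sum(x * x for x in n) / nsum) / (r - 1)
    alleles = sorted({g for pop in pop_pairs for pair in pop for g in pair})
    sa = sabc = 0.0
    for al in alleles:
        p = [sum(pair.count(al) for pair in pop) / (2 * len(pop)) for pop in pop_pairs]
        h = [
            sum(1 for pair in pop if (pair[0] == al) != (pair[1] == al)) / len(pop)
            for pop in pop_pairs
        ]
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / nsum
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sa += a
        sabc += a + b + c
    return sa, sabc


def test_wc_fst_against_independent_oracle():
    rng = np.random.default_rng(23)
    for _ in range(20):
        gt = random_table(rng, n_ind=18, n_loci=4, n_pops=3, n_alleles=4)
        res = wc_fst(gt, "herd")
        members = gt.herd_members()
        num = den = 0.0
        for j in range(gt.n_loci):
            pops = [
                [tuple(gt.calls[i, j]) for i in rows] for rows in members.values()
            ]
            alleles = {g for pop in pops for pair in pop for g in pair}
            if len(alleles) < 2:
                continue
            a, abc = _wc_oracle(pops)
            num += a
            den += abc
        assert res.theta == pytest.approx(num / den, abs=1e-10)


# --------------------------- jackknife ------------------------------------

def test_jackknife_duplicated_loci_sd_zero():
    rng = np.random.default_rng(2)
    gt = random_table(rng, n_ind=30, n_loci=1, n_pops=2, n_alleles=4)
    gt.calls = np.repeat(gt.calls, 5, axis=1)
    gt.loci = [f"L{j}" for j in range(5)]
    res = fst_jackknife(gt, "herd")
    assert res.sd_jackknife == pytest.approx(0.0, abs=1e-12)


def test_jackknife_matches_direct_formula():
    rng = np.random.default_rng(31)
    gt = random_table(rng, n_ind=24, n_loci=6, n_pops=2, n_alleles=4)
    res = fst_jackknife(gt, "herd")
    comps = list(res.components.values())
    L = len(comps)
    ta = sum(a for a, _ in comps)
    tabc = sum(x for _, x in comps)
    pseudo = [(ta - a) / (tabc - abc) for a, abc in comps]
    mean = sum(pseudo) / L
    sd = math.sqrt((L - 1) / L * sum((t - mean) ** 2 for t in pseudo))
    assert res.sd_jackknife == pytest.approx(sd, abs=1e-12)


def test_jackknife_needs_three_loci():
    rng = np.random.default_rng(6)
    gt = random_table(rng, n_ind=20, n_loci=2, n_pops=2)
    with pytest.raises(ValueError):
        fst_jackknife(gt, "herd")


def test_jackknife_coverage_island_model():
    """theta +/- 2 sd brackets the replicate-mean theta in >= 90% of runs."""
    thetas, intervals = [], []
    for rep in range(100):
        sim = simulate_scenario(
            SimConfig(n_herds=4, herd_size=15, n_loci=8, generations=10,
                      migration_rate=0.05, target_avg_degree=2.0,
                      sample_per_herd=(8, 8), seed=5000 + rep)
        )
        res = fst_jackknife(sim.genotypes, "herd")
        thetas.append(res.theta)
        intervals.append((res.theta - 2 * res.sd_jackknife,
                          res.theta + 2 * res.sd_jackknife))
    grand = float(np.mean(thetas))
    cover = sum(lo <= grand <= hi for lo, hi in intervals) / len(intervals)
    assert cover >= 0.90


# --------------------------- Reynolds distances ---------------------------

def test_identical_herds_distance_zero():
    rng = np.random.default_rng(13)
    gt = random_table(rng, n_ind=20, n_loci=5, n_pops=1, n_alleles=4)
    rows = list(range(20))
    th = reynolds_theta(gt, rows, rows)
    assert th == pytest.approx(0.0, abs=1e-12) or th < 0


def test_log_transform_closed_form():
    rng = np.random.default_rng(29)
    gt = random_table(rng, n_ind=24, n_loci=5, n_pops=2, n_alleles=4)
    m_theta = reynolds_matrix(gt, min_animals=1, kind="theta")
    m_dist = reynolds_matrix(gt, min_animals=1, kind="reynolds")
    th = m_theta.values[0, 1]
    assert m_dist.values[0, 1] == pytest.approx(-math.log(1 - th), abs=1e-12)
    # closed-form anchor: theta = 0.5 maps to ln 2
    assert -math.log(1 - 0.5) == pytest.approx(0.6931, abs=1e-4)


def _reynolds_oracle(pop1, pop2):
    """Independent re-derivation of the coancestry moment estimator."""
    num = den = 0.0
    L = len(pop1[0])
    for j in range(L):
        g1 = [g for pair in (row[j] for row in pop1) for g in pair]
        g2 = [g for pair in (row[j] for row in pop2) for g in pair]
        alleles = sorted(set(g1) | set(g2))
        if len(alleles) < 2:
            continue
        n1, n2 = len(g1) // 2, len(g2) // 2
        p1 = [g1.count(a) / len(g1) for a in alleles]
        p2 = [g2.count(a) / len(g2) for a in alleles]
        ssq = sum((x - y) ** 2 for x, y in zip(p1, p2))
        h1 = (2 * n1 / (2 * n1 - 1)) * (1 - sum(x * x for x in p1))
        h2 = (2 * n2 / (2 * n2 - 1)) * (1 - sum(x * x for x in p2))
        a = 0.5 * (ssq - h1 / (2 * n1) - h2 / (2 * n2))
        num += a
        den += a + 0.5 * (h1 + h2)
    return num / den


def test_reynolds_against_independent_oracle():
    rng = np.random.default_rng(37)
    for _ in range(15):
        gt = random_table(rng, n_ind=20, n_loci=4, n_pops=2, n_alleles=4)
        members = gt.herd_members()
        th = reynolds_theta(gt, members["P1"], members["P2"])
        pops = [
            [[tuple(gt.calls[i, j]) for j in range(gt.n_loci)] for i in rows]
            for rows in members.values()
        ]
        assert th == pytest.approx(_reynolds_oracle(*pops), abs=1e-10)


def test_matrix_shape_properties():
    rng = np.random.default_rng(41)
    gt = random_table(rng, n_ind=30, n_loci=5, n_pops=3, n_alleles=4)
    m = reynolds_matrix(gt, min_animals=5)
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 0.0)
    assert (m.values[~np.isnan(m.values)] >= 0).all()


def test_min_animals_threshold_enforced():
    rng = np.random.default_rng(43)
    gt = random_table(rng, n_ind=8, n_loci=3, n_pops=2)  # 4 per herd
    assert reynolds_matrix(gt, min_animals=5).herds == []
    with pytest.raises(ValueError, match="fewer than"):
        reynolds_matrix(gt, herds=["P1", "P2"], min_animals=5)


def test_drift_distance_grows_with_isolation_time():
    """Mean D_r between isolated herds rises monotonically with generations."""
    time_points = list(range(5, 55, 5))
    means = []
    for t in time_points:
        vals = []
        for rep in range(50):
            sim = simulate_scenario(
                SimConfig(n_herds=2, herd_size=15, n_loci=6, generations=t,
                          migration_rate=0.0, target_avg_degree=1.0,
                          sample_per_herd=(10, 10), seed=9000 + 100 * t + rep)
            )
            m = reynolds_matrix(sim.genotypes, min_animals=1)
            vals.append(m.values[0, 1])
        means.append(float(np.mean(vals)))
    rho, _ = spearmanr(time_points, means)
    assert rho > 0.9
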