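import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flocknet.diversity import (
    allele_frequencies,
    allelic_richness,
    bonferroni_adjust,
    hwe_exact_test,
    null_allele_estimate,
    per_locus_stats,
)
from flocknet.genio import MISSING
from conftest import make_table, random_table


# --------------------------- allele frequencies ---------------------------

def test_allele_frequencies_basic():
    gt = make_table([[(1, 1)], [(1, 2)]])
    af = allele_frequencies(gt, "herd")["H1"]["L01"]
    assert af.freqs == {1: 0.75, 2: 0.25}
    assert af.n_genes == 4


def test_all_missing_cell_is_na():
    gt = make_table([[(MISSING, MISSING)], [(MISSING, MISSING)]])
    assert allele_frequencies(gt, "herd")["H1"]["L01"] is None


def test_count_back_oracle():
    rng = np.random.default_rng(3)
    gt = random_table(rng, n_ind=16, n_loci=5, n_pops=2, missing_rate=0.1)
    for per_locus in allele_frequencies(gt, "herd").values():
        for af in per_locus.values():
            if af is None:
                continue
            total = sum(af.counts.values())
            assert total == af.n_genes
            for a, f in af.freqs.items():
                assert f * af.n_genes == pytest.approx(af.counts[a], abs=1e-12)
            assert sum(af.freqs.values()) == pytest.approx(1.0, abs=1e-12)


# --------------------------- per-locus statistics -------------------------

def test_het_closed_form():
    gt = make_table([[(1, 2)], [(1, 2)]])
    s = per_locus_stats(gt, "herd")["H1"][0]
    assert s.Ho == 1.0
    assert s.He == pytest.approx(4.0 / 3.0 * 0.5)


def test_monomorphic_locus():
    gt = make_table([[(3, 3)], [(3, 3)]])
    s = per_locus_stats(gt, "herd")["H1"][0]
    assert (s.Ho, s.He, s.Fis) == (0.0, 0.0, None)


def _stats_oracle(pairs):
    """Direct-summation Ho/He/WC-f oracle, coded independently."""
    n = len(pairs)
    ho = sum(1 for a, b in pairs if a != b) / n
    genes = [g for p in pairs for g in p]
    alleles = sorted(set(genes))
    he = (2 * n / (2 * n - 1)) * (
        1 - sum((genes.count(a) / (2 * n)) ** 2 for a in alleles)
    )
    sb = sc = 0.0
    for a in alleles:
        p = genes.count(a) / (2 * n)
        h = sum(1 for x, y in pairs if (x == a) != (y == a)) / n
        sb += (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        sc += h / 2
    f = 1 - sc / (sb + sc) if sb + sc > 0 else None
    return ho, he, f


def test_stats_against_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        gt = random_table(rng, n_ind=10, n_loci=3, n_pops=1, n_alleles=3)
        for s in per_locus_stats(gt, "herd")["P1"]:
            j = gt.loci.index(s.locus)
            pairs = [tuple(gt.calls[i, j]) for i in range(gt.n_individuals)]
            ho, he, f = _stats_oracle(pairs)
            if s.n_alleles == 1:
                continue
            assert s.Ho == pytest.approx(ho, abs=1e-10)
            assert s.He == pytest.approx(he, abs=1e-10)
            assert s.Fis == pytest.approx(f, abs=1e-10)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_heterozygosity_bounds(seed):
    gt = random_table(np.random.default_rng(seed), n_ind=8, n_loci=2, n_pops=1)
    for s in per_locus_stats(gt, "herd")["P1"]:
        assert 0.0 <= s.Ho <= 1.0
        assert 0.0 <= s.He <= 1.0


# --------------------------- allelic richness -----------------------------

def test_richness_monomorphic_and_full_sample():
    gt = make_table([[(1, 1), (1, 2)], [(1, 1), (2, 3)]])
    res = allelic_richness(gt, "herd", g=2)[0]
    assert res.per_locus["L01"] == pytest.approx(1.0)
    res_full = allelic_richness(gt, "herd", g=4)[0]
    assert res_full.per_locus["L01"] == pytest.approx(1.0)
    assert res_full.per_locus["L02"] == pytest.approx(3.0)  # g = 2N identity


def _richness_enumeration(genes, g):
    """Mean distinct alleles over all g-subsets of genes (brute force)."""
    vals = [len(set(sub)) for sub in itertools.combinations(genes, g)]
    return sum(vals) / len(vals)


def test_richness_vs_subset_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(5):
        gt = random_table(rng, n_ind=5, n_loci=2, n_pops=1, n_alleles=4)
        for g in (2, 4, 6):
            res = allelic_richness(gt, "herd", g=g)[0]
            for loc, ar in res.per_locus.items():
                j = gt.loci.index(loc)
                genes = list(gt.calls[:, j, :].ravel())
                assert ar == pytest.approx(
                    _richness_enumeration(genes, g), abs=1e-10
                )


def test_richness_monotone_in_g():
    rng = np.random.default_rng(9)
    gt = random_table(rng, n_ind=10, n_loci=3, n_pops=1, n_alleles=5)
    values = [allelic_richness(gt, "herd", g=g)[0].AR_value for g in range(2, 20, 2)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


def test_richness_bad_g():
    gt = make_table([[(1, 2)], [(1, 2)]])
    with pytest.raises(ValueError):
        allelic_richness(gt, "herd", g=1)


# --------------------------- HWE exact test -------------------------------

def _hwe_exact_two_alleles(pairs):
    """Full enumeration of the conditional distribution for 2 alleles."""
    n = len(pairs)
    genes = [g for p in pairs for g in p]
    alleles = sorted(set(genes))
    na = genes.count(alleles[0])
    obs_het = sum(1 for a, b in pairs if a != b)

    def log_prob(nh):
        naa = (na - nh) // 2
        nbb = n - naa - nh
        return (
            nh * math.log(2)
            - math.lgamma(naa + 1)
            - math.lgamma(nh + 1)
            - math.lgamma(nbb + 1)
        )

    hs = [h for h in range(min(na, 2 * n - na) + 1) if (na - h) % 2 == 0]
    logs = {h: log_prob(h) for h in hs}
    mx = max(logs.values())
    z = sum(math.exp(v - mx) for v in logs.values())
    probs = {h: math.exp(v - mx) / z for h, v in logs.items()}
    p_obs = probs[obs_het]
    return sum(p for p in probs.values() if p <= p_obs + 1e-12)


def test_hwe_against_enumeration_oracle():
    rng = np.random.default_rng(21)
    for _ in range(4):
        gt = random_table(rng, n_ind=15, n_loci=1, n_pops=1, n_alleles=2)
        pairs = [tuple(gt.calls[i, 0]) for i in range(gt.n_individuals)]
        if len({g for p in pairs for g in p}) < 2:
            continue
        exact = _hwe_exact_two_alleles(pairs)
        res = hwe_exact_test(
            gt, "herd", "P1", "L01",
            batches=20, iters_per_batch=500, dememorization=2000, seed=1,
        )
        assert res.p == pytest.approx(exact, abs=max(3 * res.se, 0.02))


def test_hwe_proportioned_sample_p_near_one():
    # exact HWE proportions: 25 AA, 50 AB, 25 BB
    pairs = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
    gt = make_table(pairs)
    res = hwe_exact_test(gt, "herd", "H1", "L01",
                         batches=10, iters_per_batch=500,
                         dememorization=1000, seed=2)
    assert res.p > 0.9


def test_hwe_determinism_and_monomorphic():
    rng = np.random.default_rng(4)
    gt = random_table(rng, n_ind=12, n_loci=1, n_pops=1, n_alleles=3)
    kw = dict(batches=5, iters_per_batch=200, dememorization=500, seed=9)
    r1 = hwe_exact_test(gt, "herd", "P1", "L01", **kw)
    r2 = hwe_exact_test(gt, "herd", "P1", "L01", **kw)
    assert r1.p == r2.p and r1.se == r2.se
    mono = make_table([[(1, 1)], [(1, 1)]])
    res = hwe_exact_test(mono, "herd", "H1", "L01", seed=1)
    assert res.p is None and "monomorphic" in res.reason


# --------------------------- Bonferroni / null alleles --------------------

def test_bonferroni():
    assert bonferroni_adjust([0.001, 0.03], alpha=0.05) == [True, False]
    assert bonferroni_adjust([0.001, 0.02], alpha=0.05) == [True, True]
    assert bonferroni_adjust([0.04], alpha=0.05) == [True]
    assert bonferroni_adjust([], alpha=0.05) == []
    rng = np.random.default_rng(0)
    ps = rng.random(20).tolist()
    flags = bonferroni_adjust(ps, alpha=0.05)
    assert flags == [p <= 0.05 / 20 for p in ps]


def test_null_allele_closed_forms():
    gt = make_table([[(1, 2)], [(1, 2)]])  # Ho=1 > He
    r, flag = null_allele_estimate(gt, "herd", "H1", "L01")
    assert not flag and r < 0
    mono = make_table([[(1, 1)], [(1, 1)]])
    assert null_allele_estimate(mono, "herd", "H1", "L01") == (None, False)


def test_null_allele_simulation_recovery():
    """Mean Brookfield-1 estimate near the true null frequency (10%)."""
    rng = np.random.default_rng(8)
    true_null = 0.10
    ests = []
    for _ in range(200):
        freqs = np.array([0.3, 0.3, 0.3, true_null])  # allele 4 = null
        n = 60
        geno = rng.choice(4, size=(n, 2), p=freqs) + 1
        null_mask = geno == 4
        # null homozygotes appear as missing, null heterozygotes as homozygotes
        rows = []
        for a, b in geno:
            if a == 4 and b == 4:
                rows.append([(MISSING, MISSING)])
            elif a == 4:
                rows.append([(b, b)])
            elif b == 4:
                rows.append([(a, a)])
            else:
                rows.append([(a, b)])
        gt = make_table(rows)
        r, _ = null_allele_estimate(gt, "herd", "H1", "L01")
        ests.append(r)
    assert abs(float(np.mean(ests)) - true_null) < 0.05
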