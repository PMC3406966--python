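import numpy as np
import pytest

from flocknet.genio import MISSING, GenotypeTable


def make_table(genotypes, herds=None, loci=None, breed="X"):
    """Build a GenotypeTable from a nested list: genotypes[i][j] = (a1, a2)."""
    n = len(genotypes)
    L = len(genotypes[0])
    inds = [f"I{i + 1:02d}" for i in range(n)]
    if herds is None:
        herds = ["H1"] * n
    if loci is None:
        loci = [f"L{j + 1:02d}" for j in range(L)]
    calls = np.array(genotypes, dtype=np.int64)
    return GenotypeTable(
        inds, loci, calls,
        {i: h for i, h in zip(inds, herds)},
        {i: breed for i in inds},
    )


def random_table(rng, n_ind=12, n_loci=4, n_pops=2, n_alleles=4, missing_rate=0.0):
    """Random multi-population genotype table for oracle comparisons."""
    freqs = rng.dirichlet(np.ones(n_alleles), size=(n_pops, n_loci))
    rows, herds = [], []
    per_pop = n_ind // n_pops
    for p in range(n_pops):
        for _ in range(per_pop):
            row = [
                tuple(rng.choice(n_alleles, size=2, p=freqs[p, j]) + 1)
                for j in range(n_loci)
            ]
            rows.append(row)
            herds.append(f"P{p + 1}")
    gt = make_table(rows, herds=herds)
    if missing_rate > 0:
        mask = rng.random(gt.calls.shape[:2]) < missing_rate
        gt.calls[mask] = MISSING
    return gt


@pytest.fixture
def two_pop_separated():
    """Two populations fixed for disjoint allele sets at every locus."""
    rng = np.random.default_rng(42)
    n, L = 20, 6
    rows, herds = [], []
    for k in range(2 * n):
        lo = 1 if k < n else 5
        rows.append([tuple(rng.integers(lo, lo + 3, size=2)) for _ in range(L)])
        herds.append("A" if k < n else "B")
    return make_table(rows, herds=herds)
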