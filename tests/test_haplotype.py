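import numpy as np
import pytest
from scipy.optimize import minimize

from breedmap.association import PermutationConfig
from breedmap.genotype_io import MISSING
from breedmap.haplotype import (
    block_haplotype_frequencies,
    chromosome_haplotype_scan,
    em_haplotype_frequencies,
    em_pair_frequencies,
    four_gamete_blocks,
    haplotype_association,
)

from conftest import make_dataset, random_dataset

# ---------------------------------------------------------------------------
# independent likelihood oracles (enumerate haplotype pairs directly)
# ---------------------------------------------------------------------------


def loglik_oracle(freqs, calls):
    """Observed-data log-likelihood over all haplotype pairs, by brute force.

    ``freqs`` indexed by tuples of alleles; independent of the package's
    bit-coded EM internals.
    """
    k = calls.shape[1]
    haps = [tuple((h >> j) & 1 for j in range(k)) for h in range(2**k)]
    total = 0.0
    for g in calls:
        p = 0.0
        for h1 in haps:
            for h2 in haps:
                if all(a + b == gi for a, b, gi in zip(h1, h2, g)):
                    p += freqs[h1] * freqs[h2]
        total += np.log(max(p, 1e-300))
    return total


def maximize_likelihood_oracle(calls, n_starts=8, seed=0):
    """Grid-seeded softmax maximizer of the explicit likelihood (not EM)."""
    k = calls.shape[1]
    m = 2**k
    haps = [tuple((h >> j) & 1 for j in range(k)) for h in range(m)]
    rng = np.random.default_rng(seed)

    def negloglik(logits):
        z = np.exp(logits - logits.max())
        f = z / z.sum()
        return -loglik_oracle(dict(zip(haps, f)), calls)

    best, best_val = None, np.inf
    starts = [np.zeros(m)] + [rng.normal(0, 2, m) for _ in range(n_starts - 1)]
    for x0 in starts:
        res = minimize(negloglik, x0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 20000})
        if res.fun < best_val:
            best_val, best = res.fun, res.x
    z = np.exp(best - best.max())
    return z / z.sum()


def naive_pair_em(c1, c2, iters=2000, tol=1e-10):
    """Loop-based two-locus EM over the 9 genotype classes (oracle).

    Mirrors the implementation contract independently: a
    linkage-equilibrium start plus the two canonical phase-mode starts,
    keeping a strictly better optimum only.
    """
    keep = (c1 != MISSING) & (c2 != MISSING)
    c1, c2 = c1[keep], c2[keep]
    n = len(c1)

    def loglik(f):
        total = 0.0
        for g1, g2 in zip(c1, c2):
            if g1 == 1 and g2 == 1:
                p = 2 * f[(0, 0)] * f[(1, 1)] + 2 * f[(0, 1)] * f[(1, 0)]
            else:
                h1 = (int(g1 > 0), int(g2 > 0))
                h2 = (int(g1 == 2), int(g2 == 2))
                p = f[h1] * f[h2] * (2 if h1 != h2 else 1)
            total += np.log(max(p, 1e-300))
        return total

    def run(f):
        for _ in range(iters):
            counts = dict.fromkeys(f, 0.0)
            for g1, g2 in zip(c1, c2):
                if g1 == 1 and g2 == 1:
                    cis = f[(0, 0)] * f[(1, 1)]
                    trans = f[(0, 1)] * f[(1, 0)]
                    tot = cis + trans
                    w = 0.5 if tot == 0 else cis / tot
                    counts[(0, 0)] += w
                    counts[(1, 1)] += w
                    counts[(0, 1)] += 1 - w
                    counts[(1, 0)] += 1 - w
                else:
                    # phase-unambiguous: at most one locus is heterozygous
                    h1 = (int(g1 > 0), int(g2 > 0))
                    h2 = (int(g1 == 2), int(g2 == 2))
                    counts[h1] += 1
                    counts[h2] += 1
            new = {k_: v / (2 * n) for k_, v in counts.items()}
            delta = max(abs(new[k_] - f[k_]) for k_ in f)
            f = new
            if delta < tol:
                break
        return f

    p1, p2 = c1.mean() / 2, c2.mean() / 2
    le = {
        (0, 0): (1 - p1) * (1 - p2), (0, 1): (1 - p1) * p2,
        (1, 0): p1 * (1 - p2), (1, 1): p1 * p2,
    }
    le = {k_: max(v, 1e-12) for k_, v in le.items()}
    s = sum(le.values())
    best = run({k_: v / s for k_, v in le.items()})
    best_ll = loglik(best)
    for start in (
        {(0, 0): 0.45, (0, 1): 0.05, (1, 0): 0.05, (1, 1): 0.45},
        {(0, 0): 0.05, (0, 1): 0.45, (1, 0): 0.45, (1, 1): 0.05},
    ):
        f = run(dict(start))
        ll = loglik(f)
        if ll > best_ll + 1e-9:
            best, best_ll = f, ll
    return np.array([best[(0, 0)], best[(0, 1)], best[(1, 0)], best[(1, 1)]])


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def test_pair_em_all_homozygous_equals_counting():
    c1 = np.array([0, 0, 2, 2])
    c2 = np.array([0, 2, 0, 2])
    freqs = em_pair_frequencies(c1, c2)
    assert freqs == pytest.approx([0.25, 0.25, 0.25, 0.25], abs=1e-9)


def test_pair_em_spec_example_matches_grid_oracle():
    """Nine (2,2) individuals and one (1,1): the cis resolution dominates."""
    c1 = np.array([2] * 9 + [1])
    c2 = np.array([2] * 9 + [1])
    freqs = em_pair_frequencies(c1, c2)
    oracle = maximize_likelihood_oracle(np.column_stack([c1, c2]))
    # oracle order (0,0),(1,0),(0,1),(1,1) by bit code -> reorder to AB,Ab,aB,ab
    oracle_ordered = oracle[[0, 2, 1, 3]]
    assert freqs == pytest.approx(oracle_ordered, abs=1e-4)
    assert freqs[3] == pytest.approx(19 / 20, abs=1e-4)  # ab haplotype


def test_pair_em_sums_to_one_and_handles_missing(rng):
    for _ in range(20):
        c1 = rng.integers(0, 3, 25)
        c2 = rng.integers(0, 3, 25)
        c1[rng.integers(0, 25, 3)] = MISSING
        freqs = em_pair_frequencies(c1, c2)
        assert freqs.sum() == pytest.approx(1.0, abs=1e-6)
        assert (freqs >= -1e-12).all()


def test_pair_em_no_informative_pairs_errors():
    with pytest.raises(ValueError, match="no informative pairs"):
        em_pair_frequencies(np.array([MISSING, 1]), np.array([1, MISSING]))


def test_em_loglik_nondecreasing(rng):
    for _ in range(20):
        calls = rng.integers(0, 3, (15, 3))
        em = em_haplotype_frequencies(calls)
        assert (np.diff(em.loglik_trace) >= -1e-9).all()


def test_em_matches_naive_oracle_on_random_pairs(rng):
    for _ in range(50):
        c1 = rng.integers(0, 3, 30)
        c2 = rng.integers(0, 3, 30)
        ours = em_pair_frequencies(c1, c2)
        oracle = naive_pair_em(c1, c2)
        assert ours == pytest.approx(oracle, abs=1e-5)


def test_three_snp_em_matches_brute_force():
    """One double heterozygote among unambiguous individuals."""
    calls = np.array(
        [[0, 0, 0], [2, 2, 2], [2, 2, 2], [0, 0, 2], [1, 1, 0], [2, 2, 0]]
    )
    em = em_haplotype_frequencies(calls)
    oracle = maximize_likelihood_oracle(calls, n_starts=12)
    assert em.frequencies == pytest.approx(oracle, abs=1e-4)


def test_block_width_one_equals_allele_frequency():
    ds = make_dataset([[0], [1], [2], [1]])
    blocks = [
        b for b in _singleton_blocks(ds)
    ]
    block, em = block_haplotype_frequencies(ds, blocks[0])
    freq_b = dict(block.haplotypes)["B"]
    assert freq_b == pytest.approx(0.5)


def _singleton_blocks(ds):
    from breedmap.haplotype import HaplotypeBlock

    return [
        HaplotypeBlock(
            chromosome="1", start_idx=0, end_idx=0,
            start_bp=int(ds.snps["position_bp"].iloc[0]),
            end_bp=int(ds.snps["position_bp"].iloc[0]),
            snp_ids=[ds.snps["snp_id"].iloc[0]],
        )
    ]


def test_em_width_cap_errors(rng):
    with pytest.raises(ValueError, match="subdivide"):
        em_haplotype_frequencies(rng.integers(0, 3, (4, 13)))


# ---------------------------------------------------------------------------
# four-gamete blocks
# ---------------------------------------------------------------------------


def test_three_gametes_merge_into_one_block():
    # haplotype pairs drawn from {00, 01, 10} only (phase-unambiguous)
    calls = np.array([[0, 0], [0, 2], [2, 0], [0, 1], [1, 0], [0, 0]])
    ds = make_dataset(calls)
    blocks = four_gamete_blocks(ds, "1", freq_threshold=0.01)
    assert len(blocks) == 1
    assert (blocks[0].start_idx, blocks[0].end_idx) == (0, 1)


def test_four_gametes_split_into_singletons():
    calls = np.array([[0, 0], [0, 2], [2, 0], [2, 2]])
    ds = make_dataset(calls)
    blocks = four_gamete_blocks(ds, "1", freq_threshold=0.01)
    assert [(b.start_idx, b.end_idx) for b in blocks] == [(0, 0), (1, 1)]


def test_partition_matches_bruteforce_and_covers(rng):
    """Block partition equals an independent pair-rule oracle and is a
    partition of the chromosome."""
    for _ in range(50):
        ds = random_dataset(rng, 20, 10, missing_rate=0.05)
        blocks = four_gamete_blocks(ds, "1", freq_threshold=0.01)

        compatible = []
        for j in range(9):
            freqs = naive_pair_em(ds.calls[:, j], ds.calls[:, j + 1])
            compatible.append((freqs >= 0.01).sum() < 4)
        expected, start = [], 0
        for j in range(10):
            if j == 9 or not compatible[j]:
                expected.append((start, j))
                start = j + 1
        assert [(b.start_idx, b.end_idx) for b in blocks] == expected
        covered = [i for b in blocks for i in range(b.start_idx, b.end_idx + 1)]
        assert covered == list(range(10))


# ---------------------------------------------------------------------------
# haplotype association
# ---------------------------------------------------------------------------


def _case_fixed_dataset():
    """Cases homozygous for haplotype BB over SNPs 0-1, absent in controls."""
    calls = np.array(
        [
            [2, 2, 1, 0],
            [2, 2, 0, 1],
            [2, 2, 1, 1],
            [0, 0, 1, 0],
            [0, 0, 0, 1],
            [1, 1, 1, 1],
            [0, 0, 0, 0],
        ]
    )
    return make_dataset(
        calls, status=["case"] * 3 + ["control"] * 4
    )


def test_case_fixed_haplotype_attains_chromosome_max():
    ds = _case_fixed_dataset()
    cfg = PermutationConfig(n_permutations=200, seed=3)
    associations, snps = chromosome_haplotype_scan(ds, "1", cfg)
    rows = [
        (a.block.start_idx, r.haplotype, r.chi2, r.p_chromosome)
        for a in associations
        for r in a.tests.itertuples()
    ]
    top_stat = max(r[2] for r in rows)
    winners = [r for r in rows if r[2] >= top_stat - 1e-9]
    # the case-fixed BB haplotype attains the maximum (tied with its
    # complement AA in a two-haplotype block)
    assert any(r[0] == 0 and r[1] == "BB" for r in winners)
    assert top_stat >= snps["chi2"].max() - 1e-9
    assert min(r[3] for r in winners) == min(r[3] for r in rows)


def test_haplotype_association_single_block_interface():
    ds = _case_fixed_dataset()
    cfg = PermutationConfig(n_permutations=100, seed=5)
    blocks = four_gamete_blocks(ds, "1")
    assoc = haplotype_association(ds, blocks[0], cfg)
    assert set(assoc.tests.columns) == {
        "haplotype", "frequency", "chi2", "p_raw", "p_chromosome"
    }
    assert assoc.tests["p_chromosome"].between(0, 1).all()


def test_haplotype_scan_seeded_determinism(rng):
    ds = random_dataset(rng, 16, 6)
    cfg = PermutationConfig(n_permutations=150, seed=9, exhaustive_cap=0)
    a1, s1 = chromosome_haplotype_scan(ds, "1", cfg)
    a2, s2 = chromosome_haplotype_scan(ds, "1", cfg)
    assert np.array_equal(
        s1["p_chromosome"].to_numpy(), s2["p_chromosome"].to_numpy()
    )
    for x, y in zip(a1, a2):
        assert np.array_equal(
            x.tests["p_chromosome"].to_numpy(), y.tests["p_chromosome"].to_numpy()
        )
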