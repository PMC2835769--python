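import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from breedmap.association import (
    PermutationConfig,
    allelic_chi_square,
    genome_scan,
    locus_support_ratio,
    max_t_permutation,
)

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------------------
# allelic chi-square
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cases, controls, expected_chi2, expected_p",
    [
        ((20, 0), (0, 20), 40.0, None),
        ((10, 10), (10, 10), 0.0, 1.0),
        ((15, 5), (5, 15), 10.0, 1.565e-3),
    ],
)
def test_allelic_chi_square_known_tables(cases, controls, expected_chi2, expected_p):
    chi2, p = allelic_chi_square(cases, controls)
    assert chi2 == pytest.approx(expected_chi2, abs=1e-10)
    if expected_p is not None:
        assert p == pytest.approx(expected_p, rel=1e-3)


def test_allelic_chi_square_matches_scipy_oracle(rng):
    """1,000 random 2x2 tables agree with scipy's uncorrected Pearson test."""
    for _ in range(1000):
        a, b, c, d = rng.integers(0, 50, 4)
        if a + b == 0 or c + d == 0:
            continue
        chi2, p = allelic_chi_square((a, b), (c, d))
        if min(a + c, b + d) == 0:  # zero column margin: defined as null
            assert chi2 == 0.0 and p == 1.0
            continue
        ref_chi2, ref_p, _, _ = chi2_contingency(
            [[a, b], [c, d]], correction=False
        )
        assert chi2 == pytest.approx(ref_chi2, abs=1e-10)
        assert p == pytest.approx(ref_p, abs=1e-10)


def test_allelic_chi_square_empty_group_errors():
    with pytest.raises(ValueError, match="no data for group"):
        allelic_chi_square((0, 0), (5, 5))


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------


def test_perfectly_separating_snp_is_maximal():
    # SNP 0 separates 2 cases from 2 controls; SNP 1 is noise
    ds = make_dataset(
        [[2, 1], [2, 0], [0, 1], [0, 0]],
        status=["case", "case", "control", "control"],
    )
    res = genome_scan(ds)
    assert res["chi2"].iloc[0] == pytest.approx(8.0)
    assert res["chi2"].idxmax() == 0


def test_identical_genotypes_all_null():
    ds = make_dataset(np.ones((6, 4), dtype=np.int8))
    res = genome_scan(ds)
    assert (res["chi2"] == 0).all()
    assert (res["p_raw"] == 1).all()


def test_sample_order_invariance(rng):
    ds = random_dataset(rng, 12, 8)
    res = genome_scan(ds)
    perm = rng.permutation(12)
    shuffled = ds.take_samples(perm)
    res2 = genome_scan(shuffled)
    pd.testing.assert_frame_equal(res, res2)


def test_scan_requires_both_groups():
    ds = make_dataset([[0, 1], [1, 2]], status=["case", "case"])
    with pytest.raises(ValueError, match="control"):
        genome_scan(ds)


# ---------------------------------------------------------------------------
# max-T permutation
# ---------------------------------------------------------------------------


def test_exhaustive_two_vs_two_single_snp():
    """Of the 6 label assignments only the two grouping like with like reach
    the observed chi2, so the exact genome-wide p is 2/6."""
    ds = make_dataset([[2], [2], [0], [0]], status=["case", "case", "control", "control"])
    res = max_t_permutation(ds, PermutationConfig(n_permutations=10, seed=0))
    assert res["p_genome"].iloc[0] == pytest.approx(2 / 6)


def test_all_identical_p_genome_one():
    ds = make_dataset(np.full((5, 3), 2, dtype=np.int8))
    res = max_t_permutation(ds, PermutationConfig(n_permutations=50, seed=0))
    assert (res["p_genome"] == 1).all()


def test_seeded_determinism(rng):
    ds = random_dataset(rng, 14, 10)
    cfg = PermutationConfig(n_permutations=300, seed=42, exhaustive_cap=0)
    a = max_t_permutation(ds, cfg)
    b = max_t_permutation(ds, cfg)
    assert np.array_equal(a["p_genome"].to_numpy(), b["p_genome"].to_numpy())


def test_p_genome_dominates_p_raw_exhaustive(rng):
    """With exhaustive enumeration the corrected p is never below the
    per-SNP asymptotic p on small datasets."""
    for trial in range(10):
        ds = random_dataset(rng, 8, 4)
        res = max_t_permutation(ds, PermutationConfig(n_permutations=10, seed=trial))
        assert (res["p_genome"] >= res["p_raw"] - 1e-12).all()


def test_exhaustive_brute_force_oracle(rng):
    """Exhaustive p_genome equals an independent enumeration that rebuilds
    every 2x2 table with scipy."""
    from itertools import combinations

    ds = random_dataset(rng, 7, 3, missing_rate=0.1)
    n_cases = int(ds.case_mask.sum())
    res = max_t_permutation(ds, PermutationConfig(n_permutations=10, seed=0))

    def chi2_table(is_case):
        stats = []
        for j in range(ds.n_snps):
            col = ds.calls[:, j]
            ok = col != -1
            a = int(col[ok & is_case].sum())
            n1 = 2 * int((ok & is_case).sum())
            c = int(col[ok & ~is_case].sum())
            n2 = 2 * int((ok & ~is_case).sum())
            table = [[a, n1 - a], [c, n2 - c]]
            if min(np.sum(table, axis=0)) == 0 or min(np.sum(table, axis=1)) == 0:
                stats.append(0.0)
            else:
                stats.append(chi2_contingency(table, correction=False)[0])
        return np.array(stats)

    observed = chi2_table(ds.case_mask)
    maxima = []
    for combo in combinations(range(ds.n_samples), n_cases):
        mask = np.zeros(ds.n_samples, dtype=bool)
        mask[list(combo)] = True
        maxima.append(chi2_table(mask).max())
    maxima = np.array(maxima)
    expected = [(maxima >= o - 1e-9).mean() for o in observed]
    assert res["p_genome"].to_numpy() == pytest.approx(expected, abs=1e-12)


def test_stratified_permutation_runs(rng):
    ds = random_dataset(rng, 12, 6)
    breeds = ["X"] * 6 + ["Y"] * 6
    ds = make_dataset(
        ds.calls,
        status=["case", "control"] * 6,
        breeds=breeds,
    )
    cfg = PermutationConfig(n_permutations=100, seed=1, stratify_by_breed=True)
    res = max_t_permutation(ds, cfg)
    assert res["p_genome"].between(0, 1).all()


# ---------------------------------------------------------------------------
# locus support ratio
# ---------------------------------------------------------------------------


def _results(p_by_chrom):
    rows = []
    for chrom, ps in p_by_chrom.items():
        for i, p in enumerate(ps):
            rows.append((f"Chr{chrom}.{i + 1}", chrom, (i + 1) * 100, 50 / p, p / 2, p))
    return pd.DataFrame(
        rows, columns=["snp_id", "chromosome", "position_bp", "chi2", "p_raw", "p_genome"]
    )


def test_support_ratio_boundary_not_accepted():
    scan = locus_support_ratio(_results({"1": [1e-5, 1e-2], "2": [1e-3]}))
    assert scan.support_ratio == pytest.approx(100.0)
    assert not scan.accepted


def test_support_ratio_accepted():
    scan = locus_support_ratio(_results({"1": [2e-5], "2": [2e-2]}))
    assert scan.support_ratio == pytest.approx(1000.0)
    assert scan.accepted
    assert scan.best["snp_id"] == "Chr1.1"


def test_support_ratio_tie_is_one():
    scan = locus_support_ratio(_results({"1": [1e-4], "2": [1e-4]}))
    assert scan.support_ratio == pytest.approx(1.0)
    assert not scan.accepted


def test_support_ratio_single_chromosome_errors():
    with pytest.raises(ValueError, match="no competing chromosome"):
        locus_support_ratio(_results({"1": [1e-4, 1e-3]}))
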