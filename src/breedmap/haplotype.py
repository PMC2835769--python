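"""Haplotype blocks by the four-gamete rule and EM haplotype association.

Chromosomes are partitioned into blocks of SNPs showing no evidence of
historical recombination: two adjacent SNPs are compatible when fewer than
four of their two-locus haplotypes are observed (estimated frequency at or
above a small cutoff), and maximal runs of pairwise-compatible consecutive
SNPs form blocks. Haplotype frequencies within a block are estimated from
unphased genotypes by an expectation-maximization (EM) algorithm over all
haplotypes consistent with each individual's genotype: double heterozygotes
contribute a likelihood mixture over their phase resolutions.

Haplotype case/control association uses fractional haplotype counts — each
individual's EM posterior expected dosage of the tested haplotype — in the
same 2x2 chi-square as the single-SNP test, corrected chromosome-wide by
label permutation of the maximum statistic over *all* SNP and haplotype
tests on the chromosome.

Haplotype strings use 'A' for the major (uncounted) allele and 'B' for the
minor (counted) allele, in map order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .association import PermutationConfig, max_stat_permutation, permutation_pvalues
from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "EMResult",
    "HaplotypeBlock",
    "HaplotypeAssociation",
    "em_haplotype_frequencies",
    "em_pair_frequencies",
    "four_gamete_blocks",
    "block_haplotype_frequencies",
    "haplotype_association",
    "chromosome_haplotype_scan",
]

log = logging.getLogger(__name__)

EM_TOL = 1e-9
# convergence to a boundary optimum (a haplotype frequency heading to 0) is
# sublinear (error ~ C/iterations); a generous cap keeps such fits accurate
# to ~1e-5 while typical fits stop after tens of iterations on the tol rule
EM_MAX_ITER = 50_000
PRUNE_FREQ = 1e-4
DEFAULT_FREQ_THRESHOLD = 0.01
MAX_BLOCK_WIDTH = 12


@dataclass
class EMResult:
    """EM fit for one block of k SNPs.

    ``frequencies`` is indexed by haplotype code: an integer whose bit j is
    the (counted) allele at the block's j-th SNP. ``loglik_trace`` holds the
    observed-data log-likelihood after every iteration (non-decreasing).
    """

    n_snps: int
    frequencies: np.ndarray  # length 2**n_snps
    loglik_trace: np.ndarray
    converged: bool
    n_individuals: int

    def haplotype_string(self, code: int) -> str:
        return "".join("B" if (code >> j) & 1 else "A" for j in range(self.n_snps))


@dataclass
class HaplotypeBlock:
    """Contiguous SNP span on one chromosome with haplotype frequencies.

    ``start_idx``/``end_idx`` are inclusive indices into the chromosome's
    SNP list; ``haplotypes`` is a list of (allele string over {A,B},
    frequency) pairs, populated by `block_haplotype_frequencies`.
    """

    chromosome: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    snp_ids: list[str]
    haplotypes: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class HaplotypeAssociation:
    """Per-haplotype tests for one block, chromosome-wide corrected."""

    block: HaplotypeBlock
    tests: pd.DataFrame  # haplotype, frequency, chi2, p_raw, p_chromosome


# ---------------------------------------------------------------------------
# EM over haplotypes consistent with unphased genotypes
# ---------------------------------------------------------------------------


def _phase_pairs(genotype: np.ndarray) -> list[tuple[int, int]]:
    """Unordered haplotype-code pairs consistent with one genotype vector."""
    hom = 0
    het_bits = []
    for j, g in enumerate(genotype):
        if g == 2:
            hom |= 1 << j
        elif g == 1:
            het_bits.append(1 << j)
    if not het_bits:
        return [(hom, hom)]
    first, rest = het_bits[0], het_bits[1:]
    pairs = []
    for mask in range(1 << len(rest)):
        h1 = hom | first
        h2 = hom
        for i, bit in enumerate(rest):
            if (mask >> i) & 1:
                h1 |= bit
            else:
                h2 |= bit
        pairs.append((h1, h2))
    return pairs


def em_haplotype_frequencies(
    calls: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> EMResult:
    """Maximum-likelihood haplotype frequencies for a block of SNPs.

    ``calls`` is an (n_individuals, k) genotype matrix over {0, 1, 2};
    individuals with any missing call in the block must be excluded by the
    caller. Starts from linkage equilibrium (products of allele
    frequencies) and iterates until the largest frequency change is below
    ``tol`` or ``max_iter`` iterations (the default tolerance keeps even
    slow boundary fits within ~1e-5 of the optimum). For two-SNP fits the two canonical
    phase modes are also tried as starts and a strictly better optimum is
    kept (the two-locus likelihood can be bimodal); exact ties keep the
    linkage-equilibrium solution.
    """
    calls = np.asarray(calls)
    if calls.ndim != 2:
        raise ValueError("calls must be (n_individuals, n_snps)")
    n, k = calls.shape
    if n == 0:
        raise ValueError("no informative individuals for EM")
    if k > MAX_BLOCK_WIDTH:
        raise ValueError(
            f"block of {k} SNPs exceeds the EM width cap ({MAX_BLOCK_WIDTH}); "
            "subdivide the block"
        )
    if not np.isin(calls, (0, 1, 2)).all():
        raise ValueError("EM calls must be in {0,1,2}; drop missing rows first")

    classes, counts = np.unique(calls, axis=0, return_counts=True)
    class_pairs = [_phase_pairs(g) for g in classes]
    n_hap = 1 << k

    def run(start: np.ndarray) -> tuple[np.ndarray, list[float], bool]:
        freqs = start
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            expected = np.zeros(n_hap)
            loglik = 0.0
            for pairs, weight in zip(class_pairs, counts):
                probs = np.array(
                    [
                        (2.0 if h1 != h2 else 1.0) * freqs[h1] * freqs[h2]
                        for h1, h2 in pairs
                    ]
                )
                total = probs.sum()
                loglik += weight * np.log(max(total, 1e-300))
                if total <= 0:
                    continue
                post = probs / total
                for (h1, h2), w in zip(pairs, post):
                    expected[h1] += weight * w
                    expected[h2] += weight * w
            trace.append(loglik)
            new = expected / (2.0 * n)
            delta = np.abs(new - freqs).max()
            freqs = new
            if delta < tol:
                converged = True
                break
        return freqs, trace, converged

    # linkage-equilibrium start
    p_allele = calls.mean(axis=0) / 2.0
    codes = np.arange(n_hap)
    le = np.ones(n_hap)
    for j in range(k):
        bit = (codes >> j) & 1
        le *= np.where(bit, p_allele[j], 1.0 - p_allele[j])
    # guard a start on the simplex boundary (monomorphic SNP in the block)
    le = np.maximum(le, 1e-12)
    le /= le.sum()

    freqs, trace, converged = run(le)
    if k == 2:
        # the two-locus likelihood can be bimodal (cis vs trans phase of the
        # double heterozygotes); try both canonical modes and keep a result
        # only if it is strictly better, so symmetric ties still resolve to
        # the linkage-equilibrium start
        for start in (
            np.array([0.45, 0.05, 0.05, 0.45]),
            np.array([0.05, 0.45, 0.45, 0.05]),
        ):
            f2, t2, c2 = run(start)
            if t2[-1] > trace[-1] + 1e-9:
                freqs, trace, converged = f2, t2, c2
    return EMResult(
        n_snps=k,
        frequencies=freqs,
        loglik_trace=np.array(trace),
        converged=converged,
        n_individuals=n,
    )


def _complete_rows(dataset: GenotypeDataset, cols: np.ndarray) -> np.ndarray:
    sub = dataset.calls[:, cols]
    return np.flatnonzero((sub != MISSING).all(axis=1))


def em_pair_frequencies(
    calls_snp1: np.ndarray, calls_snp2: np.ndarray
) -> np.ndarray:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab) by EM.

    ``A``/``a`` are the major/minor alleles of the first SNP, ``B``/``b`` of
    the second (major = the allele not counted by the genotype coding).
    Individuals missing either call are excluded; raises if none remain.
    """
    c1 = np.asarray(calls_snp1)
    c2 = np.asarray(calls_snp2)
    keep = (c1 != MISSING) & (c2 != MISSING)
    if not keep.any():
        raise ValueError("no informative pairs: no individual called at both SNPs")
    calls = np.column_stack([c1[keep], c2[keep]])
    em = em_haplotype_frequencies(calls)
    # code bit0 = minor at SNP1, bit1 = minor at SNP2
    # (AB, Ab, aB, ab) = ((0,0), (0,minor2), (minor1,0), (minor1,minor2))
    return em.frequencies[[0, 2, 1, 3]]


# ---------------------------------------------------------------------------
# four-gamete blocks
# ---------------------------------------------------------------------------


def four_gamete_blocks(
    dataset: GenotypeDataset,
    chromosome: str,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
) -> list[HaplotypeBlock]:
    """Partition a chromosome into four-gamete-rule haplotype blocks.

    Adjacent SNPs are compatible when fewer than four of their estimated
    two-locus haplotypes reach ``freq_threshold`` (no evidence that all four
    gametes, hence historical recombination, exist). Maximal runs of
    pairwise-compatible consecutive SNPs become blocks; a SNP compatible
    with neither neighbour forms a singleton block. The returned blocks are
    disjoint, ordered, and cover every SNP on the chromosome; haplotype
    frequencies are left empty (see `block_haplotype_frequencies`).
    """
    cols = dataset.snp_indices(chromosome)
    if cols.size < 2:
        raise ValueError(f"chromosome {chromosome!r} has fewer than 2 SNPs")
    compatible = np.zeros(cols.size - 1, dtype=bool)
    for i in range(cols.size - 1):
        try:
            freqs = em_pair_frequencies(
                dataset.calls[:, cols[i]], dataset.calls[:, cols[i + 1]]
            )
        except ValueError:
            compatible[i] = False  # nothing jointly observed: treat as a break
            continue
        compatible[i] = int((freqs >= freq_threshold).sum()) < 4

    blocks = []
    start = 0
    for i in range(cols.size):
        if i == cols.size - 1 or not compatible[i]:
            blocks.append(_make_block(dataset, chromosome, cols, start, i))
            start = i + 1
    return blocks


def _make_block(
    dataset: GenotypeDataset, chromosome: str, cols: np.ndarray, start: int, end: int
) -> HaplotypeBlock:
    snps = dataset.snps.iloc[cols[start : end + 1]]
    return HaplotypeBlock(
        chromosome=chromosome,
        start_idx=start,
        end_idx=end,
        start_bp=int(snps["position_bp"].iloc[0]),
        end_bp=int(snps["position_bp"].iloc[-1]),
        snp_ids=list(snps["snp_id"]),
    )


def block_haplotype_frequencies(
    dataset: GenotypeDataset, block: HaplotypeBlock
) -> tuple[HaplotypeBlock, EMResult]:
    """Estimate a block's haplotype frequencies by EM.

    Individuals missing any SNP in the block are excluded. Haplotypes with
    frequency below 1e-4 are pruned from the reported list (and the
    remainder renormalized); the full spectrum stays available on the
    returned `EMResult`.
    """
    cols = dataset.snp_indices(block.chromosome)[block.start_idx : block.end_idx + 1]
    rows = _complete_rows(dataset, cols)
    if rows.size == 0:
        raise ValueError("no individual fully genotyped in block")
    em = em_haplotype_frequencies(dataset.calls[np.ix_(rows, cols)])
    keep = em.frequencies >= PRUNE_FREQ
    freqs = em.frequencies[keep] / em.frequencies[keep].sum()
    block.haplotypes = [
        (em.haplotype_string(code), float(f))
        for code, f in zip(np.flatnonzero(keep), freqs)
    ]
    return block, em


def posterior_dosage(em: EMResult, calls: np.ndarray) -> np.ndarray:
    """Expected haplotype dosage per individual given the EM frequencies.

    ``calls`` is (n, k) over {0,1,2}; the result is (n, 2**k) with rows
    summing to 2 (each individual carries two haplotypes).
    """
    calls = np.asarray(calls)
    n = calls.shape[0]
    out = np.zeros((n, 1 << em.n_snps))
    classes, inverse = np.unique(calls, axis=0, return_inverse=True)
    for ci, g in enumerate(classes):
        pairs = _phase_pairs(g)
        probs = np.array(
            [
                (2.0 if h1 != h2 else 1.0) * em.frequencies[h1] * em.frequencies[h2]
                for h1, h2 in pairs
            ]
        )
        total = probs.sum()
        row = np.zeros(1 << em.n_snps)
        if total > 0:
            post = probs / total
            for (h1, h2), w in zip(pairs, post):
                row[h1] += w
                row[h2] += w
        else:  # genotype impossible under fitted freqs: fall back to uniform
            for h1, h2 in pairs:
                row[h1] += 1.0 / len(pairs)
                row[h2] += 1.0 / len(pairs)
        out[inverse == ci] = row
    return out


# ---------------------------------------------------------------------------
# chromosome-wide haplotype association
# ---------------------------------------------------------------------------


def _subdivide_block(
    dataset: GenotypeDataset, cols: np.ndarray, block: HaplotypeBlock, width: int
) -> list[HaplotypeBlock]:
    """Split a block wider than the EM cap into consecutive <=width chunks."""
    if block.n_snps <= width:
        return [block]
    n_chunks = -(-block.n_snps // width)
    bounds = np.linspace(block.start_idx, block.end_idx + 1, n_chunks + 1).astype(int)
    return [
        _make_block(dataset, block.chromosome, cols, int(a), int(b - 1))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def chromosome_haplotype_scan(
    dataset: GenotypeDataset,
    chromosome: str,
    config: PermutationConfig,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
    min_test_freq: float = 0.01,
    blocks: list[HaplotypeBlock] | None = None,
) -> tuple[list[HaplotypeAssociation], pd.DataFrame]:
    """Blocks, haplotype tests, and SNP tests for one chromosome.

    Every haplotype with frequency >= ``min_test_freq`` in every block is
    tested haplotype-vs-all-others on fractional EM dosages, jointly with
    every single SNP on the chromosome; the permutation reference is the
    chromosome-wide maximum over all of these statistics, so the returned
    ``p_chromosome`` values are corrected for the whole chromosome's search.

    Returns (per-block associations, per-SNP DataFrame with p_chromosome).
    """
    cols = dataset.snp_indices(chromosome)
    if blocks is None:
        blocks = four_gamete_blocks(dataset, chromosome, freq_threshold)
    # EM enumerates 2^k haplotypes; blocks beyond the width cap (possible in
    # a swept, recombination-free region) are tested as consecutive chunks
    blocks = [
        sub
        for block in blocks
        for sub in _subdivide_block(dataset, cols, block, MAX_BLOCK_WIDTH)
    ]

    called = dataset.calls[:, cols] != MISSING
    dosage = np.where(called, dataset.calls[:, cols], 0).astype(np.float64)
    columns = [dosage]
    masks = [called]
    owners: list[tuple[HaplotypeBlock, str, float]] = []

    for block in blocks:
        if not block.haplotypes:
            block, em = block_haplotype_frequencies(dataset, block)
        else:
            bcols = cols[block.start_idx : block.end_idx + 1]
            rows = _complete_rows(dataset, bcols)
            em = em_haplotype_frequencies(dataset.calls[np.ix_(rows, bcols)])
        bcols = cols[block.start_idx : block.end_idx + 1]
        rows = _complete_rows(dataset, bcols)
        tested = np.flatnonzero(em.frequencies >= min_test_freq)
        if tested.size == 0:
            continue
        dose = posterior_dosage(em, dataset.calls[np.ix_(rows, bcols)])
        full = np.zeros((dataset.n_samples, tested.size))
        full[rows] = dose[:, tested]
        mask = np.zeros((dataset.n_samples, tested.size), dtype=bool)
        mask[rows] = True
        columns.append(full)
        masks.append(mask)
        owners.extend(
            (block, em.haplotype_string(h), float(em.frequencies[h])) for h in tested
        )

    all_dosage = np.concatenate(columns, axis=1)
    all_called = np.concatenate(masks, axis=1)
    observed, maxima, exhaustive = max_stat_permutation(
        all_dosage,
        all_called,
        dataset.case_mask,
        config,
        breeds=dataset.samples["breed"].to_numpy(),
    )
    pvals = permutation_pvalues(observed, maxima, exhaustive)
    n_snps = cols.size

    snp_table = dataset.snps.iloc[cols][["snp_id", "chromosome", "position_bp"]].copy()
    snp_table["chi2"] = observed[:n_snps]
    snp_table["p_raw"] = chi2_dist.sf(observed[:n_snps], 1)
    snp_table["p_chromosome"] = pvals[:n_snps]

    results: dict[int, list] = {}
    for offset, (block, hap, freq) in enumerate(owners):
        stat = observed[n_snps + offset]
        results.setdefault(id(block), []).append(
            (block, hap, freq, stat, float(chi2_dist.sf(stat, 1)), pvals[n_snps + offset])
        )
    associations = []
    for rows_ in results.values():
        block = rows_[0][0]
        tests = pd.DataFrame(
            [(h, f, s, pr, pc) for _, h, f, s, pr, pc in rows_],
            columns=["haplotype", "frequency", "chi2", "p_raw", "p_chromosome"],
        )
        associations.append(HaplotypeAssociation(block=block, tests=tests))
    return associations, snp_table


def haplotype_association(
    dataset: GenotypeDataset,
    block: HaplotypeBlock,
    config: PermutationConfig,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
    blocks: list[HaplotypeBlock] | None = None,
) -> HaplotypeAssociation:
    """Chromosome-wide-corrected haplotype tests for one block.

    The permutation reference includes all SNP and haplotype statistics on
    the block's chromosome (computing the other blocks if not supplied), so
    the block's p_chromosome values account for the full chromosome-wide
    search exactly as the per-SNP ones do.
    """
    associations, _ = chromosome_haplotype_scan(
        dataset, block.chromosome, config, freq_threshold, blocks=blocks
    )
    for assoc in associations:
        if (
            assoc.block.start_idx == block.start_idx
            and assoc.block.end_idx == block.end_idx
        ):
            return assoc
    raise ValueError("block not found in chromosome partition")
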