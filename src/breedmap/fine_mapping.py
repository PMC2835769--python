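"""Fine mapping by intersecting per-breed homozygous haplotypes.

A trait allele fixed identical-by-descent across breeds sits on a haplotype
that every affected breed carries homozygously; the haplotype extends
further in some breeds than others because recombination eroded its flanks
independently per breed. The critical interval is therefore the stretch of
SNPs, around the anchor (typically the top associated SNP), where *every*
affected breed is homozygous for the *same* allele.

Positions are 1-based; intervals are inclusive ``[start_bp, end_bp]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "BreedHomozygousRun",
    "CriticalInterval",
    "breed_homozygous_run",
    "breed_haplotype_runs",
    "overlap_interval",
]

log = logging.getLogger(__name__)


@dataclass
class BreedHomozygousRun:
    """Maximal homozygous-identical SNP run for one breed around an anchor."""

    breed: str
    chromosome: str
    anchor_snp: str
    snp_ids: list[str]
    positions: list[int]
    haplotype: str  # 'A'/'B' consensus allele per SNP, map order
    n_individuals: int

    @property
    def start_bp(self) -> int:
        return self.positions[0]

    @property
    def end_bp(self) -> int:
        return self.positions[-1]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_bp, self.end_bp)


@dataclass
class CriticalInterval:
    """Shared homozygous haplotype across all supplied runs."""

    chromosome: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]
    haplotype: str
    breeds: list[str]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_bp, self.end_bp)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def _snp_consensus(
    calls: np.ndarray, max_het_fraction: float
) -> tuple[bool, str | None, bool]:
    """Consensus for one SNP column over one breed's individuals.

    Returns (passes, consensus allele 'A'/'B' or None, any_called). A SNP
    passes when the fraction of called individuals that are heterozygous or
    homozygous for the non-consensus allele is <= max_het_fraction. The
    consensus allele is the majority homozygote.
    """
    called = calls != MISSING
    if not called.any():
        return False, None, False
    obs = calls[called]
    n_hom_a = int((obs == 0).sum())
    n_hom_b = int((obs == 2).sum())
    if n_hom_a == 0 and n_hom_b == 0:
        return False, None, True  # everyone heterozygous
    allele = "A" if n_hom_a >= n_hom_b else "B"
    discordant = obs.size - (n_hom_a if allele == "A" else n_hom_b)
    return discordant / obs.size <= max_het_fraction, allele, True


def breed_homozygous_run(
    dataset: GenotypeDataset,
    breed: str,
    anchor_snp: str,
    max_het_fraction: float = 0.0,
) -> BreedHomozygousRun:
    """Extend a homozygous-identical run outward from the anchor SNP.

    At each SNP the breed's called individuals must be homozygous for one
    shared allele, tolerating a fraction ``max_het_fraction`` of
    heterozygous or discordant-homozygous individuals (default 0: strict).
    Missing calls neither break nor support the run, but the run cannot
    extend past a SNP where no breed individual is called.

    Raises if the breed has no individuals, the anchor is uncalled in every
    breed individual, or the anchor SNP itself fails the homozygosity
    criterion (no run can contain it).
    """
    rows = np.flatnonzero(dataset.breed_mask(breed))
    if rows.size == 0:
        raise ValueError(f"breed {breed!r} has no individuals")
    j = dataset.snp_index(anchor_snp)
    chromosome = dataset.snps["chromosome"].iloc[j]
    cols = dataset.snp_indices(chromosome)
    anchor_pos = int(np.flatnonzero(cols == j)[0])

    sub = dataset.calls[np.ix_(rows, cols)]
    ok, allele, any_called = _snp_consensus(sub[:, anchor_pos], max_het_fraction)
    if not any_called:
        raise ValueError(f"anchor {anchor_snp!r} missing in all {breed!r} individuals")
    if not ok:
        raise ValueError(
            f"anchor {anchor_snp!r} is not consensus-homozygous in breed {breed!r}"
        )

    lo = hi = anchor_pos
    alleles = {anchor_pos: allele}
    while lo > 0:
        ok, a, any_called = _snp_consensus(sub[:, lo - 1], max_het_fraction)
        if not ok or not any_called:
            break
        lo -= 1
        alleles[lo] = a
    while hi < cols.size - 1:
        ok, a, any_called = _snp_consensus(sub[:, hi + 1], max_het_fraction)
        if not ok or not any_called:
            break
        hi += 1
        alleles[hi] = a

    span = list(range(lo, hi + 1))
    snps = dataset.snps.iloc[cols[span]]
    return BreedHomozygousRun(
        breed=breed,
        chromosome=chromosome,
        anchor_snp=anchor_snp,
        snp_ids=list(snps["snp_id"]),
        positions=[int(p) for p in snps["position_bp"]],
        haplotype="".join(alleles[i] for i in span),
        n_individuals=rows.size,
    )


def breed_haplotype_runs(
    dataset: GenotypeDataset,
    breed: str,
    anchor_snp: str,
    max_het_fraction: float = 0.0,
    min_individuals: int = 1,
) -> list[BreedHomozygousRun]:
    """One run per distinct within-breed homozygous anchor group.

    Breeds are not always haplotypically uniform: this mode splits the
    breed's individuals by their homozygous allele at the anchor (dropping
    anchor-heterozygous or anchor-missing dogs) and extends a run within
    each subgroup, labelling runs ``breed#A`` / ``breed#B``.
    """
    rows = np.flatnonzero(dataset.breed_mask(breed))
    if rows.size == 0:
        raise ValueError(f"breed {breed!r} has no individuals")
    j = dataset.snp_index(anchor_snp)
    runs = []
    for allele_call, tag in ((0, "A"), (2, "B")):
        sel = rows[dataset.calls[rows, j] == allele_call]
        if sel.size < min_individuals:
            continue
        group = dataset.take_samples(sel)
        label = f"{breed}#{tag}"
        group = GenotypeDataset(
            group.calls, group.samples.assign(breed=label), group.snps
        )
        runs.append(
            breed_homozygous_run(group, label, anchor_snp, max_het_fraction)
        )
    if not runs:
        raise ValueError(
            f"anchor {anchor_snp!r} homozygous in no {breed!r} individuals"
        )
    return runs


def overlap_interval(runs: list[BreedHomozygousRun]) -> CriticalInterval:
    """Critical interval shared by all runs.

    Restricts to SNPs present in every run where every run carries the
    identical consensus allele, and returns the maximal contiguous such
    stretch containing the anchor. Order-invariant and monotone: adding a
    run can only narrow the result.

    Raises if fewer than two runs are given, the runs' intervals do not
    overlap, or they disagree at the anchor/everywhere (listing the
    discordant SNPs).
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to intersect")
    chromosome = runs[0].chromosome
    anchor = runs[0].anchor_snp
    for r in runs[1:]:
        if r.chromosome != chromosome:
            raise ValueError("runs span different chromosomes")
        if r.anchor_snp != anchor:
            raise ValueError("runs have different anchor SNPs")

    maps = [dict(zip(r.snp_ids, r.haplotype)) for r in runs]
    base = runs[0]
    common: list[tuple[str, int, str, bool]] = []
    for snp_id, pos in zip(base.snp_ids, base.positions):
        if not all(snp_id in m for m in maps):
            continue
        alleles = {m[snp_id] for m in maps}
        common.append((snp_id, pos, maps[0][snp_id], len(alleles) == 1))
    if not common:
        raise ValueError("no shared haplotype: run intervals do not overlap")

    ids = [c[0] for c in common]
    if anchor not in ids:
        raise ValueError("no shared haplotype: anchor outside the runs' overlap")
    anchor_i = ids.index(anchor)
    discordant = [c[0] for c in common if not c[3]]
    if not common[anchor_i][3]:
        raise ValueError(
            f"no shared haplotype: breeds discordant at the anchor "
            f"(discordant SNPs: {', '.join(discordant)})"
        )
    lo = anchor_i
    while lo > 0 and common[lo - 1][3]:
        lo -= 1
    hi = anchor_i
    while hi < len(common) - 1 and common[hi + 1][3]:
        hi += 1
    segment = common[lo : hi + 1]
    interval = CriticalInterval(
        chromosome=chromosome,
        start_bp=segment[0][1],
        end_bp=segment[-1][1],
        snp_ids=[s for s, _, _, _ in segment],
        haplotype="".join(a for _, _, a, _ in segment),
        breeds=[r.breed for r in runs],
    )
    log.info(
        "critical interval %s:%d-%d (%d SNPs, %d bp) across %d runs",
        chromosome, interval.start_bp, interval.end_bp,
        len(segment), interval.span_bp, len(runs),
    )
    return interval
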