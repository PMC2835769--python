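"""PLINK-style PED/MAP input/output, the genotype container, and genotype QC.

Genotypes are unphased biallelic SNP calls stored as counts of the per-SNP
*minor* allele: 0 (homozygous major), 1 (heterozygous), 2 (homozygous minor),
or -1 for a missing call. The minor allele is determined once, over the whole
file, when a dataset is loaded, and is never re-derived after subsetting, so
case/control splits cannot flip which allele is counted.

Coordinates are 1-based base pairs; intervals elsewhere in the package are
inclusive ``[start_bp, end_bp]``, matching the PLINK MAP convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "QcReport",
    "QcError",
    "read_ped_map",
    "write_ped_map",
    "apply_qc",
]

log = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in the calls matrix.
MISSING = -1

CASE = "case"
CONTROL = "control"
UNKNOWN = "unknown"

_PHENO_TO_STATUS = {"2": CASE, "1": CONTROL, "0": UNKNOWN, "-9": UNKNOWN}
_STATUS_TO_PHENO = {CASE: "2", CONTROL: "1", UNKNOWN: "0"}


class QcError(RuntimeError):
    """Raised when a QC step would empty the dataset; carries the report."""

    def __init__(self, message: str, report: "QcReport"):
        super().__init__(f"{message}\n{report}")
        self.report = report


class GenotypeDataset:
    """Samples x SNPs matrix of minor-allele counts plus metadata.

    Parameters
    ----------
    calls
        Integer matrix, one row per sample and one column per SNP, with
        entries in {0, 1, 2, -1} (-1 = missing).
    samples
        DataFrame with columns ``sample_id``, ``breed``, ``status``
        (status one of ``case``/``control``/``unknown``).
    snps
        DataFrame with columns ``snp_id``, ``chromosome``, ``position_bp``.
        Positions must be strictly increasing within each chromosome.
    """

    def __init__(self, calls: np.ndarray, samples: pd.DataFrame, snps: pd.DataFrame):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x SNPs matrix")
        samples = samples.reset_index(drop=True)
        snps = snps.reset_index(drop=True)
        if calls.shape != (len(samples), len(snps)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(snps)} SNPs"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"invalid call {calls[i, j]} at sample row {i}, SNP column {j}")
        if samples["sample_id"].duplicated().any():
            dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if snps["snp_id"].duplicated().any():
            dup = snps.loc[snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")
        for chrom, grp in snps.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        self.calls = calls
        self.samples = samples
        self.snps = snps

    # -- basic shape ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.snps["chromosome"]))

    # -- masks and views -----------------------------------------------------

    @property
    def called(self) -> np.ndarray:
        """Boolean matrix: True where the call is non-missing."""
        return self.calls != MISSING

    def status_mask(self, status: str) -> np.ndarray:
        return (self.samples["status"] == status).to_numpy()

    @property
    def case_mask(self) -> np.ndarray:
        return self.status_mask(CASE)

    @property
    def control_mask(self) -> np.ndarray:
        return self.status_mask(CONTROL)

    def breed_mask(self, breed: str) -> np.ndarray:
        return (self.samples["breed"] == breed).to_numpy()

    def snp_indices(self, chromosome: str) -> np.ndarray:
        """Column indices of the SNPs on one chromosome, in map order."""
        idx = np.flatnonzero((self.snps["chromosome"] == chromosome).to_numpy())
        if idx.size == 0:
            raise KeyError(f"chromosome {chromosome!r} not in dataset")
        return idx

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero((self.snps["snp_id"] == snp_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"snp_id {snp_id!r} not in dataset")
        return int(hits[0])

    def take_samples(self, index: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            self.calls[np.asarray(index)], self.samples.iloc[np.asarray(index)], self.snps
        )

    def take_snps(self, index: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            self.calls[:, np.asarray(index)], self.samples, self.snps.iloc[np.asarray(index)]
        )

    def subset_chromosome(self, chromosome: str) -> "GenotypeDataset":
        return self.take_snps(self.snp_indices(chromosome))

    # -- per-SNP summaries ---------------------------------------------------

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele among non-missing calls.

        NaN for SNPs with no calls at all. Note the counted allele is the
        minor allele *as determined at load time*; after subsetting it may
        exceed 0.5.
        """
        called = self.called
        n_alleles = 2 * called.sum(axis=0)
        minor = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, minor / n_alleles, np.nan)

    def snp_call_rate(self) -> np.ndarray:
        return self.called.mean(axis=0) if self.n_samples else np.ones(self.n_snps)

    def sample_missing_rate(self) -> np.ndarray:
        return 1.0 - self.called.mean(axis=1) if self.n_snps else np.zeros(self.n_samples)

    # -- misc ----------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.calls, other.calls)
            and self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and self.snps.reset_index(drop=True).equals(other.snps.reset_index(drop=True))
        )

    def __repr__(self) -> str:
        return f"GenotypeDataset({self.n_samples} samples x {self.n_snps} SNPs)"


@dataclass
class QcReport:
    """Accounting of one `apply_qc` pass."""

    n_samples_in: int
    n_snps_in: int
    samples_removed_missingness: int
    snps_removed_callrate: int
    snps_removed_maf: int
    maf_min: float
    snp_callrate_min: float
    sample_missing_max: float

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_missingness

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - self.snps_removed_callrate - self.snps_removed_maf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(vars(self)), "value": list(vars(self).values())}
        )

    def __str__(self) -> str:
        return (
            f"QC: samples {self.n_samples_in} -> {self.n_samples_out} "
            f"(-{self.samples_removed_missingness} missingness > {self.sample_missing_max}); "
            f"SNPs {self.n_snps_in} -> {self.n_snps_out} "
            f"(-{self.snps_removed_callrate} call rate < {self.snp_callrate_min}, "
            f"-{self.snps_removed_maf} MAF <= {self.maf_min})"
        )


# ---------------------------------------------------------------------------
# PED/MAP text I/O
# ---------------------------------------------------------------------------


def _parse_map(map_path: Path) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) == 4:
            chrom, snp_id, _cm, pos = fields
        elif len(fields) == 3:
            chrom, snp_id, pos = fields
        else:
            raise ValueError(f"{map_path}: line {lineno}: expected 3 or 4 fields, got {len(fields)}")
        rows.append((snp_id, chrom, int(pos)))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Load a whitespace-separated PED/MAP pair into a `GenotypeDataset`.

    The PED family-ID column is interpreted as the breed label; the phenotype
    column maps 2 -> case, 1 -> control, 0/-9 -> unknown. ``0`` alleles are
    missing. Each SNP's minor allele (the rarer symbol over the whole file,
    ties broken toward the lexicographically larger symbol) becomes the
    counted allele. SNPs are sorted by position within each chromosome;
    chromosomes keep their order of first appearance in the MAP file.

    Raises
    ------
    ValueError
        On a PED/MAP dimension mismatch (naming the row) or a SNP with more
        than two allele symbols (naming the snp_id).
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    snps = _parse_map(map_path)
    n_snps = len(snps)

    meta_rows: list[tuple[str, str, str]] = []
    allele_rows: list[list[str]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 6 + 2 * n_snps:
            raise ValueError(
                f"{ped_path}: row {lineno}: expected {6 + 2 * n_snps} fields for "
                f"{n_snps} MAP SNPs, got {len(fields)}"
            )
        breed, sample_id = fields[0], fields[1]
        status = _PHENO_TO_STATUS.get(fields[5], UNKNOWN)
        meta_rows.append((sample_id, breed, status))
        allele_rows.append(fields[6:])

    samples = pd.DataFrame(meta_rows, columns=["sample_id", "breed", "status"])
    n_samples = len(samples)
    alleles = (
        np.array(allele_rows, dtype="U8").reshape(n_samples, n_snps, 2)
        if n_samples
        else np.empty((0, n_snps, 2), dtype="U8")
    )

    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        symbols, counts = np.unique(observed, return_counts=True)
        if len(symbols) > 2:
            raise ValueError(
                f"SNP {snps['snp_id'].iloc[j]!r} is not biallelic: "
                f"alleles {sorted(symbols)}"
            )
        if len(symbols) == 0:
            continue  # entirely missing column stays missing
        if len(symbols) == 1:
            minor = None  # monomorphic: counted allele unobserved
        else:
            order = np.lexsort((symbols, counts))  # by count, ties by symbol
            # rarer symbol is minor; on a count tie the lexicographically
            # larger symbol is minor so write->read round-trips (A=major).
            if counts[order[0]] == counts[order[1]]:
                minor = max(symbols)
            else:
                minor = symbols[order[0]]
        row_missing = (col == "0").any(axis=1)
        if minor is None:
            calls[~row_missing, j] = 0
        else:
            cnt = (col == minor).sum(axis=1)
            calls[~row_missing, j] = cnt[~row_missing]

    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(snps["chromosome"]))}
    order = (
        snps.assign(_c=snps["chromosome"].map(chrom_order))
        .sort_values(["_c", "position_bp"], kind="stable")
        .index.to_numpy()
    )
    ds = GenotypeDataset(calls[:, order], samples, snps.iloc[order])
    log.info("read %s: %d samples, %d SNPs", ped_path.name, ds.n_samples, ds.n_snps)
    return ds


def write_ped_map(
    dataset: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a dataset as a PED/MAP pair readable by `read_ped_map`.

    Allele symbols are fixed as A = major (uncounted) and B = minor
    (counted); missing calls become ``0 0``. Reading the files back
    reproduces the dataset exactly provided the counted allele really is
    the minor one (frequency <= 0.5) at every SNP, which holds for any
    dataset produced by `read_ped_map`; a column counting a majority
    allele is re-polarized on reload.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    with open(map_path, "w") as fh:
        for row in dataset.snps.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")

    genotype_text = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, samp in enumerate(dataset.samples.itertuples(index=False)):
            geno = "\t".join(genotype_text[int(c)] for c in dataset.calls[i])
            pheno = _STATUS_TO_PHENO.get(samp.status, "0")
            lead = f"{samp.breed}\t{samp.sample_id}\t0\t0\t0\t{pheno}"
            fh.write(lead + ("\t" + geno if geno else "") + "\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def apply_qc(
    dataset: GenotypeDataset,
    maf_min: float = 0.05,
    snp_callrate_min: float = 0.75,
    sample_missing_max: float = 0.25,
) -> tuple[GenotypeDataset, QcReport]:
    """Apply the standard association QC filters.

    Filtering order is fixed: (1) samples whose missingness over the input
    SNP set exceeds ``sample_missing_max`` are dropped; (2) SNPs with call
    rate below ``snp_callrate_min`` on the retained samples are dropped;
    (3) SNPs whose minor-allele frequency (non-missing calls, retained
    samples) is not strictly greater than ``maf_min`` are dropped. A
    ``maf_min`` of 0 disables the MAF filter (monomorphic SNPs are kept).

    Returns the filtered dataset and a `QcReport`; raises `QcError` if any
    step would remove everything.
    """
    for name, value in (
        ("maf_min", maf_min),
        ("snp_callrate_min", snp_callrate_min),
        ("sample_missing_max", sample_missing_max),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")

    n_samples_in, n_snps_in = dataset.n_samples, dataset.n_snps

    keep_samples = dataset.sample_missing_rate() <= sample_missing_max
    ds = dataset.take_samples(np.flatnonzero(keep_samples))
    n_removed_samples = int((~keep_samples).sum())

    keep_callrate = ds.snp_call_rate() >= snp_callrate_min
    n_removed_callrate = int((~keep_callrate).sum())
    ds = ds.take_snps(np.flatnonzero(keep_callrate))

    if maf_min > 0:
        maf = ds.minor_allele_frequency()
        # counted allele may exceed 0.5 after sample subsetting; fold it
        maf = np.where(np.isnan(maf), 0.0, np.minimum(maf, 1.0 - maf))
        keep_maf = maf > maf_min
    else:
        keep_maf = np.ones(ds.n_snps, dtype=bool)
    n_removed_maf = int((~keep_maf).sum())
    ds = ds.take_snps(np.flatnonzero(keep_maf))

    report = QcReport(
        n_samples_in=n_samples_in,
        n_snps_in=n_snps_in,
        samples_removed_missingness=n_removed_samples,
        snps_removed_callrate=n_removed_callrate,
        snps_removed_maf=n_removed_maf,
        maf_min=maf_min,
        snp_callrate_min=snp_callrate_min,
        sample_missing_max=sample_missing_max,
    )
    log.info("%s", report)
    if ds.n_samples == 0:
        raise QcError("QC removed every sample", report)
    if ds.n_snps == 0:
        raise QcError("QC removed every SNP", report)
    return ds, report
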