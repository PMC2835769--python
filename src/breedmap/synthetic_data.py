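"""Multi-breed genotype simulator with a planted, breed-fixed sweep locus.

The generator realizes the three population-genetic features the
across-breed mapping strategy exploits:

* **Short across-breed LD** — an ancestral haplotype pool whose allelic
  correlation between neighbouring SNPs decays exponentially with physical
  distance at scale ``ld_scale_bp``.
* **Long within-breed LD and reduced diversity** — each breed is founded
  from a small number of pool haplotypes (the breed-formation bottleneck)
  and then drifts for a few non-overlapping Wright-Fisher generations with
  recombination (1 cM/Mb), so breed members share long founder segments.
* **A shared IBD sweep** — in every affected breed, both haplotypes of
  every dog are overwritten with one single ancestral haplotype across a
  core around the causal SNP, with independent per-breed geometric erosion
  of the core's flanks. The causal allele is thereby fixed and the core is
  completely homozygous within each affected breed, while the *overlap* of
  the eroded cores across breeds narrows towards the causal SNP — the
  structure homozygosity fine mapping recovers.

Phenotype is deterministic on breed membership (the trait is fixed within
breeds); there is no penetrance model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .genotype_io import CASE, CONTROL, MISSING, GenotypeDataset

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_ancestral_pool",
    "simulate_breeds",
    "reference_study_scenario",
    "null_calibration_scenario",
]

log = logging.getLogger(__name__)

RECOMB_RATE_PER_BP = 1e-8  # 1 cM/Mb


@dataclass
class SimConfig:
    """Simulation scenario.

    Defaults describe the desk-scale study design: a 5-chromosome,
    2,000-SNP stand-in for a ~50K array at ~50 kb average spacing, breeds
    predicted to carry ~500 kb LD, 9 affected and 13 control breeds
    totalling 20 case and 31 control dogs, and a 1 Mb fixed IBD core
    around the causal locus (about twice the within-breed LD scale, the
    footprint a recent breed-defining sweep would leave at this marker
    density).
    """

    n_chromosomes: int = 5
    snps_per_chromosome: int = 400
    mean_spacing_bp: int = 50_000
    ld_scale_bp: float = 500_000.0
    n_affected_breeds: int = 9
    n_control_breeds: int = 13
    dogs_per_breed: int = 3
    affected_breed_sizes: list[int] | None = None
    control_breed_sizes: list[int] | None = None
    pool_haplotypes: int = 200
    founder_haplotypes_per_breed: int = 20
    drift_generations: int = 10
    causal_chromosome: str = "1"
    causal_position_bp: int = 10_000_000
    sweep_core_bp: int = 1_000_000
    flank_erosion_mean_snps: float = 1.5
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "n_chromosomes": self.n_chromosomes,
            "snps_per_chromosome": self.snps_per_chromosome,
            "mean_spacing_bp": self.mean_spacing_bp,
            "ld_scale_bp": self.ld_scale_bp,
            "n_affected_breeds": self.n_affected_breeds,
            "n_control_breeds": self.n_control_breeds,
            "dogs_per_breed": self.dogs_per_breed,
            "pool_haplotypes": self.pool_haplotypes,
            "founder_haplotypes_per_breed": self.founder_haplotypes_per_breed,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.drift_generations < 0 or self.sweep_core_bp < 0:
            raise ValueError("drift_generations and sweep_core_bp must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.founder_haplotypes_per_breed > self.pool_haplotypes:
            raise ValueError("founder haplotypes exceed the ancestral pool")
        if self.causal_position_bp <= 0:
            raise ValueError("causal_position_bp must be positive")
        for sizes, n in (
            (self.affected_breed_sizes, self.n_affected_breeds),
            (self.control_breed_sizes, self.n_control_breeds),
        ):
            if sizes is not None and (len(sizes) != n or min(sizes) < 1):
                raise ValueError("breed size list must match breed count, all >= 1")

    def breed_sizes(self) -> tuple[list[int], list[int]]:
        aff = self.affected_breed_sizes or [self.dogs_per_breed] * self.n_affected_breeds
        ctl = self.control_breed_sizes or [self.dogs_per_breed] * self.n_control_breeds
        return list(aff), list(ctl)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal_snp_id: str
    causal_chromosome: str
    causal_position_bp: int
    affected_breeds: list[str]
    core_start_bp: int
    core_end_bp: int
    planted_haplotype: str  # A/B string over the core SNPs
    breed_core_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def core_interval(self) -> tuple[int, int]:
        return (self.core_start_bp, self.core_end_bp)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("causal_snp_id", self.causal_snp_id),
            ("causal_chromosome", self.causal_chromosome),
            ("causal_position_bp", self.causal_position_bp),
            ("affected_breeds", ",".join(self.affected_breeds)),
            ("core_start_bp", self.core_start_bp),
            ("core_end_bp", self.core_end_bp),
            ("planted_haplotype", self.planted_haplotype),
        ]
        rows += [
            (f"core_{breed}", f"{a}-{b}")
            for breed, (a, b) in self.breed_core_intervals.items()
        ]
        return pd.DataFrame(rows, columns=["field", "value"])


@dataclass
class AncestralPool:
    """Pool of phased haplotypes plus the shared SNP map."""

    haplotypes: np.ndarray  # (pool_haplotypes, n_snps) over {0,1}
    snps: pd.DataFrame  # snp_id, chromosome, position_bp
    allele_freqs: np.ndarray


def _chromosome_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    gaps = rng.exponential(config.mean_spacing_bp, config.snps_per_chromosome)
    gaps = np.maximum(1, np.round(gaps)).astype(np.int64)
    return np.cumsum(gaps)


def simulate_ancestral_pool(
    config: SimConfig, rng: np.random.Generator | None = None
) -> AncestralPool:
    """Ancestral haplotype pool with distance-decaying LD.

    Per-SNP allele frequencies are drawn from a U-shaped Beta(0.5, 0.5)
    rescaled onto (0.05, 0.95). Along each chromosome, each haplotype is a
    thresholded latent Gaussian AR(1) path (a Gaussian copula): the latent
    correlation between SNPs at distance d is exp(-d / ld_scale_bp), which
    multiplies exactly across gaps, so the allelic r^2 decays with distance
    at scale ~ld_scale_bp / 2 regardless of the frequency draws.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_pool = config.pool_haplotypes

    hap_parts, snp_rows, freq_parts = [], [], []
    for c in range(1, config.n_chromosomes + 1):
        chrom = str(c)
        pos = _chromosome_positions(config, rng)
        s = pos.size
        p = 0.05 + 0.90 * rng.beta(0.5, 0.5, size=s)
        thresholds = ndtri(p)
        z = np.empty((n_pool, s))
        z[:, 0] = rng.standard_normal(n_pool)
        for j in range(1, s):
            a = np.exp(-(pos[j] - pos[j - 1]) / config.ld_scale_bp)
            z[:, j] = a * z[:, j - 1] + np.sqrt(1.0 - a * a) * rng.standard_normal(
                n_pool
            )
        haps = (z < thresholds[None, :]).astype(np.int8)
        hap_parts.append(haps)
        freq_parts.append(p)
        snp_rows += [(f"Chr{chrom}.{int(bp)}", chrom, int(bp)) for bp in pos]

    return AncestralPool(
        haplotypes=np.concatenate(hap_parts, axis=1),
        snps=pd.DataFrame(snp_rows, columns=["snp_id", "chromosome", "position_bp"]),
        allele_freqs=np.concatenate(freq_parts),
    )


def _recombine(
    parents: np.ndarray, pairs: np.ndarray, crossover_p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Offspring haplotypes from parent pairs with per-gap crossovers."""
    n_off = pairs.shape[0]
    n_snps = parents.shape[1]
    breaks = rng.random((n_off, n_snps - 1)) < crossover_p[None, :]
    which = np.empty((n_off, n_snps), dtype=np.int8)
    which[:, 0] = rng.integers(0, 2, n_off)
    np.bitwise_xor.accumulate(
        np.concatenate([which[:, :1], breaks.astype(np.int8)], axis=1),
        axis=1,
        out=which,
    )
    a = parents[pairs[:, 0]]
    b = parents[pairs[:, 1]]
    return np.where(which == 0, a, b)


def _drift_breed(
    founders: np.ndarray, generations: int, crossover_p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    haps = founders
    n = haps.shape[0]
    for _ in range(generations):
        pairs = rng.integers(0, n, size=(n, 2))
        haps = _recombine(haps, pairs, crossover_p, rng)
    return haps


def simulate_breeds(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate the full multi-breed case/control dataset plus ground truth.

    Breeds are labelled ``AFF1..`` (cases) and ``CTL1..`` (controls). When
    ``drift_generations`` is 0 the founder bottleneck is skipped and every
    dog's haplotypes are drawn i.i.d. from the ancestral pool — the
    exchangeable-individuals configuration used for permutation-calibration
    checks. A ``sweep_core_bp`` of 0 disables the planted sweep (null
    mode). Deterministic given ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    pool_rng, breed_rng, sweep_rng, miss_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    pool = simulate_ancestral_pool(config, pool_rng)
    snps = pool.snps
    pos = snps["position_bp"].to_numpy()
    gaps_all = np.diff(pos).astype(np.float64)
    same_chrom = (
        snps["chromosome"].to_numpy()[1:] == snps["chromosome"].to_numpy()[:-1]
    )
    crossover_p = np.where(
        same_chrom, np.minimum(0.5, gaps_all * RECOMB_RATE_PER_BP), 0.5
    )

    aff_sizes, ctl_sizes = config.breed_sizes()
    breeds = [(f"AFF{i + 1}", n, CASE) for i, n in enumerate(aff_sizes)]
    breeds += [(f"CTL{i + 1}", n, CONTROL) for i, n in enumerate(ctl_sizes)]

    # causal SNP and planted haplotype
    chrom_cols = np.flatnonzero(
        (snps["chromosome"] == config.causal_chromosome).to_numpy()
    )
    if chrom_cols.size == 0:
        raise ValueError(f"causal chromosome {config.causal_chromosome!r} not simulated")
    causal_j = int(
        chrom_cols[np.argmin(np.abs(pos[chrom_cols] - config.causal_position_bp))]
    )
    causal_pos = int(pos[causal_j])

    planted = None
    core_cols = np.array([causal_j])
    if config.sweep_core_bp > 0:
        half = config.sweep_core_bp / 2
        core_cols = chrom_cols[
            (pos[chrom_cols] >= causal_pos - half) & (pos[chrom_cols] <= causal_pos + half)
        ]
        # the trait allele is the rarer one at the causal SNP: pick a pool
        # haplotype carrying it as the shared ancestral trait haplotype
        freq = pool.allele_freqs[causal_j]
        trait_allele = 1 if freq <= 0.5 else 0
        carriers = np.flatnonzero(pool.haplotypes[:, causal_j] == trait_allele)
        if carriers.size == 0:  # extreme frequency draw: fall back to any
            carriers = np.arange(pool.haplotypes.shape[0])
        planted = pool.haplotypes[sweep_rng.choice(carriers)].copy()

    sample_rows, call_rows = [], []
    truth_breed_cores: dict[str, tuple[int, int]] = {}
    for breed, n_dogs, status in breeds:
        if config.drift_generations == 0:
            haps = pool.haplotypes[
                breed_rng.integers(0, pool.haplotypes.shape[0], size=2 * n_dogs)
            ].copy()
        else:
            founder_idx = breed_rng.choice(
                pool.haplotypes.shape[0],
                config.founder_haplotypes_per_breed,
                replace=False,
            )
            drifted = _drift_breed(
                pool.haplotypes[founder_idx],
                config.drift_generations,
                crossover_p,
                breed_rng,
            )
            haps = drifted[
                breed_rng.integers(0, drifted.shape[0], size=2 * n_dogs)
            ].copy()

        if planted is not None and status == CASE:
            erode_l, erode_r = sweep_rng.geometric(
                1.0 / (1.0 + config.flank_erosion_mean_snps), size=2
            ) - 1
            lo = np.searchsorted(core_cols, causal_j)
            left = min(int(erode_l), lo)
            right = min(int(erode_r), core_cols.size - 1 - lo)
            breed_core = core_cols[left : core_cols.size - right]
            haps[:, breed_core] = planted[breed_core]
            truth_breed_cores[breed] = (
                int(pos[breed_core[0]]),
                int(pos[breed_core[-1]]),
            )

        geno = haps[0::2] + haps[1::2]
        call_rows.append(geno.astype(np.int8))
        sample_rows += [
            (f"{breed}_{d + 1}", breed, status) for d in range(n_dogs)
        ]

    calls = np.concatenate(call_rows, axis=0)
    if config.missing_rate > 0:
        mask = miss_rng.random(calls.shape) < config.missing_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "breed", "status"])
    dataset = GenotypeDataset(calls, samples, snps)
    truth = SimTruth(
        causal_snp_id=snps["snp_id"].iloc[causal_j],
        causal_chromosome=config.causal_chromosome,
        causal_position_bp=causal_pos,
        affected_breeds=[b for b, _, s in breeds if s == CASE],
        core_start_bp=int(pos[core_cols[0]]),
        core_end_bp=int(pos[core_cols[-1]]),
        planted_haplotype=(
            "".join("B" if a else "A" for a in planted[core_cols])
            if planted is not None
            else ""
        ),
        breed_core_intervals=truth_breed_cores,
    )
    log.info(
        "simulated %d dogs x %d SNPs; causal %s, core %d-%d",
        dataset.n_samples, dataset.n_snps, truth.causal_snp_id,
        truth.core_start_bp, truth.core_end_bp,
    )
    return dataset, truth


def reference_study_scenario() -> SimConfig:
    """The reference across-breed study design at desk scale.

    Nine affected breeds carrying 20 case dogs and thirteen control breeds
    carrying 31 control dogs, genotyped on a 5-chromosome x 400-SNP map at
    ~50 kb spacing with ~500 kb LD, and a 1 Mb planted sweep core on
    chromosome 1.
    """
    return SimConfig(
        affected_breed_sizes=[3, 3, 2, 2, 2, 2, 2, 2, 2],  # 20 cases
        control_breed_sizes=[3, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2],  # 31 controls
    )


def null_calibration_scenario(seed: int = 0) -> SimConfig:
    """Exchangeable-individuals null for permutation-calibration checks.

    No planted sweep (``sweep_core_bp = 0``) and no breed bottleneck
    (``drift_generations = 0``: haplotypes i.i.d. from the pool), so
    case/control labels are exchangeable over individuals and an
    individual-label permutation test should be exactly calibrated. Breed
    labels remain attached to whole breeds, so "which breeds are cases" is
    random only through symmetry. Scaled down for replicate studies.
    """
    return SimConfig(
        n_chromosomes=2,
        snps_per_chromosome=150,
        n_affected_breeds=5,
        n_control_breeds=5,
        dogs_per_breed=3,
        drift_generations=0,
        sweep_core_bp=0,
        causal_position_bp=4_000_000,
        missing_rate=0.02,
        seed=seed,
    )
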