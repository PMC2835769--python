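"""End-to-end orchestration: simulate/load -> QC -> association -> haplotypes
-> sweep scan -> fine mapping, with per-stage TSV artifacts and a run report.

Random-number streams are split per stage from the master seed, so changing
one stage's settings (e.g. the permutation count) does not perturb the
others' draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    PermutationConfig,
    ScanResult,
    locus_support_ratio,
    max_t_permutation,
)
from .fine_mapping import (
    BreedHomozygousRun,
    CriticalInterval,
    breed_homozygous_run,
    overlap_interval,
)
from .genotype_io import GenotypeDataset, QcReport, apply_qc, read_ped_map, write_ped_map
from .haplotype import HaplotypeAssociation, chromosome_haplotype_scan
from .sweep_scan import SweepProfile, sliding_profile, sweep_qc
from .synthetic_data import (
    SimConfig,
    SimTruth,
    reference_study_scenario,
    null_calibration_scenario,
    simulate_breeds,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    Exactly one of (``ped_path`` + ``map_path``) or ``scenario`` must be
    given. ``n_permutations`` is genome-wide, ``n_permutations_chromosome``
    chromosome-wide (the haplotype stage); both derive their seeds from
    ``seed``.
    """

    ped_path: str | None = None
    map_path: str | None = None
    scenario: SimConfig | None = None
    out_dir: str = "breedmap_out"
    seed: int = 0
    maf_min: float = 0.05
    snp_callrate_min: float = 0.75
    sample_missing_max: float = 0.25
    n_permutations: int = 100_000
    n_permutations_chromosome: int = 50_000
    sweep_window_snps: int = 5
    finemap_anchor: str | None = None  # default: top association SNP
    finemap_max_het_fraction: float = 0.0
    run_haplotypes: bool = True

    def validate(self) -> None:
        file_mode = self.ped_path is not None or self.map_path is not None
        if file_mode == (self.scenario is not None):
            raise ValueError("give exactly one of PED/MAP paths or a simulation scenario")
        if file_mode and (self.ped_path is None or self.map_path is None):
            raise ValueError("file mode needs both ped_path and map_path")
        if file_mode:
            for p in (self.ped_path, self.map_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenario = raw.pop("scenario", None)
        cfg = cls(**raw)
        if scenario is not None:
            if isinstance(scenario, str):
                cfg.scenario = named_scenario(scenario, seed=cfg.seed)
            else:
                cfg.scenario = SimConfig(**scenario)
        return cfg


def named_scenario(name: str, seed: int = 0) -> SimConfig:
    from dataclasses import replace

    if name == "default":
        return replace(reference_study_scenario(), seed=seed)
    if name == "null":
        return null_calibration_scenario(seed=seed)
    raise ValueError(f"unknown scenario {name!r} (use 'default' or 'null')")


@dataclass
class RunReport:
    """Stage-by-stage outcome of one pipeline run."""

    seed: int
    version: str
    qc: QcReport
    scan: ScanResult
    haplotype_hits: list[HaplotypeAssociation]
    sweep: SweepProfile | None
    sweep_minimum: pd.Series | None
    runs: list[BreedHomozygousRun]
    skipped_breeds: list[str]
    critical_interval: CriticalInterval | None
    truth: SimTruth | None = None
    stage_notes: dict[str, str] = field(default_factory=dict)

    def to_text(self) -> str:
        best = self.scan.best
        lines = [
            f"breedmap {self.version} run report (seed {self.seed})",
            "",
            f"[qc] {self.qc}",
            f"[association] top locus {best['snp_id']} "
            f"chr{best['chromosome']}:{best['position_bp']} "
            f"chi2={best['chi2']:.3f} p_raw={best['p_raw']:.3g} "
            f"p_genome={best['p_genome']:.3g}",
            f"[association] support ratio {self.scan.support_ratio:.1f} -> "
            f"{'accepted' if self.scan.accepted else 'not accepted'} (threshold >100)",
        ]
        if self.haplotype_hits:
            top = min(
                (
                    (assoc, row)
                    for assoc in self.haplotype_hits
                    for row in assoc.tests.itertuples()
                ),
                key=lambda t: (t[1].p_chromosome, -t[1].chi2),
            )
            assoc, row = top
            lines.append(
                f"[haplotype] best haplotype {row.haplotype} "
                f"in block {assoc.block.start_bp}-{assoc.block.end_bp} "
                f"({assoc.block.n_snps} SNPs, {assoc.block.span_bp} bp): "
                f"freq={row.frequency:.3f} chi2={row.chi2:.3f} "
                f"p_chromosome={row.p_chromosome:.3g}"
            )
        if self.sweep_minimum is not None:
            lines.append(
                f"[sweep] minimum normalized relative heterozygosity "
                f"{self.sweep_minimum['normalized']:.3f} at "
                f"{self.sweep_minimum['midpoint_bp']:.0f} bp "
                f"({self.sweep.window_snps}-SNP windows)"
            )
        if self.critical_interval is not None:
            ci = self.critical_interval
            lines.append(
                f"[finemap] critical interval chr{ci.chromosome}:"
                f"{ci.start_bp}-{ci.end_bp} ({ci.span_bp} bp, "
                f"{len(ci.snp_ids)} SNPs) across {len(ci.breeds)} breed runs"
            )
        if self.skipped_breeds:
            lines.append(
                f"[finemap] skipped breeds without a consensus-homozygous anchor: "
                f"{', '.join(self.skipped_breeds)}"
            )
        for stage, note in self.stage_notes.items():
            lines.append(f"[{stage}] {note}")
        if self.truth is not None:
            lines.append(
                f"[truth] causal {self.truth.causal_snp_id} core "
                f"{self.truth.core_start_bp}-{self.truth.core_end_bp}"
            )
        return "\n".join(lines) + "\n"


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence(master).spawn(stage + 1)[stage].generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full across-breed mapping workflow.

    Stage order follows the analysis narrative: genotype QC, genome-wide
    max-T association, best-locus acceptance, chromosome-wide haplotype
    analysis on the top chromosome, sweep scan on the top chromosome, and
    homozygosity fine mapping anchored at the top SNP. All stage artifacts
    are written to ``config.out_dir`` as TSV; a failure in one stage aborts
    with the stage name while earlier artifacts persist. Deterministic
    given ``config.seed``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.scenario is not None:
        dataset, truth = simulate_breeds(config.scenario)
        write_ped_map(dataset, out / "simulated.ped", out / "simulated.map")
        truth.to_frame().to_csv(out / "sim_truth.tsv", sep="\t", index=False)
    else:
        dataset = read_ped_map(config.ped_path, config.map_path)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    qc_ds, qc_report = stage(
        "qc",
        lambda: apply_qc(
            dataset,
            maf_min=config.maf_min,
            snp_callrate_min=config.snp_callrate_min,
            sample_missing_max=config.sample_missing_max,
        ),
    )
    qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)

    assoc = stage(
        "association",
        lambda: max_t_permutation(
            qc_ds,
            PermutationConfig(
                n_permutations=config.n_permutations, seed=_stage_seed(config.seed, 0)
            ),
        ),
    )
    assoc.to_csv(out / "association.tsv", sep="\t", index=False)
    scan = stage("association", lambda: locus_support_ratio(assoc))
    top_chrom = str(scan.best["chromosome"])

    notes: dict[str, str] = {}
    haplotype_hits: list[HaplotypeAssociation] = []
    if config.run_haplotypes:
        haplotype_hits, hap_snps = stage(
            "haplotype",
            lambda: chromosome_haplotype_scan(
                qc_ds,
                top_chrom,
                PermutationConfig(
                    n_permutations=config.n_permutations_chromosome,
                    seed=_stage_seed(config.seed, 1),
                ),
            ),
        )
        rows = []
        for assoc_h in haplotype_hits:
            for r in assoc_h.tests.itertuples():
                rows.append(
                    (
                        assoc_h.block.chromosome,
                        assoc_h.block.start_bp,
                        assoc_h.block.end_bp,
                        r.haplotype,
                        r.frequency,
                        r.chi2,
                        r.p_raw,
                        r.p_chromosome,
                    )
                )
        pd.DataFrame(
            rows,
            columns=[
                "chromosome", "start_bp", "end_bp", "haplotype",
                "frequency", "chi2", "p_raw", "p_chromosome",
            ],
        ).to_csv(out / "haplotype_association.tsv", sep="\t", index=False)
    else:
        notes["haplotype"] = "skipped by configuration"

    sweep_ds = stage("sweep", lambda: sweep_qc(dataset))
    profile = stage(
        "sweep",
        lambda: sliding_profile(sweep_ds, top_chrom, config.sweep_window_snps),
    )
    profile.windows.to_csv(out / "sweep_profile.tsv", sep="\t", index=False)
    # localize the sweep on the floor-mode profile: under the literal
    # formula a fully swept window (ratio 0) scores -1 and would be
    # out-ranked by any near-zero-ratio window elsewhere
    floor_profile = stage(
        "sweep",
        lambda: sliding_profile(
            sweep_ds, top_chrom, config.sweep_window_snps, zero_mode="floor"
        ),
    )
    sweep_min = floor_profile.minimum()

    # anchor at the top association; when the affected breeds share no
    # homozygous haplotype there (the top SNP can sit at the eroded edge of
    # the shared segment), fall back to the next most-associated SNPs
    if config.finemap_anchor is not None:
        anchors = [config.finemap_anchor]
    else:
        top_snps = assoc.loc[assoc["chromosome"] == top_chrom].sort_values(
            ["p_genome", "chi2"], ascending=[True, False], kind="stable"
        )
        anchors = list(top_snps["snp_id"].head(10))
    affected = sorted(set(qc_ds.samples.loc[qc_ds.case_mask, "breed"]))
    runs: list[BreedHomozygousRun] = []
    skipped: list[str] = []
    critical = None
    for anchor in anchors:
        runs, skipped = [], []
        for breed in affected:
            try:
                runs.append(
                    breed_homozygous_run(
                        qc_ds, breed, anchor, config.finemap_max_het_fraction
                    )
                )
            except (ValueError, KeyError) as exc:
                log.warning("fine mapping: skipping breed %s: %s", breed, exc)
                skipped.append(breed)
        if len(runs) < 2:
            notes["finemap"] = "fewer than two usable breed runs"
            continue
        try:
            critical = overlap_interval(runs)
            notes.pop("finemap", None)
            if anchor != anchors[0]:
                notes["finemap"] = f"anchored at fallback SNP {anchor}"
            break
        except ValueError as exc:
            notes["finemap"] = f"no critical interval: {exc}"
    if runs:
        pd.DataFrame(
            [
                (r.breed, r.chromosome, r.start_bp, r.end_bp, len(r.snp_ids),
                 r.n_individuals, r.haplotype)
                for r in runs
            ],
            columns=["breed", "chromosome", "start_bp", "end_bp", "n_snps",
                     "n_individuals", "haplotype"],
        ).to_csv(out / "homozygous_runs.tsv", sep="\t", index=False)
    if critical is not None:
        with open(out / "critical_interval.bed", "w") as fh:
            fh.write(
                f"{critical.chromosome}\t{critical.start_bp - 1}\t"
                f"{critical.end_bp}\tcritical_interval\n"
            )

    report = RunReport(
        seed=config.seed,
        version=__version__,
        qc=qc_report,
        scan=scan,
        haplotype_hits=haplotype_hits,
        sweep=profile,
        sweep_minimum=sweep_min,
        runs=runs,
        skipped_breeds=skipped,
        critical_interval=critical,
        truth=truth,
        stage_notes=notes,
    )
    (out / "run_report.txt").write_text(report.to_text())
    return report
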