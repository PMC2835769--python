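# Methods

## The mapping problem

A trait fixed within breeds cannot be mapped within a breed: there is no
phenotypic contrast. Across-breed mapping substitutes the between-breed
contrast — breeds fixed for the trait versus unlike breeds — and leans on
three population-genetic properties of purebred dogs:

* within breeds, founder bottlenecks and closed stud books leave long
  stretches of LD and substantial homozygosity;
* across breeds, LD is short, because breeds were drawn from a much larger
  ancestral population;
* a trait allele shared by many breeds is usually identical by descent, so
  affected breeds are homozygous for one ancestral haplotype at the locus,
  and strong artificial selection has swept diversity from its
  neighbourhood.

The package chains four analyses that exploit these properties —
single-marker association with permutation correction, haplotype-block
association, a relative-heterozygosity sweep scan, and homozygosity-overlap
fine mapping — and a simulator that generates data with exactly these
properties plus ground truth.

## Genotype representation and QC

Genotypes are counts of each SNP's minor allele (0/1/2, −1 missing),
polarized once at load time so later subsetting cannot flip the counted
allele. Association QC applies, in a fixed order: sample missingness ≤ 25%
(computed on the input SNP set), SNP call rate ≥ 75% (on retained samples),
then MAF strictly > 5% (on retained samples; `maf_min = 0` disables the
filter, so vacuous thresholds are the identity). The order matters and is
pinned; a second pass is a no-op for unstructured missingness, though
adversarial missingness patterns (a sample missing one whole SNP stratum)
can in principle re-trigger the sample filter after SNP removal. The sweep
scan uses its own, looser filters (samples > 75% called, SNPs ≥ 95%
called), reflecting its descriptive role.

Array-calling confidence filters applied upstream of PED/MAP export cannot
be reproduced from genotype input and simply appear as missingness.

## Association and max-T permutation

Each SNP is tested by the 1-df Pearson chi-square on the 2×2 table of
allele counts in cases versus controls; missing calls drop out of the
table, and a zero margin yields chi2 = 0, p = 1. Genome-wide correction is
max-T label permutation: statuses are reassigned at random preserving group
sizes, all statistics recomputed, and each observed statistic compared with
the permutation distribution of the genome-wide maximum. The Monte-Carlo
estimator is (1 + count) / (1 + B), which cannot return zero; when the
number of distinct assignments is at most `exhaustive_cap` (default 10⁶)
the assignments are enumerated instead and the p-value is the exact
fraction count / total (the observed assignment is among those counted).
The genome-wide default is 100,000 permutations and the chromosome-wide
(haplotype) default 50,000 — the two counts conventionally used at the two
scopes — both configurable.

Permutation swaps labels over individuals, as a default PLINK-style
permutation would; a breed-stratified mode (permuting within breeds) exists
but is off by default. Individual-label permutation is exactly calibrated
only when individuals are exchangeable under the null. When status is
constant within breeds and breeds are genetically differentiated, the test
is anti-conservative — a real property of across-breed designs, which is
why the workflow adds the support-ratio heuristic: the best locus is
*accepted* only when its best permutation p is more than 100-fold smaller
than the best on any other chromosome (ties break toward larger chi2, then
map order). The null-calibration study therefore evaluates the machinery
under its own null — no planted sweep, no founder bottleneck
(`drift_generations = 0`, haplotypes i.i.d. from the ancestral pool), with
breeds assigned to case/control status at random — where the 5% level must
and does hold.

## Haplotype blocks and EM

Adjacent SNPs are merged by the four-gamete rule: a pair is compatible when
fewer than four two-locus haplotypes reach frequency 0.01 (configurable),
i.e. there is no evidence of historical recombination between them; maximal
runs of compatible pairs form blocks, singletons included, so the blocks
partition the chromosome.

Haplotype frequencies come from an EM algorithm over all haplotypes
consistent with each unphased genotype (double heterozygotes contribute a
mixture over their phase resolutions). The fit starts at linkage
equilibrium and stops when the largest frequency change falls below 1e-9 or
after 50,000 iterations; the tight tolerance and generous cap matter only
for boundary optima (a frequency heading to 0), where EM converges
sublinearly — with them the fit stays within ~1e-5 of the maximum. The
two-locus likelihood can be bimodal (cis versus trans resolution of double
heterozygotes), and the linkage-equilibrium basin occasionally excludes the
global mode, so pair fits also try the two canonical phase-mode starts and
keep a strictly better optimum; exact ties (e.g. a lone double
heterozygote) deliberately keep the symmetric linkage-equilibrium solution,
which is a saddle, not a fabricated phase. Individuals missing any SNP in a
block are excluded from that block's EM rather than imputed. Full-block EM
enumerates 2^k haplotypes and is capped at k = 12 SNPs; a swept,
recombination-free region can produce much wider blocks, which the
chromosome scan tests as consecutive ≤ 12-SNP chunks. Haplotypes below
frequency 1e-4 are pruned from reports (the remainder renormalized).

Haplotype association tests each block haplotype with frequency ≥ 0.01
haplotype-vs-all-others, using each individual's posterior expected
haplotype dosage (fractional counts) in the same 2×2 chi-square as the SNP
test. The EM is fit on the pooled sample, so posteriors do not depend on
case/control labels; group totals are then label sums — an interpretation
choice (best-guess phases would be the alternative) that also makes the
permutation test exact, since only labels move. Correction is
chromosome-wide: the permutation maximum is taken over *all* SNP and
haplotype statistics on the chromosome.

## Sweep scan

Per window of `window_snps` consecutive SNPs (default 5; 10 suits denser
or larger second-pass datasets), per-SNP heterozygosity rates are averaged
within cases and within controls, and the ratio r = case mean / control
mean is normalized to `1 − 1/r` for 0 < r < 1 and `r − 1` otherwise —
antisymmetric under r ↔ 1/r, negative exactly when cases are less
heterozygous. Averaging rates before forming the ratio (rather than
averaging per-SNP ratios) keeps windows defined when individual control
SNPs are monomorphic; a window whose control mean is 0 while the case mean
is positive has no defined ratio and is emitted as missing.

The literal formula maps r = 0 — complete case fixation, the strongest
possible sweep signal — to −1, the same value as r = 0.5, while a window
with tiny-but-nonzero r maps to an arbitrarily negative value. The formula
is kept literally as the default, but for *localization* the pipeline uses
the optional floor mode, which assigns fully swept windows the minimum of
the other defined values; the profile minimum then prefers, among ties,
windows with r = 0 and then larger control heterozygosity. Without this,
the profile minimum lands on a random low-heterozygosity window outside a
true sweep in a substantial fraction of simulated replicates.

## Fine mapping

For each affected breed, a homozygous run extends outward from an anchor
SNP while every called individual of the breed is homozygous for the same
allele (a tolerance `max_het_fraction` relaxes this; default 0). Missing
calls neither break nor support a run, but a SNP with no called individual
stops the extension. The critical interval is the maximal contiguous
stretch of SNPs containing the anchor at which *all* breed runs carry the
identical allele — order-invariant, and monotone in that adding breeds can
only narrow it. Breeds that are not haplotypically uniform can be split
into one run per homozygous anchor-allele subgroup (`breed_haplotype_runs`),
mirroring how fine-mapping panels group dogs by haplotype.

The pipeline anchors at the top associated SNP. Because permutation
p-values floor at 1/(B+1), many SNPs in a swept region tie, and the
largest-chi2 tie-breaker can select a SNP at the eroded edge of the shared
segment where the breeds genuinely share no haplotype; when the overlap
fails there, the pipeline retries the next most-associated SNPs (up to 10)
rather than reporting nothing. An interval that *is* found at the first
anchor is reported as-is, even when it is off-centre.

## The simulator

`simulate_ancestral_pool` draws, per chromosome, SNP positions as a Poisson
process (exponential gaps, mean 50 kb — a ~50K-array density), per-SNP
allele frequencies from a U-shaped Beta(0.5, 0.5) rescaled to (0.05, 0.95),
and haplotypes as thresholded latent Gaussian AR(1) paths whose latent
correlation decays as exp(−d / ld_scale) with ld_scale = 500 kb — the LD
predicted for the breeds this design targets. Latent correlations multiply
exactly across gaps, so allelic r² decays at scale ~ld_scale/2 regardless
of the frequency draws (a plain binary Markov chain fails here: feasibility
clipping between unequal frequencies compounds per step and shortens the
realized LD several-fold).

`simulate_breeds` founds each breed from 20 pool haplotypes (the
breed-formation bottleneck), drifts it for 10 non-overlapping Wright–Fisher
generations with recombination at 1 cM/Mb, and samples the dogs'
haplotypes from the drifted population — enough to leave clear within-breed
homozygosity and breed differentiation without fixing whole chromosomes. A
generative pool-plus-drift model was chosen over a coalescent simulator
because it is desk-scale, dependency-free, and directly realizes the three
properties the analysis exploits. In affected breeds, both haplotypes of
every dog are overwritten with one pool haplotype carrying the rarer causal
allele, across a 1 Mb core (≈ twice the within-breed LD scale) centred on
the causal SNP and eroded per breed by geometric flank lengths (mean 1.5
SNPs) that always retain the causal SNP — producing the fixed, IBD-shared,
breed-wise-eroded sweep that fine mapping must recover. Genotypes are
finally masked missing at 2%. Phenotype is deterministic on breed (the
trait is fixed; no penetrance model). `reference_study_scenario` sets 9
affected breeds totalling 20 case dogs and 13 control breeds totalling 31
controls on 5 × 400 SNPs — the reference design's sample sizes at a
desk-scale stand-in for a 38-autosome 50K array.

What the simulator does *not* emulate: mutation, ongoing selection during
drift, overlapping generations and pedigree structure, variable
recombination rates, genotyping batch effects, X-chromosome inheritance,
and phenotyping error. Passing tests therefore demonstrate that the
analyses recover the statistical structure they assume; they do not
validate robustness to those unmodelled features of real array data.

## Problem sizes and determinism

Replicate studies in the tests and the acceptance script use the reference
design at 50 and 25 replicates (association permutations 1,000 per
replicate, enough to rank loci, whose order is permutation-free) and a
smaller 2 × 150-SNP exchangeable design at 200 and 100 replicates with 399
permutations for null calibration — sizes chosen so the whole suite runs in
minutes on one CPU while the binomial error bands stay meaningful. Every
random stage consumes a seed derived from a single master seed via
`numpy.random.SeedSequence` spawning, so partial reruns and full runs are
bit-reproducible; the permutation engine guards float-path noise with a
relative 1e-12 slack when comparing statistics to the permutation maxima.

## Known limitations

* Individual-label permutation under breed-level phenotype assignment is
  anti-conservative (see above); the support-ratio heuristic mitigates but
  does not calibrate it.
* The EM is exact maximum likelihood only up to its (multi-start) search;
  for k > 2 SNPs only the linkage-equilibrium start is used.
* Four-gamete blocks depend on the 0.01 frequency cutoff; near-threshold
  haplotypes can flip a pair's compatibility between otherwise equivalent
  fits.
* The critical interval assumes a single shared ancestral haplotype; allelic
  heterogeneity across affected breeds would (correctly) produce a
  "no shared haplotype" failure rather than a wrong interval.
* PED/MAP is the only input dialect (no binary BED/VCF; autosomes only).
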