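# Methods

This note documents the models, conventions, and design choices behind
`speedcon`, in the spirit of a statistical-software methods appendix. It
describes what the code computes and why; every number quoted here is
produced by the test suite or `scripts/acceptance.py` at run time.

## Genotype model and the selection statistic

Genotypes are encoded relative to the *recipient* strain's reference genome
(the pipeline this package consumes aligns reads to the recipient
assembly): `HOM_REF` = homozygous recipient allele ("AA"), `HET` ("AB"),
`HOM_ALT` = homozygous donor allele ("BB"), `MISSING` = failed call. The
per-sample selection statistic is

pct_recipient = 100 · (2·n_AA + n_AB) / (2·n_genotyped),

computed over autosome + X loci only. Conventions:

- **Missing calls** are excluded from the denominator. Genotyping success
  is reported separately (`pct_genotyped`), so folding failures into the
  percentage would conflate assay performance with ancestry.
- **Y loci never enter the percentage.** The Y does not recombine, so its
  ancestry is fixed by the breeding design; Y calls remain available in raw
  reports.
- **Hemizygous male X** calls are counted as two identical alleles (a
  haploid VCF call `0` maps to `HOM_REF`, `1` to `HOM_ALT`). One formula
  then serves both sexes without inflating or deflating heterozygosity.
- Breeder ranking is descending by pct_recipient, ties broken by higher
  genotyping success then lexicographic sample id; candidates with zero
  genotyped diagnostic loci sort last and are flagged.
- Thresholds are configuration, not constants: congenic declaration
  defaults to 99.8 % (standard congenics practice), low-quality flagging to
  90 % genotyping success, low-depth flagging to a median of 10 mapped
  reads per SNP (below which genotyping success degrades sharply).

## Diagnostic SNP discovery

For a donor → recipient cross, starting from the autosome+X panel:

1. remove loci that failed to genotype in more than `max_failures` donor
   replicates (default 1, with 2–3 replicate donor individuals expected);
2. remove loci where **any** donor replicate is heterozygous or homozygous
   for the recipient allele.

Step order matters: a locus missing in one donor but homozygous-donor in
the others is retained. Filtering is per donor *source* — the same strain
from different vendors can carry fixed differences, so each source earns
its own diagnostic set. The `verify_recipient` report checks the
recipient-equals-reference assumption on recipient samples (warning below
99.5 % recipient alleles at the diagnostic loci).

Pairwise prediction across a strain × SNP consensus table counts, for each
strain pair, loci where both strains are homozygous (`A`/`B`) for different
alleles; heterozygous (`H`) or missing (`N`) entries exclude a locus from
that pair only. This is the conservative reading of "different genotypes";
summary statistics (mean, SD, fraction of pairs above a threshold, default
300) are over the upper triangle.

## Depth QC

Per-sample five-number summaries + mean of mapped reads per SNP. Quantiles
use linear interpolation on sorted values (numpy's default, "type 7") —
stated because quantile conventions differ. Panel loci absent from a depth
file count as zero reads: absence of coverage is the signal.

## The backcross simulator

The simulator is a first-class, tested component, not a fixture. It exists
to (i) validate the marker-based ancestry estimator against exact truth and
(ii) replay the reference six-generation speed-congenics experiment.

**Genome.** mm10 physical chromosome lengths; genetic length = physical ×
0.56 cM/Mb (≈ 1 470 cM over autosomes + X), linear cM↔bp interpolation. A
per-chromosome genetic-length table can override the uniform rate.

**Meiosis.** No-interference (Poisson/Haldane) model: crossover count per
chromosome ~ Poisson(genetic length in Morgans), positions uniform in
genetic coordinate, gamete alternates between parental haplotypes starting
from a fair coin. Simplest model consistent with trajectory-level
validation; crossover interference and obligate chiasmata are deliberately
omitted (a config hook for per-chromosome genetic lengths remains). The X
recombines only in female meiosis; a male transmits his X intact to
daughters and a non-recombining Y label to sons.

**Individuals** are ancestry-labelled segment lists per chromosome copy;
segment tiling (no gaps/overlaps, alternating labels) is enforced at every
construction. The truth value `recipient_fraction` is the length-weighted
recipient fraction over all autosome + X copies the individual carries
(X twice in females, once in males; Y excluded). With
`scope="autosome"` it restricts to autosomes, for which the classical
unselected-backcross expectation 1 − 2⁻ᵍ holds exactly; under this male-line
design the X is fully recipient from F1 onward, so the closed form is an
autosomal statement.

**Synthetic assay.** 1591 autosomal + 49 X + 29 Y SNPs spread across
chromosomes proportionally to length, evenly spaced with ±30 % jitter; 819
autosome+X loci (plus all Y loci) are divergent: the donor is homozygous
for the alternate allele there and shares the reference allele elsewhere.
These counts mirror the real assay's composition and its BALB/c→C57BL/6J
diagnostic density. Genotyping applies a per-call missingness of 2.5 %
(matching observed 94.5–98.4 % genotyping success) and an optional per-call
error rate (default 0).

**Breeding scheme defaults** replicate the reference experiment: one donor
male × two recipient females; three F1 males; carrier offspring counts
13/8/14/28/6 at backcross generations 2–6 (generation numbering starts at
2); top 3 then top 2 ranked carriers kept as breeders; the gene of interest
at the midpoint of chromosome 11 (the approximate location of the Il4/Il13
cluster; configurable, and carrier conditioning produces realistic linkage
drag). Breeding continues until the per-generation *carrier* count is
reached, because only gene-of-interest offspring are genotyped in practice
— the published sample sizes are carrier counts.

**Breeder sex.** Selection is sex-blind by default
(`BreedingScheme.select_sex="any"`): the top-ranked carriers become
breeders, males mated to fresh recipient females and females to recipient
males. This follows the source protocol's wording (offspring of both sexes
were genotyped and "individuals" with the highest percentage chosen; only
the F1 step is explicitly male) and reproduces the observed selection
response, which a males-only rule (`select_sex="male"`, provided as an
option) underestimates by ~1–2 percentage points in mid generations.

**Determinism.** All randomness flows through one `numpy` Generator;
identical seeds give byte-identical VCF/TSV outputs.

## Validation scales and what they show

- Reference trajectory: 30 replicate programs (a few seconds each) give
  generation means ≈ 74.8 / 89.6 / 95.7 / 98.3 / 99.4 % and a mean
  generation-6 maximum ≈ 99.6 %, against published values 73.6 / 89.6 /
  96.5 / 99.0 / 99.4 and 99.8.
- Unselected closed form: 2 000 independent lineages match 1 − 2⁻ᵍ within
  3 Monte-Carlo SE for g = 2…6.
- Estimator fidelity: at ~819 markers the marker percentage tracks true
  ancestry with mean absolute error < 2 percentage points on backcross-2
  individuals (dominated by finite-marker sampling, not missingness).
- Diagnostic filter: exact equivalence with a brute-force predicate
  evaluator on 500 random matrices; monotonicity in `max_failures` and in
  donor replicates.
- Format round-trips: VCF and BED write→read identity on random fixtures.

**What the simulator does not model** — and hence what passing tests do not
establish about real data: genotype-calling errors correlated with read
depth, crossover interference, segregation distortion, de novo variation,
litter-size and sex-ratio effects, substrain heterogeneity within founders,
and real marker ascertainment (synthetic marker positions are jittered
uniform, slightly more even than the real panel). Trajectory agreement is
at the level of generation means and extremes, not individual pedigrees.

## Degenerate inputs and numerical notes

- pct_recipient is undefined (flagged `None`, or an error where a decision
  is required) when zero loci genotyped.
- Empty SNP sets give empty spacing reports; gap statistics are `None` when
  no chromosome carries two markers. Per-chromosome SNP means are reported
  both over occupied chromosomes and over all chromosomes in scope, since
  the two conventions differ for sparse sets.
- Multiallelic or non-SNP VCF records at panel coordinates demote to
  `MISSING` with a warning tally rather than erroring: joint genotyping
  emits them occasionally, and the four-state summary cannot represent
  them.
- BED is 0-based half-open on disk, 1-based internally; the panel BED is
  the source of truth for locus membership and VCF records outside it are
  skipped.
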