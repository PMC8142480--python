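# speedcon

Analysis toolkit and simulator for **speed congenics** — marker-assisted
backcross breeding in mice.

## The problem

Moving a gene of interest (a transgene or mutation) onto a clean inbred
background traditionally takes ~10 backcross generations. Speed congenics
cuts that roughly in half: at every generation, offspring carrying the gene
are genotyped at a genome-wide panel of **diagnostic SNPs** — markers at
which donor and recipient strains are homozygous for different alleles — and
the individuals with the highest fraction of recipient-strain alleles are
chosen as the next breeders.

`speedcon` covers the decision-making side of such a program, downstream of
a standard joint-genotyping pipeline (reads → BWA → GATK → multi-sample
VCF). It is aimed at core-facility bioinformaticians and mouse geneticists
running SNP-panel genotyping assays (e.g. 1640 autosomal + X markers plus 29
Y markers).

The selection statistic, per sample over the diagnostic autosome+X markers,
is the percent of recipient-strain alleles

```
pct_recipient = 100 · (2·n_AA + n_AB) / (2 · n_genotyped)
```

with `n_AA`, `n_AB`, `n_BB` the counts of homozygous-recipient,
heterozygous, and homozygous-donor calls (failed calls excluded from the
denominator). A line is conventionally declared congenic at ≥ 99.8 %.

What the package does:

- **Panel & genotypes** — validated SNP-panel model (BED in/out, 1-based
  internally) and a dense samples × loci genotype matrix read from
  multi-sample VCF (via cyvcf2).
- **Diagnostic SNP discovery** — the two-step filter on replicate donor
  genotypes (drop loci failing in > 1 donor; drop loci where any donor is
  heterozygous or carries the recipient allele), run per donor source, plus
  pairwise diagnostic-count prediction across a strain genotype table.
- **Congenic summaries** — per-sample genotype reports, percent recipient
  alleles, genotyping-success flags, breeder ranking, congenic calls.
- **Marker spacing & depth QC** — SNPs per chromosome, inter-marker
  distances (Mb), per-sample read-depth distributions with the median-10
  heuristic.
- **Backcross simulator** — meiosis-level simulation (Poisson/Haldane
  crossovers on an mm10 genome, 0.56 cM/Mb) of the whole breeding program,
  with exact ancestry truth values for validating the marker estimator.

## Worked example

Simulate a full program (donor male × 2 recipient females; 3 F1 males;
carrier counts 13/8/14/28/6 at backcross generations 2–6; top-ranked
carriers kept as breeders; ~819 diagnostic markers, 2.5 % genotype
missingness):

```
$ speedcon simulate --seed 1 --out-dir out/
generation 2: n=13 carriers, mean 74.1% / max 81.2% recipient alleles; selected breeders: BC2_06, BC2_07, BC2_11
generation 3: n=8 carriers, mean 87.8% / max 90.1% recipient alleles; selected breeders: BC3_04, BC3_02
generation 4: n=14 carriers, mean 95.2% / max 97.3% recipient alleles; selected breeders: BC4_08, BC4_05
generation 5: n=28 carriers, mean 98.3% / max 99.3% recipient alleles; selected breeders: BC5_25, BC5_26
generation 6: n=6 carriers, mean 99.3% / max 99.4% recipient alleles; selected breeders: -
```

Each generation's mean climbs from ~74 % (the backcross-2 expectation of
75 % minus linkage drag around the gene of interest) towards the congenic
threshold; by generation 6 the best offspring are ≥ 99 % recipient. The run
writes per-generation VCFs, ancestry truth tables, the recovered diagnostic
SNP BED, and a JSON metadata sidecar.

Summarize any generation's VCF over the diagnostic markers:

```
$ speedcon summarize --vcf out/generation_6.vcf --bed out/panel.bed \
      --diagnostic-snps out/diagnostic_snps.bed --scope diagnostic --out summary/
$ head -3 summary/genotype_summary.tsv
LibraryID	BB	AB	AA	failed	TotalGenotyped	ProportionAA	ProportionA
BC6_01	0	10	779	27	789	0.9873	0.9937
BC6_02	0	11	781	24	792	0.9861	0.9931
```

`ProportionA = 0.9937` means 99.37 % of BC6_01's diagnostic alleles match
the recipient strain (10 markers still heterozygous, mostly linked to the
gene of interest). Other subcommands: `diagnose`, `predict`, `spacing`,
`qc` — see `speedcon --help`.

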