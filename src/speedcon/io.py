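"""Readers and writers for the formats the toolkit touches.

* 4-column BED of panel SNP coordinates (0-based half-open, one base per
  record), with an extended 6-column dialect carrying ref/alt alleles;
* multi-sample VCF v4.x of joint-genotyped calls (read via cyvcf2; written
  as a minimal GT-only VCF v4.2);
* per-sample/per-SNP mapped-read-count tables (TSV, long or wide);
* the per-sample genotype summary report (TSV).

The panel BED is the source of truth for locus membership: VCF records at
coordinates outside the panel are skipped — the upstream pipeline maps reads
genome-wide, but genotypes are evaluated only at target SNPs.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .congenic import GenotypeSummary
from .panel import (
    CHROM_ORDER,
    GenotypeCall,
    GenotypeMatrix,
    Panel,
    PanelError,
    SnpLocus,
    normalize_chrom,
)

__all__ = [
    "read_panel_bed",
    "write_panel_bed",
    "read_vcf",
    "write_vcf",
    "DepthTable",
    "read_depth_table",
    "write_summary_table",
    "FormatError",
]

log = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_panel_bed(path) -> Panel:
    """Read a SNP panel from BED (chrom, start, end, name[, ref, alt]).

    Coordinates are 0-based half-open with ``end == start + 1`` for a SNP;
    internally positions become 1-based (``pos = start + 1``).  If columns 5
    and 6 are single nucleotides they are taken as ref/alt alleles
    (extended dialect); otherwise alleles stay provisional until a VCF
    supplies them.
    """
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 BED columns")
            try:
                chrom = normalize_chrom(fields[0])
                start, end = int(fields[1]), int(fields[2])
            except (ValueError, PanelError) as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            if end != start + 1:
                raise FormatError(
                    f"{path}:{lineno}: SNP record must have end == start + 1, "
                    f"got [{start}, {end})"
                )
            ref = alt = None
            if len(fields) >= 6 and fields[4] in _NUCLEOTIDES and fields[5] in _NUCLEOTIDES:
                ref, alt = fields[4], fields[5]
            try:
                loci.append(
                    SnpLocus(id=fields[3], chrom=chrom, pos=start + 1,
                             ref_allele=ref, alt_allele=alt)
                )
            except PanelError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
    if not loci:
        raise FormatError(f"{path}: no SNP records")
    return Panel(loci)


def write_panel_bed(panel: Panel, path) -> None:
    """Write a panel as BED; 6 columns when every locus has alleles, else 4."""
    with_alleles = all(l.has_alleles for l in panel)
    with open(path, "w") as fh:
        for l in panel:
            row = [l.chrom, str(l.pos - 1), str(l.pos), l.id]
            if with_alleles:
                row += [l.ref_allele, l.alt_allele]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, panel: Panel) -> GenotypeMatrix:
    """Read GT calls at panel loci from a multi-sample VCF.

    Mapping: 0/0 -> HOM_REF, 0/1 or 1/0 -> HET, 1/1 -> HOM_ALT, ./. ->
    MISSING; phased separators are accepted; haploid calls (male X/Y under a
    haploid model) map 0 -> HOM_REF and 1 -> HOM_ALT.  Panel loci absent
    from the VCF are MISSING for all samples.  Multiallelic or non-SNP
    records at panel coordinates are demoted to MISSING and tallied in
    ``matrix.warnings`` — joint genotyping can emit them, but the summary
    statistics only recognize biallelic states.

    Provisional panel alleles are filled in from REF/ALT of matched records.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF contains no samples")

    calls = np.full((len(samples), len(panel)), int(GenotypeCall.MISSING), dtype=np.int8)
    alleles: dict[str, tuple[str, str]] = {}
    n_multi = n_nonsnp = 0
    for var in vcf:
        try:
            col = panel.find(var.CHROM, var.POS)
        except PanelError:
            continue  # contig outside the karyotype model
        if col is None:
            continue
        lid = panel[col].id
        if len(var.ALT) != 1:
            n_multi += 1
            continue  # stays MISSING
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
            n_nonsnp += 1
            continue
        alleles[lid] = (ref, alt)
        for i, gt in enumerate(var.genotypes):
            gt_alleles = gt[:-1]  # last element is the phased flag
            if any(a < 0 for a in gt_alleles):
                continue  # MISSING
            if len(gt_alleles) == 1:  # haploid call: count the allele twice
                calls[i, col] = 2 * gt_alleles[0]
            else:
                calls[i, col] = sum(gt_alleles)
    if n_multi or n_nonsnp:
        log.warning(
            "%s: demoted to MISSING at panel loci: %d multiallelic, %d non-SNP records",
            path, n_multi, n_nonsnp,
        )
    matrix = GenotypeMatrix(samples, panel.with_alleles(alleles), calls)
    matrix.warnings = {"multiallelic_records": n_multi, "non_snp_records": n_nonsnp}
    return matrix


_GT_STRING = {
    int(GenotypeCall.MISSING): "./.",
    int(GenotypeCall.HOM_REF): "0/0",
    int(GenotypeCall.HET): "0/1",
    int(GenotypeCall.HOM_ALT): "1/1",
}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF v4.2 that :func:`read_vcf` inverts exactly.

    HET is always written ``0/1`` (canonical form); MISSING as ``./.``.
    Every panel locus must have concrete alleles.
    """
    provisional = [l.id for l in matrix.panel if not l.has_alleles]
    if provisional:
        raise FormatError(
            f"cannot write VCF: loci with provisional alleles: {provisional[:5]}"
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in CHROM_ORDER:
            if any(l.chrom == c for l in matrix.panel):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids) + "\n"
        )
        for j, l in enumerate(matrix.panel):
            gts = "\t".join(_GT_STRING[int(v)] for v in matrix.calls[:, j])
            fh.write(
                f"{l.chrom}\t{l.pos}\t{l.id}\t{l.ref_allele}\t{l.alt_allele}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Depth table
# ---------------------------------------------------------------------------

class DepthTable:
    """Mapped-read counts per (sample, SNP), dense over the panel.

    Internally a loci x samples integer frame; panel loci absent from the
    input file are stored as zero reads.
    """

    def __init__(self, frame: pd.DataFrame, panel: Panel):
        unknown = set(frame.index) - set(panel.ids)
        if unknown:
            raise FormatError(f"depth table has locus ids not in panel: {sorted(unknown)[:10]}")
        if (frame.to_numpy() < 0).any():
            raise FormatError("depth table contains negative counts")
        self.panel = panel
        # dense re-index over the full panel, absent loci -> 0
        self.frame = frame.reindex(list(panel.ids)).fillna(0).astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    def sample_depths(self, sample_id: str) -> np.ndarray:
        """Counts for one sample over every panel locus (panel order)."""
        return self.frame[sample_id].to_numpy()

    def get(self, sample_id: str, locus_id: str) -> int:
        return int(self.frame.at[locus_id, sample_id])


def read_depth_table(path, panel: Panel) -> DepthTable:
    """Read a depth TSV, either long or wide format.

    Long format is recognized by its header — exactly the columns
    ``sample``, ``locus``, ``count`` (case-insensitive).  Anything else is
    wide format: rows keyed by locus id (first column), header = sample ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if [c.lower() for c in df.columns] == ["sample", "locus", "count"]:
        long = df.copy()
        long.columns = ["sample", "locus", "count"]
        try:
            long["count"] = long["count"].astype(np.int64)
        except ValueError as e:
            raise FormatError(f"{path}: non-integer depth values ({e})") from None
        wide = long.pivot(index="locus", columns="sample", values="count")
        wide = wide.fillna(0).astype(np.int64)
        return DepthTable(wide, panel)
    wide = df.set_index(df.columns[0])
    try:
        wide = wide.astype(np.int64)
    except ValueError as e:
        raise FormatError(f"{path}: non-integer depth values ({e})") from None
    return DepthTable(wide, panel)


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------

def write_summary_table(summaries: Sequence[GenotypeSummary], path) -> None:
    """Write the per-sample genotype report TSV.

    Columns: LibraryID, BB, AB, AA, failed, TotalGenotyped, ProportionAA
    (fraction of genotyped SNPs homozygous reference) and ProportionA
    (fraction of reference alleles among genotyped SNPs), proportions with 4
    decimal places; ``NA`` when nothing genotyped.
    """
    if not summaries:
        raise FormatError("no summaries to write")
    with open(path, "w") as fh:
        fh.write("LibraryID\tBB\tAB\tAA\tfailed\tTotalGenotyped\tProportionAA\tProportionA\n")
        for s in summaries:
            tot = s.n_genotyped
            prop_aa = f"{s.n_AA / tot:.4f}" if tot else "NA"
            prop_a = f"{(2 * s.n_AA + s.n_AB) / (2 * tot):.4f}" if tot else "NA"
            fh.write(
                f"{s.sample_id}\t{s.n_BB}\t{s.n_AB}\t{s.n_AA}\t{s.n_failed}"
                f"\t{tot}\t{prop_aa}\t{prop_a}\n"
            )
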