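"""Genomic-distribution statistics for a SNP set.

The usefulness of a diagnostic panel depends not just on marker count but on
how evenly markers cover the genome: per-chromosome counts and the physical
distances between adjacent markers (in Mb) summarize that coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .panel import CHROM_ORDER, ChromClass, Panel

__all__ = ["SpacingReport", "spacing_report", "positions_table"]

_AX_CHROMS = tuple(c for c in CHROM_ORDER if c != "Y")


class Stats(NamedTuple):
    mean: float
    min: float
    max: float


@dataclass(frozen=True)
class SpacingReport:
    """Per-chromosome SNP counts and adjacent-SNP gap statistics.

    ``per_chrom`` maps every chromosome in scope to (n_snps, gaps in Mb);
    chromosomes carrying no SNP of the set are listed with zero count.
    ``snps_per_chrom_stats`` is over occupied chromosomes only (so the
    minimum reflects the sparsest chromosome that has markers at all);
    ``mean_snps_all_chroms`` averages over every chromosome in scope.
    ``gap_stats`` is over all gaps genome-wide, None when no chromosome has
    two or more SNPs.
    """

    per_chrom: dict[str, tuple[int, tuple[float, ...]]]
    snps_per_chrom_stats: Stats | None
    mean_snps_all_chroms: float
    gap_stats: Stats | None

    @property
    def n_snps(self) -> int:
        return sum(n for n, _ in self.per_chrom.values())


def spacing_report(locus_ids: Sequence[str], panel: Panel) -> SpacingReport:
    """Compute per-chromosome counts and adjacent-marker gaps for a SNP set.

    Gaps are between consecutive markers on the same chromosome, in Mb
    (pos2 - pos1)/1e6; there are no inter-chromosome gaps.  The default
    scope lists autosomes 1..19 and X; Y appears only if the set contains
    Y loci.
    """
    wanted = set(locus_ids)
    loci = [l for l in panel if l.id in wanted]
    missing = wanted - {l.id for l in loci}
    if missing:
        raise KeyError(f"locus ids not in panel: {sorted(missing)}")

    chroms = list(_AX_CHROMS)
    if any(l.chrom_class is ChromClass.Y for l in loci):
        chroms.append("Y")
    per_chrom: dict[str, tuple[int, tuple[float, ...]]] = {}
    all_gaps: list[float] = []
    for c in chroms:
        pos = np.array([l.pos for l in loci if l.chrom == c], dtype=np.int64)
        gaps = tuple(np.diff(pos) / 1e6) if len(pos) > 1 else ()
        per_chrom[c] = (len(pos), gaps)
        all_gaps.extend(gaps)

    counts = np.array([n for n, _ in per_chrom.values()], dtype=float)
    occupied = counts[counts > 0]
    return SpacingReport(
        per_chrom=per_chrom,
        snps_per_chrom_stats=(
            Stats(float(occupied.mean()), float(occupied.min()), float(occupied.max()))
            if len(occupied)
            else None
        ),
        mean_snps_all_chroms=float(counts.mean()) if len(counts) else 0.0,
        gap_stats=(
            Stats(float(np.mean(all_gaps)), float(np.min(all_gaps)), float(np.max(all_gaps)))
            if all_gaps
            else None
        ),
    )


def positions_table(locus_ids: Sequence[str], panel: Panel) -> pd.DataFrame:
    """Tidy (chrom, pos, id) table in panel order — plot-ready for ideogram maps."""
    wanted = set(locus_ids)
    rows = [(l.chrom, l.pos, l.id) for l in panel if l.id in wanted]
    return pd.DataFrame(rows, columns=["chrom", "pos", "id"])
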