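"""Per-sample congenic-ancestry summaries and breeder selection.

The decision statistic of a marker-assisted backcross program is the percent
of alleles matching the recipient strain over the autosomal + X markers::

    pct_recipient = 100 * (2*n_AA + n_AB) / (2 * n_genotyped)

where ``n_AA``/``n_AB``/``n_BB`` count loci homozygous-recipient,
heterozygous, and homozygous-donor, and ``n_genotyped`` excludes failed
calls.  Y-chromosome markers never enter the percentage: the Y does not
recombine, so its ancestry is fixed by the breeding design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .panel import GenotypeCall, GenotypeMatrix, PanelError

__all__ = [
    "GenotypeSummary",
    "RankedCandidate",
    "summarize_sample",
    "rank_for_breeding",
    "flag_low_quality",
    "is_congenic",
    "DEFAULT_CONGENIC_THRESHOLD",
    "DEFAULT_LOW_QUALITY_THRESHOLD",
]

#: A line is conventionally declared congenic once >= 99.8% of diagnostic
#: alleles match the recipient strain.
DEFAULT_CONGENIC_THRESHOLD = 99.8
#: Samples genotyping at fewer than this percent of loci are flagged as
#: poor-performing libraries.
DEFAULT_LOW_QUALITY_THRESHOLD = 90.0


@dataclass(frozen=True)
class GenotypeSummary:
    """Genotype-state counts and the recipient-allele percentage for one sample."""

    sample_id: str
    n_AA: int
    n_AB: int
    n_BB: int
    n_failed: int
    locus_scope: str = "panel"

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_AB, self.n_BB, self.n_failed) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_genotyped(self) -> int:
        return self.n_AA + self.n_AB + self.n_BB

    @property
    def pct_genotyped(self) -> float:
        total = self.n_genotyped + self.n_failed
        return 100.0 * self.n_genotyped / total if total else float("nan")

    @property
    def pct_recipient(self) -> float | None:
        """Percent recipient alleles over genotyped loci; None if nothing genotyped."""
        if self.n_genotyped == 0:
            return None
        return 100.0 * (2 * self.n_AA + self.n_AB) / (2 * self.n_genotyped)


def summarize_sample(
    matrix: GenotypeMatrix,
    sample_id: str,
    loci: Sequence[str] | None = None,
    locus_scope: str | None = None,
) -> GenotypeSummary:
    """Count genotype states for one sample over a locus set.

    ``loci`` defaults to the full autosome+X panel (Y excluded); callers pass
    a diagnostic set to obtain the selection statistic.
    """
    if loci is None:
        loci = matrix.panel.autosome_x_ids()
        scope = locus_scope or "autosome+X panel"
    else:
        scope = locus_scope or "custom"
    calls = matrix.sample_calls(sample_id, list(loci))
    return GenotypeSummary(
        sample_id=sample_id,
        n_AA=int(np.count_nonzero(calls == GenotypeCall.HOM_REF)),
        n_AB=int(np.count_nonzero(calls == GenotypeCall.HET)),
        n_BB=int(np.count_nonzero(calls == GenotypeCall.HOM_ALT)),
        n_failed=int(np.count_nonzero(calls == GenotypeCall.MISSING)),
        locus_scope=scope,
    )


class RankedCandidate(NamedTuple):
    sample_id: str
    pct_recipient: float | None
    pct_genotyped: float
    flagged: bool  # True when zero diagnostic loci genotyped


def rank_for_breeding(
    matrix: GenotypeMatrix,
    diagnostic,
    candidates: Sequence[str] | None = None,
) -> list[RankedCandidate]:
    """Rank candidate breeders by percent recipient alleles at diagnostic loci.

    Descending by ``pct_recipient``; ties broken by higher genotyping success,
    then lexicographic sample id (stable).  Candidates with zero genotyped
    diagnostic loci are placed last and flagged.
    """
    locus_ids = list(getattr(diagnostic, "locus_ids", diagnostic))
    if not locus_ids:
        raise PanelError("diagnostic set is empty")
    if candidates is None:
        candidates = matrix.sample_ids
    entries = []
    for s in candidates:
        summ = summarize_sample(matrix, s, locus_ids, locus_scope="diagnostic")
        entries.append(
            RankedCandidate(s, summ.pct_recipient, summ.pct_genotyped, summ.pct_recipient is None)
        )
    return sorted(
        entries,
        key=lambda e: (e.flagged, -(e.pct_recipient or 0.0), -e.pct_genotyped, e.sample_id),
    )


def flag_low_quality(
    summaries: Sequence[GenotypeSummary],
    min_pct_genotyped: float = DEFAULT_LOW_QUALITY_THRESHOLD,
) -> set[str]:
    """Samples whose genotyping success rate falls below the threshold."""
    if not 0 <= min_pct_genotyped <= 100:
        raise ValueError("threshold must be a percentage in [0, 100]")
    return {s.sample_id for s in summaries if s.pct_genotyped < min_pct_genotyped}


def is_congenic(
    summary: GenotypeSummary, threshold_pct: float = DEFAULT_CONGENIC_THRESHOLD
) -> tuple[bool, str]:
    """Whether a sample meets the congenic threshold, with a report line."""
    pct = summary.pct_recipient
    if pct is None:
        raise PanelError(
            f"sample {summary.sample_id!r}: percent recipient undefined (no genotyped loci)"
        )
    ok = pct >= threshold_pct
    verdict = "CONGENIC" if ok else "not congenic"
    line = (
        f"{summary.sample_id}\t{pct:.2f}% recipient alleles over {summary.locus_scope} "
        f"({summary.n_genotyped} loci)\t{verdict} at {threshold_pct}%"
    )
    return ok, line
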