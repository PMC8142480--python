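"""Diagnostic-SNP discovery for a donor -> recipient backcross.

A SNP is *diagnostic* for a cross when donor and recipient strains are
homozygous for different alleles there, so each marker reads out local
ancestry in backcross offspring.  With genotypes aligned to the recipient's
reference genome (HOM_REF == recipient allele), diagnostic SNPs are found
from a few replicate donor individuals by two conjunctive filters applied to
the autosome+X panel:

1. drop loci that failed to genotype in more than ``max_failures`` donor
   individuals (default 1);
2. drop loci where any donor individual is heterozygous or homozygous for
   the recipient allele.

Filtering is run separately per donor *source*: the same strain obtained
from different vendors can carry fixed differences, so each source gets its
own diagnostic set.  The module also predicts diagnostic-SNP counts for
arbitrary strain pairs from a consensus strain x SNP genotype table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .congenic import summarize_sample
from .panel import GenotypeCall, GenotypeMatrix, Panel, PanelError

__all__ = [
    "DiagnosticSet",
    "StrainGenotypeTable",
    "RecipientCheck",
    "PairwiseSummary",
    "call_diagnostic_snps",
    "verify_recipient",
    "predict_pairwise_diagnostics",
    "summarize_pairwise",
    "write_diagnostic_bed",
]


@dataclass(frozen=True)
class DiagnosticSet:
    """The panel subset diagnostic for one donor source against one recipient.

    ``provenance`` records how many autosome+X loci each filter step removed;
    the counts always account for the whole autosome+X panel.
    """

    donor_label: str
    recipient_label: str
    locus_ids: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.locus_ids)


def call_diagnostic_snps(
    matrix: GenotypeMatrix,
    donor_samples: Sequence[str],
    max_failures: int = 1,
    donor_label: str = "donor",
    recipient_label: str = "recipient",
) -> DiagnosticSet:
    """Apply the two-step diagnostic filter to replicate donor genotypes.

    Starting from the autosome+X panel loci: loci MISSING in more than
    ``max_failures`` donor samples are removed first, then loci at which any
    donor sample is HET or HOM_REF.  Survivors are homozygous-donor at every
    successfully genotyped donor replicate and are returned in panel order.
    """
    if not donor_samples:
        raise PanelError("donor_samples must be non-empty")
    rows = [matrix.sample_index(s) for s in donor_samples]
    ax_ids = matrix.panel.autosome_x_ids()
    idx = np.array([matrix.panel.index_of(l) for l in ax_ids], dtype=np.intp)
    calls = matrix.calls[np.ix_(rows, idx)]  # donors x AX loci

    n_missing = np.count_nonzero(calls == GenotypeCall.MISSING, axis=0)
    pass1 = n_missing <= max_failures
    bad_allele = np.any(
        (calls == GenotypeCall.HET) | (calls == GenotypeCall.HOM_REF), axis=0
    )
    keep = pass1 & ~bad_allele
    kept = tuple(l for l, k in zip(ax_ids, keep) if k)
    provenance = {
        "panel_autosome_x": len(ax_ids),
        "removed_missingness": int(np.count_nonzero(~pass1)),
        "removed_donor_het_or_recipient_allele": int(np.count_nonzero(pass1 & bad_allele)),
        "diagnostic": len(kept),
    }
    return DiagnosticSet(donor_label, recipient_label, kept, provenance)


class RecipientCheck(NamedTuple):
    sample_id: str
    pct_recipient: float | None
    warn: bool


def verify_recipient(
    matrix: GenotypeMatrix,
    recipient_samples: Sequence[str],
    diagnostic: DiagnosticSet,
    min_pct: float = 99.5,
) -> list[RecipientCheck]:
    """Check the recipient-equals-reference assumption on recipient samples.

    Each recipient individual should be near-100% HOM_REF at the diagnostic
    loci; a sample below ``min_pct`` recipient alleles is flagged, indicating
    either sample contamination or mispolarized loci.
    """
    if not diagnostic.locus_ids:
        raise PanelError("diagnostic set is empty")
    report = []
    for s in recipient_samples:
        summ = summarize_sample(matrix, s, diagnostic.locus_ids, locus_scope="diagnostic")
        pct = summ.pct_recipient
        report.append(RecipientCheck(s, pct, pct is None or pct < min_pct))
    return report


# ---------------------------------------------------------------------------
# Pairwise prediction from a strain consensus genotype table
# ---------------------------------------------------------------------------

_VALID_CODES = frozenset({"A", "B", "H", "N"})


class StrainGenotypeTable:
    """Consensus genotypes of many inbred strains at shared panel SNPs.

    Codes per (strain, locus): ``A``/``B`` the two homozygous states, ``H``
    heterozygous/segregating, ``N`` missing.
    """

    def __init__(self, genotypes: pd.DataFrame):
        df = genotypes.astype(str)
        bad = set(np.unique(df.to_numpy())) - _VALID_CODES
        if bad:
            raise PanelError(f"unknown genotype codes in strain table: {sorted(bad)}")
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise PanelError("duplicate strain or locus ids in strain table")
        self.genotypes = df

    @property
    def strain_ids(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @classmethod
    def read_tsv(cls, path) -> "StrainGenotypeTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(df.fillna("N"))


def predict_pairwise_diagnostics(table: StrainGenotypeTable) -> pd.DataFrame:
    """Predicted diagnostic-SNP counts for every strain pair.

    A locus counts for a pair only when both strains are homozygous (A or B)
    and for different alleles; H or N in either strain excludes the locus
    from that pair.  Returns a symmetric strain x strain integer matrix with
    zero diagonal.
    """
    if len(table.strain_ids) < 2:
        raise PanelError("pairwise prediction needs at least 2 strains")
    g = table.genotypes.to_numpy()
    is_a = g == "A"
    is_b = g == "B"
    hom = is_a | is_b
    # differ(i,j,l) = hom_i & hom_j & (a_i != a_j); vectorize over pairs
    n = g.shape[0]
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        both_hom = hom[i] & hom
        differ = both_hom & (is_a[i] != is_a)
        counts[i] = differ.sum(axis=1)
    np.fill_diagonal(counts, 0)
    return pd.DataFrame(counts, index=table.strain_ids, columns=table.strain_ids)


class PairwiseSummary(NamedTuple):
    mean: float
    sd: float
    frac_above_threshold: float
    n_pairs: int


def summarize_pairwise(counts: pd.DataFrame, threshold: int = 300) -> PairwiseSummary:
    """Mean, SD, and the fraction of strain pairs exceeding ``threshold``.

    Statistics are over the upper triangle (each unordered pair once).
    """
    m = counts.to_numpy()
    if m.shape[0] < 2 or not np.array_equal(m, m.T):
        raise PanelError("expected a symmetric pairwise count matrix with >= 2 strains")
    iu = np.triu_indices(m.shape[0], k=1)
    vals = m[iu].astype(float)
    return PairwiseSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        frac_above_threshold=float(np.mean(vals > threshold)),
        n_pairs=len(vals),
    )


def write_diagnostic_bed(diagnostic: DiagnosticSet, panel: Panel, bed_path, provenance_path=None):
    """Write a diagnostic set as 4-column BED (+ optional provenance TSV)."""
    with open(bed_path, "w") as fh:
        for lid in diagnostic.locus_ids:
            l = panel.locus(lid)
            fh.write(f"{l.chrom}\t{l.pos - 1}\t{l.pos}\t{l.id}\n")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            fh.write("step\tcount\n")
            for k, v in diagnostic.provenance.items():
                fh.write(f"{k}\t{v}\n")
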