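"""Core data model for a SNP genotyping panel and multi-sample genotype calls.

A :class:`Panel` is an ordered map of SNP loci (the marker panel of the
assay); a :class:`GenotypeMatrix` holds the joint-genotyped calls of many
samples at those loci.  Genotype states are encoded relative to the backcross
*recipient* strain's reference genome: ``HOM_REF`` means homozygous for the
recipient allele (report code ``AA``), ``HOM_ALT`` homozygous for the
non-recipient allele (``BB``), ``HET`` heterozygous (``AB``), and ``MISSING``
a failed genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "CHROM_ORDER",
    "ChromClass",
    "GenotypeCall",
    "SnpLocus",
    "Panel",
    "GenotypeMatrix",
    "PanelError",
    "build_panel",
    "subset_panel",
    "normalize_chrom",
]

#: Canonical chromosome order: autosomes 1..19, then X, then Y (mouse karyotype).
CHROM_ORDER: tuple[str, ...] = tuple(str(i) for i in range(1, 20)) + ("X", "Y")
_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}

_NUCLEOTIDES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised on invalid panel or genotype-matrix construction."""


class ChromClass(Enum):
    AUTOSOME = "autosome"
    X = "X"
    Y = "Y"


class GenotypeCall(IntEnum):
    """Genotype state of one sample at one biallelic SNP.

    Integer codes double as the number of non-recipient (alternate) alleles,
    with ``MISSING`` as the sentinel -1.
    """

    MISSING = -1
    HOM_REF = 0  # "AA": homozygous recipient/reference allele
    HET = 1      # "AB"
    HOM_ALT = 2  # "BB": homozygous donor/alternate allele


def normalize_chrom(label: str) -> str:
    """Canonicalize a chromosome label ("chr1" and "1" both -> "1").

    Raises :class:`PanelError` for anything outside 1..19, X, Y
    (mitochondrial and unplaced contigs are not part of the assay).
    """
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("X", "Y"):
        c = c.upper()
    if c not in _CHROM_RANK:
        raise PanelError(f"unknown chromosome label: {label!r}")
    return c


@dataclass(frozen=True)
class SnpLocus:
    """One panel SNP: name, 1-based genomic coordinate, and its two alleles.

    Alleles may be ``None`` ("provisional") when the locus comes from a plain
    4-column BED file; they are filled in from VCF REF/ALT at read time.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str | None = None
    alt_allele: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise PanelError(f"locus {self.id!r}: position must be >= 1, got {self.pos}")
        for name, a in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if a is not None and a not in _NUCLEOTIDES:
                raise PanelError(
                    f"locus {self.id!r}: {name} allele must be a single nucleotide, got {a!r}"
                )
        if self.ref_allele is not None and self.ref_allele == self.alt_allele:
            raise PanelError(f"locus {self.id!r}: ref and alt alleles are identical")

    @property
    def chrom_class(self) -> ChromClass:
        if self.chrom == "X":
            return ChromClass.X
        if self.chrom == "Y":
            return ChromClass.Y
        return ChromClass.AUTOSOME

    @property
    def has_alleles(self) -> bool:
        return self.ref_allele is not None and self.alt_allele is not None


class Panel:
    """Ordered, validated collection of :class:`SnpLocus`.

    Loci are sorted by chromosome (1..19, X, Y) then position; ids and
    (chrom, pos) pairs are unique.
    """

    def __init__(self, loci: Iterable[SnpLocus]):
        loci = sorted(loci, key=lambda l: (_CHROM_RANK[l.chrom], l.pos))
        seen_ids: dict[str, SnpLocus] = {}
        seen_pos: dict[tuple[str, int], SnpLocus] = {}
        dup_ids, dup_pos = [], []
        for l in loci:
            if l.id in seen_ids:
                dup_ids.append(l.id)
            seen_ids[l.id] = l
            key = (l.chrom, l.pos)
            if key in seen_pos:
                dup_pos.append(key)
            seen_pos[key] = l
        if dup_ids:
            raise PanelError(f"duplicate locus ids: {sorted(set(dup_ids))}")
        if dup_pos:
            raise PanelError(f"duplicate (chrom, pos) coordinates: {sorted(set(dup_pos))}")
        self._loci: tuple[SnpLocus, ...] = tuple(loci)
        self._index = {l.id: i for i, l in enumerate(self._loci)}
        self._pos_index = {(l.chrom, l.pos): i for i, l in enumerate(self._loci)}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._loci)

    def __iter__(self) -> Iterator[SnpLocus]:
        return iter(self._loci)

    def __getitem__(self, i: int) -> SnpLocus:
        return self._loci[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Panel) and self._loci == other._loci

    def __repr__(self) -> str:
        a, x, y = self.counts_by_class()
        return f"Panel({len(self)} loci: {a} autosomal, {x} X, {y} Y)"

    # -- lookups ------------------------------------------------------------
    @property
    def loci(self) -> tuple[SnpLocus, ...]:
        return self._loci

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(l.id for l in self._loci)

    def index_of(self, locus_id: str) -> int:
        try:
            return self._index[locus_id]
        except KeyError:
            raise PanelError(f"locus id not in panel: {locus_id!r}") from None

    def locus(self, locus_id: str) -> SnpLocus:
        return self._loci[self.index_of(locus_id)]

    def find(self, chrom: str, pos: int) -> int | None:
        """Index of the locus at (chrom, pos), or None."""
        return self._pos_index.get((normalize_chrom(chrom), pos))

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._index

    # -- summaries ----------------------------------------------------------
    def counts_by_class(self) -> tuple[int, int, int]:
        """(n_autosome, n_X, n_Y)."""
        a = sum(l.chrom_class is ChromClass.AUTOSOME for l in self._loci)
        x = sum(l.chrom_class is ChromClass.X for l in self._loci)
        return a, x, len(self._loci) - a - x

    def ids_by_class(self, classes: set[ChromClass]) -> tuple[str, ...]:
        return tuple(l.id for l in self._loci if l.chrom_class in classes)

    def autosome_x_ids(self) -> tuple[str, ...]:
        return self.ids_by_class({ChromClass.AUTOSOME, ChromClass.X})

    def with_alleles(self, alleles: dict[str, tuple[str, str]]) -> "Panel":
        """New panel with provisional alleles filled in where given."""
        new = []
        for l in self._loci:
            if l.id in alleles and not l.has_alleles:
                ref, alt = alleles[l.id]
                new.append(replace(l, ref_allele=ref, alt_allele=alt))
            else:
                new.append(l)
        return Panel(new)


def build_panel(records: Sequence[tuple]) -> Panel:
    """Build a :class:`Panel` from (chrom, pos, id[, ref, alt]) tuples.

    Records may arrive in any order; the panel sorts them.  Duplicate ids or
    coordinates and unknown chromosome labels raise :class:`PanelError`.
    """
    if not records:
        raise PanelError("cannot build a panel from zero records")
    loci = []
    for rec in records:
        chrom, pos, lid = rec[0], int(rec[1]), str(rec[2])
        ref = rec[3] if len(rec) > 3 else None
        alt = rec[4] if len(rec) > 4 else None
        loci.append(SnpLocus(id=lid, chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt))
    return Panel(loci)


def subset_panel(panel: Panel, classes: set[ChromClass]) -> Panel:
    """Panel restricted to the given chromosome classes (order preserved).

    An empty result is allowed and returns an empty panel.
    """
    if not classes:
        raise PanelError("classes must be non-empty")
    sub = Panel.__new__(Panel)
    kept = tuple(l for l in panel if l.chrom_class in classes)
    sub._loci = kept
    sub._index = {l.id: i for i, l in enumerate(kept)}
    sub._pos_index = {(l.chrom, l.pos): i for i, l in enumerate(kept)}
    return sub


class GenotypeMatrix:
    """Dense samples x panel-loci genotype calls.

    Calls are stored as an int8 array using :class:`GenotypeCall` codes; every
    (sample, locus) pair is present (``MISSING`` allowed).
    """

    def __init__(self, sample_ids: Sequence[str], panel: Panel, calls: np.ndarray):
        sample_ids = list(map(str, sample_ids))
        if len(set(sample_ids)) != len(sample_ids):
            raise PanelError("duplicate sample ids")
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(sample_ids), len(panel)):
            raise PanelError(
                f"calls shape {calls.shape} != (n_samples={len(sample_ids)}, n_loci={len(panel)})"
            )
        valid = np.isin(calls, [-1, 0, 1, 2])
        if not valid.all():
            raise PanelError("calls contain codes outside {MISSING, HOM_REF, HET, HOM_ALT}")
        self.sample_ids = sample_ids
        self.panel = panel
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}
        #: populated by VCF readers: e.g. {"multiallelic_records": 3}
        self.warnings: dict[str, int] = {}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise PanelError(f"sample not in matrix: {sample_id!r}") from None

    def get(self, sample_id: str, locus_id: str) -> GenotypeCall:
        return GenotypeCall(
            int(self.calls[self.sample_index(sample_id), self.panel.index_of(locus_id)])
        )

    def sample_calls(self, sample_id: str, locus_ids: Sequence[str] | None = None) -> np.ndarray:
        """Call codes for one sample, optionally restricted to locus ids (panel order)."""
        row = self.calls[self.sample_index(sample_id)]
        if locus_ids is None:
            return row
        idx = np.fromiter(
            (self.panel.index_of(l) for l in locus_ids), dtype=np.intp, count=len(locus_ids)
        )
        return row[idx]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.panel, self.calls[idx])

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to a locus subset; loci are reordered to panel order."""
        wanted = set(locus_ids)
        kept = [l for l in self.panel if l.id in wanted]
        missing = wanted - {l.id for l in kept}
        if missing:
            raise PanelError(f"locus ids not in panel: {sorted(missing)}")
        sub_panel = Panel(kept)
        idx = np.array([self.panel.index_of(l.id) for l in kept], dtype=np.intp)
        return GenotypeMatrix(self.sample_ids, sub_panel, self.calls[:, idx])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.sample_ids == other.sample_ids
            and self.panel == other.panel
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {len(self.panel)} loci)"
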