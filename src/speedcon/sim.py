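"""In-silico speed-congenics: genomes, meiosis, breeding, and genotyping.

Diploid mouse genomes are modeled as ancestry-labelled chromosome segments
(DONOR vs RECIPIENT).  Meiosis follows the no-interference (Poisson/Haldane)
model: the crossover count per chromosome is Poisson with mean equal to the
genetic length in Morgans, crossover positions are uniform in genetic
coordinates and mapped linearly to physical coordinates, and the gamete
alternates between the two parental haplotypes at the crossovers starting
from a fair-coin choice.  The X recombines only in female meiosis (a male
transmits his single X intact to daughters); the Y is a non-recombining
paternal label.

On top of these primitives the module reproduces a marker-assisted backcross
program: a donor male carrying the gene of interest is crossed into a
recipient strain, carrier offspring are genotyped at the diagnostic markers
with realistic missingness, and the top-ranked carriers breed the next
generation.  Truth tables of each individual's length-weighted recipient
ancestry fraction let every marker-based estimate be validated exactly.

The default genome uses mm10 physical chromosome lengths with a uniform
0.56 cM/Mb rate (~1470 cM over autosomes + X), and the default synthetic
assay mirrors the real panel's composition: 1591 autosomal + 49 X + 29 Y
SNPs, of which 819 autosome+X loci are divergent between donor and
recipient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .congenic import rank_for_breeding
from .diagnostics import DiagnosticSet, call_diagnostic_snps
from .panel import ChromClass, GenotypeCall, GenotypeMatrix, Panel, SnpLocus

__all__ = [
    "RECIPIENT",
    "DONOR",
    "MM10_CHROM_LENGTHS",
    "DEFAULT_CM_PER_MB",
    "GenomeMap",
    "Haplotype",
    "Individual",
    "BreedingScheme",
    "SimulationError",
    "make_founder",
    "meiosis",
    "cross",
    "recipient_fraction",
    "genotype_individual",
    "simulate_breeding_program",
    "simulate_unselected_lineages",
    "simulate_assay",
    "founder_matrix",
    "load_scheme",
    "GenerationResult",
    "ProgramResult",
]

RECIPIENT = 0
DONOR = 1

#: mm10 (GRCm38) chromosome lengths in bp.
MM10_CHROM_LENGTHS: dict[str, int] = {
    "1": 195471971, "2": 182113224, "3": 160039680, "4": 156508116,
    "5": 151834684, "6": 149736546, "7": 145441459, "8": 129401213,
    "9": 124595110, "10": 130694993, "11": 122082543, "12": 120129022,
    "13": 120421639, "14": 124902244, "15": 104043685, "16": 98207768,
    "17": 94987271, "18": 90702639, "19": 61431566,
    "X": 171031299, "Y": 91744698,
}

#: Uniform recombination rate; reproduces a mouse genetic map of ~1470 cM
#: over autosomes + X.
DEFAULT_CM_PER_MB = 0.56


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GenomeMap:
    """Physical and genetic chromosome lengths (autosomes + X; Y label-only)."""

    physical: dict[str, int] = field(default_factory=lambda: dict(MM10_CHROM_LENGTHS))
    cm_per_mb: float = DEFAULT_CM_PER_MB
    #: optional per-chromosome genetic lengths (cM) overriding the uniform rate
    genetic: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.physical.values()):
            raise SimulationError("chromosome lengths must be positive")

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.physical if c not in ("X", "Y"))

    @property
    def recombining_chroms(self) -> tuple[str, ...]:
        return self.autosomes + (("X",) if "X" in self.physical else ())

    def length(self, chrom: str) -> int:
        return self.physical[chrom]

    def genetic_length(self, chrom: str) -> float:
        """Genetic length in cM."""
        if self.genetic and chrom in self.genetic:
            return self.genetic[chrom]
        return self.physical[chrom] / 1e6 * self.cm_per_mb


class Haplotype:
    """One chromosome copy as ancestry-labelled segments.

    ``ends`` are strictly increasing segment end positions (1-based,
    inclusive; the last equals the chromosome length) and ``labels`` the
    ancestry of each segment; adjacent segments always carry different
    labels (equal neighbours are merged on construction).
    """

    __slots__ = ("chrom", "ends", "labels")

    def __init__(self, chrom: str, ends: np.ndarray, labels: np.ndarray):
        ends = np.asarray(ends, dtype=np.int64)
        labels = np.asarray(labels, dtype=np.int8)
        if len(ends) != len(labels) or len(ends) == 0:
            raise SimulationError("ends and labels must be non-empty and equal length")
        if np.any(np.diff(ends) <= 0):
            raise SimulationError("segment ends must be strictly increasing")
        # merge adjacent equal-label segments
        if len(labels) > 1:
            keep = np.append(labels[:-1] != labels[1:], True)
            ends, labels = ends[keep], labels[keep]
        self.chrom = chrom
        self.ends = ends
        self.labels = labels

    @classmethod
    def pure(cls, chrom: str, length: int, label: int) -> "Haplotype":
        return cls(chrom, np.array([length]), np.array([label]))

    @property
    def length(self) -> int:
        return int(self.ends[-1])

    def label_at(self, positions: np.ndarray) -> np.ndarray:
        """Ancestry labels at 1-based positions (vectorized)."""
        idx = np.searchsorted(self.ends, positions, side="left")
        return self.labels[idx]

    def label_lengths(self) -> tuple[int, int]:
        """(recipient_bp, donor_bp)."""
        starts = np.concatenate(([0], self.ends[:-1]))
        seg = self.ends - starts
        donor = int(seg[self.labels == DONOR].sum())
        return self.length - donor, donor

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Haplotype)
            and self.chrom == other.chrom
            and np.array_equal(self.ends, other.ends)
            and np.array_equal(self.labels, other.labels)
        )


def _splice(hap_a: Haplotype, hap_b: Haplotype, cuts: np.ndarray, start_with_a: bool) -> Haplotype:
    """Form a recombinant: hap_a up to the first cut, then alternate sources."""
    if len(cuts) == 0:
        src = hap_a if start_with_a else hap_b
        return Haplotype(src.chrom, src.ends.copy(), src.labels.copy())
    length = hap_a.length
    bounds = np.concatenate(([0], cuts, [length]))
    ends_out: list[int] = []
    labels_out: list[int] = []
    use_a = start_with_a
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        src = hap_a if use_a else hap_b
        use_a = not use_a
        # segments of src intersecting (lo, hi]
        i = int(np.searchsorted(src.ends, lo + 1, side="left"))
        while i < len(src.ends) and (not ends_out or ends_out[-1] < hi):
            ends_out.append(min(int(src.ends[i]), int(hi)))
            labels_out.append(int(src.labels[i]))
            if src.ends[i] >= hi:
                break
            i += 1
    return Haplotype(hap_a.chrom, np.array(ends_out), np.array(labels_out))


def meiosis(parent: "Individual", chrom: str, rng: np.random.Generator,
            gmap: GenomeMap | None = None) -> Haplotype:
    """One gamete haplotype for a chromosome, under the Haldane model.

    Crossover count ~ Poisson(genetic_length / 100); positions uniform in
    genetic coordinates, mapped linearly to physical.  A male parent's X is
    transmitted intact (no meiotic partner).
    """
    gmap = gmap or parent.gmap
    haps = parent.haplotypes(chrom)
    if len(haps) == 1:  # hemizygous male X
        h = haps[0]
        return Haplotype(chrom, h.ends.copy(), h.labels.copy())
    hap_a, hap_b = haps
    length = gmap.length(chrom)
    n_xo = rng.poisson(gmap.genetic_length(chrom) / 100.0)
    if n_xo:
        # uniform in genetic coordinate == uniform in physical under a linear map
        cuts = np.unique((rng.uniform(0, 1, size=n_xo) * (length - 1)).astype(np.int64) + 1)
        cuts = cuts[cuts < length]
    else:
        cuts = np.empty(0, dtype=np.int64)
    first = bool(rng.integers(2))
    return _splice(hap_a, hap_b, cuts, start_with_a=first)


@dataclass
class Individual:
    """A simulated mouse: ancestry-labelled diploid genome plus metadata.

    ``generation`` follows the experiment's numbering: founders are "F0",
    their offspring "F1", and backcross generations are integers starting
    at 2 (stored as "BC<n>").
    """

    id: str
    sex: str  # "M" or "F"
    generation: str
    autosome_haps: dict[str, tuple[Haplotype, Haplotype]]
    x_haps: tuple[Haplotype, ...]  # two for females, one for males
    y_label: int | None  # males only
    carrier: bool
    gmap: GenomeMap

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise SimulationError(f"sex must be M or F, got {self.sex!r}")
        n_x = len(self.x_haps)
        if (self.sex == "F" and (n_x != 2 or self.y_label is not None)) or (
            self.sex == "M" and (n_x != 1 or self.y_label is None)
        ):
            raise SimulationError(f"{self.id}: inconsistent sex chromosomes for sex {self.sex}")

    def haplotypes(self, chrom: str) -> tuple[Haplotype, ...]:
        if chrom == "X":
            return self.x_haps
        if chrom == "Y":
            raise SimulationError("Y is modeled as a label, not a haplotype")
        return self.autosome_haps[chrom]

    def ancestry_at(self, chrom: str, pos: int) -> tuple[int, ...]:
        """Ancestry labels of each chromosome copy at a position."""
        p = np.array([pos])
        return tuple(int(h.label_at(p)[0]) for h in self.haplotypes(chrom))


def make_founder(strain_role: int, sex: str, gmap: GenomeMap | None = None,
                 id: str = "founder", generation: str = "F0") -> Individual:
    """An ancestry-pure founder; donor founders carry the gene of interest."""
    gmap = gmap or GenomeMap()
    autosomes = {
        c: (Haplotype.pure(c, gmap.length(c), strain_role),
            Haplotype.pure(c, gmap.length(c), strain_role))
        for c in gmap.autosomes
    }
    x_one = Haplotype.pure("X", gmap.length("X"), strain_role)
    if sex == "F":
        x = (x_one, Haplotype.pure("X", gmap.length("X"), strain_role))
        y = None
    else:
        x = (x_one,)
        y = strain_role
    return Individual(
        id=id, sex=sex, generation=generation, autosome_haps=autosomes,
        x_haps=x, y_label=y, carrier=(strain_role == DONOR), gmap=gmap,
    )


def cross(dam: Individual, sire: Individual, n_offspring: int, rng: np.random.Generator,
          gene_locus: tuple[str, int] | None = None, id_prefix: str = "off",
          generation: str = "?") -> list[Individual]:
    """Mate a dam and a sire; returns ``n_offspring`` pups.

    Offspring sex is a fair coin.  Daughters receive the sire's X intact;
    sons receive his Y label.  When ``gene_locus`` is given, an offspring is
    a carrier iff any chromosome copy at that locus has DONOR ancestry;
    otherwise every offspring counts as a carrier.
    """
    if dam.sex != "F" or sire.sex != "M":
        raise SimulationError("cross requires a female dam and a male sire")
    gmap = dam.gmap
    out = []
    for k in range(n_offspring):
        sex = "M" if rng.integers(2) else "F"
        autosomes = {
            c: (meiosis(dam, c, rng, gmap), meiosis(sire, c, rng, gmap))
            for c in gmap.autosomes
        }
        x_dam = meiosis(dam, "X", rng, gmap)
        if sex == "F":
            x = (x_dam, meiosis(sire, "X", rng, gmap))
            y = None
        else:
            x = (x_dam,)
            y = sire.y_label
        ind = Individual(
            id=f"{id_prefix}{k:03d}", sex=sex, generation=generation,
            autosome_haps=autosomes, x_haps=x, y_label=y, carrier=True, gmap=gmap,
        )
        if gene_locus is not None:
            c, pos = gene_locus
            ind.carrier = DONOR in ind.ancestry_at(c, pos)
        out.append(ind)
    return out


def recipient_fraction(ind: Individual, gmap: GenomeMap | None = None,
                       scope: str = "autosome+X") -> float:
    """Length-weighted RECIPIENT ancestry fraction (truth value).

    Counts both haplotypes of every autosome, plus the X copies the
    individual actually carries (two in females, one in males); the Y is
    excluded.  ``scope="autosome"`` restricts to autosomes, for which the
    classical backcross expectation 1 - 2^-g holds exactly.
    """
    gmap = gmap or ind.gmap
    chroms: Iterable[str] = gmap.autosomes if scope == "autosome" else gmap.recombining_chroms
    rec = tot = 0
    for c in chroms:
        for h in ind.haplotypes(c):
            r, d = h.label_lengths()
            rec += r
            tot += r + d
    return rec / tot


def _panel_by_chrom(panel: Panel) -> dict[str, tuple[np.ndarray, np.ndarray, tuple[str, ...]]]:
    """Cache (column indices, positions, ids) per chromosome on the panel."""
    cached = getattr(panel, "_sim_by_chrom", None)
    if cached is None:
        cached = {}
        for i, l in enumerate(panel):
            cached.setdefault(l.chrom, []).append((i, l.pos, l.id))
        cached = {
            c: (
                np.array([t[0] for t in triples], dtype=np.intp),
                np.array([t[1] for t in triples], dtype=np.int64),
                tuple(t[2] for t in triples),
            )
            for c, triples in cached.items()
        }
        panel._sim_by_chrom = cached  # type: ignore[attr-defined]
    return cached


def genotype_individual(ind: Individual, panel: Panel, diagnostic: DiagnosticSet | Sequence[str],
                        missing_rate: float = 0.025, error_rate: float = 0.0,
                        rng: np.random.Generator | None = None,
                        divergent_ids: set[str] | None = None) -> np.ndarray:
    """Genotype one individual at every panel locus (call-code array).

    At divergent loci (default: the diagnostic set) the ancestry pair maps
    REC/REC -> HOM_REF, DON/REC -> HET, DON/DON -> HOM_ALT; a hemizygous
    male X copy counts twice (REC -> HOM_REF, DON -> HOM_ALT).  At
    non-divergent loci both strains share the reference allele, so the call
    is HOM_REF regardless of ancestry.  Y loci are MISSING in females.  Each
    call then fails with probability ``missing_rate`` and, independently, is
    replaced by a uniformly chosen different call with probability
    ``error_rate``.
    """
    rng = rng or np.random.default_rng()
    if divergent_ids is None:
        divergent_ids = set(getattr(diagnostic, "locus_ids", diagnostic))
    calls = np.full(len(panel), int(GenotypeCall.HOM_REF), dtype=np.int8)
    gmap = ind.gmap
    by_chrom = _panel_by_chrom(panel)
    for chrom, (cols, positions, ids) in by_chrom.items():
        if positions.max(initial=0) > gmap.physical.get(chrom, 0):
            raise SimulationError(f"panel locus beyond chromosome {chrom} length")
        div = np.array([i in divergent_ids for i in ids], dtype=bool)
        if chrom == "Y":
            if ind.sex == "F":
                calls[cols] = int(GenotypeCall.MISSING)
            else:
                calls[cols[div]] = (
                    int(GenotypeCall.HOM_ALT) if ind.y_label == DONOR
                    else int(GenotypeCall.HOM_REF)
                )
            continue
        haps = ind.haplotypes(chrom)
        dosage = sum(h.label_at(positions).astype(np.int8) for h in haps)
        if len(haps) == 1:  # male X: one copy counted twice
            dosage = 2 * dosage
        calls[cols[div]] = dosage[div]
    # genotyping noise
    fail = rng.random(len(calls)) < missing_rate
    if error_rate:
        err = (rng.random(len(calls)) < error_rate) & ~fail & (calls != GenotypeCall.MISSING)
        for i in np.nonzero(err)[0]:
            others = [g for g in (0, 1, 2) if g != calls[i]]
            calls[i] = others[rng.integers(len(others))]
    calls[fail] = int(GenotypeCall.MISSING)
    return calls


# ---------------------------------------------------------------------------
# Synthetic assay (panel + strain divergence model)
# ---------------------------------------------------------------------------

def simulate_assay(seed: int = 0, n_autosomal: int = 1591, n_x: int = 49, n_y: int = 29,
                   n_diagnostic: int = 819, gmap: GenomeMap | None = None
                   ) -> tuple[Panel, tuple[str, ...]]:
    """Synthetic SNP panel emulating the real assay's composition.

    Loci are spread across chromosomes proportionally to physical length,
    evenly spaced with jitter.  ``n_diagnostic`` autosome+X loci (plus all Y
    loci) are marked divergent between donor and recipient: the donor strain
    is homozygous for the alternate allele there and shares the reference
    allele everywhere else.  Returns (panel, diagnostic_truth_ids) where the
    truth ids are the divergent autosome+X loci in panel order.
    """
    gmap = gmap or GenomeMap()
    rng = np.random.default_rng(seed)
    nts = np.array(list("ACGT"))
    loci: list[SnpLocus] = []

    def scatter(chrom: str, n: int, tag: str):
        length = gmap.physical[chrom]
        spacing = length / n
        raw = ((np.arange(n) + 0.5) * spacing
               + rng.uniform(-0.3, 0.3, size=n) * spacing)
        pos = np.unique(np.clip(raw.astype(np.int64), 1, length))
        for k, p in enumerate(pos):
            ref = nts[rng.integers(4)]
            alt = nts[(list("ACGT").index(ref) + 1 + rng.integers(3)) % 4]
            loci.append(SnpLocus(id=f"{tag}{chrom}_{k:04d}", chrom=chrom, pos=int(p),
                                 ref_allele=str(ref), alt_allele=str(alt)))

    # proportional allocation of autosomal loci by chromosome length
    auto = gmap.autosomes
    lens = np.array([gmap.physical[c] for c in auto], dtype=float)
    alloc = np.floor(n_autosomal * lens / lens.sum()).astype(int)
    remainder = n_autosomal - alloc.sum()
    order = np.argsort(-(n_autosomal * lens / lens.sum() - alloc))
    alloc[order[:remainder]] += 1
    for c, n in zip(auto, alloc):
        scatter(c, int(n), "snp")
    scatter("X", n_x, "snp")
    if n_y:
        scatter("Y", n_y, "snpY_")
    panel = Panel(loci)

    ax_ids = panel.autosome_x_ids()
    chosen = rng.choice(len(ax_ids), size=n_diagnostic, replace=False)
    diag = tuple(ax_ids[i] for i in sorted(chosen))
    return panel, diag


def founder_matrix(panel: Panel, divergent_ids: Sequence[str], n_donor: int = 3,
                   n_recipient: int = 3, missing_rate: float = 0.025,
                   seed: int = 0, gmap: GenomeMap | None = None) -> GenotypeMatrix:
    """Genotype pure donor and recipient founders on the panel.

    Sample ids are ``donor_1..n`` and ``recipient_1..n``; founders are male
    so Y loci genotype.  Used to exercise diagnostic-SNP calling the way the
    real study genotyped replicate founder mice.
    """
    gmap = gmap or GenomeMap()
    rng = np.random.default_rng(seed)
    div = set(divergent_ids) | {l.id for l in panel if l.chrom == "Y"}
    rows, ids = [], []
    for role, label, n in ((DONOR, "donor", n_donor), (RECIPIENT, "recipient", n_recipient)):
        for i in range(n):
            ind = make_founder(role, "M", gmap, id=f"{label}_{i + 1}")
            rows.append(genotype_individual(ind, panel, div, missing_rate, 0.0, rng,
                                            divergent_ids=div))
            ids.append(ind.id)
    return GenotypeMatrix(ids, panel, np.vstack(rows))


# ---------------------------------------------------------------------------
# The breeding program
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreedingScheme:
    """Parameters of a marker-assisted backcross program.

    Defaults mirror the reference experiment: one donor male bred to two
    recipient females, three F1 males each bred to two recipient females,
    carrier offspring counts of 13, 8, 14, 28, 6 at backcross generations
    2-6, with the top 3 then top 2 ranked carriers (either sex) kept as
    breeders; ``select_sex="male"`` restricts selection to sires.
    """

    gene_locus: tuple[str, int] | None = ("11", MM10_CHROM_LENGTHS["11"] // 2)
    n_founder_dams: int = 2
    n_f1_sires: int = 3
    dams_per_sire: int = 2
    carriers_per_generation: tuple[int, ...] = (13, 8, 14, 28, 6)
    n_select: tuple[int, ...] = (3, 2, 2, 2)
    missing_rate: float = 0.025
    error_rate: float = 0.0
    selection: str = "top"  # "top" | "random"
    select_sex: str = "any"  # "any": best carriers of either sex; "male": sires only
    first_generation_number: int = 2

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.carriers_per_generation):
            raise SimulationError("carrier counts must be >= 1")
        if len(self.n_select) != len(self.carriers_per_generation) - 1:
            raise SimulationError(
                "n_select must have one entry per generation transition "
                f"({len(self.carriers_per_generation) - 1})"
            )
        for r in (self.missing_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise SimulationError("rates must lie in [0, 1]")
        if self.selection not in ("top", "random"):
            raise SimulationError(f"unknown selection mode {self.selection!r}")
        if self.select_sex not in ("any", "male"):
            raise SimulationError(f"unknown select_sex {self.select_sex!r}")


@dataclass
class GenerationResult:
    generation: int
    matrix: GenotypeMatrix
    truth: dict[str, float]  # sample id -> true recipient fraction (autosome+X)
    ranking: list
    selected_breeders: list[str]


@dataclass
class ProgramResult:
    generations: list[GenerationResult]

    def mean_pct_recipient(self, generation: int) -> float:
        g = self._get(generation)
        return float(np.mean([e.pct_recipient for e in g.ranking if e.pct_recipient is not None]))

    def max_pct_recipient(self, generation: int) -> float:
        g = self._get(generation)
        return float(np.max([e.pct_recipient for e in g.ranking if e.pct_recipient is not None]))

    def _get(self, generation: int) -> GenerationResult:
        for g in self.generations:
            if g.generation == generation:
                return g
        raise KeyError(f"no generation {generation}")


_MAX_ATTEMPTS_PER_CARRIER = 400


def _produce_carriers(breeders: list[Individual], n_carriers: int, scheme: BreedingScheme,
                      rng: np.random.Generator, gmap: GenomeMap, gen_label: str
                      ) -> list[Individual]:
    """Backcross selected breeders to fresh recipient founders until n carriers.

    A male breeder is mated to fresh recipient females, a female breeder to
    a recipient male; litters cycle over the breeders.  Non-carrier pups are
    discarded, matching a program in which only gene-of-interest offspring
    are genotyped.
    """
    carriers: list[Individual] = []
    attempts = 0
    bi = 0
    while len(carriers) < n_carriers:
        attempts += 1
        if attempts > _MAX_ATTEMPTS_PER_CARRIER * n_carriers:
            raise SimulationError(f"{gen_label}: failed to produce {n_carriers} carriers")
        breeder = breeders[bi % len(breeders)]
        bi += 1
        if breeder.sex == "M":
            dam = make_founder(RECIPIENT, "F", gmap, id="recipient_dam")
            litter = cross(dam, breeder, 4, rng, gene_locus=scheme.gene_locus,
                           id_prefix=f"{gen_label}_tmp", generation=gen_label)
        else:
            sire = make_founder(RECIPIENT, "M", gmap, id="recipient_sire")
            litter = cross(breeder, sire, 4, rng, gene_locus=scheme.gene_locus,
                           id_prefix=f"{gen_label}_tmp", generation=gen_label)
        for pup in litter:
            if pup.carrier and len(carriers) < n_carriers:
                pup.id = f"{gen_label}_{len(carriers) + 1:02d}"
                carriers.append(pup)
    return carriers


def simulate_breeding_program(scheme: BreedingScheme, panel: Panel,
                              diagnostic: DiagnosticSet | Sequence[str],
                              rng: np.random.Generator | int,
                              gmap: GenomeMap | None = None) -> ProgramResult:
    """Run the full marker-assisted backcross program.

    Per backcross generation g: selected breeders are mated to fresh recipient
    females until the scheme's carrier count is reached; carriers are
    genotyped at the panel (diagnostic loci divergent) with the scheme's
    missingness; carriers are ranked by percent recipient alleles over the
    diagnostic loci; the top carriers (random ones for selection="random",
    males only for select_sex="male") become the next breeders.  Fully
    reproducible from the seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    gmap = gmap or GenomeMap()
    diag_ids = tuple(getattr(diagnostic, "locus_ids", diagnostic))

    donor_sire = make_founder(DONOR, "M", gmap, id="donor_F0")
    # F1 males: offspring of donor male x recipient females, all carriers
    f1_males: list[Individual] = []
    attempts = 0
    while len(f1_males) < scheme.n_f1_sires:
        attempts += 1
        if attempts > 200:
            raise SimulationError("F1: failed to obtain enough male offspring")
        dam = make_founder(RECIPIENT, "F", gmap, id="recipient_F0")
        for pup in cross(dam, donor_sire, 4, rng, gene_locus=None,
                         id_prefix="F1_", generation="F1"):
            if pup.sex == "M" and len(f1_males) < scheme.n_f1_sires:
                pup.id = f"F1_{len(f1_males) + 1}"
                f1_males.append(pup)

    breeders: list[Individual] = f1_males
    results: list[GenerationResult] = []
    for gi, n_carriers in enumerate(scheme.carriers_per_generation):
        gen_no = scheme.first_generation_number + gi
        label = f"BC{gen_no}"
        carriers = _produce_carriers(breeders, n_carriers, scheme, rng, gmap, label)
        calls = np.vstack([
            genotype_individual(ind, panel, diag_ids, scheme.missing_rate,
                                scheme.error_rate, rng)
            for ind in carriers
        ])
        matrix = GenotypeMatrix([ind.id for ind in carriers], panel, calls)
        truth = {ind.id: recipient_fraction(ind, gmap) for ind in carriers}
        ranking = rank_for_breeding(matrix, diag_ids)
        selected: list[str] = []
        if gi < len(scheme.n_select):
            by_id = {ind.id: ind for ind in carriers}
            if scheme.select_sex == "male":
                pool = [e.sample_id for e in ranking if by_id[e.sample_id].sex == "M"]
                if not pool:
                    raise SimulationError(f"{label}: no male carriers available for selection")
            else:
                pool = [e.sample_id for e in ranking]
            k = min(scheme.n_select[gi], len(pool))
            if scheme.selection == "random":
                selected = [str(s) for s in rng.choice(pool, size=k, replace=False)]
            else:
                selected = pool[:k]
            breeders = [by_id[s] for s in selected]
        results.append(GenerationResult(gen_no, matrix, truth, ranking, selected))
    return ProgramResult(results)


def simulate_unselected_lineages(n_lineages: int, n_generations: int,
                                 rng: np.random.Generator | int,
                                 gmap: GenomeMap | None = None) -> np.ndarray:
    """Independent backcross lineages without marker selection.

    Each lineage starts from an F1 and is backcrossed to fresh recipient
    founders for ``n_generations`` steps, keeping one offspring per step
    regardless of sex or genotype.  Returns an (n_lineages, n_generations)
    array of *autosomal* recipient fractions, whose expectation at backcross
    generation g (first step = generation 2) is exactly 1 - 2^-g.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    gmap = gmap or GenomeMap()
    donor = make_founder(DONOR, "M", gmap, id="donor")
    rec_dam = make_founder(RECIPIENT, "F", gmap, id="rdam")
    rec_sire = make_founder(RECIPIENT, "M", gmap, id="rsire")
    out = np.empty((n_lineages, n_generations))
    for i in range(n_lineages):
        parent = cross(rec_dam, donor, 1, rng, generation="F1")[0]
        for g in range(n_generations):
            if parent.sex == "M":
                child = cross(rec_dam, parent, 1, rng, generation=f"BC{g + 2}")[0]
            else:
                child = cross(parent, rec_sire, 1, rng, generation=f"BC{g + 2}")[0]
            out[i, g] = recipient_fraction(child, gmap, scope="autosome")
            parent = child
    return out


def replicate_trajectory(n_replicates: int, seed: int,
                         scheme: BreedingScheme | None = None,
                         gmap: GenomeMap | None = None) -> dict:
    """Run many independent breeding programs and collect the trajectory.

    Each replicate simulates the assay, genotypes three donor and three
    recipient founders, recovers the diagnostic set from the donors, and
    runs the full selected program.  The rare replicate in which a
    generation yields no male carrier is discarded and replaced (at most
    ``3 * n_replicates`` attempts).  Returns a dict with ``generations``
    (list of generation numbers), ``means`` (replicates x generations array
    of per-generation mean percent recipient alleles), and ``maxima``
    (per-replicate maximum at the final generation).
    """
    scheme = scheme or BreedingScheme()
    master = np.random.default_rng(seed)
    gens = [scheme.first_generation_number + i
            for i in range(len(scheme.carriers_per_generation))]
    means, maxima = [], []
    attempts = 0
    while len(means) < n_replicates:
        attempts += 1
        if attempts > 3 * n_replicates:
            raise SimulationError("too many failed replicate programs")
        assay_seed, founder_seed, prog_seed = master.integers(2**31, size=3)
        panel, diag_truth = simulate_assay(seed=int(assay_seed), gmap=gmap)
        founders = founder_matrix(panel, diag_truth, seed=int(founder_seed), gmap=gmap)
        diag = call_diagnostic_snps(founders, ["donor_1", "donor_2", "donor_3"],
                                    donor_label="sim_donor", recipient_label="sim_recipient")
        try:
            res = simulate_breeding_program(scheme, panel, diag, rng=int(prog_seed), gmap=gmap)
        except SimulationError:
            continue
        means.append([res.mean_pct_recipient(g) for g in gens])
        maxima.append(res.max_pct_recipient(gens[-1]))
    return {
        "generations": gens,
        "means": np.array(means),
        "maxima": np.array(maxima),
    }


def load_scheme(path) -> BreedingScheme:
    """Load a :class:`BreedingScheme` from a YAML mapping of its fields."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "gene_locus" in cfg and cfg["gene_locus"] is not None:
        c, p = cfg["gene_locus"]
        cfg["gene_locus"] = (str(c), int(p))
    for key in ("carriers_per_generation", "n_select"):
        if key in cfg:
            cfg[key] = tuple(int(v) for v in cfg[key])
    return BreedingScheme(**cfg)
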