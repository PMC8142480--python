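import numpy as np
import pytest

from speedcon.diagnostics import call_diagnostic_snps
from speedcon.panel import GenotypeCall
from speedcon.sim import (
    DONOR,
    RECIPIENT,
    BreedingScheme,
    GenomeMap,
    Haplotype,
    Individual,
    SimulationError,
    cross,
    founder_matrix,
    genotype_individual,
    load_scheme,
    make_founder,
    meiosis,
    recipient_fraction,
    simulate_breeding_program,
    simulate_unselected_lineages,
)


def assert_tiles(ind: Individual, gmap: GenomeMap):
    """Every haplotype tiles its chromosome exactly, labels alternating."""
    for c in gmap.recombining_chroms:
        for h in ind.haplotypes(c):
            assert h.length == gmap.length(c)
            assert np.all(np.diff(h.ends) > 0)
            assert np.all(h.labels[:-1] != h.labels[1:])


class TestFounders:
    def test_recipient_founder_fraction_one(self, toy_gmap):
        f = make_founder(RECIPIENT, "F", toy_gmap)
        assert recipient_fraction(f, toy_gmap) == 1.0
        assert not f.carrier

    def test_donor_founder_fraction_zero_and_carrier(self, toy_gmap):
        m = make_founder(DONOR, "M", toy_gmap)
        assert recipient_fraction(m, toy_gmap) == 0.0
        assert m.carrier
        assert m.y_label == DONOR


class TestMeiosis:
    def test_homozygous_parent_gives_pure_gamete(self, toy_gmap):
        rng = np.random.default_rng(0)
        f = make_founder(RECIPIENT, "F", toy_gmap)
        for _ in range(20):
            g = meiosis(f, "1", rng, toy_gmap)
            assert g.labels.tolist() == [RECIPIENT]

    def test_zero_crossover_gamete_equals_a_parental_haplotype(self):
        gmap = GenomeMap(physical={"1": 10_000_000, "X": 10_000_000},
                         genetic={"1": 1e-12, "X": 1e-12})
        rng = np.random.default_rng(1)
        dam = make_founder(RECIPIENT, "F", gmap)
        sire = make_founder(DONOR, "M", gmap)
        f1 = cross(dam, sire, 1, rng)[0]
        g = meiosis(f1, "1", rng, gmap)
        assert g == f1.haplotypes("1")[0] or g == f1.haplotypes("1")[1]

    def test_mean_crossover_count_matches_poisson_expectation(self):
        # 100 cM chromosome: expected 1 crossover per meiosis (+/- 3 SE at 10k)
        gmap = GenomeMap(physical={"1": 100_000_000, "X": 10_000_000},
                         genetic={"1": 100.0, "X": 5.0})
        rng = np.random.default_rng(2)
        dam = make_founder(RECIPIENT, "F", gmap)
        sire = make_founder(DONOR, "M", gmap)
        f1 = cross(dam, sire, 1, rng)[0]
        n_switches = 0
        n_meioses = 10_000
        for _ in range(n_meioses):
            g = meiosis(f1, "1", rng, gmap)
            n_switches += len(g.ends) - 1  # ancestry switches == crossovers in an F1
        assert n_switches / n_meioses == pytest.approx(1.0, abs=0.03)

    def test_male_x_transmitted_intact(self, toy_gmap):
        rng = np.random.default_rng(3)
        sire = make_founder(DONOR, "M", toy_gmap)
        g = meiosis(sire, "X", rng, toy_gmap)
        assert g == sire.x_haps[0]


class TestCross:
    def test_f1_structure(self, toy_gmap):
        rng = np.random.default_rng(4)
        dam = make_founder(RECIPIENT, "F", toy_gmap)
        sire = make_founder(DONOR, "M", toy_gmap)
        for pup in cross(dam, sire, 10, rng):
            assert_tiles(pup, toy_gmap)
            # each autosome pair: one pure recipient + one pure donor haplotype
            for c in toy_gmap.autosomes:
                labels = sorted(h.labels.tolist() for h in pup.haplotypes(c))
                assert labels == [[RECIPIENT], [DONOR]]
            assert recipient_fraction(pup, toy_gmap, scope="autosome") == 0.5

    def test_recipient_by_recipient_stays_pure(self, toy_gmap):
        rng = np.random.default_rng(5)
        pups = cross(make_founder(RECIPIENT, "F", toy_gmap),
                     make_founder(RECIPIENT, "M", toy_gmap), 5, rng)
        assert all(recipient_fraction(p, toy_gmap) == 1.0 for p in pups)

    def test_same_sex_cross_rejected(self, toy_gmap):
        rng = np.random.default_rng(6)
        with pytest.raises(SimulationError):
            cross(make_founder(RECIPIENT, "M", toy_gmap),
                  make_founder(DONOR, "M", toy_gmap), 1, rng)

    def test_carrier_transmission_is_mendelian(self, toy_gmap):
        # heterozygous carrier x recipient: half the offspring inherit the gene
        rng = np.random.default_rng(7)
        dam = make_founder(RECIPIENT, "F", toy_gmap)
        sire = make_founder(DONOR, "M", toy_gmap)
        f1_male = None
        while f1_male is None:
            p = cross(dam, sire, 4, rng)
            f1_male = next((x for x in p if x.sex == "M"), None)
        gene_locus = ("1", toy_gmap.length("1") // 2)
        pups = cross(dam, f1_male, 10_000, rng, gene_locus=gene_locus)
        frac = np.mean([p.carrier for p in pups])
        assert frac == pytest.approx(0.5, abs=0.015)  # 3 SE at n=10,000

    def test_segment_tiling_preserved_across_generations(self, toy_gmap):
        rng = np.random.default_rng(8)
        dam = make_founder(RECIPIENT, "F", toy_gmap)
        parent = cross(dam, make_founder(DONOR, "M", toy_gmap), 1, rng)[0]
        for g in range(5):
            if parent.sex == "M":
                child = cross(dam, parent, 1, rng)[0]
            else:
                child = cross(parent, make_founder(RECIPIENT, "M", toy_gmap), 1, rng)[0]
            assert_tiles(child, toy_gmap)
            parent = child


class TestRecipientFraction:
    def test_half_donor_chromosome_segment_arithmetic(self, toy_gmap):
        # one haplotype of chrom 1 is donor on its first half, all else recipient
        ind = make_founder(RECIPIENT, "F", toy_gmap, id="x")
        L1 = toy_gmap.length("1")
        half_donor = Haplotype("1", np.array([L1 // 2, L1]),
                               np.array([DONOR, RECIPIENT]))
        ind.autosome_haps["1"] = (half_donor, ind.autosome_haps["1"][1])
        total = 2 * (toy_gmap.length("1") + toy_gmap.length("2") + toy_gmap.length("X"))
        expected = 1 - (L1 // 2) / total
        assert recipient_fraction(ind, toy_gmap) == pytest.approx(expected)

    def test_autosome_scope_excludes_x(self, toy_gmap):
        ind = make_founder(RECIPIENT, "F", toy_gmap, id="x")
        ind.x_haps = (Haplotype.pure("X", toy_gmap.length("X"), DONOR),
                      ind.x_haps[1])
        assert recipient_fraction(ind, toy_gmap, scope="autosome") == 1.0
        assert recipient_fraction(ind, toy_gmap) < 1.0


class TestGenotyping:
    def test_f1_female_all_het_at_diagnostic_loci(self, assay):
        panel, diag = assay
        rng = np.random.default_rng(9)
        f1 = None
        while f1 is None:
            pups = cross(make_founder(RECIPIENT, "F"), make_founder(DONOR, "M"), 4, rng)
            f1 = next((p for p in pups if p.sex == "F"), None)
        calls = genotype_individual(f1, panel, diag, missing_rate=0.0, rng=rng)
        idx = [panel.index_of(l) for l in diag]
        assert np.all(calls[idx] == GenotypeCall.HET)
        y_idx = [i for i, l in enumerate(panel) if l.chrom == "Y"]
        assert np.all(calls[y_idx] == GenotypeCall.MISSING)  # no Y in females

    def test_recipient_founder_all_hom_ref(self, assay):
        panel, diag = assay
        rng = np.random.default_rng(10)
        r = make_founder(RECIPIENT, "M")
        calls = genotype_individual(r, panel, diag, missing_rate=0.0, rng=rng)
        assert np.all(calls == GenotypeCall.HOM_REF)

    def test_missingness_rate_binomial_expectation(self, assay):
        panel, diag = assay
        rng = np.random.default_rng(11)
        r = make_founder(RECIPIENT, "M")
        idx = [panel.index_of(l) for l in diag]
        n_missing = 0
        reps = 100
        for _ in range(reps):
            calls = genotype_individual(r, panel, diag, missing_rate=0.025, rng=rng)
            n_missing += int(np.sum(calls[idx] == GenotypeCall.MISSING))
        frac_genotyped = 1 - n_missing / (reps * len(diag))
        se = np.sqrt(0.025 * 0.975 / (reps * len(diag)))
        assert frac_genotyped == pytest.approx(0.975, abs=3 * se)


@pytest.fixture(scope="module")
def diag_set(assay):
    panel, truth = assay
    m = founder_matrix(panel, truth, seed=5)
    return call_diagnostic_snps(m, ["donor_1", "donor_2", "donor_3"])


class TestBreedingProgram:
    def test_deterministic_given_seed(self, assay, diag_set):
        panel, _ = assay
        scheme = BreedingScheme(carriers_per_generation=(6, 6), n_select=(2,))
        a = simulate_breeding_program(scheme, panel, diag_set, rng=123)
        b = simulate_breeding_program(scheme, panel, diag_set, rng=123)
        for ga, gb in zip(a.generations, b.generations):
            assert ga.matrix == gb.matrix
            assert ga.truth == gb.truth
            assert ga.selected_breeders == gb.selected_breeders

    def test_marker_estimate_tracks_truth(self, assay, diag_set):
        panel, _ = assay
        scheme = BreedingScheme(carriers_per_generation=(12, 12), n_select=(2,))
        res = simulate_breeding_program(scheme, panel, diag_set, rng=77)
        errs = []
        for g in res.generations:
            pct = {e.sample_id: e.pct_recipient for e in g.ranking}
            errs += [abs(pct[s] - 100 * f) for s, f in g.truth.items()]
        assert np.mean(errs) < 2.0

    def test_selection_beats_random_choice(self, assay, diag_set):
        panel, _ = assay
        rng = np.random.default_rng(42)
        final = {"top": [], "random": []}
        for mode in final:
            scheme = BreedingScheme(selection=mode)
            for _ in range(50):
                res = simulate_breeding_program(scheme, panel, diag_set,
                                                rng=int(rng.integers(2**31)))
                final[mode].append(res.mean_pct_recipient(6))
        assert np.mean(final["top"]) > np.mean(final["random"])

    def test_unselected_lineages_start_at_three_quarters(self, toy_gmap):
        fr = simulate_unselected_lineages(400, 1, rng=13, gmap=toy_gmap)
        assert fr.mean() == pytest.approx(0.75, abs=3 * fr.std() / 20)

    def test_scheme_validation(self):
        with pytest.raises(SimulationError):
            BreedingScheme(missing_rate=1.5)
        with pytest.raises(SimulationError):
            BreedingScheme(n_select=(3,))
        with pytest.raises(SimulationError):
            BreedingScheme(selection="psychic")

    def test_load_scheme_yaml(self, tmp_path):
        cfg = tmp_path / "scheme.yaml"
        cfg.write_text(
            "gene_locus: ['11', 61041271]\n"
            "carriers_per_generation: [6, 6]\n"
            "n_select: [2]\n"
            "missing_rate: 0.01\n"
        )
        scheme = load_scheme(cfg)
        assert scheme.gene_locus == ("11", 61041271)
        assert scheme.carriers_per_generation == (6, 6)
        assert scheme.missing_rate == 0.01
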