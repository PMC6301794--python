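"""Forward backcross-introgression simulator: tract bookkeeping, Mendelian
expectations, selection guarantees, maternal mitochondria."""

import numpy as np
import pandas as pd
import pytest

from macrospace import introgression_sim as isim


def tracts_tile(ind, cmap):
    try:
        ind.validate(cmap)
    except ValueError:
        return False
    return True


class TestF1:
    def test_f1_is_heterozygous_everywhere(self, small_map):
        pop = isim.make_f1(5, small_map)
        for ind in pop:
            assert ind.sex == "F"
            assert tracts_tile(ind, small_map)
            assert isim.donor_fraction(ind, small_map, ("autosome",)) == 0.5
            assert isim.donor_fraction(ind, small_map, ("X",)) == 0.5
            x_haps = ind.haplotypes["X"]
            origins = sorted(h[0][2] for h in x_haps)
            assert origins == [isim.RECIPIENT, isim.DONOR]
            assert ind.mito_origin == isim.DONOR

    def test_invalid_n(self, small_map):
        with pytest.raises(ValueError):
            isim.make_f1(0, small_map)


class TestMeiosis:
    def test_zero_genetic_length_returns_parental_haplotype(self, rng):
        cmap = isim.ChromosomeMap(
            (
                isim.Chromosome("a", 1000, 0.0),
                isim.Chromosome("mito", 100, 0.0, kind="mito"),
            )
        )
        mother = isim.make_f1(1, cmap)[0]
        for _ in range(10):
            g = isim.meiosis(mother, cmap["a"], rng)
            assert g in (mother.haplotypes["a"][0], mother.haplotypes["a"][1])

    def test_homozygous_parent_gamete_identical(self, rng):
        cmap = isim.ChromosomeMap(
            (
                isim.Chromosome("a", 10_000, 2.0),
                isim.Chromosome("mito", 100, 0.0, kind="mito"),
            )
        )
        hap = [(0, 10_000, isim.DONOR)]
        mother = isim.Individual(
            sex="F", haplotypes={"a": [list(hap), list(hap)]}, mito_origin=isim.DONOR
        )
        for _ in range(20):
            assert isim.meiosis(mother, cmap["a"], rng) == hap

    def test_male_parent_rejected(self, small_map, rng):
        ind = isim.make_f1(1, small_map)[0]
        ind.sex = "M"
        with pytest.raises(ValueError, match="female"):
            isim.meiosis(ind, small_map["2"], rng)

    def test_poisson_crossover_count(self, rng):
        # 1 Morgan chromosome: mean crossovers 1.0; count breakpoints as
        # origin switches in gametes of a fully heterozygous mother
        cmap = isim.ChromosomeMap(
            (
                isim.Chromosome("a", 10_000_000, 1.0),
                isim.Chromosome("mito", 100, 0.0, kind="mito"),
            )
        )
        mother = isim.make_f1(1, cmap)[0]
        n = 10_000
        switches = [len(isim.meiosis(mother, cmap["a"], rng)) - 1 for _ in range(n)]
        # switches undercount crossovers (pairs of crossovers between the
        # same haplotypes cancel); compare against the analytic expectation
        # E[switches] = E[#distinct breakpoints with odd parity] -- for
        # Poisson(1) crossovers the mean observed switch count is
        # sum_k P(k) * E[odd-parity breaks | k]; with uniform breakpoints
        # every breakpoint survives (parity 1), so switches == crossovers.
        se = 1.0 / np.sqrt(n)
        assert abs(np.mean(switches) - 1.0) < 3 * se

    def test_gamete_is_valid_tract_set(self, small_map, rng):
        mother = isim.make_f1(1, small_map)[0]
        for _ in range(50):
            g = isim.meiosis(mother, small_map["2"], rng)
            hap_holder = isim.Individual(
                sex="M",
                haplotypes={"2": [g], "X": [g], "mito": []},
                mito_origin=isim.DONOR,
            )
            isim._check_tracts(g, small_map["2"].length_bp)


class TestBackcross:
    def test_mendelian_probability_without_selection(self, small_map, rng):
        scheme = isim.IntrogressionScheme(
            selection=False, population_size=400, tolerance_loci=()
        )
        mothers = isim.make_f1(5, small_map)
        kids = isim.backcross_generation(mothers, scheme, small_map, rng)
        locus = ("2", 6_000_000)
        carriers = sum(
            isim.donor_tract_containing(k, *locus) is not None for k in kids
        )
        p_hat = carriers / len(kids)
        se = np.sqrt(0.25 / len(kids))
        assert abs(p_hat - 0.5) < 3 * se

    def test_selection_guarantees_donor_allele(self, small_map, rng):
        scheme = isim.IntrogressionScheme(
            selection=True, tolerance_loci=(("2", 6_000_000),), population_size=100
        )
        mothers = isim.make_f1(5, small_map)
        kids = isim.backcross_generation(mothers, scheme, small_map, rng)
        assert all(
            isim.donor_tract_containing(k, "2", 6_000_000) is not None for k in kids
        )

    def test_tracts_tile_after_every_generation(self, small_map):
        scheme = isim.IntrogressionScheme(
            n_backcross=4, selection=False, population_size=10, n_sib_mating=2
        )
        rng = np.random.default_rng(3)
        pop = isim.make_f1(10, small_map)
        for g in range(4):
            pop = isim.backcross_generation(pop, scheme, small_map, rng, g)
            for ind in pop:
                assert tracts_tile(ind, small_map)
        for s in range(2):
            pop = isim.sib_generation(pop, scheme, small_map, rng, s)
            for ind in pop:
                assert tracts_tile(ind, small_map)

    def test_halving_law_g3(self, small_map):
        # selection off, 3 backcrosses: mean donor fraction 2^-4
        reps = 300
        means = []
        for seed in range(reps):
            scheme = isim.IntrogressionScheme(
                n_backcross=3, selection=False, population_size=12, n_sib_mating=0
            )
            res = isim.run_introgression(scheme, small_map, seed=seed)
            means.append(res.trace.iloc[-1]["donor_fraction_autosome"])
        se = np.std(means, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(means) - 2**-4) < 3 * se

    def test_x_fraction_matches_analytic_recursion(self, small_map):
        reps = 300
        means = []
        for seed in range(reps):
            scheme = isim.IntrogressionScheme(
                n_backcross=2, selection=False, population_size=12, n_sib_mating=0
            )
            res = isim.run_introgression(scheme, small_map, seed=10_000 + seed)
            females = [i for i in res.population if i.sex == "F"]
            means.append(
                np.mean([isim.donor_fraction(i, small_map, ("X",)) for i in females])
            )
        expect = isim.expected_donor_fraction(2)["X_female"]
        se = np.std(means, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(means) - expect) < 3 * se

    def test_extinction_signalled_with_generation(self, small_map, rng):
        # mothers with no donor material cannot satisfy all-required selection
        scheme = isim.IntrogressionScheme(
            selection=True, tolerance_loci=(("2", 1_000),),
            population_size=5, max_attempts_factor=20,
        )
        hap = lambda c: [(0, c.length_bp, isim.RECIPIENT)]
        mothers = [
            isim.Individual(
                sex="F",
                haplotypes={
                    c.name: [hap(c), hap(c)]
                    for c in small_map
                    if c.kind != "mito"
                },
                mito_origin=isim.RECIPIENT,
            )
        ]
        with pytest.raises(isim.ExtinctionError) as err:
            isim.backcross_generation(mothers, scheme, small_map, rng, generation=7)
        assert err.value.generation == 7

    def test_locus_outside_bounds_rejected(self, small_map):
        scheme = isim.IntrogressionScheme(tolerance_loci=(("2", 10**9),))
        with pytest.raises(ValueError, match="bounds"):
            isim.run_introgression(scheme, small_map, seed=0)


class TestFullScheme:
    def test_g0_returns_f1_population(self, small_map):
        scheme = isim.IntrogressionScheme(
            n_backcross=0, selection=False, population_size=8, n_sib_mating=0
        )
        res = isim.run_introgression(scheme, small_map, seed=0)
        assert res.trace.iloc[-1]["donor_fraction_autosome"] == 0.5
        assert len(res.population) == 8

    def test_mitochondria_donor_in_every_generation(self, small_map):
        scheme = isim.IntrogressionScheme(
            n_backcross=3, selection=False, population_size=10, n_sib_mating=2
        )
        res = isim.run_introgression(scheme, small_map, seed=1)
        assert (res.trace["mito_donor_fraction"] == 1.0).all()

    def test_seeded_determinism(self, small_map):
        scheme = isim.IntrogressionScheme(
            n_backcross=2, selection=False, population_size=6, n_sib_mating=1
        )
        r1 = isim.run_introgression(scheme, small_map, seed=42)
        r2 = isim.run_introgression(scheme, small_map, seed=42)
        pd.testing.assert_frame_equal(r1.trace, r2.trace)


class TestPoolCounts:
    @staticmethod
    def _snps(n=1000, length=47_000_000):
        pos = np.linspace(1, length, n, dtype=np.int64)
        return pd.DataFrame({"chrom": "2", "pos": pos})

    def test_pure_recipient_pool_gives_zero_reads(self, small_map):
        hap = lambda c: [(0, c.length_bp, isim.RECIPIENT)]
        pop = [
            isim.Individual(
                sex="F",
                haplotypes={c.name: [hap(c), hap(c)] for c in small_map if c.kind != "mito"},
                mito_origin=isim.RECIPIENT,
            )
            for _ in range(10)
        ]
        pc = isim.pool_counts(pop, self._snps(), 50, 10, seed=0)
        assert (pc["donor_reads"] == 0).all()

    def test_pure_donor_pool_gives_frequency_one(self, small_map):
        hap = lambda c: [(0, c.length_bp, isim.DONOR)]
        pop = [
            isim.Individual(
                sex="F",
                haplotypes={c.name: [hap(c), hap(c)] for c in small_map if c.kind != "mito"},
                mito_origin=isim.DONOR,
            )
            for _ in range(10)
        ]
        pc = isim.pool_counts(pop, self._snps(), 50, 10, seed=0)
        covered = pc[pc["depth"] > 0]
        assert (covered["donor_reads"] == covered["depth"]).all()

    def test_binomial_law_at_half_frequency(self, small_map):
        # heterozygous pool: donor frequency exactly 0.5 at every SNP
        pop = isim.make_f1(10, small_map)
        pc = isim.pool_counts(pop, self._snps(10_000), 50, 10, seed=1)
        covered = pc[pc["depth"] > 0]
        freq = covered["donor_reads"].sum() / covered["depth"].sum()
        se = 0.5 / np.sqrt(covered["depth"].sum())
        assert abs(freq - 0.5) < 3 * se

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            isim.pool_counts([], self._snps(10), 50, 10)


def test_default_map_has_one_mito_and_positive_lengths():
    cmap = isim.default_chromosome_map()
    assert sum(c.kind == "mito" for c in cmap) == 1
    assert all(c.length_bp > 0 for c in cmap)
    with pytest.raises(ValueError):
        isim.ChromosomeMap((isim.Chromosome("2", 100, 1.0),))


def test_ancestry_bed_round_trip(tmp_path, small_map):
    scheme = isim.IntrogressionScheme(
        n_backcross=2, selection=False, population_size=4, n_sib_mating=0
    )
    res = isim.run_introgression(scheme, small_map, seed=2)
    path = tmp_path / "tracts.bed"
    isim.write_ancestry_bed(res.population[0], small_map, path)
    bed = pd.read_csv(path, sep="\t", header=None)
    assert (bed[2] > bed[1]).all()
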