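"""Diploid genetics over system coefficients: meiosis, hybrids, X linkage."""

import numpy as np
import pytest

import sysdrift as sd
from sysdrift import genetics as g


@pytest.fixture
def lmap():
    return g.a_matrix_loci(2)


@pytest.fixture
def parents(lmap):
    return (
        g.homozygote(lmap, sd.oscillator_family(0.0)),
        g.homozygote(lmap, sd.oscillator_family(-2.0)),
    )


class TestLocusMap:
    def test_one_locus_per_A_entry(self, lmap):
        assert len(lmap.loci) == 4
        assert all(l.chromosome == "autosome" for l in lmap.loci)

    def test_duplicate_address_rejected(self):
        with pytest.raises(ValueError, match="more than one locus"):
            g.LocusMap(
                loci=(
                    g.Locus("a", (("A", 0, 0),)),
                    g.Locus("b", (("A", 0, 0),)),
                ),
                n=2, m=1, l=1,
            )

    def test_out_of_bounds_address_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            g.LocusMap(loci=(g.Locus("a", (("A", 2, 0),)),), n=2, m=1, l=1)

    def test_row_linked_loci_supported(self):
        # cis linkage: a promoter row inherited as one unit
        lm = g.LocusMap(
            loci=(
                g.Locus("row1", (("A", 0, 0), ("A", 0, 1))),
                g.Locus("row2", (("A", 1, 0), ("A", 1, 1))),
            ),
            n=2, m=1, l=1,
        )
        hap = g.haplotype_from_system(lm, sd.oscillator())
        assert hap["row1"] == (0.0, 1.0)


class TestDiploidSystem:
    def test_homozygote_expresses_own_system(self, lmap):
        sys = sd.oscillator_family(0.3)
        geno = g.homozygote(lmap, sys)
        np.testing.assert_array_equal(g.diploid_system(geno).A, sys.A)

    def test_f1_is_coefficient_average(self, parents):
        f1 = g.f1_hybrid(*parents)
        np.testing.assert_allclose(
            g.diploid_system(f1).A, [[1.0, 0.0], [2.0, -1.0]], atol=1e-14
        )

    def test_example_hybrid_has_exponential_phenotype(self, parents):
        # F1 of two perfect oscillators fails to oscillate: h(t) = e^t
        f1_sys = g.diploid_system(g.f1_hybrid(*parents))
        t = np.linspace(0, 3, 40)
        h = sd.impulse_response(f1_sys, t).values[:, 0, 0]
        np.testing.assert_allclose(h, np.exp(t), rtol=1e-8)


class TestGamete:
    def test_homozygote_gamete_is_parental_haplotype(self, lmap, rng):
        geno = g.homozygote(lmap, sd.oscillator())
        gam = g.gamete(geno, rng)
        assert gam.alleles == geno.hap1.alleles

    def test_segregation_is_fair_and_independent(self, parents, rng):
        f1 = g.f1_hybrid(*parents)
        n = 4000
        counts = {l.name: 0 for l in f1.locus_map.loci}
        for _ in range(n):
            gam = g.gamete(f1, rng)
            for name in counts:
                if gam[name] == f1.hap1[name]:
                    counts[name] += 1
        for name, c in counts.items():
            assert abs(c / n - 0.5) < 4 * 0.5 / np.sqrt(n)  # 4-sigma binomial band

    def test_reproducible_given_seed(self, parents):
        f1 = g.f1_hybrid(*parents)
        g1 = [g.gamete(f1, np.random.default_rng(7)).alleles for _ in range(3)]
        assert g1[0] == g1[1] == g1[2]


class TestCross:
    def test_homozygous_parents_give_identical_f1s(self, parents, rng):
        ens = g.cross(*parents, n_offspring=20, rng=rng)
        a0 = ens.systems[0].A
        assert all(np.array_equal(s.A, a0) for s in ens.systems)

    def test_selfing_homozygote_reproduces_parent(self, lmap, rng):
        geno = g.homozygote(lmap, sd.oscillator())
        ens = g.cross(geno, geno, 5, rng)
        for s in ens.systems:
            np.testing.assert_array_equal(s.A, sd.oscillator().A)

    def test_f2_per_locus_mendelian_ratios(self, parents, rng):
        f1 = g.f1_hybrid(*parents)
        n = 4000
        ens = g.cross(f1, f1, n, rng, generation="F2")
        x, y = parents[0].hap1["A11"], parents[1].hap1["A11"]
        states = [
            tuple(sorted([geno.hap1["A11"], geno.hap2["A11"]]))
            for geno in ens.genotypes
        ]
        hom1 = np.mean([s == (x, x) for s in states])
        het = np.mean([s == tuple(sorted([x, y])) for s in states])
        assert abs(hom1 - 0.25) < 4 * np.sqrt(0.25 * 0.75 / n)
        assert abs(het - 0.5) < 4 * np.sqrt(0.5 * 0.5 / n)

    def test_incompatible_locus_maps_rejected(self, parents):
        other = g.homozygote(g.a_matrix_loci(2, x_columns=[1]), sd.oscillator())
        with pytest.raises(ValueError, match="incompatible"):
            g.cross(parents[0], other, 1, np.random.default_rng(0))


class TestF2Enumerate:
    def test_two_gene_parents_give_81_genotypes(self, parents):
        ens = g.f2_enumerate(*parents)
        assert len(ens) == 3**4 == 81
        assert abs(ens.weights.sum() - 1) < 1e-12
        assert abs(ens.uniform_weights.sum() - 1) < 1e-12

    def test_single_locus_mendelian_weights(self):
        lm = g.LocusMap(loci=(g.Locus("a", (("A", 0, 0),)),), n=2, m=1, l=1)
        p1 = g.homozygote(lm, sd.oscillator())
        p2 = g.homozygote(lm, sd.oscillator_family(0.5))
        ens = g.f2_enumerate(p1, p2)
        assert len(ens) == 3
        np.testing.assert_allclose(ens.weights, [0.25, 0.5, 0.25])

    def test_identical_parents_collapse(self, lmap):
        p = g.homozygote(lmap, sd.oscillator())
        ens = g.f2_enumerate(p, p)
        for s in ens.systems:
            np.testing.assert_array_equal(s.A, sd.oscillator().A)

    def test_weighted_mean_equals_f1(self, parents):
        # Mendelian expectation: E[F2 coefficients] = F1 coefficients
        ens = g.f2_enumerate(*parents)
        mean_A = sum(w * s.A for w, s in zip(ens.weights, ens.systems))
        f1_A = g.diploid_system(g.f1_hybrid(*parents)).A
        np.testing.assert_allclose(mean_A, f1_A, atol=1e-12)

    def test_coefficients_within_parental_interval(self, parents):
        ens = g.f2_enumerate(*parents)
        lo = np.minimum(parents[0].base.A, sd.oscillator_family(-2.0).A)
        hi = np.maximum(parents[0].base.A, sd.oscillator_family(-2.0).A)
        for s in ens.systems:
            assert np.all(s.A >= lo - 1e-12) and np.all(s.A <= hi + 1e-12)

    def test_heterozygous_parent_rejected(self, parents, rng):
        f1 = g.f1_hybrid(*parents)
        with pytest.raises(ValueError, match="homozygous"):
            g.f2_enumerate(f1, parents[0])

    def test_cap_exceeded_advises_sampling(self):
        lm = g.a_matrix_loci(4)  # 16 loci -> 3^16 states
        p1 = g.homozygote(lm, sd.random_system(4, seed=0))
        p2 = g.homozygote(lm, sd.random_system(4, seed=1))
        with pytest.raises(ValueError, match="f2_sample"):
            g.f2_enumerate(p1, p2)


class TestHaldane:
    @pytest.fixture
    def xmap(self):
        return g.a_matrix_loci(2, x_columns=[1])

    def test_f1_male_matrix_form(self, xmap):
        # autosomal column averaged, X column maternal, dosage 2
        A0, Am = sd.oscillator(), sd.oscillator_family(0.2)
        father = g.homozygote(xmap, A0, sex="male")
        mother = g.homozygote(xmap, Am, sex="female")
        son = g.haldane_f1(father, mother, sex="male")
        S = g.diploid_system(son, dosage=2.0)
        expected = np.column_stack([(A0.A[:, 0] + Am.A[:, 0]) / 2.0, Am.A[:, 1]])
        np.testing.assert_allclose(S.A, expected, atol=1e-14)

    def test_f1_female_equals_autosomal_average(self, xmap):
        A0, Am = sd.oscillator(), sd.oscillator_family(0.2)
        father = g.homozygote(xmap, A0, sex="male")
        mother = g.homozygote(xmap, Am, sex="female")
        daughter = g.haldane_f1(father, mother, sex="female")
        np.testing.assert_allclose(
            g.diploid_system(daughter).A, (A0.A + Am.A) / 2.0, atol=1e-14
        )

    def test_male_state_is_member_of_autosomal_f2_enumeration(self, xmap):
        # F1 male = het at autosomal loci, maternal-homozygous at X loci:
        # that per-locus state occurs among the 81 autosomal F2 classes
        A0, Am = sd.oscillator(), sd.oscillator_family(0.2)
        son = g.haldane_f1(
            g.homozygote(xmap, A0, sex="male"),
            g.homozygote(xmap, Am, sex="female"),
            sex="male",
        )
        S = g.diploid_system(son, dosage=2.0)
        amap = g.a_matrix_loci(2)
        ens = g.f2_enumerate(g.homozygote(amap, A0), g.homozygote(amap, Am))
        matches = [
            st for st, s in zip(ens.states, ens.systems)
            if np.allclose(s.A, S.A, atol=1e-12)
        ]
        assert matches
        # loci ordered A11, A12, A21, A22: autosomal column het, X column from p2
        assert matches[0] == (1, 2, 1, 2)

    def test_all_autosomal_sexes_agree(self, lmap):
        # without X loci the construction is undefined; cross() covers it and
        # male = female = standard F1
        p1 = g.homozygote(lmap, sd.oscillator())
        p2 = g.homozygote(lmap, sd.oscillator_family(0.3))
        with pytest.raises(ValueError, match="X-linked"):
            g.haldane_f1(p1, p2, sex="male")

    def test_dosage_required_for_hemizygote(self, xmap):
        son = g.haldane_f1(
            g.homozygote(xmap, sd.oscillator(), sex="male"),
            g.homozygote(xmap, sd.oscillator_family(0.2), sex="female"),
            sex="male",
        )
        with pytest.raises(ValueError, match="dosage"):
            g.diploid_system(son, dosage=None)


class TestGeneticDistance:
    def test_identical_systems_zero(self, osc):
        assert g.genetic_distance(osc, osc) == 0.0

    def test_family_endpoints_sqrt48(self):
        d = g.genetic_distance(sd.oscillator_family(0.0), sd.oscillator_family(-2.0))
        np.testing.assert_allclose(d, np.sqrt(48.0), rtol=1e-14)

    def test_symmetric(self):
        s1, s2 = sd.random_system(3, seed=1), sd.random_system(3, seed=2)
        assert g.genetic_distance(s1, s2) == g.genetic_distance(s2, s1)

    def test_dimension_mismatch_rejected(self, osc):
        with pytest.raises(ValueError, match="dimensions"):
            g.genetic_distance(osc, sd.random_system(3, seed=0))
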