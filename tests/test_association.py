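import numpy as np
import pytest

from gdti.association import (
    ENUMERATION_CAP,
    GDTI,
    AssociationResults,
    gdt_me_test,
    gdt_test,
    gdti_test,
    information_closed_form,
    information_enumeration,
    kinship_matrix,
    pedigree_components,
    pedigree_score_s,
    pedigree_scores_gdti,
)
from gdti.pedigree import Individual, MarkerGenotype, Pedigree, PedigreeSet
from gdti.scoring import decompose_scores

from conftest import simulated_set

M1M1 = MarkerGenotype(1, 1)
M1M2 = MarkerGenotype(1, 2)
M2M2 = MarkerGenotype(2, 2)


def _swap_all(ped: Pedigree) -> Pedigree:
    return ped.with_genotypes({m.iid: m.genotype.swapped() for m in ped})


class TestPedigreeScore:
    def test_worked_trio(self, trio):
        assert pedigree_score_s(trio) == pytest.approx(2 / 3, abs=1e-15)

    def test_constant_genotypes_score_zero(self):
        ped = Pedigree(
            "1",
            [
                Individual("A", affection=1, genotype=M1M2),
                Individual("B", affection=0, genotype=M1M2),
            ],
        )
        assert pedigree_score_s(ped) == 0.0

    def test_allele_relabelling_negates_score(self, trio):
        assert pedigree_score_s(_swap_all(trio)) == pytest.approx(
            -pedigree_score_s(trio)
        )

    def test_concordant_pedigree_skipped(self):
        ped = Pedigree(
            "1",
            [
                Individual("A", affection=1, genotype=M1M1),
                Individual("B", affection=1, genotype=M2M2),
            ],
        )
        assert pedigree_score_s(ped) is None


class TestGDTME:
    def test_single_pedigree_statistic_is_one(self, trio_set):
        res = gdt_me_test(trio_set)
        assert res.statistic == pytest.approx(1.0)
        assert res.df is None
        assert res.n_pedigrees_used == 1

    def test_opposite_scores_cancel(self, trio):
        swapped = Pedigree("2", _swap_all(trio).members)
        res = gdt_me_test(PedigreeSet([trio, swapped]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_k_identical_pedigrees_scale_as_sqrt_k(self, trio):
        k = 9
        copies = [Pedigree(str(i), trio.members) for i in range(k)]
        res = gdt_me_test(PedigreeSet(copies))
        assert res.statistic == pytest.approx(np.sqrt(k))

    def test_all_zero_scores_flagged_degenerate(self):
        ped = Pedigree(
            "1",
            [
                Individual("A", affection=1, genotype=M1M2),
                Individual("B", affection=0, genotype=M1M2),
            ],
        )
        res = gdt_me_test(PedigreeSet([ped]))
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert "degenerate_variance" in res.flags


class TestKinship:
    def test_textbook_coefficients(self):
        ped = Pedigree(
            "1",
            [
                Individual("GF", sex=1),
                Individual("GM", sex=2),
                Individual("F", "GF", "GM", sex=1),
                Individual("S2", "GF", "GM", sex=2),
                Individual("M", sex=2),
                Individual("C", "F", "M"),
            ],
        )
        kin = kinship_matrix(ped)
        assert kin["GF", "GF"] == pytest.approx(0.5)
        assert kin["F", "C"] == pytest.approx(0.25)  # parent-offspring
        assert kin["F", "S2"] == pytest.approx(0.25)  # full siblings
        assert kin["GF", "C"] == pytest.approx(0.125)  # grandparent
        assert kin["S2", "C"] == pytest.approx(0.125)  # avuncular
        assert kin["M", "GF"] == 0.0  # married-in founder
        assert np.allclose(kin.phi, kin.phi.T)

    def test_inbred_offspring_diagonal(self):
        ped = Pedigree(
            "1",
            [
                Individual("F", sex=1),
                Individual("M", sex=2),
                Individual("S", "F", "M", sex=1),
                Individual("D", "F", "M", sex=2),
                Individual("I", "S", "D"),
            ],
        )
        kin = kinship_matrix(ped)
        # parents are full sibs: phi_fm = 1/4 -> diagonal 1/2 + 1/8
        assert kin["I", "I"] == pytest.approx(0.625)


class TestGDT:
    def test_unrelated_pair_variance(self):
        # one affected M1M1 and one unaffected M2M2 'pedigree' of unrelateds:
        # V = (1/N^2)(U^2 + A^2) * 2p(1-p) = 0.25 at p = 0.5, S = 1
        ped = Pedigree(
            "1",
            [
                Individual("A", affection=1, genotype=M1M1),
                Individual("B", affection=0, genotype=M2M2),
            ],
        )
        res = gdt_test(PedigreeSet([ped]), allele_freq=0.5)
        assert res.statistic == pytest.approx(1.0 / np.sqrt(0.25))

    def test_variance_vanishes_with_rare_allele(self):
        ped = Pedigree(
            "1",
            [
                Individual("A", affection=1, genotype=M1M1),
                Individual("B", affection=0, genotype=M2M2),
            ],
        )
        strong = gdt_test(PedigreeSet([ped]), allele_freq=0.5)
        weak = gdt_test(PedigreeSet([ped]), allele_freq=1e-6)
        # V ~ 2p(1-p) -> statistic magnitude explodes as p -> 0
        assert abs(weak.statistic) > abs(strong.statistic)

    def test_invalid_frequency_rejected(self, trio_set):
        with pytest.raises(ValueError):
            gdt_test(trio_set, allele_freq=1.5)


class TestGDTIScores:
    def test_worked_trio_d_components(self, trio):
        d1, d2 = pedigree_scores_gdti(trio)
        assert d1 == pytest.approx(1 / 3, abs=1e-15)
        assert d2 == pytest.approx(1 / 3, abs=1e-15)

    def test_d_components_sum_to_s(self):
        for ped in simulated_set(seed=41, per_template=5):
            comp = pedigree_components(ped)
            if comp is None:
                continue
            assert comp.d1 + comp.d2 == pytest.approx(comp.s, abs=1e-12)

    def test_equal_scores_give_zero(self):
        ped = Pedigree(
            "1",
            [
                Individual("A", affection=1, genotype=M1M1),
                Individual("B", affection=0, genotype=M1M1),
            ],
        )
        assert pedigree_scores_gdti(ped) == (0.0, 0.0)


class TestInformation:
    def test_worked_trio_both_routes(self, trio):
        enum = information_enumeration(trio)
        closed = information_closed_form(trio)
        assert enum[0] == pytest.approx(1 / 18, abs=1e-14)
        assert np.allclose(enum, closed, atol=1e-12)

    def test_closed_form_matches_enumeration_on_random_pedigrees(self):
        """The subset-variance closed form reproduces brute enumeration."""
        checked = 0
        for seed in (51, 52):
            for ped in simulated_set(seed=seed, per_template=4):
                if ped.n_affected() in (0, ped.n):
                    continue
                enum = information_enumeration(ped)
                closed = information_closed_form(ped)
                assert np.allclose(enum, closed, atol=1e-12)
                checked += 1
        assert checked >= 10

    def test_cross_information_equals_marginal_when_scores_coincide(self, trio):
        i11, i22, i12 = information_enumeration(trio)
        assert i12 == pytest.approx(i11)
        assert i22 == pytest.approx(i11)

    def test_constant_scores_zero_information(self):
        ped = Pedigree(
            "1",
            [
                Individual("A", affection=1, genotype=M2M2),
                Individual("B", affection=0, genotype=M2M2),
            ],
        )
        assert information_enumeration(ped) == (0.0, 0.0, 0.0)
        assert information_closed_form(ped) == (0.0, 0.0, 0.0)

    def test_enumeration_cap(self, monkeypatch):
        import gdti.association as assoc

        monkeypatch.setattr(assoc, "ENUMERATION_CAP", 2)
        ped = simulated_set(seed=53, per_template=1).pedigrees[1]
        if ped.n_affected() in (0, ped.n):
            pytest.skip("degenerate draw")
        with pytest.raises(ValueError, match="closed_form"):
            information_enumeration(ped)

    def test_summed_information_is_psd(self):
        total = np.zeros((2, 2))
        for ped in simulated_set(seed=54, per_template=5):
            comp = pedigree_components(ped)
            if comp is None:
                continue
            eig = np.linalg.eigvalsh(comp.information)
            assert eig.min() >= -1e-12
            total += comp.information
        assert np.linalg.eigvalsh(total).min() >= -1e-12


class TestGDTITest:
    def test_zero_scores_give_unit_pvalue(self):
        peds = PedigreeSet(
            [
                Pedigree(
                    "1",
                    [
                        Individual("A", affection=1, genotype=M1M1),
                        Individual("B", affection=0, genotype=M1M1),
                    ],
                )
            ]
        )
        res = gdti_test(peds)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_rank_one_pseudo_inverse_convention(self, trio_set):
        # paternal and maternal score vectors coincide on this trio, so the
        # information has rank 1 and the statistic collapses to
        # (D1 + D2)^2 / (I11 + 2 I12 + I22)
        res = gdti_test(trio_set)
        d = 2 / 3
        i = 4 / 18
        assert "singular_information" in res.flags
        assert res.df == 1
        assert res.statistic == pytest.approx(d**2 / i)

    def test_allele_relabelling_invariance(self):
        peds = simulated_set(seed=55, per_template=5)
        swapped = PedigreeSet([_swap_all(p) for p in peds])
        r1 = gdti_test(peds)
        r2 = gdti_test(swapped)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.df == r2.df

    def test_skip_counting(self, trio):
        concordant = Pedigree(
            "2",
            [
                Individual("A", affection=1, genotype=M1M1),
                Individual("B", affection=1, genotype=M2M2),
            ],
        )
        res = gdti_test(PedigreeSet([trio, concordant]))
        assert res.n_pedigrees_used == 1
        assert res.n_pedigrees_skipped == 1

    def test_model_results_summary(self, trio_set):
        res = GDTI(trio_set).fit()
        assert isinstance(res, AssociationResults)
        text = res.summary()
        assert "GDTI" in text and "p-value" in text


class TestPermutationMean:
    def test_mean_subset_score_over_label_permutations(self):
        """E over random affection relabelings of the score sum matches the
        combinatorial mean A*cbar used in the information's first term."""
        rng = np.random.default_rng(77)
        ped = simulated_set(seed=56, per_template=2).pedigrees[0]
        scores = decompose_scores(ped)
        xp = np.array([scores[m.iid].xp for m in ped])
        resolved = ped.resolved_affection()
        aff = np.array([bool(resolved[m.iid]) for m in ped])
        a = int(aff.sum())
        if a in (0, ped.n):
            pytest.skip("degenerate draw")
        un = ~aff
        c = un.sum() * xp - xp[un].sum()
        draws = []
        for _ in range(4000):
            perm = rng.permutation(ped.n)[:a]
            draws.append(c[perm].sum())
        expected = a * c.mean()
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - expected) < 4 * se + 1e-12
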