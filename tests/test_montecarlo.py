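import itertools

import numpy as np
import pytest
from scipy import stats

import gdti.montecarlo as mc
from gdti.association import gdt_me_test, gdti_test, pedigree_components
from gdti.montecarlo import (
    MCConfig,
    enumerate_completions,
    estimate_allele_frequency,
    mc_components,
    mcgdt_me_test,
    mcgdti_test,
    peel_likelihood,
    sample_missing,
)
from gdti.pedigree import Individual, MarkerGenotype, Pedigree

from conftest import simulated_set

M1M1 = MarkerGenotype(1, 1)
M1M2 = MarkerGenotype(1, 2)
M2M2 = MarkerGenotype(2, 2)


def brute_force_likelihood(ped: Pedigree, p: float) -> float:
    """Independent joint-probability oracle by full enumeration."""
    ids = [m.iid for m in ped.members]
    observed = {m.iid: m.genotype.m1_count for m in ped if m.genotype}
    total = 0.0
    for combo in itertools.product(range(3), repeat=len(ids)):
        assign = dict(zip(ids, combo))
        if any(assign[i] != g for i, g in observed.items()):
            continue
        prob = 1.0
        for m in ped.members:
            g = assign[m.iid]
            if m.is_founder:
                prob *= ((1 - p) ** 2, 2 * p * (1 - p), p * p)[g]
            else:
                pf = assign[m.father_iid] / 2
                pm = assign[m.mother_iid] / 2
                prob *= (
                    (1 - pf) * (1 - pm),
                    pf * (1 - pm) + (1 - pf) * pm,
                    pf * pm,
                )[g]
        total += prob
    return total


def brute_force_conditional(ped: Pedigree, p: float) -> dict[tuple, float]:
    """Conditional P(G_m | G_o) over missing-genotype assignments."""
    missing = [m.iid for m in ped if m.genotype is None]
    weights: dict[tuple, float] = {}
    for combo in itertools.product(range(3), repeat=len(missing)):
        completed = ped.with_genotypes(
            {
                iid: (M2M2, M1M2, M1M1)[g]
                for iid, g in zip(missing, combo)
            }
        )
        weights[combo] = brute_force_likelihood(completed, p)
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


@pytest.fixture
def trio_missing_parents() -> Pedigree:
    return Pedigree(
        "1",
        [
            Individual("F", sex=1, affection=0),
            Individual("M", sex=2, affection=0),
            Individual("C", "F", "M", sex=1, affection=1, genotype=M1M2),
        ],
    )


class TestAlleleFrequency:
    def test_founder_gene_counting(self):
        ped = Pedigree(
            "1",
            [
                Individual("A", sex=1, genotype=M1M2),
                Individual("B", sex=2, genotype=M2M2),
                Individual("C", "A", "B", genotype=M1M2),
            ],
        )
        assert estimate_allele_frequency([ped], "founders") == pytest.approx(0.25)
        assert estimate_allele_frequency(
            [ped], "all_individuals"
        ) == pytest.approx(2 / 6)

    def test_degenerate_estimate_rejected(self):
        ped = Pedigree("1", [Individual("A", genotype=M1M1)])
        with pytest.raises(ValueError, match="degenerate"):
            estimate_allele_frequency([ped], "founders")

    def test_no_typed_individuals_rejected(self):
        ped = Pedigree("1", [Individual("A")])
        with pytest.raises(ValueError, match="no genotyped"):
            estimate_allele_frequency([ped], "founders")

    def test_true_mode_returns_supplied_value(self):
        assert estimate_allele_frequency([], "true", value=0.15) == 0.15


class TestPeeling:
    def test_hwe_founder_pair(self):
        ped = Pedigree(
            "1",
            [
                Individual("A", sex=1, genotype=M1M2),
                Individual("B", sex=2, genotype=M1M2),
            ],
        )
        assert peel_likelihood(ped, p=0.5) == pytest.approx(0.25)

    def test_marginalising_parents_recovers_hwe(self):
        ped = Pedigree(
            "1",
            [
                Individual("F", sex=1),
                Individual("M", sex=2),
                Individual("C", "F", "M", genotype=M1M1),
            ],
        )
        assert peel_likelihood(ped, p=0.5) == pytest.approx(0.25, abs=1e-12)

    def test_empty_evidence_is_one(self):
        ped = Pedigree(
            "1",
            [
                Individual("F", sex=1),
                Individual("M", sex=2),
                Individual("C", "F", "M"),
            ],
        )
        assert peel_likelihood(ped, p=0.3) == pytest.approx(1.0, abs=1e-12)

    def test_impossible_observation_is_zero(self):
        ped = Pedigree(
            "1",
            [
                Individual("F", sex=1, genotype=M2M2),
                Individual("M", sex=2, genotype=M2M2),
                Individual("C", "F", "M", genotype=M1M1),
            ],
        )
        assert peel_likelihood(ped, p=0.4) == 0.0

    def test_matches_brute_force_on_random_masked_pedigrees(self):
        """Peeling equals full enumeration for random data and masks."""
        rng = np.random.default_rng(8)
        checked = 0
        for ped in simulated_set(seed=81, per_template=2).pedigrees:
            if ped.n > 10:
                continue  # keep the brute-force oracle fast
            masked = ped.with_genotypes(
                {
                    m.iid: None
                    for m in ped.members
                    if rng.random() < 0.4
                }
            )
            for p in (0.2, 0.5):
                lhs = peel_likelihood(masked, p=p)
                rhs = brute_force_likelihood(masked, p)
                assert lhs == pytest.approx(rhs, rel=1e-12)
            checked += 1
        assert checked >= 3


class TestSampler:
    def test_no_missing_is_degenerate(self, trio):
        cfg = MCConfig(k=5, seed=1, allele_freq=0.5, freq_mode="true")
        draws = sample_missing(trio, cfg=cfg)
        assert len(draws) == 5
        for d in draws:
            assert d == {m.iid: m.genotype for m in trio}

    def test_impossible_observation_raises(self):
        ped = Pedigree(
            "1",
            [
                Individual("F", sex=1, genotype=M2M2),
                Individual("M", sex=2, genotype=M2M2),
                Individual("C", "F", "M", genotype=M1M1),
                Individual("D", "F", "M"),
            ],
        )
        cfg = MCConfig(k=5, seed=1, allele_freq=0.5, freq_mode="true")
        with pytest.raises(ValueError, match="1"):
            sample_missing(ped, cfg=cfg)

    def test_empirical_distribution_matches_conditional(
        self, trio_missing_parents
    ):
        """Draws of the 9 parental genotype pairs follow P(G_m | G_o)."""
        ped = trio_missing_parents
        expected = brute_force_conditional(ped, p=0.5)
        cfg = MCConfig(k=50_000, seed=9, allele_freq=0.5, freq_mode="true")
        draws = sample_missing(ped, cfg=cfg)
        counts: dict[tuple, int] = {}
        for d in draws:
            key = (d["F"].m1_count, d["M"].m1_count)
            counts[key] = counts.get(key, 0) + 1
        keys = [k for k, v in expected.items() if v > 0]
        assert all(k in keys for k in counts)
        obs = np.array([counts.get(k, 0) for k in keys])
        exp = np.array([expected[k] for k in keys]) * cfg.k
        gof = stats.chisquare(obs, exp)
        assert gof.pvalue > 0.001

    def test_chain_rule_fallback_matches_conditional(
        self, trio_missing_parents, monkeypatch
    ):
        monkeypatch.setattr(mc, "ENUM_MISSING_CAP", 1)
        ped = trio_missing_parents
        expected = brute_force_conditional(ped, p=0.5)
        cfg = MCConfig(k=3000, seed=10, allele_freq=0.5, freq_mode="true")
        draws = sample_missing(ped, cfg=cfg)
        counts: dict[tuple, int] = {}
        for d in draws:
            key = (d["F"].m1_count, d["M"].m1_count)
            counts[key] = counts.get(key, 0) + 1
        keys = [k for k, v in expected.items() if v > 0]
        obs = np.array([counts.get(k, 0) for k in keys])
        exp = np.array([expected[k] for k in keys]) * cfg.k
        assert stats.chisquare(obs, exp).pvalue > 0.001

    def test_untyped_connector_respects_both_sides(self):
        """The conditional of a connector reflects typed relatives above
        and below it."""
        ped = Pedigree(
            "1",
            [
                Individual("G", sex=1, genotype=M1M1),
                Individual("S", sex=2, genotype=M2M2),
                Individual("P", "G", "S", sex=1),  # untyped connector
                Individual("Q", sex=2, genotype=M2M2),
                Individual("C", "P", "Q", genotype=M1M2),
            ],
        )
        expected = brute_force_conditional(ped, p=0.5)
        missing, counts, w = enumerate_completions(ped, p=0.5)
        assert missing == ["P"]
        cond = w / w.sum()
        for row, c in zip(counts, cond):
            assert c == pytest.approx(expected[tuple(row)], rel=1e-12)
        # parent of M1M1 x M2M2 must be M1M2 regardless of the child below
        assert cond[1] == pytest.approx(1.0)


class TestMCComponents:
    def test_complete_data_reduction_is_exact(self, trio):
        exact = pedigree_components(trio)
        for k in (1, 7):
            cfg = MCConfig(k=k, seed=3, allele_freq=0.5, freq_mode="true")
            got = mc_components(trio, cfg=cfg)
            assert got == exact

    def test_large_k_converges_to_conditional_expectation(
        self, trio_missing_parents
    ):
        ped = trio_missing_parents
        expected = brute_force_conditional(ped, p=0.5)
        mean_d1 = 0.0
        var_terms = []
        for combo, prob in expected.items():
            if prob == 0.0:
                continue
            completed = ped.with_genotypes(
                {
                    iid: (M2M2, M1M2, M1M1)[g]
                    for iid, g in zip(["F", "M"], combo)
                }
            )
            comp = pedigree_components(completed)
            mean_d1 += prob * comp.d1
            var_terms.append((prob, comp.d1))
        var_d1 = sum(p * (d - mean_d1) ** 2 for p, d in var_terms)
        k = 50_000
        cfg = MCConfig(k=k, seed=4, allele_freq=0.5, freq_mode="true")
        got = mc_components(ped, cfg=cfg)
        assert abs(got.d1 - mean_d1) < 4 * np.sqrt(var_d1 / k) + 1e-12

    def test_mc_average_preserves_score_additivity(self):
        peds = simulated_set(seed=82, per_template=3, incomplete=True)
        cfg = MCConfig(k=25, seed=5, allele_freq=0.25, freq_mode="true")
        checked = 0
        for ped in peds:
            comp = mc_components(ped, cfg=cfg)
            if comp is None:
                continue
            assert comp.d1 + comp.d2 == pytest.approx(comp.s, abs=1e-12)
            checked += 1
        assert checked >= 5


class TestMCTests:
    def test_reduction_on_complete_data(self):
        peds = simulated_set(seed=83, per_template=4)
        cfg = MCConfig(k=13, seed=6, allele_freq=0.25, freq_mode="true")
        assert mcgdti_test(peds, cfg).statistic == gdti_test(peds).statistic
        assert (
            mcgdt_me_test(peds, cfg).statistic == gdt_me_test(peds).statistic
        )

    def test_seed_determinism(self):
        peds = simulated_set(seed=84, per_template=4, incomplete=True)
        cfg = MCConfig(k=20, seed=11, allele_freq=0.25, freq_mode="true")
        r1 = mcgdti_test(peds, cfg)
        r2 = mcgdti_test(peds, cfg)
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value

    def test_large_k_seed_stability(self):
        peds = simulated_set(seed=85, per_template=4, incomplete=True)
        stats_ = []
        for seed in (21, 22):
            cfg = MCConfig(
                k=5000, seed=seed, allele_freq=0.25, freq_mode="true"
            )
            stats_.append(mcgdti_test(peds, cfg).statistic)
        assert stats_[0] == pytest.approx(stats_[1], abs=0.25)

    def test_estimated_frequency_mode_runs(self):
        peds = simulated_set(seed=86, per_template=3, incomplete=True)
        cfg = MCConfig(k=10, seed=12, freq_mode="founders")
        res = mcgdti_test(peds, cfg)
        assert 0.0 <= res.p_value <= 1.0
        assert 0.0 < res.extras["p_hat"] < 1.0


class TestEngineMCPath:
    def test_batch_mc_matches_conditional_expectation(self):
        from gdti import _engine
        from gdti.simulate import TEMPLATES

        peds = simulated_set(seed=87, per_template=1, incomplete=True)
        ped = peds.pedigrees[0]  # two_gen_5 with individual 1 masked
        template = TEMPLATES["two_gen_5"]
        expected = brute_force_conditional(ped, p=0.25)
        mean_d1 = 0.0
        for combo, prob in expected.items():
            if prob == 0.0:
                continue
            completed = ped.with_genotypes(
                {"1": (M2M2, M1M2, M1M1)[combo[0]]}
            )
            mean_d1 += prob * pedigree_components(completed).d1
        ta = _engine.TemplateArrays.from_template(template)
        g = np.array(
            [[0 if m.genotype is None else m.genotype.m1_count for m in ped]],
            dtype=np.int8,
        )
        aff = np.array([[m.affection == 1 for m in ped]])
        rng = np.random.default_rng(3)
        comp, valid = _engine.mc_components_batch(
            g, aff, ta, p=0.25, k=50_000, rng=rng
        )
        assert valid[0]
        assert comp["d1"][0] == pytest.approx(mean_d1, abs=0.02)
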