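"""Segregation-analysis imputation: rules, peeling exactness, calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genepeel.pedigree import Individual, Pedigree
from genepeel.peeling import (
    MISSING,
    MendelianConflictError,
    PeelingOptions,
    PeelingWarning,
    TRANSMISSION,
    estimate_allele_frequency,
    impute_all,
    mendelian_rules_fill,
    peel_all,
    peel_locus,
    transmission_probability,
)
from genepeel.simulate import GenotypeMatrix

from helpers import brute_force_marginals, random_tree_pedigree, sample_single_locus

EXACT = PeelingOptions(tolerance=1e-12, max_rounds=60)


def trio() -> Pedigree:
    return Pedigree([Individual("s"), Individual("d"), Individual("c", "s", "d")])


class TestTransmission:
    @pytest.mark.parametrize(
        "g_off, g_sire, g_dam, expected",
        [
            (0, 0, 0, 1.0),
            (1, 1, 1, 0.5),
            (0, 1, 1, 0.25),
            (2, 1, 1, 0.25),
            (2, 0, 0, 0.0),
            (2, 0, 2, 0.0),
            (1, 2, 0, 1.0),
            (2, 2, 1, 0.5),
        ],
    )
    def test_single_locus_mendelian_table(self, g_off, g_sire, g_dam, expected):
        assert transmission_probability(g_off, g_sire, g_dam) == expected

    def test_distribution_over_offspring_sums_to_one(self):
        assert np.allclose(TRANSMISSION.sum(axis=2), 1.0)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            transmission_probability(3, 0, 0)


class TestAlleleFrequency:
    def test_mean_code_over_two(self):
        obs = GenotypeMatrix(["a", "b", "c"], [[0], [1], [2]])
        f = estimate_allele_frequency(obs, ["a", "b", "c"])
        assert f[0] == pytest.approx(0.5)

    def test_fixed_snp_is_clamped_not_zero(self):
        obs = GenotypeMatrix(["a", "b"], [[0], [0]])
        f = estimate_allele_frequency(obs, ["a", "b"])
        assert 0 < f[0] <= 1.0 / 6.0  # clamp = 1/(2*2+2)

    def test_masked_rows_do_not_affect_frequency(self):
        obs1 = GenotypeMatrix(["a", "b", "x"], [[2], [1], [MISSING]])
        obs2 = GenotypeMatrix(["a", "b", "x"], [[2], [1], [0]])
        ref = ["a", "b"]
        assert estimate_allele_frequency(obs1, ref) == estimate_allele_frequency(
            obs2, ref
        )

    def test_all_missing_snp_raises(self):
        obs = GenotypeMatrix(["a"], [[MISSING]])
        with pytest.raises(ValueError, match="no observed"):
            estimate_allele_frequency(obs, ["a"])


class TestMendelianRules:
    def test_opposite_homozygous_parents_force_heterozygote(self):
        ped = trio()
        obs = GenotypeMatrix(["s", "d", "c"], [[2], [0], [MISSING]])
        filled = mendelian_rules_fill(ped, obs)
        assert filled.row("c")[0] == 1

    def test_single_homozygous_parent_forces_nothing(self):
        ped = trio()
        obs = GenotypeMatrix(["s", "d", "c"], [[2], [1], [MISSING]])
        filled = mendelian_rules_fill(ped, obs)
        assert filled.row("c")[0] == MISSING

    def test_opposite_homozygous_offspring_force_parent_heterozygous(self):
        ped = Pedigree(
            [
                Individual("dam"),
                Individual("s1"),
                Individual("s2"),
                Individual("k1", "s1", "dam"),
                Individual("k2", "s2", "dam"),
            ]
        )
        obs = GenotypeMatrix(
            ["dam", "s1", "s2", "k1", "k2"],
            [[MISSING], [MISSING], [MISSING], [2], [0]],
        )
        filled = mendelian_rules_fill(ped, obs)
        assert filled.row("dam")[0] == 1

    def test_conflict_names_the_trio(self):
        ped = trio()
        obs = GenotypeMatrix(["s", "d", "c"], [[0], [0], [2]])
        with pytest.raises(MendelianConflictError, match="'c'"):
            mendelian_rules_fill(ped, obs)

    def test_chained_deductions_reach_fixpoint(self):
        # grandparents force the dam, which then forces the grandchild
        ped = Pedigree(
            [
                Individual("gs"),
                Individual("gd"),
                Individual("dam", "gs", "gd"),
                Individual("sire"),
                Individual("kid", "sire", "dam"),
            ]
        )
        obs = GenotypeMatrix(
            ["gs", "gd", "dam", "sire", "kid"],
            [[2], [2], [MISSING], [2], [MISSING]],
        )
        filled = mendelian_rules_fill(ped, obs)
        assert filled.row("dam")[0] == 2
        assert filled.row("kid")[0] == 2


class TestPeelLocus:
    @pytest.mark.parametrize("p", [0.1, 0.37, 0.5, 0.8])
    def test_no_information_returns_hardy_weinberg(self, p):
        ped = Pedigree([Individual("x")])
        tri = peel_locus(ped, [MISSING], p, EXACT)
        np.testing.assert_allclose(
            tri[0], [(1 - p) ** 2, 2 * p * (1 - p), p**2], atol=1e-12
        )

    @pytest.mark.parametrize("p", [0.2, 0.5, 0.73])
    def test_homozygous_sire_unknown_dam_dosage_is_one_plus_p(self, p):
        # the sire transmits allele 1 for sure, the dam side follows the
        # population frequency: exact enumeration gives dosage 1 + p
        tri = peel_locus(trio(), [2, MISSING, MISSING], p, EXACT)
        dosage = tri[2, 1] + 2 * tri[2, 2]
        assert dosage == pytest.approx(1 + p, abs=1e-9)

    @pytest.mark.parametrize("gs", [0, 1, 2])
    @pytest.mark.parametrize("gd", [0, 1, 2])
    def test_both_parents_observed_dosage_is_parent_average(self, gs, gd):
        tri = peel_locus(trio(), [gs, gd, MISSING], 0.3, EXACT)
        dosage = tri[2, 1] + 2 * tri[2, 2]
        assert dosage == pytest.approx((gs + gd) / 2, abs=1e-9)

    def test_heterozygous_parents_give_quarter_half_quarter(self):
        tri = peel_locus(trio(), [1, 1, MISSING], 0.5, EXACT)
        np.testing.assert_allclose(tri[2], [0.25, 0.5, 0.25], atol=1e-9)

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            peel_locus(trio(), [MISSING] * 3, 0.0)


class TestPeelingExactness:
    """Iterative peeling equals brute-force enumeration on loop-free pedigrees."""

    def test_matches_enumeration_on_random_pedigrees(self):
        rng = np.random.default_rng(21)
        worst = 0.0
        for _ in range(25):
            n = int(rng.integers(4, 12))
            ped = random_tree_pedigree(rng, n)
            p = float(rng.uniform(0.1, 0.9))
            g = sample_single_locus(rng, ped, p)
            column = np.where(rng.random(n) < 0.5, g, MISSING).astype(np.int8)
            tri = peel_locus(ped, column, p, EXACT)
            oracle = brute_force_marginals(ped, column, p)
            worst = max(worst, float(np.abs(tri - oracle).max()))
            assert np.allclose(tri.sum(axis=1), 1.0, atol=1e-8)
        assert worst < 1e-6

    def test_deduced_genotypes_receive_probability_one(self):
        # peeling on the raw observations must certify every genotype the
        # deterministic rules can force
        rng = np.random.default_rng(33)
        for _ in range(10):
            ped = random_tree_pedigree(rng, 10)
            p = float(rng.uniform(0.2, 0.8))
            g = sample_single_locus(rng, ped, p)
            column = np.where(rng.random(len(ped)) < 0.6, g, MISSING).astype(np.int8)
            obs = GenotypeMatrix(ped.ids, column.reshape(-1, 1))
            filled = mendelian_rules_fill(ped, obs)
            tri = peel_locus(ped, column, p, EXACT)
            for k in range(len(ped)):
                fg = filled.codes[k, 0]
                if fg != MISSING:
                    assert tri[k, fg] == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(
        codes=st.lists(
            st.sampled_from([0, 1, 2, MISSING]), min_size=3, max_size=3
        ),
        p=st.floats(0.05, 0.95),
    )
    def test_trio_triplets_normalize_and_bound_dosage(self, codes, p):
        try:
            tri = peel_locus(trio(), codes, p, EXACT)
        except MendelianConflictError:
            return  # impossible observation sets are rejected, not peeled
        assert np.allclose(tri.sum(axis=1), 1.0, atol=1e-8)
        dosage = tri[:, 1] + 2 * tri[:, 2]
        assert np.all((dosage >= -1e-9) & (dosage <= 2 + 1e-9))


class TestMonotoneInformation:
    def test_genotyped_offspring_reduce_mean_entropy(self):
        # cow with genotyped sire; offspring genotypes are added one by one
        rng = np.random.default_rng(55)
        entropies = {0: [], 1: [], 2: []}
        for _ in range(40):
            p = 0.4
            ped = Pedigree(
                [
                    Individual("sire"),
                    Individual("cow", "sire", "0"),
                    Individual("m0"),
                    Individual("m1"),
                    Individual("k0", "m0", "cow"),
                    Individual("k1", "m1", "cow"),
                ]
            )
            g = sample_single_locus(rng, ped, p)
            for k in (0, 1, 2):
                column = np.full(len(ped), MISSING, dtype=np.int8)
                column[0] = g[0]  # sire observed
                for j in range(k):
                    column[4 + j] = g[4 + j]
                tri = peel_locus(ped, column, p, EXACT)
                cow = np.clip(tri[1], 1e-12, 1.0)
                entropies[k].append(float(-(cow * np.log(cow)).sum()))
        means = [np.mean(entropies[k]) for k in (0, 1, 2)]
        assert means[0] >= means[1] >= means[2]


class TestImputeAll:
    def test_called_genotypes_respect_threshold_and_argmax(self):
        rng = np.random.default_rng(77)
        ped = random_tree_pedigree(rng, 15)
        cols = np.stack(
            [sample_single_locus(rng, ped, 0.5) for _ in range(30)], axis=1
        )
        mask = rng.random(cols.shape) < 0.5
        obs = GenotypeMatrix(ped.ids, np.where(mask, cols, MISSING))
        result = impute_all(ped, obs)
        probs = result.probabilities.probs
        called = result.called.codes
        thr = PeelingOptions().call_threshold
        hard = called != MISSING
        assert np.all(called[hard] == probs.argmax(axis=-1)[hard])
        assert np.all(probs.max(axis=-1)[hard] >= thr - 1e-12)
        assert np.all(probs.max(axis=-1)[~hard] < thr)

    def test_heterozygous_parents_not_called_but_dosage_kept(self):
        ped = trio()
        obs = GenotypeMatrix(["s", "d", "c"], [[1], [1], [MISSING]])
        result = impute_all(ped, obs)
        assert result.called.row("c")[0] == MISSING
        assert result.probabilities.dosage_row("c")[0] == pytest.approx(1.0, abs=1e-6)

    def test_homozygous_parents_called_with_certainty(self):
        ped = trio()
        obs = GenotypeMatrix(["s", "d", "c"], [[2], [2], [MISSING]])
        result = impute_all(ped, obs)
        assert result.called.row("c")[0] == 2
        assert result.probabilities.row("c")[0, 2] == pytest.approx(1.0)

    def test_calls_never_conflict_with_parents(self):
        rng = np.random.default_rng(88)
        ped = random_tree_pedigree(rng, 20)
        cols = np.stack(
            [sample_single_locus(rng, ped, 0.3) for _ in range(40)], axis=1
        )
        mask = rng.random(cols.shape) < 0.6
        obs = GenotypeMatrix(ped.ids, np.where(mask, cols, MISSING))
        result = impute_all(ped, obs)
        called = result.called.codes
        sire, dam = ped.parent_positions()
        for k in range(len(ped)):
            if sire[k] < 0 or dam[k] < 0:
                continue
            trio_codes = called[[sire[k], dam[k], k]]
            for j in range(cols.shape[1]):
                gs, gd, gc = trio_codes[:, j]
                if MISSING in (gs, gd, gc):
                    continue
                assert TRANSMISSION[gs, gd, gc] > 0

    def test_nonconvergence_warns_and_returns_state(self):
        ped = Pedigree(
            [
                Individual("s"),
                Individual("d"),
                Individual("a", "s", "d"),
                Individual("b", "s", "d"),
                Individual("x", "a", "b"),  # inbreeding loop
            ]
        )
        column = np.array([2, MISSING, MISSING, MISSING, 0], dtype=np.int8)
        with pytest.warns(PeelingWarning):
            tri = peel_all(
                ped,
                column.reshape(-1, 1),
                np.array([0.5]),
                PeelingOptions(max_rounds=1),
            )
        assert np.allclose(tri.sum(axis=-1), 1.0, atol=1e-8)
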