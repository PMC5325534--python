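"""Exact-test machinery: frequencies, chi-square, Fisher exact
probability, exact G, Hardy-Weinberg and Fisher's combination."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from bovisnp.model import Breed, GenotypeTable, ValidationError
from bovisnp.popgen import (
    ContingencyTable,
    ExactTestResult,
    McSettings,
    allele_count_table,
    chi_square_differentiation,
    enumerate_tables,
    exact_g_test,
    fisher_exact_probability,
    genotype_allele_frequencies,
    global_fisher_combine,
    hwe_exact_test,
    hwe_heterozygote_distribution,
    marker_is_monomorphic,
    table_probability,
    validate_markers,
)


def gt_table(counts_per_breed, marker="M"):
    """counts_per_breed: {Breed: (n_RR, n_RA, n_AA)}"""
    t = GenotypeTable(marker, "C", "T")
    for breed, (rr, ra, aa) in counts_per_breed.items():
        i = 0
        for g, n in zip(("RR", "RA", "AA"), (rr, ra, aa)):
            for _ in range(n):
                t.calls.append((f"{breed.value}{i}", breed, g))
                i += 1
    return t


class TestFrequencies:
    def test_all_homozygous_reference(self):
        t = gt_table({Breed.POLISH_RED: (10, 0, 0)})
        f = genotype_allele_frequencies(t)[Breed.POLISH_RED]
        assert f["allele_freqs"]["C"] == 1.0
        assert f["allele_freqs"]["T"] == 0.0

    def test_symmetric_counts_give_half(self):
        t = gt_table({Breed.POLISH_RED: (1, 2, 1)})
        f = genotype_allele_frequencies(t)[Breed.POLISH_RED]
        assert f["allele_freqs"]["C"] == 0.5

    def test_random_counts_match_direct_count(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rr, ra, aa = (int(x) for x in rng.integers(0, 15, size=3))
            if rr + ra + aa == 0:
                continue
            t = gt_table({Breed.HEREFORD: (rr, ra, aa)})
            f = genotype_allele_frequencies(t)[Breed.HEREFORD]
            n = rr + ra + aa
            assert f["allele_freqs"]["C"] == pytest.approx(
                (2 * rr + ra) / (2 * n))
            assert sum(f["genotype_freqs"].values()) == pytest.approx(1.0)

    def test_untyped_breed_excluded_with_warning(self):
        t = gt_table({Breed.POLISH_RED: (2, 1, 0)})
        t.calls.append(("h0", Breed.HEREFORD, "--"))
        with pytest.warns(UserWarning, match="no typed animals"):
            f = genotype_allele_frequencies(t)
        assert Breed.HEREFORD not in f

    def test_allele_count_table_doubles_homozygotes(self):
        t = gt_table({Breed.POLISH_RED: (3, 2, 1), Breed.HEREFORD: (1, 0, 4)})
        ct = allele_count_table(t)
        assert ct.counts == ((8, 4), (2, 8))


class TestChiSquare:
    def test_identical_rows_zero_statistic(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), ((10, 5), (10, 5)))
        stat, dof, p = chi_square_differentiation(ct)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_2x2_closed_form(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), ((10, 0), (0, 10)))
        stat, dof, p = chi_square_differentiation(ct)
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_random_3x2_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        counts = tuple(tuple(int(x) for x in rng.integers(1, 30, size=2))
                       for _ in range(3))
        ct = ContingencyTable(("a", "b", "c"), ("x", "y"), counts)
        stat, dof, _ = chi_square_differentiation(ct)
        m = np.array(counts, dtype=float)
        expected = np.outer(m.sum(1), m.sum(0)) / m.sum()
        assert stat == pytest.approx(((m - expected) ** 2 / expected).sum())
        assert dof == 2

    def test_low_expected_counts_warn(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), ((2, 1), (1, 2)))
        with pytest.warns(UserWarning, match="exact"):
            chi_square_differentiation(ct)


class TestEnumerationMachinery:
    def test_null_mass_sums_to_one_exactly(self):
        rs, cs = (7, 5), (6, 4, 2)
        total = sum(rs)
        mass = sum((table_probability(t, rs, cs, total)
                    for t in enumerate_tables(rs, cs)), Fraction(0))
        assert mass == 1

    def test_hwe_distribution_sums_to_one(self):
        dist = hwe_heterozygote_distribution(11, 9)
        assert sum(dist.values()) == 1
        assert set(dist) == {1, 3, 5, 7, 9}


class TestFisherExactProbability:
    def test_balanced_table_p_one(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), ((5, 5), (5, 5)))
        assert fisher_exact_probability(ct).p_value == pytest.approx(1.0)

    def test_zero_margin_p_one(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), ((5, 0), (3, 0)))
        assert fisher_exact_probability(ct).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [
        ((8, 2), (1, 5)), ((3, 7), (6, 2)), ((12, 1), (4, 9)), ((1, 1), (9, 2)),
    ])
    def test_2x2_matches_scipy_two_sided(self, counts):
        ct = ContingencyTable(("a", "b"), ("x", "y"), counts)
        res = fisher_exact_probability(ct)
        _, p_scipy = stats.fisher_exact(np.array(counts))
        assert res.p_value == pytest.approx(p_scipy, abs=1e-12)
        assert res.method == "enumeration"

    def test_label_permutation_invariance(self):
        a = ContingencyTable(("a", "b"), ("x", "y"), ((8, 2), (1, 5)))
        b = ContingencyTable(("a", "b"), ("y", "x"), ((2, 8), (5, 1)))
        assert fisher_exact_probability(a).p_value == \
            pytest.approx(fisher_exact_probability(b).p_value)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(("a",), ("x", "y"), ((3, -1),))


class TestExactG:
    def test_identical_rows_p_one(self):
        ct = ContingencyTable(("a", "b"), ("x", "y", "z"),
                              ((5, 3, 2), (5, 3, 2)))
        assert exact_g_test(ct).p_value == pytest.approx(1.0)

    def test_mc_within_three_se_of_enumeration(self):
        ct = ContingencyTable(("a", "b"), ("x", "y"), ((8, 2), (1, 5)))
        p_enum = exact_g_test(ct).p_value
        mc = McSettings(seed=42, dememorization=1000, batches=20,
                        iterations_per_batch=500)
        res = exact_g_test(ct, mc_settings=mc, enumeration_limit=1)
        assert res.method == "markov_chain"
        assert res.mc_std_error is not None
        assert abs(res.p_value - p_enum) <= 3 * res.mc_std_error + 1e-9

    def test_doubling_counts_never_raises_p(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            counts = tuple(tuple(int(x) for x in rng.integers(1, 6, size=2))
                           for _ in range(2))
            doubled = tuple(tuple(2 * c for c in row) for row in counts)
            p1 = exact_g_test(ContingencyTable(("a", "b"), ("x", "y"),
                                               counts)).p_value
            p2 = exact_g_test(ContingencyTable(("a", "b"), ("x", "y"),
                                               doubled)).p_value
            assert p2 <= p1 + 1e-9


def hwe_brute_force(n_rr, n_ra, n_aa):
    """Independent parity-constrained enumeration of the HWE exact p."""
    n = n_rr + n_ra + n_aa
    n_r, n_a = 2 * n_rr + n_ra, 2 * n_aa + n_ra
    h_max = min(n_r, n_a)
    masses = {}
    for h in range(h_max % 2, h_max + 1, 2):
        rr, aa = (n_r - h) // 2, (n_a - h) // 2
        masses[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(rr) * math.factorial(h) * math.factorial(aa))
    z = sum(masses.values())
    obs = masses[n_ra]
    return float(sum(m for m in masses.values() if m <= obs) / z)


class TestHWE:
    def test_single_genotype_class_p_one(self):
        assert hwe_exact_test(5, 0, 0).p_value == pytest.approx(1.0)

    def test_parity_constrained_brute_force(self):
        res = hwe_exact_test(3, 5, 2)
        assert res.p_value == pytest.approx(hwe_brute_force(3, 5, 2))

    def test_brute_force_sweep(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            rr, ra, aa = (int(x) for x in rng.integers(0, 12, size=3))
            if rr + ra + aa == 0:
                continue
            assert hwe_exact_test(rr, ra, aa).p_value == pytest.approx(
                hwe_brute_force(rr, ra, aa)), (rr, ra, aa)

    def test_all_heterozygote_tail_with_mc(self):
        # all-heterozygote observations sit in the minimal-probability tail;
        # the chain estimate must agree within 3 SE plus its own resolution
        p_enum = hwe_exact_test(0, 30, 0).p_value
        mc = McSettings(seed=5, dememorization=1000, batches=20,
                        iterations_per_batch=500)
        res = hwe_exact_test(0, 30, 0, method="markov_chain", mc_settings=mc)
        resolution = 1 / (mc.batches * mc.iterations_per_batch)
        assert abs(res.p_value - p_enum) <= 3 * res.mc_std_error + resolution

    def test_label_swap_invariance(self):
        # swapping which allele is called reference mirrors the triple
        assert hwe_exact_test(3, 5, 2).p_value == pytest.approx(
            hwe_exact_test(2, 5, 3).p_value)

    def test_mc_requires_settings(self):
        with pytest.raises(ValidationError):
            hwe_exact_test(3, 5, 2, method="markov_chain")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            hwe_exact_test(-1, 2, 3)


class TestGlobalCombination:
    def test_single_p_returned_unchanged(self):
        assert global_fisher_combine([0.37]) == pytest.approx(0.37)

    def test_all_ones_combine_to_one(self):
        assert global_fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_direct_chi_square_survival(self):
        rng = np.random.default_rng(8)
        ps = rng.uniform(0.01, 1, size=5).tolist()
        x = -2 * sum(math.log(p) for p in ps)
        assert global_fisher_combine(ps) == pytest.approx(
            stats.chi2.sf(x, df=10))

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = global_fisher_combine([0.0, 0.5])
        assert 0 < p < 1


class TestResultInvariant:
    def test_mc_std_error_presence_tied_to_method(self):
        with pytest.raises(ValidationError):
            ExactTestResult(p_value=0.5, method="enumeration",
                            statistic=1.0, mc_std_error=0.01)
        with pytest.raises(ValidationError):
            ExactTestResult(p_value=0.5, method="markov_chain", statistic=1.0)


class TestMarkerOrchestration:
    def test_homozygous_markers_excluded(self):
        mono = gt_table({Breed.POLISH_RED: (5, 0, 0),
                         Breed.HEREFORD: (4, 0, 0)}, marker="IGFBP4_like")
        poly = gt_table({Breed.POLISH_RED: (5, 4, 1),
                         Breed.HEREFORD: (1, 3, 6)}, marker="CTNS_like")
        assert marker_is_monomorphic(mono)
        assert not marker_is_monomorphic(poly)
        report = validate_markers([mono, poly], McSettings(seed=1))
        assert report["excluded_monomorphic"] == ["IGFBP4_like"]
        assert set(report["markers"]) == {"CTNS_like"}
        entry = report["markers"]["CTNS_like"]
        assert 0 <= entry["genic_differentiation"].p_value <= 1
        assert 0 <= entry["genotypic_differentiation"].p_value <= 1
        assert set(entry["hwe"]) == {Breed.POLISH_RED, Breed.HEREFORD}
        assert "global" in report
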