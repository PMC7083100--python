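"""Exact conditional HWE test: oracle agreement, worked examples, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetexc import (
    GenotypeCounts,
    InvalidInputError,
    UndefinedRatioError,
    UntestableSiteError,
    conditional_het_distribution,
    expected_het_given_hom,
    het_fold_excess,
    hwe_exact_midp,
    min_detectable_het_af,
)
from conftest import enumerate_het_distribution, enumerate_midp


class TestConditionalDistribution:
    def test_single_minor_allele_is_always_heterozygous(self):
        dist = conditional_het_distribution(n=5, m=1)
        assert list(dist.support) == [1]
        assert dist.probabilities[0] == pytest.approx(1.0)

    def test_probabilities_sum_to_one_and_mode_matches_direct_evaluation(self):
        dist = conditional_het_distribution(n=12482, m=1121)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        # independent mode check: maximise the exact log-likelihood directly
        best, best_ll = None, -math.inf
        for het in dist.support:
            ha = (1121 - het) // 2
            hr = 12482 - het - ha
            ll = (
                -math.lgamma(hr + 1) - math.lgamma(het + 1) - math.lgamma(ha + 1)
                + het * math.log(2.0)
            )
            if ll > best_ll:
                best, best_ll = int(het), ll
        assert dist.mode == best
        assert abs(dist.mode - 1070) <= 2

    def test_matches_brute_force_enumeration(self):
        dist = conditional_het_distribution(n=10, m=6)
        oracle = enumerate_het_distribution(10, 6)
        assert set(int(h) for h in dist.support) == set(oracle)
        for het, p in oracle.items():
            assert dist.pmf(het) == pytest.approx(float(p), abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            conditional_het_distribution(n=10, m=11)  # not the minor allele
        with pytest.raises(InvalidInputError):
            conditional_het_distribution(n=0, m=0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 200))
    def test_distribution_is_a_probability_measure(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 2000))
        m = int(rng.integers(0, n + 1))
        dist = conditional_het_distribution(n, m)
        assert (dist.probabilities >= 0).all()
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


class TestMidP:
    def test_sickle_cell_trait_counts(self):
        """~9% African carriers with only 4 homozygotes: strong excess."""
        r = hwe_exact_midp(GenotypeCounts(11365, 1113, 4))
        assert r.mid_p == pytest.approx(1.38e-07, rel=0.05)
        assert r.direction == "excess"
        assert r.significant

    def test_single_copy_minor_allele(self):
        r = hwe_exact_midp(GenotypeCounts(4, 1, 0))
        assert r.p_two_sided == pytest.approx(1.0)
        assert r.mid_p == pytest.approx(0.5)

    def test_matches_enumeration_on_five_point_support(self):
        r = hwe_exact_midp(GenotypeCounts(2, 4, 2))
        mid, two = enumerate_midp(8, 8, 4)
        assert r.mid_p == pytest.approx(float(mid), abs=1e-12)
        assert r.p_two_sided == pytest.approx(float(two), abs=1e-12)

    def test_monomorphic_site_is_untestable(self):
        with pytest.raises(UntestableSiteError):
            hwe_exact_midp(GenotypeCounts(100, 0, 0))
        with pytest.raises(UntestableSiteError):
            hwe_exact_midp(GenotypeCounts(0, 0, 100))

    def test_direction_classification(self):
        assert hwe_exact_midp(GenotypeCounts(90, 0, 10)).direction == "deficit"
        assert hwe_exact_midp(GenotypeCounts(80, 20, 0)).direction == "excess"
        # n=4, m=4, het=2: expected 2*0.5*0.5*4 = 2 = observed
        assert hwe_exact_midp(GenotypeCounts(1, 2, 1)).direction == "none"

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(1, 10_000))
    def test_midp_strictly_below_two_sided(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5000))
        m = int(rng.integers(1, n + 1))
        het = int(rng.choice(conditional_het_distribution(n, m).support))
        ha = (m - het) // 2
        r = hwe_exact_midp(GenotypeCounts(n - het - ha, het, ha))
        assert r.mid_p < r.p_two_sided
        assert 0.0 < r.mid_p <= r.p_two_sided <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(1, 10_000))
    def test_symmetry_in_hom_ref_and_hom_alt(self, seed):
        rng = np.random.default_rng(seed)
        hr, het, ha = (int(x) for x in rng.integers(0, 50, size=3))
        if hr + het + ha == 0 or min(2 * ha + het, 2 * hr + het) == 0:
            return
        a = hwe_exact_midp(GenotypeCounts(hr, het, ha))
        b = hwe_exact_midp(GenotypeCounts(ha, het, hr))
        assert a.mid_p == pytest.approx(b.mid_p, abs=1e-12)
        assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)

    def test_large_sample_stability(self):
        """Population-scale input must not overflow or underflow."""
        n, m = 5_000_000, 10_000
        dist = conditional_het_distribution(n, m)
        assert np.isfinite(dist.probabilities).all()
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        r = hwe_exact_midp(GenotypeCounts(n - 10_000, 10_000, 0))
        assert np.isfinite(r.mid_p) and 0 < r.mid_p <= 1


class TestExpectedHetGivenHom:
    @pytest.mark.parametrize(
        "n,hom,expected",
        [
            (12482, 4, 438.89),  # the sickle-cell worked example
            (10_000, 0, 0.0),
            (10_000, 100, 1800.0),
        ],
    )
    def test_closed_form(self, n, hom, expected):
        assert expected_het_given_hom(n, hom) == pytest.approx(expected, abs=0.01)

    def test_invalid(self):
        with pytest.raises(InvalidInputError):
            expected_het_given_hom(10, 11)


class TestFoldExcess:
    def test_worked_example(self):
        assert het_fold_excess(1113, expected_het_given_hom(12482, 4)) == pytest.approx(
            2.54, abs=0.01
        )

    def test_identity_and_zero(self):
        assert het_fold_excess(439, 439.0) == 1.0
        assert het_fold_excess(0, 439.0) == 0.0

    def test_sentinels(self):
        assert het_fold_excess(5, 0.0) == math.inf
        with pytest.raises(UndefinedRatioError):
            het_fold_excess(0, 0.0)


class TestMinDetectableAF:
    def test_small_cohort_with_strict_alpha(self):
        """104 individuals, alpha 0.001: detectability needs AF ~0.23."""
        d = min_detectable_het_af(104, alpha=0.001)
        assert d.min_af == pytest.approx(0.23, abs=0.01)
        # bracketing: the count below must not be significant on either lattice
        below = [
            hwe_exact_midp(GenotypeCounts(104 - h, h, 0)).mid_p
            for h in (d.min_het_count - 1, d.min_het_count - 2)
        ]
        assert all(p > 0.001 for p in below)
        at = hwe_exact_midp(GenotypeCounts(104 - d.min_het_count, d.min_het_count, 0))
        assert at.mid_p <= 0.001

    def test_monotone_in_n_and_alpha(self):
        afs = [min_detectable_het_af(n, 0.05).min_af for n in (500, 2000, 10_000, 50_000)]
        assert afs == sorted(afs, reverse=True)
        by_alpha = [min_detectable_het_af(2000, a).min_af for a in (0.001, 0.01, 0.05)]
        assert by_alpha == sorted(by_alpha, reverse=True)

    def test_not_detectable_sentinel(self):
        # 2 individuals can never reach mid-P <= 1e-6
        d = min_detectable_het_af(2, alpha=1e-6)
        assert not d.detectable
        assert d.min_het_count is None
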