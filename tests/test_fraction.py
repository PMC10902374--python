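"""Unit and property tests for the ctDNA-fraction estimation hierarchy."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ctdnatools import (
    DomainError,
    EstimatorConfig,
    GeneCopyNumber,
    GermlineSNP,
    SomaticMutation,
    ValidationError,
    classify_fraction,
    estimate_ctdna_fraction,
    hsaf_based_estimate,
    hsaf_to_fraction,
    major_allele_frequency,
    mutation_based_estimate,
    outlier_corrected_vaf,
    qualitative_fallback_estimate,
    vaf_to_fraction,
)


def make_mutation(alt, ref, chrom="1", lr=0.0, status="somatic_confirmed", gene="G1", pos=100):
    return SomaticMutation(
        sample_id="s", gene=gene, chrom=chrom, pos=pos,
        ref_count=ref, alt_count=alt, vaf=alt / (alt + ref),
        gene_log_ratio=lr, somatic_status=status,
    )


class TestFormulas:
    @pytest.mark.parametrize(
        "vaf,expected",
        [(0.0, 0.0), (1.0, 1.0), (1 / 3, 0.5)],
    )
    def test_vaf_inversion(self, vaf, expected):
        assert vaf_to_fraction(vaf) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "hsaf,expected",
        [(0.5, 0.0), (1.0, 1.0), (2 / 3, 0.5)],
    )
    def test_hsaf_inversion(self, hsaf, expected):
        assert hsaf_to_fraction(hsaf) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("vaf,expected", [(0.5, 0.5), (0.2, 0.8), (0.8, 0.8)])
    def test_major_allele_frequency(self, vaf, expected):
        assert major_allele_frequency(vaf) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0))
    def test_maf_symmetric_about_half(self, v):
        assert major_allele_frequency(v) == pytest.approx(
            major_allele_frequency(1.0 - v), abs=1e-12
        )

    def test_forward_model_round_trip_on_grid(self):
        """Inverting the forward mixture models recovers t to 1e-12."""
        t = np.linspace(0.0, 1.0, 1000)
        for ti in t:
            assert vaf_to_fraction(ti / (2.0 - ti)) == pytest.approx(ti, abs=1e-12)
            assert hsaf_to_fraction(1.0 / (2.0 - ti)) == pytest.approx(ti, abs=1e-12)

    @pytest.mark.parametrize("func,bad", [
        (vaf_to_fraction, -0.1), (vaf_to_fraction, 1.1),
        (hsaf_to_fraction, 0.4), (major_allele_frequency, 2.0),
    ])
    def test_domain_errors(self, func, bad):
        with pytest.raises(DomainError):
            func(bad)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_vaf_to_fraction_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert vaf_to_fraction(lo) <= vaf_to_fraction(hi) + 1e-15


class TestOutlierCorrection:
    def test_zero_alt_gives_zero(self):
        assert outlier_corrected_vaf(0, 100) == 0.0

    def test_all_alt_closed_form(self):
        # P(X = n | n, p) = p^n = 0.05  =>  p = 0.05^(1/n)
        assert outlier_corrected_vaf(100, 100) == pytest.approx(
            0.05 ** (1 / 100), abs=1e-12
        )

    def test_matches_bisection_oracle(self, rng):
        """Independent bisection on the exact binomial survival function."""
        for _ in range(50):
            n = int(rng.integers(1, 5000))
            k = int(rng.integers(1, n + 1))
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                # P(X >= k) = sf(k-1)
                if stats.binom.sf(k - 1, n, mid) < 0.05:
                    lo = mid
                else:
                    hi = mid
            assert outlier_corrected_vaf(k, n) == pytest.approx(
                0.5 * (lo + hi), abs=1e-8
            )

    @given(st.integers(1, 2000))
    def test_conservative_never_exceeds_raw_vaf(self, n):
        for k in {0, 1, n // 2, n}:
            corrected = outlier_corrected_vaf(k, n)
            assert corrected <= k / n + 1e-12
            if k > 0:
                assert corrected < k / n

    @pytest.mark.parametrize("n", [10**2, 10**4, 10**6])
    def test_correction_vanishes_at_large_depth(self, n):
        k = n // 5  # fixed k/n = 0.2
        gap = 0.2 - outlier_corrected_vaf(k, n)
        assert gap > 0
        # gap shrinks like 1/sqrt(n)
        assert gap < 3.0 * np.sqrt(0.2 * 0.8 / n) * 2.0

    def test_invalid_arguments(self):
        with pytest.raises(DomainError):
            outlier_corrected_vaf(5, 4)
        with pytest.raises(DomainError):
            outlier_corrected_vaf(0, 0)


class TestMutationEstimate:
    def test_matches_bruteforce_max_over_closed_forms(self, rng):
        """Overall estimate equals the max over per-mutation closed forms."""
        muts = [
            make_mutation(int(rng.integers(0, 200)), int(rng.integers(1, 400)),
                          gene=f"G{i}", pos=100 + i)
            for i in range(20)
        ]
        expected = max(
            2 * p / (1 + p)
            for m in muts
            for p in [
                0.0 if m.alt_count == 0
                else stats.beta.ppf(0.05, m.alt_count, m.depth - m.alt_count + 1)
            ]
        )
        result = mutation_based_estimate(muts)
        assert result is not None
        assert result[0] == pytest.approx(expected, abs=1e-12)
        assert len(result[1]) == 20

    def test_two_eligible_mutations_max_adopted(self):
        # corrected VAFs are monotone in counts; check overall = max formula
        m1 = make_mutation(100, 900)   # raw VAF 0.10
        m2 = make_mutation(300, 700, pos=200)   # raw VAF 0.30
        frac, per = mutation_based_estimate([m1, m2])
        assert frac == max(e.fraction for e in per)
        assert frac == pytest.approx(
            vaf_to_fraction(outlier_corrected_vaf(300, 1000)), abs=1e-12
        )

    def test_sex_chromosome_mutations_ineligible(self):
        assert mutation_based_estimate([make_mutation(50, 50, chrom="X")]) is None
        assert mutation_based_estimate([make_mutation(50, 50, chrom="chrY")]) is None

    def test_amplified_host_gene_excluded(self):
        assert mutation_based_estimate([make_mutation(50, 50, lr=0.25)]) is None
        assert mutation_based_estimate([make_mutation(50, 50, lr=0.19)]) is not None

    def test_missing_log_ratio_treated_as_eligible_but_flagged(self):
        m = SomaticMutation("s", "G1", "1", 100, 50, 50, 0.5, gene_log_ratio=None)
        result = mutation_based_estimate([m])
        assert result is not None
        assert result[1][0].log_ratio_missing

    def test_excluded_status_ignored(self):
        assert mutation_based_estimate(
            [make_mutation(50, 50, status="excluded")]
        ) is None

    def test_estimate_monotone_under_set_inclusion(self, rng):
        muts = [make_mutation(int(rng.integers(1, 50)), 100, gene=f"G{i}", pos=i + 1)
                for i in range(5)]
        base, _ = mutation_based_estimate(muts)
        bigger, _ = mutation_based_estimate(muts + [make_mutation(80, 20, pos=99)])
        assert bigger >= base


class TestHSAFEstimate:
    def _snps(self, vafs, gene="G", depth=100):
        return [
            GermlineSNP("s", gene, "1", i + 1,
                        depth - int(round(v * depth)), int(round(v * depth)))
            for i, v in enumerate(vafs)
        ]

    def test_hand_computed_example(self):
        # VAFs {0.30,0.32,0.70,0.66} -> MAFs {0.70,0.68,0.70,0.66},
        # median 0.69, fraction 2 - 1/0.69
        snps = self._snps([0.30, 0.32, 0.70, 0.66])
        cn = [GeneCopyNumber("s", "G", -0.5)]
        frac, per = hsaf_based_estimate(snps, cn)
        assert per[0].median_maf == pytest.approx(0.69)
        assert frac == pytest.approx(2 - 1 / 0.69, abs=1e-9)

    def test_gene_with_three_snps_excluded(self):
        snps = self._snps([0.3, 0.3, 0.7])
        assert hsaf_based_estimate(snps, [GeneCopyNumber("s", "G", -0.5)]) is None

    def test_log_ratio_outside_deletion_window_excluded(self):
        snps = self._snps([0.3, 0.3, 0.7, 0.7])
        assert hsaf_based_estimate(snps, [GeneCopyNumber("s", "G", -0.2)]) is None
        assert hsaf_based_estimate(snps, [GeneCopyNumber("s", "G", -0.75)]) is None
        assert hsaf_based_estimate(snps, [GeneCopyNumber("s", "G", -0.7)]) is not None

    def test_maximum_over_eligible_genes(self):
        snps = self._snps([0.3, 0.3, 0.7, 0.7], gene="A") + self._snps(
            [0.4, 0.4, 0.6, 0.6], gene="B"
        )
        cn = [GeneCopyNumber("s", "A", -0.5), GeneCopyNumber("s", "B", -0.5)]
        frac, per = hsaf_based_estimate(snps, cn)
        assert len(per) == 2
        assert frac == max(e.fraction for e in per)


class TestQualitativeFallback:
    def test_mean_deletion_inversion(self):
        cn = [GeneCopyNumber("s", "G", -0.3)]
        assert qualitative_fallback_estimate(cn) == pytest.approx(
            2 - 2**0.7, abs=1e-12
        )

    def test_gain_inversion(self):
        cn = [GeneCopyNumber("s", "G", 0.3)]
        assert qualitative_fallback_estimate(cn) == pytest.approx(
            2**1.3 - 2, abs=1e-12
        )

    def test_ar_excluded_from_gain_class(self):
        cn = [GeneCopyNumber("s", "AR", 0.3, is_ar=True)]
        assert qualitative_fallback_estimate(cn) is None

    def test_no_evidence_absent(self):
        assert qualitative_fallback_estimate([]) is None
        assert qualitative_fallback_estimate(
            [GeneCopyNumber("s", "G", 0.0)]
        ) is None


class TestHierarchy:
    def test_isolated_ar_gain_heuristic(self):
        est = estimate_ctdna_fraction(
            cn=[GeneCopyNumber("s", "AR", 0.8, is_ar=True)]
        )
        assert est.fraction == 0.05
        assert est.tier == "ar_gain"

    def test_no_evidence_undetected(self):
        est = estimate_ctdna_fraction()
        assert est.tier == "undetected"
        assert est.fraction == 0.0
        assert est.category == "undetected"

    def test_mutation_tier_preferred_over_hsaf(self):
        muts = [make_mutation(400, 600)]
        snps = [
            GermlineSNP("s", "G", "2", i + 1, 100 - v, v)
            for i, v in enumerate([30, 32, 70, 66])
        ]
        cn = [GeneCopyNumber("s", "G", -0.5)]
        est = estimate_ctdna_fraction(muts, snps, cn)
        assert est.tier == "mutation"
        assert est.n_eligible_genes == 1
        assert est.concordance_flag is not None

    def test_concordance_flag(self):
        muts = [make_mutation(3333, 6667)]  # corrected VAF ~0.325 -> t ~0.49
        snps = [
            GermlineSNP("s", "G", "2", i + 1, 1000 - v, v)
            for i, v in enumerate([333, 334, 666, 667])  # t ~0.5
        ]
        cn = [GeneCopyNumber("s", "G", -0.5)]
        est = estimate_ctdna_fraction(muts, snps, cn)
        assert est.concordance_flag is True

    def test_subthreshold_mutation_keeps_value_but_undetected_category(self):
        muts = [make_mutation(10, 1990)]  # corrected VAF well below 1%
        est = estimate_ctdna_fraction(muts)
        assert est.tier == "mutation"
        assert 0 < est.fraction < 0.02
        assert est.category == "undetected"

    def test_conflicting_sample_ids_error(self):
        m = make_mutation(10, 90)
        cn = [GeneCopyNumber("other", "G", -0.5)]
        with pytest.raises(ValidationError):
            estimate_ctdna_fraction([m], [], cn)

    def test_qualitative_tier_when_no_mutations_or_snps(self):
        est = estimate_ctdna_fraction(cn=[GeneCopyNumber("s", "G", -0.5)])
        assert est.tier == "qualitative"
        assert est.fraction == pytest.approx(2 - 2**0.5, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "fraction,category",
        [(0.0, "undetected"), (0.01, "undetected"), (0.0199, "undetected"),
         (0.02, "low"), (0.30, "low"), (0.31, "high"), (1.0, "high")],
    )
    def test_category_boundaries(self, fraction, category):
        assert classify_fraction(fraction) == category

    @given(st.floats(0.0, 1.0))
    def test_partition(self, f):
        counts = sum(
            classify_fraction(f) == c for c in ("undetected", "low", "high")
        )
        assert counts == 1

    def test_domain_error(self):
        with pytest.raises(DomainError):
            classify_fraction(1.5)


class TestConfig:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            EstimatorConfig(detect_threshold=0.5, high_threshold=0.3)
        with pytest.raises(ValidationError):
            EstimatorConfig(del_lr_low=-0.3, del_lr_high=-0.7)
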