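"""Hard-filter semantics, exact Hardy–Weinberg test, and the cascade."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from germid import simdata
from germid.snp_filter import (
    FilterThresholds,
    hard_filter_site,
    hwe_exact_test,
    minor_allele_frequency,
    site_filters,
)
from germid.variant_io import MISSING, VariantAnnotations

from conftest import make_matrix


def _annotations(site_dict, n_samples):
    site = pd.DataFrame(site_dict)
    m = len(site)
    return VariantAnnotations(site, np.full((n_samples, m), 99.0),
                              np.full((n_samples, m), 30.0))


PASSING = dict(QD=[25.0], MQ=[60.0], FS=[1.0], SOR=[1.0],
               MQRankSum=[0.0], ReadPosRankSum=[0.0])


class TestHardFilter:
    def test_boundary_values_pass(self):
        # printed rules use strict inequalities: QD = 2.0 exactly passes
        site = dict(PASSING, QD=[2.0], MQ=[40.0], FS=[60.0], SOR=[3.0],
                    MQRankSum=[-12.5], ReadPosRankSum=[-8.0])
        ann = _annotations(site, 2)
        ok, reasons = hard_filter_site(ann, 0)
        assert ok and reasons == []

    def test_single_violation_named(self):
        ann = _annotations(dict(PASSING, FS=[61.0]), 2)
        ok, reasons = hard_filter_site(ann, 0)
        assert not ok and reasons == ["FS"]

    def test_missing_metric_not_evaluable(self):
        ann = _annotations(dict(PASSING, QD=[np.nan]), 2)
        ok, _ = hard_filter_site(ann, 0)
        assert ok


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Independent route: direct conditional probabilities via binomial
    coefficients, P(nAa | allele counts) = C(n, nAA,nAa,naa) 2^nAa / C(2n, na)."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    configs = []
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        aa = (n_a - het) // 2
        AA = n - het - aa
        if AA < 0:
            continue
        weight = (comb(n, AA) * comb(n - AA, het)) * 2**het
        configs.append((het, weight))
    total = sum(w for _, w in configs)
    probs = {h: w / total for h, w in configs}
    p_obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHWE:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_all_heterozygote_matches_enumeration(self):
        assert hwe_exact_test(0, 10, 0) == pytest.approx(
            hwe_enumeration_oracle(0, 10, 0), rel=1e-12
        )

    def test_small_sweep_matches_enumeration(self):
        # exhaustive check for all genotype configurations with n <= 12
        # (full n <= 30 sweep lives in the acceptance suite)
        for n in range(1, 13):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                        hwe_enumeration_oracle(n_AA, n_Aa, n_aa), rel=1e-9
                    ), (n_AA, n_Aa, n_aa)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


def _balanced_panel(n_loci=5, reps=2):
    """Panel in exact HW proportions at p=0.5: (AA, Aa, Aa, aa) blocks."""
    block = np.array([0, 1, 1, 2], dtype=np.int8)
    col = np.tile(block, reps)
    dosages = np.tile(col[:, None], (1, n_loci))
    return make_matrix(dosages)


class TestCascade:
    def test_clean_panel_passes_through(self):
        matrix = _balanced_panel()
        out, report = site_filters(matrix, None)
        assert report.n_output == matrix.n_loci
        assert report.fail_reasons == {}

    def test_maf_boundary_strict(self):
        # MAF exactly 0.05 must be removed (printed rule is "> 0.05")
        n = 20  # 40 alleles; 2 alt alleles -> MAF = 0.05
        col = np.zeros(n, dtype=np.int8)
        col[0] = 1
        col[1] = 1
        dosages = np.column_stack([col, _balanced_panel(1, 5).dosages[:, 0]])
        matrix = make_matrix(dosages)
        assert minor_allele_frequency(col) == pytest.approx(0.05)
        out, report = site_filters(matrix, None)
        assert out.n_loci == 1
        assert "maf" in report.fail_reasons[matrix.loci["id"].iloc[0]]

    def test_planted_failures_counted_per_stage(self, small_panel):
        matrix, _ = small_panel
        ann, planted = simdata.simulate_annotations(
            matrix, 0.1, seed=4, low_gq_rate=0.0
        )
        out, report = site_filters(matrix, ann)
        assert report.removed_per_stage["hard_filter"] == len(planted)
        hard_fail_ids = {matrix.loci["id"].iloc[j] for j in planted}
        reported = {lid for lid, rs in report.fail_reasons.items()
                    if any(r.startswith("hard_filter") for r in rs)}
        assert reported == hard_fail_ids

    def test_gq_masking_then_missingness(self):
        matrix = _balanced_panel(n_loci=2, reps=25)  # 100 samples
        n, m = matrix.dosages.shape
        gq = np.full((n, m), 99.0)
        gq[:5, 0] = 10.0  # 5% of calls at locus 0 get masked -> >1% missing
        ann = VariantAnnotations(
            pd.DataFrame({k: v * m for k, v in PASSING.items()}),
            gq, np.full((n, m), 30.0),
        )
        out, report = site_filters(matrix, ann)
        assert report.removed_per_stage["genotypes_masked_gq"] == 5
        assert report.removed_per_stage["post_mask_missing"] == 1
        assert out.n_loci == 1

    def test_depth_window(self):
        matrix = _balanced_panel(n_loci=3, reps=2)
        n, m = matrix.dosages.shape
        dp = np.full((n, m), 30.0)
        dp[:, 1] = 2.0    # below 3x
        dp[:, 2] = 150.0  # above 100x
        ann = VariantAnnotations(
            pd.DataFrame({k: v * m for k, v in PASSING.items()}),
            np.full((n, m), 99.0), dp,
        )
        out, report = site_filters(matrix, ann)
        assert report.removed_per_stage["mean_depth"] == 2
        assert out.n_loci == 1

    def test_retained_set_invariant_to_orderings(self, small_panel):
        matrix, _ = small_panel
        ann, _ = simdata.simulate_annotations(matrix, 0.1, seed=4)
        base, _ = site_filters(matrix, ann)
        rng = np.random.default_rng(0)
        perm_s = rng.permutation(matrix.n_samples)
        shuffled = matrix.subset_samples(perm_s)
        ann_s = VariantAnnotations(ann.site, ann.gq[perm_s], ann.dp[perm_s])
        out_s, _ = site_filters(shuffled, ann_s)
        assert set(out_s.loci["id"]) == set(base.loci["id"])

    def test_output_satisfies_all_criteria(self, small_panel):
        matrix, _ = small_panel
        ann, _ = simdata.simulate_annotations(matrix, 0.1, seed=4)
        out, _ = site_filters(matrix, ann)
        thr = FilterThresholds()
        kept = matrix.locus_index(out.loci["id"])
        for k, j in enumerate(kept):
            assert hard_filter_site(ann, int(j))[0]
            col = out.dosages[:, k]
            obs = col[col != MISSING]
            assert np.mean(col == MISSING) <= thr.post_mask_missing_max
            assert minor_allele_frequency(col) > thr.maf_min
            counts = [int(np.sum(obs == d)) for d in (0, 1, 2)]
            assert hwe_exact_test(*counts) >= thr.hwe_p_min

    def test_relaxing_threshold_never_shrinks_retained_set(self, small_panel):
        matrix, _ = small_panel
        ann, _ = simdata.simulate_annotations(matrix, 0.1, seed=4)
        strict, _ = site_filters(matrix, ann, FilterThresholds())
        relaxed, _ = site_filters(
            matrix, ann, FilterThresholds(maf_min=0.01, post_mask_missing_max=0.05)
        )
        assert set(strict.loci["id"]) <= set(relaxed.loci["id"])

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(maf_min=0.7).validate()
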