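"""Diversity indices, trait summaries, correlations, PCA, membership scores."""

import math

import numpy as np
import pandas as pd
import pytest

from germid import diversity, simdata
from germid.variant_io import MISSING

from conftest import make_matrix


class TestLocusStats:
    def test_symmetric_biallelic_closed_forms(self):
        matrix = make_matrix([[0], [1], [2], [1]])  # p = 0.5
        s = diversity.locus_stats(matrix, 0)
        assert s.He == pytest.approx(0.5)
        assert s.Ne == pytest.approx(2.0)
        assert s.H_prime == pytest.approx(math.log(2))
        assert s.PIC == pytest.approx(0.375)
        assert s.Nei == s.He
        assert s.Na == 2

    def test_monomorphic_degenerate(self):
        matrix = make_matrix([[0], [0], [0]])
        s = diversity.locus_stats(matrix, 0)
        assert (s.Na, s.Ne) == (1, 1.0)
        assert s.He == s.Ho == s.PIC == s.H_prime == 0.0

    def test_allele_freq_counting_oracle(self, small_panel):
        matrix, _ = small_panel
        rng = np.random.default_rng(1)
        for j in rng.choice(matrix.n_loci, 10, replace=False):
            col = matrix.dosages[:, j]
            obs = col[col != MISSING]
            tally = (np.sum(obs == 1) + 2 * np.sum(obs == 2)) / (2 * obs.size)
            assert diversity.allele_freqs(matrix, int(j))[1] == pytest.approx(tally)

    def test_pic_bounded_by_he_and_maximum(self):
        # max PIC for a biallelic marker is 0.375 at p = 0.5
        grid = np.linspace(0.01, 0.5, 50)
        pics = []
        for p in grid:
            s = diversity._stats_from_freqs(np.array([1 - p, p]), ho=0.0)
            assert s.PIC <= s.He + 1e-12
            assert s.Ne <= s.Na
            pics.append(s.PIC)
        assert max(pics) == pytest.approx(0.375)
        assert np.argmax(pics) == len(grid) - 1

    def test_indices_invariant_to_allele_label_swap(self, small_panel):
        matrix, _ = small_panel
        swapped_dos = matrix.dosages.copy()
        ok = swapped_dos != MISSING
        swapped_dos[ok] = 2 - swapped_dos[ok]
        swapped = make_matrix(swapped_dos)
        for j in (0, 5, 11):
            a = diversity.locus_stats(matrix, j)
            b = diversity.locus_stats(swapped, j)
            for fieldname in ("Na", "Ne", "Ho", "He", "PIC", "H_prime", "Nei"):
                assert getattr(a, fieldname) == pytest.approx(getattr(b, fieldname))

    def test_all_missing_locus_errors(self):
        matrix = make_matrix([[MISSING], [MISSING]])
        with pytest.raises(ValueError):
            diversity.locus_stats(matrix, 0)


class TestGroupDiversity:
    def test_single_group_equals_locus_means(self, clean_panel):
        table = diversity.locus_stats_table(clean_panel)
        report = diversity.group_diversity(
            clean_panel, groups=["all"] * clean_panel.n_samples
        )
        assert report["He"].iloc[0] == pytest.approx(table["He"].mean())
        assert report["PIC"].iloc[0] == pytest.approx(table["PIC"].mean())

    def test_clone_group_degenerate(self):
        row = np.array([0, 1, 2, 1], dtype=np.int8)
        matrix = make_matrix(np.tile(row, (4, 1)))
        report = diversity.group_diversity(matrix, groups=["c"] * 4)
        per_locus = diversity.locus_stats_table(matrix)
        assert set(per_locus["Ho"].unique()) <= {0.0, 1.0}
        assert report["Ho"].iloc[0] == pytest.approx(per_locus["Ho"].mean())

    def test_ranks_high_vs_low_diversity_groups(self):
        rng = np.random.default_rng(7)
        # high-diversity group: p ~ 0.5; low: p ~ 0.05
        high = rng.binomial(2, 0.5, size=(30, 40)).astype(np.int8)
        low = rng.binomial(2, 0.05, size=(30, 40)).astype(np.int8)
        matrix = make_matrix(np.vstack([high, low]),
                             groups=["high"] * 30 + ["low"] * 30)
        report = diversity.group_diversity(matrix).set_index("group")
        for col in ("He", "PIC", "H_prime"):
            assert report.loc["high", col] > report.loc["low", col]

    def test_singleton_group_skipped_with_warning(self, clean_panel):
        groups = ["a"] * (clean_panel.n_samples - 1) + ["solo"]
        with pytest.warns(UserWarning, match="solo"):
            report = diversity.group_diversity(clean_panel, groups=groups)
        assert list(report["group"]) == ["a"]

    def test_he_ho_gap_recovers_inbreeding_coefficient(self):
        # genotypes drawn with P(het) = 2pq(1-F): mean(1 - Ho/He) estimates F
        f_true = 0.3
        rng = np.random.default_rng(21)
        estimates = []
        for rep in range(20):
            p = rng.uniform(0.2, 0.5, 80)
            het = 2 * p * (1 - p) * (1 - f_true)
            hom_alt = p**2 + f_true * p * (1 - p)
            u = rng.random((60, 80))
            dos = np.where(u < het, 1, np.where(u < het + hom_alt, 2, 0)).astype(np.int8)
            table = diversity.locus_stats_table(make_matrix(dos))
            estimates.append(1 - table["Ho"].sum() / table["He"].sum())
        est, se = np.mean(estimates), np.std(estimates, ddof=1) / np.sqrt(20)
        assert abs(est - f_true) < 2 * se + 0.02


class TestTraitSummary:
    def test_constant_trait_all_zero(self):
        # a trait fixed at code 3 across the panel: SD = CV = H' = 0
        traits = pd.DataFrame({"leafcolor": [3] * 297})
        s = diversity.trait_summary(traits, "leafcolor")
        assert (s.maximum, s.minimum, s.mean) == (3, 3, 3)
        assert s.sd == 0 and s.cv == 0 and s.H_prime == 0

    def test_two_point_distribution(self):
        traits = pd.DataFrame({"t": [1, 3, 1, 3]})
        s = diversity.trait_summary(traits, "t")
        assert s.mean == 2 and s.sd == 1 and s.cv == pytest.approx(50.0)

    @pytest.mark.parametrize("k", range(2, 7))
    def test_uniform_classes_entropy_ln_k(self, k):
        traits = pd.DataFrame({"t": list(range(1, k + 1)) * 6})
        s = diversity.trait_summary(traits, "t")
        assert s.H_prime == pytest.approx(math.log(k))

    def test_continuous_binning_used_for_entropy(self):
        rng = np.random.default_rng(0)
        traits = pd.DataFrame({"t": rng.normal(10, 2, 500)})
        s = diversity.trait_summary(traits, "t", continuous=True, n_bins=10)
        assert 0 < s.H_prime <= math.log(10) + 1e-9


class TestCorrelationsAndPca:
    def test_self_and_negation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        traits = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=30)})
        corr = diversity.trait_correlations(traits)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_longhand_formula(self):
        rng = np.random.default_rng(4)
        traits = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("xyz"))
        corr = diversity.trait_correlations(traits)
        x, y = traits["x"].to_numpy(), traits["y"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert corr.loc["x", "y"] == pytest.approx(r, abs=1e-12)

    def test_rank_one_explains_everything(self):
        x = np.arange(10, dtype=float)
        traits = pd.DataFrame({"a": x, "b": 3 * x + 1})
        _, _, explained = diversity.pheno_pca(traits)
        assert explained[0] == pytest.approx(100.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(5)
        traits = pd.DataFrame(rng.normal(size=(20, 4)))
        scores, loadings, explained = diversity.pheno_pca(traits)
        z = (traits - traits.mean()) / traits.std(ddof=0)
        np.testing.assert_allclose(scores @ loadings.T, z.to_numpy(), atol=1e-9)
        assert explained.sum() == pytest.approx(100.0)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            diversity.pheno_pca(pd.DataFrame({"a": [1, 1, 1]}))


class TestMembership:
    def test_extremes_and_midpoint(self):
        traits = pd.DataFrame({"a": [0, 5, 10], "b": [2, 5, 8]})
        d = diversity.membership_D(traits)
        assert d.iloc[0] == pytest.approx(0.0)
        assert d.iloc[2] == pytest.approx(1.0)
        assert d.iloc[1] == pytest.approx(0.5)

    def test_smaller_better_reverses(self):
        traits = pd.DataFrame({"a": [0.0, 10.0]})
        d = diversity.membership_D(traits, directions={"a": "smaller-better"})
        assert list(d) == [1.0, 0.0]

    def test_constant_trait_with_weight_errors(self):
        traits = pd.DataFrame({"a": [1, 1], "b": [0, 1]})
        with pytest.raises(ValueError, match="constant"):
            diversity.membership_D(traits, weights={"a": 0.5, "b": 0.5})
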