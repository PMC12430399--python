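"""Genotype PCA, UPGMA dendrograms, LD scan/decay, and Evanno ΔK."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from germid import popstruct, simdata

from conftest import make_matrix


class TestGenoPca:
    def test_two_clusters_rank_one(self):
        dos = np.array([[0, 0, 0, 0]] * 5 + [[2, 2, 2, 2]] * 5, dtype=np.int8)
        res = popstruct.geno_pca(make_matrix(dos), n_components=3)
        assert res.explained[0] == pytest.approx(100.0)
        assert np.sign(res.scores[0, 0]) != np.sign(res.scores[-1, 0])

    def test_duplicated_locus_columns_share_loadings(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 20).astype(np.int8)
        dos = np.column_stack([col, col, rng.integers(0, 3, 20)]).astype(np.int8)
        res = popstruct.geno_pca(make_matrix(dos), n_components=2)
        np.testing.assert_allclose(res.loadings[0], res.loadings[1], atol=1e-9)

    def test_full_rank_explained_sums_to_100_and_scores_uncorrelated(self, clean_panel):
        res = popstruct.geno_pca(clean_panel, n_components=clean_panel.n_samples - 1)
        assert res.explained.sum() == pytest.approx(100.0)
        cov = np.cov(res.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8 * max(1.0, np.max(np.diag(cov)))

    def test_monomorphic_panel_errors(self):
        with pytest.raises(ValueError):
            popstruct.geno_pca(make_matrix(np.ones((4, 3), dtype=np.int8)))


class TestUpgma:
    def test_two_samples_root_height(self):
        dos = np.array([[0, 0], [2, 2]], dtype=np.int8)
        newick = popstruct.distance_upgma(make_matrix(dos))
        d = np.sqrt(8.0)
        assert f":{d/2:.6g}" in newick
        assert newick.endswith(";")

    def test_forced_merge_order(self):
        # distances: d(1,2)=2, d(1,3)=d(2,3) large -> 1,2 merge first
        dos = np.array([[0, 0], [2, 0], [2, 2]], dtype=np.int8)
        merges = popstruct.upgma_linkage(
            squareform(pdist(dos.astype(float)))
        )
        assert {int(merges[0, 0]), int(merges[0, 1])} == {0, 1}

    def test_matches_scipy_average_linkage_heights(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 5))
        d = pdist(x)
        ours = popstruct.upgma_linkage(d)
        theirs = linkage(d, method="average")
        np.testing.assert_allclose(np.sort(ours[:, 2]), np.sort(theirs[:, 2]),
                                   rtol=1e-9)

    def test_cophenetic_ultrametricity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 4))
        merges = popstruct.upgma_linkage(pdist(x))
        coph = squareform(cophenet(merges))
        n = coph.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(n):
                    if k in (i, j):
                        continue
                    assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-9

    def test_duplicate_ids_rejected(self):
        matrix = make_matrix([[0, 1], [1, 2]], sample_ids=["X", "X"])
        with pytest.raises(ValueError, match="duplicate"):
            popstruct.distance_upgma(matrix)

    def test_topology_invariant_to_input_order(self):
        rng = np.random.default_rng(8)
        dos = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        matrix = make_matrix(dos)
        newick_a = popstruct.distance_upgma(matrix)
        perm = rng.permutation(8)
        newick_b = popstruct.distance_upgma(matrix.subset_samples(perm))
        # same leaf partition at the root regardless of sample order
        import re

        def leaves(s):
            return set(re.findall(r"S\d+", s))

        assert leaves(newick_a) == leaves(newick_b)
        coph_a = squareform(cophenet(popstruct.upgma_linkage(
            pdist(matrix.dosages.astype(float)))))
        dos_b = matrix.dosages[perm].astype(float)
        coph_b = squareform(cophenet(popstruct.upgma_linkage(pdist(dos_b))))
        inv = np.argsort(perm)
        np.testing.assert_allclose(coph_a, coph_b[np.ix_(inv, inv)], rtol=1e-9)


class TestLd:
    def test_duplicate_locus_r2_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 40).astype(np.int8)
        matrix = make_matrix(np.column_stack([col, col]), positions=[100, 500])
        pairs = popstruct.ld_scan(matrix)
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)
        assert pairs["distance"].iloc[0] == 400

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, 40).astype(np.int8)
        matrix = make_matrix(np.column_stack([col, 2 - col]))
        pairs = popstruct.ld_scan(matrix)
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_null_mean_r2_close_to_one_over_n(self):
        # independent loci: E[r^2] ~ 1/n; light version (acceptance suite
        # runs the full Monte-Carlo check)
        n, reps = 200, 120
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(reps):
            a = rng.binomial(2, 0.3, n).astype(float)
            b = rng.binomial(2, 0.3, n).astype(float)
            r = np.corrcoef(a, b)[0, 1]
            vals.append(r * r)
        se = np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(vals) - 1 / n) < 3 * se

    def test_decay_aggregation_and_bounds(self):
        pairs = pd.DataFrame({"locus_a": "a", "locus_b": "b",
                              "distance": [10, 20, 3000], "r2": [0.9, 0.5, 0.1]})
        curve = popstruct.ld_decay(pairs, bin_width=1000)
        assert len(curve) == 2
        assert curve["mean_r2"].iloc[0] == pytest.approx(0.7)
        assert curve["n_pairs"].tolist() == [2, 1]
        single = popstruct.ld_decay(pairs, bin_width=10_000)
        assert len(single) == 1
        assert single["mean_r2"].iloc[0] == pytest.approx(pairs["r2"].mean())

    def test_block_structure_gives_higher_within_block_ld(self):
        rng = np.random.default_rng(9)
        block1 = rng.integers(0, 3, 50).astype(np.int8)
        block2 = rng.integers(0, 3, 50).astype(np.int8)
        dos = np.column_stack([block1, block1, block2, block2])
        matrix = make_matrix(dos, positions=[100, 200, 10_100, 10_200])
        pairs = popstruct.ld_scan(matrix)
        curve = popstruct.ld_decay(pairs, bin_width=1000)
        assert curve["mean_r2"].iloc[0] > curve["mean_r2"].iloc[-1]

    def test_nonpositive_bin_width(self):
        with pytest.raises(ValueError):
            popstruct.ld_decay(pd.DataFrame({"distance": [1], "r2": [0.5]}), 0)


class TestEvanno:
    def test_hand_arithmetic_example(self):
        # mean L = (-100, -50, -45, -44), replicate sd 1 at each K:
        # ΔK(2) = |-45 - 2(-50) + (-100)| / 1 = 45 and is maximal
        means = np.array([-100.0, -50.0, -45.0, -44.0])
        # two replicates at m +/- sqrt(1/2) have sample sd exactly 1
        reps = np.column_stack([means - np.sqrt(0.5), means + np.sqrt(0.5)])
        table = popstruct.evanno_delta_k(pd.DataFrame(reps, index=[1, 2, 3, 4]))
        assert table.loc[2, "delta_K"] == pytest.approx(45.0)
        assert table.attrs["best_k"] == 2

    def test_linear_loglik_no_peak(self):
        means = np.array([-30.0, -20.0, -10.0, 0.0])
        reps = np.column_stack([means - np.sqrt(0.5), means + np.sqrt(0.5)])
        table = popstruct.evanno_delta_k(pd.DataFrame(reps, index=[1, 2, 3, 4]))
        np.testing.assert_allclose(table["L_doubleprime_abs"].dropna(), 0.0,
                                   atol=1e-9)
        assert table.attrs["best_k"] is None

    def test_replicate_permutation_invariance(self):
        rng = np.random.default_rng(4)
        data = rng.normal(-100, 5, size=(5, 6))
        df = pd.DataFrame(data, index=range(1, 6))
        base = popstruct.evanno_delta_k(df)
        shuffled = df.copy()
        for k in shuffled.index:
            shuffled.loc[k] = rng.permutation(shuffled.loc[k].to_numpy())
        again = popstruct.evanno_delta_k(shuffled)
        pd.testing.assert_frame_equal(base, again)

    def test_non_consecutive_grid_rejected(self):
        df = pd.DataFrame(np.zeros((3, 2)), index=[1, 3, 5])
        with pytest.raises(ValueError, match="consecutive"):
            popstruct.evanno_delta_k(df)
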