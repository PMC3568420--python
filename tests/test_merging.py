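"""Behaviour of the six merging methods and the pairwise fold."""

import numpy as np
import pandas as pd
import pytest

from xmerge import (
    MergeRequest,
    XmergeError,
    combine_pairwise,
    derive_seed,
    intersect_genes,
    merge,
    merge_bmc,
    merge_combat,
    merge_dwd,
    merge_genenorm,
    merge_xpn,
    simulate_studies,
)

from conftest import duplicate_study, make_study


class TestDispatcher:
    def test_none_is_column_concatenation(self, fixture_pair):
        a, b = fixture_pair
        merged = merge([a, b], "NONE")
        assert merged.n_samples == a.n_samples + b.n_samples
        np.testing.assert_array_equal(
            merged.values[a.samples].to_numpy(), a.values.loc[merged.genes].to_numpy()
        )
        assert merged.batches.tolist() == ["FIXA"] * 3 + ["FIXB"] * 2

    def test_unknown_method_lists_valid_names(self, fixture_pair):
        with pytest.raises(XmergeError, match="FOO.*NONE"):
            merge(list(fixture_pair), "FOO")

    def test_single_study_rejected(self, fixture_pair):
        with pytest.raises(XmergeError, match="two studies"):
            merge([fixture_pair[0]], "NONE")

    def test_merge_request_equivalent_to_kwargs(self, fixture_pair):
        req = MergeRequest(studies=list(fixture_pair), method="BMC")
        np.testing.assert_array_equal(
            merge(req).matrix, merge(list(fixture_pair), "BMC").matrix
        )

    def test_all_methods_share_output_contract(self, fixture_pair):
        a, b = fixture_pair
        for method in ("NONE", "BMC", "GENENORM"):
            merged = merge([a, b], method)
            assert merged.genes == sorted(set(a.genes) & set(b.genes))
            assert merged.samples == a.samples + b.samples
            assert np.isfinite(merged.matrix).all()
            assert merged.provenance["method"] == method


class TestBMC:
    def test_hand_computed_centering(self):
        a = make_study("A", [[1.0, 2.0, 3.0]])
        b = make_study("B", [[4.0, 6.0]], sample_prefix="T")
        merged = merge_bmc(intersect_genes([a, b]))
        np.testing.assert_allclose(merged.matrix[0], [-1, 0, 1, -1, 1])

    def test_constant_gene_becomes_zero(self):
        a = make_study("A", [[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        b = make_study("B", [[2.0, 2.0], [0.0, 4.0]], sample_prefix="T")
        merged = merge_bmc(intersect_genes([a, b]))
        np.testing.assert_array_equal(merged.matrix[0], np.zeros(5))

    def test_per_gene_per_batch_mean_zero_brute_force(self):
        rng = np.random.default_rng(77)
        a = make_study("A", rng.normal(7, 2, (100, 20)))
        b = make_study("B", rng.normal(5, 3, (100, 30)), sample_prefix="T")
        merged = merge_bmc(intersect_genes([a, b]))
        batches = merged.batches.to_numpy()
        for batch in ("A", "B"):
            block = merged.matrix[:, batches == batch]
            for row in block:                     # brute-force loop per gene
                assert abs(row.mean()) < 1e-12


class TestGenenorm:
    def test_hand_computed_zscore(self):
        a = make_study("A", [[1.0, 2.0, 3.0]])
        b = make_study("B", [[10.0, 30.0]], sample_prefix="T")
        merged = merge_genenorm(intersect_genes([a, b]))
        # sd of (1,2,3) is 1 -> z-scores (-1, 0, 1)
        np.testing.assert_allclose(merged.matrix[0, :3], [-1, 0, 1])

    def test_zero_variance_gene_centered_and_flagged(self):
        a = make_study("A", [[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        b = make_study("B", [[1.0, 2.0], [0.0, 4.0]], sample_prefix="T")
        merged = merge_genenorm(intersect_genes([a, b]))
        np.testing.assert_array_equal(merged.matrix[0, :3], np.zeros(3))
        assert merged.provenance["zero_variance_genes"] == {"A": ["G001"]}

    def test_single_sample_batch_rejected(self):
        a = make_study("A", [[1.0, 2.0]])
        b = make_study("B", [[1.0]], sample_prefix="T")
        with pytest.raises(XmergeError, match="standard deviation"):
            merge_genenorm(intersect_genes([a, b]))

    def test_mean_zero_sd_one_brute_force(self):
        rng = np.random.default_rng(78)
        a = make_study("A", rng.normal(7, 2, (100, 20)))
        b = make_study("B", rng.normal(5, 3, (100, 30)), sample_prefix="T")
        merged = merge_genenorm(intersect_genes([a, b]))
        batches = merged.batches.to_numpy()
        for batch in ("A", "B"):
            block = merged.matrix[:, batches == batch]
            for row in block:
                assert abs(row.mean()) < 1e-9
                assert abs(row.std(ddof=1) - 1.0) < 1e-9


class TestCombat:
    def test_single_batch_rejected(self, fixture_pair):
        with pytest.raises(XmergeError):
            merge_combat([fixture_pair[0]])

    def test_shrinkage_toward_prior_without_batch_effect(self):
        studies, _ = simulate_studies(
            n_genes=500, samples_per_study=(50, 50),
            additive_batch_sd=0.0, multiplicative_batch_shape=0.0, seed=5,
        )
        _, model = merge_combat(intersect_genes(studies))
        assert np.abs(model.gamma_star).mean() < np.abs(model.gamma_hat).mean()

    def test_gamma_star_is_convex_combination(self):
        studies, _ = simulate_studies(n_genes=300, samples_per_study=(20, 25), seed=6)
        _, model = merge_combat(intersect_genes(studies))
        assert model.shrinkage_holds()
        assert (model.delta2_star > 0).all()

    def test_shrinkage_vanishes_with_sample_size(self):
        # |gamma* - gamma_hat| decreases stochastically as batches grow
        gaps = []
        for n in (5, 500):
            studies, _ = simulate_studies(
                n_genes=200, samples_per_study=(n, n), additive_batch_sd=1.0, seed=8,
            )
            _, model = merge_combat(intersect_genes(studies))
            gaps.append(np.abs(model.gamma_star - model.gamma_hat).mean())
        assert gaps[1] < gaps[0]

    def test_additive_shift_recovery(self):
        # per-batch shifts gamma_g ~ N(0, 2^2); the identifiable quantity is
        # the deviation from the sample-size-weighted mean shift
        studies, truth = simulate_studies(
            n_genes=1000, samples_per_study=(50, 50), additive_batch_sd=2.0, seed=13,
        )
        _, model = merge_combat(intersect_genes(studies))
        g1 = truth["gamma"]["STUDY1"].loc[model.genes].to_numpy()
        g2 = truth["gamma"]["STUDY2"].loc[model.genes].to_numpy()
        contrast = g1 - 0.5 * (g1 + g2)
        r = np.corrcoef(model.gamma_star[0], contrast)[0, 1]
        assert r > 0.9

    def test_agrees_with_independent_eb_implementation(self):
        # cross-check against scanpy's empirical-Bayes batch correction,
        # an independent implementation of the same location/scale model
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import anndata as ad
            import scanpy as sc

        studies, _ = simulate_studies(n_genes=100, samples_per_study=(15, 20), seed=21)
        aligned = intersect_genes(studies)
        merged, _ = merge_combat(aligned)
        X = np.hstack([s.matrix for s in aligned])
        obs = pd.DataFrame({"batch": ["A"] * 15 + ["B"] * 20}, index=merged.samples)
        adata = ad.AnnData(X.T.copy(), obs=obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.combat(adata, key="batch")
        assert np.abs(adata.X.T - merged.matrix).max() < 5e-3

    def test_covariate_confounded_design_rejected(self):
        a = make_study("A", np.arange(8, dtype=float).reshape(2, 4))
        b = make_study("B", np.arange(8, 16, dtype=float).reshape(2, 4), sample_prefix="T")
        a.annotations["Group"] = ["x"] * 4
        b.annotations["Group"] = ["y"] * 4
        with pytest.raises(Exception, match="confounded"):
            merge_combat(intersect_genes([a, b]), covariate_key="Group")

    def test_covariate_effect_preserved(self):
        studies, truth = simulate_studies(n_genes=100, samples_per_study=(30, 30), seed=3)
        merged, model = merge_combat(intersect_genes(studies), covariate_key="Disease")
        assert model.converged
        de = truth["de_genes"][0]
        labels = merged.annotation_column("Disease").to_numpy()
        diff = (merged.values.loc[de][labels == "case"].mean()
                - merged.values.loc[de][labels == "control"].mean())
        assert diff == pytest.approx(truth["config"]["de_effect"], abs=0.5)


class TestDWD:
    def _shifted_pair(self, c=3.0, m=120, n=25, seed=0):
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, 0.5, (m, n))
        noise -= noise.mean(axis=0, keepdims=True)   # scatter orthogonal to the shift
        base = rng.normal(7, 2, (m, 1)) + noise
        a = make_study("A", base)
        b = make_study("B", base + c, sample_prefix="T")
        return a, b

    def test_pure_mean_shift_equalizes_batch_means(self):
        a, b = self._shifted_pair()
        merged = merge_dwd(intersect_genes([a, b]))
        batches = merged.batches.to_numpy()
        mu_a = merged.matrix[:, batches == "A"].mean(axis=1)
        mu_b = merged.matrix[:, batches == "B"].mean(axis=1)
        assert np.max(np.abs(mu_a - mu_b)) < 1e-6

    def test_batch_mean_deviation_projection_zero(self):
        studies, _ = simulate_studies(n_genes=150, samples_per_study=(15, 20), seed=4)
        aligned = intersect_genes(studies)
        from xmerge.merging import _dwd_direction

        w, _ = _dwd_direction(aligned[0].matrix, aligned[1].matrix)
        merged = merge_dwd(aligned)
        batches = merged.batches.to_numpy()
        grand = merged.matrix.mean(axis=1)
        for batch in np.unique(batches):
            dev = merged.matrix[:, batches == batch].mean(axis=1) - grand
            assert abs(dev @ w) < 1e-8

    def test_identical_batches_untouched(self, fixture_pair):
        a, _ = fixture_pair
        b = duplicate_study(a)
        merged = merge_dwd(intersect_genes([a, b]))
        assert np.max(np.abs(merged.matrix[:, :3] - a.values.loc[merged.genes].to_numpy())) < 1e-6

    def test_three_studies_rejected_directly(self):
        studies, _ = simulate_studies(n_genes=20, samples_per_study=(5, 5, 5), seed=1)
        with pytest.raises(XmergeError, match="pairwise"):
            merge_dwd(intersect_genes(studies))


class TestXPN:
    def test_seeded_determinism_bit_identical(self):
        studies, _ = simulate_studies(n_genes=60, samples_per_study=(12, 10), seed=2)
        m1 = merge(studies, "XPN", seed=9, n_repetitions=3)
        m2 = merge(studies, "XPN", seed=9, n_repetitions=3)
        np.testing.assert_array_equal(m1.matrix, m2.matrix)

    def test_duplicated_studies_near_identity(self):
        studies, _ = simulate_studies(n_genes=80, samples_per_study=(15,), seed=3)
        a = studies[0]
        b = duplicate_study(a)
        merged = merge(studies=[a, b], method="XPN", seed=1, n_repetitions=2)
        expected = a.values.loc[merged.genes].to_numpy()
        assert np.max(np.abs(merged.matrix[:, :15] - expected)) < 1e-6
        assert np.max(np.abs(merged.matrix[:, 15:] - expected)) < 1e-6

    def test_explicit_excess_cluster_counts_rejected(self):
        studies, _ = simulate_studies(n_genes=10, samples_per_study=(4, 4), seed=0)
        aligned = intersect_genes(studies)
        with pytest.raises(XmergeError, match="n_gene_clusters"):
            merge_xpn(aligned, n_gene_clusters=50)
        with pytest.raises(XmergeError, match="n_sample_clusters"):
            merge_xpn(aligned, n_sample_clusters=10)

    def test_repetition_averaging_reduces_run_variance(self):
        studies, _ = simulate_studies(n_genes=60, samples_per_study=(12, 12), seed=6)
        aligned = intersect_genes(studies)

        def run_spread(n_rep):
            outs = [merge_xpn(aligned, n_repetitions=n_rep, seed=s).matrix
                    for s in range(4)]
            return np.var(np.stack(outs), axis=0).mean()

        assert run_spread(8) < run_spread(1)


class TestCombinePairwise:
    def test_base_case_equals_direct_call(self):
        studies, _ = simulate_studies(n_genes=40, samples_per_study=(8, 9), seed=1)
        aligned = intersect_genes(studies)
        folded = combine_pairwise(aligned, "XPN", {"seed": 3, "n_repetitions": 2})
        direct = merge_xpn(aligned, seed=3, n_repetitions=2)
        np.testing.assert_array_equal(folded.matrix, direct.matrix)

    def test_three_studies_equal_explicit_fold(self):
        studies, _ = simulate_studies(n_genes=40, samples_per_study=(8, 9, 7), seed=2)
        aligned = intersect_genes(studies)
        folded = merge(studies, "XPN", seed=5, n_repetitions=2)
        step0 = merge_xpn(aligned[:2], seed=5, n_repetitions=2)
        manual = merge_xpn([step0, aligned[2]], seed=derive_seed(5, 1), n_repetitions=2)
        np.testing.assert_array_equal(folded.matrix, manual.matrix)

    def test_four_studies_bookkeeping(self):
        studies, _ = simulate_studies(n_genes=30, samples_per_study=(6, 7, 8, 5), seed=3)
        merged = combine_pairwise(studies, "DWD")
        assert merged.n_samples == 26
        for s in studies:
            labels = merged.batches.loc[s.samples]
            assert (labels == s.study_id).all()

    def test_pair_errors_identify_failing_pair(self):
        studies, _ = simulate_studies(n_genes=30, samples_per_study=(6, 6, 1), seed=3)
        with pytest.raises(XmergeError, match="STUDY3"):
            combine_pairwise(studies, "DWD")
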