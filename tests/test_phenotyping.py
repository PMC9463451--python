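"""HCPC phenotyping: PCA, clustering, axis naming, projection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from timescope import PhenotypeModel, fit_phenotype_model, generate_feature_table
from timescope.synthetic import BCC_LIKE_CLUSTERS, CANONICAL_FEATURES


def make_table(values, features=CANONICAL_FEATURES):
    return pd.DataFrame(np.asarray(values), columns=list(features))


class TestValidation:
    def test_zero_variance_feature_named(self):
        table, _ = generate_feature_table(
            12, [((1, 2, 3, 0, 1, 2), 12, 0.5)], noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="number_of_vessels"):
            PhenotypeModel(table).fit()

    def test_too_few_samples(self):
        table = make_table([[0, 1, 2, 3, 0, 1]] * 3)
        with pytest.raises(ValueError, match="4"):
            PhenotypeModel(table)

    def test_non_integer_grades_rejected(self):
        table = make_table(np.full((6, 6), 1.5))
        with pytest.raises(ValueError, match="integer"):
            PhenotypeModel(table)


class TestPCA:
    def test_rank_two_data_needs_two_components(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 20)
        b = rng.integers(0, 4, 20)
        table = make_table(np.column_stack([a, a, a, b, b, b]))
        res = PhenotypeModel(table).fit()
        assert res.n_retained == 2
        assert res.explained_variance_ratio[:2].sum() == pytest.approx(1.0)

    def test_loadings_orthonormal_eigenvalues_sorted(self, bcc_table):
        table, _ = bcc_table
        res = fit_phenotype_model(table)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_reconstruction_error_bounded_by_discarded_mass(self, bcc_table):
        table, _ = bcc_table
        res = fit_phenotype_model(table)
        x = res.model.grades.to_numpy()
        z = (x - res.feature_means) / res.feature_sds
        recon = res.scores @ res.loadings[:, :res.n_retained].T
        mse = ((z - recon) ** 2).sum() / len(z)
        discarded = res.eigenvalues[res.n_retained:].sum()
        assert mse == pytest.approx(discarded, rel=1e-8, abs=1e-10)

    def test_contributions_sum_to_100(self, bcc_table):
        table, _ = bcc_table
        res = fit_phenotype_model(table)
        for c in range(1, res.n_retained + 1):
            assert res.variable_contributions(c).sum() == pytest.approx(100.0)

    def test_invalid_component_rejected(self, bcc_table):
        table, _ = bcc_table
        res = fit_phenotype_model(table)
        with pytest.raises(ValueError):
            res.variable_contributions(res.n_retained + 1)

    def test_dominant_feature_dominates_pc1(self):
        rng = np.random.default_rng(1)
        strong = np.repeat([0, 3], 10)
        weak = rng.integers(1, 3, 20)
        # one feature switching 0<->3 carries most variance after the weak
        # features' near-constant jitter
        table = make_table(np.column_stack(
            [strong, strong, strong, weak, rng.integers(1, 3, 20),
             rng.integers(1, 3, 20)]))
        res = PhenotypeModel(table).fit()
        contrib = res.variable_contributions(1)
        assert contrib[["number_of_vessels", "dilated_vessels",
                        "trafficking"]].sum() > 90


class TestClustering:
    def test_three_planted_clusters_recovered(self):
        table, truth = generate_feature_table(30, BCC_LIKE_CLUSTERS,
                                              noise_sd=0.1, seed=0)
        res = fit_phenotype_model(table, n_clusters="auto")
        assert res.n_clusters == 3
        assert adjusted_rand_score(truth.cluster_of_sample,
                                   res.cluster_of_sample) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_auto_cluster_count_stable_across_seeds(self, seed):
        table, _ = generate_feature_table(30, BCC_LIKE_CLUSTERS,
                                          noise_sd=0.25, seed=seed)
        assert fit_phenotype_model(table, n_clusters="auto").n_clusters == 3

    def test_auto_finds_two_when_two_planted(self):
        spec = [((3, 3, 3, 0, 1, 0), 15, 0.2), ((0, 1, 0, 3, 2, 3), 15, 0.8)]
        table, _ = generate_feature_table(30, spec, noise_sd=0.25, seed=0)
        assert fit_phenotype_model(table).n_clusters == 2

    def test_forced_two_clusters(self, bcc_table):
        table, _ = bcc_table
        res = fit_phenotype_model(table, n_clusters=2)
        assert res.n_clusters == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_recovery_at_wide_separation(self, seed):
        # planted Euclidean separation far exceeds 6 noise SDs
        table, truth = generate_feature_table(30, BCC_LIKE_CLUSTERS,
                                              noise_sd=0.25, seed=seed)
        res = fit_phenotype_model(table, n_clusters=3)
        assert adjusted_rand_score(truth.cluster_of_sample,
                                   res.cluster_of_sample) == 1.0

    def test_partition_invariant_to_sample_and_feature_order(self, bcc_table):
        table, _ = bcc_table
        res = fit_phenotype_model(table, n_clusters=3)
        rng = np.random.default_rng(3)
        row_perm = rng.permutation(len(table))
        col_perm = list(rng.permutation(
            [c for c in table.columns if c != "response"])) + ["response"]
        shuffled = table.iloc[row_perm][col_perm]
        res2 = fit_phenotype_model(shuffled, n_clusters=3)
        assert adjusted_rand_score(res.cluster_of_sample[row_perm],
                                   res2.cluster_of_sample) == 1.0


class TestAxisNaming:
    def test_bcc_like_axes_and_high_vascular_label(self, bcc_table):
        table, truth = bcc_table
        res = fit_phenotype_model(table, n_clusters=3)
        res.assign_phenotype_labels()
        # vascular features dominate dimension 1 in the BCC-like layout
        assert res.vascular_axis == 1
        assert res.inflammation_axis == 2
        fitted = np.bincount(
            res.cluster_of_sample[truth.cluster_of_sample == 0]).argmax()
        assert res.cluster_labels[fitted] == "Inflam^LOW Vasc^HIGH"

    def test_four_corner_layout_names_every_cluster(self):
        # a 2x2 factorial layout decorrelates the vascular and inflammation
        # blocks, so the PCA axes align with them and all four labels follow
        vasc = {"L": (0, 1, 0), "H": (3, 3, 3)}
        inflam = {"L": (0, 1, 0), "H": (3, 2, 3)}
        spec, expected = [], []
        for v in "LH":
            for i in "LH":
                spec.append((vasc[v] + inflam[i], 7, 0.5))
                expected.append(f"Inflam^{'HIGH' if i == 'H' else 'LOW'} "
                                f"Vasc^{'HIGH' if v == 'H' else 'LOW'}")
        table, truth = generate_feature_table(28, spec, noise_sd=0.2, seed=1)
        res = fit_phenotype_model(table, n_clusters=4)
        res.assign_phenotype_labels()
        for planted, want in enumerate(expected):
            fitted = np.bincount(
                res.cluster_of_sample[truth.cluster_of_sample == planted]
            ).argmax()
            assert res.cluster_labels[fitted] == want

    def test_overlapping_feature_sets_rejected(self, bcc_table):
        table, _ = bcc_table
        res = fit_phenotype_model(table)
        with pytest.raises(ValueError, match="overlap"):
            res.assign_phenotype_labels(
                vascular_features=("trafficking",),
                inflammation_features=("trafficking",))

    def test_shared_dominant_component_rejected(self):
        # all six features identical: one component captures everything,
        # so both feature sets dominate it
        base = np.repeat([0, 1, 2, 3], 5)
        table = make_table(np.tile(base[:, None], (1, 6)))
        res = PhenotypeModel(table).fit(n_clusters=2)
        assert res.n_retained == 1
        with pytest.raises(ValueError, match="dominate"):
            res.assign_phenotype_labels()


class TestProjection:
    def test_training_samples_reproject_identically(self, bcc_table):
        table, _ = bcc_table
        res = fit_phenotype_model(table, n_clusters=3)
        proj = res.project(table.drop(columns="response"))
        np.testing.assert_allclose(
            proj[[f"PC{i+1}" for i in range(res.n_retained)]].to_numpy(),
            res.scores, atol=1e-10)
        assert (proj["cluster"].to_numpy() == res.cluster_of_sample).all()

    def test_cluster_mean_sample_assigned_to_cluster(self, bcc_table):
        table, truth = bcc_table
        res = fit_phenotype_model(table, n_clusters=3)
        mean_rows = np.rint(truth.cluster_means).astype(int)
        new = pd.DataFrame(mean_rows, columns=res.model.feature_names)
        proj = res.project(new)
        for planted, assigned in enumerate(proj["cluster"]):
            fitted = np.bincount(
                res.cluster_of_sample[truth.cluster_of_sample == planted]
            ).argmax()
            assert assigned == fitted

    def test_grand_mean_sample_scores_near_origin(self, bcc_table):
        table, _ = bcc_table
        res = fit_phenotype_model(table)
        grand = np.rint(res.feature_means).astype(int)
        new = pd.DataFrame([grand], columns=res.model.feature_names)
        proj = res.project(new)
        scores = proj[[f"PC{i+1}" for i in range(res.n_retained)]].to_numpy()
        # rounding to integer grades keeps it near, not exactly at, 0
        assert np.abs(scores).max() < 1.0

    def test_missing_feature_rejected(self, bcc_table):
        table, _ = bcc_table
        res = fit_phenotype_model(table)
        with pytest.raises(KeyError):
            res.project(table.drop(columns=["trafficking", "response"]))


def test_summary_mentions_clusters_and_axes(bcc_table):
    table, _ = bcc_table
    res = fit_phenotype_model(table, n_clusters=3).assign_phenotype_labels()
    text = res.summary()
    assert "retained components" in text
    assert "Inflam^" in text
    assert "vascular axis: PC1" in text
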