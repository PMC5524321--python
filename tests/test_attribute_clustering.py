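"""Attribute-space clustering, Region-1 selection and the coarse pathway."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from acdc_ssn.attribute_clustering import (
    ATTRIBUTE_COLUMNS,
    ClusterModel,
    NoRegion1Error,
    coarse_grain_pathway,
    coarse_grain_regions,
    filter_la_outliers,
    pca_project,
    select_num_clusters,
    select_region1,
)
from acdc_ssn.synthetic import GeneratorConfig, generate_region_pathway_sample


def _links_from(matrix):
    df = pd.DataFrame(np.asarray(matrix, dtype=float), columns=list(ATTRIBUTE_COLUMNS))
    df.insert(0, "node_b", [f"b{i}" for i in range(len(df))])
    df.insert(0, "node_a", [f"a{i}" for i in range(len(df))])
    from acdc_ssn.attribute_scaling import ensure_distance

    return ensure_distance(df)


def _model(means_sa, random_state=0):
    """ClusterModel with prescribed cluster-mean s_a (other attrs follow s_a)."""
    means = pd.DataFrame(
        {
            "l_a": [0.5 + 0.4 * s for s in means_sa],
            "f_id": [0.3 + 0.5 * s for s in means_sa],
            "f_m": [0.6 - 0.4 * s for s in means_sa],
            "s_a": means_sa,
        }
    ).rename_axis("cluster")
    return ClusterModel(
        n_clusters=len(means_sa),
        assignment=np.zeros(1, dtype=int),
        means=means,
        ch_curve={},
        pca_rotation=np.eye(4),
    )


class TestPCA:
    def test_total_variance_preserved_by_rotation(self, clean_ssn):
        projected, pca = pca_project(clean_ssn.links)
        x = clean_ssn.links.loc[:, list(ATTRIBUTE_COLUMNS)].to_numpy()
        assert projected.shape == x.shape
        assert np.var(projected, axis=0).sum() == pytest.approx(np.var(x, axis=0).sum())
        # components ordered by non-increasing explained variance
        assert np.all(np.diff(pca.explained_variance_) <= 1e-12)

    def test_rank_one_data_loads_on_first_component(self):
        t = np.linspace(0, 1, 60)
        x = np.outer(t, [0.5, 0.3, -0.2, 0.8]) + [0.2, 0.3, 0.5, 0.1]
        projected, pca = pca_project(_links_from(x))
        ratio = pca.explained_variance_ratio_
        assert ratio[0] > 0.999

    def test_axis_aligned_data_gives_signed_permutation(self):
        rng = np.random.default_rng(0)
        x = np.zeros((200, 4))
        for axis, scale in enumerate((1.0, 0.3, 3.0, 0.1)):  # distinct variances
            x[:, axis] = rng.normal(scale=scale, size=200)
        _, pca = pca_project(_links_from(0.2 + 0.1 * np.tanh(x)))
        # each principal axis is essentially one attribute axis
        loadings = np.abs(pca.components_)
        assert (loadings.max(axis=1) > 0.97).all()

    def test_fewer_than_two_links_rejected(self):
        with pytest.raises(ValueError):
            pca_project(_links_from([[1, 1, 0, 1]]))


class TestSelectNumClusters:
    @staticmethod
    def _blobs(rng, centers, n_per=60, scale=0.15):
        parts = [rng.normal(loc=c, scale=scale, size=(n_per, 4)) for c in centers]
        return np.vstack(parts)

    def test_three_well_separated_blobs_give_three(self):
        rng = np.random.default_rng(21)
        x = self._blobs(rng, [(0, 0, 0, 0), (4, 4, 0, 0), (0, 4, 4, 4)])
        q, ch_curve, _ = select_num_clusters(x, replicas=20, random_state=0)
        assert q == 3
        assert max(ch_curve, key=ch_curve.get) == 3  # CH itself peaks there too

    def test_single_blob_stays_small(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=(150, 4))
        q, _, _ = select_num_clusters(x, replicas=20, random_state=0)
        assert q <= 3

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(23)
        x = self._blobs(rng, [(0, 0, 0, 0), (3, 3, 3, 3)])
        out1 = select_num_clusters(x, replicas=10, random_state=7)
        out2 = select_num_clusters(x, replicas=10, random_state=7)
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]

    def test_candidates_capped_by_sample_size(self):
        rng = np.random.default_rng(24)
        x = rng.normal(size=(6, 4))
        with pytest.warns(UserWarning, match="skipping"):
            q, ch_curve, _ = select_num_clusters(x, k_max=10, replicas=5, random_state=0)
        assert max(ch_curve) <= 5


class TestCoarseGrainRegions:
    def test_two_means_split_of_mean_vectors(self):
        model = _model([0.6, 0.45, 0.1])
        region1 = coarse_grain_regions(model)
        assert region1 == {0, 1}

    def test_mean_sa_floor_forces_membership(self):
        """A cluster at s_a = 0.41 grouped low is still pulled into Region 1."""
        model = _model([0.95, 0.9, 0.41, 0.12, 0.05])
        region1 = coarse_grain_regions(model)
        assert 2 in region1  # the 0.41 cluster
        # and the forcing rule leaves nothing above the floor outside
        outside = set(model.means.index) - region1
        assert (model.means.loc[sorted(outside), "s_a"] < 0.30).all()

    def test_all_low_clusters_is_an_error(self):
        model = _model([0.05, 0.08, 0.1])
        with pytest.raises(NoRegion1Error):
            coarse_grain_regions(model)

    @pytest.mark.parametrize("sa, ok", [(0.5, True), (0.1, False)])
    def test_single_cluster_depends_on_floor(self, sa, ok):
        model = _model([sa])
        if ok:
            assert coarse_grain_regions(model) == {0}
        else:
            with pytest.raises(NoRegion1Error):
                coarse_grain_regions(model)


class TestFilterLaOutliers:
    def test_low_la_link_is_excluded(self):
        rng = np.random.default_rng(31)
        n = 200
        x = np.column_stack(
            [
                np.append(rng.uniform(0.9, 1.0, n), 0.1),  # one l_a outlier
                np.full(n + 1, 0.6),
                np.full(n + 1, 0.2),
                np.append(rng.uniform(0.5, 0.9, n), 0.55),
            ]
        )
        selection = filter_la_outliers(_links_from(x))
        assert 0.1 in selection.excluded_outliers["l_a"].tolist()
        assert 0.1 not in selection.links["l_a"].tolist()
        assert len(selection.links) >= 0.95 * n

    def test_homogeneous_la_keeps_everything(self):
        rng = np.random.default_rng(32)
        x = np.column_stack(
            [
                rng.uniform(0.93, 0.97, 30),
                np.full(30, 0.6),
                np.full(30, 0.2),
                rng.uniform(0.4, 0.9, 30),
            ]
        )
        selection = filter_la_outliers(_links_from(x))
        assert len(selection.excluded_outliers) == 0
        assert len(selection.links) == 30

    def test_survivors_sorted_by_ascending_d(self, clean_ssn):
        selection = filter_la_outliers(clean_ssn.links)
        d = selection.links["d"].to_numpy()
        assert np.all(np.diff(d) >= 0)


class TestRegion1Pipeline:
    def test_planted_regions_are_recovered(self, clean_ssn):
        """>=95% of intra-family links survive; >=95% of Region-2 links excluded."""
        selection, model = select_region1(clean_ssn.links, replicas=30, random_state=0)
        kept = clean_ssn.links.loc[
            clean_ssn.links.index.isin(
                clean_ssn.links.reset_index().merge(
                    selection.links, on=["node_a", "node_b"]
                )["index"]
            )
        ]
        region = clean_ssn.links["region"]
        n_r1 = (region == "region1").sum()
        n_r2 = (region == "region2").sum()
        kept_regions = kept["region"].value_counts()
        assert kept_regions.get("region1", 0) >= 0.95 * n_r1
        assert kept_regions.get("region2", 0) <= 0.05 * n_r2
        # the forcing rule holds exactly
        assert {
            int(c)
            for c in model.means.index[model.means["s_a"] >= 0.30]
        } <= model.region1_clusters


class TestPathway:
    def test_pathway_is_sorted_by_sa_with_planted_endpoints(self):
        config = GeneratorConfig(seed=5)
        sample = generate_region_pathway_sample(config, n_points=900)
        path = coarse_grain_pathway(sample, points_per_cluster=100, random_state=0)
        sa = path["s_a"].to_numpy()
        assert np.all(np.diff(sa) >= 0)
        # endpoints near the planted Region-2 / Region-1 centers (2 SE slack)
        r1 = sample.loc[sample["region"] == "region1", list(ATTRIBUTE_COLUMNS)]
        r2 = sample.loc[sample["region"] == "region2", list(ATTRIBUTE_COLUMNS)]
        for col in ("l_a", "s_a"):
            se1 = r1[col].std() / np.sqrt(len(path))
            assert abs(path[col].iloc[-1] - r1[col].mean()) < max(
                2 * r1[col].std(), 4 * se1
            )
            assert abs(path[col].iloc[0] - r2[col].mean()) < 2 * r2[col].std()

    def test_small_sample_collapses_to_grand_mean(self):
        rng = np.random.default_rng(44)
        x = rng.uniform(0.2, 0.8, size=(30, 4))
        path = coarse_grain_pathway(_links_from(x), points_per_cluster=100)
        assert len(path) == 1
        np.testing.assert_allclose(
            path.iloc[0].to_numpy(), x.mean(axis=0), rtol=0, atol=1e-12
        )
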