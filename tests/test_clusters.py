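"""DFA cluster posteriors, cell classification and KDE composition."""

import numpy as np
import pytest
from scipy import stats

from isomatch import (ClusterModel, FeatherSample, IsoscapeRaster,
                      IsoscapeStack, classify_cells, cluster_composition,
                      cluster_posteriors, correspondence_count)
from isomatch.assignment import BinaryMask
from isomatch.clusters import ClusterPosterior, posterior_table


def one_d_model(means=(0.0, 10.0), sd=1.0):
    """Two clusters separated along delta-13C only (delta-15N uninformative)."""
    k = len(means)
    return ClusterModel(
        isotopes=("13C", "15N"),
        means=np.array([[m, 0.0] for m in means]),
        sds=np.full((k, 2), sd),
    )


def sample_cn(c13, n15=0.0, id="s"):
    return FeatherSample(id, d13C=c13, d15N=n15)


class TestPosteriors:
    def test_far_separated_clusters(self):
        post = cluster_posteriors(sample_cn(0.0), one_d_model())
        assert post.hard_label == 1
        assert post.probs[0] == pytest.approx(1.0, abs=1e-12)
        # 10-sigma gap: other cluster's posterior ~ exp(-50)
        assert post.probs[1] == pytest.approx(np.exp(-50.0), rel=1e-6)

    def test_midpoint_symmetry(self):
        post = cluster_posteriors(sample_cn(5.0), one_d_model())
        assert post.probs == pytest.approx([0.5, 0.5], abs=1e-12)
        assert post.hard_label == 1  # tie breaks to the lowest cluster id

    def test_matches_bayes_rule_oracle(self):
        """Random 3-cluster 2-isotope model vs an independent scipy Bayes rule."""
        rng = np.random.default_rng(21)
        model = ClusterModel(
            isotopes=("13C", "15N"),
            means=rng.normal(0, 5, (3, 2)),
            sds=rng.uniform(0.5, 2.5, (3, 2)),
            priors=np.array([0.2, 0.5, 0.3]),
        )
        pooled = np.einsum("c,ci->i", model.priors, model.sds**2)
        worst = 0.0
        for _ in range(50):
            x = rng.normal(0, 6, 2)
            s = FeatherSample("r", d13C=x[0], d15N=x[1])
            post = cluster_posteriors(s, model)
            like = np.array([
                stats.multivariate_normal.pdf(x, mean=model.means[c], cov=np.diag(pooled))
                for c in range(3)
            ])
            ref = model.priors * like
            ref /= ref.sum()
            worst = max(worst, np.abs(post.probs - ref).max() / ref.max())
        assert worst <= 1e-12

    def test_posterior_normalized_and_stable_under_duplication(self):
        model = one_d_model((0.0, 4.0, 9.0))
        s = sample_cn(3.7, 1.2)
        a = cluster_posteriors(s, model)
        b = cluster_posteriors(s, model)
        assert a.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert a.hard_label == b.hard_label
        assert np.array_equal(a.probs, b.probs)

    def test_missing_isotope_rejected(self):
        model = ClusterModel(isotopes=("2H", "13C", "15N"),
                             means=np.zeros((2, 3)) + [[0], [10]],
                             sds=np.ones((2, 3)))
        with pytest.raises(KeyError):
            cluster_posteriors(sample_cn(0.0), model)

    def test_priors_shift_posteriors(self):
        flat = cluster_posteriors(sample_cn(5.0), one_d_model())
        skew_model = one_d_model()
        skew_model.priors = np.array([0.9, 0.1])
        skew = cluster_posteriors(sample_cn(5.0), skew_model)
        assert skew.probs[0] > flat.probs[0]
        assert skew.probs[0] == pytest.approx(0.9, abs=1e-12)


class TestClassifyCells:
    def _stack_from_fields(self, grid, c13, n15):
        return IsoscapeStack([
            IsoscapeRaster(grid=grid, isotope="13C", mean=c13),
            IsoscapeRaster(grid=grid, isotope="15N", mean=n15),
        ])

    def test_constant_stack_labels_single_cluster(self, grid10):
        model = one_d_model((0.0, 10.0))
        stack = self._stack_from_fields(grid10, np.full(grid10.shape, 10.0),
                                        np.zeros(grid10.shape))
        labels = classify_cells(stack, model).labels
        assert (labels == 2).all()

    def test_decision_boundary_at_midpoint(self, grid10):
        # monotone gradient 0..9.x along lon; equal SDs/priors -> boundary at 5
        model = one_d_model((0.0, 10.0))
        lon_grad = np.tile(grid10.lon_centers(), (grid10.n_rows, 1))
        stack = self._stack_from_fields(grid10, lon_grad, np.zeros(grid10.shape))
        labels = classify_cells(stack, model).labels
        assert (labels[:, :5] == 1).all() and (labels[:, 5:] == 2).all()

    def test_affine_invariance(self, grid10):
        rng = np.random.default_rng(8)
        model = ClusterModel(isotopes=("13C", "15N"),
                             means=rng.normal(0, 3, (3, 2)),
                             sds=rng.uniform(0.5, 2, (3, 2)))
        c13 = rng.normal(0, 4, grid10.shape)
        n15 = rng.normal(0, 4, grid10.shape)
        base = classify_cells(self._stack_from_fields(grid10, c13, n15), model).labels
        a, b = 2.5, -7.0
        scaled_model = ClusterModel(isotopes=("13C", "15N"),
                                    means=a * model.means + b, sds=a * model.sds)
        scaled = classify_cells(
            self._stack_from_fields(grid10, a * c13 + b, a * n15 + b), scaled_model
        ).labels
        assert np.array_equal(base, scaled)

    def test_invalid_cells_stay_unlabeled(self, grid10):
        mask = np.ones(grid10.shape, bool)
        mask[:2] = False
        stack = IsoscapeStack([
            IsoscapeRaster(grid=grid10, isotope="13C", mean=np.zeros(grid10.shape),
                           valid_mask=mask),
            IsoscapeRaster(grid=grid10, isotope="15N", mean=np.zeros(grid10.shape)),
        ])
        labels = classify_cells(stack, one_d_model()).labels
        assert (labels[:2] == 0).all() and (labels[2:] > 0).all()


class TestComposition:
    def test_single_cluster_mask(self, grid10):
        model = one_d_model((0.0, 10.0))
        stack = IsoscapeStack([
            IsoscapeRaster(grid=grid10, isotope="13C", mean=np.zeros(grid10.shape)),
            IsoscapeRaster(grid=grid10, isotope="15N", mean=np.zeros(grid10.shape)),
        ])
        clusters = classify_cells(stack, model)
        cells = np.zeros(grid10.shape, bool)
        cells[4:7, 4:7] = True
        mask = BinaryMask(grid=grid10, id="m", q=0.5, cells=cells)
        comp = cluster_composition(mask, clusters)
        assert comp.tolist() == [100.0, 0.0]

    def test_three_to_one_split(self, grid10):
        from isomatch.clusters import ClusterRaster
        labels = np.ones(grid10.shape, int)
        labels[0, 3] = 2  # mask of 4 cells split 3:1
        clusters = ClusterRaster(grid=grid10, labels=labels, k=2)
        cells = np.zeros(grid10.shape, bool)
        cells[0, :4] = True
        comp = cluster_composition(BinaryMask(grid=grid10, id="m", q=0.5, cells=cells),
                                   clusters)
        assert comp.tolist() == [75.0, 25.0]

    def test_whole_domain_sums_to_100(self, small_world):
        model = small_world.cluster_models["CN"]
        clusters = classify_cells(small_world.feather_stack, model)
        cells = small_world.feather_stack.joint_valid_mask
        mask = BinaryMask(grid=small_world.feather_stack.grid, id="all", q=0.5,
                          cells=cells)
        comp = cluster_composition(mask, clusters, decimals=-1)
        assert comp.sum() == pytest.approx(100.0, abs=0.1)

    def test_empty_mask_rejected(self, grid10):
        from isomatch.clusters import ClusterRaster
        clusters = ClusterRaster(grid=grid10, labels=np.ones(grid10.shape, int), k=2)
        empty = BinaryMask(grid=grid10, id="m", q=0.5,
                           cells=np.zeros(grid10.shape, bool))
        with pytest.raises(ValueError):
            cluster_composition(empty, clusters)


class TestCorrespondence:
    def _post(self, id, label, k=4):
        probs = np.full(k, 0.0)
        probs[label - 1] = 1.0
        return ClusterPosterior(id=id, probs=probs, hard_label=label)

    def test_dominant_cluster_counted(self):
        post = [self._post("a", 2)]
        comp = {"a": np.array([30.0, 70.0, 0.0, 0.0])}
        assert correspondence_count(post, comp, threshold=50) == 1

    def test_exact_threshold_rules(self):
        post = [self._post("a", 1)]
        comp = {"a": np.array([50.0, 50.0, 0.0, 0.0])}
        assert correspondence_count(post, comp, rule="at_least") == 1
        assert correspondence_count(post, comp, rule="strict") == 0

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correspondence_count([self._post("a", 1)], {"b": np.zeros(4)})

    def test_high_separation_recovers_generating_cluster(self):
        """>= 4 pooled-SD separation recovers the generating cluster >= 95%."""
        rng = np.random.default_rng(17)
        model = ClusterModel(
            isotopes=("13C", "15N"),
            means=np.array([[0.0, 0.0], [4.5, 4.5], [9.0, 0.0]]),
            sds=np.ones((3, 2)),
        )
        correct = 0
        n = 1000
        for i in range(n):
            c = i % 3
            x = rng.normal(model.means[c], 1.0)
            post = cluster_posteriors(FeatherSample(f"i{i}", d13C=x[0], d15N=x[1]),
                                      model)
            correct += post.hard_label == c + 1
        assert correct / n >= 0.95


def test_posterior_table_renders_integer_percentages():
    posts = [
        ClusterPosterior(id="a", probs=np.array([0.96, 0.04]), hard_label=1),
        ClusterPosterior(id="b", probs=np.array([0.5, 0.5]), hard_label=1),
    ]
    df = posterior_table(posts)
    assert list(df.columns) == ["id", "C1", "C2"]
    assert df.loc[0, "C1"] == 96 and df.loc[1, "C2"] == 50


def test_cluster_stats_csv_roundtrip(tmp_path, small_world):
    model = small_world.cluster_models["HCN"]
    p = tmp_path / "stats.csv"
    model.to_csv(p)
    back = ClusterModel.from_csv(p)
    assert tuple(back.isotopes) == tuple(model.isotopes)
    assert np.allclose(back.means, model.means)
    assert np.allclose(back.sds, model.sds)


def test_extra_columns_warn(tmp_path):
    import pandas as pd
    df = pd.DataFrame({
        "cluster": [1, 1, 2, 2], "isotope": ["13C", "15N", "13C", "15N"],
        "mean": [0.0, 0.0, 5.0, 5.0], "sd": [1.0, 1.0, 1.0, 1.0],
        "min": [-3.0, -3.0, 2.0, 2.0], "max": [3.0, 3.0, 8.0, 8.0],
    })
    p = tmp_path / "stats.csv"
    df.to_csv(p, index=False)
    with pytest.warns(UserWarning, match="ignoring extra"):
        model = ClusterModel.from_csv(p)
    assert model.k == 2
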