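"""rclr algebra, matrix completion, PERMANOVA oracles, RDA identities."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from periomip.ordination import (
    matrix_complete,
    pairwise_distance_groups,
    permanova,
    rclr,
    rda_effect_sizes,
    rpca,
    sample_distances,
)


class TestRclr:
    def test_hand_computed_row(self):
        table = pd.DataFrame([[1, 10, 100, 0]], index=["s"], columns=list("abcd"))
        out = rclr(table)
        expected = [-np.log(10), 0.0, np.log(10), np.nan]
        np.testing.assert_allclose(out.loc["s"].to_numpy()[:3], expected[:3], atol=1e-12)
        assert np.isnan(out.loc["s", "d"])

    def test_constant_row_centers_to_zero(self):
        out = rclr(pd.DataFrame([[7, 7, 7]]))
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_scale_invariance(self, planted_cohort):
        table = planted_cohort[0]
        factors = np.random.default_rng(0).integers(1, 101, size=len(table))
        scaled = table.mul(factors, axis=0)
        a, b = rclr(table), rclr(scaled)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-11)

    def test_nonmissing_entries_row_center(self, planted_cohort):
        out = rclr(planted_cohort[0])
        sums = np.nansum(out.to_numpy(), axis=1)
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_too_few_nonzeros_rejected(self):
        table = pd.DataFrame([[5, 0, 0]], index=["only"], columns=list("abc"))
        with pytest.raises(ValueError, match="only"):
            rclr(table)


class TestMatrixCompletion:
    def test_exact_low_rank_recovery(self):
        rng = np.random.default_rng(1)
        M = np.outer(rng.normal(size=12), rng.normal(size=8))
        U, V, _, converged = matrix_complete(M, np.ones_like(M, bool), rank=1, seed=0)
        assert converged
        assert np.abs(U @ V.T - M).max() < 1e-6

    def test_rank_too_large_rejected(self):
        M = np.zeros((4, 3))
        with pytest.raises(ValueError, match="rank"):
            matrix_complete(M, np.ones_like(M, bool), rank=3)


class TestRpca:
    def test_eigenvalues_sorted_and_proportions(self, planted_rpca):
        eig = planted_rpca.eigenvalues_
        assert np.all(np.diff(eig) <= 0) and np.all(eig >= 0)
        prop = planted_rpca.proportion_explained_
        assert np.all(np.diff(prop) <= 0)
        assert prop.sum() <= 1 + 1e-9

    def test_axis1_separates_planted_groups(self, planted_cohort, planted_rpca):
        from sklearn.metrics import silhouette_score

        meta = planted_cohort[1]
        labels = meta.loc[planted_rpca.sample_scores_.index, "site_class"]
        s = silhouette_score(planted_rpca.sample_scores_.iloc[:, [0]], labels)
        assert s > 0

    def test_distances_invariant_to_sample_rescaling(self, planted_cohort, planted_rpca):
        table = planted_cohort[0]
        factors = np.random.default_rng(3).integers(1, 101, size=len(table))
        scaled = table.mul(factors, axis=0)
        other = rpca(scaled, rank=3, seed=0)
        d0 = sample_distances(planted_rpca).to_numpy()
        d1 = sample_distances(other).to_numpy()
        denom = np.maximum(d0, 1e-9)
        off = ~np.eye(len(d0), dtype=bool)
        assert np.max(np.abs(d0 - d1)[off] / denom[off]) < 1e-6


class TestSampleDistances:
    def test_pythagoras(self):
        scores = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        d = sample_distances(scores)
        assert d.loc["a", "b"] == pytest.approx(5.0)
        assert d.loc["a", "a"] == 0.0

    @given(
        arrays(
            float,
            (6, 3),
            elements=st.floats(-50, 50, allow_nan=False, allow_infinity=False, width=32),
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_triangle_inequality(self, scores):
        d = sample_distances(pd.DataFrame(scores)).to_numpy()
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-6


def _exhaustive_permanova_p(d, labels):
    """Brute-force permutation p over all distinct label orderings."""
    f_obs, _ = permanova(d, labels, permutations=[labels])
    perms = np.array(sorted(set(permutations(labels))))
    _, p = permanova(d, labels, permutations=perms)
    return f_obs, p


class TestPermanova:
    @pytest.fixture()
    def small_design(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(1.5, 1, (3, 2))])
        d = sample_distances(pd.DataFrame(pts))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        return d, labels

    def test_matches_exhaustive_enumeration(self, small_design):
        d, labels = small_design
        _, p_exact = _exhaustive_permanova_p(d, labels)
        _, p_sampled = permanova(d, labels, n_perm=999, seed=0)
        assert abs(p_exact - p_sampled) < 0.05

    def test_pseudo_f_matches_skbio(self, small_design):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        d, labels = small_design
        f_ours, _ = permanova(d, labels, n_perm=9, seed=0)
        res = skbio_permanova(DistanceMatrix(d.to_numpy()), list(labels), permutations=9)
        assert f_ours == pytest.approx(res["test statistic"], rel=1e-9)

    def test_saturated_separation_hits_floor(self):
        # n large enough that no random permutation recreates the partition
        pts = np.vstack(
            [np.zeros((15, 2)), 100 + np.random.default_rng(0).normal(size=(15, 2))]
        )
        d = sample_distances(pd.DataFrame(pts))
        labels = ["a"] * 15 + ["b"] * 15
        _, p = permanova(d, labels, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self, small_design):
        d, labels = small_design
        assert permanova(d, labels, seed=7) == permanova(d, labels, seed=7)

    def test_singleton_group_rejected(self, small_design):
        d, _ = small_design
        with pytest.raises(ValueError, match="singleton"):
            permanova(d, ["a", "b", "b", "b", "b", "b"])


class TestPairwiseDistanceGroups:
    @pytest.fixture()
    def three_participants(self):
        samples = ["p1.S", "p1.D", "p2.S", "p2.D", "p3.S"]
        rng = np.random.default_rng(5)
        d = sample_distances(pd.DataFrame(rng.normal(size=(5, 2)), index=samples))
        meta = pd.DataFrame(
            {
                "participant_id": ["p1", "p1", "p2", "p2", "p3"],
                "site_class": ["shallow", "deep", "shallow", "deep", "shallow"],
            },
            index=samples,
        )
        return d, meta

    def test_combinatorial_category_sizes(self, three_participants):
        d, meta = three_participants
        with pytest.warns(UserWarning):  # deep-deep has a single pair
            groups, _ = pairwise_distance_groups(d, meta)
        sizes = {k: len(v) for k, v in groups.items()}
        assert sizes == {
            "shallow_shallow_between": 3,
            "deep_deep_between": 1,
            "shallow_deep_within": 2,
            "shallow_deep_between": 4,
        }

    def test_categories_partition_all_pairs(self, planted_cohort, planted_rpca):
        meta = planted_cohort[1]
        d = sample_distances(planted_rpca)
        groups, result = pairwise_distance_groups(d, meta)
        n = len(d)
        assert sum(len(v) for v in groups.values()) == n * (n - 1) // 2
        assert 0 <= result["anova_p"] <= 1
        assert len(result["tukey"]) == 6


class TestRdaEffectSizes:
    def test_axis_aligned_covariate_recovers_axis_variance(self, planted_rpca):
        covs = pd.DataFrame({"axis1": planted_rpca.sample_scores_["PC1"]})
        out = rda_effect_sizes(planted_rpca.completed_, covs, n_perm=9, seed=0)
        assert out.loc["axis1", "effect_size"] == pytest.approx(
            planted_rpca.proportion_explained_[0], abs=0.02
        )

    def test_random_covariate_has_null_adjusted_r2(self, planted_rpca):
        rng = np.random.default_rng(6)
        vals = []
        response = planted_rpca.completed_
        for _ in range(100):
            covs = pd.DataFrame(
                {"noise": rng.normal(size=len(response))}, index=response.index
            )
            out = rda_effect_sizes(response, covs, n_perm=0, seed=0)
            vals.append(out.loc["noise", "r2"] - (1 - out.loc["noise", "r2"]) / (len(response) - 2))
        assert abs(float(np.mean(vals))) < 0.01

    def test_planted_driver_ranks_first(self, planted_cohort, planted_rpca):
        _, meta, _, _, _ = planted_cohort
        covs = meta.loc[planted_rpca.completed_.index, ["site_class", "age", "sex", "bmi"]]
        out = rda_effect_sizes(planted_rpca.completed_, covs, n_perm=99, seed=0)
        assert out["effect_size"].idxmax() == "site_class"
        assert out.loc["site_class", "p_value"] <= 0.05

    def test_constant_covariate_skipped_with_warning(self, planted_rpca):
        covs = pd.DataFrame(
            {"const": 1.0}, index=planted_rpca.completed_.index
        )
        with pytest.warns(UserWarning, match="constant"):
            out = rda_effect_sizes(planted_rpca.completed_, covs, n_perm=9)
        assert out.empty
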