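"""Faith's PD oracle, adjusted models, quartile trends, correlations."""

import io

import numpy as np
import pandas as pd
import pytest

from periomip.association import (
    adjusted_linear_model,
    faiths_pd,
    pearson,
    quartile_trend_model,
    run_association_suite,
)
from periomip.io import read_tree
from periomip.simulate import _random_coalescent


def _tree(newick, tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text(newick)
    return read_tree(p)


def _brute_force_pd(tree, present_tips):
    """Union of root paths, summed."""
    edges = set()
    for tip in tree.tips():
        if tip.name not in present_tips:
            continue
        node = tip
        while node.parent is not None:
            edges.add(id(node))
            node = node.parent
    by_id = {id(n): n for n in tree.traverse(include_self=False)}
    return sum(by_id[e].length or 0.0 for e in edges)


class TestFaithsPD:
    def test_full_sample_sums_all_branches(self, tmp_path):
        tree = _tree("((A:1,B:1):1,C:2);", tmp_path)
        table = pd.DataFrame({"A": [1], "B": [1], "C": [1]}, index=["s"])
        assert faiths_pd(table, tree)["s"] == pytest.approx(5.0)

    def test_single_tip_includes_stem_to_root(self, tmp_path):
        tree = _tree("((A:1,B:1):1,C:2);", tmp_path)
        table = pd.DataFrame({"A": [1], "B": [0], "C": [0]}, index=["s"])
        assert faiths_pd(table, tree)["s"] == pytest.approx(2.0)

    def test_adding_a_feature_never_decreases_pd(self, tmp_path):
        tree = _tree("((A:1,B:3):1,(C:2,D:1):4);", tmp_path)
        prev = 0.0
        present = {}
        for feat in ["A", "C", "B", "D"]:
            present[feat] = [1]
            table = pd.DataFrame({f: present.get(f, [0]) for f in "ABCD"}, index=["s"])
            cur = faiths_pd(table, tree)["s"]
            assert cur >= prev - 1e-12
            prev = cur

    def test_matches_union_of_root_paths_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for rep in range(100):
            n_leaves = int(rng.integers(3, 21))
            labels = [f"L{i}" for i in range(n_leaves)]
            tree = _random_coalescent(labels, rng)
            presence = rng.random(n_leaves) < 0.5
            if not presence.any():
                presence[0] = True
            table = pd.DataFrame(
                [presence.astype(int)], index=["s"], columns=labels
            )
            ours = faiths_pd(table, tree)["s"]
            oracle = _brute_force_pd(tree, {l for l, p in zip(labels, presence) if p})
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_feature_missing_from_tree_rejected(self, tmp_path):
        tree = _tree("((A:1,B:1):1,C:2);", tmp_path)
        table = pd.DataFrame({"A": [1], "Z": [1]}, index=["s"])
        with pytest.raises(ValueError, match="Z"):
            faiths_pd(table, tree)


class TestAdjustedLinearModel:
    def test_exact_linear_relation(self):
        data = pd.DataFrame({"mip": np.linspace(-2, 2, 30)})
        data["outcome"] = 2.0 * data["mip"]
        res = adjusted_linear_model(data, "outcome", "mip", covariates=())
        assert res.estimate == pytest.approx(2.0, abs=1e-10)
        assert res.p_value < 1e-20

    def test_listwise_deletion_n_is_auditable(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {
                "mip": rng.normal(size=50),
                "age": rng.normal(50, 8, size=50),
                "outcome": rng.normal(size=50),
            }
        )
        data.loc[data.index[:7], "age"] = np.nan
        data.loc[data.index[7:10], "outcome"] = np.nan
        res = adjusted_linear_model(data, "outcome", "mip", covariates=("age",))
        assert res.n == 40

    def test_coefficient_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {
                "mip": rng.normal(size=80),
                "age": rng.normal(50, 8, size=80),
            }
        )
        data["outcome"] = 1.5 * data["mip"] + 0.1 * data["age"] + rng.normal(size=80)
        a = adjusted_linear_model(data, "outcome", "mip", covariates=("age",))
        data["age"] = data["age"] * 12 + 1000
        b = adjusted_linear_model(data, "outcome", "mip", covariates=("age",))
        assert a.estimate == pytest.approx(b.estimate, abs=1e-8)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({"mip": rng.normal(size=30), "age": rng.normal(size=30)})
        data["age2"] = data["age"]
        data["outcome"] = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank-deficient"):
            adjusted_linear_model(data, "outcome", "mip", covariates=("age", "age2"))


class TestQuartileTrend:
    def test_noiseless_monotone_outcome(self):
        data = pd.DataFrame(
            {
                "quartile": np.repeat([1, 2, 3, 4], 10).astype(float),
                "participant_id": [f"p{i}" for i in range(40)],
            }
        )
        data["outcome"] = data["quartile"] * 3.0
        res = quartile_trend_model(data, "outcome", covariates=())
        means = res.table["adjusted_mean"]
        assert (means.diff().dropna() > 0).all()
        assert res.trend_p < 1e-12
        assert res.model == "ols"

    def test_mixed_model_agrees_with_aggregation_within_one_se(self):
        rng = np.random.default_rng(3)
        n_part = 40
        part = np.repeat([f"p{i}" for i in range(n_part)], 2)
        u = np.repeat(rng.normal(0, 1, n_part), 2)
        quart = np.repeat(rng.integers(1, 5, n_part), 2).astype(float)
        outcome = 2.0 * quart + u + rng.normal(0, 0.5, 2 * n_part)
        data = pd.DataFrame(
            {"participant_id": part, "quartile": quart, "outcome": outcome}
        )
        mixed = quartile_trend_model(data, "outcome", covariates=())
        assert mixed.model == "mixed"
        agg = (
            data.groupby("participant_id")
            .agg({"quartile": "first", "outcome": "mean"})
            .reset_index()
        )
        ols = quartile_trend_model(agg, "outcome", covariates=())
        for q in (1, 2, 3, 4):
            delta = abs(
                mixed.table.loc[q, "adjusted_mean"] - ols.table.loc[q, "adjusted_mean"]
            )
            assert delta <= max(
                mixed.table.loc[q, "std_error"], ols.table.loc[q, "std_error"]
            )

    def test_empty_quartile_rejected(self):
        data = pd.DataFrame(
            {
                "quartile": [1.0, 1, 2, 2, 3, 3],
                "participant_id": list("abcdef"),
                "outcome": [1.0, 2, 3, 4, 5, 6],
            }
        )
        with pytest.raises(ValueError, match="quartile"):
            quartile_trend_model(data, "outcome", covariates=())


class TestPearson:
    def test_perfect_correlations(self):
        r, _ = pearson([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        r, _ = pearson([1.0, 2, 3], [-1.0, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_pairwise_complete(self):
        r, _ = pearson([1, 2, 3, np.nan], [2, 4, 6, 100])
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [2, 4, 6])


class TestSuite:
    def test_coupled_vs_uncoupled_pattern(self, planted_cohort):
        table, meta, taxonomy, tree, _ = planted_cohort
        panels = run_association_suite(table, meta, taxonomy, tree, stratum="all")
        peri = panels["periodontal"]
        metab = panels["metabolic"]
        assert peri.loc["pct_bop", "p_value"] < 0.05  # coupled outcome detected
        assert metab.loc["meansbp", "p_value"] < 0.05
        assert metab.loc["hba1c", "p_value"] > 0.05  # uncoupled panel stays null

    def test_shallow_only_stratum_retains_association(self, planted_cohort):
        table, meta, taxonomy, _, _ = planted_cohort
        panels = run_association_suite(table, meta, taxonomy, stratum="shallow_only")
        assert panels["periodontal"].loc["pct_bop", "p_value"] < 0.05

    def test_empty_stratum_rejected(self):
        from periomip.simulate import CohortDesign, simulate_cohort

        table, meta, taxonomy, tree, _ = simulate_cohort(
            CohortDesign(n_participants=12, frac_with_deep_site=0.0, seed=8)
        )
        with pytest.raises(ValueError, match="empty"):
            run_association_suite(table, meta, taxonomy, stratum="moderate_severe_only")
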