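"""Resampled splits, the seven models and importance aggregation."""

import numpy as np
import pandas as pd
import pytest

from ec11.cohort import Cohort, encode_cohort
from ec11.lasso import LassoFit
from ec11.ranking import (
    SEVEN_MODELS,
    fit_tree,
    make_splits,
    rank_variants,
    select_top,
    variable_importance,
)
from ec11.simulate import EffectModel, paper_like_config, simulate_cohort, simulate_genotypes, simulate_phenotypes
from tests.conftest import cohort_from_calls


@pytest.fixture(scope="module")
def small_cohort():
    """120-sample cohort; splits are checked on a common-variant panel
    (ultra-rare variants would make every draw fixed at this size)."""
    from ec11.panels import builtin_panel

    cfg = paper_like_config(120, seed=100)
    return simulate_cohort(cfg), builtin_panel("irisplex6")


class TestMakeSplits:
    def test_train_test_sizes(self, small_cohort):
        cohort, panel = small_cohort
        coded = encode_cohort(cohort, panel)
        splits = make_splits(coded, 3, seed=0)
        n = coded.values.shape[0]
        for s in splits:
            assert len(s.train_ids) == round(2 * n / 3)
            assert len(s.test_ids) == n - round(2 * n / 3)
            assert not set(s.train_ids) & set(s.test_ids)

    def test_paper_sized_cohort_split(self):
        # 757 samples -> 505 train / 252 test
        assert round(2 * 757 / 3) == 505

    def test_no_fixed_variant_in_training_part(self, small_cohort):
        cohort, panel = small_cohort
        coded = encode_cohort(cohort, panel)
        for s in make_splits(coded, 5, seed=1):
            train = coded.values.loc[list(s.train_ids)]
            assert (train.nunique() > 1).all()

    def test_globally_fixed_variant_is_named(self, snp_panel):
        cohort = cohort_from_calls(
            {
                "rs1": ["AA"] * 12,  # fixed everywhere
                "rs2": ["CC", "CT", "TT"] * 4,
                "rs3": ["GG", "GC", "CC"] * 4,
            },
            [0.0] * 12,
        )
        coded = encode_cohort(cohort, snp_panel)
        with pytest.raises(ValueError, match="rs1"):
            make_splits(coded, 2, seed=0)

    def test_same_seed_same_splits(self, small_cohort):
        cohort, panel = small_cohort
        coded = encode_cohort(cohort, panel)
        assert make_splits(coded, 4, seed=9) == make_splits(coded, 4, seed=9)


class TestTreeImportance:
    def test_single_deterministic_splitter_takes_all(self, rng):
        values = pd.DataFrame(
            {
                "a": rng.integers(0, 3, 300),
                "b": rng.integers(0, 3, 300),
                "c": rng.integers(0, 2, 300),
            }
        )
        y = (values["a"] >= 1).astype(float).to_numpy()
        tree = fit_tree(values, y, "continuous")
        imp = variable_importance(tree, list(values.columns), values.columns)
        assert imp["a"] == pytest.approx(imp.sum())
        assert imp["a"] > 0

    def test_constant_response_all_zero(self, rng):
        values = pd.DataFrame({"a": rng.integers(0, 3, 50), "b": rng.integers(0, 3, 50)})
        tree = fit_tree(values, np.ones(50), "continuous")
        imp = variable_importance(tree, list(values.columns), values.columns)
        assert (imp == 0).all()

    def test_additive_effects_rank_by_magnitude(self, rng):
        n = 2000
        values = pd.DataFrame(
            {"big": rng.integers(0, 3, n), "small": rng.integers(0, 3, n)}
        )
        y = 3.0 * values["big"] + 0.7 * values["small"]
        tree = fit_tree(values, y.to_numpy(), "continuous")
        imp = variable_importance(tree, list(values.columns), values.columns)
        assert imp["big"] > imp["small"] > 0


class TestImportanceAttribution:
    def test_lasso_absolute_coefficients(self):
        fit = LassoFit(
            family="gaussian", lambda_=0.1, lambdas=np.array([0.1]),
            coef_std=np.array([2.0, -0.5, 0.0]), intercept=0.0,
            cv_mean=np.zeros(1), cv_se=np.zeros(1), lambda_min=0.1,
        )
        imp = variable_importance(fit, ["a", "b", "c"], ["a", "b", "c"])
        assert list(imp) == [2.0, 0.5, 0.0]

    def test_interaction_coefficient_accrues_to_both_partners(self):
        fit = LassoFit(
            family="gaussian", lambda_=0.1, lambdas=np.array([0.1]),
            coef_std=np.array([1.0, 0.0, 0.5]), intercept=0.0,
            cv_mean=np.zeros(1), cv_se=np.zeros(1), lambda_min=0.1,
        )
        names = ["rs12913832", "rsB", "rs12913832:rsB"]
        imp = variable_importance(fit, names, ["rs12913832", "rsB"])
        assert imp["rsB"] == pytest.approx(1.5 - 1.0)  # 0.5 interaction share
        assert imp["rs12913832"] == pytest.approx(1.5)  # main 1.0 + 0.5

    def test_all_zero_fit_gives_zero_vector(self):
        fit = LassoFit(
            family="gaussian", lambda_=0.1, lambdas=np.array([0.1]),
            coef_std=np.zeros(3), intercept=0.0,
            cv_mean=np.zeros(1), cv_se=np.zeros(1), lambda_min=0.1,
        )
        imp = variable_importance(fit, ["a", "b", "c"], ["a", "b", "c"])
        assert (imp == 0).all()


class TestRankVariants:
    @pytest.fixture(scope="class")
    def ranked(self):
        from ec11.panels import builtin_panel

        cohort = simulate_cohort(paper_like_config(400, seed=21))
        table = rank_variants(cohort, builtin_panel("discovery44"), n_reps=3, seed=2)
        return table

    def test_seven_models_per_replicate(self, ranked):
        models = ranked.per_model.index.get_level_values("model").unique()
        assert len(models) == 7
        assert set(models) == {m.label for m in SEVEN_MODELS}

    def test_importances_standardised_within_cells(self, ranked):
        sums = ranked.per_model.sum(axis=1)
        nonzero = sums[sums > 0]
        assert np.allclose(nonzero, 1.0, atol=1e-9)
        assert (sums <= 1.0 + 1e-9).all()

    def test_mean_importance_sums_to_at_most_one(self, ranked):
        assert ranked.mean_importance.sum() <= 1.0 + 1e-9

    def test_ranks_are_a_permutation(self, ranked):
        r = sorted(ranked.rank)
        assert r == list(range(1, len(ranked.rank) + 1))

    def test_strong_dominant_variant_ranks_first(self, ranked):
        assert ranked.rank["rs12913832"] == 1
        assert ranked.mean_importance["rs12913832"] > 0.5

    def test_deterministic(self):
        from ec11.panels import builtin_panel

        cohort = simulate_cohort(paper_like_config(150, seed=33))
        panel = builtin_panel("discovery44")
        t1 = rank_variants(cohort, panel, n_reps=1, seed=4)
        t2 = rank_variants(cohort, panel, n_reps=1, seed=4)
        pd.testing.assert_frame_equal(t1.per_model, t2.per_model)

    def test_test_errors_recorded(self, ranked):
        assert len(ranked.test_errors) == 3 * 7
        assert ranked.test_errors["test_error"].notna().all()


class TestNullModel:
    def test_noise_cohort_shows_no_dominant_variable(self):
        """With no genotype-phenotype signal, the lasso cells select
        nothing (the 1-SE rule collapses to the intercept) and no variable
        accumulates anywhere near the importance a causal variant earns.
        (Tree cells do split on noise occasionally — an inherent property
        of CART at cp=0.01 — so small nonzero importances remain.)"""
        from ec11.panels import builtin_panel
        from ec11.simulate import EffectModel, SimulationConfig

        panel = builtin_panel("discovery44")
        null = EffectModel(intercept=0.0, noise_sd=1.0)
        cohort = simulate_cohort(SimulationConfig(750, panel, null, seed=1))
        table = rank_variants(cohort, panel, n_reps=5, seed=1)
        lasso_cells = table.per_model[
            table.per_model.index.get_level_values("model").str.contains("lasso")
        ]
        frac_empty = (lasso_cells.sum(axis=1) == 0).mean()
        assert frac_empty >= 0.5
        assert table.mean_importance.max() < 0.2


class TestSelectTop:
    def test_printed_importance_table_selects_eleven(self):
        """The published mean importances with the 0.3% cutoff keep 11
        variables (the last, at exactly 0.32%, makes the cut)."""
        printed = {
            "rs12913832": 0.7463,
            "rs121918166+rs74653330": 0.0854,
            "rs16891982": 0.0623,
            "rs1800407": 0.0526,
            "rs1408799": 0.0154,
            "rs4904927": 0.0119,
            "rs12896399": 0.0068,
            "rs1126809": 0.0047,
            "rs7120151": 0.0046,
            "rs10131374": 0.0032,
            "rs1800401": 0.0032,
            # below the cutoff
            "rs1393350": 0.0028,
            "rs62008729": 0.0011,
        }
        table = _table_from_means(printed)
        selected = select_top(table, cutoff=0.003)
        assert len(selected) == 11
        assert "rs1393350" not in selected
        assert selected[0] == "rs12913832"

    def test_cutoff_one_empty(self):
        table = _table_from_means({"a": 0.9, "b": 0.1})
        assert select_top(table, cutoff=1.0) == []

    def test_cutoff_zero_selects_all_in_rank_order(self):
        table = _table_from_means({"a": 0.2, "b": 0.7, "c": 0.1})
        assert select_top(table, cutoff=0.0) == ["b", "a", "c"]


def _table_from_means(means: dict):
    from ec11.ranking import ImportanceTable

    s = pd.Series(means)
    order = s.sort_values(ascending=False, kind="stable")
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.index).reindex(s.index)
    return ImportanceTable(
        per_model=pd.DataFrame([s], index=pd.MultiIndex.from_tuples(
            [(0, "quantitative/lasso_main")], names=["replicate", "model"])),
        mean_importance=s,
        rank=rank,
        test_errors=pd.DataFrame(),
        n_replicates=1,
    )
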