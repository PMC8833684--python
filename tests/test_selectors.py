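"""Selector contracts: subset validity, determinism, oracle agreement."""

import itertools

import numpy as np
import pytest

from efsbench.catalog_io import FeatureTable
from efsbench.classify import CVScheme, balanced_accuracy, fit_lda, predict
from efsbench.selectors import (
    GAParams,
    HAFFParams,
    HCFRParams,
    RFEParams,
    SDAParams,
    _sda_design,
    _sda_solve,
    dual_phase,
    ga_fitness,
    haff_filter,
    select_ga,
    select_hcfr,
    select_random,
    select_rfe,
    select_rfe_cv_auto,
    select_sda,
)
from efsbench.synthetic import planted_config, simulate_dataset


def _table(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return FeatureTable(
        [str(i) for i in range(len(values))],
        [f"{prefix}{j}" for j in range(values.shape[1])],
        values,
    )


class TestRandom:
    def test_full_p_returns_all_features(self, study_table):
        res = select_random(study_table, study_table.n_features, seed=1)
        assert res.selected == study_table.feature_names

    def test_returns_p_distinct_names(self, study_table):
        res = select_random(study_table, 10, seed=3)
        assert len(res.selected) == len(set(res.selected)) == 10
        assert set(res.selected) <= set(study_table.feature_names)

    def test_p_out_of_range_rejected(self, study_table):
        with pytest.raises(ValueError):
            select_random(study_table, 121, seed=0)

    def test_selection_frequencies_are_uniform(self, study_table):
        """Over many seeded draws of p=10 from d=120 every feature's
        frequency stays within 3 binomial standard errors of 1/12."""
        R, p, d = 10000, 10, 120
        counts = np.zeros(d)
        for seed in range(R):
            res = select_random(study_table, p, seed=seed)
            for f in res.selected:
                counts[study_table.feature_names.index(f)] += 1
        frac = counts / R
        se = np.sqrt((p / d) * (1 - p / d) / R)
        assert np.all(np.abs(frac - p / d) <= 3.3 * se)


class TestHCFR:
    def test_duplicate_pairs_collapse_to_one_representative_each(self, rng):
        a = rng.standard_normal(50)
        c = rng.standard_normal(50)
        e = rng.standard_normal(50)
        table = _table(np.column_stack([a, a, c, c, e]))
        res = select_hcfr(table, HCFRParams(0.95, seed=0))
        assert len(res.selected) == 3
        assert len({f for f in res.selected} & {"g0", "g1"}) == 1
        assert len({f for f in res.selected} & {"g2", "g3"}) == 1

    def test_independent_features_all_kept(self, rng):
        X = rng.standard_normal((500, 8))
        table = _table(X)
        C = np.abs(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(C, 0)
        assert C.max() < 0.95  # fixture sanity
        res = select_hcfr(table, HCFRParams(0.95, seed=0))
        assert sorted(res.selected) == sorted(table.feature_names)

    def test_pairwise_bound_holds_on_study_data(self, study_table):
        res = select_hcfr(study_table, HCFRParams(0.95, seed=4))
        sub = study_table.subset(res.selected)
        C = np.abs(np.corrcoef(sub.values, rowvar=False))
        np.fill_diagonal(C, 0)
        assert C.max() <= 0.95

    def test_constant_feature_becomes_own_cluster(self, rng):
        X = rng.standard_normal((40, 3))
        X[:, 1] = 2.5
        res = select_hcfr(_table(X), HCFRParams(0.95, seed=0))
        assert "g1" in res.selected
        assert res.details["constant_features"] == ["g1"]


class TestRFE:
    def test_target_d_returns_everything_with_empty_trace(self, study_table, study_labels):
        res = select_rfe(study_table, study_labels.task("pathologic"),
                         RFEParams(target_p=120))
        assert res.selected == study_table.feature_names
        assert res.trace == []

    def test_recovers_single_planted_feature(self, small_planted):
        table, y = small_planted
        res = select_rfe(table, y, RFEParams(target_p=1))
        assert res.selected == [table.feature_names[-1]]

    def test_trace_counts_strictly_decreasing_with_step_arithmetic(self, small_planted):
        table, y = small_planted
        res = select_rfe(table, y, RFEParams(target_p=5))
        counts = [c for c, _, _ in res.trace]
        assert counts == list(range(20, 5, -1))

    def test_elimination_is_nested_across_targets(self, small_planted):
        table, y = small_planted
        big = select_rfe(table, y, RFEParams(target_p=10))
        small = select_rfe(table, y, RFEParams(target_p=3))
        assert set(small.selected) <= set(big.selected)

    def test_cv_variant_records_fold_sd(self, small_planted):
        table, y = small_planted
        res = select_rfe(table, y, RFEParams(target_p=15, cv=CVScheme(3, True, 0)))
        assert res.selector_name == "RFECV"
        assert any(sd > 0 for _, _, sd in res.trace)


class TestRFECVAuto:
    def test_zero_trade_off_picks_best_mean_smallest_count(self, small_planted):
        table, y = small_planted
        res = select_rfe_cv_auto(table, y, CVScheme(3, True, 1), trade_off_sd=0.0)
        means = {c: m for c, m, _ in res.trace}
        best = max(means.values())
        assert res.details["chosen_count"] == min(
            c for c, m in means.items() if m == best
        )

    def test_flat_noise_path_prefers_minimum_count(self):
        table, labels = simulate_dataset(
            planted_config(15, 0, effect_size=0.0, n_samples=80, seed=5)
        )
        res = select_rfe_cv_auto(table, labels.task("pathologic"),
                                 CVScheme(3, True, 5), trade_off_sd=2.0)
        assert res.details["chosen_count"] == 1

    def test_planted_feature_survives_auto_selection(self, small_planted):
        table, y = small_planted
        res = select_rfe_cv_auto(table, y, CVScheme(5, True, 6), trade_off_sd=1.0)
        assert table.feature_names[-1] in res.selected


class TestHAFF:
    def test_removes_exactly_one_member_of_injected_pair(self, rng):
        X = rng.standard_normal((100, 6))
        X[:, 1] = -X[:, 0] + 0.05 * rng.standard_normal(100)  # r < -0.99
        y = (X[:, 2] > 0).astype(int)
        res = haff_filter(_table(X), y, HAFFParams(0.95))
        assert len(res.selected) == 5
        assert len({"g0", "g1"} & set(res.selected)) == 1
        assert {"g2", "g3", "g4", "g5"} <= set(res.selected)

    def test_identity_when_no_anti_pairs(self, rng):
        X = rng.standard_normal((80, 5))
        y = (X[:, 0] > 0).astype(int)
        res = haff_filter(_table(X), y, HAFFParams(0.95))
        assert res.selected == [f"g{j}" for j in range(5)]
        assert res.trace == []

    def test_output_correlation_floor_on_study_data(self, study_table, study_labels):
        res = haff_filter(study_table, study_labels.task("pathologic"),
                          HAFFParams(0.95))
        sub = study_table.subset(res.selected)
        C = np.corrcoef(sub.values, rowvar=False)
        assert C.min() >= -0.95
        assert len(res.details["removed"]) == 2  # one per injected anti-pair


class TestSDA:
    def test_lambda_above_null_threshold_gives_empty_support(self, study_table, study_labels):
        y = study_labels.task("pathologic")
        Z, yc = _sda_design(study_table, np.asarray(y))
        lam_null = 2 * float(np.max(np.abs(Z.T @ yc)))
        beta = _sda_solve(Z, yc, lam_null * 1.01, 0.1)
        assert np.count_nonzero(beta) == 0

    def test_unpenalized_solution_matches_normal_equations(self, study_table, study_labels):
        y = study_labels.task("pathologic")
        res = select_sda(study_table, y, SDAParams(target_p=120, gamma=0.0))
        beta = res.details["beta"]
        Z, yc = _sda_design(study_table, np.asarray(y))
        oracle = np.linalg.pinv(Z.T @ Z) @ (Z.T @ yc)
        cos = beta @ oracle / (np.linalg.norm(beta) * np.linalg.norm(oracle))
        assert cos > 0.999

    def test_bisection_hits_exact_cardinality(self, study_table, study_labels):
        y = study_labels.task("pathologic_with_ECS")
        res = select_sda(study_table, y, SDAParams(target_p=10))
        assert len(res.selected) == 10
        beta = res.details["beta"]
        assert np.count_nonzero(np.abs(beta) > 1e-10) == 10

    def test_support_monotone_along_lambda_grid(self, study_table, study_labels):
        """Support size shrinks with the L1 penalty: exactly monotone when
        the ridge term dominates; at weak ridge the lasso path may re-admit
        the odd feature locally, so only near-monotonicity is guaranteed."""
        y = study_labels.task("pathologic")
        Z, yc = _sda_design(study_table, np.asarray(y))
        lam_null = 2 * float(np.max(np.abs(Z.T @ yc)))
        grid = np.geomspace(lam_null * 1e-4, lam_null, 12)
        strong = [
            np.count_nonzero(np.abs(_sda_solve(Z, yc, lam, 1.0)) > 1e-10)
            for lam in grid
        ]
        assert all(a >= b for a, b in zip(strong, strong[1:]))
        weak = [
            np.count_nonzero(np.abs(_sda_solve(Z, yc, lam, 0.1)) > 1e-10)
            for lam in grid
        ]
        assert all(a >= b - 2 for a, b in zip(weak, weak[1:]))
        assert weak[0] > weak[-1]

    def test_unreachable_cardinality_warns(self, study_table, study_labels):
        y = study_labels.task("pathologic")
        Z, yc = _sda_design(study_table, np.asarray(y))
        hi = 2 * float(np.max(np.abs(Z.T @ yc))) * 1.001
        res = select_sda(
            study_table, y,
            SDAParams(target_p=5, lambda_bracket=(hi * 0.999, hi)),
        )
        assert "cardinality_miss" in res.details


class TestGA:
    def test_fitness_penalizes_cardinality_excess_only(self, small_planted):
        table, y = small_planted
        params = GAParams(target_p=5)
        scheme = CVScheme(3, True, 0)
        d = table.n_features
        small = np.zeros(d, bool); small[:5] = True
        big = np.zeros(d, bool); big[:10] = True
        f_small = ga_fitness(small, table, y, params, scheme)
        f_big = ga_fitness(big, table, y, params, scheme)
        # same-accuracy check is data dependent; the penalty term alone
        # must separate the two by at least (10-5) - |bacc difference|
        assert f_big - f_small > 5 - 1.0

    def test_empty_mask_scores_chance(self, small_planted):
        table, y = small_planted
        # c1 = 0 and c2 pinned at chance (-0.5), minimized objective
        f = ga_fitness(np.zeros(table.n_features, bool), table, y,
                       GAParams(target_p=5), CVScheme(3, True, 0))
        assert f == pytest.approx(-0.5)

    def test_masks_at_or_below_target_unpenalized(self, small_planted):
        table, y = small_planted
        params = GAParams(target_p=5)
        scheme = CVScheme(3, True, 0)
        mask = np.zeros(table.n_features, bool)
        mask[:3] = True
        from efsbench.classify import cv_bacc

        expected = -cv_bacc(table.values[:, mask], y, scheme).mean
        assert ga_fitness(mask, table, y, params, scheme) == pytest.approx(expected)

    def test_printed_min_penalty_form_available(self, small_planted):
        table, y = small_planted
        scheme = CVScheme(3, True, 0)
        mask = np.zeros(table.n_features, bool)
        mask[:3] = True
        f_corr = ga_fitness(mask, table, y, GAParams(target_p=5), scheme)
        f_prin = ga_fitness(
            mask, table, y, GAParams(target_p=5, penalty_form="printed_min"), scheme
        )
        assert f_prin == pytest.approx(f_corr - 2)  # min(3-5,0) = -2

    def test_seeded_run_is_reproducible(self, small_planted):
        table, y = small_planted
        params = GAParams(target_p=3, population=20, generations=15, seed=11)
        scheme = CVScheme(3, True, 11)
        r1 = select_ga(table, y, params, scheme)
        r2 = select_ga(table, y, params, scheme)
        assert r1.selected == r2.selected
        assert r1.details["best_fitness"] == r2.details["best_fitness"]

    def test_generation_best_fitness_never_worsens(self, small_planted):
        table, y = small_planted
        res = select_ga(table, y,
                        GAParams(target_p=3, population=20, generations=20, seed=2),
                        CVScheme(3, True, 2))
        best = res.details["best_fitness_per_generation"]
        assert all(a >= b for a, b in zip(best, best[1:]))

    def test_matches_exhaustive_enumeration_on_small_problem(self):
        table, labels = simulate_dataset(
            planted_config(10, 2, n_samples=60, seed=4)
        )
        y = labels.task("pathologic")
        params = GAParams(target_p=3, population=30, generations=80, seed=4)
        scheme = CVScheme(3, True, 4)
        res = select_ga(table, y, params, scheme)
        best = min(
            ga_fitness(np.array(bits, bool), table, y, params, scheme)
            for bits in itertools.product([0, 1], repeat=10)
        )
        assert res.details["best_fitness"] == pytest.approx(best, abs=1e-12)

    def test_tiny_population_rejected(self, small_planted):
        table, y = small_planted
        with pytest.raises(ValueError):
            select_ga(table, y, GAParams(target_p=3, population=2),
                      CVScheme(3, True, 0))


class TestDualPhase:
    def test_composition_contract(self, small_planted):
        table, y = small_planted
        res = dual_phase(
            table, y, "SDA", 10,
            GAParams(target_p=3, population=20, generations=20),
            CVScheme(3, True, 0), seed=0,
        )
        assert res.selector_name == "SDA10GA3_nohaff_BACC"
        assert len(res.selected) <= 10
        assert set(res.selected) <= set(table.feature_names)

    def test_phase1_target_d_degenerates_to_plain_ga(self):
        table, labels = simulate_dataset(planted_config(12, 2, n_samples=60, seed=2))
        y = labels.task("pathologic")
        ga = GAParams(target_p=3, population=20, generations=30)
        scheme = CVScheme(3, True, 2)
        dp = dual_phase(table, y, "RFE", 12, ga, scheme, seed=9)
        plain = select_ga(table, y, GAParams(**{**ga.__dict__, "seed": 9}), scheme)
        assert dp.selected == plain.selected

    def test_invalid_phase_order_rejected(self, small_planted):
        table, y = small_planted
        with pytest.raises(ValueError):
            dual_phase(table, y, "SDA", 2, GAParams(target_p=5),
                       CVScheme(3, True, 0))
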