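"""TSTR harness: task construction, CV evaluation, rank and prediction stability."""

import itertools

import numpy as np
import pytest
from scipy.stats import kendalltau

from synthehr.refine import refine_for_prediction
from synthehr.runner import split_cohort
from synthehr.simulate import SimConfig, simulate_cohort
from synthehr.tstr import (
    auroc_by_group,
    build_task,
    hyperbolic_weighted_tau,
    prediction_distribution_stability,
    run_tstr,
)

from conftest import record, small_catalog, toy_cohort


class TestBuildTask:
    def test_pre_anchor_history_included(self):
        cohort = toy_cohort(
            [record("a", "female", [(55, {"HTN"}), (60, {"DM"}), (70, {"CKD"})])]
        )
        task = build_task(cohort)
        i = task.feature_names.index("HTN")
        assert task.X[0, i] == 1.0 and task.y[0]

    def test_post_anchor_comorbidity_excluded(self):
        cohort = toy_cohort(
            [record("a", "female", [(60, {"DM"}), (65, {"HTN"})])]
        )
        task = build_task(cohort)
        i = task.feature_names.index("HTN")
        assert task.X[0, i] == 0.0 and task.X[0, i + 1] == -1.0

    def test_endpoint_never_a_feature(self, small_cohort):
        task = build_task(small_cohort)
        assert "CKD" not in task.feature_names
        assert "age_CKD" not in task.feature_names

    def test_leakage_guard_perturbation_oracle(self, small_cohort):
        pred, _ = refine_for_prediction(small_cohort)
        task = build_task(pred)
        # delete every post-anchor visit and rebuild: features must not change
        stripped = []
        for r in pred.records:
            anchor_age = r.first_age_of(pred.anchor_code)
            visits = tuple(v for v in r.visits if v.effective_age <= anchor_age)
            stripped.append(
                type(r)(id=r.id, sex=r.sex, visits=visits, diagnosis_year=r.diagnosis_year)
            )
        task2 = build_task(pred.with_records(stripped))
        assert np.array_equal(task.X, task2.X)

    def test_label_variation_check(self):
        cohort = toy_cohort([record("a", "female", [(60, {"DM"})])])
        with pytest.raises(ValueError):
            build_task(cohort, require_label_variation=True)


@pytest.fixture(scope="module")
def tasks():
    cohort = simulate_cohort(SimConfig(n_patients=3000, diseases=small_catalog(), seed=17))
    pred, _ = refine_for_prediction(cohort)
    train, test = split_cohort(pred, 0.8, 0)
    return build_task(train), build_task(test)


class TestRunTSTR:
    def test_separable_task_near_perfect_auroc(self):
        # a feature that determines the endpoint exactly
        recs = []
        for i in range(300):
            sick = i % 2 == 0
            visits = [(50, {"DM", "HTN"} if sick else {"DM"})]
            if sick:
                visits.append((60, {"CKD"}))
            recs.append(record(f"r{i}", "female", visits))
        task = build_task(toy_cohort(recs))
        res = run_tstr(task, None, task, scenario="real", cv=(1, 4), seed=0)
        assert res.mean_auroc > 0.99

    def test_shuffled_labels_near_half(self, tasks):
        train, test = tasks
        rng = np.random.default_rng(0)
        shuffled = type(train)(
            X=train.X,
            y=rng.permutation(train.y),
            feature_names=train.feature_names,
            sex=train.sex,
            diagnosis_year=train.diagnosis_year,
        )
        res = run_tstr(shuffled, None, test, scenario="real", cv=(1, 3), seed=0)
        assert abs(res.mean_auroc - 0.5) < 0.06

    def test_synthetic_copy_matches_real_scenario(self, tasks):
        train, test = tasks
        real = run_tstr(train, None, test, scenario="real", cv=(1, 4), seed=0)
        synth = run_tstr(train, train, test, scenario="synthetic", cv=(1, 4), seed=0)
        assert abs(real.mean_auroc - synth.mean_auroc) < 3 * (real.sd_auroc + synth.sd_auroc) + 0.01

    def test_unknown_scenario_rejected(self, tasks):
        train, test = tasks
        with pytest.raises(ValueError):
            run_tstr(train, None, test, scenario="imaginary")

    def test_year_trend_recovered_with_year_dependent_label_noise(self):
        cfg = SimConfig(
            n_patients=8000, diseases=small_catalog(), seed=23,
            year_range=(2003, 2010), label_noise_by_year=(0.45, 0.0),
        )
        cohort = simulate_cohort(cfg)
        pred, _ = refine_for_prediction(cohort)
        train, test = split_cohort(pred, 0.8, 0)
        res = run_tstr(build_task(train), None, build_task(test), scenario="real", cv=(1, 3), seed=0)
        test_task = build_task(test)
        by_year = auroc_by_group(
            res.full_probabilities, test_task.y, test_task.diagnosis_year
        ).dropna()
        rho = kendalltau(by_year["group"], by_year["auroc"])[0]
        assert rho > 0.4  # noisier early years -> lower AUROC early on

    def test_by_sex_strata(self, tasks):
        train, test = tasks
        res = run_tstr(train, None, test, scenario="real", cv=(1, 3), seed=0)
        table = auroc_by_group(res.full_probabilities, test.y, test.sex)
        assert set(table["group"]) == {"female", "male"}
        assert table["auroc"].notna().all()


class TestHyperbolicWeightedTau:
    def test_identical_rankings_one(self):
        assert hyperbolic_weighted_tau(list("abcd"), list("abcd")) == 1.0

    def test_reversed_rankings_minus_one(self):
        assert hyperbolic_weighted_tau(list("abcd"), list("dcba")) == pytest.approx(-1.0)

    def test_top_disagreement_penalized_more(self):
        base = list("abcdef")
        swap_top = ["b", "a"] + base[2:]
        swap_bottom = base[:4] + ["f", "e"]
        assert hyperbolic_weighted_tau(base, swap_top) < hyperbolic_weighted_tau(base, swap_bottom)

    def test_all_permutations_of_four_match_brute_force(self):
        items = list("abcd")

        def oracle(pa, pb):
            # direct definition: symmetrized weighted concordance
            def side(ref, other):
                num = den = 0.0
                for u, v in itertools.combinations(items, 2):
                    w = 1.0 / (1 + ref[u]) + 1.0 / (1 + ref[v])
                    s = np.sign((ref[u] - ref[v]) * (other[u] - other[v]))
                    num += w * s
                    den += w
                return num / den

            return 0.5 * (side(pa, pb) + side(pb, pa))

        for perm in itertools.permutations(items):
            pa = {x: i for i, x in enumerate(items)}
            pb = {x: i for i, x in enumerate(perm)}
            got = hyperbolic_weighted_tau(items, list(perm))
            assert got == pytest.approx(oracle(pa, pb), abs=1e-12)

    def test_equal_weights_reduce_to_kendall_tau(self):
        rng = np.random.default_rng(1)
        items = [f"f{i}" for i in range(12)]
        for _ in range(20):
            perm = list(rng.permutation(items))
            got = hyperbolic_weighted_tau(items, perm, weighted=False)
            ranks_a = np.arange(len(items))
            ranks_b = np.array([perm.index(x) for x in items])
            expect = kendalltau(ranks_a, ranks_b)[0]
            assert got == pytest.approx(expect, abs=1e-12)

    def test_mismatched_item_sets_rejected(self):
        with pytest.raises(ValueError):
            hyperbolic_weighted_tau(["a", "b"], ["a", "c"])


class TestPredictionStability:
    def test_identical_models_zero_differences(self):
        p = np.array([0.2, 0.6, 0.9])
        out = prediction_distribution_stability([p, p], p)
        assert all(v == 0.0 for v in out.values())

    def test_constant_offset_model(self):
        p = np.array([0.2, 0.6, 0.9])
        out = prediction_distribution_stability([p + 0.05], p)
        assert out["q50"] == pytest.approx(0.05)

    def test_stable_simulated_task_median_near_zero(self, tasks):
        train, test = tasks
        res = run_tstr(train, None, test, scenario="real", cv=(1, 4), seed=0)
        out = prediction_distribution_stability(res.cv_probabilities, res.full_probabilities)
        assert abs(out["q50"]) < 0.01
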