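"""Fidelity metrics: worked examples, brute-force oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

from synthehr.fidelity import (
    boundary_adherence,
    category_adherence,
    contingency_similarity,
    cooccurrence_correlation,
    correlation_similarity,
    cramers_v,
    ks_complement,
    sliced_wasserstein,
    tv_complement,
)
from synthehr.records import BOOLEAN, CATEGORICAL, CONTINUOUS, PatientFeatureTable

from conftest import record, toy_cohort


def table(df, schema):
    return PatientFeatureTable(frame=df.reset_index(drop=True), schema=schema)


def cont(values, name="x"):
    return table(pd.DataFrame({name: values}, dtype=float), {name: CONTINUOUS})


def cat(values, name="c"):
    return table(pd.DataFrame({name: values}), {name: CATEGORICAL})


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def ks_oracle(x, y):
    """Max ECDF gap by scanning every observed value."""
    best = 0.0
    for v in set(x) | set(y):
        fx = sum(xi <= v for xi in x) / len(x)
        fy = sum(yi <= v for yi in y) / len(y)
        best = max(best, abs(fx - fy))
    return best


def tvd_oracle(a, b):
    cats = set(a) | set(b)
    return 0.5 * sum(abs(a.count(c) / len(a) - b.count(c) / len(b)) for c in cats)


def cramers_v_oracle(x, y):
    xs, ys = sorted(set(x)), sorted(set(y))
    n = len(x)
    chi2 = 0.0
    for xv in xs:
        for yv in ys:
            obs = sum(1 for a, b in zip(x, y) if a == xv and b == yv)
            exp = x.count(xv) * y.count(yv) / n
            if exp > 0:
                chi2 += (obs - exp) ** 2 / exp
    k = min(len(xs), len(ys)) - 1
    return 0.0 if k < 1 else np.sqrt(chi2 / (n * k))


class TestWorkedExamples:
    def test_boundary_adherence_fraction(self):
        r = cont([0.0, 1.0, 2.0, 3.0])
        s = cont([0.5, 1.5, 2.5, 9.0])  # one of four outside [0, 3]
        assert boundary_adherence(r, s).score == 0.75

    def test_boundary_missing_invalid_when_real_complete(self):
        r = cont([0.0, 1.0])
        s = cont([0.5, np.nan])
        assert boundary_adherence(r, s).score == 0.5

    def test_category_new_category_half_rows(self):
        r = cat(["a", "a", "b", "b"])
        s = cat(["a", "z", "b", "z"])
        assert category_adherence(r, s).score == 0.5

    def test_boolean_column_all_valid(self):
        r = table(pd.DataFrame({"f": [True, False]}), {"f": BOOLEAN})
        s = table(pd.DataFrame({"f": [False, False]}), {"f": BOOLEAN})
        assert category_adherence(r, s).score == 1.0

    def test_ks_complement_worked_example(self):
        assert ks_complement(cont([1, 2, 3, 4]), cont([1, 2, 3, 10])).score == 0.75

    def test_ks_disjoint_supports(self):
        assert ks_complement(cont([0, 0, 0]), cont([1, 1, 1])).score == 0.0

    def test_tv_complement_worked_example(self):
        r = cat(["a"] * 6 + ["b"] * 4)
        s = cat(["a"] * 4 + ["b"] * 6)
        assert tv_complement(r, s).score == pytest.approx(0.8)

    def test_tv_disjoint_categories(self):
        assert tv_complement(cat(["a", "a"]), cat(["b", "b"])).score == 0.0

    def test_correlation_similarity_formula(self):
        # construct pairs with r_real = 1 and r_synth = -1 -> score 0
        df_r = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [0.0, 1, 2, 3]})
        df_s = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [3.0, 2, 1, 0]})
        schema = {"x": CONTINUOUS, "y": CONTINUOUS}
        assert correlation_similarity(table(df_r, schema), table(df_s, schema)).score == pytest.approx(0.0)

    def test_contingency_sign_flip(self):
        # perfectly associated 2x2 in real vs independent-ish synth -> near 0
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 400).astype(bool)
        df_r = pd.DataFrame({"u": a, "v": a})
        b = rng.integers(0, 2, 400).astype(bool)
        df_s = pd.DataFrame({"u": rng.integers(0, 2, 400).astype(bool), "v": b})
        schema = {"u": BOOLEAN, "v": BOOLEAN}
        score = contingency_similarity(table(df_r, schema), table(df_s, schema)).score
        assert score < 0.15

    def test_single_level_pair_degenerate_v_zero(self):
        df = pd.DataFrame({"u": [True] * 5, "v": [True] * 5})
        schema = {"u": BOOLEAN, "v": BOOLEAN}
        assert contingency_similarity(table(df, schema), table(df, schema)).score == 1.0


class TestOracleEquivalence:
    def test_ks_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(size=rng.integers(5, 50)).round(2)
            y = rng.normal(size=rng.integers(5, 50)).round(2)
            got = ks_complement(cont(x), cont(y)).score
            assert got == pytest.approx(1.0 - ks_oracle(list(x), list(y)), abs=1e-12)

    def test_tv_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = list(rng.choice(list("abcd"), size=rng.integers(5, 50)))
            b = list(rng.choice(list("abce"), size=rng.integers(5, 50)))
            got = tv_complement(cat(a), cat(b)).score
            assert got == pytest.approx(1.0 - tvd_oracle(a, b), abs=1e-12)

    def test_cramers_v_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(10, 50))
            x = list(rng.choice(list("abc"), size=n))
            y = list(rng.choice(list("xy"), size=n))
            got = cramers_v(pd.Series(x), pd.Series(y))
            assert got == pytest.approx(cramers_v_oracle(x, y), abs=1e-12)


class TestIdentityAndInvariance:
    def _tables(self, cohort):
        from synthehr.records import flatten

        return flatten(cohort)

    def test_row_permutation_scores_perfect(self, small_cohort):
        from synthehr.records import flatten

        real = flatten(small_cohort)
        perm = np.random.default_rng(0).permutation(len(real))
        synth = PatientFeatureTable(
            real.frame.iloc[perm].reset_index(drop=True), real.schema
        )
        assert boundary_adherence(real, synth).score == 1.0
        assert category_adherence(real, synth).score == 1.0
        assert ks_complement(real, synth).score == 1.0
        assert tv_complement(real, synth).score == 1.0
        assert sliced_wasserstein(real, synth, n_directions=50, seed=0).score == pytest.approx(0.0, abs=1e-12)

    def test_metrics_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        r = cont(rng.normal(size=30))
        s_vals = rng.normal(size=30)
        s1 = cont(s_vals)
        s2 = cont(s_vals[::-1].copy())
        assert ks_complement(r, s1).score == ks_complement(r, s2).score

    def test_ks_monotone_degradation_under_noise(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=400)
        r = cont(base)
        prev = 1.0
        noise = rng.uniform(-1, 1, size=400)
        for amp in [0.0, 0.5, 1.0, 2.0, 4.0]:
            s = cont(base + amp * noise)
            score = ks_complement(r, s).score
            assert score <= prev + 1e-9
            prev = score


class TestSlicedWasserstein:
    def test_point_masses_match_monte_carlo_oracle(self):
        # single informative feature: real is (almost) a point mass at 0 (one
        # row at 1 fixes the normalization range), synth a point mass at 1;
        # each direction u then contributes |u| * 20/21 to the 1D distance
        df_r = pd.DataFrame({"x": [0.0] * 20 + [1.0], "y": [1.0] * 21})
        df_s = pd.DataFrame({"x": [1.0] * 21, "y": [1.0] * 21})
        # y has zero range in real data -> excluded, single projection dim
        schema = {"x": CONTINUOUS, "y": CONTINUOUS}
        res = sliced_wasserstein(table(df_r, schema), table(df_s, schema), 500, seed=8)
        rng = np.random.default_rng(8)
        dirs = rng.normal(size=(500, 1))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        expect = np.abs(dirs[:, 0]).mean() * 20 / 21
        assert res.score == pytest.approx(expect, abs=1e-12)

    def test_direction_count_changes_within_monte_carlo_error(self):
        rng = np.random.default_rng(6)
        df_r = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        df_s = pd.DataFrame(rng.normal(0.3, 1.2, size=(100, 3)), columns=list("abc"))
        schema = {c: CONTINUOUS for c in "abc"}
        d1 = sliced_wasserstein(table(df_r, schema), table(df_s, schema), 400, seed=0).score
        d2 = sliced_wasserstein(table(df_r, schema), table(df_s, schema), 800, seed=1).score
        assert abs(d1 - d2) < 0.02


class TestCooccurrence:
    def test_identity_scores_one(self, small_cohort):
        assert cooccurrence_correlation(small_cohort, small_cohort).score == pytest.approx(1.0)

    def test_reversed_trajectories_negative_correlation(self):
        fwd, rev = [], []
        for i in range(30):
            fwd.append(record(f"f{i}", "female", [(40, {"HTN"}), (50, {"OBE"}), (60, {"DEP"})]))
            rev.append(record(f"r{i}", "female", [(40, {"DEP"}), (50, {"OBE"}), (60, {"HTN"})]))
        # a little asymmetry so frequencies are not all equal
        fwd.append(record("fx", "male", [(40, {"HTN"}), (50, {"DEP"})]))
        rev.append(record("rx", "male", [(40, {"DEP"}), (50, {"HTN"})]))
        a, b = toy_cohort(fwd), toy_cohort(rev)
        assert cooccurrence_correlation(a, b).score < 0

    def test_precedence_frequency_matches_brute_force(self):
        recs = [
            record("a", "female", [(40, {"HTN"}), (50, {"OBE", "DEP"})]),
            record("b", "male", [(40, {"OBE"}), (50, {"HTN"})]),
            record("c", "female", [(40, {"HTN", "OBE"})]),
        ]
        cohort = toy_cohort(recs)
        from synthehr.fidelity import _precedence_frequencies

        f = _precedence_frequencies(cohort)
        # brute force over ordered pairs of the 4 non-anchor codes
        codes = [c for c in cohort.vocabulary if c != "DM"]
        expected = []
        for a in codes:
            for b in codes:
                if a == b:
                    continue
                count = 0
                for r in recs:
                    fa = next((i for i, v in enumerate(r.visits) if a in v.codes), None)
                    fb = next((i for i, v in enumerate(r.visits) if b in v.codes), None)
                    if fa is not None and fb is not None and fa < fb:
                        count += 1
                expected.append(count / len(recs))
        # same-visit pairs count for neither direction
        assert np.allclose(sorted(f), sorted(expected))

    def test_no_multicode_patients_flagged_undefined(self):
        a = toy_cohort([record("a", "female", [(50, {"DM"})])])
        assert not cooccurrence_correlation(a, a).defined


class TestDegenerateInputs:
    def test_no_continuous_columns_flagged(self):
        r = cat(["a", "b"])
        res = boundary_adherence(r, r)
        assert not res.defined and res.notes
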