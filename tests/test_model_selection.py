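"""Model fitting, AICc ranking, support rules, averaging, t test."""

import math

import numpy as np
import pandas as pd
import pytest

from motuskit import (FitResult, aicc, all_subsets, fit_gamma_log, fit_linear,
                      fit_lmm, flag_uninformative, group_t_test, model_average,
                      rank_models, supported_set)
from motuskit.model_selection import run_response_analysis


def _fr(terms, ll, k, n):
    est = {"intercept": 0.0, **{t: 1.0 for t in terms}}
    se = {c: 1.0 for c in est}
    return FitResult(terms=tuple(terms), estimates=est, std_errors=se,
                     loglik=ll, k=k, n=n, family="gaussian_lm")


class TestAicc:
    def test_arithmetic(self):
        assert aicc((-100.0, 3, 20)) == pytest.approx(207.5)

    def test_large_n_limits_to_aic(self):
        val = aicc((-100.0, 3, 10 ** 7))
        assert val == pytest.approx(206.0, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc((-10.0, 5, 6))

    def test_matches_independent_recomputation_for_fits(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"y": rng.normal(10, 2, 40),
                              "x": rng.normal(0, 1, 40)})
        fit = fit_linear(frame, "y", ["x"])
        by_hand = (-2 * fit.loglik + 2 * fit.k
                   + 2 * fit.k * (fit.k + 1) / (fit.n - fit.k - 1))
        assert aicc(fit) == pytest.approx(by_hand, abs=1e-9)


class TestAllSubsets:
    def test_two_terms_give_four_models(self):
        assert sorted(all_subsets(["a", "b"])) == sorted(
            [(), ("a",), ("b",), ("a", "b")])

    def test_marginality_restricts_interaction(self):
        subsets = all_subsets(["a", "b", "a:b"], marginality=True)
        assert len(subsets) == 5
        assert ("a", "b", "a:b") in subsets
        assert all({"a", "b"} <= set(s) for s in subsets if "a:b" in s)

    def test_without_marginality_full_power_set(self):
        assert len(all_subsets(["a", "b", "a:b"], marginality=False)) == 8

    def test_intercept_only_always_present(self):
        for terms in (["a"], ["a", "b", "c"], []):
            assert () in all_subsets(terms)


class TestRanking:
    def test_delta_two_weight_split(self):
        f1 = _fr(("a",), -50.0, 3, 30)
        f2 = _fr(("b",), -50.0 - 1.0, 3, 30)  # exactly 2 higher AICc
        tab = rank_models([f1, f2])
        assert tab["weight"].iloc[0] == pytest.approx(0.7310585, abs=1e-4)
        assert tab["weight"].iloc[1] == pytest.approx(0.2689414, abs=1e-4)

    def test_identical_aicc_equal_weights_and_sum_one(self):
        fits = [_fr(("a",), -50.0, 3, 30), _fr(("b",), -50.0, 3, 30)]
        tab = rank_models(fits)
        assert tab["weight"].iloc[0] == pytest.approx(0.5)
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_differing_n_rejected(self):
        with pytest.raises(ValueError, match="differing row counts"):
            rank_models([_fr(("a",), -50.0, 3, 30), _fr(("b",), -50.0, 3, 31)])


class TestSupportRule:
    def test_joint_rule(self):
        best = _fr(("a",), -50.0, 3, 30)
        near = _fr(("a", "b"), -49.5, 4, 30)        # delta ~ 1.7
        far = _fr(("b",), -51.6, 3, 30)             # delta ~ 3.2
        null = _fr((), -54.0, 2, 30)                # ~5 worse than best
        got = supported_set([best, near, far, null], None)
        assert [f.terms for f in got] == [("a",), ("a", "b")]

    def test_best_is_intercept_only_gives_empty(self):
        null = _fr((), -50.0, 2, 30)
        other = _fr(("a",), -50.0, 3, 30)
        assert supported_set([null, other], None) == []

    def test_close_to_intercept_excluded(self):
        # models within delta 2 but < 2 better than the null all fail
        best = _fr(("a",), -50.3, 3, 30)
        null = _fr((), -51.0, 2, 30)  # null AICc lower than best here
        assert supported_set([best, null], None) == []


class TestUninformative:
    def test_costly_extra_term_flagged(self):
        base = _fr(("age",), -48.0, 3, 30)
        extra = _fr(("age", "sex"), -47.9, 4, 30)  # gains ~0.1 LL for 1 k
        null = _fr((), -60.0, 2, 30)
        flags = flag_uninformative([base, extra, null], [base, extra])
        assert "sex" in flags and "age" not in flags

    def test_beneficial_term_not_flagged(self):
        base = _fr(("age",), -48.0, 3, 30)
        extra = _fr(("age", "tailwind"), -43.0, 4, 30)
        flags = flag_uninformative([base, extra], [base, extra])
        assert "tailwind" not in flags


class TestModelAverage:
    def test_single_model_degeneracy(self):
        m = _fr(("a",), -50.0, 3, 30)
        avg = model_average([m]).set_index("coefficient")
        assert avg.loc["a", "estimate"] == pytest.approx(1.0)
        assert avg.loc["a", "se"] == pytest.approx(1.0)

    def test_zero_substitution(self):
        # coef present (10) in model A, absent in B; renormalized w = .6/.4
        a = FitResult(terms=("x",), estimates={"intercept": 0.0, "x": 10.0},
                      std_errors={"intercept": 1.0, "x": 1.0},
                      loglik=-50.0, k=3, n=30, family="gaussian_lm")
        delta = 2.0 * math.log(0.6 / 0.4)
        # engineer AICc(b) - AICc(a) so that weights are exactly .6/.4
        target = aicc(a) + delta
        ll_b = -(target - 2 * 2 - 2 * 2 * 3 / (30 - 2 - 1)) / 2.0
        b = FitResult(terms=(), estimates={"intercept": 0.0},
                      std_errors={"intercept": 1.0}, loglik=ll_b, k=2, n=30,
                      family="gaussian_lm")
        avg = model_average([a, b]).set_index("coefficient")
        assert avg.loc["x", "estimate"] == pytest.approx(6.0, abs=1e-9)

    def test_empty_supported_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            model_average([])


class TestGroupTTest:
    def test_closed_form(self):
        t, df, p = group_t_test([1, 2, 3, 3, 4, 5],
                                ["a", "a", "a", "b", "b", "b"])
        assert t == pytest.approx(-2.449, abs=0.001)
        assert df == 4

    def test_identical_groups_zero(self):
        t, _, p = group_t_test([1, 2, 3, 1, 2, 3],
                               ["a", "a", "a", "b", "b", "b"])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_label_swap_negates(self):
        vals = [1, 2, 3, 5, 6, 9]
        g1 = ["a", "a", "a", "b", "b", "b"]
        g2 = ["b", "b", "b", "a", "a", "a"]
        assert group_t_test(vals, g1)[0] == pytest.approx(
            -group_t_test(vals, g2)[0])


class TestFitters:
    def test_linear_exact_fit(self):
        frame = pd.DataFrame({"y": [2.0, 4.0, 6.0, 8.0],
                              "x": [1.0, 2.0, 3.0, 4.0]})
        fit = fit_linear(frame, "y", ["x"])
        assert fit.estimates["x"] == pytest.approx(2.0)
        assert fit.k == 3  # intercept + slope + residual variance

    def test_linear_intercept_only(self):
        frame = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0]})
        fit = fit_linear(frame, "y", [])
        assert fit.estimates["intercept"] == pytest.approx(2.5)
        assert fit.k == 2

    def test_rank_deficient_rejected(self):
        frame = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_linear(frame, "y", ["x"])

    def test_gamma_intercept_is_log_mean_for_constant_response(self):
        frame = pd.DataFrame({"y": [7.0] * 12 + [7.0 + 1e-9] * 2})
        fit = fit_gamma_log(frame, "y", [])
        assert fit.estimates["intercept"] == pytest.approx(math.log(7.0), abs=1e-6)
        assert fit.k == 2

    def test_gamma_rejects_nonpositive(self):
        frame = pd.DataFrame({"y": [3.0, -1.0, 2.0, 5.0, 1.0]})
        with pytest.raises(ValueError, match="positive"):
            fit_gamma_log(frame, "y", [])

    def test_gamma_age_coefficient_matches_group_mean_ratio(self):
        # log-link algebra: exp(beta_age) equals the adult/juvenile ratio
        rng = np.random.default_rng(42)
        n = 400
        age = np.repeat([1.0, 0.0], n // 2)
        mu = np.where(age == 1, 72.0, 93.0)
        shape = 6.0
        y = rng.gamma(shape, mu / shape)
        frame = pd.DataFrame({"y": y, "age": age})
        fit = fit_gamma_log(frame, "y", ["age"])
        implied = math.exp(fit.estimates["age"])
        assert implied == pytest.approx(72.0 / 93.0, rel=0.05)

    def test_lmm_singleton_groups_match_ols(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({"y": rng.normal(50, 10, 25),
                              "x": rng.normal(0, 1, 25),
                              "tag_id": [f"b{i}" for i in range(25)]})
        lmm = fit_lmm(frame, "y", ["x"])
        ols = fit_linear(frame, "y", ["x"])
        assert lmm.estimates["x"] == pytest.approx(ols.estimates["x"], abs=1e-5)
        # total likelihood is the identifiable quantity with singletons
        assert lmm.loglik == pytest.approx(ols.loglik, abs=1e-4)
        assert lmm.k == ols.k + 1

    def test_lmm_k_bookkeeping_five_fixed_terms(self):
        rng = np.random.default_rng(2)
        n = 40
        frame = pd.DataFrame({c: rng.normal(size=n)
                              for c in ["y", "a", "b", "c", "d"]})
        frame["tag_id"] = [f"g{i // 2}" for i in range(n)]
        fit = fit_lmm(frame, "y", ["a", "b", "c", "d"])
        # intercept + 4 slopes = 5 fixed coefficients -> k = 7
        assert fit.k == 7

    def test_lmm_recovers_between_bird_variance(self):
        hits = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            groups = np.repeat(np.arange(12), 3)
            re = rng.normal(0, 10.0, 12)[groups]
            y = 60.0 + re + rng.normal(0, 5.0, len(groups))
            frame = pd.DataFrame({"y": y,
                                  "tag_id": [f"b{g}" for g in groups]})
            fit = fit_lmm(frame, "y", [])
            if not fit.singular:
                hits += 1
        assert hits >= 10  # positive RI variance found in most replicates


class TestRunResponseAnalysis:
    def test_matches_brute_force_enumeration(self):
        """Oracle: hand-enumerated 8 fits on a 3-term toy problem."""
        rng = np.random.default_rng(7)
        n = 60
        frame = pd.DataFrame({
            "age": rng.integers(0, 2, n).astype(float),
            "sex": rng.integers(0, 2, n).astype(float),
            "year": rng.integers(2016, 2020, n).astype(float),
            "tag_id": [f"b{i}" for i in range(n)],
        })
        frame["speed_kmh"] = (40 + 8 * frame["age"]
                              + rng.normal(0, 6, n))
        res = run_response_analysis(frame, "speed_kmh",
                                    global_terms=("age", "sex", "year"),
                                    family="gaussian_lm")
        # brute force, independent of all_subsets/rank_models
        from itertools import combinations
        brute = []
        for r in range(4):
            for combo in combinations(["age", "sex", "year"], r):
                f = fit_linear(frame, "speed_kmh", list(combo))
                brute.append((set(combo), aicc(f)))
        assert len(res.table) == len(brute) == 8
        best_brute = min(a for _, a in brute)
        assert res.table["aicc"].min() == pytest.approx(best_brute, abs=1e-9)
        for terms, a in brute:
            label = " + ".join(t for t in ("age", "sex", "year") if t in terms) \
                or "(intercept)"
            row = res.table[res.table["terms"] == label]
            assert row["aicc"].iloc[0] == pytest.approx(a, abs=1e-9)
        assert res.table["weight"].sum() == pytest.approx(1.0)
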