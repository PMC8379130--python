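import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hccwashout.cohort_stats import (
    ContingencyTable2x2,
    diagnostic_parameters,
    dichotomize_response,
    fisher_exact_2x2,
    logistic_fit,
    mad,
    mann_whitney_u,
    odds_ratio,
    risk_ratio,
    roc_auc,
    select_threshold,
    stratify,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def fisher_oracle(t: ContingencyTable2x2) -> float:
    """Direct hypergeometric enumeration with the small-p two-sided rule."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = t.n

    def prob(a):
        return (
            math.comb(r1, a)
            * math.comb(r2, c1 - a)
            / math.comb(n, c1)
        )

    p_obs = prob(t.a)
    total = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(a)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def mann_whitney_oracle(x, y):
    """Full permutation distribution of U (midrank ties), two-sided p."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    order = pooled.argsort()
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - nx * (nx + 1) / 2.0
    u_obs = u_of(range(nx))
    mean_u = nx * (len(pooled) - nx) / 2.0
    dist = [u_of(c) for c in itertools.combinations(range(len(pooled)), nx)]
    dev = abs(u_obs - mean_u)
    p = sum(1 for u in dist if abs(u - mean_u) >= dev - 1e-12) / len(dist)
    return u_obs, min(1.0, p)


def auc_oracle(scores, labels):
    """Concordant pairs + half ties over all positive x negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def threshold_scan_oracle(scores, labels, criterion):
    """Exhaustive scan over every distinct inclusive cut; ties -> higher cut."""
    evaluated = []
    for cut in sorted(set(scores)):
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= cut)
        fn = sum(1 for s, l in zip(scores, labels) if l and s < cut)
        tn = sum(1 for s, l in zip(scores, labels) if not l and s < cut)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s >= cut)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if criterion == "youden":
            val = sens + spec - 1
        elif criterion == "harmonic":
            val = 2 * sens * spec / (sens + spec) if sens + spec > 0 else 0.0
        else:
            val = -math.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)
        evaluated.append((cut, val))
    best = max(val for _, val in evaluated)
    return max(cut for cut, val in evaluated if abs(val - best) <= 1e-12)


small_samples = st.lists(st.integers(0, 30), min_size=1, max_size=8)
labelled = st.lists(
    st.tuples(st.integers(0, 12), st.booleans()), min_size=4, max_size=24
).filter(lambda xs: any(l for _, l in xs) and any(not l for _, l in xs))


# ---------------------------------------------------------------------------
# contingency inference
# ---------------------------------------------------------------------------


class TestFisher:
    def test_dpar_table_frozen(self):
        p = fisher_exact_2x2(ContingencyTable2x2(41, 21, 23, 44))
        assert round(p, 4) == 0.0004

    def test_balanced_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 7)) == 1.0

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        assert fisher_exact_2x2(t) == pytest.approx(fisher_oracle(t), rel=1e-9)


class TestEffectMeasures:
    def test_printed_or_and_woolf_ci(self):
        res = odds_ratio(ContingencyTable2x2(41, 21, 23, 44))
        assert round(res["or"], 1) == 3.7
        assert round(res["ci_low"], 1) == 1.8
        assert round(res["ci_high"], 1) == 7.7

    def test_cross_product_hand_value(self):
        res = odds_ratio(ContingencyTable2x2(26, 7, 11, 31))
        assert round(res["or"], 1) == 10.5

    def test_null_or_when_ad_equals_bc(self):
        assert odds_ratio(ContingencyTable2x2(6, 3, 10, 5))["or"] == pytest.approx(1.0)

    def test_zero_cell_needs_explicit_fallback(self):
        with pytest.raises(ValueError, match="zero cell"):
            odds_ratio(ContingencyTable2x2(5, 0, 3, 7))
        with pytest.warns(UserWarning, match="continuity"):
            res = odds_ratio(ContingencyTable2x2(5, 0, 3, 7), continuity=True)
        assert math.isfinite(res["or"])

    def test_printed_rr_and_katz_ci(self):
        res = risk_ratio(ContingencyTable2x2(26, 7, 11, 31))
        assert round(res["rr"]) == 3
        assert round(res["ci_low"]) == 2
        assert round(res["ci_high"]) == 5

    def test_equal_risks_unit_rr(self):
        assert risk_ratio(ContingencyTable2x2(5, 5, 8, 8))["rr"] == pytest.approx(1.0)

    def test_unit_table_symmetric_in_log(self):
        res = risk_ratio(ContingencyTable2x2(1, 1, 1, 1))
        assert res["rr"] == pytest.approx(1.0)
        assert math.log(res["ci_low"]) == pytest.approx(-math.log(res["ci_high"]), abs=1e-9)

    def test_zero_unexposed_risk_rejected(self):
        with pytest.raises(ValueError, match="unexposed"):
            risk_ratio(ContingencyTable2x2(5, 5, 0, 8))


class TestDiagnosticParameters:
    def test_dpar_table_two_decimals(self):
        res = diagnostic_parameters(ContingencyTable2x2(41, 21, 23, 44))
        assert {k: round(v, 2) for k, v in res.items()} == {
            "sensitivity": 0.64,
            "specificity": 0.68,
            "ppv": 0.66,
            "npv": 0.66,
            "accuracy": 0.66,
        }

    def test_perfect_table(self):
        res = diagnostic_parameters(ContingencyTable2x2(12, 0, 0, 9))
        assert all(v == 1.0 for v in res.values())

    def test_uninformative_test_ppv_equals_prevalence(self):
        t = ContingencyTable2x2(6, 6, 4, 4)  # risk 0.5 in both arms
        res = diagnostic_parameters(t)
        assert res["ppv"] == pytest.approx((t.a + t.c) / t.n)


# ---------------------------------------------------------------------------
# rank tests and dispersion
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_identical_samples_no_separation(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["p"] >= 0.99

    def test_complete_separation_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(0.1)  # 2 * 1/20

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(
        x=st.lists(st.integers(0, 40), min_size=2, max_size=6),
        y=st.lists(st.integers(0, 40), min_size=2, max_size=6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_permutation_oracle_untied(self, x, y):
        x, y = np.array(x, float), np.array(y, float)
        if np.unique(np.concatenate([x, y])).size != x.size + y.size:
            return  # exact path is only claimed without ties
        res = mann_whitney_u(x, y)
        u_obs, p_exp = mann_whitney_oracle(x, y)
        assert res["u"] == pytest.approx(u_obs)
        assert res["p"] == pytest.approx(p_exp, rel=1e-9)


class TestMad:
    def test_constant_sample_zero(self):
        assert mad([7.0] * 5) == 0.0

    def test_hand_computation_outlier_resistant(self):
        assert mad([1, 2, 3, 4, 100]) == 1.0

    def test_translation_invariance(self, rng):
        x = rng.normal(0, 3, 25)
        assert mad(x + 123.4) == pytest.approx(mad(x), abs=1e-12)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert res["auc"] == pytest.approx(1.0)

    def test_constant_score_chance(self):
        res = roc_auc([5.0] * 8, [True, False] * 4)
        assert res["auc"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc([1, 2, 3], [True, True, True])

    @given(labelled)
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_pair_enumeration_oracle(self, data):
        scores = [float(s) for s, _ in data]
        labels = [l for _, l in data]
        res = roc_auc(scores, labels)
        assert res["auc"] == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    @given(labelled)
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_auc_equals_scaled_mann_whitney_u(self, data):
        scores = np.array([float(s) for s, _ in data])
        labels = np.array([l for _, l in data])
        auc = roc_auc(scores, labels)["auc"]
        u = mann_whitney_u(scores[labels], scores[~labels])["u"]
        assert auc == pytest.approx(u / (labels.sum() * (~labels).sum()), abs=1e-12)

    def test_curve_monotone_with_endpoints(self, exact_cohort_indexed):
        df = exact_cohort_indexed
        labels = (df["response"] == "CR").to_numpy()
        curve = roc_auc(df["dpar"].to_numpy(), labels)["curve"]
        assert np.all(np.diff(curve.sensitivity) <= 1e-12)
        assert np.all(np.diff(curve.specificity) >= -1e-12)
        assert (curve.sensitivity[0], curve.specificity[0]) == (1.0, 0.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (0.0, 1.0)


class TestSelectThreshold:
    def test_perfect_separation_gap_midpoint(self):
        res = select_threshold([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        for key in ("by_youden", "by_harmonic_mean", "by_corner_distance"):
            assert res[key]["threshold"] == pytest.approx(6.5)
        assert res["consensus"]["agreed"]

    @given(labelled)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_scan_oracle(self, data):
        scores = [float(s) for s, _ in data]
        labels = [l for _, l in data]
        res = select_threshold(scores, labels)
        for key, crit in (
            ("by_youden", "youden"),
            ("by_harmonic_mean", "harmonic"),
            ("by_corner_distance", "corner"),
        ):
            assert res[key]["cut"] == pytest.approx(
                threshold_scan_oracle(scores, labels, crit)
            )

    def test_synthetic_cohort_consensus_near_120(self, exact_cohort_indexed):
        df = exact_cohort_indexed
        res = select_threshold(df["dpar"].to_numpy(), (df["response"] == "CR").to_numpy())
        assert 115 <= res["consensus"]["threshold"] <= 125


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def _stratified_design():
    rows = []
    from hccwashout.synthetic import STRATIFICATION_CELLS

    for (high, smooth), (n, n_cr) in STRATIFICATION_CELLS.items():
        for i in range(n):
            rows.append((float(high), float(smooth), float(i < n_cr)))
    arr = np.array(rows)
    X = pd.DataFrame({"dpar_high": arr[:, 0], "smooth_margins": arr[:, 1]})
    return X, arr[:, 2]


class TestLogisticFit:
    def test_single_predictor_equals_cross_product_or(self):
        """One binary predictor: the BLR OR is analytically ad/(bc)."""
        t = ContingencyTable2x2(41, 21, 23, 44)
        x = [1.0] * 62 + [0.0] * 67
        y = [1.0] * 41 + [0.0] * 21 + [1.0] * 23 + [0.0] * 44
        fit = logistic_fit(pd.DataFrame({"dpar_high": x}), y)
        assert fit.predictors["dpar_high"]["or"] == pytest.approx(
            odds_ratio(t)["or"], rel=1e-8
        )

    def test_independent_outcome_null_ors(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=400), "b": rng.integers(0, 2, 400)})
        y = rng.integers(0, 2, 400)
        fit = logistic_fit(X, y)
        for v in fit.predictors.values():
            assert abs(v["coef"]) < 0.35
            assert v["or_ci_low"] < 1.0 < v["or_ci_high"]

    def test_two_predictor_fit_inside_printed_cis(self):
        X, y = _stratified_design()
        fit = logistic_fit(X, y)
        assert 1.5 <= fit.predictors["dpar_high"]["or"] <= 7.2
        assert 1.1 <= fit.predictors["smooth_margins"]["or"] <= 5.5

    def test_two_predictor_solution_is_likelihood_optimum(self):
        """Coarse grid around the fit: no neighbor improves the log-likelihood."""
        X, y = _stratified_design()
        fit = logistic_fit(X, y)
        b0 = fit.intercept["coef"]
        b = np.array([fit.predictors["dpar_high"]["coef"],
                      fit.predictors["smooth_margins"]["coef"]])
        Xm = X.to_numpy()

        def loglik(beta0, beta):
            eta = beta0 + Xm @ beta
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        best = loglik(b0, b)
        for d0 in (-0.05, 0.0, 0.05):
            for d1 in (-0.05, 0.0, 0.05):
                for d2 in (-0.05, 0.0, 0.05):
                    assert loglik(b0 + d0, b + [d1, d2]) <= best + 1e-9

    def test_separation_reported_by_name(self):
        X = pd.DataFrame({"sep": [0.0, 0.1, 0.2, 5.0, 5.1, 5.2]})
        y = [0, 0, 0, 1, 1, 1]
        with pytest.raises(ValueError, match="separation on predictor 'sep'"):
            logistic_fit(X, y)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            logistic_fit(pd.DataFrame({"x": [1.0, 2.0]}), [0.0, 2.0])


# ---------------------------------------------------------------------------
# stratification and response dichotomization
# ---------------------------------------------------------------------------


class TestStratify:
    def test_published_cell_rates(self, exact_cohort_indexed):
        res = stratify(exact_cohort_indexed)
        rates = {k: v["cr_rate_pct"] for k, v in res["cells"].items()}
        assert rates == {
            "dpar_high_smooth": 78.8,
            "dpar_high_other": 51.7,
            "dpar_low_smooth": 48.0,
            "dpar_low_other": 26.2,
        }
        assert res["one_predictor"]["n"] == 54
        assert res["one_predictor"]["cr_rate_pct"] == 50.0

    def test_extreme_cell_effects(self, exact_cohort_indexed):
        res = stratify(exact_cohort_indexed)["extreme_cells"]
        assert round(res["risk_ratio"]["rr"]) == 3
        assert res["fisher_p"] < 0.0001

    def test_all_cr_cohort(self):
        df = pd.DataFrame(
            {
                "dpar": [125.0, 118.0, 130.0, 110.0],
                "margins": ["smooth", "smooth", "other", "other"],
                "response": ["CR"] * 4,
            }
        )
        res = stratify(df)
        for cell in res["cells"].values():
            if cell["n"]:
                assert cell["cr_rate_pct"] == 100.0

    def test_non_evaluable_excluded_with_count(self):
        df = pd.DataFrame(
            {
                "dpar": [125.0, float("nan"), 110.0],
                "margins": ["smooth", "smooth", "other"],
                "response": ["CR", "PR", "PD"],
            }
        )
        res = stratify(df)
        assert res["excluded_non_evaluable"] == 1
        assert sum(c["n"] for c in res["cells"].values()) == res["n_analyzed"] == 2


class TestDichotomizeResponse:
    def test_published_mix(self):
        responses = ["CR"] * 64 + ["PR"] * 53 + ["SD"] * 7 + ["PD"] * 5
        flags = [dichotomize_response(r) for r in responses]
        assert sum(flags) == 64
        assert len(flags) - sum(flags) == 65

    @pytest.mark.parametrize("cat, expected", [("CR", True), ("PR", False), ("SD", False), ("PD", False)])
    def test_categories(self, cat, expected):
        assert dichotomize_response(cat) is expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="mRECIST"):
            dichotomize_response("CRX")
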