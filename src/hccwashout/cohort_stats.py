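"""Cohort-level inference: univariate tests, effect measures, ROC, BLR.

The analysis contract mirrors a per-lesion predictive study of early
complete response (CR) to DEB-TACE: non-parametric univariate comparisons
(Mann-Whitney for continuous, Fisher exact for categorical), odds and risk
ratios with Woolf/Katz log-method confidence intervals, median absolute
deviation for dispersion, empirical ROC analysis with three threshold
criteria (Youden, harmonic mean of sensitivity and specificity, distance to
the upper-left corner), binary logistic regression, and the four-cell
stratification by (DPAR >= 120) x margins.

Conventions frozen here because they reproduce the printed results:
two-sided Fisher p sums hypergeometric tables with probability <= observed;
OR CI is Woolf log method with z = 1.96 and no continuity correction; RR CI
is Katz log method; threshold-criterion ties break toward the higher
(more specific) cut.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.contingency_tables import Table2x2
from statsmodels.tools.sm_exceptions import PerfectSeparationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# contingency tables and effect measures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts: a/b exposed, c/d unexposed; a/c outcome+."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_binary(cls, exposure, outcome) -> "ContingencyTable2x2":
        e = np.asarray(exposure, dtype=bool)
        o = np.asarray(outcome, dtype=bool)
        if e.shape != o.shape:
            raise ValueError("exposure and outcome must align")
        return cls(
            a=int((e & o).sum()),
            b=int((e & ~o).sum()),
            c=int((~e & o).sum()),
            d=int((~e & ~o).sum()),
        )


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (sum of tables with probability <= observed)."""
    arr = table.as_array()
    if min(arr.sum(axis=0).min(), arr.sum(axis=1).min()) == 0:
        warnings.warn("degenerate margin in 2x2 table; Fisher p = 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def odds_ratio(table: ContingencyTable2x2, continuity: bool = False) -> dict[str, float]:
    """Cross-product odds ratio with Woolf log-method 95% CI.

    With a zero cell the OR/CI are undefined; ``continuity=True`` applies
    the documented 0.5-per-cell fallback (with a warning) instead of
    raising.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ValueError("zero cell: enable the 0.5 continuity fallback explicitly")
        warnings.warn("zero cell: applying 0.5 continuity correction to all cells", stacklevel=2)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    t = Table2x2(np.array([[a, b], [c, d]], dtype=float))
    lo, hi = t.oddsratio_confint(alpha=0.05)
    return {"or": float(t.oddsratio), "ci_low": float(lo), "ci_high": float(hi)}


def risk_ratio(table: ContingencyTable2x2) -> dict[str, float]:
    """Risk ratio with Katz log-method 95% CI."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("empty exposure row")
    if c == 0:
        raise ValueError("zero unexposed risk: risk ratio undefined")
    t = Table2x2(table.as_array())
    lo, hi = t.riskratio_confint(alpha=0.05)
    return {"rr": float(t.riskratio), "ci_low": float(lo), "ci_high": float(hi)}


def diagnostic_parameters(table: ContingencyTable2x2) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and accuracy of a test x disease table.

    Here "exposed" is test-positive and "outcome+" is diseased.  Undefined
    ratios (an empty margin) come back as NaN rather than raising.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    nan = float("nan")
    return {
        "sensitivity": a / (a + c) if a + c else nan,
        "specificity": d / (b + d) if b + d else nan,
        "ppv": a / (a + b) if a + b else nan,
        "npv": d / (c + d) if c + d else nan,
        "accuracy": (a + d) / table.n if table.n else nan,
    }


# ---------------------------------------------------------------------------
# univariate tests and dispersion
# ---------------------------------------------------------------------------


def mann_whitney_u(x, y) -> dict[str, float]:
    """Mann-Whitney U with midrank ties.

    Exact enumeration when both samples have n <= 8 and no ties span the
    groups; otherwise the normal approximation with tie and continuity
    correction.  Returns the U statistic of the first sample and the
    two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return {"u": float(res.statistic), "p": float(res.pvalue), "method": method}


def mad(x) -> float:
    """Median absolute deviation from the median, unscaled."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    return float(np.median(np.abs(x - np.median(x))))


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC over all distinct inclusive cuts (positive iff score >= t).

    Thresholds rise from -inf (everything positive: sens 1, spec 0) to +inf
    (nothing positive: sens 0, spec 1); sensitivity is non-increasing and
    specificity non-decreasing along the way.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    direction: str = "greater"  # higher score -> outcome+

    def points(self) -> np.ndarray:
        """(FPR, TPR) pairs ordered with the thresholds."""
        return np.column_stack([1.0 - self.specificity, self.sensitivity])


def _curve_from_scores(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    pos = scores[labels]
    neg = scores[~labels]
    cuts = np.unique(scores)
    thresholds = np.concatenate([[-np.inf], cuts, [np.inf]])
    # sens(t) = P(pos >= t); count via searchsorted on sorted arrays
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong 95% CI for the empirical AUC (placement-value variance)."""
    # V10_i = mean_j psi(pos_i, neg_j); psi = 1, .5, 0 for >, =, <
    n1, n0 = pos.size, neg.size
    neg_sorted = np.sort(neg)
    lt = np.searchsorted(neg_sorted, pos, side="left")
    le = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / n0
    pos_sorted = np.sort(pos)
    lt = np.searchsorted(pos_sorted, neg, side="left")
    le = np.searchsorted(pos_sorted, neg, side="right")
    v01 = 1.0 - (lt + 0.5 * (le - lt)) / n1
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    se = math.sqrt(s10 / n1 + s01 / n0)
    return (max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se))


def roc_auc(scores, labels) -> dict:
    """Empirical ROC curve, trapezoid AUC and DeLong 95% CI.

    The trapezoid AUC over all distinct cuts equals the tie-corrected
    concordance probability P(score+ > score-) + 0.5 P(=), i.e. the
    Mann-Whitney U statistic scaled by 1/(n+ * n-).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if labels.all() or not labels.any():
        raise ValueError("both outcome classes must be present")
    curve = _curve_from_scores(scores, labels)
    # walk the staircase from (0,0) (threshold +inf) to (1,1): both
    # coordinates are monotone along falling thresholds, so the trapezoid
    # rule applies directly without re-sorting (which would unpair ties)
    pts = curve.points()[::-1]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    ci = _delong_ci(scores[labels], scores[~labels], auc)
    return {"curve": curve, "auc": auc, "ci_low": ci[0], "ci_high": ci[1]}


def select_threshold(scores, labels) -> dict:
    """Pick a dichotomization cut by three ROC criteria plus their consensus.

    Candidates are the distinct observed scores (positive iff score >= cut).
    Criteria: maximize Youden's J = sens + spec - 1; maximize the harmonic
    mean 2*sens*spec/(sens+spec); minimize the Euclidean distance of the
    ROC point from the upper-left corner.  Ties break toward the higher
    (more specific) cut.  ``consensus`` is the common value when all three
    agree, else the Youden cut, with all three always reported.  The
    reported ``threshold`` is the midpoint between the selected cut and the
    next lower distinct score (the decision boundary is anywhere in that
    gap); the cut itself is reported as ``cut``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cuts = np.unique(scores)
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    if pos_sorted.size == 0 or neg_sorted.size == 0:
        raise ValueError("both outcome classes must be present")
    sens = 1.0 - np.searchsorted(pos_sorted, cuts, side="left") / pos_sorted.size
    spec = np.searchsorted(neg_sorted, cuts, side="left") / neg_sorted.size

    youden = sens + spec - 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        harm = np.where(sens + spec > 0, 2.0 * sens * spec / (sens + spec), 0.0)
    corner = np.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)

    def pick(values: np.ndarray, maximize: bool) -> int:
        best = values.max() if maximize else values.min()
        idx = np.flatnonzero(np.isclose(values, best, rtol=0.0, atol=1e-12))
        return int(idx[-1])  # ties -> higher cut

    out: dict = {}
    for name, values, maximize in (
        ("by_youden", youden, True),
        ("by_harmonic_mean", harm, True),
        ("by_corner_distance", corner, False),
    ):
        i = pick(values, maximize)
        cut = float(cuts[i])
        below = cuts[cuts < cut]
        thr = float((cut + below[-1]) / 2.0) if below.size else cut
        out[name] = {
            "cut": cut,
            "threshold": thr,
            "sensitivity": float(sens[i]),
            "specificity": float(spec[i]),
            "criterion_value": float(values[i]),
        }
    cuts3 = {out[k]["cut"] for k in ("by_youden", "by_harmonic_mean", "by_corner_distance")}
    consensus_key = "by_youden"
    out["consensus"] = dict(out[consensus_key], agreed=len(cuts3) == 1)
    return out


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    """Per-predictor Wald summary of a maximum-likelihood logistic fit."""

    predictors: dict[str, dict[str, float]]
    intercept: dict[str, float]
    converged: bool
    n_obs: int
    n_iter: int | None = None
    warnings: list[str] = field(default_factory=list)


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        if np.unique(col).size <= 1:
            continue
        lo, hi = col[y == 0], col[y == 1]
        if lo.size and hi.size and (lo.max() < hi.min() or hi.max() < lo.min()):
            raise ValueError(f"complete separation on predictor {name!r}")


def logistic_fit(design: pd.DataFrame, outcome) -> LogisticFit:
    """Binary logistic regression with Wald standard errors.

    Newton-Raphson maximum likelihood (equivalent to iteratively reweighted
    least squares), convergence tolerance 1e-10, at most 100 iterations.
    Complete separation is detected per predictor and reported by name;
    non-convergence raises with the optimizer trace.
    """
    X = pd.DataFrame(design).astype(float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    _check_separation(X, y)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except PerfectSeparationError as exc:  # pragma: no cover - guarded above
        raise ValueError(f"complete separation: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")
    conf = res.conf_int(alpha=0.05)
    predictors = {}
    for name in X.columns:
        beta = float(res.params[name])
        predictors[name] = {
            "coef": beta,
            "se": float(res.bse[name]),
            "p": float(res.pvalues[name]),
            "or": math.exp(beta),
            "or_ci_low": math.exp(float(conf.loc[name, 0])),
            "or_ci_high": math.exp(float(conf.loc[name, 1])),
        }
    intercept = {
        "coef": float(res.params["const"]),
        "se": float(res.bse["const"]),
        "p": float(res.pvalues["const"]),
    }
    return LogisticFit(
        predictors=predictors,
        intercept=intercept,
        converged=True,
        n_obs=int(res.nobs),
        n_iter=res.mle_retvals.get("iterations"),
    )


# ---------------------------------------------------------------------------
# response dichotomization and stratification
# ---------------------------------------------------------------------------


def dichotomize_response(response: str) -> bool:
    """Early radiological response: CR -> True (CR+), PR/SD/PD -> False (CR-)."""
    if response == "CR":
        return True
    if response in ("PR", "SD", "PD"):
        return False
    raise ValueError(f"unknown mRECIST category {response!r}")


def stratify(df: pd.DataFrame, dpar_col: str = "dpar", threshold: float = 120.0) -> dict:
    """Four-cell outcome report by (DPAR >= threshold) x margins.

    Returns per-cell lesion counts, CR+ counts and CR+ rates; the pooled
    rate of the two single-favorable-predictor cells; OR and RR contrasting
    the two-favorable vs no-favorable extremes; and the number of lesions
    excluded for non-evaluable DPAR.
    """
    dpar = pd.to_numeric(df[dpar_col], errors="coerce")
    evaluable = np.isfinite(dpar.to_numpy(dtype=float))
    excluded = int((~evaluable).sum())
    sub = df[evaluable]
    dpar = dpar[evaluable]

    high = dpar.to_numpy(dtype=float) >= threshold
    smooth = sub["margins"].to_numpy() == "smooth"
    cr = np.array([dichotomize_response(r) for r in sub["response"]])

    cells = {}
    for key, mask in (
        ("dpar_high_smooth", high & smooth),
        ("dpar_high_other", high & ~smooth),
        ("dpar_low_smooth", ~high & smooth),
        ("dpar_low_other", ~high & ~smooth),
    ):
        n = int(mask.sum())
        k = int((mask & cr).sum())
        cells[key] = {
            "n": n,
            "cr": k,
            "cr_rate_pct": round(100.0 * k / n, 1) if n else float("nan"),
        }
    one_n = cells["dpar_high_other"]["n"] + cells["dpar_low_smooth"]["n"]
    one_k = cells["dpar_high_other"]["cr"] + cells["dpar_low_smooth"]["cr"]

    extreme = ContingencyTable2x2(
        a=cells["dpar_high_smooth"]["cr"],
        b=cells["dpar_high_smooth"]["n"] - cells["dpar_high_smooth"]["cr"],
        c=cells["dpar_low_other"]["cr"],
        d=cells["dpar_low_other"]["n"] - cells["dpar_low_other"]["cr"],
    )
    effects: dict = {}
    try:
        effects["odds_ratio"] = odds_ratio(extreme)
        effects["risk_ratio"] = risk_ratio(extreme)
        effects["fisher_p"] = fisher_exact_2x2(extreme)
    except ValueError as exc:
        effects["flag"] = str(exc)

    return {
        "threshold": threshold,
        "cells": cells,
        "one_predictor": {
            "n": one_n,
            "cr": one_k,
            "cr_rate_pct": round(100.0 * one_k / one_n, 1) if one_n else float("nan"),
        },
        "extreme_cells": effects,
        "excluded_non_evaluable": excluded,
        "n_analyzed": int(evaluable.sum()),
    }


def format_p(p: float) -> str:
    """Display convention: four decimals or '<0.0001'."""
    if not math.isfinite(p):
        return "NA"
    return "<0.0001" if p < 0.0001 else f"{p:.4f}"
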