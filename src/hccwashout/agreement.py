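"""Inter-reader agreement for quantitative indices and categorical calls.

Two blinded readers measure the same lesions; agreement on continuous
indices is summarized by the paired Wilcoxon signed-rank test (systematic
shift), the intraclass correlation coefficient and Cronbach's alpha
(consistency), and agreement on margin calls by Cohen's kappa.

The ICC form is fixed to ICC(2,1): two-way random effects, absolute
agreement, single measurement — the standard choice for two human readers
each rating every lesion once.  "Cronbach's coefficient" for two raters is
implemented as Cronbach's alpha, ``2 * (1 - (V1 + V2) / V(x1 + x2))``;
an eta-squared reading of the same label is possible and documented, but
alpha is what the reliability literature computes for paired raters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score


@dataclass(frozen=True)
class PairedReadings:
    """Aligned per-lesion values from two readers (quantitative or categorical)."""

    reader1: np.ndarray
    reader2: np.ndarray

    def __post_init__(self) -> None:
        r1 = np.asarray(self.reader1)
        r2 = np.asarray(self.reader2)
        if r1.shape != r2.shape or r1.ndim != 1:
            raise ValueError("readers must supply equal-length 1-D aligned readings")
        object.__setattr__(self, "reader1", r1)
        object.__setattr__(self, "reader2", r2)

    def __len__(self) -> int:
        return self.reader1.size

    @classmethod
    def from_frames(cls, df1: pd.DataFrame, df2: pd.DataFrame, column: str) -> "PairedReadings":
        """Align two lesion tables on ``lesion_id`` and pair one column."""
        merged = df1[["lesion_id", column]].merge(
            df2[["lesion_id", column]], on="lesion_id", suffixes=("_1", "_2")
        )
        return cls(merged[f"{column}_1"].to_numpy(), merged[f"{column}_2"].to_numpy())


def wilcoxon_signed_rank(pairs: PairedReadings) -> dict:
    """Two-sided Wilcoxon signed-rank p for a paired shift between readers.

    Zero differences are excluded, ties get midranks; the null distribution
    is enumerated exactly for up to 12 nonzero untied differences and
    normal-approximated (with continuity correction) beyond.
    """
    r1, r2 = _finite_pairs(pairs)
    d = r1 - r2
    nz = d[d != 0.0]
    if nz.size == 0:
        warnings.warn("no nonzero differences between readers; p = 1", stacklevel=2)
        return {"statistic": 0.0, "p": 1.0, "n_nonzero": 0}
    exact = nz.size <= 12
    res = sps.wilcoxon(
        nz,
        alternative="two-sided",
        method="exact" if exact else "approx",
        correction=True,
    )
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n_nonzero": int(nz.size),
        "method": "exact" if exact else "approx",
    }


def _finite_pairs(pairs: PairedReadings) -> tuple[np.ndarray, np.ndarray]:
    r1 = pairs.reader1.astype(float)
    r2 = pairs.reader2.astype(float)
    mask = np.isfinite(r1) & np.isfinite(r2)
    return r1[mask], r2[mask]


def icc(pairs: PairedReadings) -> dict:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Non-evaluable (non-finite) pairs are dropped; zero between-lesion
    variance is flagged degenerate rather than divided through.
    """
    r1, r2 = _finite_pairs(pairs)
    n = r1.size
    if n < 3:
        raise ValueError("ICC requires at least 3 lesions")
    if np.var(np.concatenate([r1, r2])) == 0 or np.var((r1 + r2) / 2) == 0:
        return {"icc": float("nan"), "degenerate": True}
    if np.array_equal(r1, r2):
        # perfect agreement with spread: ICC is exactly 1, and the ANOVA
        # F ratios degenerate to inf
        return {"icc": 1.0, "ci_low": 1.0, "ci_high": 1.0, "degenerate": False}
    long = pd.DataFrame(
        {
            "lesion": np.tile(np.arange(n), 2),
            "reader": np.repeat([1, 2], n),
            "value": np.concatenate([r1, r2]),
        }
    )
    table = pg.intraclass_corr(data=long, targets="lesion", raters="reader", ratings="value")
    table = table.set_index("Type")
    # label differs across pingouin versions: "ICC2" (Shrout-Fleiss) vs
    # "ICC(A,1)" (McGraw-Wong); both are two-way random, absolute, single
    label = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[label]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = row[ci_col]
    return {
        "icc": float(row["ICC"]),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "degenerate": False,
    }


def cronbach_coefficient(pairs: PairedReadings) -> dict:
    """Two-rater Cronbach's alpha: ``2 * (1 - (V1 + V2) / V(x1 + x2))``."""
    r1, r2 = _finite_pairs(pairs)
    if r1.size < 3:
        raise ValueError("Cronbach's coefficient requires at least 3 lesions")
    v_sum = np.var(r1 + r2, ddof=1)
    if v_sum == 0:
        return {"alpha": float("nan"), "degenerate": True}
    alpha = 2.0 * (1.0 - (np.var(r1, ddof=1) + np.var(r2, ddof=1)) / v_sum)
    return {"alpha": float(alpha), "degenerate": False}


def cohen_kappa(pairs: PairedReadings) -> dict:
    """Cohen's kappa with marginal-product expected agreement."""
    r1 = np.asarray(pairs.reader1)
    r2 = np.asarray(pairs.reader2)
    cats = np.unique(np.concatenate([r1, r2]))
    if cats.size < 2:
        raise ValueError("kappa requires at least 2 observed categories")
    p_o = float(np.mean(r1 == r2))
    if p_o == 1.0:
        # p_e < 1 is guaranteed by >= 2 categories, but sklearn handles the
        # perfect-agreement case with a 0/0 guard we want to bypass cleanly
        return {"kappa": 1.0, "observed_agreement": 1.0, "degenerate": False}
    k = float(cohen_kappa_score(r1, r2))
    if math.isnan(k):
        return {"kappa": float("nan"), "observed_agreement": p_o, "degenerate": True}
    return {"kappa": k, "observed_agreement": p_o, "degenerate": False}


def agreement_table(
    df1: pd.DataFrame,
    df2: pd.DataFrame,
    variables: list[str],
    margins: bool = True,
) -> dict:
    """Per-variable agreement summary for two readers of the same cohort.

    ``variables`` are continuous columns (indices, diameters); set
    ``margins=True`` to add Cohen's kappa on the margin calls.
    """
    out: dict = {"variables": {}}
    for var in variables:
        pairs = PairedReadings.from_frames(df1, df2, var)
        mask = np.isfinite(pairs.reader1.astype(float)) & np.isfinite(pairs.reader2.astype(float))
        pairs = PairedReadings(pairs.reader1[mask].astype(float), pairs.reader2[mask].astype(float))
        out["variables"][var] = {
            "n": len(pairs),
            "wilcoxon": wilcoxon_signed_rank(pairs),
            "icc": icc(pairs),
            "cronbach": cronbach_coefficient(pairs),
        }
    if margins:
        pairs = PairedReadings.from_frames(df1, df2, "margins")
        out["margins_kappa"] = cohen_kappa(pairs)
    return out
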