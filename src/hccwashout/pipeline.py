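"""End-to-end orchestration: cohort in, versioned analysis report out.

``run_full_analysis`` ties the stages together — index computation from raw
HU measurements, per-group univariate comparisons, ROC analysis of DPAR
with threshold selection, binary logistic regression, the four-cell
stratification, and (when a second reader's table is supplied) the
agreement block.  Reports are plain dicts serialized deterministically, so
the same inputs, config and seed always yield byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import agreement as agr
from . import cohort_stats as cs
from . import io as hio
from .indices import DPAR_THRESHOLD, INDEX_NAMES
from .measurement import count_protocol_rois
from .synthetic import CohortSpec, generate_cohort, generator_metadata

SCHEMA_VERSION = "1.0"

_CONFIG_FIELDS = {
    "input_path",
    "reader2_path",
    "threshold_mode",
    "threshold_value",
    "blr_covariates",
    "seed",
    "output_formats",
    "calibration_preset",
}


@dataclass
class AnalysisConfig:
    """Serializable run configuration (YAML round-trip, unknown keys rejected)."""

    input_path: str | None = None
    reader2_path: str | None = None
    threshold_mode: str = "fixed"  # "fixed" | "auto"
    threshold_value: float = DPAR_THRESHOLD
    blr_covariates: list[str] = field(default_factory=lambda: ["dpar", "margins"])
    seed: int = 0
    output_formats: list[str] = field(default_factory=lambda: ["json"])
    calibration_preset: str = "default"

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("fixed", "auto"):
            raise ValueError("threshold_mode must be 'fixed' or 'auto'")
        bad = set(self.blr_covariates) - {"dpar", "margins", "diameter"}
        if bad:
            raise ValueError(f"unknown BLR covariates: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _r1(x: float) -> float:
    return round(float(x), 1) if math.isfinite(x) else float("nan")


def _quartile_summary(values: np.ndarray) -> dict:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {"median": float("nan"), "q1": float("nan"), "q3": float("nan"), "n": 0}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": _r1(med), "q1": _r1(q1), "q3": _r1(q3), "n": int(v.size)}


def _cohort_summary(df: pd.DataFrame, cr: np.ndarray) -> dict:
    resp_counts = df["response"].value_counts().to_dict()
    n = len(df)
    per_group: dict = {}
    for label, mask in (("CR+", cr), ("CR-", ~cr)):
        g = df[mask]
        block = {
            "n": int(mask.sum()),
            "smooth_margins": int((g["margins"] == "smooth").sum()),
            "diameter_mm": _quartile_summary(g["diameter_mm"].to_numpy(dtype=float)),
        }
        for name in INDEX_NAMES:
            block[name] = _quartile_summary(g[name].to_numpy(dtype=float))
        per_group[label] = block

    univariate: dict = {}
    if cr.any() and (~cr).any() and min(cr.sum(), (~cr).sum()) >= 2:
        for name in (*INDEX_NAMES, "diameter_mm"):
            x = df.loc[cr, name].to_numpy(dtype=float)
            y = df.loc[~cr, name].to_numpy(dtype=float)
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            if x.size and y.size:
                univariate[name] = cs.format_p(cs.mann_whitney_u(x, y)["p"])
        t = cs.ContingencyTable2x2.from_binary(df["margins"] == "smooth", cr)
        univariate["smooth_margins"] = cs.format_p(cs.fisher_exact_2x2(t))
    else:
        univariate = {"flag": "insufficient n"}

    phase_mad = {
        "UE": _r1(cs.mad(df["hu_lesion_ue"])),
        "ART": _r1(cs.mad(df["hu_lesion_art"])),
        "DEL": _r1(cs.mad(df["hu_lesion_del"])),
    }
    return {
        "n_lesions": n,
        "response_counts": {k: int(resp_counts.get(k, 0)) for k in ("CR", "PR", "SD", "PD")},
        "cr_rate_pct": _r1(100.0 * cr.sum() / n) if n else float("nan"),
        "per_group": per_group,
        "univariate_p": univariate,
        "lesion_hu_mad_by_phase": phase_mad,
    }


def run_full_analysis(
    config: AnalysisConfig,
    df: pd.DataFrame | None = None,
    reader2: pd.DataFrame | None = None,
) -> dict:
    """Run the whole analysis and return the versioned report dict.

    ``df`` may be passed directly (it must follow the lesion-table schema)
    or loaded from ``config.input_path``.  Lesions with non-evaluable DPAR
    are excluded from DPAR-based blocks with their count reported; a cohort
    whose DPAR is entirely non-evaluable aborts.
    """
    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        report = _run(config, df, reader2)
        collected = sorted({str(w.message) for w in caught})
    report["provenance"]["warnings"] = collected
    return report


def _run(config: AnalysisConfig, df: pd.DataFrame | None, reader2: pd.DataFrame | None) -> dict:
    if df is None:
        if config.input_path is None:
            raise ValueError("no input: pass a DataFrame or set config.input_path")
        df = hio.read_lesion_table(config.input_path)
    else:
        hio.validate_lesion_table(df)
    if reader2 is None and config.reader2_path:
        reader2 = hio.read_lesion_table(config.reader2_path)

    df = hio.add_indices(df)
    dpar = df["dpar"].to_numpy(dtype=float)
    evaluable = np.isfinite(dpar)
    if not evaluable.any():
        raise ValueError("all lesions have non-evaluable DPAR; nothing to analyze")

    cr = np.array([cs.dichotomize_response(r) for r in df["response"]])
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.digest(),
            "config": asdict(config),
            "n_input_rows": int(len(df)),
            "n_dpar_non_evaluable": int((~evaluable).sum()),
        },
        "cohort_summary": _cohort_summary(df, cr),
    }

    sub = df[evaluable]
    sub_cr = cr[evaluable]
    enough = sub_cr.sum() >= 2 and (~sub_cr).sum() >= 2

    if not enough:
        flag = {"flag": "insufficient n"}
        report["roc"] = dict(flag)
        report["threshold_selection"] = dict(flag)
        report["stratification"] = dict(flag)
        report["effect_measures"] = dict(flag)
        report["blr"] = dict(flag)
        threshold = config.threshold_value
    else:
        scores = sub["dpar"].to_numpy(dtype=float)
        roc = cs.roc_auc(scores, sub_cr)
        report["roc"] = {
            "auc": round(roc["auc"], 2),
            "ci_low": round(roc["ci_low"], 2),
            "ci_high": round(roc["ci_high"], 2),
            "n_pos": int(sub_cr.sum()),
            "n_neg": int((~sub_cr).sum()),
        }
        sel = cs.select_threshold(scores, sub_cr)
        report["threshold_selection"] = {
            k: {kk: (round(vv, 2) if isinstance(vv, float) else vv) for kk, vv in v.items()}
            for k, v in sel.items()
        }
        threshold = (
            float(sel["consensus"]["threshold"])
            if config.threshold_mode == "auto"
            else float(config.threshold_value)
        )
        report["stratification"] = cs.stratify(df, threshold=threshold)

        high = sub["dpar"].to_numpy(dtype=float) >= threshold
        t = cs.ContingencyTable2x2.from_binary(high, sub_cr)
        eff = {"dpar_table": [t.a, t.b, t.c, t.d], "fisher_p": cs.format_p(cs.fisher_exact_2x2(t))}
        try:
            orr = cs.odds_ratio(t)
            eff["odds_ratio"] = {
                "or": _r1(orr["or"]),
                "ci_low": _r1(orr["ci_low"]),
                "ci_high": _r1(orr["ci_high"]),
            }
        except ValueError as exc:
            eff["odds_ratio"] = {"flag": str(exc)}
        report["effect_measures"] = eff

        design = pd.DataFrame(index=sub.index)
        if "dpar" in config.blr_covariates:
            design["dpar_high"] = high.astype(float)
        if "margins" in config.blr_covariates:
            design["smooth_margins"] = (sub["margins"] == "smooth").astype(float)
        if "diameter" in config.blr_covariates:
            design["diameter_mm"] = sub["diameter_mm"].astype(float)
        try:
            fit = cs.logistic_fit(design, sub_cr.astype(float))
            report["blr"] = {
                name: {
                    "coef": round(v["coef"], 2),
                    "p": cs.format_p(v["p"]),
                    "or": _r1(v["or"]),
                    "or_ci_low": _r1(v["or_ci_low"]),
                    "or_ci_high": _r1(v["or_ci_high"]),
                }
                for name, v in fit.predictors.items()
            }
        except (ValueError, RuntimeError) as exc:
            report["blr"] = {"flag": str(exc)}

    report["threshold_used"] = threshold

    if reader2 is not None:
        reader2 = hio.add_indices(reader2)
        report["agreement"] = _agreement_block(df, reader2)
    return report


def _agreement_block(df: pd.DataFrame, reader2: pd.DataFrame) -> dict:
    block = agr.agreement_table(df, reader2, variables=["dpar"], margins=True)
    out: dict = {}
    for var, stats_ in block["variables"].items():
        out[var] = {
            "n": stats_["n"],
            "wilcoxon_p": cs.format_p(stats_["wilcoxon"]["p"]),
            "icc": round(stats_["icc"]["icc"], 2),
            "cronbach_alpha": round(stats_["cronbach"]["alpha"], 2),
        }
    out["margins_kappa"] = round(block["margins_kappa"]["kappa"], 2)
    return out


def report_to_json(report: dict) -> str:
    """Deterministic serialization: sorted keys, fixed indentation, NaN-safe."""

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            f = float(obj)
            return None if not math.isfinite(f) else f
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        return obj

    return json.dumps(clean(report), sort_keys=True, indent=2) + "\n"


def report_to_markdown(report: dict) -> str:
    """Compact human-readable rendering of the report's headline blocks."""
    lines = [f"# Analysis report (schema {report['schema_version']})", ""]
    summ = report["cohort_summary"]
    lines += [
        f"Lesions: {summ['n_lesions']}  |  CR rate: {summ['cr_rate_pct']}%",
        f"Responses: {summ['response_counts']}",
        "",
    ]
    roc = report.get("roc", {})
    if "auc" in roc:
        lines.append(f"DPAR ROC AUC: {roc['auc']} (95% CI {roc['ci_low']}-{roc['ci_high']})")
    lines.append(f"Threshold used: DPAR >= {report['threshold_used']}")
    strat = report.get("stratification", {})
    if "cells" in strat:
        lines += ["", "| cell | n | CR+ | rate % |", "|---|---|---|---|"]
        for key, cell in strat["cells"].items():
            lines.append(f"| {key} | {cell['n']} | {cell['cr']} | {cell['cr_rate_pct']} |")
        one = strat["one_predictor"]
        lines.append(f"| one favorable predictor | {one['n']} | {one['cr']} | {one['cr_rate_pct']} |")
    if "agreement" in report:
        lines += ["", f"Agreement: {report['agreement']}"]
    return "\n".join(lines) + "\n"


def simulate_command(
    spec: CohortSpec,
    output: str | Path,
    n_phantoms: int = 0,
    force: bool = False,
) -> list[Path]:
    """Write a simulated lesion table (and optional phantom series) to disk."""
    output = Path(output)
    if output.exists() and not force:
        raise FileExistsError(f"{output} exists (use force=True / --force)")
    df = generate_cohort(spec)
    hio.write_lesion_table(df, output, provenance=generator_metadata(spec))
    written = [output]
    if n_phantoms > 0:
        from .indices import compute_indices
        from .synthetic import generate_phantom_series

        for i in range(n_phantoms):
            profile = hio.profile_from_row(df.iloc[i])
            series = generate_phantom_series(
                compute_indices(profile), ue_anchor=profile.hu_lesion_ue, seed=spec.seed + i
            )
            base = output.with_suffix("").with_name(output.stem + f"_phantom{i + 1}")
            written += hio.save_phantom_series(series, base)
    return written


def roi_count_command(n_lesions: int, n_readers: int = 2) -> dict:
    """Protocol ROI bookkeeping (3 lesion + 4 liver ROIs per lesion per reader)."""
    return count_protocol_rois(n_lesions, n_readers)
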