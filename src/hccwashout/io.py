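"""Reading and writing the package's on-disk formats.

Two formats exist: the per-lesion table (CSV, one row per lesion, raw HU
measurements plus categorical descriptors) and phantom series (one 16-bit
single-channel TIFF per phase plus a JSON truth sidecar that declares the
integer HU offset).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import tifffile

from .indices import INDEX_NAMES, compute_indices, dichotomize_dpar
from .measurement import AttenuationProfile, Phase

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import PhantomSeries

MARGIN_CATEGORIES = ("smooth", "other")
LOCATION_CATEGORIES = ("right", "median", "left")
RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")

LESION_COLUMNS = [
    "lesion_id",
    "patient_id",
    "hu_lesion_ue",
    "hu_lesion_art",
    "hu_lesion_del",
    "hu_liver_art_1",
    "hu_liver_art_2",
    "hu_liver_del_1",
    "hu_liver_del_2",
    "margins",
    "diameter_mm",
    "location",
    "response",
]

HU_COLUMNS = [c for c in LESION_COLUMNS if c.startswith("hu_")]

#: stored-value = HU + offset so negative HU fit in uint16
TIFF_HU_OFFSET = 1024


class LesionTableError(ValueError):
    """Schema violation in a lesion-table CSV."""


def validate_lesion_table(df: pd.DataFrame) -> None:
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        raise LesionTableError(f"lesion table missing columns: {missing}")
    bad_rows: list[str] = []
    for col, cats in (
        ("margins", MARGIN_CATEGORIES),
        ("location", LOCATION_CATEGORIES),
        ("response", RESPONSE_CATEGORIES),
    ):
        bad = ~df[col].isin(cats)
        if bad.any():
            bad_rows.append(f"{col}: rows {df.index[bad].tolist()[:10]}")
    for col in HU_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals)
        if bad.any():
            bad_rows.append(f"{col}: non-numeric rows {df.index[bad].tolist()[:10]}")
    if bad_rows:
        raise LesionTableError("invalid lesion table values — " + "; ".join(bad_rows))


def read_lesion_table(path: str | Path) -> pd.DataFrame:
    """Read a per-lesion CSV (UTF-8, '.' decimal, '#' comment lines allowed)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    validate_lesion_table(df)
    return df


def write_lesion_table(
    df: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a per-lesion CSV with an optional '#'-prefixed provenance header."""
    validate_lesion_table(df)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            for key in sorted(provenance):
                fh.write(f"# {key}: {provenance[key]}\n")
        # repr round-trips doubles exactly; pandas' default display rounding
        # would perturb HU values on re-read
        df.to_csv(fh, index=False, float_format=lambda x: repr(float(x)))


def profile_from_row(row: pd.Series) -> AttenuationProfile:
    """Assemble one lesion's attenuation profile from its table row."""
    return AttenuationProfile.from_measurements(
        hu_lesion_ue=row["hu_lesion_ue"],
        hu_lesion_art=row["hu_lesion_art"],
        hu_lesion_del=row["hu_lesion_del"],
        liver_art=(row["hu_liver_art_1"], row["hu_liver_art_2"]),
        liver_del=(row["hu_liver_del_1"], row["hu_liver_del_2"]),
    )


def add_indices(df: pd.DataFrame, threshold: float = 120.0) -> pd.DataFrame:
    """Return a copy with the five index columns and the DPAR dichotomization.

    Adds ``cer``, ``llc``, ``wo_abs``, ``wo_rel``, ``dpar`` (NaN where
    non-evaluable) and ``dpar_class`` ("high"/"low"/"non-evaluable").
    """
    out = df.copy()
    vals = {n: [] for n in INDEX_NAMES}
    for _, row in df.iterrows():
        idx = compute_indices(profile_from_row(row))
        for n in INDEX_NAMES:
            vals[n].append(getattr(idx, n))
    for n in INDEX_NAMES:
        out[n] = vals[n]
    out["dpar_class"] = [dichotomize_dpar(v, threshold) for v in out["dpar"]]
    return out


def save_phantom_series(series: "PhantomSeries", basepath: str | Path) -> list[Path]:
    """Write one 16-bit TIFF per phase plus the JSON truth sidecar.

    Stored pixel value is ``HU + TIFF_HU_OFFSET`` (declared in the sidecar),
    rounded to the nearest integer, so the on-disk series quantizes to
    whole HU.
    """
    basepath = Path(basepath)
    written: list[Path] = []
    for phase, img in series.images.items():
        stored = np.round(img + TIFF_HU_OFFSET)
        if stored.min() < 0 or stored.max() > 65535:
            raise ValueError("HU values outside the uint16 storable range")
        p = basepath.with_name(basepath.name + f"_{phase.value}.tif")
        tifffile.imwrite(p, stored.astype(np.uint16))
        written.append(p)
    sidecar = dict(series.truth)
    sidecar["hu_offset"] = TIFF_HU_OFFSET
    p = basepath.with_name(basepath.name + "_truth.json")
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    written.append(p)
    return written


def load_phantom_images(basepath: str | Path) -> tuple[dict[Phase, np.ndarray], dict]:
    """Load a saved phantom series back into HU arrays plus its truth dict."""
    basepath = Path(basepath)
    with open(basepath.with_name(basepath.name + "_truth.json"), encoding="utf-8") as fh:
        truth = json.load(fh)
    offset = truth.get("hu_offset", TIFF_HU_OFFSET)
    images: dict[Phase, np.ndarray] = {}
    for phase in (Phase.UE, Phase.ART, Phase.DEL):
        p = basepath.with_name(basepath.name + f"_{phase.value}.tif")
        images[phase] = tifffile.imread(p).astype(float) - offset
    return images, truth


def round_or_nan(x: float, ndigits: int) -> float:
    return round(x, ndigits) if isinstance(x, (int, float)) and math.isfinite(x) else float("nan")
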