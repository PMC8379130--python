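"""ROI geometry and Hounsfield-unit bookkeeping for multiphase liver CT.

Quantitative wash-in/wash-out analysis of an HCC nodule starts from mean
attenuation measurements (Hounsfield units, HU) inside elliptic regions of
interest (ROIs): one ROI traced on the largest axial tumor area in the
unenhanced (UE), arterial (ART) and delayed (DEL) phases, plus two ROIs on
adjacent healthy parenchyma in the arterial and delayed phases whose average
is the liver reference.  The portal venous phase may be present in a series
but carries no ROI and feeds no index.

Pixel-inclusion rule: a pixel belongs to an ellipse iff its *center* lies
inside or on the boundary, with 0-based row/col indices and pixel centers at
integer coordinates.  This makes every mean exactly reproducible by
exhaustive enumeration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

HU_MIN = -1000.0
HU_MAX = 3000.0

#: number of parenchyma ROIs the protocol requires per contrast phase
LIVER_ROIS_PER_PHASE = 2


class Phase(str, Enum):
    """Acquisition phase of a four-phase contrast-enhanced CT study.

    ``PV`` (portal venous) is accepted in data files for completeness but is
    never used by any index computation.
    """

    UE = "UE"
    ART = "ART"
    PV = "PV"
    DEL = "DEL"


@dataclass(frozen=True)
class RoiSpec:
    """An elliptic ROI in pixel coordinates on a single phase image."""

    center_row: float
    center_col: float
    semi_axis_a: float  # row semi-axis, pixels
    semi_axis_b: float  # col semi-axis, pixels
    phase: Phase = Phase.UE
    target: str = "lesion"  # "lesion" | "liver"

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ROI semi-axes must be strictly positive")
        if self.target not in ("lesion", "liver"):
            raise ValueError(f"unknown ROI target {self.target!r}")

    @property
    def area_px(self) -> float:
        """Analytic ellipse area in squared pixel units."""
        return math.pi * self.semi_axis_a * self.semi_axis_b


class RoiMean(NamedTuple):
    """Mean HU over an ROI plus the bookkeeping the protocol reports."""

    mean: float
    n_pixels: int
    area_px: float


def ellipse_mask(shape: tuple[int, int], roi: RoiSpec) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside ``roi`` (inclusive)."""
    rows, cols = np.ogrid[0 : shape[0], 0 : shape[1]]
    r2 = ((rows - roi.center_row) / roi.semi_axis_a) ** 2
    c2 = ((cols - roi.center_col) / roi.semi_axis_b) ** 2
    return r2 + c2 <= 1.0


def roi_mean(image: np.ndarray, roi: RoiSpec) -> RoiMean:
    """Mean attenuation of the pixels inside an elliptic ROI.

    Parameters
    ----------
    image
        2-D array of finite HU values.
    roi
        Ellipse specification; only pixels whose centers satisfy
        ``((r-cr)/a)^2 + ((c-cc)/b)^2 <= 1`` contribute.

    Returns
    -------
    RoiMean
        Arithmetic mean, number of contributing pixels, and the analytic
        ellipse area in pixel units.

    Raises
    ------
    ValueError
        If the image is not 2-D/finite or the ellipse contains no pixel
        center ("empty ROI", including ellipses fully outside the image).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    mask = ellipse_mask(image.shape, roi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI: ellipse contains no pixel center inside the image")
    return RoiMean(float(image[mask].mean()), n, roi.area_px)


def liver_reference(mean1: float, mean2: float) -> float:
    """Average of the two parenchyma ROI means — the per-phase liver reference.

    The protocol requires exactly two adjacent-liver ROIs per contrast phase;
    a missing or non-finite value is a protocol violation, not a degenerate
    average.
    """
    if mean1 is None or mean2 is None:
        raise ValueError("protocol requires two liver ROIs")
    m1, m2 = float(mean1), float(mean2)
    if not (math.isfinite(m1) and math.isfinite(m2)):
        raise ValueError("protocol requires two liver ROIs with finite means")
    return (m1 + m2) / 2.0


@dataclass(frozen=True)
class AttenuationProfile:
    """The five HU measurements that feed every enhancement index.

    ``hu_liver_art`` and ``hu_liver_del`` are each the average of exactly two
    parenchyma ROI means (tagged by ``n_liver_rois``).
    """

    hu_lesion_ue: float
    hu_lesion_art: float
    hu_lesion_del: float
    hu_liver_art: float
    hu_liver_del: float
    n_liver_rois: int = field(default=LIVER_ROIS_PER_PHASE)

    def __post_init__(self) -> None:
        for name in (
            "hu_lesion_ue",
            "hu_lesion_art",
            "hu_lesion_del",
            "hu_liver_art",
            "hu_liver_del",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if not (HU_MIN <= v <= HU_MAX):
                raise ValueError(f"{name}={v} outside plausible HU range [{HU_MIN}, {HU_MAX}]")
        if self.n_liver_rois != LIVER_ROIS_PER_PHASE:
            raise ValueError("liver references must average exactly two ROIs")

    @classmethod
    def from_measurements(
        cls,
        hu_lesion_ue: float,
        hu_lesion_art: float,
        hu_lesion_del: float,
        liver_art: tuple[float, float],
        liver_del: tuple[float, float],
    ) -> "AttenuationProfile":
        """Build a profile from raw per-ROI means (two liver ROIs per phase)."""
        return cls(
            hu_lesion_ue=float(hu_lesion_ue),
            hu_lesion_art=float(hu_lesion_art),
            hu_lesion_del=float(hu_lesion_del),
            hu_liver_art=liver_reference(*liver_art),
            hu_liver_del=liver_reference(*liver_del),
        )


def count_protocol_rois(n_lesions: int, n_readers: int = 1) -> dict[str, int]:
    """Protocol ROI bookkeeping for a cohort.

    Each reader traces, per lesion, 3 lesion ROIs (UE/ART/DEL) and 4 liver
    ROIs (2 ROIs x 2 contrast phases) — 7 in total; no ROI is traced on the
    portal venous phase.
    """
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    if n_readers < 1:
        raise ValueError("n_readers must be >= 1")
    lesion_rois = 3 * n_lesions
    liver_rois = 2 * LIVER_ROIS_PER_PHASE * n_lesions
    total = lesion_rois + liver_rois
    return {
        "lesion_rois": lesion_rois,
        "liver_rois": liver_rois,
        "total_per_reader": total,
        "grand_total": total * n_readers,
    }


def note_portal_venous_ignored(phase: Phase | str) -> bool:
    """True (with a log notice) when a portal-venous measurement is ignored."""
    if Phase(phase) is Phase.PV:
        logger.info("portal venous phase carried in input but ignored: no index uses it")
        return True
    return False
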