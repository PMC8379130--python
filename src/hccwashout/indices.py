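"""The five quantitative wash-in/wash-out indices for HCC on multiphase CT.

Wash-in (arterial hyper-enhancement) is quantified by

* ``CER``  — contrast enhancement ratio, (ART − UE) / UE x 100
* ``LLC``  — lesion-to-liver contrast ratio, (ART − LIVART) / LIVART x 100

and wash-out (the subsequent attenuation drop relative to liver) by

* ``WO_abs`` — absolute wash-out, (ART − DEL) / (ART − UE) x 100
* ``WO_rel`` — relative wash-out, (ART − DEL) / ART x 100
* ``DPAR``   — delayed percentage attenuation ratio, LIVDEL / DEL x 100,
  the only index computed from the delayed phase alone; DPAR > 100 means
  the lesion is hypoattenuating relative to liver (washed out), and
  DPAR >= 120 is the dichotomization associated with early complete
  response to DEB-TACE.

Indices are defined only where their denominator is strictly positive
(HU can legitimately be <= 0); a lesion failing a domain rule gets that
index flagged non-evaluable (NaN) rather than being dropped silently.
All indices are scale-invariant: multiplying the five HU values by any
k > 0 leaves them unchanged, which is why a profile can be reconstructed
from an index vector only up to one anchored HU value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .measurement import AttenuationProfile

INDEX_NAMES = ("cer", "llc", "wo_abs", "wo_rel", "dpar")

#: DPAR cut associated with early complete response (inclusive >=)
DPAR_THRESHOLD = 120.0

#: tolerance on the printed-rounding residual of the wo_abs identity
WO_ABS_RESIDUAL_TOL = 0.15


@dataclass(frozen=True)
class EnhancementIndices:
    """Index vector for one lesion; NaN marks a non-evaluable index."""

    cer: float
    llc: float
    wo_abs: float
    wo_rel: float
    dpar: float

    @property
    def non_evaluable(self) -> tuple[str, ...]:
        return tuple(n for n in INDEX_NAMES if not math.isfinite(getattr(self, n)))

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in INDEX_NAMES}

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Display form — printed to one decimal by convention."""
        return {
            n: (round(v, ndigits) if math.isfinite(v) else float("nan"))
            for n, v in self.as_dict().items()
        }


def compute_indices(profile: AttenuationProfile) -> EnhancementIndices:
    """Compute all five indices from one lesion's attenuation profile.

    Domain rules (denominator strictly positive): ``UE`` for CER, ``LIVART``
    for LLC, ``ART − UE`` for WO_abs, ``ART`` for WO_rel, ``DEL`` for DPAR.
    A failed rule yields NaN for that index; a profile with no evaluable
    index at all raises a warning.
    """
    ue = profile.hu_lesion_ue
    art = profile.hu_lesion_art
    del_ = profile.hu_lesion_del
    liv_art = profile.hu_liver_art
    liv_del = profile.hu_liver_del

    nan = float("nan")
    cer = (art - ue) / ue * 100.0 if ue > 0 else nan
    llc = (art - liv_art) / liv_art * 100.0 if liv_art > 0 else nan
    wo_abs = (art - del_) / (art - ue) * 100.0 if art - ue > 0 else nan
    wo_rel = (art - del_) / art * 100.0 if art > 0 else nan
    dpar = liv_del / del_ * 100.0 if del_ > 0 else nan

    out = EnhancementIndices(cer, llc, wo_abs, wo_rel, dpar)
    if len(out.non_evaluable) == len(INDEX_NAMES):
        warnings.warn("all five indices non-evaluable for this profile", stacklevel=2)
    return out


def wo_abs_from_identity(cer: float, wo_rel: float) -> float:
    """WO_abs implied by CER and WO_rel.

    The three formulas share numerators/denominators, so algebraically
    ``wo_abs = wo_rel * (cer + 100) / cer`` for any valid profile.  Returns
    NaN (non-evaluable) when ``cer <= 0``.
    """
    if not math.isfinite(cer) or cer <= 0 or not math.isfinite(wo_rel):
        return float("nan")
    return wo_rel * (cer + 100.0) / cer


def reconstruct_profile(
    indices: EnhancementIndices,
    ue_anchor: float,
    wo_abs_tol: float = WO_ABS_RESIDUAL_TOL,
) -> AttenuationProfile:
    """Invert the index system back to an attenuation profile.

    The indices are scale-invariant, so the unenhanced lesion attenuation
    must be anchored; every other HU value then follows in closed form::

        ART    = ue_anchor * (1 + cer/100)
        LIVART = ART / (1 + llc/100)
        DEL    = ART * (1 - wo_rel/100)
        LIVDEL = DEL * dpar / 100

    ``wo_abs`` is redundant given ``cer`` and ``wo_rel``; if the supplied
    triple is inconsistent beyond ``wo_abs_tol`` (printed-rounding slack),
    a warning reports the residual.  Round-tripping through
    :func:`compute_indices` reproduces cer, llc, wo_rel and dpar exactly
    and wo_abs up to that rounding.
    """
    if ue_anchor <= 0:
        raise ValueError("ue_anchor must be > 0")
    if not indices.cer > -100:
        raise ValueError("cer must exceed -100 for a positive arterial value")
    if not indices.llc > -100:
        raise ValueError("llc must exceed -100 for a positive liver reference")
    if not indices.dpar > 0:
        raise ValueError("dpar must be > 0")

    art = ue_anchor * (1.0 + indices.cer / 100.0)
    liv_art = art / (1.0 + indices.llc / 100.0)
    dele = art * (1.0 - indices.wo_rel / 100.0)
    liv_del = dele * indices.dpar / 100.0

    if math.isfinite(indices.wo_abs):
        implied = wo_abs_from_identity(indices.cer, indices.wo_rel)
        if math.isfinite(implied):
            residual = implied - indices.wo_abs
            if abs(residual) > wo_abs_tol:
                warnings.warn(
                    f"wo_abs inconsistent with (cer, wo_rel): residual {residual:+.3f} "
                    f"exceeds tolerance {wo_abs_tol}",
                    stacklevel=2,
                )

    return AttenuationProfile(
        hu_lesion_ue=float(ue_anchor),
        hu_lesion_art=art,
        hu_lesion_del=dele,
        hu_liver_art=liv_art,
        hu_liver_del=liv_del,
    )


def dichotomize_dpar(dpar: float, threshold: float = DPAR_THRESHOLD) -> str:
    """Dichotomize DPAR at the response-associated cut (inclusive >=).

    Returns ``"high"``, ``"low"`` or ``"non-evaluable"`` (NaN propagates).
    """
    if dpar is None or not math.isfinite(dpar):
        return "non-evaluable"
    return "high" if dpar >= threshold else "low"
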