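"""Operational malnutrition screen: Hamwi ideal body weight and albumin.

A person is classified malnourished when their measured weight is below 90%
of Hamwi ideal body weight and/or their serum albumin is below 3.5 g/dL.
Both comparisons are strict; a value exactly at a threshold is not flagged.
The Hamwi rule is imperial (106 lb + 6 lb/inch over 5 ft for men, 100 lb +
5 lb/inch over 5 ft for women); microdata arrive metric and are converted
internally.  Heights below 5 ft extrapolate the same slope downward, floored
at a configurable minimum so ideal weight stays positive.

Missing serum albumin leaves the albumin criterion unknown: the overall
status is then unknown unless the weight criterion already decides it.
Records missing height or weight cannot be assessed at all and are excluded
(never silently classified non-malnourished).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CM_PER_INCH = 2.54
KG_PER_LB = 0.45359237

#: default thresholds of the screen
PCT_IBW_THRESHOLD = 0.90
ALBUMIN_THRESHOLD_GDL = 3.5
#: default floor (lb) for extrapolated ideal weights at very short statures
IBW_FLOOR_LB = 50.0


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs of the malnutrition screen (overridable for sensitivity runs)."""

    pct_ibw: float = PCT_IBW_THRESHOLD
    albumin_gdl: float = ALBUMIN_THRESHOLD_GDL
    ibw_floor_lb: float = IBW_FLOOR_LB


@dataclass(frozen=True)
class MalnutritionAssessment:
    """Outcome of the screen for one person.

    ``low_albumin`` and ``malnourished`` are ``None`` when undetermined
    (albumin missing and the weight criterion alone does not decide).
    """

    ideal_weight_lb: float
    percent_ibw: float
    low_weight: bool
    low_albumin: bool | None
    malnourished: bool | None


def hamwi_ideal_weight(sex, height_cm=None, *, height_in=None, floor_lb: float = IBW_FLOOR_LB):
    """Hamwi ideal body weight in pounds.

    Males: 106 lb + 6 lb per inch over 60 in; females: 100 lb + 5 lb per
    inch over 60 in.  The same linear form extends below 60 in, floored at
    ``floor_lb``.  Accepts scalars or arrays; exactly one of ``height_cm`` /
    ``height_in`` must be given.
    """
    if (height_cm is None) == (height_in is None):
        raise ValueError("provide exactly one of height_cm or height_in")
    h_in = np.asarray(height_in if height_in is not None else np.asarray(height_cm) / CM_PER_INCH,
                      dtype=float)
    if np.any(h_in <= 0):
        raise ValueError("height must be positive")
    sex_arr = np.asarray(sex)
    male = sex_arr == "male"
    ok = np.atleast_1d(male | (sex_arr == "female"))
    if not ok.all():
        bad = sorted({str(s) for s in np.atleast_1d(sex_arr)[~ok]})
        raise ValueError(f"sex must be 'male' or 'female', got {bad}")
    ibw = np.where(male, 106.0 + 6.0 * (h_in - 60.0), 100.0 + 5.0 * (h_in - 60.0))
    ibw = np.maximum(ibw, floor_lb)
    if np.ndim(sex) == 0 and np.ndim(h_in) == 0:
        return float(ibw)
    return ibw


def classify(
    sex: str,
    height_cm: float,
    weight_kg: float,
    albumin_gdl: float | None = None,
    thresholds: Thresholds = Thresholds(),
) -> MalnutritionAssessment:
    """Classify one person against the percent-IBW / albumin rule.

    Raises ``ValueError`` if height or weight is missing or nonpositive:
    such records must be excluded upstream, not classified.
    """
    if height_cm is None or weight_kg is None or np.isnan(height_cm) or np.isnan(weight_kg):
        raise ValueError("height and weight are required for malnutrition assessment")
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    ibw_lb = hamwi_ideal_weight(sex, height_cm, floor_lb=thresholds.ibw_floor_lb)
    pct = (weight_kg / KG_PER_LB) / ibw_lb
    low_weight = bool(pct < thresholds.pct_ibw)
    if albumin_gdl is None or (isinstance(albumin_gdl, float) and np.isnan(albumin_gdl)):
        low_albumin: bool | None = None
    else:
        low_albumin = bool(albumin_gdl < thresholds.albumin_gdl)
    if low_weight or low_albumin:
        status: bool | None = True
    elif low_albumin is None:
        status = None
    else:
        status = False
    return MalnutritionAssessment(
        ideal_weight_lb=float(ibw_lb),
        percent_ibw=float(pct),
        low_weight=low_weight,
        low_albumin=low_albumin,
        malnourished=status,
    )


def classify_records(
    records: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized screen over an examination survey table.

    Returns ``(indicator, assessable)`` where ``indicator`` is a float array
    with 1.0 = malnourished, 0.0 = not malnourished, NaN = unknown, and
    ``assessable`` marks records with usable height and weight.  Records with
    ``assessable == False`` carry NaN in ``indicator`` and must not enter any
    prevalence denominator.
    """
    height = records["height_cm"].to_numpy(dtype=float)
    weight = records["weight_kg"].to_numpy(dtype=float)
    if "albumin_gdl" in records.columns:
        albumin = records["albumin_gdl"].to_numpy(dtype=float)
    else:
        albumin = np.full(len(records), np.nan)
    sex = records["sex"].to_numpy()

    assessable = np.isfinite(height) & np.isfinite(weight) & (height > 0) & (weight > 0)
    indicator = np.full(len(records), np.nan)
    if assessable.any():
        ibw_lb = hamwi_ideal_weight(
            sex[assessable], height[assessable], floor_lb=thresholds.ibw_floor_lb
        )
        pct = (weight[assessable] / KG_PER_LB) / ibw_lb
        low_w = pct < thresholds.pct_ibw
        alb = albumin[assessable]
        alb_known = np.isfinite(alb)
        low_a = alb_known & (alb < thresholds.albumin_gdl)
        out = np.full(low_w.shape, np.nan)
        out[low_w | low_a] = 1.0
        out[~low_w & alb_known & ~low_a] = 0.0
        indicator[assessable] = out
    return indicator, assessable
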