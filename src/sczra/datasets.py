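"""Reference measurements used as worked-example inputs.

The split-cell study that this package analyses reports, per treatment, the
weight-loss corrosion rate of each coupon and a current-predicted biotic
corrosion rate (all in mpy).  The raw masses and current traces behind
those numbers are not deposited, so the reported rates themselves are the
inputs for the ratio/difference/accuracy arithmetic.
"""

from __future__ import annotations

import pandas as pd

from .corrosion import CorrosionRate, biotic_rate_actual, corrosion_rate_ratio
from .faradaic import prediction_accuracy

__all__ = ["reference_treatment_rates", "reference_table_metrics"]

_ROWS = [
    # treatment, rate_we1_mpy, rate_we2_mpy, predicted_biotic_mpy
    ("with_bicarbonate__uninoculated", 3.9, 3.9, 0.2),
    ("with_bicarbonate__WE1_inoculated", 4.7, 3.6, 1.0),
    ("without_bicarbonate__uninoculated", 4.5, 4.9, 0.2),
    ("without_bicarbonate__WE1_inoculated", 1.4, 2.7, 1.1),
]


def reference_treatment_rates() -> pd.DataFrame:
    """Reported per-treatment coupon rates and predicted biotic rates (mpy)."""
    return pd.DataFrame(_ROWS, columns=["treatment", "rate_we1_mpy",
                                        "rate_we2_mpy", "predicted_biotic_mpy"])


def reference_table_metrics() -> pd.DataFrame:
    """Recompute CRR, actual biotic rate and prediction accuracy from the
    reported coupon rates.

    Returns one row per treatment with one-decimal CRR and biotic rates
    (matching reported precision) and the percent agreement between the
    predicted and actual biotic rates (None where the actual rate is zero).
    """
    rows = []
    for treatment, r1, r2, pred in _ROWS:
        cr1 = CorrosionRate(r1, "mpy")
        cr2 = CorrosionRate(r2, "mpy")
        biotic, anode = biotic_rate_actual(cr1, cr2)
        acc = prediction_accuracy(CorrosionRate(pred, "mpy"), biotic)
        rows.append({
            "treatment": treatment,
            "rate_we1_mpy": r1,
            "rate_we2_mpy": r2,
            "crr": round(corrosion_rate_ratio(cr1, cr2), 1),
            "biotic_actual_mpy": round(biotic.value, 1),
            "net_anode": anode,
            "predicted_biotic_mpy": pred,
            "accuracy_percent": acc,
        })
    return pd.DataFrame(rows)
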