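"""End-to-end treatment analysis: coupons + trace -> TreatmentResult.

Combines the weight-loss route (converged mass loss -> rate, CRR, actual
biotic rate) with the faradaic route (charge integral -> predicted biotic
rate, net-anode call, prediction accuracy).
"""

from __future__ import annotations

from typing import Optional

from .corrosion import (CorrosionRate, TreatmentResult, biotic_rate_actual,
                        corrosion_rate_ratio, coupon_corrosion_rate,
                        DEFAULT_MASS_TOLERANCE)
from .faradaic import FaradayParams, prediction_accuracy, predicted_biotic_rate
from .io import CouponRecord, ElectrochemTrace

__all__ = ["analyze_treatment"]


def analyze_treatment(coupon_we1: CouponRecord, coupon_we2: CouponRecord,
                      trace: Optional[ElectrochemTrace] = None,
                      treatment: str = "",
                      faraday: FaradayParams = FaradayParams(),
                      mass_tolerance: float = DEFAULT_MASS_TOLERANCE) -> TreatmentResult:
    """Analyse one treatment from its two coupons and (optionally) its trace.

    The actual biotic rate comes from the coupon mass losses; when a trace
    is supplied the predicted biotic rate, net-anode call and accuracy are
    added.  The predicted rate uses the anodic coupon's geometry (the two
    coupons are nominally identical).
    """
    r1 = coupon_corrosion_rate(coupon_we1, tolerance=mass_tolerance, units="mpy")
    r2 = coupon_corrosion_rate(coupon_we2, tolerance=mass_tolerance, units="mpy")
    crr = corrosion_rate_ratio(r1, r2)
    biotic, anode_actual = biotic_rate_actual(r1, r2)

    pred: Optional[CorrosionRate] = None
    anode_pred: Optional[str] = None
    acc: Optional[float] = None
    if trace is not None:
        anode_coupon = coupon_we2 if _leans_we2(trace) else coupon_we1
        pred, anode_pred = predicted_biotic_rate(trace, anode_coupon,
                                                 params=faraday, units="mpy")
        acc = prediction_accuracy(pred, biotic)

    return TreatmentResult(
        treatment=treatment,
        rate_we1=r1, rate_we2=r2, crr=crr,
        biotic_rate_actual=biotic, net_anode_actual=anode_actual,
        biotic_rate_predicted=pred, net_anode_predicted=anode_pred,
        accuracy_percent=acc,
    )


def _leans_we2(trace: ElectrochemTrace) -> bool:
    from .faradaic import integrate_charge
    return integrate_charge(trace).total < 0
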