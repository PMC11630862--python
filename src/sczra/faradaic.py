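"""Faradaic analysis of zero-resistance ammetry traces.

The charge passed between the shorted coupons, Q = ∫ I dt, converts to an
equivalent iron mass loss through Faraday's law,

    Δm = |Q| · a / (n · F)

with a = 55.845 g/mol (Fe), n = 2 (Fe0 → Fe2+ + 2 e−) and
F = 96485 C/mol.  Pushed through the weight-loss rate formula this yields a
current-predicted biotic corrosion rate that can be compared with the
coupon-measured one.  The sign of Q localises the net anode: positive total
charge means electrons left WE1 (WE1 anodic), negative means WE2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .corrosion import CorrosionRate, Units, corrosion_rate
from .io import CouponRecord, ElectrochemTrace

#: Faraday constant, C/mol.
FARADAY = 96485.0

#: Atomic mass of iron, g/mol.
ATOMIC_MASS_FE = 55.845

SECONDS_PER_HOUR = 3600.0

#: Default |Q| threshold below which the cell is called "balanced",
#: expressed per 30 days of window and scaled linearly with window length.
BALANCED_Q_PER_30D = 1.0  # coulombs


@dataclass(frozen=True)
class FaradayParams:
    """Faraday's-law parameters for converting charge to metal mass."""

    atomic_mass: float = ATOMIC_MASS_FE  # g/mol
    valence: int = 2                     # electrons per metal atom oxidised
    faraday_constant: float = FARADAY    # C/mol

    def __post_init__(self) -> None:
        if self.atomic_mass <= 0 or self.faraday_constant <= 0:
            raise ValueError("atomic mass and Faraday constant must be positive")
        if int(self.valence) != self.valence or self.valence < 1:
            raise ValueError(f"valence must be an integer >= 1, got {self.valence}")


@dataclass
class ChargeSummary:
    """Signed total charge plus its sign-partitioned components (coulombs)."""

    total: float      # = positive + negative
    positive: float   # >= 0
    negative: float   # <= 0
    window: tuple[float, float]  # hours

    @property
    def window_hours(self) -> float:
        return self.window[1] - self.window[0]


def integrate_charge(trace: ElectrochemTrace,
                     window: Optional[tuple[float, float]] = None) -> ChargeSummary:
    """Trapezoidal charge integral over a time window, in coulombs.

    Works on irregular timestamps without resampling (the trapezoid rule is
    exact for piecewise-linear current).  Positive and negative components
    are integrated separately over sign-partitioned segments, splitting
    mixed-sign segments at the linearly interpolated zero crossing, so that
    ``total == positive + negative`` exactly.
    """
    t, i = trace.time, trace.current
    lo, hi = trace.span
    if window is None:
        window = (lo, hi)
    w0, w1 = window
    if w0 < lo - 1e-12 or w1 > hi + 1e-12 or w1 <= w0:
        raise ValueError(f"window {window} outside trace span ({lo}, {hi})")
    mask = (t > w0) & (t < w1)
    tt = np.concatenate(([w0], t[mask], [w1]))
    ii = np.concatenate(([np.interp(w0, t, i)], i[mask], [np.interp(w1, t, i)]))
    if len(tt) < 2:
        raise ValueError("need at least 2 samples inside the window")

    pos = neg = 0.0
    for k in range(len(tt) - 1):
        dt = (tt[k + 1] - tt[k]) * SECONDS_PER_HOUR
        a, b = ii[k], ii[k + 1]
        if a * b < 0:
            # split at the zero crossing; two triangles of opposite sign
            f = a / (a - b)
            area1 = 0.5 * a * f * dt
            area2 = 0.5 * b * (1.0 - f) * dt
            for area in (area1, area2):
                if area >= 0:
                    pos += area
                else:
                    neg += area
        else:
            area = 0.5 * (a + b) * dt
            if area >= 0:
                pos += area
            else:
                neg += area
    return ChargeSummary(total=pos + neg, positive=pos, negative=neg, window=(w0, w1))


def faraday_mass(Q: float, params: FaradayParams = FaradayParams()) -> float:
    """Metal mass (g) equivalent to |Q| coulombs: Δm = |Q|·a/(n·F)."""
    return abs(Q) * params.atomic_mass / (params.valence * params.faraday_constant)


def infer_net_anode(trace: ElectrochemTrace,
                    threshold_per_30d: float = BALANCED_Q_PER_30D,
                    window: Optional[tuple[float, float]] = None) -> str:
    """Localise the net anode from the sign of the total charge.

    Positive total charge -> electrons left WE1 -> "WE1"; negative -> "WE2";
    |Q| below the (window-scaled) threshold -> "balanced".
    """
    summary = integrate_charge(trace, window)
    threshold = threshold_per_30d * summary.window_hours / 720.0
    if abs(summary.total) < threshold:
        return "balanced"
    return "WE1" if summary.total > 0 else "WE2"


def predicted_biotic_rate(trace: ElectrochemTrace, coupon: CouponRecord,
                          params: FaradayParams = FaradayParams(),
                          units: Units = "mm_per_yr") -> tuple[CorrosionRate, str]:
    """Current-predicted biotic corrosion rate and the net-anode call.

    Charge is integrated over the full trace (assumed to span the coupon
    exposure), converted to mass by Faraday's law and pushed through the
    weight-loss rate formula with the coupon's area, exposure time and
    density.
    """
    lo, hi = trace.span
    if hi - lo > coupon.exposure_time + 1e-9:
        raise ValueError(
            f"trace span {hi - lo:.3f} h exceeds coupon exposure {coupon.exposure_time} h"
        )
    summary = integrate_charge(trace)
    dm = faraday_mass(summary.total, params)
    rate = corrosion_rate(dm, coupon.exposed_area, coupon.exposure_time,
                          coupon.density, units=units)
    return rate, infer_net_anode(trace)


def prediction_accuracy(predicted: CorrosionRate, actual: CorrosionRate) -> Optional[float]:
    """Relative agreement, percent: 100·(1 − |predicted − actual|/actual).

    Floored at 0.  Returns None when the actual biotic rate is zero (the
    uninoculated case, where accuracy is not applicable).
    """
    a = actual.value
    p = predicted.to(actual.units).value
    if a == 0:
        return None
    return max(0.0, 100.0 * (1.0 - abs(p - a) / a))
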