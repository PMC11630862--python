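"""Weight-loss corrosion metrics for split-cell coupon experiments.

The weight-loss corrosion rate follows the ASTM G1 form

    CR [mm/yr] = K * W / (D * A * t)

with K = 8.76e4, W the converged mass loss in grams, A the exposed area in
cm^2, t the exposure time in hours and D the alloy density in g/cm^3.  The
corrosion rate ratio (CRR) divides the rate of the optionally-inoculated
chamber's coupon (WE1) by the uninoculated chamber's coupon (WE2); abiotic
corrosion is assumed to act on both coupons equally, so the absolute rate
difference is attributed to microbial activity ("biotic" rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

from .io import CouponRecord

#: ASTM G1 constant giving mm/yr from g, cm^2, h, g/cm^3.
K_MM_PER_YR = 8.76e4

#: Exact conversion from mm/yr to mils (thousandths of an inch) per year.
MPY_PER_MM_YR = 39.3701

#: Handbook density of UNS G10180 carbon steel, g/cm^3 (overridable).
DENSITY_UNS_G10180 = 7.87

#: Mass-change tolerance (g) below which successive oxide-stripping cycles
#: are considered converged ("no mass lost between wash cycles").
DEFAULT_MASS_TOLERANCE = 0.001

Units = Literal["mm_per_yr", "mpy"]


@dataclass(frozen=True)
class CorrosionRate:
    """A non-negative corrosion rate with explicit penetration units."""

    value: float
    units: Units = "mm_per_yr"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"corrosion rate must be >= 0, got {self.value}")
        if self.units not in ("mm_per_yr", "mpy"):
            raise ValueError(f"unknown units {self.units!r}")

    def to(self, units: Units) -> "CorrosionRate":
        if units == self.units:
            return self
        if units == "mpy":
            return CorrosionRate(self.value * MPY_PER_MM_YR, "mpy")
        return CorrosionRate(self.value / MPY_PER_MM_YR, "mm_per_yr")

    @property
    def mpy(self) -> float:
        return self.to("mpy").value

    @property
    def mm_per_yr(self) -> float:
        return self.to("mm_per_yr").value


@dataclass
class MassLossResult:
    """Converged weight loss of one coupon through repeated cleaning cycles."""

    mass_loss: float          # grams
    converged_cycle: int      # 1-based index of the first converged cycle
    converged: bool           # False -> last cycle used, flagged


@dataclass
class TreatmentResult:
    """Per-treatment corrosion summary (rates, CRR, biotic rates, accuracy)."""

    treatment: str
    rate_we1: CorrosionRate
    rate_we2: CorrosionRate
    crr: float
    biotic_rate_actual: CorrosionRate
    net_anode_actual: Literal["WE1", "WE2", "balanced"]
    biotic_rate_predicted: Optional[CorrosionRate] = None
    net_anode_predicted: Optional[str] = None
    accuracy_percent: Optional[float] = None
    provenance: dict = field(default_factory=dict)


def mass_loss(coupon: CouponRecord, tolerance: float = DEFAULT_MASS_TOLERANCE) -> MassLossResult:
    """Converged mass loss W = initial mass - first converged cycle mass.

    Convergence is the first cleaning cycle whose mass change relative to the
    previous weighing (the initial mass for cycle 1) is below ``tolerance``.
    If no cycle converges, the last cycle is used and the result is flagged.
    """
    cycles = coupon.cleaning_cycle_masses
    if len(cycles) == 0:
        raise ValueError(f"coupon {coupon.coupon_id}: no cleaning cycles recorded")
    prev = coupon.initial_mass
    for i, m in enumerate(cycles):
        if abs(prev - m) < tolerance:
            return MassLossResult(coupon.initial_mass - m, i + 1, True)
        prev = m
    return MassLossResult(coupon.initial_mass - cycles[-1], len(cycles), False)


def corrosion_rate(
    W: float,
    A: float,
    t: float,
    D: float = DENSITY_UNS_G10180,
    units: Units = "mm_per_yr",
) -> CorrosionRate:
    """Weight-loss corrosion rate CR = K*W/(D*A*t), K = 8.76e4 -> mm/yr.

    Parameters are grams, cm^2, hours, g/cm^3.  ``units`` selects the
    presentation unit; the computation is always done in mm/yr first.
    """
    if A <= 0 or t <= 0 or D <= 0:
        raise ValueError(f"A, t, D must be positive (got A={A}, t={t}, D={D})")
    if W < 0:
        raise ValueError(f"mass loss must be >= 0, got {W}")
    cr = CorrosionRate(K_MM_PER_YR * W / (D * A * t), "mm_per_yr")
    return cr.to(units)


def coupon_corrosion_rate(
    coupon: CouponRecord,
    tolerance: float = DEFAULT_MASS_TOLERANCE,
    units: Units = "mm_per_yr",
) -> CorrosionRate:
    """Convenience: converged mass loss pushed through the rate formula."""
    W = mass_loss(coupon, tolerance=tolerance).mass_loss
    return corrosion_rate(W, coupon.exposed_area, coupon.exposure_time,
                          coupon.density, units=units)


def corrosion_rate_ratio(r1: CorrosionRate, r2: CorrosionRate) -> float:
    """CRR = rate(WE1) / rate(WE2); requires a nonzero WE2 rate."""
    a, b = _same_units(r1, r2)
    if b == 0:
        raise ZeroDivisionError("corrosion rate ratio undefined: WE2 rate is zero")
    return a / b


def biotic_rate_actual(r1: CorrosionRate, r2: CorrosionRate) -> tuple[CorrosionRate, str]:
    """|rate(WE1) - rate(WE2)| with the faster-corroding electrode annotated.

    Returns the absolute difference in the units of ``r1`` and the net-anode
    annotation: "WE1" if WE1 corroded faster, "WE2" if WE2 did, "balanced"
    on an exact tie.
    """
    a, b = _same_units(r1, r2)
    diff = a - b
    if diff > 0:
        anode = "WE1"
    elif diff < 0:
        anode = "WE2"
    else:
        anode = "balanced"
    return CorrosionRate(abs(diff), r1.units), anode


def _same_units(r1: CorrosionRate, r2: CorrosionRate) -> tuple[float, float]:
    return r1.value, r2.to(r1.units).value


def round_for_report(x: Optional[float], ndigits: int = 1) -> Optional[float]:
    """One-decimal rounding used for table-style reporting."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return round(x, ndigits)
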