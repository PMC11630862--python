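"""Charge-balance pH speciation for the synthetic brine.

The brine is modelled as strong chloride salts (NaCl, CaCl2, MgCl2, KCl)
plus three weak-acid systems: carbonate (closed total or CO2-fixed open
system), acetate, and a lumped monoprotic "background" buffer standing in
for phosphate, yeast extract and biomass.  pH is the unique root of the
charge balance

    Z + [buffer counter-cation] + [H+]
        = [OH−] + [HCO3−] + 2[CO3 2−] + [Ac−] + [B−]

found by bracketed root finding on pH ∈ (0, 14).  Concentration-based
equilibria are used (activity coefficients ignored despite the high ionic
strength); all constants are configurable so an ionic-strength correction
can be layered on later.

K2HPO4 (0.05 mM) is excluded from the strong-ion charge: its potassium is
balanced by its phosphate, which is folded into the background buffer.
With the default recipe this makes the chloride-salt charge close exactly,
so the strong-ion excess Z equals the NaHCO3 sodium (30 mM with
bicarbonate, 0 without).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from scipy.optimize import brentq

__all__ = ["MediumComposition", "EquilibriumConstants", "SpeciationState",
            "solve_pH", "InfeasibleCompositionError"]


class InfeasibleCompositionError(ValueError):
    """Charge balance has no root in (0, 14)."""


@dataclass(frozen=True)
class EquilibriumConstants:
    """Mixed (concentration-based) equilibrium constants at 25 °C, as pK."""

    pka_acetic: float = 4.756
    pk1_carbonic: float = 6.35
    pk2_carbonic: float = 10.33
    pkw: float = 14.00


@dataclass
class MediumComposition:
    """Synthetic brine recipe (mM) with carbonate-system handling flags.

    Defaults follow the brine used to mimic gas-transmission-line fluids:
    350 NaCl, 30 NaHCO3, 25 CaCl2, 15 MgCl2, 2 KCl, 0.05 K2HPO4 and 20 mM
    glucose.  ``co2_open`` selects a fixed dissolved CO2 (80:20 N2:CO2
    headspace) instead of a closed carbonate total; the bicarbonate-free
    treatment uses an N2 headspace, i.e. a closed system with zero total
    carbonate.

    The background buffer (total ``buffer_total`` at ``buffer_pka``, added
    half-neutralised) lumps phosphate, yeast extract and biomass; it is a
    calibration artifact sized so ~20 mM accumulated acetate brings the
    unbuffered chamber close to pH 4.5.
    """

    nacl: float = 350.0
    nahco3: float = 30.0
    cacl2: float = 25.0
    mgcl2: float = 15.0
    kcl: float = 2.0
    k2hpo4: float = 0.05
    glucose: float = 20.0
    bicarbonate_present: bool = True
    co2_open: bool = True
    co2_aq_mM: float = 6.8          # Henry's-law CO2(aq) at 0.2 atm, ~0.034 M/atm
    buffer_total: float = 14.4      # mM
    buffer_pka: float = 6.8

    def __post_init__(self) -> None:
        for name in ("nacl", "nahco3", "cacl2", "mgcl2", "kcl", "k2hpo4",
                     "glucose", "co2_aq_mM", "buffer_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.bicarbonate_present:
            self.nahco3 = 0.0
            self.co2_open = False

    @property
    def strong_ion_excess_mM(self) -> float:
        """Net strong-ion charge Z (mM): cations minus chloride."""
        cations = self.nacl + self.nahco3 + 2 * self.cacl2 + 2 * self.mgcl2 + self.kcl
        anions = self.nacl + 2 * self.cacl2 + 2 * self.mgcl2 + self.kcl
        return cations - anions


@dataclass
class SpeciationState:
    """Resolved equilibrium speciation of one chamber (concentrations in M)."""

    pH: float
    h: float
    oh: float
    co2_aq: float
    hco3: float
    co3: float
    acetate_ion: float
    acetic_acid: float
    strong_ion_charge: float   # Z + buffer counter-cation, M
    charge_residual: float     # M; |residual| < 1e-10 by construction


def _species(pH: float, comp: MediumComposition, total_acetate_M: float,
             ks: EquilibriumConstants) -> dict[str, float]:
    h = 10.0 ** (-pH)
    kw = 10.0 ** (-ks.pkw)
    k1 = 10.0 ** (-ks.pk1_carbonic)
    k2 = 10.0 ** (-ks.pk2_carbonic)
    ka = 10.0 ** (-ks.pka_acetic)
    kb = 10.0 ** (-comp.buffer_pka)

    oh = kw / h
    if comp.bicarbonate_present and comp.co2_open:
        co2 = comp.co2_aq_mM * 1e-3
        hco3 = k1 * co2 / h
        co3 = k2 * hco3 / h
    else:
        ct = comp.nahco3 * 1e-3
        denom = h * h + k1 * h + k1 * k2
        co2 = ct * h * h / denom
        hco3 = ct * k1 * h / denom
        co3 = ct * k1 * k2 / denom
    ac = total_acetate_M * ka / (ka + h)
    hac = total_acetate_M - ac
    bmin = comp.buffer_total * 1e-3 * kb / (kb + h)
    return {"h": h, "oh": oh, "co2": co2, "hco3": hco3, "co3": co3,
            "ac": ac, "hac": hac, "bmin": bmin}


def _charge_balance(pH: float, comp: MediumComposition, total_acetate_M: float,
                    ks: EquilibriumConstants) -> float:
    s = _species(pH, comp, total_acetate_M, ks)
    z = comp.strong_ion_excess_mM * 1e-3 + 0.5 * comp.buffer_total * 1e-3
    return (z + s["h"]) - (s["oh"] + s["hco3"] + 2 * s["co3"] + s["ac"] + s["bmin"])


def solve_pH(composition: MediumComposition, total_acetate: float = 0.0,
             constants: Optional[EquilibriumConstants] = None) -> SpeciationState:
    """Solve the chamber pH from the charge balance by bracketed root finding.

    Parameters
    ----------
    composition:
        Brine recipe and carbonate-system flags.
    total_acetate:
        Total acetate (dissociated + undissociated), mM.
    constants:
        Equilibrium constants; defaults to 25 °C values.

    The charge-balance residual is strictly decreasing in pH, so the root in
    (0, 14) is unique when it exists.
    """
    if total_acetate < 0:
        raise ValueError("total_acetate must be >= 0")
    ks = constants or EquilibriumConstants()
    at = total_acetate * 1e-3
    f = lambda pH: _charge_balance(pH, composition, at, ks)
    lo, hi = 1e-8, 14.0 - 1e-8
    flo, fhi = f(lo), f(hi)
    if flo < 0 or fhi > 0:
        raise InfeasibleCompositionError(
            f"charge balance has no root in (0, 14): f(0)={flo:.3g}, f(14)={fhi:.3g}"
        )
    pH = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    s = _species(pH, composition, at, ks)
    return SpeciationState(
        pH=float(pH), h=s["h"], oh=s["oh"], co2_aq=s["co2"], hco3=s["hco3"],
        co3=s["co3"], acetate_ion=s["ac"], acetic_acid=s["hac"],
        strong_ion_charge=composition.strong_ion_excess_mM * 1e-3
        + 0.5 * composition.buffer_total * 1e-3,
        charge_residual=float(f(pH)),
    )
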