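"""Synthetic split-cell generator: fermentation, acidification, galvanic current.

The generator reproduces the mechanism under study.  Fermentative growth in
the inoculated chamber consumes glucose by Monod kinetics and excretes
acetate; the accumulated acetate acidifies the chamber through the brine
charge balance; and the pH asymmetry between the chambers drives a
Tafel-like galvanic current between the shorted coupons,

    I(t) = −k0 · (10^(−β·pH_WE1) − 10^(−β·pH_WE2)),

so a more acidic WE1 chamber (cathodic proton reduction at WE1) gives
negative current, i.e. electrons flowing WE2 → WE1 and anodic iron
dissolution on WE2.  Ground-truth coupon mass losses are a constant
abiotic baseline on both coupons plus the Faraday equivalent of the
(noise-free) integrated charge added to the net anode, so the emitted trace
integrates exactly to the imposed differential mass loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .corrosion import DENSITY_UNS_G10180, K_MM_PER_YR, corrosion_rate
from .faradaic import FaradayParams, SECONDS_PER_HOUR, faraday_mass
from .io import (ChamberChemistry, CouponRecord, ElectrochemTrace,
                 TreatmentConfig, write_chemistry, write_coupon_table,
                 write_trace)
from .speciation import MediumComposition, SpeciationState, solve_pH

__all__ = ["FermentationParams", "GalvanicModelParams", "FermentationSeries",
           "SimulatedTreatment", "simulate_fermentation", "simulate_sczra",
           "default_treatments", "generate_fixture_suite",
           "MediumComposition"]

#: Exposed coupon area, cm^2 (652 mm^2).
DEFAULT_AREA_CM2 = 6.52
DEFAULT_INITIAL_MASS_G = 25.0
DEFAULT_DURATION_H = 720.0
DEFAULT_DT_H = 0.25            # 15-min potentiostat logging
CHEMISTRY_SAMPLING_H = 24.0    # periodic chamber sampling


@dataclass(frozen=True)
class FermentationParams:
    """Monod fermentation kinetics of the glucose-fermenting enrichment.

    ``biomass_yield`` is in A600 units per mM glucose; ``acetate_yield`` in
    mol acetate per mol glucose (stoichiometric ceiling 3 for a C6 sugar).
    Defaults describe a culture inoculated at A600 = 1 into 20 mM glucose,
    reaching stationary phase within a few days.
    """

    mu_max: float = 0.05          # 1/h
    ks: float = 2.0               # mM glucose
    biomass_yield: float = 0.05   # A600 per mM glucose
    acetate_yield: float = 1.0    # mol acetate / mol glucose
    lag: float = 12.0             # h
    initial_a600: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu_max", "ks", "biomass_yield", "acetate_yield",
                     "lag", "initial_a600"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.acetate_yield > 3:
            raise ValueError("acetate_yield exceeds the stoichiometric ceiling of 3")


@dataclass(frozen=True)
class GalvanicModelParams:
    """pH-driven galvanic current model and abiotic baseline.

    ``k0`` (A) scales the decadic driving force 10^(−β·pH); it is anchored
    so the default unbuffered-inoculated run yields a predicted biotic rate
    of order 1 mpy.  ``baseline_rate_mm_yr`` is the abiotic weight-loss rate
    applied identically to both coupons (~4 mpy), contributing no current.
    """

    k0: float = 0.5                   # A per unit decadic driving force
    beta: float = 1.0                 # decades of cathodic current per pH unit
    baseline_rate_mm_yr: float = 0.10
    noise_sd: float = 0.05            # relative (multiplicative) current noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 < 0 or self.beta < 0:
            raise ValueError("k0 and beta must be >= 0")


@dataclass
class FermentationSeries:
    """Chamber fermentation time series."""

    time: np.ndarray      # h
    glucose: np.ndarray   # mM
    acetate: np.ndarray   # mM
    a600: np.ndarray


@dataclass
class SimulatedTreatment:
    """One synthetic treatment: trace, chemistry, coupons and ground truth."""

    config: TreatmentConfig
    trace: ElectrochemTrace
    chemistry: dict[str, ChamberChemistry]
    coupons: dict[str, CouponRecord]
    ground_truth: dict


def simulate_fermentation(params: FermentationParams, medium: MediumComposition,
                          duration: float, dt: float = DEFAULT_DT_H) -> FermentationSeries:
    """Integrate Monod growth/glucose/acetate on a regular time grid.

    dX/dt = mu_max·S/(Ks+S)·X after the lag; dS/dt = −(1/Y_X)·dX/dt with S
    floored at zero; acetate = Y_ac·(S0 − S) (exact stoichiometric coupling).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    time = np.arange(0.0, duration + dt / 2, dt)
    s0 = medium.glucose
    x0 = params.initial_a600
    glucose = np.full_like(time, s0)
    a600 = np.full_like(time, x0)
    if x0 > 0 and duration > params.lag and params.mu_max > 0 and s0 > 0:
        def rhs(_t, y):
            x, s = y
            mu = params.mu_max * max(s, 0.0) / (params.ks + max(s, 0.0))
            dx = mu * x
            return [dx, -dx / params.biomass_yield]

        t_active = time[time >= params.lag]
        sol = solve_ivp(rhs, (params.lag, time[-1]), [x0, s0],
                        t_eval=t_active, rtol=1e-9, atol=1e-10, method="RK45")
        x_t = sol.y[0]
        s_t = np.clip(sol.y[1], 0.0, None)
        glucose[time >= params.lag] = s_t
        a600[time >= params.lag] = x_t
    acetate = params.acetate_yield * (s0 - glucose)
    return FermentationSeries(time=time, glucose=glucose, acetate=acetate, a600=a600)


def simulate_sczra(treatment: TreatmentConfig,
                   ferm: Optional[FermentationParams] = None,
                   galv: Optional[GalvanicModelParams] = None,
                   dt: float = DEFAULT_DT_H,
                   area_cm2: float = DEFAULT_AREA_CM2,
                   density: float = DENSITY_UNS_G10180) -> SimulatedTreatment:
    """Simulate one split-cell treatment end to end.

    Produces the 15-min ZRA trace (optionally noisy), periodic chamber
    chemistry for both chambers, synthetic coupon cleaning-cycle records,
    and a ground-truth manifest (noise-free charge, imposed mass losses and
    the rates/CRR they imply).
    """
    ferm = ferm or FermentationParams()
    galv = galv or GalvanicModelParams()
    medium = treatment.medium or MediumComposition(
        bicarbonate_present=treatment.bicarbonate_present)
    if medium.bicarbonate_present != treatment.bicarbonate_present:
        medium = replace(medium, bicarbonate_present=treatment.bicarbonate_present)

    time = np.arange(0.0, treatment.duration + dt / 2, dt)
    n = len(time)

    # chamber chemistry: fermentation only in the inoculated chamber
    blank = FermentationSeries(time=time,
                               glucose=np.full(n, medium.glucose),
                               acetate=np.zeros(n), a600=np.zeros(n))
    series = {"WE1": blank, "WE2": blank}
    if treatment.inoculated_chamber in ("WE1", "WE2"):
        fs = simulate_fermentation(ferm, medium, treatment.duration, dt)
        series = dict(series)
        series[treatment.inoculated_chamber] = fs

    pH = {}
    for chamber in ("WE1", "WE2"):
        ac = series[chamber].acetate
        if np.ptp(ac) == 0:
            pH[chamber] = np.full(n, solve_pH(medium, float(ac[0])).pH)
        else:
            pH[chamber] = np.array([solve_pH(medium, float(a)).pH for a in ac])

    # Tafel-like pH-difference current; more acidic WE1 -> negative current
    drive = 10.0 ** (-galv.beta * pH["WE1"]) - 10.0 ** (-galv.beta * pH["WE2"])
    current_true = -galv.k0 * drive

    rng = np.random.default_rng(galv.seed)
    if galv.noise_sd > 0:
        current = current_true * (1.0 + galv.noise_sd * rng.standard_normal(n))
    else:
        current = current_true.copy()

    potential = -0.68 + 0.005 * (pH["WE1"] - pH["WE1"][0])
    trace = ElectrochemTrace(time, current, potential,
                             sampling_interval_nominal=dt)

    # ground truth: noise-free trapezoidal charge and imposed mass losses
    q_true = float(np.trapezoid(current_true, time * SECONDS_PER_HOUR))
    fparams = FaradayParams()
    dm_biotic = faraday_mass(q_true, fparams)
    w_abiotic = galv.baseline_rate_mm_yr * density * area_cm2 * treatment.duration / K_MM_PER_YR
    net_anode = "balanced" if q_true == 0 else ("WE1" if q_true > 0 else "WE2")
    w = {"WE1": w_abiotic, "WE2": w_abiotic}
    if net_anode in w:
        w[net_anode] += dm_biotic

    coupons = {
        ch: _coupon_from_mass_loss(f"{treatment.label}_{ch}", w[ch],
                                   area_cm2, density, treatment.duration)
        for ch in ("WE1", "WE2")
    }

    rates = {ch: corrosion_rate(w[ch], area_cm2, treatment.duration, density)
             for ch in ("WE1", "WE2")}
    biotic_pred = corrosion_rate(dm_biotic, area_cm2, treatment.duration, density)
    ground_truth = {
        "treatment": treatment.label,
        "q_true_C": q_true,
        "mass_loss_g": {ch: w[ch] for ch in ("WE1", "WE2")},
        "abiotic_mass_loss_g": w_abiotic,
        "biotic_mass_loss_g": dm_biotic,
        "net_anode": net_anode,
        "rate_mpy": {ch: rates[ch].mpy for ch in ("WE1", "WE2")},
        "crr": rates["WE1"].mpy / rates["WE2"].mpy,
        "biotic_rate_actual_mpy": abs(rates["WE1"].mpy - rates["WE2"].mpy),
        "biotic_rate_predicted_mpy": biotic_pred.mpy,
        "noise_sd": galv.noise_sd,
        "seed": galv.seed,
    }

    chem_mask = np.isclose(time % CHEMISTRY_SAMPLING_H, 0.0) | np.isclose(
        time % CHEMISTRY_SAMPLING_H, CHEMISTRY_SAMPLING_H)
    chemistry = {
        ch: ChamberChemistry(
            chamber_id=ch,  # type: ignore[arg-type]
            sample_times=time[chem_mask],
            pH=pH[ch][chem_mask],
            glucose=series[ch].glucose[chem_mask],
            acetate=series[ch].acetate[chem_mask],
        )
        for ch in ("WE1", "WE2")
    }

    return SimulatedTreatment(config=treatment, trace=trace, chemistry=chemistry,
                              coupons=coupons, ground_truth=ground_truth)


def _coupon_from_mass_loss(coupon_id: str, w: float, area: float, density: float,
                           exposure: float,
                           initial_mass: float = DEFAULT_INITIAL_MASS_G) -> CouponRecord:
    """Synthetic cleaning-cycle record converging exactly to the imposed loss.

    Early cycles retain residual oxide mass; the final two cycles are equal,
    mirroring the "no mass lost between wash cycles" stopping rule.
    """
    mf = initial_mass - w
    cycles = [mf + 0.008, mf + 0.0015, mf, mf]
    return CouponRecord(
        coupon_id=coupon_id, alloy_label="UNS G10180", exposed_area=area,
        density=density, initial_mass=initial_mass,
        cleaning_cycle_masses=cycles, exposure_time=exposure,
    )


def default_treatments(duration: float = DEFAULT_DURATION_H) -> list[TreatmentConfig]:
    """The four study treatments: buffered/unbuffered × uninoculated/WE1."""
    out = []
    for bicarb in (True, False):
        headspace = "80:20 N2:CO2" if bicarb else "N2"
        for inoc in ("none", "WE1"):
            out.append(TreatmentConfig(
                bicarbonate_present=bicarb, inoculated_chamber=inoc,
                duration=duration, headspace_label=headspace,
                medium=MediumComposition(bicarbonate_present=bicarb),
            ))
    return out


def generate_fixture_suite(seed: int, outdir: str | Path,
                           duration: float = DEFAULT_DURATION_H,
                           noise_sd: float = 0.05) -> dict:
    """Write all four treatments to disk plus a ground-truth manifest.

    Each treatment gets its trace, two chamber-chemistry tables and a coupon
    table in the package's delimited formats; ``manifest.json`` collects the
    ground truth.  Deterministic for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "duration_h": duration, "treatments": {}}
    for k, cfg in enumerate(default_treatments(duration)):
        galv = GalvanicModelParams(noise_sd=noise_sd, seed=(seed * 13 + k) % (2**31 - 1))
        sim = simulate_sczra(cfg, galv=galv)
        label = cfg.label
        write_trace(sim.trace, outdir / f"{label}_trace.csv")
        for ch, chem in sim.chemistry.items():
            write_chemistry(chem, outdir / f"{label}_chem_{ch.lower()}.csv")
        write_coupon_table(list(sim.coupons.values()), outdir / f"{label}_coupons.csv")
        manifest["treatments"][label] = sim.ground_truth
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
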