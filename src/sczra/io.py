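"""Domain types and delimited-text I/O for split-cell corrosion experiments.

Canonical internal units are hours, amperes, volts, grams, cm^2 and
g/cm^3; unit conversion happens once at the file boundary, driven by an
explicit :class:`TraceDialect` rather than sniffing, because potentiostat
exports vary widely in column naming and units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .corrosion import TreatmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "ElectrochemTrace",
    "CouponRecord",
    "ChamberChemistry",
    "TreatmentConfig",
    "TraceDialect",
    "TraceFormatError",
    "TraceValidationError",
    "read_trace",
    "write_trace",
    "read_coupon_table",
    "write_coupon_table",
    "read_chemistry",
    "write_chemistry",
    "write_treatment_report",
    "read_treatment_report",
    "load_treatment_config",
]


class TraceFormatError(ValueError):
    """Raised when a file lacks the declared columns."""


class TraceValidationError(ValueError):
    """Raised when parsed data violate a physical invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ElectrochemTrace:
    """Zero-resistance ammetry time series between the shorted coupons.

    ``current`` is signed: positive current means electrons flow from WE1 to
    WE2 (WE1 is the momentary anode); negative means WE2 to WE1.
    """

    time: np.ndarray       # hours since deployment, strictly increasing
    current: np.ndarray    # amperes, signed
    potential: np.ndarray  # volts vs. SCE
    sampling_interval_nominal: float = 0.25  # hours (15-min logging)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        if not (len(self.time) == len(self.current) == len(self.potential)):
            raise TraceValidationError("time/current/potential lengths differ")
        for name, arr in (("time", self.time), ("current", self.current),
                          ("potential", self.potential)):
            if not np.all(np.isfinite(arr)):
                raise TraceValidationError(f"non-finite values in {name}")
        if np.any(self.time < 0):
            raise TraceValidationError("time values must be non-negative")
        bad = np.nonzero(np.diff(self.time) <= 0)[0]
        if bad.size:
            raise TraceValidationError(
                f"time not strictly increasing at row {bad[0] + 1} "
                f"(t={self.time[bad[0] + 1]!r} after t={self.time[bad[0]]!r})"
            )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])


@dataclass
class CouponRecord:
    """One carbon-steel coupon with its repeated-cleaning mass record.

    ``cleaning_cycle_masses`` are the masses after each oxide-stripping
    cycle; they must be non-increasing (cleaning cannot add metal).
    """

    coupon_id: str
    alloy_label: str
    exposed_area: float        # cm^2
    density: float             # g/cm^3
    initial_mass: float        # g
    cleaning_cycle_masses: list[float]
    exposure_time: float       # hours

    def __post_init__(self) -> None:
        if self.exposed_area <= 0:
            raise ValueError(f"{self.coupon_id}: exposed_area must be > 0")
        if self.density <= 0:
            raise ValueError(f"{self.coupon_id}: density must be > 0")
        if self.exposure_time <= 0:
            raise ValueError(f"{self.coupon_id}: exposure_time must be > 0")
        ms = list(self.cleaning_cycle_masses)
        for i in range(1, len(ms)):
            if ms[i] > ms[i - 1] + 1e-12:
                raise ValueError(
                    f"{self.coupon_id}: cleaning-cycle mass increased at cycle "
                    f"{i + 1} ({ms[i - 1]} -> {ms[i]} g); physically impossible"
                )
        self.cleaning_cycle_masses = ms


@dataclass
class ChamberChemistry:
    """Periodic chamber samples: pH, glucose and acetate versus time."""

    chamber_id: Literal["WE1", "WE2"]
    sample_times: np.ndarray  # hours
    pH: np.ndarray
    glucose: np.ndarray       # mM
    acetate: np.ndarray       # mM

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.pH = np.asarray(self.pH, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.acetate = np.asarray(self.acetate, dtype=float)
        n = len(self.sample_times)
        if not (len(self.pH) == len(self.glucose) == len(self.acetate) == n):
            raise ValueError("chemistry series lengths differ")
        if np.any(self.glucose < 0) or np.any(self.acetate < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any((self.pH <= 0) | (self.pH >= 14)):
            raise ValueError("pH out of (0, 14)")


@dataclass
class TreatmentConfig:
    """Split-cell experiment configuration (one of the four treatments)."""

    bicarbonate_present: bool
    inoculated_chamber: Literal["WE1", "WE2", "none"]
    duration: float            # hours
    headspace_label: str = ""
    medium: Optional[object] = None  # MediumComposition, set by the simulator layer

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.inoculated_chamber not in ("WE1", "WE2", "none"):
            raise ValueError(f"bad inoculated_chamber {self.inoculated_chamber!r}")

    @property
    def label(self) -> str:
        buf = "with_bicarbonate" if self.bicarbonate_present else "without_bicarbonate"
        ino = ("uninoculated" if self.inoculated_chamber == "none"
               else f"{self.inoculated_chamber}_inoculated")
        return f"{buf}__{ino}"


# --------------------------------------------------------------------------
# trace I/O
# --------------------------------------------------------------------------

_TIME_FACTORS = {"h": 1.0, "hours": 1.0, "s": 1 / 3600.0, "seconds": 1 / 3600.0,
                 "min": 1 / 60.0, "minutes": 1 / 60.0}
_CURRENT_FACTORS = {"A": 1.0, "mA": 1e-3, "uA": 1e-6, "µA": 1e-6, "nA": 1e-9}
_POTENTIAL_FACTORS = {"V": 1.0, "mV": 1e-3}


@dataclass
class TraceDialect:
    """Explicit column naming and units of a potentiostat export."""

    time_column: str = "time_h"
    current_column: str = "current_A"
    potential_column: str = "potential_V"
    time_unit: str = "h"
    current_unit: str = "A"
    potential_unit: str = "V"
    delimiter: str = ","

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraceDialect":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def read_trace(path: str | Path, dialect: TraceDialect | None = None) -> ElectrochemTrace:
    """Read a delimited trace file into canonical units (h, A, V).

    Rows containing non-finite values are dropped (count logged, not
    interpolated); the charge integrator handles irregular spacing natively.
    """
    dialect = dialect or TraceDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, comment="#")
    for col in (dialect.time_column, dialect.current_column, dialect.potential_column):
        if col not in df.columns:
            raise TraceFormatError(
                f"{path}: missing column {col!r}; found {list(df.columns)}"
            )
    sub = df[[dialect.time_column, dialect.current_column, dialect.potential_column]]
    sub = sub.apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(sub.to_numpy(dtype=float)).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("%s: dropped %d rows with missing/non-finite values", path, dropped)
    sub = sub[keep]
    time = sub[dialect.time_column].to_numpy() * _unit(_TIME_FACTORS, dialect.time_unit)
    cur = sub[dialect.current_column].to_numpy() * _unit(_CURRENT_FACTORS, dialect.current_unit)
    pot = sub[dialect.potential_column].to_numpy() * _unit(_POTENTIAL_FACTORS, dialect.potential_unit)
    nominal = float(np.median(np.diff(time))) if len(time) > 1 else 0.25
    return ElectrochemTrace(time, cur, pot, sampling_interval_nominal=nominal)


def _unit(table: dict[str, float], unit: str) -> float:
    try:
        return table[unit]
    except KeyError:
        raise TraceFormatError(f"unknown unit {unit!r}; expected one of {sorted(table)}")


def write_trace(trace: ElectrochemTrace, path: str | Path) -> None:
    """Write a trace in the canonical dialect (time_h, current_A, potential_V)."""
    pd.DataFrame({
        "time_h": trace.time,
        "current_A": trace.current,
        "potential_V": trace.potential,
    }).to_csv(path, index=False, float_format="%.10g")


# --------------------------------------------------------------------------
# coupon tables
# --------------------------------------------------------------------------

_COUPON_COLUMNS = ["coupon_id", "alloy_label", "exposed_area_cm2", "density_g_cm3",
                   "initial_mass_g", "exposure_h", "cycle", "mass_g"]


def read_coupon_table(path: str | Path, delimiter: str = ",") -> list[CouponRecord]:
    """Read a long-format coupon table: one row per cleaning cycle per coupon."""
    df = pd.read_csv(path, sep=delimiter, comment="#")
    missing = [c for c in _COUPON_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing coupon columns {missing}")
    records = []
    for cid, grp in df.groupby("coupon_id", sort=False):
        grp = grp.sort_values("cycle")
        first = grp.iloc[0]
        records.append(CouponRecord(
            coupon_id=str(cid),
            alloy_label=str(first["alloy_label"]),
            exposed_area=float(first["exposed_area_cm2"]),
            density=float(first["density_g_cm3"]),
            initial_mass=float(first["initial_mass_g"]),
            cleaning_cycle_masses=[float(m) for m in grp["mass_g"]],
            exposure_time=float(first["exposure_h"]),
        ))
    return records


def write_coupon_table(coupons: Sequence[CouponRecord], path: str | Path) -> None:
    rows = []
    for c in coupons:
        for i, m in enumerate(c.cleaning_cycle_masses, start=1):
            rows.append({
                "coupon_id": c.coupon_id, "alloy_label": c.alloy_label,
                "exposed_area_cm2": c.exposed_area, "density_g_cm3": c.density,
                "initial_mass_g": c.initial_mass, "exposure_h": c.exposure_time,
                "cycle": i, "mass_g": m,
            })
    pd.DataFrame(rows, columns=_COUPON_COLUMNS).to_csv(path, index=False, float_format="%.6f")


# --------------------------------------------------------------------------
# chamber chemistry
# --------------------------------------------------------------------------

def write_chemistry(chem: ChamberChemistry, path: str | Path) -> None:
    pd.DataFrame({
        "chamber_id": chem.chamber_id,
        "time_h": chem.sample_times,
        "pH": chem.pH,
        "glucose_mM": chem.glucose,
        "acetate_mM": chem.acetate,
    }).to_csv(path, index=False, float_format="%.6f")


def read_chemistry(path: str | Path) -> ChamberChemistry:
    df = pd.read_csv(path, comment="#")
    chamber = str(df["chamber_id"].iloc[0])
    return ChamberChemistry(
        chamber_id=chamber,  # type: ignore[arg-type]
        sample_times=df["time_h"].to_numpy(float),
        pH=df["pH"].to_numpy(float),
        glucose=df["glucose_mM"].to_numpy(float),
        acetate=df["acetate_mM"].to_numpy(float),
    )


# --------------------------------------------------------------------------
# treatment reports
# --------------------------------------------------------------------------

_REPORT_COLUMNS = ["treatment", "rate_we1_mpy", "rate_we2_mpy", "crr",
                   "biotic_actual_mpy", "net_anode_actual",
                   "biotic_predicted_mpy", "net_anode_predicted",
                   "accuracy_percent"]


def write_treatment_report(results: "Sequence[TreatmentResult]", path: str | Path,
                           provenance: Optional[dict] = None) -> None:
    """Write the four-column-group treatment report with provenance comments."""
    from . import __version__

    rows = []
    for r in results:
        rows.append({
            "treatment": r.treatment,
            "rate_we1_mpy": r.rate_we1.mpy,
            "rate_we2_mpy": r.rate_we2.mpy,
            "crr": r.crr,
            "biotic_actual_mpy": r.biotic_rate_actual.mpy,
            "net_anode_actual": r.net_anode_actual,
            "biotic_predicted_mpy": (r.biotic_rate_predicted.mpy
                                     if r.biotic_rate_predicted is not None else np.nan),
            "net_anode_predicted": r.net_anode_predicted or "",
            "accuracy_percent": (r.accuracy_percent
                                 if r.accuracy_percent is not None else np.nan),
        })
    header = [f"# sczra treatment report (software version {__version__})"]
    for key, val in (provenance or {}).items():
        header.append(f"# {key}: {val}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(fh, index=False,
                                                           float_format="%.6f")


def read_treatment_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# --------------------------------------------------------------------------
# experiment configuration
# --------------------------------------------------------------------------

def load_treatment_config(path: str | Path) -> TreatmentConfig:
    """Load a treatment configuration from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    medium = raw.pop("medium", None)
    cfg = TreatmentConfig(**raw)
    if medium is not None:
        from .simulator import MediumComposition
        cfg.medium = MediumComposition(**medium)
    return cfg
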