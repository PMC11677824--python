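"""Derivation chain from paired density/sound-velocity scans to lipid elasticity.

The measurable quantities are the density ``rho`` (g·cm⁻³) and sound velocity
``u`` (m·s⁻¹) of a solvent and of a dilute lipid suspension at known
concentration ``c`` (mg·mL⁻¹), recorded as a function of temperature.  From a
paired scan the module derives, per temperature,

* the adiabatic compressibility of solvent and suspension,
  ``beta = 1 / (u² rho)`` (Pa⁻¹, with rho in SI units),
* the sound-velocity concentration increment
  ``[u] = (u − u0) / (u0 c)`` (mL·g⁻¹, with c in g·mL⁻¹),
* the apparent specific partial volume
  ``phi_v = [1 − (rho − rho0)/c] / rho0`` (mL·g⁻¹),
* the specific adiabatic compressibility
  ``phi_k/beta0 = −2[u] − 1/rho0 + 2 phi_v`` (mL·g⁻¹),
* the lipid adiabatic compressibility ``beta_lipid`` and its reciprocal, the
  bulk (volumetric elastic) modulus ``K_lipid = 1/beta_lipid`` (Pa).

All measurement uncertainties are propagated to every derived quantity by
first-order (delta-method) propagation assuming independent Gaussian errors
on each reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MediumPoint",
    "SuspensionPoint",
    "PairedScan",
    "InstrumentPrecision",
    "AcousticDerivation",
    "DerivedScan",
    "NonPhysicalCompressibilityWarning",
    "EQ5_PARSES",
    "compressibility",
    "velocity_increment",
    "apparent_specific_volume",
    "specific_compressibility",
    "lipid_compressibility",
    "bulk_modulus",
    "derive_scan",
]

# unit conversions applied internally; recorded in DerivedScan.metadata
G_CM3_TO_KG_M3 = 1000.0  # density g·cm⁻³ -> kg·m⁻³ (for Pa⁻¹ compressibility)
MG_ML_TO_G_ML = 1.0e-3   # concentration mg·mL⁻¹ -> g·mL⁻¹ (for mL·g⁻¹ increments)

#: Supported readings of the lipid-compressibility equation.  The default,
#: ``"two_minus_u_over_phiv"``, is beta_lipid = beta0·(2 − [u]/phi_v); the
#: alternative ``"phik_over_phiv"`` is beta_lipid = beta0·(phi_k/beta0)/phi_v.
EQ5_PARSES = ("two_minus_u_over_phiv", "phik_over_phiv")


class NonPhysicalCompressibilityWarning(UserWarning):
    """Raised (as a warning) when beta_lipid comes out non-positive."""


@dataclass(frozen=True)
class MediumPoint:
    """One solvent reading: temperature (°C), density (g·cm⁻³), sound velocity (m·s⁻¹)."""

    temperature: float
    density: float
    sound_velocity: float

    def __post_init__(self) -> None:
        if not (0.0 < self.temperature < 100.0):
            raise ValueError(f"temperature {self.temperature} °C outside (0, 100)")
        if self.density <= 0 or self.sound_velocity <= 0:
            raise ValueError("density and sound velocity must be positive")


@dataclass(frozen=True)
class SuspensionPoint:
    """One suspension reading; adds the lipid concentration (mg·mL⁻¹)."""

    temperature: float
    density: float
    sound_velocity: float
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.density <= 0 or self.sound_velocity <= 0:
            raise ValueError("density and sound velocity must be positive")


@dataclass(frozen=True)
class InstrumentPrecision:
    """1-sigma repeatability of the densimeter / sound-velocity analyser.

    Defaults follow the instrument-class repeatability of a vibrating-tube
    densimeter with ultrasound cell: 1e-5 g·cm⁻³, 0.01 m·s⁻¹, 0.01 °C.
    """

    sigma_density: float = 1.0e-5
    sigma_velocity: float = 0.01
    sigma_temperature: float = 0.01

    def __post_init__(self) -> None:
        if min(self.sigma_density, self.sigma_velocity, self.sigma_temperature) < 0:
            raise ValueError("precisions must be non-negative")


@dataclass
class PairedScan:
    """Temperature-aligned solvent and suspension series.

    Both series must be strictly monotone in temperature (the instrument scans
    up or down).  Solvent values are linearly interpolated onto suspension
    temperatures; extrapolation beyond ``temperature_tolerance`` is refused.
    """

    solvent: Sequence[MediumPoint]
    suspension: Sequence[SuspensionPoint]
    temperature_tolerance: float = 0.05

    def __post_init__(self) -> None:
        for name, series in (("solvent", self.solvent), ("suspension", self.suspension)):
            t = np.array([p.temperature for p in series], dtype=float)
            if t.size == 0:
                raise ValueError(f"{name} series is empty")
            d = np.diff(t)
            if t.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} series temperatures are not strictly monotone")

    @classmethod
    def from_arrays(
        cls,
        solvent_T: np.ndarray,
        solvent_rho: np.ndarray,
        solvent_u: np.ndarray,
        susp_T: np.ndarray,
        susp_rho: np.ndarray,
        susp_u: np.ndarray,
        concentration: float,
        temperature_tolerance: float = 0.05,
    ) -> "PairedScan":
        solvent = [MediumPoint(*xyz) for xyz in zip(solvent_T, solvent_rho, solvent_u)]
        susp = [
            SuspensionPoint(t, r, u, concentration)
            for t, r, u in zip(susp_T, susp_rho, susp_u)
        ]
        return cls(solvent, susp, temperature_tolerance)

    def solvent_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.array([p.temperature for p in self.solvent])
        r = np.array([p.density for p in self.solvent])
        u = np.array([p.sound_velocity for p in self.solvent])
        order = np.argsort(t)
        return t[order], r[order], u[order]

    def suspension_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        t = np.array([p.temperature for p in self.suspension])
        r = np.array([p.density for p in self.suspension])
        u = np.array([p.sound_velocity for p in self.suspension])
        c = np.array([p.concentration for p in self.suspension])
        return t, r, u, c


@dataclass(frozen=True)
class AcousticDerivation:
    """Per-temperature derived quantities with 1-sigma uncertainties."""

    temperature: float
    beta0: float
    beta_s: float
    u_increment: float
    phi_v: float
    phi_k_over_beta0: float
    beta_lipid: float
    K_lipid: float
    sigma: dict = field(default_factory=dict)
    nonphysical: bool = False


@dataclass
class DerivedScan:
    """Result of :func:`derive_scan`: a tidy table plus provenance metadata."""

    table: pd.DataFrame
    metadata: dict

    def rows(self) -> list[AcousticDerivation]:
        out = []
        sig_cols = [c for c in self.table.columns if c.startswith("sigma_")]
        for _, r in self.table.iterrows():
            out.append(
                AcousticDerivation(
                    temperature=r["temperature_C"],
                    beta0=r["beta0_Pa"],
                    beta_s=r["beta_s_Pa"],
                    u_increment=r["u_increment_mL_per_g"],
                    phi_v=r["phi_v_mL_per_g"],
                    phi_k_over_beta0=r["phi_k_over_beta0_mL_per_g"],
                    beta_lipid=r["beta_lipid_Pa"],
                    K_lipid=r["K_lipid_Pa"],
                    sigma={c: r[c] for c in sig_cols},
                    nonphysical=bool(r["nonphysical"]),
                )
            )
        return out


# ---------------------------------------------------------------------------
# single-value operations (vectorised: scalars or ndarrays)
# ---------------------------------------------------------------------------

def compressibility(u, rho):
    """Adiabatic compressibility 1/(u²·rho) in Pa⁻¹.

    ``u`` in m·s⁻¹, ``rho`` in g·cm⁻³ (converted internally to kg·m⁻³).
    """
    u = np.asarray(u, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(u <= 0) or np.any(rho <= 0):
        raise ValueError("sound velocity and density must be positive")
    out = 1.0 / (u**2 * rho * G_CM3_TO_KG_M3)
    return out if out.ndim else float(out)


def velocity_increment(u, u0, c):
    """Sound-velocity concentration increment [u] = (u − u0)/(u0·c) in mL·g⁻¹.

    ``c`` in mg·mL⁻¹ (converted internally to g·mL⁻¹).
    """
    u = np.asarray(u, dtype=float)
    u0 = np.asarray(u0, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(u0 <= 0):
        raise ValueError("solvent sound velocity must be positive")
    if np.any(c <= 0):
        raise ValueError("concentration must be positive")
    out = (u - u0) / (u0 * c * MG_ML_TO_G_ML)
    return out if out.ndim else float(out)


def apparent_specific_volume(rho, rho0, c):
    """Apparent specific partial volume phi_v = [1 − (rho − rho0)/c]·(1/rho0), mL·g⁻¹.

    Densities in g·cm⁻³ (≡ g·mL⁻¹), ``c`` in mg·mL⁻¹.
    """
    rho = np.asarray(rho, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(rho0 <= 0):
        raise ValueError("solvent density must be positive")
    if np.any(c <= 0):
        raise ValueError("concentration must be positive")
    out = (1.0 - (rho - rho0) / (c * MG_ML_TO_G_ML)) / rho0
    return out if out.ndim else float(out)


def specific_compressibility(u_inc, phi_v, rho0):
    """Specific adiabatic compressibility phi_k/beta0 = −2[u] − 1/rho0 + 2 phi_v (mL·g⁻¹)."""
    u_inc = np.asarray(u_inc, dtype=float)
    phi_v = np.asarray(phi_v, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    if np.any(rho0 <= 0):
        raise ValueError("solvent density must be positive")
    out = -2.0 * u_inc - 1.0 / rho0 + 2.0 * phi_v
    return out if out.ndim else float(out)


def lipid_compressibility(beta0, u_inc, phi_v, parse: str = "two_minus_u_over_phiv"):
    """Adiabatic compressibility of the lipid phase (Pa⁻¹).

    Under the default parse, beta_lipid = beta0·(2 − [u]/phi_v).  The
    alternative ``"phik_over_phiv"`` reads beta_lipid = beta0·(phi_k/beta0)/phi_v
    with phi_k/beta0 from :func:`specific_compressibility` — note that reading
    additionally needs the solvent density, so it is only available through
    :func:`derive_scan`; here the two-argument default form is computed.

    Non-positive results (possible for noisy edge points with [u]/phi_v ≥ 2)
    are returned as computed but flagged with
    :class:`NonPhysicalCompressibilityWarning` rather than raised.
    """
    if parse not in EQ5_PARSES:
        raise ValueError(f"unknown parse {parse!r}; expected one of {EQ5_PARSES}")
    beta0 = np.asarray(beta0, dtype=float)
    u_inc = np.asarray(u_inc, dtype=float)
    phi_v = np.asarray(phi_v, dtype=float)
    if np.any(beta0 <= 0):
        raise ValueError("solvent compressibility must be positive")
    if np.any(phi_v <= 0):
        raise ValueError("apparent specific volume must be positive")
    if parse == "two_minus_u_over_phiv":
        out = beta0 * (2.0 - u_inc / phi_v)
    else:  # phik_over_phiv is handled with rho0 in derive_scan; without rho0
        raise ValueError(
            "parse 'phik_over_phiv' requires the solvent density; use derive_scan"
        )
    if np.any(np.asarray(out) <= 0):
        warnings.warn(
            "non-physical beta_lipid <= 0 ([u]/phi_v >= 2); value reported, not raised",
            NonPhysicalCompressibilityWarning,
            stacklevel=2,
        )
    return out if out.ndim else float(out)


def bulk_modulus(beta_lipid):
    """Bulk (volumetric elastic) modulus K = 1/beta_lipid (Pa)."""
    beta_lipid = np.asarray(beta_lipid, dtype=float)
    if np.any(beta_lipid <= 0):
        raise ValueError("compressibility must be positive to take a bulk modulus")
    out = 1.0 / beta_lipid
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# full-scan derivation with uncertainty propagation
# ---------------------------------------------------------------------------

_OUTPUT_COLS = (
    "beta0_Pa",
    "beta_s_Pa",
    "u_increment_mL_per_g",
    "phi_v_mL_per_g",
    "phi_k_over_beta0_mL_per_g",
    "beta_lipid_Pa",
    "K_lipid_Pa",
)


def _chain(u, u0, rho, rho0, c, parse):
    """Evaluate the whole derivation for aligned arrays; no validation."""
    cp = c * MG_ML_TO_G_ML
    beta0 = 1.0 / (u0**2 * rho0 * G_CM3_TO_KG_M3)
    beta_s = 1.0 / (u**2 * rho * G_CM3_TO_KG_M3)
    u_inc = (u - u0) / (u0 * cp)
    phi_v = (1.0 - (rho - rho0) / cp) / rho0
    phi_k = -2.0 * u_inc - 1.0 / rho0 + 2.0 * phi_v
    if parse == "two_minus_u_over_phiv":
        beta_lip = beta0 * (2.0 - u_inc / phi_v)
    else:
        beta_lip = beta0 * phi_k / phi_v
    with np.errstate(divide="ignore"):
        K = np.where(beta_lip > 0, 1.0 / np.where(beta_lip == 0, np.nan, beta_lip), np.nan)
    return np.stack([beta0, beta_s, u_inc, phi_v, phi_k, beta_lip, K])


def derive_scan(
    scan: PairedScan,
    precision: InstrumentPrecision | None = None,
    parse: str = "two_minus_u_over_phiv",
) -> DerivedScan:
    """Derive compressibility/elasticity quantities for every suspension temperature.

    Solvent density and sound velocity are linearly interpolated onto the
    suspension temperatures.  Suspension temperatures outside the solvent
    range by more than ``scan.temperature_tolerance`` raise, listing the
    offending rows.  Uncertainties are propagated by the delta method from
    ``precision`` treating the four readings (u, u0, rho, rho0) as independent;
    the temperature repeatability enters through the local slope of the
    interpolated solvent baselines.
    """
    if parse not in EQ5_PARSES:
        raise ValueError(f"unknown parse {parse!r}; expected one of {EQ5_PARSES}")
    precision = precision or InstrumentPrecision()

    sT, sRho, sU = scan.solvent_arrays()
    T, rho, u, c = scan.suspension_arrays()

    lo, hi = sT.min(), sT.max()
    bad = np.where((T < lo - scan.temperature_tolerance) | (T > hi + scan.temperature_tolerance))[0]
    if bad.size:
        rows = ", ".join(f"{i} (T={T[i]:g} °C)" for i in bad)
        raise ValueError(
            f"suspension rows outside solvent temperature range "
            f"[{lo:g}, {hi:g}] ± {scan.temperature_tolerance:g} °C: {rows}"
        )
    Tq = np.clip(T, lo, hi)
    rho0 = np.interp(Tq, sT, sRho)
    u0 = np.interp(Tq, sT, sU)

    vals = _chain(u, u0, rho, rho0, c, parse)

    # delta-method propagation: numerical Jacobian wrt the four readings
    sig_u = precision.sigma_velocity
    sig_r = precision.sigma_density
    # temperature repeatability maps onto the interpolated solvent values
    # through the local baseline slope
    eps_T = 1e-3
    du0_dT = (np.interp(np.clip(Tq + eps_T, lo, hi), sT, sU)
              - np.interp(np.clip(Tq - eps_T, lo, hi), sT, sU)) / (2 * eps_T)
    drho0_dT = (np.interp(np.clip(Tq + eps_T, lo, hi), sT, sRho)
                - np.interp(np.clip(Tq - eps_T, lo, hi), sT, sRho)) / (2 * eps_T)
    sig_u0 = np.hypot(sig_u, du0_dT * precision.sigma_temperature)
    sig_rho0 = np.hypot(sig_r, drho0_dT * precision.sigma_temperature)

    inputs = {"u": (u, np.full_like(u, sig_u)),
              "u0": (u0, sig_u0 * np.ones_like(u0)),
              "rho": (rho, np.full_like(rho, sig_r)),
              "rho0": (rho0, sig_rho0 * np.ones_like(rho0))}
    var = np.zeros_like(vals)
    for name, (x, sx) in inputs.items():
        h = 1e-7 * np.maximum(np.abs(x), 1.0)
        kw = {"u": u, "u0": u0, "rho": rho, "rho0": rho0}
        kw[name] = x + h
        hi_v = _chain(kw["u"], kw["u0"], kw["rho"], kw["rho0"], c, parse)
        kw[name] = x - h
        lo_v = _chain(kw["u"], kw["u0"], kw["rho"], kw["rho0"], c, parse)
        jac = (hi_v - lo_v) / (2 * h)
        var += (jac * sx) ** 2
    sig = np.sqrt(var)

    nonphys = vals[5] <= 0
    if np.any(nonphys):
        warnings.warn(
            f"{int(nonphys.sum())} derived point(s) have non-physical beta_lipid <= 0; "
            "flagged in the 'nonphysical' column",
            NonPhysicalCompressibilityWarning,
            stacklevel=2,
        )

    table = pd.DataFrame({"temperature_C": T})
    for i, col in enumerate(_OUTPUT_COLS):
        table[col] = vals[i]
    for i, col in enumerate(_OUTPUT_COLS):
        table["sigma_" + col] = sig[i]
    table["nonphysical"] = nonphys

    metadata = {
        "eq5_parse": parse,
        "unit_conversions": {
            "density": "g_per_cm3 -> kg_per_m3 (x1000) for Pa^-1 compressibilities",
            "concentration": "mg_per_mL -> g_per_mL (x1e-3) for mL_per_g increments",
        },
        "temperature_tolerance_C": scan.temperature_tolerance,
        "precision": {
            "sigma_density_g_per_cm3": precision.sigma_density,
            "sigma_velocity_m_per_s": precision.sigma_velocity,
            "sigma_temperature_C": precision.sigma_temperature,
        },
        "propagation": "first-order delta method, independent reading errors",
    }
    return DerivedScan(table=table, metadata=metadata)
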