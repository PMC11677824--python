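"""Synthetic instrument data with recorded ground truth.

Every input the pipeline consumes can be generated here by inverting the
derivation chain: paired solvent/suspension temperature scans consistent
with a prescribed sound-velocity increment [u](T) (including a muted
Gaussian dip at the transition temperature Tm) and apparent specific volume
phi_v(T); ellipse-shaped particle ensembles with a prescribed roundness
distribution; lognormal vesicle diameters for number-weighted DLS
distributions; and plain Gaussian zeta-potential replicate groups.

Defaults emulate a dilute (2 mg/mL) lipid vesicle suspension in a water-like
solvent scanned from 10 to 45 °C: solvent baselines are quadratics fit to
handbook water density/sound velocity, instrument noise matches the stated
repeatability (1e-5 g/cm³, 0.01 m/s), and the [u]/phi_v baselines put the
derived specific compressibility near 0.94 mL/g and the bulk modulus near
1.18 GPa at 37 °C, the regime of cholesterol-containing model membranes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .acoustics import (
    MG_ML_TO_G_ML,
    InstrumentPrecision,
    PairedScan,
    compressibility,
    lipid_compressibility,
    specific_compressibility,
)
from .morphology import ParticleRecord, SizeDistribution

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_scans",
    "generate_particles",
    "generate_particle_mask",
    "generate_dls",
    "generate_zeta",
]

# quadratic (highest power first) fits to water at 10/25/37 °C
_WATER_RHO_COEFFS = (-4.90617284e-06, -5.15061728e-06, 1.00024212e00)   # g/cm³
_WATER_U_COEFFS = (-3.94012346e-02, 4.67370988e00, 1.40447302e03)       # m/s


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the simulated study conditions."""

    # temperature grid, °C
    t_start: float = 10.0
    t_stop: float = 45.0
    t_step: float = 1.0
    # lipid concentration, mg/mL
    concentration: float = 2.0
    # solvent baselines rho0(T), u0(T): quadratic coefficients, highest first
    rho0_coeffs: tuple = _WATER_RHO_COEFFS
    u0_coeffs: tuple = _WATER_U_COEFFS
    # [u](T) baseline: level at t_ref (mL/g) and slope (mL/g per °C);
    # kept bounded away from zero so increments survive the u − u0 cancellation
    u_inc_level: float = 0.032
    u_inc_slope: float = 0.001
    t_ref: float = 25.0
    # transition dip in [u](T): negative Gaussian bump; [u] transiently
    # crosses zero at the transition as in real vesicle scans
    dip_Tm: float = 22.5
    dip_depth: float = 0.065
    dip_width: float = 2.0
    # phi_v(T) baseline, mL/g
    phi_v_level: float = 1.018
    phi_v_slope: float = 0.0004
    # instrument repeatability
    precision: InstrumentPrecision = field(default_factory=InstrumentPrecision)
    eq5_parse: str = "two_minus_u_over_phiv"
    # particle ensemble (TEM-like)
    n_particles: int = 220
    particle_mean_diameter: float = 104.0   # nm
    particle_sigma_log: float = 0.45        # lognormal shape of diameters
    roundness_mean: float = 0.83
    roundness_kappa: float = 40.0           # Beta concentration of roundness
    # DLS ensemble
    n_dls: int = 2000
    dls_median: float = 100.0               # nm, lognormal median exp(mu)
    dls_sigma_log: float = 0.25
    # zeta-potential replicate groups
    zeta_mean: float = -55.0                # mV
    zeta_sd: float = 8.0
    n_zeta: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dip_width <= 0:
            raise ValueError("dip width must be positive")
        for name in ("t_step", "concentration", "particle_sigma_log",
                     "dls_sigma_log", "zeta_sd", "roundness_kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def grid(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)

    def u_increment_true(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        base = self.u_inc_level + self.u_inc_slope * (T - self.t_ref)
        dip = self.dip_depth * np.exp(-0.5 * ((T - self.dip_Tm) / self.dip_width) ** 2)
        return base - dip

    def phi_v_true(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return self.phi_v_level + self.phi_v_slope * (T - self.t_ref)


@dataclass
class GroundTruth:
    """Noise-free truth recorded alongside every generated dataset."""

    seed: int
    temperatures: np.ndarray | None = None
    u_increment: np.ndarray | None = None
    phi_v: np.ndarray | None = None
    phi_k_over_beta0: np.ndarray | None = None
    beta_lipid: np.ndarray | None = None
    K_lipid: np.ndarray | None = None
    Tm: float | None = None
    roundness: np.ndarray | None = None
    mean_roundness: float | None = None
    diameters: np.ndarray | None = None
    number_mean_diameter: float | None = None
    intensity_mean_diameter: float | None = None

    def to_dict(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            if v is None:
                continue
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return out


def generate_scans(cfg: SyntheticConfig, seed: int | None = None
                   ) -> tuple[PairedScan, GroundTruth]:
    """Emit a paired solvent/suspension scan consistent with the ground truth.

    Inverting the increment definitions: u(T) = u0(T)·(1 + [u](T)·c') and
    rho(T) = rho0(T) + c'·(1 − phi_v(T)·rho0(T)) with c' in g/mL.  Gaussian
    noise at the configured repeatability is added to all four emitted
    readings; the recorded GroundTruth is noise-free and internally
    consistent with the derivation chain under the configured parse.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    T = cfg.grid()
    rho0 = np.polyval(cfg.rho0_coeffs, T)
    u0 = np.polyval(cfg.u0_coeffs, T)
    cp = cfg.concentration * MG_ML_TO_G_ML

    u_inc = cfg.u_increment_true(T)
    phi_v = cfg.phi_v_true(T)
    u = u0 * (1.0 + u_inc * cp)
    rho = rho0 + cp * (1.0 - phi_v * rho0)

    sig_r = cfg.precision.sigma_density
    sig_u = cfg.precision.sigma_velocity
    scan = PairedScan.from_arrays(
        solvent_T=T,
        solvent_rho=rho0 + rng.normal(0, sig_r, T.size) if sig_r else rho0,
        solvent_u=u0 + rng.normal(0, sig_u, T.size) if sig_u else u0,
        susp_T=T,
        susp_rho=rho + rng.normal(0, sig_r, T.size) if sig_r else rho,
        susp_u=u + rng.normal(0, sig_u, T.size) if sig_u else u,
        concentration=cfg.concentration,
    )

    beta0 = compressibility(u0, rho0)
    phi_k = specific_compressibility(u_inc, phi_v, rho0)
    if cfg.eq5_parse == "two_minus_u_over_phiv":
        beta_lip = lipid_compressibility(beta0, u_inc, phi_v)
    else:
        beta_lip = beta0 * phi_k / phi_v
    truth = GroundTruth(
        seed=seed,
        temperatures=T,
        u_increment=u_inc,
        phi_v=phi_v,
        phi_k_over_beta0=phi_k,
        beta_lipid=beta_lip,
        K_lipid=1.0 / beta_lip,
        Tm=cfg.dip_Tm,
    )
    return scan, truth


def generate_particles(cfg: SyntheticConfig, seed: int | None = None
                       ) -> tuple[list[ParticleRecord], GroundTruth]:
    """Ellipse-shaped particles with Beta-distributed roundness.

    Roundness r ~ Beta(mean·kappa, (1−mean)·kappa) (mean exactly
    ``roundness_mean``); the full major axis is a lognormal diameter and the
    minor semi-axis is r times the major semi-axis, so the analytic roundness
    of each emitted record equals the drawn r.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = cfg.n_particles
    if n < 1:
        raise ValueError("need at least one particle")
    m, k = cfg.roundness_mean, cfg.roundness_kappa
    if k > 0 and 0 < m < 1:
        r = rng.beta(m * k, (1.0 - m) * k, n)
    else:
        r = np.full(n, m)
    mu = np.log(cfg.particle_mean_diameter) - 0.5 * cfg.particle_sigma_log**2
    major = rng.lognormal(mu, cfg.particle_sigma_log, n)
    a = major / 2.0
    b = r * a
    records = [
        ParticleRecord(area=float(np.pi * ai * bi), major_axis=float(2 * ai))
        for ai, bi in zip(a, b)
    ]
    truth = GroundTruth(seed=seed, roundness=r, mean_roundness=float(m))
    return records, truth


def generate_particle_mask(aspect_ratio: float, radius_px: int = 50,
                           angle: float = 0.0) -> np.ndarray:
    """Rasterise one ellipse mask with semi-axes (radius_px, radius_px/aspect_ratio)."""
    from skimage.draw import ellipse as _ellipse

    if aspect_ratio < 1:
        raise ValueError("aspect ratio is major/minor, must be >= 1")
    pad = int(radius_px * 1.5) + 5
    shape = (2 * pad, 2 * pad)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _ellipse(pad, pad, radius_px, radius_px / aspect_ratio,
                      shape=shape, rotation=angle)
    mask[rr, cc] = True
    return mask


def generate_dls(cfg: SyntheticConfig, seed: int | None = None
                 ) -> tuple[SizeDistribution, GroundTruth]:
    """Lognormal vesicle diameters as a number-weighted size distribution.

    The ground truth records the analytic intensity-weighted mean under the
    Rayleigh d⁶ rule, the lognormal moment ratio
    E[d⁷]/E[d⁶] = exp(mu + 6.5·sigma²).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if cfg.n_dls < 1:
        raise ValueError("need at least one diameter")
    mu = np.log(cfg.dls_median)
    s = cfg.dls_sigma_log
    d = rng.lognormal(mu, s, cfg.n_dls) if s > 0 else np.full(cfg.n_dls, cfg.dls_median)
    dist = SizeDistribution.from_sample(d)
    truth = GroundTruth(
        seed=seed,
        diameters=d,
        number_mean_diameter=float(np.exp(mu + 0.5 * s**2)),
        intensity_mean_diameter=float(np.exp(mu + 6.5 * s**2)),
    )
    return dist, truth


def generate_zeta(cfg: SyntheticConfig, seed: int | None = None) -> np.ndarray:
    """Gaussian zeta-potential replicates (mV); plain samples for group statistics."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    return rng.normal(cfg.zeta_mean, cfg.zeta_sd, cfg.n_zeta)
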