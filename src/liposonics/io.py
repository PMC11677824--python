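"""CSV/JSON/YAML interfaces and the end-to-end condition report.

All tabular files are CSV with explicit unit-bearing headers:

* medium scans: ``temperature_C, density_g_per_cm3, sound_velocity_m_per_s``
  (suspensions add ``concentration_mg_per_mL``); a long-format file may carry
  both media with a ``medium`` column (``solvent``/``suspension``);
* derived scans: the :data:`liposonics.acoustics.DerivedScan` table plus a
  JSON metadata side-car;
* particles: ``area_nm2, major_axis_nm``; DLS: ``diameter_nm, weight``.

``run_pipeline`` composes the synthetic generator, the derivation chain, dip
detection, morphology and group statistics into one summary per condition at
a chosen reporting temperature (default 37 °C, the physiological anchor).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustics, group_stats, morphology, synthetic, thermal

__all__ = [
    "ConditionReport",
    "read_medium_csv",
    "read_suspension_csv",
    "read_paired_csv",
    "write_medium_csv",
    "write_suspension_csv",
    "write_derived",
    "read_derived",
    "read_particles_csv",
    "write_particles_csv",
    "read_dls_csv",
    "write_dls_csv",
    "run_pipeline",
    "default_conditions",
    "report_frame",
]

_MEDIUM_COLS = ["temperature_C", "density_g_per_cm3", "sound_velocity_m_per_s"]
_SUSP_COLS = _MEDIUM_COLS + ["concentration_mg_per_mL"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing unit-bearing columns {missing}; found {list(df.columns)}")


def _rows_to_points(df: pd.DataFrame, cls, cols, path):
    points = []
    for i, row in df.iterrows():
        try:
            points.append(cls(*[float(row[c]) for c in cols]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row {i}: {exc}") from exc
    return points


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_medium_csv(path) -> list[acoustics.MediumPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _MEDIUM_COLS, path)
    return _rows_to_points(df, acoustics.MediumPoint, _MEDIUM_COLS, path)


def read_suspension_csv(path) -> list[acoustics.SuspensionPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _SUSP_COLS, path)
    return _rows_to_points(df, acoustics.SuspensionPoint, _SUSP_COLS, path)


def read_paired_csv(path, temperature_tolerance: float = 0.05) -> acoustics.PairedScan:
    """Read a long-format scan file carrying a ``medium`` column."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _MEDIUM_COLS + ["medium"], path)
    solv = df[df["medium"] == "solvent"]
    susp = df[df["medium"] == "suspension"]
    if solv.empty or susp.empty:
        raise ValueError(f"{path}: need both 'solvent' and 'suspension' rows")
    _require_columns(susp, _SUSP_COLS, path)
    return acoustics.PairedScan(
        _rows_to_points(solv, acoustics.MediumPoint, _MEDIUM_COLS, path),
        _rows_to_points(susp, acoustics.SuspensionPoint, _SUSP_COLS, path),
        temperature_tolerance,
    )


def write_medium_csv(points, path) -> None:
    pd.DataFrame(
        [(p.temperature, p.density, p.sound_velocity) for p in points],
        columns=_MEDIUM_COLS,
    ).to_csv(path, index=False, float_format="%.17g")


def write_suspension_csv(points, path) -> None:
    pd.DataFrame(
        [(p.temperature, p.density, p.sound_velocity, p.concentration) for p in points],
        columns=_SUSP_COLS,
    ).to_csv(path, index=False, float_format="%.17g")


def write_derived(derived: acoustics.DerivedScan, csv_path, meta_path=None) -> None:
    derived.table.to_csv(csv_path, index=False, float_format="%.17g")
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(derived.metadata, indent=2))


def read_derived(csv_path, meta_path=None) -> acoustics.DerivedScan:
    table = pd.read_csv(csv_path, float_precision="round_trip")
    meta = json.loads(Path(meta_path).read_text()) if meta_path else {}
    return acoustics.DerivedScan(table=table, metadata=meta)


def read_particles_csv(path) -> list[morphology.ParticleRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["area_nm2", "major_axis_nm"], path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                morphology.ParticleRecord(
                    float(row["area_nm2"]), float(row["major_axis_nm"]),
                    image_id=str(row["image_id"]) if "image_id" in df.columns else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return out


def write_particles_csv(records, path) -> None:
    pd.DataFrame(
        [(p.area, p.major_axis, p.image_id) for p in records],
        columns=["area_nm2", "major_axis_nm", "image_id"],
    ).to_csv(path, index=False, float_format="%.17g")


def read_dls_csv(path, weighting: str = "number") -> morphology.SizeDistribution:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["diameter_nm", "weight"], path)
    return morphology.SizeDistribution(
        df["diameter_nm"].to_numpy(), df["weight"].to_numpy(), weighting
    )


def write_dls_csv(dist: morphology.SizeDistribution, path) -> None:
    pd.DataFrame(
        {"diameter_nm": dist.diameters, "weight": dist.weights}
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# condition report (summary-table layout)
# ---------------------------------------------------------------------------

@dataclass
class ConditionReport:
    """One condition's summary at the reporting temperature.

    ``values`` maps quantity name -> dict(value, ci_lo, ci_hi, units);
    ``metadata`` records seed, equation-parse choice and input provenance.
    """

    label: str
    temperature: float
    values: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "temperature_C": self.temperature,
            "values": self.values,
            "metadata": self.metadata,
        }


def default_conditions() -> list[dict]:
    """Three-condition fixture convention (omega-3 fraction labels)."""
    return [
        {"label": "0% PDPC", "u_inc_level": 0.012, "roundness_mean": 0.70,
         "zeta_mean": -59.5},
        {"label": "50% PDPC", "u_inc_level": 0.015, "roundness_mean": 0.838,
         "zeta_mean": -46.4},
        {"label": "100% PDPC", "u_inc_level": 0.018, "roundness_mean": 0.832,
         "zeta_mean": -54.5},
    ]


def _child_seed(base: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(base), *key]).generate_state(1)[0] % 2**31)


def run_pipeline(config: dict | None = None, seed: int = 0,
                 report_temperature: float = 37.0) -> list[ConditionReport]:
    """Simulate, derive and summarise every condition into a report table.

    ``config`` may override ``conditions`` (a list of dicts with ``label``
    plus :class:`liposonics.synthetic.SyntheticConfig` field overrides),
    ``report_temperature`` and any base SyntheticConfig field.  All
    randomness flows from ``seed``.
    """
    config = dict(config or {})
    conditions = config.pop("conditions", None) or default_conditions()
    report_temperature = config.pop("report_temperature", report_temperature)
    base_kwargs = config

    reports = []
    for i, cond in enumerate(conditions):
        cond = dict(cond)
        label = cond.pop("label", f"condition-{i}")
        kwargs = {**base_kwargs, **cond}
        if "precision" in kwargs and isinstance(kwargs["precision"], dict):
            kwargs["precision"] = acoustics.InstrumentPrecision(**kwargs["precision"])
        cfg = synthetic.SyntheticConfig(**kwargs)

        scan, truth = synthetic.generate_scans(cfg, seed=_child_seed(seed, i, 0))
        derived = acoustics.derive_scan(scan, cfg.precision, parse=cfg.eq5_parse)
        tab = derived.table
        j = int((tab["temperature_C"] - report_temperature).abs().idxmin())
        row = tab.loc[j]

        dip = thermal.detect_dip(
            thermal.ThermalSeries(
                tab["temperature_C"].to_numpy(),
                tab["u_increment_mL_per_g"].to_numpy(),
                tab["sigma_u_increment_mL_per_g"].to_numpy(),
            )
        )

        particles, _ = synthetic.generate_particles(cfg, seed=_child_seed(seed, i, 1))
        round_vals = np.array([morphology.roundness(p) for p in particles])
        round_sum = morphology.summarize_sizes(round_vals)
        # equivalent-area diameter of the emitted ellipses
        tem_d = np.array([2.0 * np.sqrt(p.area / np.pi) for p in particles])
        tem_sum = morphology.summarize_sizes(tem_d)

        dls, _ = synthetic.generate_dls(cfg, seed=_child_seed(seed, i, 2))
        intens = morphology.to_intensity_weighted(dls)
        d_mean = intens.mean()
        d_sd = float(np.sqrt(np.sum(intens.weights * (intens.diameters - d_mean) ** 2)))
        d_lo, d_hi = group_stats.confidence_interval(d_mean, d_sd, dls.diameters.size)

        zeta = synthetic.generate_zeta(cfg, seed=_child_seed(seed, i, 3))
        z_sum = morphology.summarize_sizes(zeta)

        c = 1.959963984540054  # normal 0.975 quantile, the reporting convention
        values = {
            "specific_compressibility_mL_per_g": {
                "value": float(row["phi_k_over_beta0_mL_per_g"]),
                "ci_lo": float(row["phi_k_over_beta0_mL_per_g"] - c * row["sigma_phi_k_over_beta0_mL_per_g"]),
                "ci_hi": float(row["phi_k_over_beta0_mL_per_g"] + c * row["sigma_phi_k_over_beta0_mL_per_g"]),
                "units": "mL/g",
            },
            "elastic_modulus_GPa": {
                "value": float(row["K_lipid_Pa"]) / 1e9,
                "ci_lo": float(row["K_lipid_Pa"] - c * row["sigma_K_lipid_Pa"]) / 1e9,
                "ci_hi": float(row["K_lipid_Pa"] + c * row["sigma_K_lipid_Pa"]) / 1e9,
                "units": "GPa",
            },
            "zeta_potential_mV": {
                "value": z_sum.mean, "ci_lo": z_sum.ci_lo, "ci_hi": z_sum.ci_hi,
                "units": "mV",
            },
            "hydrodynamic_diameter_nm": {
                "value": d_mean, "ci_lo": float(d_lo), "ci_hi": float(d_hi),
                "units": "nm",
            },
            "tem_diameter_nm": {
                "value": tem_sum.mean, "ci_lo": tem_sum.ci_lo, "ci_hi": tem_sum.ci_hi,
                "units": "nm",
            },
            "roundness": {
                "value": round_sum.mean, "ci_lo": round_sum.ci_lo, "ci_hi": round_sum.ci_hi,
                "units": "dimensionless",
            },
        }
        cfg_json = json.dumps({k: str(v) for k, v in sorted(kwargs.items())})
        reports.append(
            ConditionReport(
                label=label,
                temperature=float(row["temperature_C"]),
                values=values,
                metadata={
                    "seed": seed,
                    "condition_seed_children": [_child_seed(seed, i, k) for k in range(4)],
                    "eq5_parse": derived.metadata["eq5_parse"],
                    "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
                    "dip": {
                        "found": dip.dip_found,
                        "T_min_C": dip.T_min,
                        "depth_mL_per_g": dip.depth,
                    },
                    "true_Tm_C": truth.Tm,
                },
            )
        )
    return reports


def report_frame(reports: list[ConditionReport]) -> pd.DataFrame:
    """Summary-table layout: one row per property, one column per condition."""
    rows = {}
    for rep in reports:
        for name, v in rep.values.items():
            half = (v["ci_hi"] - v["ci_lo"]) / 2.0
            rows.setdefault(f"{name} ({v['units']})", {})[rep.label] = (
                f"{v['value']:.4g} ± {half:.2g}"
            )
    return pd.DataFrame(rows).T
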