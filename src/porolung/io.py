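"""File formats: experiment record directories, materials JSON, configs.

An experiment record is a directory of plain-text files:

* ``pv.csv`` — columns t_s, p_kPa, V_added_mL (exactly 20 rows, first
  volume 0)
* ``strain_stats.csv`` — columns lobe, stage_fraction, mean_strain,
  std_strain (exactly 15 rows: 5 lobes x 3 stages)
* ``meta.json`` — geometry scalars, the pressure ramp, and provenance

Floats are written at full precision so a write/read round trip is
lossless.  Calibration run configs are JSON or YAML with strict key
validation (unknown keys are rejected with a list of offenders).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import DEFAULT_BOUNDS, DEFAULT_STARTS, TerminationCriteria
from .forward import (
    LOBES,
    STAGE_FRACTIONS,
    ForwardResult,
    LobeStrainStats,
    LungGeometry,
    MaterialSet,
    PressureRamp,
    sample_pv,
)
from .metrics import ExperimentRecord, N_PV_POINTS

__all__ = [
    "write_experiment",
    "read_experiment",
    "write_forward_result",
    "materials_to_json",
    "materials_from_json",
    "read_biaxial_csv",
    "load_calibration_config",
]

_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A file failed schema or count validation."""


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_experiment(record: ExperimentRecord, path) -> None:
    """Write an experiment record directory (pv.csv, strain_stats.csv, meta.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _df_to_csv(record.pv, path / "pv.csv")
    _df_to_csv(record.strain_stats.to_frame(), path / "strain_stats.csv")
    geom = record.geometry
    meta = {
        "geometry": {
            "V_total_mL": geom.V_total_mL,
            "lobe_fractions": list(geom.lobe_fractions),
            "m_lung_g": geom.m_lung_g,
            "rho_lung_g_cm3": geom.rho_lung_g_cm3,
        },
        "ramp": {
            "times_s": record.ramp.times_s.tolist(),
            "pressures_kPa": record.ramp.pressures_kPa.tolist(),
        },
        "provenance": record.provenance,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def read_experiment(path) -> ExperimentRecord:
    """Read and validate an experiment record directory."""
    path = Path(path)
    for name in ("pv.csv", "strain_stats.csv", "meta.json"):
        if not (path / name).exists():
            raise FormatError(f"experiment directory is missing {name}")
    pv = pd.read_csv(path / "pv.csv", float_precision="round_trip")
    missing = {"t_s", "p_kPa", "V_added_mL"} - set(pv.columns)
    if missing:
        raise FormatError(f"pv.csv is missing columns {sorted(missing)}")
    if len(pv) != N_PV_POINTS:
        raise FormatError(
            f"pv.csv must contain exactly {N_PV_POINTS} pressure/volume rows, "
            f"got {len(pv)}"
        )
    ss = pd.read_csv(path / "strain_stats.csv", float_precision="round_trip")
    missing = {"lobe", "stage_fraction", "mean_strain", "std_strain"} - set(ss.columns)
    if missing:
        raise FormatError(f"strain_stats.csv is missing columns {sorted(missing)}")
    n_expected = len(LOBES) * len(STAGE_FRACTIONS)
    if len(ss) != n_expected:
        raise FormatError(
            f"strain_stats.csv must contain exactly {n_expected} rows "
            f"(2 x {n_expected} = 30 strain statistics), got {len(ss)}"
        )
    means = np.empty((len(LOBES), len(STAGE_FRACTIONS)))
    stds = np.empty_like(means)
    for i, lobe in enumerate(LOBES):
        for j, frac in enumerate(STAGE_FRACTIONS):
            row = ss[(ss["lobe"] == lobe) & (np.isclose(ss["stage_fraction"], frac))]
            if len(row) != 1:
                raise FormatError(
                    f"strain_stats.csv needs exactly one row for lobe {lobe} "
                    f"at stage {frac}, found {len(row)}"
                )
            means[i, j] = row["mean_strain"].iloc[0]
            stds[i, j] = row["std_strain"].iloc[0]
    meta = json.loads((path / "meta.json").read_text())
    for key in ("geometry", "ramp", "provenance"):
        if key not in meta:
            raise FormatError(f"meta.json is missing the '{key}' section")
    g = meta["geometry"]
    geometry = LungGeometry(
        V_total_mL=g["V_total_mL"],
        lobe_fractions=tuple(g["lobe_fractions"]),
        m_lung_g=g["m_lung_g"],
        rho_lung_g_cm3=g["rho_lung_g_cm3"],
    )
    ramp = PressureRamp(
        times_s=np.array(meta["ramp"]["times_s"]),
        pressures_kPa=np.array(meta["ramp"]["pressures_kPa"]),
    )
    return ExperimentRecord(
        pv=pv,
        strain_stats=LobeStrainStats(means=means, stds=stds),
        geometry=geometry,
        ramp=ramp,
        provenance=meta["provenance"],
    )


def write_forward_result(result: ForwardResult, path, n_pv: int = N_PV_POINTS) -> None:
    """Export a simulation: pv.csv (sampled) and strain_stats.csv."""
    from .forward import extract_strain_stats

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _df_to_csv(sample_pv(result, n_pv), path / "pv.csv")
    stats = extract_strain_stats(result, result.ramp)
    _df_to_csv(stats.to_frame(), path / "strain_stats.csv")


def materials_to_json(mats: MaterialSet) -> str:
    """Unit-annotated JSON for a material set."""
    return json.dumps(
        {
            "mu_kPa": mats.parenchyma.mu_kPa,
            "alpha": mats.parenchyma.alpha,
            "nu": mats.parenchyma.nu,
            "k_1e-3_mm2_per_s": list(mats.permeabilities_1e3_mm2_s),
            "C10_kPa": mats.airways.C10_kPa,
            "pleura_lambda": mats.pleura.scale_lambda,
            "pleura_baseline_kPa": list(mats.pleura.baseline.coefficients_kPa),
            "pleura_thickness_mm": mats.pleura.thickness0_mm,
            "airway_fraction": mats.airway_fraction,
            "heterogeneity_sigma": mats.heterogeneity_sigma,
        },
        indent=2,
    )


def materials_from_json(text: str) -> MaterialSet:
    from .constitutive import (
        HyperfoamParams,
        NeoHookeanParams,
        PleuraMaterial,
        ReducedPolynomialParams,
    )

    d = json.loads(text)
    allowed = {
        "mu_kPa", "alpha", "nu", "k_1e-3_mm2_per_s", "C10_kPa", "pleura_lambda",
        "pleura_baseline_kPa", "pleura_thickness_mm", "airway_fraction",
        "heterogeneity_sigma",
    }
    unknown = set(d) - allowed
    if unknown:
        raise FormatError(f"unknown material keys: {sorted(unknown)}")
    return MaterialSet(
        parenchyma=HyperfoamParams(d["mu_kPa"], d["alpha"], d.get("nu", 0.0)),
        permeabilities_1e3_mm2_s=tuple(d["k_1e-3_mm2_per_s"]),
        airways=NeoHookeanParams(d["C10_kPa"]),
        pleura=PleuraMaterial(
            ReducedPolynomialParams(tuple(d["pleura_baseline_kPa"])),
            scale_lambda=d["pleura_lambda"],
            thickness0_mm=d.get("pleura_thickness_mm", 0.06),
        ),
        airway_fraction=d.get("airway_fraction", 0.02),
        heterogeneity_sigma=d.get("heterogeneity_sigma", 0.3),
    )


def read_biaxial_csv(path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read a biaxial dataset into per-sample (strain, stress) curves."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"sample_id", "nominal_strain", "nominal_stress_kPa"} - set(df.columns)
    if missing:
        raise FormatError(f"biaxial CSV is missing columns {sorted(missing)}")
    return [
        (g["nominal_strain"].to_numpy(), g["nominal_stress_kPa"].to_numpy())
        for _, g in df.groupby("sample_id", sort=True)
    ]


_CONFIG_KEYS = {
    "bounds", "starts", "criteria", "seed", "n_patches", "sim_config", "noise",
}
_CRITERIA_KEYS = {"function_tol", "max_fevals", "max_iters", "optimality_tol", "step_tol"}


def load_calibration_config(path) -> dict:
    """Load and validate a calibration config (JSON or YAML by extension).

    Returns a dict with keys bounds, starts, criteria (a
    TerminationCriteria), seed, n_patches, sim_config, noise; absent keys
    take the package defaults.  Unknown keys anywhere are rejected.
    """
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(raw, dict):
        raise FormatError("calibration config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    crit_raw = raw.get("criteria", {})
    unknown = set(crit_raw) - _CRITERIA_KEYS
    if unknown:
        raise FormatError(f"unknown criteria keys: {sorted(unknown)}")
    bounds = raw.get("bounds", [list(b) for b in DEFAULT_BOUNDS])
    if len(bounds) != len(DEFAULT_BOUNDS) or any(len(b) != 2 for b in bounds):
        raise FormatError("bounds must be 10 [lower, upper] pairs")
    starts = raw.get("starts", [list(s) for s in DEFAULT_STARTS])
    if any(len(s) != len(DEFAULT_STARTS[0]) for s in starts):
        raise FormatError("each start must list all 10 parameter components")
    return {
        "bounds": tuple(tuple(b) for b in bounds),
        "starts": tuple(tuple(s) for s in starts),
        "criteria": TerminationCriteria(**crit_raw),
        "seed": int(raw.get("seed", 0)),
        # None defers to the experiment's own provenance
        "n_patches": (int(raw["n_patches"]) if "n_patches" in raw else None),
        "sim_config": raw.get("sim_config"),
        "noise": raw.get("noise"),
    }
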