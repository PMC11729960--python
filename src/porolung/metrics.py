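"""Volume bookkeeping, relative error metrics and the normalized residual.

The calibration target is an experiment record with 20 pressure/volume
pairs and 30 lobe strain statistics (5 lobes x 3 stages x {mean, std}).
The objective is the squared norm of a 50-component residual vector: 20
volume residuals, 15 mean-strain residuals, 15 std-strain residuals, each
block divided by the standard deviation of the corresponding experimental
values so that the three blocks are comparable in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .forward import LOBES, LobeStrainStats, LungGeometry, PressureRamp

__all__ = [
    "InitialVolumes",
    "ExperimentRecord",
    "ErrorBreakdown",
    "initial_volumes",
    "scale_model_volume",
    "relative_volume_error",
    "strain_errors",
    "residual_vector",
    "error_breakdown",
    "N_PV_POINTS",
    "N_STRAIN_POINTS",
    "RESIDUAL_LENGTH",
]

N_PV_POINTS = 20
N_STRAIN_POINTS = 30  # 15 means + 15 standard deviations
RESIDUAL_LENGTH = N_PV_POINTS + N_STRAIN_POINTS


class InitialVolumes(NamedTuple):
    V_tissue_mL: float
    V_air0_mL: float
    porosity0: float


def initial_volumes(
    m_lung_g: float, rho_lung_g_cm3: float, V_total_mL: float
) -> InitialVolumes:
    """Tissue volume, initial air volume and porosity from bookkeeping.

    V_tissue = m/rho (1 g/cm^3 tissue density by convention), V_air0 =
    V_total - V_tissue, porosity = V_air0/V_total.  The porosity must be
    strictly inside (0, 1): a lung with no air (or no tissue) is rejected.
    """
    if m_lung_g <= 0 or rho_lung_g_cm3 <= 0 or V_total_mL <= 0:
        raise ValueError("mass, density and total volume must be positive")
    v_tissue = m_lung_g / rho_lung_g_cm3
    v_air0 = V_total_mL - v_tissue
    porosity = v_air0 / V_total_mL
    if not 0.0 < porosity < 1.0:
        raise ValueError(
            f"porosity must lie strictly in (0, 1), got {porosity:.4g} "
            f"(V_total = {V_total_mL} mL, V_tissue = {v_tissue} mL)"
        )
    return InitialVolumes(v_tissue, v_air0, porosity)


def scale_model_volume(geom: LungGeometry, V_total_target_mL: float) -> LungGeometry:
    """Rescale the model so its total volume matches the measured lung.

    Lobe fractions are untouched; tissue mass is scaled with volume so the
    porosity is invariant (the mesh-scaling convention: geometry changes,
    material does not).
    """
    if V_total_target_mL <= 0:
        raise ValueError("target volume must be positive")
    ratio = V_total_target_mL / geom.V_total_mL
    return replace(
        geom, V_total_mL=V_total_target_mL, m_lung_g=geom.m_lung_g * ratio
    )


def relative_volume_error(V_exp_mL, V_num_mL) -> tuple[np.ndarray, float]:
    """Pointwise percent error 100 |V_exp - V_num| / V_exp and its mean.

    Points with V_exp = 0 (the zeroed inflation origin) are NaN in the
    series and excluded from the mean.
    """
    v_exp = np.asarray(V_exp_mL, dtype=float)
    v_num = np.asarray(V_num_mL, dtype=float)
    if v_exp.shape != v_num.shape:
        raise ValueError("volume series must have equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        err = 100.0 * np.abs(v_exp - v_num) / np.abs(v_exp)
    err = np.where(v_exp == 0.0, np.nan, err)
    valid = err[~np.isnan(err)]
    if valid.size == 0:
        raise ValueError("no nonzero experimental volumes to compare")
    return err, float(valid.mean())


def strain_errors(
    exp: LobeStrainStats, num: LobeStrainStats
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Percent errors for the 15 strain means and 15 strain stds.

    Same relative form as the volume error; components whose experimental
    value is exactly zero are excluded from the block aggregates (they
    carry no relative scale).
    """

    def block(e, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            err = 100.0 * np.abs(e - n) / np.abs(e)
        err = np.where(e == 0.0, np.nan, err)
        valid = err[~np.isnan(err)]
        if valid.size == 0:
            raise ValueError("all experimental strain values in a block are zero")
        return err, float(valid.mean())

    mean_err, mean_agg = block(exp.flat_means(), num.flat_means())
    std_err, std_agg = block(exp.flat_stds(), num.flat_stds())
    return mean_err, std_err, mean_agg, std_agg


@dataclass(frozen=True)
class ErrorBreakdown:
    """Mean absolute relative errors (%) per comparison block."""

    volume_pct: float
    mean_strain_pct: float
    std_strain_pct: float

    def overall(self) -> float:
        return (self.volume_pct + self.mean_strain_pct + self.std_strain_pct) / 3.0


@dataclass(frozen=True)
class ExperimentRecord:
    """A ventilation experiment: the calibration target.

    pv is a DataFrame with columns t_s, p_kPa, V_added_mL (exactly 20
    rows, first added volume 0); strain_stats holds the 30 lobe strain
    statistics.  provenance records how the record was made: kind
    ("measured" or "synthetic"), and for synthetic records the generating
    seed, ground-truth parameter vector and forward-model settings needed
    to reproduce the simulation exactly.
    """

    pv: pd.DataFrame
    strain_stats: LobeStrainStats
    geometry: LungGeometry
    ramp: PressureRamp
    provenance: dict

    def __post_init__(self) -> None:
        pv = self.pv.reset_index(drop=True)
        object.__setattr__(self, "pv", pv)
        required = {"t_s", "p_kPa", "V_added_mL"}
        if not required.issubset(pv.columns):
            raise ValueError(f"pv must have columns {sorted(required)}")
        if len(pv) != N_PV_POINTS:
            raise ValueError(
                f"experiment must contain exactly {N_PV_POINTS} PV pairs, got {len(pv)}"
            )
        if pv["V_added_mL"].iloc[0] != 0.0:
            raise ValueError("first PV volume must be zero (zeroed origin)")
        if "kind" not in self.provenance:
            raise ValueError("provenance must declare its kind")
        if self.provenance["kind"] not in ("measured", "synthetic"):
            raise ValueError("provenance kind must be 'measured' or 'synthetic'")


def residual_vector(
    exp: ExperimentRecord, sim_pv_mL, sim_stats: LobeStrainStats
) -> np.ndarray:
    """The 50-component normalized residual behind the objective.

    Components are (experimental - simulated) divided by the block
    normalizer: delta_V = std of the 20 experimental volumes (the zero
    origin included), delta_xbar and delta_sigma = stds of the 15
    experimental strain means and stds.  The objective is
    phi = sum of squared components (least-squares convention).
    """
    v_exp = exp.pv["V_added_mL"].to_numpy()
    v_num = np.asarray(sim_pv_mL, dtype=float)
    if v_num.shape != (N_PV_POINTS,):
        raise ValueError(f"simulated volumes must have length {N_PV_POINTS}")
    blocks = []
    for e, n, name in (
        (v_exp, v_num, "volume"),
        (exp.strain_stats.flat_means(), sim_stats.flat_means(), "mean-strain"),
        (exp.strain_stats.flat_stds(), sim_stats.flat_stds(), "std-strain"),
    ):
        delta = float(np.std(e, ddof=0))
        if delta == 0.0:
            raise ValueError(
                f"degenerate experiment: {name} block has zero spread"
            )
        blocks.append((e - n) / delta)
    r = np.concatenate(blocks)
    if not np.all(np.isfinite(r)):
        raise ValueError("residual vector contains non-finite components")
    return r


def error_breakdown(
    exp: ExperimentRecord, sim_pv_mL, sim_stats: LobeStrainStats
) -> ErrorBreakdown:
    """The three-block mean relative error triplet for reporting."""
    _, vol = relative_volume_error(exp.pv["V_added_mL"].to_numpy(), sim_pv_mL)
    _, _, mean_agg, std_agg = strain_errors(exp.strain_stats, sim_stats)
    return ErrorBreakdown(vol, mean_agg, std_agg)
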