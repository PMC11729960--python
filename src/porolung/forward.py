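"""Reduced-order five-lobe poroelastic inflation simulator.

Tracheal pressure drives permeability-limited airflow into five lobes, each
discretized as parallel spherical "patches" of parenchyma.  A patch of
initial volume V0 inflates isotropically (stretch lam = (V/V0)^(1/3))
against three recoil contributions sharing a single pressure balance:

* the compressible foam Cauchy stress of the parenchyma,
* a uniaxial Neo-Hookean surrogate for the embedded airway tree, weighted
  by a small volume fraction,
* a Laplace membrane term for the pleura
  (2 t0 P_b(lam) / (r0 lam^2), with P_b the scaled equibiaxial nominal
  stress of the membrane).

Air flow into each patch follows a Darcy-type law through a geometric
conductance 4 pi r0 lam (the conductance of a sphere with a pressure
gradient over one radius), optionally reduced by a Forchheimer drag term.
Permeability carries the conventional 1e-3 mm^2/s unit of the calibration
box; because a kPa-normalized Darcy law in these units is not
dimensionally closed, the flux carries a fixed dimensionless gain
(``flow_gain``) chosen once so that compartment filling time constants are
a fraction of the 2 s breath for mid-range permeabilities (see
docs/methods.md).  The gain is a model constant, never calibrated.

Lobe order everywhere: UL, LL, UR, MR, LR (upper/lower left, upper/middle/
lower right).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constitutive import (
    HyperfoamParams,
    NeoHookeanParams,
    PleuraMaterial,
    equibiaxial_nominal_stress,
    poisson_to_beta,
    scale_reduced_polynomial,
)

__all__ = [
    "LOBES",
    "STAGE_FRACTIONS",
    "LungGeometry",
    "MaterialSet",
    "PressureRamp",
    "PatchSet",
    "SimulationConfig",
    "ForwardResult",
    "LobeStrainStats",
    "build_lobes",
    "recoil_pressure",
    "simulate_inflation",
    "extract_strain_stats",
    "sample_pv",
    "equilibrium_added_volume",
]

LOBES = ("UL", "LL", "UR", "MR", "LR")
STAGE_FRACTIONS = (0.3, 0.6, 1.0)

#: Default lobe volume fractions (UL, LL, UR, MR, LR).  Configurable
#: bookkeeping, not measured values.
DEFAULT_LOBE_FRACTIONS = (0.20, 0.25, 0.20, 0.10, 0.25)


@dataclass(frozen=True)
class LungGeometry:
    """Whole-organ volume bookkeeping.

    V_total_mL is the submersion-test total volume; tissue volume derives
    from mass over density, and the initial air volume / porosity follow by
    difference under full saturation.
    """

    V_total_mL: float
    lobe_fractions: tuple[float, ...] = DEFAULT_LOBE_FRACTIONS
    m_lung_g: float = 818.0
    rho_lung_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.lobe_fractions)
        object.__setattr__(self, "lobe_fractions", fr)
        if len(fr) != len(LOBES):
            raise ValueError(f"need {len(LOBES)} lobe fractions, got {len(fr)}")
        if any(f < 0 for f in fr):
            raise ValueError("lobe fractions must be nonnegative")
        if abs(sum(fr) - 1.0) > 1e-12:
            raise ValueError(f"lobe fractions must sum to 1, got {sum(fr)}")
        if self.m_lung_g <= 0 or self.rho_lung_g_cm3 <= 0 or self.V_total_mL <= 0:
            raise ValueError("mass, density and total volume must be positive")
        if not self.V_total_mL > self.V_tissue_mL:
            raise ValueError(
                "total volume must exceed tissue volume (porosity in (0, 1))"
            )

    @property
    def V_tissue_mL(self) -> float:
        return self.m_lung_g / self.rho_lung_g_cm3

    @property
    def V_air0_mL(self) -> float:
        return self.V_total_mL - self.V_tissue_mL

    @property
    def porosity0(self) -> float:
        return self.V_air0_mL / self.V_total_mL


@dataclass(frozen=True)
class MaterialSet:
    """The nine calibrated parameters plus fixed model constants.

    permeabilities_1e3_mm2_s holds the five lobe permeabilities in the
    conventional 1e-3 mm^2/s scaling (so values are O(0.1-100), matching
    the calibration box).
    """

    parenchyma: HyperfoamParams
    permeabilities_1e3_mm2_s: tuple[float, ...]
    airways: NeoHookeanParams
    pleura: PleuraMaterial
    airway_fraction: float = 0.02
    heterogeneity_sigma: float = 0.3

    def __post_init__(self) -> None:
        ks = tuple(float(k) for k in self.permeabilities_1e3_mm2_s)
        object.__setattr__(self, "permeabilities_1e3_mm2_s", ks)
        if len(ks) != len(LOBES):
            raise ValueError(f"need {len(LOBES)} permeabilities, got {len(ks)}")
        if any(k < 0 for k in ks):
            # k = 0 (sealed lobe) is a legitimate limit; the calibration
            # box, not the material, enforces the 0.1 lower bound.
            raise ValueError("permeabilities must be nonnegative")
        if self.airway_fraction < 0:
            raise ValueError("airway_fraction must be nonnegative")
        if self.heterogeneity_sigma < 0:
            raise ValueError("heterogeneity_sigma must be nonnegative")


@dataclass(frozen=True)
class PressureRamp:
    """Tracheal pressure history p(t), nondecreasing from 0 (kPa)."""

    times_s: np.ndarray
    pressures_kPa: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        p = np.asarray(self.pressures_kPa, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "pressures_kPa", p)
        if t.ndim != 1 or t.size < 2 or t.size != p.size:
            raise ValueError("times and pressures must be 1-d of equal length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if p[0] != 0.0:
            raise ValueError("ramp must start at zero pressure")
        if np.any(np.diff(p) < 0):
            raise ValueError("ramp pressures must be nondecreasing")

    @property
    def p_max_kPa(self) -> float:
        return float(self.pressures_kPa[-1])

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    def pressure_at(self, t):
        return np.interp(t, self.times_s, self.pressures_kPa)


@dataclass(frozen=True)
class PatchSet:
    """Per-patch discretization of the five lobes.

    Each lobe is split into ``n_patches`` parallel spherical compartments
    of equal initial volume; patch permeability is the lobe value times a
    lognormal multiplier (median 1) standing in for sub-lobar
    heterogeneity of local inflation.
    """

    lobe_index: np.ndarray  # (n,) int, index into LOBES
    V0_mm3: np.ndarray  # (n,) initial patch volumes
    r0_mm: np.ndarray  # (n,) equivalent sphere radii
    k_eff_mm2_s: np.ndarray  # (n,) permeability incl. multiplier, mm^2/s
    multipliers: np.ndarray  # (n,) the lognormal draws
    seed: int
    n_patches: int

    @property
    def n_total(self) -> int:
        return int(self.lobe_index.size)


def build_lobes(
    geom: LungGeometry, mats: MaterialSet, n_patches: int = 20, seed: int = 0
) -> PatchSet:
    """Discretize the lobes into patches; deterministic given ``seed``."""
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    lobe_index = np.repeat(np.arange(len(LOBES)), n_patches)
    fractions = np.asarray(geom.lobe_fractions)
    V0_mL = fractions[lobe_index] * geom.V_total_mL / n_patches
    V0_mm3 = 1e3 * V0_mL
    r0_mm = (3.0 * V0_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    # lognormal with median 1: exp(sigma * z)
    z = rng.standard_normal(lobe_index.size)
    multipliers = np.exp(mats.heterogeneity_sigma * z)
    k_lobe = np.asarray(mats.permeabilities_1e3_mm2_s)[lobe_index]
    k_eff = 1e-3 * k_lobe * multipliers
    return PatchSet(
        lobe_index=lobe_index,
        V0_mm3=V0_mm3,
        r0_mm=r0_mm,
        k_eff_mm2_s=k_eff,
        multipliers=multipliers,
        seed=int(seed),
        n_patches=int(n_patches),
    )


def recoil_pressure(mats: MaterialSet, lam, r0_mm):
    """Elastic recoil pressure of a patch at isotropic stretch lam (kPa).

    p_rec = sigma_foam + p_airway + p_membrane with

    * sigma_foam = (2 mu / (alpha lam^3)) (lam^alpha - lam^(-3 alpha beta)),
      the isotropic principal Cauchy stress of the foam (J = lam^3);
    * p_airway = airway_fraction * 2 C10 (lam - lam^-2), a uniaxial
      Neo-Hookean nominal stress weighted by the airway volume fraction;
    * p_membrane = 2 t0 P_b(lam) / (r0 lam^2), the Laplace pressure of an
      incompressible spherical membrane with scaled-pleura equibiaxial
      nominal stress P_b.

    Vanishes at lam = 1; lam < 1 returns the (negative) deflation branch.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    p = mats.parenchyma
    a = p.alpha
    beta = poisson_to_beta(p.nu)
    sigma_foam = 2.0 * p.mu_kPa / a * (lam ** (a - 3.0) - lam ** (-3.0 * a * beta - 3.0))
    p_air = mats.airway_fraction * 2.0 * mats.airways.C10_kPa * (lam - lam**-2)
    pb = equibiaxial_nominal_stress(scale_reduced_polynomial(mats.pleura), lam)
    p_mem = 2.0 * mats.pleura.thickness0_mm * pb / (np.asarray(r0_mm) * lam**2)
    out = sigma_foam + p_air + p_mem
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator and flux-law settings.

    n_steps is the uniform output grid (>= 50); the integrator itself is
    adaptive (stiff-capable LSODA) with relative tolerance ``rtol`` and
    absolute tolerance ``atol_mm3`` on patch volumes.
    """

    n_steps: int = 200
    rtol: float = 1e-6
    atol_mm3: float = 1e-6  # = 1e-9 mL
    method: str = "LSODA"
    flow_gain: float = 1.0e5
    p_ref_kPa: float = 1.0
    forchheimer_beta: float = 0.0  # s/mm^3, Darcy limit by default

    def __post_init__(self) -> None:
        if self.n_steps < 50:
            raise ValueError("solver step count must be >= 50")


@dataclass(frozen=True)
class LobeStrainStats:
    """Per-lobe mean/std of major nominal strain at the three stages.

    Arrays are (5 lobes, 3 stages), lobe order UL, LL, UR, MR, LR and
    stages 30/60/100% of peak pressure.  Flattening is lobe-major
    (stage index varies fastest), the fixed ordering of the residual
    vector.
    """

    means: np.ndarray  # (5, 3)
    stds: np.ndarray  # (5, 3)

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.stds, dtype=float)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "stds", s)
        if m.shape != (len(LOBES), len(STAGE_FRACTIONS)) or s.shape != m.shape:
            raise ValueError("strain statistics must have shape (5, 3)")
        if np.any(s < 0):
            raise ValueError("strain standard deviations must be nonnegative")

    def flat_means(self) -> np.ndarray:
        return self.means.ravel()

    def flat_stds(self) -> np.ndarray:
        return self.stds.ravel()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (LOBES[i], STAGE_FRACTIONS[j], self.means[i, j], self.stds[i, j])
            for i in range(len(LOBES))
            for j in range(len(STAGE_FRACTIONS))
        ]
        return pd.DataFrame(
            rows, columns=["lobe", "stage_fraction", "mean_strain", "std_strain"]
        )


@dataclass(frozen=True)
class ForwardResult:
    """Dense simulation output plus derived summaries."""

    patches: PatchSet
    ramp: PressureRamp
    times_s: np.ndarray  # (nt,)
    pressures_kPa: np.ndarray  # (nt,) applied tracheal pressure
    V_mm3: np.ndarray  # (n_patch, nt)
    lam: np.ndarray  # (n_patch, nt)
    pore_pressure_kPa: np.ndarray  # (n_patch, nt) patch recoil pressure
    V_added_mL: np.ndarray  # (nt,)
    cumulative_inflow_mL: np.ndarray  # (nt,) integral of total flux

    def conservation_error(self) -> float:
        """Relative mismatch between added volume and integrated inflow."""
        v_end = self.V_added_mL[-1]
        if v_end == 0.0:
            return float(abs(self.cumulative_inflow_mL[-1]))
        return float(abs(v_end - self.cumulative_inflow_mL[-1]) / v_end)


def _flux_mm3_s(patches, mats, cfg, t, V, ramp):
    lam = np.cbrt(V / patches.V0_mm3)
    p_rec = recoil_pressure(mats, lam, patches.r0_mm)
    p_tr = ramp.pressure_at(t)
    cond = cfg.flow_gain * 4.0 * np.pi * patches.r0_mm * lam * patches.k_eff_mm2_s
    q = cond * (p_tr - p_rec) / cfg.p_ref_kPa
    if cfg.forchheimer_beta > 0.0:
        q = q / (1.0 + cfg.forchheimer_beta * np.abs(q))
    return q, lam, p_rec


def simulate_inflation(
    patches: PatchSet,
    mats: MaterialSet,
    ramp: PressureRamp,
    config: SimulationConfig | None = None,
) -> ForwardResult:
    """Integrate the quasi-static patch filling ODEs over the ramp.

    Per patch, dV/dt = flow_gain * 4 pi r0 lam * k_eff * (p_tr - p_rec)
    / p_ref; an auxiliary state accumulates total inflow so volume
    conservation can be verified against the summed patch volumes.
    """
    cfg = config or SimulationConfig()
    n = patches.n_total

    def rhs(t, y):
        q, _, _ = _flux_mm3_s(patches, mats, cfg, t, y[:n], ramp)
        return np.concatenate([q, [q.sum()]])

    y0 = np.concatenate([patches.V0_mm3, [0.0]])
    t_eval = np.linspace(ramp.times_s[0], ramp.times_s[-1], cfg.n_steps + 1)

    def attempt(method):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # lsoda chatter on stiff corners
            return solve_ivp(
                rhs,
                (t_eval[0], t_eval[-1]),
                y0,
                method=method,
                t_eval=t_eval,
                rtol=cfg.rtol,
                atol=cfg.atol_mm3,
            )

    sol = attempt(cfg.method)
    if not sol.success and cfg.method == "LSODA":
        # extremely fast-filling corners of the parameter box exceed
        # LSODA's comfort; BDF handles them
        sol = attempt("BDF")
    if not sol.success:
        y = np.asarray(sol.y)
        t_fail = sol.t[-1] if np.size(sol.t) else ramp.times_s[0]
        if y.ndim == 2 and y.shape[1] > 0:
            lam_last = np.cbrt(y[:n, -1] / patches.V0_mm3)
            worst = int(np.argmax(np.abs(lam_last - 1.0)))
            where = f"patch {worst}, lobe {LOBES[patches.lobe_index[worst]]}"
        else:
            where = "before the first output step"
        raise RuntimeError(
            f"inflation integration failed at t = {t_fail:.4g} s ({where}): "
            f"{sol.message}"
        )
    V = sol.y[:n]
    lam = np.cbrt(V / patches.V0_mm3[:, None])
    p_rec = np.empty_like(lam)
    for j in range(lam.shape[1]):
        p_rec[:, j] = recoil_pressure(mats, lam[:, j], patches.r0_mm)
    V_added = (V - patches.V0_mm3[:, None]).sum(axis=0) / 1e3
    inflow = sol.y[n] / 1e3
    return ForwardResult(
        patches=patches,
        ramp=ramp,
        times_s=sol.t,
        pressures_kPa=ramp.pressure_at(sol.t),
        V_mm3=V,
        lam=lam,
        pore_pressure_kPa=p_rec,
        V_added_mL=V_added,
        cumulative_inflow_mL=inflow,
    )


def _interp_columns(t_query, times, matrix):
    """Linear interpolation of each matrix row at a scalar time."""
    j = np.searchsorted(times, t_query, side="right") - 1
    j = min(max(j, 0), times.size - 2)
    w = (t_query - times[j]) / (times[j + 1] - times[j])
    return (1.0 - w) * matrix[:, j] + w * matrix[:, j + 1]


def extract_strain_stats(result: ForwardResult, ramp: PressureRamp) -> LobeStrainStats:
    """Lobe-wise mean/std of major nominal strain at 30/60/100% of p_max.

    Stage times are located by linear interpolation of the applied
    pressure; the major nominal strain of a patch is lam - 1; statistics
    are the per-lobe mean and population standard deviation over patches.
    """
    p_max = ramp.p_max_kPa
    if p_max <= 0:
        raise ValueError("ramp peak pressure must be positive")
    times = result.times_s
    p = result.pressures_kPa
    means = np.empty((len(LOBES), len(STAGE_FRACTIONS)))
    stds = np.empty_like(means)
    for j, frac in enumerate(STAGE_FRACTIONS):
        if frac >= 1.0:
            t_stage = times[-1]
        else:
            t_stage = float(np.interp(frac * p_max, p, times))
        lam_stage = _interp_columns(t_stage, times, result.lam)
        strain = lam_stage - 1.0
        for i in range(len(LOBES)):
            sel = strain[result.patches.lobe_index == i]
            means[i, j] = sel.mean()
            stds[i, j] = sel.std(ddof=0)
    return LobeStrainStats(means=means, stds=stds)


def sample_pv(result: ForwardResult, n: int = 20) -> pd.DataFrame:
    """Sample n (pressure, added volume) pairs uniform in time over the ramp.

    The first sample sits at t = 0 where the added volume is zero by
    construction, matching the zeroed-origin convention of the
    experimental records.
    """
    if n < 2:
        raise ValueError("need at least 2 PV samples")
    t = np.linspace(result.times_s[0], result.times_s[-1], n)
    return pd.DataFrame(
        {
            "t_s": t,
            "p_kPa": result.ramp.pressure_at(t),
            "V_added_mL": np.interp(t, result.times_s, result.V_added_mL),
        }
    )


def equilibrium_added_volume(
    patches: PatchSet, mats: MaterialSet, p_kPa: float, lam_max: float = 50.0
) -> float:
    """Closed-form equilibrium added volume (mL) at pressure p (no ODE).

    Inverts p = p_rec(lam) per patch by bisection; the infinite-
    permeability limit of the simulator must approach this curve.  Raises
    if a patch has no equilibrium below ``lam_max`` (strain-softening
    material with p above its recoil maximum).
    """
    from scipy.optimize import brentq

    total = 0.0
    for i in range(patches.n_total):
        r0 = patches.r0_mm[i]
        if p_kPa <= 0.0:
            lam_eq = 1.0
        else:
            f = lambda lam: recoil_pressure(mats, lam, r0) - p_kPa
            if f(lam_max) < 0:
                raise ValueError(
                    f"no equilibrium below lam = {lam_max} at p = {p_kPa} kPa"
                )
            lam_eq = brentq(f, 1.0, lam_max, xtol=1e-12, rtol=1e-14)
        total += patches.V0_mm3[i] * (lam_eq**3 - 1.0)
    return total / 1e3
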