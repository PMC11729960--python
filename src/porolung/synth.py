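"""Synthetic ventilation experiments and biaxial pleura datasets.

No public dataset of whole-lung ventilation with lobe-wise surface strain
exists, so every stage of the pipeline is exercised against synthetic
records generated by the forward model itself with known ground truth.
The generator's defaults emulate the study conditions of the cadaveric
donor lung the model is built around: a 2430 mL lung (818 g of tissue,
66% initial porosity) inflated to 2.1 kPa over a 2 s breath, producing an
S-shaped pressure-volume curve with organ-scale added volume and lobe
strains of order 0.1-0.2 with sub-lobar spread.

The default true material set uses the calibrated permeability pattern
(fast middle-right lobe), airway stiffness and pleura scale of the
mid-stiffness calibrated solution, and a stiffening foam exponent chosen
so the compartment model reproduces the physiological S-shaped PV
morphology (see docs/methods.md for why a softening foam cannot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import (
    DEFAULT_PLEURA_BASELINE,
    HyperfoamParams,
    NeoHookeanParams,
    PleuraMaterial,
    ReducedPolynomialParams,
    equibiaxial_nominal_stress,
)
from .forward import (
    LungGeometry,
    MaterialSet,
    PressureRamp,
    SimulationConfig,
    build_lobes,
    extract_strain_stats,
    sample_pv,
    simulate_inflation,
)
from .metrics import ExperimentRecord, N_PV_POINTS

__all__ = [
    "NoiseSpec",
    "BiaxialGeneratorSpec",
    "PLEURA_BASELINE",
    "default_geometry",
    "default_true_materials",
    "make_ramp",
    "make_experiment",
    "make_biaxial",
]

#: Baseline reduced-polynomial pleura coefficients; see
#: :data:`porolung.constitutive.DEFAULT_PLEURA_BASELINE`.
PLEURA_BASELINE = DEFAULT_PLEURA_BASELINE

PLEURA_THICKNESS_MM = 0.06


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic experiments.

    Volume noise is relative (transducer-style), strain-statistic noise is
    absolute (DIC-floor-style); both Gaussian and independent.
    """

    pv_rel_sd: float = 0.02
    strain_abs_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pv_rel_sd < 0 or self.strain_abs_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")


def default_geometry() -> LungGeometry:
    """The donor lung's bookkeeping scalars (2430 mL, 818 g, 1.0 g/cm^3)."""
    return LungGeometry(V_total_mL=2430.0)


def default_true_materials() -> MaterialSet:
    """Ground-truth material set for the default synthetic lung."""
    return MaterialSet(
        parenchyma=HyperfoamParams(mu_kPa=3.0, alpha=9.5, nu=0.3),
        permeabilities_1e3_mm2_s=(3.4, 7.3, 3.5, 10.0, 5.7),
        airways=NeoHookeanParams(C10_kPa=0.4),
        pleura=PleuraMaterial(PLEURA_BASELINE, scale_lambda=1.3e-2),
    )


def make_ramp(
    p_max_kPa: float = 2.1,
    duration_s: float = 2.0,
    shape: str = "linear",
    n_steps: int = 200,
) -> PressureRamp:
    """Monotone tracheal pressure ramp from 0 to p_max.

    ``linear`` rises at constant rate; ``smoothstep`` follows
    p_max * (3 s^2 - 2 s^3) with s = t/duration (zero rate at both ends).
    The default peak and duration are the donor protocol (2.1 kPa over the
    2 s inflation of a 15 breaths/min cycle).
    """
    if p_max_kPa <= 0:
        raise ValueError("peak pressure must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    t = np.linspace(0.0, duration_s, n_steps + 1)
    s = t / duration_s
    if shape == "linear":
        p = p_max_kPa * s
    elif shape == "smoothstep":
        p = p_max_kPa * (3.0 * s**2 - 2.0 * s**3)
    else:
        raise ValueError(f"unknown ramp shape {shape!r}")
    return PressureRamp(times_s=t, pressures_kPa=p)


def make_experiment(
    mats: MaterialSet | None = None,
    geom: LungGeometry | None = None,
    ramp: PressureRamp | None = None,
    noise: NoiseSpec = NoiseSpec(),
    n_patches: int = 20,
    sim_config: SimulationConfig | None = None,
) -> ExperimentRecord:
    """Generate a synthetic ventilation experiment with known ground truth.

    Runs the forward model, samples the 20 PV pairs and 30 strain
    statistics, and perturbs them with Gaussian noise per ``noise``.  The
    first PV volume is forced back to zero (the zeroed-origin convention)
    and noisy strain stds are clipped at zero.  Provenance records the
    seed, ground truth and simulation settings; regenerating with the same
    spec is bit-identical.
    """
    from .calibrate import materials_to_theta  # local import to avoid cycle

    mats = mats or default_true_materials()
    geom = geom or default_geometry()
    ramp = ramp or make_ramp()
    # Tight integrator tolerances: calibration differentiates the record's
    # regenerated simulation by finite differences, so integrator noise
    # must sit well below the weakest parameter sensitivities.
    cfg = sim_config or SimulationConfig(n_steps=100, rtol=1e-9, atol_mm3=1e-9)
    patches = build_lobes(geom, mats, n_patches=n_patches, seed=noise.seed)
    result = simulate_inflation(patches, mats, ramp, cfg)
    pv = sample_pv(result, N_PV_POINTS)
    stats = extract_strain_stats(result, ramp)

    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 911]))
    v = pv["V_added_mL"].to_numpy().copy()
    v *= 1.0 + noise.pv_rel_sd * rng.standard_normal(v.size)
    v[0] = 0.0
    pv = pv.assign(V_added_mL=v)
    means = stats.means + noise.strain_abs_sd * rng.standard_normal(stats.means.shape)
    stds = stats.stds + noise.strain_abs_sd * rng.standard_normal(stats.stds.shape)
    stds = np.clip(stds, 0.0, None)
    noisy_stats = type(stats)(means=means, stds=stds)

    provenance = {
        "kind": "synthetic",
        "seed": int(noise.seed),
        "theta_true": [float(x) for x in materials_to_theta(mats)],
        "airway_fraction": mats.airway_fraction,
        "heterogeneity_sigma": mats.heterogeneity_sigma,
        "pleura_baseline_kPa": list(mats.pleura.baseline.coefficients_kPa),
        "pleura_thickness_mm": mats.pleura.thickness0_mm,
        "n_patches": int(n_patches),
        "sim_config": {
            "n_steps": cfg.n_steps,
            "rtol": cfg.rtol,
            "atol_mm3": cfg.atol_mm3,
            "method": cfg.method,
            "flow_gain": cfg.flow_gain,
            "p_ref_kPa": cfg.p_ref_kPa,
            "forchheimer_beta": cfg.forchheimer_beta,
        },
        "noise": {
            "pv_rel_sd": noise.pv_rel_sd,
            "strain_abs_sd": noise.strain_abs_sd,
        },
    }
    return ExperimentRecord(
        pv=pv, strain_stats=noisy_stats, geometry=geom, ramp=ramp,
        provenance=provenance,
    )


@dataclass(frozen=True)
class BiaxialGeneratorSpec:
    """Generator settings for synthetic pleura biaxial test campaigns.

    Emulates a multi-donor campaign: each donor carries a lognormal
    stiffness multiplier (median 1) applied to the baseline coefficients,
    and each 1 cm x 1 cm sample contributes one noisy stress-strain curve.
    Defaults mirror the 9-donor, 12-samples-per-donor protocol (108
    curves).
    """

    baseline: ReducedPolynomialParams = PLEURA_BASELINE
    n_donors: int = 9
    samples_per_donor: int = 12
    donor_sigma: float = 0.5
    noise_sd_kPa: float = 0.05
    strain_max: float = 0.6
    n_points: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1 or self.samples_per_donor < 1:
            raise ValueError("donor and sample counts must be >= 1")
        if self.donor_sigma < 0 or self.noise_sd_kPa < 0:
            raise ValueError("spread parameters must be nonnegative")


def make_biaxial(spec: BiaxialGeneratorSpec = BiaxialGeneratorSpec()):
    """Synthetic equibiaxial pleura dataset.

    Returns ``(frame, truth)``: a DataFrame with columns sample_id,
    nominal_strain, nominal_stress_kPa, and a dict holding the baseline
    coefficients, per-donor multipliers and seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 37]))
    multipliers = np.exp(spec.donor_sigma * rng.standard_normal(spec.n_donors))
    eps = np.linspace(0.0, spec.strain_max, spec.n_points)
    frames = []
    sid = 0
    for d in range(spec.n_donors):
        scaled = ReducedPolynomialParams(
            tuple(multipliers[d] * c for c in spec.baseline.coefficients_kPa)
        )
        clean = equibiaxial_nominal_stress(scaled, 1.0 + eps)
        for _ in range(spec.samples_per_donor):
            stress = clean + spec.noise_sd_kPa * rng.standard_normal(eps.size)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "nominal_strain": eps,
                        "nominal_stress_kPa": stress,
                    }
                )
            )
            sid += 1
    truth = {
        "baseline_kPa": list(spec.baseline.coefficients_kPa),
        "donor_multipliers": multipliers.tolist(),
        "seed": spec.seed,
    }
    return pd.concat(frames, ignore_index=True), truth
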