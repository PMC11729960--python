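"""Hyperelastic constitutive laws for the three lung constituents.

The parenchyma is a compressible Ogden-type foam (``hyperfoam``) written in
principal stretches, the embedded airways are an incompressible Neo-Hookean
solid, and the visceral pleura is an incompressible reduced-polynomial
membrane whose baseline coefficients come from equibiaxial stress-strain
tests and are rescaled by a single dimensionless multiplier ``lambda``.

All stresses are in kPa, lengths in mm, and stretches dimensionless.
Energies are energy densities (kPa = mJ/cm^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "HyperfoamParams",
    "NeoHookeanParams",
    "ReducedPolynomialParams",
    "PleuraMaterial",
    "PrincipalStretches",
    "ConvexityReport",
    "DEFAULT_PLEURA_BASELINE",
    "poisson_to_beta",
    "hyperfoam_energy",
    "hyperfoam_principal_cauchy_stress",
    "scale_reduced_polynomial",
    "initial_shear_modulus",
    "equibiaxial_nominal_stress",
    "reduced_polynomial_energy",
    "fit_reduced_polynomial",
    "check_convexity",
]

# Below this |beta| the volumetric term switches to its analytic nu -> 0 limit.
_BETA_SWITCH = 1e-10


def poisson_to_beta(nu: float) -> float:
    """Volumetric coupling exponent beta = nu / (1 - 2 nu).

    Defined for 0 <= nu < 0.5; diverges at the incompressible limit.
    """
    if not 0.0 <= nu < 0.5:
        raise ValueError(f"Poisson's ratio must satisfy 0 <= nu < 0.5, got {nu}")
    return nu / (1.0 - 2.0 * nu)


@dataclass(frozen=True)
class HyperfoamParams:
    """One-term compressible foam parameters (parenchyma).

    mu_kPa
        Initial shear modulus.
    alpha
        Dimensionless stretch exponent; alpha -> 0 degenerates the law.
    nu
        Poisson's ratio, 0 <= nu < 0.5.  nu = 0 is a fully compressible
        skeleton (no lateral coupling), the physiological choice for
        air-filled parenchyma.
    """

    mu_kPa: float
    alpha: float
    nu: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_kPa <= 0:
            raise ValueError(f"mu must be positive, got {self.mu_kPa}")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        poisson_to_beta(self.nu)  # validates range

    @property
    def beta(self) -> float:
        return poisson_to_beta(self.nu)


@dataclass(frozen=True)
class NeoHookeanParams:
    """Neo-Hookean parameters (airway surrogate).

    D_per_kPa = 0 means the material is treated as analytically
    incompressible: responses are only ever evaluated on isochoric paths
    and no volumetric penalty term is computed.
    """

    C10_kPa: float
    D_per_kPa: float = 0.0

    def __post_init__(self) -> None:
        if self.C10_kPa <= 0:
            raise ValueError(f"C10 must be positive, got {self.C10_kPa}")
        if self.D_per_kPa < 0:
            raise ValueError(f"D must be nonnegative, got {self.D_per_kPa}")


@dataclass(frozen=True)
class ReducedPolynomialParams:
    """Reduced-polynomial energy U = sum_i C_i0 (I1bar - 3)^i, i = 1..n."""

    coefficients_kPa: tuple[float, ...]

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients_kPa)
        object.__setattr__(self, "coefficients_kPa", coeffs)
        if len(coeffs) < 1:
            raise ValueError("at least one coefficient is required")
        if coeffs[0] <= 0:
            raise ValueError("C10 (first coefficient) must be positive")

    @property
    def order(self) -> int:
        return len(self.coefficients_kPa)


#: Pooled-fit baseline pleura coefficients (kPa): 2*C10 = 2.4 kPa initial
#: shear modulus, with second-order stiffening that renders the membrane
#: nearly inextensible beyond ~40% strain (the bilinear biaxial shape).
DEFAULT_PLEURA_BASELINE = ReducedPolynomialParams((1.2, 6.0))


@dataclass(frozen=True)
class PleuraMaterial:
    """Pleura membrane: baseline reduced polynomial times a scale factor.

    The effective coefficients are C_i0* = scale_lambda * C_i0; the scale
    adapts the pooled-donor baseline fit to an individual lung while
    preserving the bilinear shape of the stress-strain response.
    """

    baseline: ReducedPolynomialParams
    scale_lambda: float = 1.0
    thickness0_mm: float = 0.06

    def __post_init__(self) -> None:
        if not 1e-6 <= self.scale_lambda <= 3.0:
            raise ValueError(
                f"scale_lambda must lie in [1e-6, 3], got {self.scale_lambda}"
            )
        if self.thickness0_mm <= 0:
            raise ValueError("thickness0 must be positive")


@dataclass(frozen=True)
class PrincipalStretches:
    """A principal-stretch state (lam1, lam2, lam3); J = lam1*lam2*lam3."""

    lam1: float
    lam2: float
    lam3: float

    def __post_init__(self) -> None:
        if min(self.lam1, self.lam2, self.lam3) <= 0:
            raise ValueError("principal stretches must be positive")

    @property
    def J(self) -> float:
        return self.lam1 * self.lam2 * self.lam3

    def as_array(self) -> np.ndarray:
        return np.array([self.lam1, self.lam2, self.lam3])


def hyperfoam_energy(p: HyperfoamParams, s: PrincipalStretches) -> float:
    """Foam strain-energy density (kPa).

    U = (2 mu / alpha^2) [lam1^a + lam2^a + lam3^a - 3
                          + (1/beta)(J^(-a beta) - 1)]

    with the analytic limit (1/beta)(J^(-a b) - 1) -> -alpha ln J as
    beta -> 0, used below |beta| < 1e-10 so that nu = 0 (a bound of the
    calibration box) never divides by zero.
    """
    lam = s.as_array()
    a = p.alpha
    beta = p.beta
    J = s.J
    dev = np.sum(lam**a) - 3.0
    if abs(beta) < _BETA_SWITCH:
        vol = -a * math.log(J)
    else:
        # expm1 keeps the volumetric term accurate as beta -> 0
        vol = math.expm1(-a * beta * math.log(J)) / beta
    return 2.0 * p.mu_kPa / a**2 * (dev + vol)


def hyperfoam_principal_cauchy_stress(
    p: HyperfoamParams, s: PrincipalStretches
) -> np.ndarray:
    """Principal Cauchy stresses sigma_i = (lam_i / J) dU/dlam_i (kPa).

    Closed form sigma_i = (2 mu / (alpha J)) (lam_i^alpha - J^(-alpha beta));
    continuous across beta = 0 because J^0 = 1.
    """
    lam = s.as_array()
    a = p.alpha
    J = s.J
    return 2.0 * p.mu_kPa / (a * J) * (lam**a - J ** (-a * p.beta))


def scale_reduced_polynomial(m: PleuraMaterial) -> ReducedPolynomialParams:
    """Effective pleura coefficients C_i0* = scale_lambda * C_i0."""
    return ReducedPolynomialParams(
        tuple(m.scale_lambda * c for c in m.baseline.coefficients_kPa)
    )


def initial_shear_modulus(material) -> float:
    """Small-strain shear modulus of any of the three laws (kPa).

    Hyperfoam -> mu; Neo-Hookean and reduced polynomial -> 2*C10.
    """
    if isinstance(material, HyperfoamParams):
        return material.mu_kPa
    if isinstance(material, NeoHookeanParams):
        return 2.0 * material.C10_kPa
    if isinstance(material, ReducedPolynomialParams):
        return 2.0 * material.coefficients_kPa[0]
    if isinstance(material, PleuraMaterial):
        return 2.0 * scale_reduced_polynomial(material).coefficients_kPa[0]
    raise TypeError(f"unsupported material type: {type(material).__name__}")


def _equibiaxial_i1bar(lam):
    return 2.0 * lam**2 + lam**-4


def reduced_polynomial_energy(rp: ReducedPolynomialParams, i1bar):
    """U_RP = sum_i C_i0 (I1bar - 3)^i, vectorized over I1bar."""
    x = np.asarray(i1bar, dtype=float) - 3.0
    u = np.zeros_like(x)
    for i, c in enumerate(rp.coefficients_kPa, start=1):
        u += c * x**i
    return u if u.ndim else float(u)


def equibiaxial_nominal_stress(rp: ReducedPolynomialParams, lam):
    """Equibiaxial nominal (first Piola) stress of an incompressible sheet.

    Kinematics lam1 = lam2 = lam, lam3 = lam^-2, so
    I1bar = 2 lam^2 + lam^-4 and

        P(lam) = 2 (lam - lam^-5) sum_i i C_i0 (I1bar - 3)^(i-1)  [kPa].

    Vectorized over lam.  For a single coefficient this is the familiar
    Neo-Hookean 2 C10 (lam - lam^-5).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    x = _equibiaxial_i1bar(lam) - 3.0
    dudi1 = np.zeros_like(x)
    for i, c in enumerate(rp.coefficients_kPa, start=1):
        dudi1 += i * c * x ** (i - 1)
    out = 2.0 * (lam - lam**-5) * dudi1
    return out if out.ndim else float(out)


def fit_reduced_polynomial(
    curves: Sequence[tuple[np.ndarray, np.ndarray]], order: int = 2
) -> ReducedPolynomialParams:
    """Least-squares fit of reduced-polynomial coefficients to biaxial data.

    Parameters
    ----------
    curves
        Sequence of (nominal_strain, nominal_stress_kPa) pairs of 1-d
        arrays, one per tested sample.  All points are pooled: the pooled
        least-squares target coincides with fitting the averaged curve for
        balanced sampling and is robust to unequal curve lengths.
    order
        Number of coefficients n >= 1.

    The model is linear in the coefficients, so the fit is a deterministic
    linear least-squares solve.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    eps = np.concatenate([np.asarray(c[0], dtype=float) for c in curves])
    sig = np.concatenate([np.asarray(c[1], dtype=float) for c in curves])
    if eps.size != sig.size:
        raise ValueError("strain and stress arrays must have equal length")
    if np.any(eps < 0):
        raise ValueError("nominal strains must be nonnegative")
    if not np.all(np.isfinite(sig)):
        raise ValueError("stresses must be finite")
    if eps.size < order:
        raise ValueError(
            f"{eps.size} points cannot determine {order} coefficients"
        )
    lam = 1.0 + eps
    x = _equibiaxial_i1bar(lam) - 3.0
    kin = 2.0 * (lam - lam**-5)
    design = np.stack(
        [kin * i * x ** (i - 1) for i in range(1, order + 1)], axis=1
    )
    coeffs, *_ = np.linalg.lstsq(design, sig, rcond=None)
    return ReducedPolynomialParams(tuple(coeffs))


@dataclass(frozen=True)
class ConvexityReport:
    convex: bool
    min_eigenvalue: float
    worst_point: tuple[float, float]  # (lam1, lam2)
    tolerance: float


def check_convexity(
    rp: ReducedPolynomialParams,
    lam_range: tuple[float, float] = (0.7, 2.0),
    n_grid: int = 50,
) -> ConvexityReport:
    """Numerical convexity check of U_RP in Green-Lagrange strain.

    Evaluates the 2x2 Hessian of the incompressible membrane energy with
    respect to the in-plane Green-Lagrange components (E1, E2), with
    lam3 = 1/(lam1 lam2), by central finite differences over an
    ``n_grid x n_grid`` biaxial stretch grid.  The material passes iff the
    smallest eigenvalue is >= -tol everywhere, tol = 1e-9 * max |Hessian|.
    """
    lo, hi = lam_range
    if not (0.5 <= lo < hi <= 3.0):
        raise ValueError("lam_range must be non-degenerate and within [0.5, 3]")
    if n_grid < 2:
        raise ValueError("grid must contain at least 2 points per axis")

    def energy(e1, e2):
        l1sq = 1.0 + 2.0 * e1
        l2sq = 1.0 + 2.0 * e2
        i1 = l1sq + l2sq + 1.0 / (l1sq * l2sq)
        return reduced_polynomial_energy(rp, i1)

    lams = np.linspace(lo, hi, n_grid)
    e_grid = 0.5 * (lams**2 - 1.0)
    h = 1e-5
    worst_eig = np.inf
    worst_pt = (lams[0], lams[0])
    hess_max = 0.0
    for e1 in e_grid:
        for e2 in e_grid:
            u11 = (energy(e1 + h, e2) - 2 * energy(e1, e2) + energy(e1 - h, e2)) / h**2
            u22 = (energy(e1, e2 + h) - 2 * energy(e1, e2) + energy(e1, e2 - h)) / h**2
            u12 = (
                energy(e1 + h, e2 + h)
                - energy(e1 + h, e2 - h)
                - energy(e1 - h, e2 + h)
                + energy(e1 - h, e2 - h)
            ) / (4 * h**2)
            hess = np.array([[u11, u12], [u12, u22]])
            hess_max = max(hess_max, np.abs(hess).max())
            eig = np.linalg.eigvalsh(hess)[0]
            if eig < worst_eig:
                worst_eig = eig
                worst_pt = (
                    float(math.sqrt(1.0 + 2.0 * e1)),
                    float(math.sqrt(1.0 + 2.0 * e2)),
                )
    tol = 1e-9 * hess_max
    return ConvexityReport(
        convex=bool(worst_eig >= -tol),
        min_eigenvalue=float(worst_eig),
        worst_point=worst_pt,
        tolerance=float(tol),
    )
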