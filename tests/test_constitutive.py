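"""Constitutive laws: energies, stresses, fitting and convexity."""

import math

import numpy as np
import pytest

from porolung.constitutive import (
    DEFAULT_PLEURA_BASELINE,
    ConvexityReport,
    HyperfoamParams,
    NeoHookeanParams,
    PleuraMaterial,
    PrincipalStretches,
    ReducedPolynomialParams,
    check_convexity,
    equibiaxial_nominal_stress,
    fit_reduced_polynomial,
    hyperfoam_energy,
    hyperfoam_principal_cauchy_stress,
    initial_shear_modulus,
    poisson_to_beta,
    reduced_polynomial_energy,
    scale_reduced_polynomial,
)
from porolung.synth import BiaxialGeneratorSpec, make_biaxial


def random_states(n, seed=0):
    """Random admissible (params, stretches) pairs for oracle sweeps."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        p = HyperfoamParams(
            mu_kPa=10 ** rng.uniform(-1, 1.5),
            alpha=rng.uniform(0.5, 9.5),
            nu=rng.uniform(0.0, 0.45),
        )
        s = PrincipalStretches(*np.exp(rng.uniform(-0.4, 0.6, size=3)))
        out.append((p, s))
    return out


class TestPoissonToBeta:
    @pytest.mark.parametrize("nu,expected", [(0.0, 0.0), (0.25, 0.5), (0.4, 2.0)])
    def test_values(self, nu, expected):
        assert poisson_to_beta(nu) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("nu", [-0.01, 0.5, 0.7])
    def test_domain(self, nu):
        with pytest.raises(ValueError):
            poisson_to_beta(nu)


class TestHyperfoamEnergy:
    def test_zero_at_identity(self):
        for p, _ in random_states(10, seed=1):
            assert hyperfoam_energy(p, PrincipalStretches(1, 1, 1)) == 0.0

    def test_frozen_high_precision_value(self):
        # U(mu=1, alpha=2, nu=0.3, lam=(1.2,1,1)) = -67/150 + 5*sqrt(30)/54,
        # an exact closed form evaluated to machine precision.
        p = HyperfoamParams(1.0, 2.0, 0.3)
        s = PrincipalStretches(1.2, 1.0, 1.0)
        assert hyperfoam_energy(p, s) == pytest.approx(
            0.06048384954182048, rel=1e-14
        )

    def test_linear_in_mu(self):
        s = PrincipalStretches(1.3, 0.9, 1.1)
        u1 = hyperfoam_energy(HyperfoamParams(1.0, 3.0, 0.2), s)
        u2 = hyperfoam_energy(HyperfoamParams(2.0, 3.0, 0.2), s)
        assert u2 == pytest.approx(2.0 * u1, rel=1e-14)

    def test_beta_limit_continuity(self):
        # The nu -> 0 analytic-limit branch must join the generic branch.
        for _, s in random_states(20, seed=2):
            u0 = hyperfoam_energy(HyperfoamParams(2.8, 3e-3, 0.0), s)
            u_eps = hyperfoam_energy(HyperfoamParams(2.8, 3e-3, 1e-8), s)
            assert abs(u_eps - u0) < 1e-6 * (1.0 + abs(u0))

    def test_hessian_positive_definite_at_identity(self):
        # Material stability of the reference state for admissible params.
        h = 1e-4
        for p in (
            HyperfoamParams(1.0, 2.0, 0.0),
            HyperfoamParams(2.8, 3e-3, 0.3),
            HyperfoamParams(50.0, 8.0, 0.45),
        ):
            def u(lams):
                return hyperfoam_energy(p, PrincipalStretches(*lams))

            H = np.empty((3, 3))
            e = np.eye(3)
            x0 = np.ones(3)
            for i in range(3):
                for j in range(3):
                    H[i, j] = (
                        u(x0 + h * e[i] + h * e[j])
                        - u(x0 + h * e[i] - h * e[j])
                        - u(x0 - h * e[i] + h * e[j])
                        + u(x0 - h * e[i] - h * e[j])
                    ) / (4 * h * h)
            assert np.all(np.linalg.eigvalsh(H) > 0)


class TestHyperfoamStress:
    def test_zero_at_identity(self):
        p = HyperfoamParams(2.8, 3e-3, 0.0)
        np.testing.assert_allclose(
            hyperfoam_principal_cauchy_stress(p, PrincipalStretches(1, 1, 1)),
            0.0,
            atol=1e-15,
        )

    def test_matches_energy_differentiation(self):
        # sigma_i = (lam_i / J) dU/dlam_i against central differences of
        # the energy: the closed form must agree to 1e-6 relative on 100
        # random admissible states.
        h = 1e-6
        for p, s in random_states(100, seed=42):
            lams = s.as_array()
            sigma = hyperfoam_principal_cauchy_stress(p, s)
            for i in range(3):
                lp, lm = lams.copy(), lams.copy()
                lp[i] += h
                lm[i] -= h
                dU = (
                    hyperfoam_energy(p, PrincipalStretches(*lp))
                    - hyperfoam_energy(p, PrincipalStretches(*lm))
                ) / (2 * h)
                expected = lams[i] / s.J * dU
                assert sigma[i] == pytest.approx(expected, rel=1e-6, abs=1e-10)

    def test_equal_stretches_give_equal_stresses(self):
        p = HyperfoamParams(2.8, 3e-3, 0.0)
        sigma = hyperfoam_principal_cauchy_stress(p, PrincipalStretches(1.3, 1.3, 1.3))
        assert sigma[0] == sigma[1] == sigma[2]

    def test_small_strain_shear_modulus(self):
        # Simple shear of magnitude g has principal stretches ~ 1 +- g/2;
        # the apparent modulus (sig1 - sig2)/(2 g) must approach mu.
        p = HyperfoamParams(2.8, 3e-3, 0.0)
        g = 1e-4
        s = PrincipalStretches(1 + g / 2, 1 - g / 2, 1.0)
        sigma = hyperfoam_principal_cauchy_stress(p, s)
        mu_app = (sigma[0] - sigma[1]) / (2 * g)
        assert mu_app == pytest.approx(p.mu_kPa, rel=0.01)


class TestShearModulusConversions:
    def test_pleura_scaling_identity(self):
        m = PleuraMaterial(DEFAULT_PLEURA_BASELINE, scale_lambda=1.0)
        assert (
            scale_reduced_polynomial(m).coefficients_kPa
            == DEFAULT_PLEURA_BASELINE.coefficients_kPa
        )

    @pytest.mark.parametrize(
        "lam,expected_Pa",
        [(0.7e-3, 1.68), (1.3e-2, 31.2)],
    )
    def test_scaled_pleura_modulus(self, lam, expected_Pa):
        # 2 * lambda * C10 with the 2.4 kPa baseline: 1.68 Pa (prints as
        # 1.7 at two significant figures) and 31.2 Pa (prints as 31).
        m = PleuraMaterial(DEFAULT_PLEURA_BASELINE, scale_lambda=lam)
        mu_Pa = 1e3 * initial_shear_modulus(m)
        assert mu_Pa == pytest.approx(expected_Pa, rel=1e-12)

    @pytest.mark.parametrize(
        "material,expected",
        [
            (NeoHookeanParams(0.1), 0.2),
            (NeoHookeanParams(0.4), 0.8),
            (NeoHookeanParams(1.1), 2.2),
            (HyperfoamParams(2.8, 3e-3, 0.0), 2.8),
            (ReducedPolynomialParams((1.2, 6.0)), 2.4),
        ],
    )
    def test_initial_shear_modulus(self, material, expected):
        assert initial_shear_modulus(material) == pytest.approx(expected, rel=1e-14)


class TestEquibiaxialStress:
    def test_zero_at_reference(self):
        assert equibiaxial_nominal_stress(DEFAULT_PLEURA_BASELINE, 1.0) == 0.0

    def test_neo_hookean_closed_form(self):
        rp = ReducedPolynomialParams((0.1,))
        lam = 1.2
        assert equibiaxial_nominal_stress(rp, lam) == pytest.approx(
            0.2 * (lam - lam**-5), rel=1e-14
        )

    def test_linear_in_coefficients(self):
        lams = np.linspace(1.0, 1.6, 7)
        p1 = equibiaxial_nominal_stress(ReducedPolynomialParams((1.2, 6.0)), lams)
        p2 = equibiaxial_nominal_stress(ReducedPolynomialParams((2.4, 12.0)), lams)
        np.testing.assert_allclose(p2, 2 * p1, rtol=1e-14)

    def test_energy_path_derivative_oracle(self):
        # P(lam) = (1/2) d/dlam U_RP along the incompressible equibiaxial
        # path (two in-plane directions work in parallel).
        rp = ReducedPolynomialParams((1.2, 6.0, -0.5))
        h = 1e-6

        def u(lam):
            return reduced_polynomial_energy(rp, 2 * lam**2 + lam**-4)

        for lam in np.linspace(1.05, 1.8, 12):
            oracle = 0.5 * (u(lam + h) - u(lam - h)) / (2 * h)
            assert equibiaxial_nominal_stress(rp, lam) == pytest.approx(
                oracle, rel=1e-6
            )

    def test_domain(self):
        with pytest.raises(ValueError):
            equibiaxial_nominal_stress(DEFAULT_PLEURA_BASELINE, -0.5)


class TestFitReducedPolynomial:
    def test_noiseless_round_trip(self):
        truth = ReducedPolynomialParams((1.2, 6.0))
        eps = np.linspace(0, 0.6, 30)
        stress = equibiaxial_nominal_stress(truth, 1 + eps)
        fitted = fit_reduced_polynomial([(eps, stress)], order=2)
        np.testing.assert_allclose(
            fitted.coefficients_kPa, truth.coefficients_kPa, rtol=1e-10
        )

    def test_neo_hookean_recovery(self):
        eps = np.linspace(0, 0.4, 15)
        stress = equibiaxial_nominal_stress(ReducedPolynomialParams((0.1,)), 1 + eps)
        fitted = fit_reduced_polynomial([(eps, stress)], order=1)
        assert fitted.coefficients_kPa[0] == pytest.approx(0.1, rel=1e-8)

    def test_projection_property(self):
        # Refitting the fit's own predictions returns the same coefficients.
        rng = np.random.default_rng(5)
        eps = np.linspace(0, 0.5, 20)
        noisy = [
            (eps, equibiaxial_nominal_stress(ReducedPolynomialParams((1.0, 4.0)), 1 + eps)
             + 0.1 * rng.standard_normal(eps.size))
            for _ in range(3)
        ]
        first = fit_reduced_polynomial(noisy, order=2)
        pred = equibiaxial_nominal_stress(first, 1 + eps)
        second = fit_reduced_polynomial([(eps, pred)], order=2)
        np.testing.assert_allclose(
            second.coefficients_kPa, first.coefficients_kPa, rtol=1e-9
        )

    def test_synthetic_donor_spread(self):
        # Pooled fit of the multi-donor campaign lands within the spread
        # of the generated donor stiffnesses.
        frame, truth = make_biaxial(BiaxialGeneratorSpec(noise_sd_kPa=0.0, seed=9))
        curves = [
            (g["nominal_strain"].to_numpy(), g["nominal_stress_kPa"].to_numpy())
            for _, g in frame.groupby("sample_id")
        ]
        fitted = fit_reduced_polynomial(curves, order=2)
        mults = np.array(truth["donor_multipliers"])
        c10_base = truth["baseline_kPa"][0]
        assert mults.min() * c10_base <= fitted.coefficients_kPa[0] <= mults.max() * c10_base

    def test_ill_posed(self):
        with pytest.raises(ValueError):
            fit_reduced_polynomial([(np.array([0.1]), np.array([0.2]))], order=3)


class TestConvexity:
    def test_neo_hookean_convex(self):
        report = check_convexity(ReducedPolynomialParams((0.1,)))
        assert isinstance(report, ConvexityReport)
        assert report.convex

    def test_negative_second_order_flagged(self):
        report = check_convexity(ReducedPolynomialParams((0.01, -10.0)))
        assert not report.convex
        assert report.min_eigenvalue < 0

    def test_verdict_scale_invariant(self):
        for coeffs in ((0.1,), (0.01, -10.0), (1.2, 6.0)):
            a = check_convexity(ReducedPolynomialParams(coeffs), n_grid=15)
            scaled = tuple(7.3 * c for c in coeffs)
            b = check_convexity(ReducedPolynomialParams(scaled), n_grid=15)
            assert a.convex == b.convex

    @pytest.mark.parametrize(
        "kwargs", [{"lam_range": (0.4, 2.0)}, {"lam_range": (1.2, 1.2)}, {"n_grid": 1}]
    )
    def test_degenerate_grid(self, kwargs):
        with pytest.raises(ValueError):
            check_convexity(DEFAULT_PLEURA_BASELINE, **kwargs)


class TestTypeInvariants:
    def test_rejects_incompressible_foam(self):
        with pytest.raises(ValueError):
            HyperfoamParams(1.0, 2.0, 0.5)

    def test_rejects_zero_alpha(self):
        with pytest.raises(ValueError):
            HyperfoamParams(1.0, 0.0, 0.1)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(ValueError):
            PrincipalStretches(1.0, -0.2, 1.0)

    def test_rejects_out_of_range_pleura_scale(self):
        with pytest.raises(ValueError):
            PleuraMaterial(DEFAULT_PLEURA_BASELINE, scale_lambda=5.0)
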