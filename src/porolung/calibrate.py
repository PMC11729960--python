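"""Inverse calibration of the nine lung material parameters.

The parameter vector, in fixed order, is

    (mu, alpha, nu, k_UL, k_LL, k_UR, k_MR, k_LR, C10, lambda)
     ---------------  --------------------------  ----  ------
       parenchyma        lobe permeabilities      airways pleura

nine free values (permeabilities in their conventional 1e-3 mm^2/s
scaling so every component is O(0.1-100), which conditions the forward
differences).  Calibration is bounded nonlinear least squares on the
50-component normalized residual, run from several starting points
(MultiStart), with an explicit protocol wrapper that checks five
termination criteria in a fixed order after every iteration:

1. function tolerance   |phi_i - phi_{i+1}| < 1e-6 (1 + |phi_i|)
2. evaluation budget    nfev > 100 * n_params
3. iteration budget     nit > 400
4. first-order optimality  max_i |v_i g_i| < 1e-6, where v_i = x_i - b_i
   when the negative gradient points toward bound b_i and 1 otherwise
5. step tolerance       |x_i - x_{i+1}|_inf < 5e-4

The underlying engine is scipy's trust-region-reflective least-squares
solver; its native tolerances are disabled so the protocol wrapper owns
termination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constitutive import (
    DEFAULT_PLEURA_BASELINE,
    HyperfoamParams,
    NeoHookeanParams,
    PleuraMaterial,
    ReducedPolynomialParams,
)
from .forward import (
    LOBES,
    MaterialSet,
    SimulationConfig,
    build_lobes,
    extract_strain_stats,
    sample_pv,
    simulate_inflation,
)
from .metrics import (
    N_PV_POINTS,
    ErrorBreakdown,
    ExperimentRecord,
    error_breakdown,
    residual_vector,
)

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "DEFAULT_STARTS",
    "TerminationCriteria",
    "ProtocolResult",
    "CalibrationEntry",
    "CalibrationOutcome",
    "theta_to_materials",
    "materials_to_theta",
    "objective",
    "least_squares_with_protocol",
    "minimize_single",
    "multistart",
    "rank_minima",
    "sensitivity_sweep",
]

PARAM_NAMES = (
    "mu_kPa",
    "alpha",
    "nu",
    "k_UL",
    "k_LL",
    "k_UR",
    "k_MR",
    "k_LR",
    "C10_kPa",
    "lambda_pleura",
)
N_PARAMS = len(PARAM_NAMES)  # 10 decision-vector components
#: Evaluation-budget parameter count.  The budget convention counts nine
#: calibrated material quantities (mu, alpha, nu, permeability, C10,
#: lambda, with permeability lobe-resolved into five vector components),
#: so the default cap is 100 * 9 = 900 evaluations per start.
N_BUDGET_PARAMS = 9

#: Calibration box, one (lower, upper) pair per parameter.
DEFAULT_BOUNDS = (
    (0.1, 100.0),  # mu (kPa)
    (1e-6, 10.0),  # alpha
    (0.0, 0.5),  # nu
    (0.1, 100.0),  # k_UL (1e-3 mm^2/s)
    (0.1, 100.0),  # k_LL
    (0.1, 100.0),  # k_UR
    (0.1, 100.0),  # k_MR
    (0.1, 100.0),  # k_LR
    (0.1, 100.0),  # C10 (kPa)
    (1e-6, 3.0),  # lambda (pleura scale)
)

#: The three standard multistart starting points.
DEFAULT_STARTS = (
    (5.0, 1.0, 0.0, 10.0, 10.0, 10.0, 10.0, 10.0, 1.0, 1.0e-2),
    (40.0, 9.6, 0.4, 79.0, 39.0, 69.0, 49.0, 12.0, 7.0, 0.8),
    (8.0, 9.7, 0.3, 65.0, 17.0, 95.0, 64.0, 95.0, 10.0, 0.9),
)

# Termination reasons, in the order the criteria are checked.
REASON_FUNCTION_TOL = "function_tolerance"
REASON_MAX_FEVALS = "max_function_evaluations"
REASON_MAX_ITERS = "max_iterations"
REASON_OPTIMALITY = "optimality_tolerance"
REASON_STEP_TOL = "step_tolerance"


@dataclass(frozen=True)
class TerminationCriteria:
    """The five stopping thresholds (first satisfied criterion wins)."""

    function_tol: float = 1e-6
    max_fevals: int | None = None  # None -> 100 * n_params
    max_iters: int = 400
    optimality_tol: float = 1e-6
    step_tol: float = 5e-4

    def __post_init__(self) -> None:
        vals = [self.function_tol, self.max_iters, self.optimality_tol, self.step_tol]
        if self.max_fevals is not None:
            vals.append(self.max_fevals)
        if any(v <= 0 for v in vals):
            raise ValueError("all termination thresholds must be positive")

    def feval_cap(self, n_params: int) -> int:
        return self.max_fevals if self.max_fevals is not None else 100 * n_params


def theta_to_materials(
    theta,
    pleura_baseline: ReducedPolynomialParams = DEFAULT_PLEURA_BASELINE,
    pleura_thickness_mm: float = 0.06,
    airway_fraction: float = 0.02,
    heterogeneity_sigma: float = 0.3,
) -> MaterialSet:
    """Assemble a MaterialSet from the 9-parameter vector plus constants."""
    t = np.asarray(theta, dtype=float)
    if t.shape != (N_PARAMS,):
        raise ValueError(f"parameter vector must have length {N_PARAMS}")
    mu, alpha, nu = t[0], t[1], t[2]
    return MaterialSet(
        parenchyma=HyperfoamParams(mu_kPa=mu, alpha=alpha, nu=nu),
        permeabilities_1e3_mm2_s=tuple(t[3:8]),
        airways=NeoHookeanParams(C10_kPa=t[8]),
        pleura=PleuraMaterial(
            baseline=pleura_baseline,
            scale_lambda=t[9],
            thickness0_mm=pleura_thickness_mm,
        ),
        airway_fraction=airway_fraction,
        heterogeneity_sigma=heterogeneity_sigma,
    )


def materials_to_theta(mats: MaterialSet) -> np.ndarray:
    """Inverse of :func:`theta_to_materials` (fixed constants dropped)."""
    return np.array(
        [
            mats.parenchyma.mu_kPa,
            mats.parenchyma.alpha,
            mats.parenchyma.nu,
            *mats.permeabilities_1e3_mm2_s,
            mats.airways.C10_kPa,
            mats.pleura.scale_lambda,
        ]
    )


def _sim_config_from_provenance(prov: dict) -> SimulationConfig:
    sc = prov.get("sim_config")
    if sc is None:
        return SimulationConfig(n_steps=100, rtol=1e-9, atol_mm3=1e-9)
    return SimulationConfig(**sc)


def _forward_summaries(theta, exp: ExperimentRecord, sim_config=None, n_patches=None):
    """Run the forward model at theta under the experiment's conditions."""
    prov = exp.provenance
    mats = theta_to_materials(
        theta,
        pleura_baseline=ReducedPolynomialParams(
            tuple(prov.get("pleura_baseline_kPa", DEFAULT_PLEURA_BASELINE.coefficients_kPa))
        ),
        pleura_thickness_mm=prov.get("pleura_thickness_mm", 0.06),
        airway_fraction=prov.get("airway_fraction", 0.02),
        heterogeneity_sigma=prov.get("heterogeneity_sigma", 0.3),
    )
    cfg = sim_config or _sim_config_from_provenance(prov)
    npatch = n_patches or prov.get("n_patches", 20)
    patches = build_lobes(exp.geometry, mats, n_patches=npatch, seed=prov.get("seed", 0))
    result = simulate_inflation(patches, mats, exp.ramp, cfg)
    pv = sample_pv(result, N_PV_POINTS)
    stats = extract_strain_stats(result, exp.ramp)
    return pv["V_added_mL"].to_numpy(), stats


def objective(
    theta, exp: ExperimentRecord, sim_config=None, n_patches=None
) -> tuple[float, np.ndarray, ErrorBreakdown]:
    """phi, residual vector and error triplet at a parameter vector.

    Deterministic given (theta, experiment): the patch layout is rebuilt
    from the seed recorded in the experiment's provenance, so the model
    and the record share their discretization.
    """
    v_num, stats = _forward_summaries(theta, exp, sim_config, n_patches)
    r = residual_vector(exp, v_num, stats)
    return float(r @ r), r, error_breakdown(exp, v_num, stats)


class _FevalBudget(Exception):
    pass


@dataclass
class ProtocolResult:
    """Outcome of a single protocol-wrapped least-squares run."""

    x: np.ndarray
    phi: float
    reason: str
    n_iters: int
    n_fevals: int
    trace: pd.DataFrame  # per-iteration: nit, phi, step_inf, optimality, params
    penalized_evals: int = 0


def least_squares_with_protocol(
    fun,
    x0,
    bounds=DEFAULT_BOUNDS,
    criteria: TerminationCriteria = TerminationCriteria(),
    n_budget: int | None = None,
) -> ProtocolResult:
    """Bounded least squares with the five-criteria termination protocol.

    ``fun(x) -> residual vector``.  The Jacobian is built by forward
    differences with absolute step 1e-6 * (bound width) per parameter
    (reflected to a backward step at the upper bound); every residual
    evaluation, including differencing, counts toward the evaluation
    budget.
    """
    x0 = np.asarray(x0, dtype=float)
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    if x0.size != lb.size:
        raise ValueError("start and bounds dimensions disagree")
    if np.any(x0 < lb) or np.any(x0 > ub):
        raise ValueError("starting point lies outside the bounds")
    n = x0.size
    cap = criteria.feval_cap(n_budget if n_budget is not None else n)
    h = 1e-6 * (ub - lb)

    state = {
        "nfev": 0,
        "best_phi": np.inf,
        "best_x": x0.copy(),
        "reason": None,
        "prev_phi": None,
        "prev_x": None,
        "nit": 0,
        "jac_x": None,
        "jac": None,
        "last_r": None,
        "rows": [],
    }

    def counted(x):
        if state["nfev"] >= cap:
            raise _FevalBudget
        state["nfev"] += 1
        r = np.atleast_1d(np.asarray(fun(x), dtype=float))
        phi = float(r @ r)
        if phi < state["best_phi"]:
            state["best_phi"] = phi
            state["best_x"] = np.asarray(x, dtype=float).copy()
        state["last_r"] = r
        state["last_x"] = np.asarray(x, dtype=float).copy()
        return r

    def jac(x):
        if state["last_x"] is not None and np.array_equal(state["last_x"], x):
            r0 = state["last_r"]
        else:
            r0 = counted(x)
        J = np.empty((r0.size, n))
        for i in range(n):
            step = h[i] if x[i] + h[i] <= ub[i] else -h[i]
            xp = x.copy()
            xp[i] += step
            J[:, i] = (counted(xp) - r0) / step
        state["jac_x"] = np.asarray(x, dtype=float).copy()
        state["jac"] = J
        return J

    def optimality_measure(x, r):
        if state["jac"] is None:
            return np.inf
        g = 2.0 * state["jac"].T @ r  # gradient of phi = |r|^2
        v = np.ones(n)
        toward_upper = -g > 0
        toward_lower = -g < 0
        v[toward_upper] = x[toward_upper] - ub[toward_upper]
        v[toward_lower] = x[toward_lower] - lb[toward_lower]
        return float(np.max(np.abs(v * g)))

    def check(x_new, phi_new, nit, r_new):
        """The five criteria, in printed order; returns a reason or None."""
        prev_phi, prev_x = state["prev_phi"], state["prev_x"]
        if (
            prev_phi is not None
            and abs(prev_phi - phi_new) < criteria.function_tol * (1.0 + abs(prev_phi))
        ):
            return REASON_FUNCTION_TOL
        if state["nfev"] >= cap:
            return REASON_MAX_FEVALS
        if nit > criteria.max_iters:
            return REASON_MAX_ITERS
        if optimality_measure(x_new, r_new) < criteria.optimality_tol:
            return REASON_OPTIMALITY
        if prev_x is not None and np.max(np.abs(x_new - prev_x)) < criteria.step_tol:
            return REASON_STEP_TOL
        return None

    def callback(intermediate_result):
        res = intermediate_result
        x_new = np.asarray(res.x, dtype=float)
        phi_new = 2.0 * float(res.cost)
        nit = int(res.nit)
        state["nit"] = nit
        step_inf = (
            np.max(np.abs(x_new - state["prev_x"]))
            if state["prev_x"] is not None
            else np.nan
        )
        r_new = np.atleast_1d(np.asarray(res.fun, dtype=float))
        opt = optimality_measure(x_new, r_new)
        state["rows"].append((nit, phi_new, step_inf, opt, *x_new))
        reason = check(x_new, phi_new, nit, r_new)
        state["prev_phi"] = phi_new
        state["prev_x"] = x_new.copy()
        if reason is not None:
            state["reason"] = reason
            raise StopIteration

    state["last_x"] = None
    try:
        res = least_squares(
            counted,
            np.clip(x0, lb, ub),
            jac=jac,
            bounds=(lb, ub),
            method="trf",
            ftol=1e-15,
            xtol=1e-15,
            gtol=1e-15,
            max_nfev=10**9,
            callback=callback,
        )
        x_final = np.asarray(res.x, dtype=float)
        phi_final = 2.0 * float(res.cost)
        reason = state["reason"]
        if reason is None:
            # scipy stopped on its own (exact convergence); re-check the
            # protocol on the final state, else record the solver message.
            r_final = np.atleast_1d(np.asarray(res.fun, dtype=float))
            reason = (
                check(x_final, phi_final, state["nit"], r_final)
                or f"solver:{res.status}"
            )
    except _FevalBudget:
        x_final = state["best_x"]
        phi_final = state["best_phi"]
        reason = REASON_MAX_FEVALS
    if state["best_phi"] < phi_final:
        x_final, phi_final = state["best_x"], state["best_phi"]
    trace = pd.DataFrame(
        state["rows"],
        columns=["nit", "phi", "step_inf", "optimality", *[f"x{i}" for i in range(n)]],
    )
    return ProtocolResult(
        x=np.asarray(x_final, dtype=float),
        phi=float(phi_final),
        reason=reason,
        n_iters=int(state["nit"]),
        n_fevals=int(state["nfev"]),
        trace=trace,
    )


@dataclass
class CalibrationEntry:
    """One local solution of the multistart calibration."""

    start: np.ndarray
    theta: np.ndarray
    phi: float
    breakdown: ErrorBreakdown
    reason: str
    n_iters: int
    n_fevals: int
    trace: pd.DataFrame
    penalized_evals: int


@dataclass
class CalibrationOutcome:
    entries: list
    best_index: int
    total_fevals: int

    @property
    def best(self) -> CalibrationEntry:
        return self.entries[self.best_index]


def minimize_single(
    start,
    exp: ExperimentRecord,
    bounds=DEFAULT_BOUNDS,
    criteria: TerminationCriteria = TerminationCriteria(),
    sim_config=None,
    n_patches=None,
) -> CalibrationEntry:
    """Protocol-wrapped bounded least squares from one starting point.

    Failed forward evaluations do not abort the run: they return a large
    penalty residual (1e6 * (1 + worst successful phi), spread over the 50
    components) and are counted, keeping the optimizer inside the box
    where the model does converge.
    """
    penalty_state = {"worst_phi": 0.0, "count": 0}

    def residuals(theta):
        try:
            phi, r, _ = objective(theta, exp, sim_config, n_patches)
        except Exception as err:  # noqa: BLE001 - any forward failure
            penalty_state["count"] += 1
            phi_pen = 1e6 * (1.0 + penalty_state["worst_phi"])
            warnings.warn(
                f"forward model failed at theta={np.asarray(theta)}: {err}; "
                f"penalty value {phi_pen:.3g} returned",
                RuntimeWarning,
                stacklevel=2,
            )
            return np.full(50, np.sqrt(phi_pen / 50.0))
        penalty_state["worst_phi"] = max(penalty_state["worst_phi"], phi)
        return r

    res = least_squares_with_protocol(
        residuals, start, bounds, criteria, n_budget=N_BUDGET_PARAMS
    )
    phi, _, breakdown = objective(res.x, exp, sim_config, n_patches)
    return CalibrationEntry(
        start=np.asarray(start, dtype=float),
        theta=res.x,
        phi=phi,
        breakdown=breakdown,
        reason=res.reason,
        n_iters=res.n_iters,
        n_fevals=res.n_fevals,
        trace=res.trace,
        penalized_evals=penalty_state["count"],
    )


def multistart(
    exp: ExperimentRecord,
    starts=DEFAULT_STARTS,
    bounds=DEFAULT_BOUNDS,
    criteria: TerminationCriteria = TerminationCriteria(),
    sim_config=None,
    n_patches=None,
) -> CalibrationOutcome:
    """Run the local solver from every start; best = lowest phi.

    Starts are independent, so the outcome is insensitive to their order.
    """
    if len(starts) < 1:
        raise ValueError("at least one starting point is required")
    entries, failures = [], []
    for s in starts:
        try:
            entries.append(
                minimize_single(s, exp, bounds, criteria, sim_config, n_patches)
            )
        except Exception as err:  # noqa: BLE001
            failures.append((np.asarray(s, dtype=float), repr(err)))
    if not entries:
        lines = "; ".join(f"start {s}: {msg}" for s, msg in failures)
        raise RuntimeError(f"all starts failed: {lines}")
    best = int(np.argmin([e.phi for e in entries]))
    return CalibrationOutcome(
        entries=entries,
        best_index=best,
        total_fevals=sum(e.n_fevals for e in entries),
    )


def rank_minima(entries, exp: ExperimentRecord, sim_config=None, n_patches=None):
    """Rank local minima by the mean of the three block errors.

    Returns a DataFrame (one row per candidate, best first) with the
    error triplet, phi, and the parameter values.  Ranking recomputes the
    triplet from the forward model, so it is insensitive to the input
    order and to stale breakdowns.
    """
    if len(entries) < 1:
        raise ValueError("nothing to rank")
    rows = []
    for j, e in enumerate(entries):
        theta = np.asarray(e.theta if hasattr(e, "theta") else e, dtype=float)
        phi, _, bd = objective(theta, exp, sim_config, n_patches)
        rows.append(
            {
                "candidate": j,
                "overall_error_pct": bd.overall(),
                "volume_error_pct": bd.volume_pct,
                "mean_strain_error_pct": bd.mean_strain_pct,
                "std_strain_error_pct": bd.std_strain_pct,
                "phi": phi,
                **{name: theta[i] for i, name in enumerate(PARAM_NAMES[:3])},
                **{name: theta[3 + i] for i, name in enumerate(PARAM_NAMES[3:8])},
                "C10_kPa": theta[8],
                "lambda_pleura": theta[9],
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["overall_error_pct", "candidate"], kind="stable"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


def sensitivity_sweep(
    theta,
    exp: ExperimentRecord,
    rel_step: float = 0.05,
    sim_config=None,
    n_patches=None,
) -> pd.DataFrame:
    """One-at-a-time +/- relative perturbation of each parameter.

    Reports the change in phi and in each error block per parameter and
    direction; perturbations that leave the calibration box are skipped
    and flagged in the ``in_bounds`` column.
    """
    theta = np.asarray(theta, dtype=float)
    if rel_step < 0:
        raise ValueError("rel_step must be nonnegative")
    phi0, _, bd0 = objective(theta, exp, sim_config, n_patches)
    lb = np.array([b[0] for b in DEFAULT_BOUNDS])
    ub = np.array([b[1] for b in DEFAULT_BOUNDS])
    rows = []
    for i, name in enumerate(PARAM_NAMES):
        for sign in (+1, -1):
            t = theta.copy()
            t[i] = theta[i] * (1.0 + sign * rel_step)
            in_bounds = lb[i] <= t[i] <= ub[i]
            if in_bounds and rel_step > 0:
                phi, _, bd = objective(t, exp, sim_config, n_patches)
                d_phi = phi - phi0
                d_vol = bd.volume_pct - bd0.volume_pct
                d_mean = bd.mean_strain_pct - bd0.mean_strain_pct
                d_std = bd.std_strain_pct - bd0.std_strain_pct
            elif rel_step == 0:
                d_phi = d_vol = d_mean = d_std = 0.0
                in_bounds = True
            else:
                d_phi = d_vol = d_mean = d_std = np.nan
            rows.append(
                {
                    "parameter": name,
                    "direction": sign,
                    "in_bounds": in_bounds,
                    "delta_phi": d_phi,
                    "delta_volume_error_pct": d_vol,
                    "delta_mean_strain_error_pct": d_mean,
                    "delta_std_strain_error_pct": d_std,
                }
            )
    return pd.DataFrame(rows)
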