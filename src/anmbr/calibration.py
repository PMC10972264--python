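"""Least-squares identification of the fouling weights from measured
flux, COD and biomass series.

The identification drives the fouling sub-model directly with the
measured (interpolated) soluble and particulate concentrations rather
than with the full coupled model: total COD is split into substrates
(ST) and SMP at a fixed ratio, COD and biomass XT are linearly
interpolated onto a common time base, the clean-membrane resistance R0
is fixed beforehand from the initial flux, and the four free weights
(Cs, Cx, Csmp, beta1) are then fitted by bound-constrained nonlinear
least squares on the flux with multi-start initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import membrane
from .params import FoulingState, MembraneParams

HOURS_PER_DAY = 24.0

FREE_PARAMS = ("Cs", "Cx", "Csmp", "beta1")


class UnderdeterminedProblemWarning(UserWarning):
    """Fewer flux measurements than free parameters."""


@dataclass
class MeasurementSeries:
    """One measured time series (times in days)."""

    times: np.ndarray
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("measured values must be nonnegative")

    def __len__(self) -> int:
        return len(self.times)


def split_cod(
    cod: np.ndarray | float, st_fraction: float = 0.85
) -> Tuple[np.ndarray, np.ndarray]:
    """Split total COD into substrates and SMP; ST + SMP = COD exactly."""
    if not 0.0 <= st_fraction <= 1.0:
        raise ValueError("st_fraction must lie in [0, 1]")
    cod = np.asarray(cod, dtype=float)
    st = st_fraction * cod
    return st, cod - st


def interpolate_series(
    series: MeasurementSeries, target_times: Sequence[float]
) -> MeasurementSeries:
    """Piecewise-linear interpolation onto new times (no extrapolation)."""
    target = np.asarray(target_times, dtype=float)
    if target.min() < series.times.min() or target.max() > series.times.max():
        raise ValueError(
            "target times fall outside the measured range "
            f"[{series.times.min()}, {series.times.max()}]"
        )
    vals = np.interp(target, series.times, series.values)
    return MeasurementSeries(target, vals, series.kind)


@dataclass
class CalibrationProblem:
    """Flux/COD/biomass series plus the fixed part of the fouling model.

    ``membrane`` supplies the fixed constants (epsilon, sigma, alpha,
    pressure, viscosity ...); its R0 is overridden from the first flux
    measurement unless ``fix_r0_from_j0`` is disabled.  The free
    parameters are the cake weights Cs, Cx, Csmp and the pore-clogging
    weight beta1, with beta2 tied as beta1 * ``beta2_ratio``.
    """

    flux: MeasurementSeries
    cod: MeasurementSeries
    xt: MeasurementSeries
    membrane: MembraneParams = field(default_factory=MembraneParams)
    st_fraction: float = 0.85
    beta2_ratio: float = 1.0 / 15.0
    bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {k: (0.0, 1.0) for k in FREE_PARAMS}
    )
    fix_r0_from_j0: bool = True
    initial_state: FoulingState = field(default_factory=FoulingState)

    def __post_init__(self) -> None:
        if len(self.flux) == 0:
            raise ValueError("need at least one flux measurement")
        if len(self.flux) < len(FREE_PARAMS):
            warnings.warn(
                f"only {len(self.flux)} flux measurements for "
                f"{len(FREE_PARAMS)} free parameters: the problem is "
                "under-determined",
                UnderdeterminedProblemWarning,
            )
        if self.fix_r0_from_j0:
            r0 = membrane.intrinsic_resistance(
                float(self.flux.values[0]),
                self.membrane.delta_P,
                self.membrane.mu_visc,
            )
            self.membrane = replace(self.membrane, R0=r0)

    def with_free(self, values: Sequence[float]) -> MembraneParams:
        cs, cx, csmp, beta1 = (float(v) for v in values)
        return replace(
            self.membrane,
            Cs=cs,
            Cx=cx,
            Csmp=csmp,
            beta1=beta1,
            beta2=beta1 * self.beta2_ratio,
        )


@dataclass
class CalibrationResult:
    """Estimated weights, fit quality and the reconstructed fouling run."""

    params: Dict[str, float]
    objective: float
    r2: float
    fitted_flux: MeasurementSeries
    trajectory: pd.DataFrame
    starts: List[dict] = field(default_factory=list)


# --------------------------------------------------------------------------
# forward model


def _simulate_fouling(
    problem: CalibrationProblem,
    p: MembraneParams,
    eval_times_h: np.ndarray,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> np.ndarray:
    """Integrate (mc, mp) driven by the interpolated concentration inputs.

    Inputs are held by linear interpolation between measurement days and
    clamped at the ends of the measured window.
    """
    cod_t = problem.cod.times * HOURS_PER_DAY
    xt_t = problem.xt.times * HOURS_PER_DAY
    st_vals, smp_vals = split_cod(problem.cod.values, problem.st_fraction)
    xt_vals = problem.xt.values

    def rhs(t, y):
        foul = FoulingState(max(y[0], 0.0), max(y[1], 0.0))
        _, qout = membrane.flux_and_outflow(foul, p)
        st = np.interp(t, cod_t, st_vals)
        smp = np.interp(t, cod_t, smp_vals)
        xt = np.interp(t, xt_t, xt_vals)
        st_drive = st + smp if p.st_includes_smp else st
        return membrane.fouling_rhs_filtration(
            foul, {"ST": st_drive, "XT": xt, "SMP": smp, "Qout": qout}, p
        )

    y0 = [problem.initial_state.mc, problem.initial_state.mp]
    t0 = min(0.0, float(eval_times_h[0]))
    sol = solve_ivp(
        rhs,
        (t0, float(eval_times_h[-1])),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"fouling sub-model integration failed: {sol.message}")
    return sol.sol(eval_times_h).T


def simulate_flux(
    problem: CalibrationProblem,
    free_values: Sequence[float],
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> np.ndarray:
    """Simulated flux (L/(h·m²)) at the flux-measurement times."""
    p = problem.with_free(free_values)
    t_h = problem.flux.times * HOURS_PER_DAY
    masses = _simulate_fouling(problem, p, t_h, rtol=rtol, atol=atol)
    return np.array(
        [
            membrane.flux_and_outflow(FoulingState(max(mc, 0.0), max(mp, 0.0)), p)[0]
            for mc, mp in masses
        ]
    )


def objective(free_values: Sequence[float], problem: CalibrationProblem) -> float:
    """Sum of squared flux residuals F = sum_i (J_i - Jsim_i)^2."""
    resid = problem.flux.values - simulate_flux(problem, free_values)
    return float(np.dot(resid, resid))


def goodness_of_fit(measured: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination r² = 1 - SSres/SStot."""
    measured = np.asarray(measured, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    ss_res = float(np.sum((measured - fitted) ** 2))
    ss_tot = float(np.sum((measured - np.mean(measured)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


# --------------------------------------------------------------------------
# estimation


def _refine_identifiable(problem, x, lo, hi):
    """Polish the best fit in the identifiable subspace.

    With SMP pinned to a fixed fraction of COD, Cs and Csmp only act
    through the lumped soluble weight st_fraction*Cs +
    (1-st_fraction)*Csmp; the resulting exactly-flat ridge makes the
    4-parameter jacobian rank-deficient and stalls the trust-region
    solver in a shallow curved valley.  Freezing the Cs:Csmp proportion
    and refitting (total soluble weight, Cx, beta1) removes the null
    direction, so the solver can descend the valley to the floor.
    """
    cs, cx, csmp, beta1 = x
    tot = cs + csmp
    prop = cs / tot if tot > 0 else 0.5

    def residuals_tight(xv):
        return problem.flux.values - simulate_flux(problem, xv)

    def unpack(z):
        return np.array([prop * z[0], z[1], (1.0 - prop) * z[0], z[2]])

    cap = min(
        hi[0] / prop if prop > 0 else np.inf,
        hi[2] / (1.0 - prop) if prop < 1 else np.inf,
    )
    z0 = np.array([tot, cx, beta1])
    fit = least_squares(
        lambda z: residuals_tight(unpack(z)),
        z0,
        bounds=([lo[0] + lo[2], lo[1], lo[3]], [cap, hi[1], hi[3]]),
        diff_step=1e-6,
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    x_ref = unpack(fit.x)
    f_ref = float(2.0 * fit.cost)
    return f_ref, x_ref


def estimate(
    problem: CalibrationProblem,
    starts: int = 16,
    seed: int = 0,
    x0: Optional[Sequence[float]] = None,
) -> CalibrationResult:
    """Multi-start bound-constrained nonlinear least squares.

    Initial points are drawn by Latin-hypercube sampling within the
    bounds (plus the optional user-supplied ``x0``); each start is
    refined with a trust-region-reflective least-squares solve and the
    best final objective wins.
    """
    if starts < 1:
        raise ValueError("need at least one start")
    lo = np.array([problem.bounds[k][0] for k in FREE_PARAMS])
    hi = np.array([problem.bounds[k][1] for k in FREE_PARAMS])

    def residuals(x):
        # stage-1 exploration runs the forward model at a faster tolerance
        return problem.flux.values - simulate_flux(problem, x, rtol=1e-8, atol=1e-10)

    sampler = qmc.LatinHypercube(d=len(FREE_PARAMS), seed=seed)
    inits = qmc.scale(sampler.random(starts), lo, hi)
    if x0 is not None:
        inits = np.vstack([np.asarray(x0, dtype=float), inits])

    best = None
    log: List[dict] = []
    for x_init in inits:
        try:
            # diff_step well above the ODE-solver noise floor, so the
            # finite-difference jacobian stays informative
            fit = least_squares(
                residuals,
                x_init,
                bounds=(lo, hi),
                diff_step=1e-5,
                xtol=1e-10,
                ftol=1e-12,
                gtol=1e-12,
            )
            cost = float(2.0 * fit.cost)
            log.append({"x0": x_init.tolist(), "F": cost, "status": fit.status})
            if best is None or cost < best[0]:
                best = (cost, fit.x)
        except Exception as exc:  # diagnostic per start
            log.append({"x0": x_init.tolist(), "error": str(exc)})
    if best is None:
        raise RuntimeError(f"all {len(inits)} starts failed: {log}")

    f_best, x_best = best
    f_best, x_best = _refine_identifiable(problem, x_best, lo, hi)
    fitted_vals = simulate_flux(problem, x_best)
    p = problem.with_free(x_best)
    t_h = problem.flux.times * HOURS_PER_DAY
    masses = _simulate_fouling(problem, p, t_h)
    rows = []
    for (mc, mp), t in zip(masses, problem.flux.times):
        foul = FoulingState(max(mc, 0.0), max(mp, 0.0))
        area = membrane.membrane_area(foul, p)
        rc, rp, r = membrane.resistances(foul, area, p)
        j, qout = membrane.flux_and_outflow(foul, p)
        rows.append(
            {"t_days": t, "mc": foul.mc, "mp": foul.mp, "A": area,
             "Rc": rc, "Rp": rp, "R": r, "J": j, "Qout": qout}
        )
    result = CalibrationResult(
        params={k: float(v) for k, v in zip(FREE_PARAMS, x_best)},
        objective=f_best,
        r2=goodness_of_fit(problem.flux.values, fitted_vals),
        fitted_flux=MeasurementSeries(problem.flux.times, fitted_vals, "flux"),
        trajectory=pd.DataFrame(rows),
        starts=log,
    )
    return result
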