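"""Synthetic measurement fixtures and reference parameter sets.

Two reference configurations are provided:

* :func:`pilot_fixture_config` — a pilot-plant-like calibration setting
  (1 m² tubular ultrafiltration membrane at 1.5 bar, 50 L working
  volume, initial flux 8.32 L/(h·m²), flux declining over weeks);
* :func:`control_experiment_config` — a faster-fouling operating point
  used for the control-strategy studies (2 h functioning periods,
  flux declining within minutes to hours).

:func:`generate_dataset` produces irregularly sampled flux / COD /
biomass series from the fouling model under known parameters, with
multiplicative observation noise, so that the calibration pipeline can
be exercised end-to-end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .calibration import (
    CalibrationProblem,
    MeasurementSeries,
    simulate_flux,
)
from .membrane import intrinsic_resistance
from .params import (
    BioParams,
    BioState,
    CleaningParams,
    ControlParams,
    MembraneParams,
    ModelParams,
)
from .units import bar_to_pa

#: initial flux of the pilot calibration cycle, L/(h·m²)
PILOT_J0 = 8.32


def pilot_membrane_params() -> MembraneParams:
    """Membrane constants for the pilot-like calibration fixture.

    Fixed constants: epsilon=0.7, sigma=sigma_prime=10 1/g, 1 m²
    membrane at 1.5 bar; cake/pore weights at their reference estimates
    (Cs=0.1970, Cx=0.1116, Csmp=0.9720, beta1=0.3999, beta2=beta1/15);
    specific resistances at a literature-scale 4e9 so that a feed around
    2 g COD/L fouls the membrane over a few weeks.  R0 follows from the
    initial flux.
    """
    delta_p = bar_to_pa(1.5)
    mu = 1.0e-3
    return MembraneParams(
        A0=1.0,
        epsilon=0.7,
        sigma=10.0,
        sigma_prime=10.0,
        alpha=4.0e9,
        alpha_prime=4.0e9,
        R0=intrinsic_resistance(PILOT_J0, delta_p, mu),
        delta_P=delta_p,
        mu_visc=mu,
        Cs=0.1970,
        Cx=0.1116,
        Csmp=0.9720,
        beta1=0.3999,
    )


def pilot_fixture_config() -> ModelParams:
    """Full coupled-model bundle for the pilot-like setting (V = 50 L)."""
    return ModelParams(
        membrane=pilot_membrane_params(),
        bio=BioParams(S1in=2.0, S2in=0.4, Qw=0.2),
        cleaning=CleaningParams(irr_fraction=0.05),
        control=ControlParams(),
    )


# --------------------------------------------------------------------------
# control-experiment operating point


def control_experiment_config() -> Tuple[ModelParams, Tuple[BioState, FoulingState]]:
    """Operating point for the 2 h control-strategy studies.

    A concentrated, SMP-rich mixed liquor and high specific resistances
    give a clean-membrane flux of 66 L/(h·m²) that declines within the
    first hour of filtration, so that relaxation scheduling and gas
    sparging have measurable effects over a 2 h functioning period.
    Relaxation detaches deposits quickly (omega = 450 1/h) but leaves
    half of them behind (irreversible fraction 0.5 per cleaning).  The
    numbers are package defaults chosen once for these studies (see
    docs/methods.md) and are not refit anywhere.
    """
    delta_p = bar_to_pa(1.5)
    mu = 1.0e-3
    j0 = 66.0
    membrane_p = MembraneParams(
        A0=1.0,
        epsilon=0.7,
        sigma=10.0,
        sigma_prime=10.0,
        alpha=6.0e10,
        alpha_prime=2.5e11,
        R0=intrinsic_resistance(j0, delta_p, mu),
        delta_P=delta_p,
        mu_visc=mu,
        Cs=0.1970,
        Cx=0.1116,
        Csmp=0.9720,
        beta1=0.3999,
    )
    bio_state = BioState(X1=9.31, X2=3.99, S1=0.8625, S2=0.2875, SMP=2.2, V=50.0)
    # anaerobic digestion is slow compared with a 2 h filtration period:
    # low growth/consumption rates and high SMP retention (beta_mem) keep
    # the bulk quasi-stationary over a functioning period
    bio_p = BioParams(
        m1=0.003,
        m2=0.003,
        m_smp=0.001,
        k1=2.0,
        k2=1.0,
        k3=2.0,
        b1=1.0,
        b2=0.5,
        b3=0.1,
        b4=0.1,
        kd1=0.002,
        kd2=0.002,
        beta_mem=0.02,
        S1in=0.8625,
        S2in=0.2875,
        Qw=0.2,
    )
    params = ModelParams(
        membrane=membrane_p,
        bio=bio_p,
        cleaning=CleaningParams(omega=450.0, omega_prime=450.0, irr_fraction=0.5),
        control=ControlParams(),
    )
    from .params import FoulingState  # local to avoid shadowing

    return params, (bio_state, FoulingState(0.0, 0.0))


# --------------------------------------------------------------------------
# synthetic measurement generation


def _default_cod_profile(t_days: np.ndarray) -> np.ndarray:
    """Slowly varying total COD around 2.3 g/L (weeks-scale swings)."""
    t = np.asarray(t_days, dtype=float)
    return 2.3 + 0.5 * np.sin(2 * np.pi * t / 55.0) + 0.15 * np.cos(2 * np.pi * t / 23.0)


def _default_xt_profile(t_days: np.ndarray) -> np.ndarray:
    """Total biomass around 2.1 g/L with a slow drift, shaped unlike COD."""
    t = np.asarray(t_days, dtype=float)
    return 2.1 + 0.4 * np.cos(2 * np.pi * t / 40.0) + 0.004 * t


@dataclass
class FixtureSpec:
    """Sampling plan and noise model for a synthetic measurement set.

    Defaults mirror a two-cycle pilot campaign: 16 flux measurements
    over days 1-39 (the calibration cycle), 29 COD and 13 biomass
    measurements spread over the whole 85-day horizon.  Noise is
    multiplicative Gaussian with the stated coefficients of variation.
    """

    membrane: MembraneParams = field(default_factory=pilot_membrane_params)
    n_flux: int = 16
    flux_window: Tuple[float, float] = (1.0, 39.0)
    n_cod: int = 29
    cod_window: Tuple[float, float] = (0.0, 85.0)
    n_xt: int = 13
    xt_window: Tuple[float, float] = (0.0, 85.0)
    cv_flux: float = 0.05
    cv_conc: float = 0.10
    seed: int = 0
    cod_profile: Callable[[np.ndarray], np.ndarray] = _default_cod_profile
    xt_profile: Callable[[np.ndarray], np.ndarray] = _default_xt_profile
    st_fraction: float = 0.85

    def __post_init__(self) -> None:
        if self.cv_flux < 0 or self.cv_conc < 0:
            raise ValueError("noise CVs must be nonnegative")
        for n in (self.n_flux, self.n_cod, self.n_xt):
            if n < 2:
                raise ValueError("need at least two samples per series")


def _sample_times(
    rng: np.random.Generator, n: int, window: Tuple[float, float]
) -> np.ndarray:
    """n strictly increasing times covering the window endpoints."""
    lo, hi = window
    interior = np.sort(rng.uniform(lo, hi, size=n - 2)) if n > 2 else np.array([])
    times = np.concatenate([[lo], interior, [hi]])
    # enforce strict monotonicity against (unlikely) duplicates
    eps = (hi - lo) * 1e-9
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + eps
    return times


def _mult_noise(
    rng: np.random.Generator, values: np.ndarray, cv: float
) -> np.ndarray:
    if cv == 0.0:
        return values.copy()
    factors = np.maximum(1.0 + cv * rng.standard_normal(values.shape), 1e-3)
    return values * factors


def generate_dataset(spec: FixtureSpec) -> Dict[str, object]:
    """Synthetic flux/COD/XT measurement set from known true parameters.

    COD and biomass series are sampled from the smooth profiles (with
    noise) first; the flux is then generated by the fouling model driven
    by exactly those sampled series, so that with ``cv_flux = 0`` the
    calibration objective evaluated at the true parameters is zero by
    construction.  Returns the three series plus a ``truth`` record.
    """
    rng = np.random.default_rng(spec.seed)

    cod_times = _sample_times(rng, spec.n_cod, spec.cod_window)
    xt_times = _sample_times(rng, spec.n_xt, spec.xt_window)
    cod_vals = _mult_noise(rng, spec.cod_profile(cod_times), spec.cv_conc)
    xt_vals = _mult_noise(rng, spec.xt_profile(xt_times), spec.cv_conc)
    cod = MeasurementSeries(cod_times, cod_vals, "cod")
    xt = MeasurementSeries(xt_times, xt_vals, "xt")

    flux_times = _sample_times(rng, spec.n_flux, spec.flux_window)
    p = spec.membrane
    problem = CalibrationProblem(
        flux=MeasurementSeries(flux_times, np.zeros_like(flux_times), "flux"),
        cod=cod,
        xt=xt,
        membrane=p,
        st_fraction=spec.st_fraction,
        fix_r0_from_j0=False,
    )
    clean_flux = simulate_flux(problem, [p.Cs, p.Cx, p.Csmp, p.beta1])
    flux_vals = _mult_noise(rng, clean_flux, spec.cv_flux)
    flux = MeasurementSeries(flux_times, flux_vals, "flux")

    truth = {
        "Cs": p.Cs,
        "Cx": p.Cx,
        "Csmp": p.Csmp,
        "beta1": p.beta1,
        "beta2": p.beta2,
        "R0": p.R0,
        "seed": spec.seed,
        "cv_flux": spec.cv_flux,
        "cv_conc": spec.cv_conc,
    }
    return {"flux": flux, "cod": cod, "xt": xt, "truth": truth}


def make_problem(
    dataset: Dict[str, object],
    membrane: Optional[MembraneParams] = None,
    fix_r0_from_j0: bool = False,
    **kwargs,
) -> CalibrationProblem:
    """Calibration problem wired to a generated dataset.

    By default R0 is taken from the fixture's membrane parameters (the
    noiseless-closure setting); pass ``fix_r0_from_j0=True`` to fix it
    from the first flux measurement instead, as done with real data.
    """
    return CalibrationProblem(
        flux=dataset["flux"],
        cod=dataset["cod"],
        xt=dataset["xt"],
        membrane=membrane or pilot_membrane_params(),
        fix_r0_from_j0=fix_r0_from_j0,
        **kwargs,
    )
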