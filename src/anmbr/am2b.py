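"""AM2b two-step anaerobic digestion kinetics with SMP dynamics.

Acidogenic biomass X1 degrades the organic substrate S1 into volatile
fatty acids S2; methanogenic biomass X2 degrades S2.  Both populations
produce soluble microbial products (SMP) during growth and decay, and X1
can re-consume SMP.  The membrane retains all biomass and the
macro-molecular part of the SMP; a fraction ``beta_mem`` of the SMP
leaves with the permeate.

Two right-hand sides are provided: the open-reactor filtration phase
(with inflow, withdrawal and the membrane-attachment sinks) and the
closed-reactor relaxation/backwash phase (feed stopped, optional
re-injection of detached matter).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .params import BioParams, BioState


# --- growth functions ------------------------------------------------------


def growth_monod(s: float, m_max: float, K: float) -> float:
    """Monod kinetics m_max*s/(K+s); zero at s=0, saturating at m_max."""
    if s < 0:
        raise ValueError("substrate concentration must be nonnegative")
    return m_max * s / (K + s)


def growth_haldane(s: float, m_max: float, K: float, Ki: float) -> float:
    """Haldane (substrate-inhibited) kinetics m_max*s/(K + s + s^2/Ki).

    Unimodal with maximum at s = sqrt(K*Ki).
    """
    if s < 0:
        raise ValueError("substrate concentration must be nonnegative")
    return m_max * s / (K + s + s * s / Ki)


def growth_smp(smp: float, m_smp: float, K_smp: float) -> float:
    """Monod kinetics on SMP re-consumption by the acidogens."""
    return growth_monod(smp, m_smp, K_smp)


def growth_rates(b: BioState, p: BioParams) -> Tuple[float, float, float]:
    """(mu1(S1), mu2(S2), mu_smp(SMP)) for the current state, 1/h."""
    mu1 = growth_monod(b.S1, p.m1, p.K1)
    mu2 = growth_haldane(b.S2, p.m2, p.K2, p.Ki)
    musmp = growth_smp(b.SMP, p.m_smp, p.K_smp)
    return mu1, mu2, musmp


# --- totals ----------------------------------------------------------------


def totals(b: BioState, include_smp: bool = False) -> Tuple[float, float]:
    """Soluble and particulate totals (ST, XT) in g/L.

    ST = S1 + S2 by default; the SMP pool is accounted separately in the
    fouling terms, so including it here would double-count (set
    ``include_smp`` to adopt the literal ST = S1 + S2 + SMP convention).
    """
    st = b.S1 + b.S2 + (b.SMP if include_smp else 0.0)
    return st, b.X1 + b.X2


# --- right-hand sides ------------------------------------------------------


def bio_rhs_filtration(b: BioState, p: BioParams, fouling_env: dict) -> np.ndarray:
    """d/dt of (X1, X2, S1, S2, SMP, V) during filtration.

    ``fouling_env`` carries ``Qout`` (L/h) and the attachment weights
    ``Cs``, ``Cx``, ``Csmp``; the matter they remove from the bulk is
    exactly what accumulates on the membrane.  The inflow is slaved to
    the permeate production, Qin = Qout + Qw, so the volume is constant.
    """
    qout = fouling_env["Qout"]
    cs = fouling_env.get("Cs", 0.0)
    cx = fouling_env.get("Cx", 0.0)
    csmp = fouling_env.get("Csmp", 0.0)
    if qout < 0:
        raise ValueError("Qout must be nonnegative")
    qin = qout + p.Qw
    v = b.V
    mu1, mu2, musmp = growth_rates(b, p)

    dX1 = (mu1 + musmp - p.kd1 - p.Qw / v - (qout / v) * cx) * b.X1
    dX2 = (mu2 - p.kd2 - p.Qw / v - (qout / v) * cx) * b.X2
    dS1 = (
        (qin / v) * p.S1in
        - ((qout + p.Qw) / v) * b.S1
        - p.k1 * mu1 * b.X1
        - (qout / v) * cs * b.S1
    )
    dS2 = (
        (qin / v) * p.S2in
        - ((qout + p.Qw) / v) * b.S2
        - p.k3 * mu2 * b.X2
        + (p.k2 * mu1 + p.b2 * musmp) * b.X1
        - (qout / v) * cs * b.S2
    )
    dSMP = (
        -(p.beta_mem * qin / v + (1.0 - p.beta_mem) * p.Qw / v) * b.SMP
        + (p.b3 * mu1 + p.kd1 - p.b1 * musmp) * b.X1
        + (p.b4 * mu2 + p.kd2) * b.X2
        - (qout / v) * csmp * b.SMP
    )
    dV = qin - qout - p.Qw  # identically zero by construction
    return np.array([dX1, dX2, dS1, dS2, dSMP, dV])


def bio_rhs_cleaning(b: BioState, p: BioParams) -> np.ndarray:
    """d/dt of (X1, X2, S1, S2, SMP, V) during relaxation/backwash.

    The feed is stopped, so no dilution terms remain; the re-injection
    coefficients Cs_r/Cx_r/Csmp_r (zero by default) model detached
    matter returning to the bulk, proportional to the bulk
    concentrations as in the cleaning-phase model.
    """
    mu1, mu2, musmp = growth_rates(b, p)
    dX1 = (mu1 + musmp - p.kd1 + p.Cx_r) * b.X1
    dX2 = (mu2 - p.kd2 + p.Cx_r) * b.X2
    dS1 = -p.k1 * mu1 * b.X1 + p.Cs_r * b.S1
    dS2 = (
        -p.k3 * mu2 * b.X2
        + (p.k2 * mu1 + p.b2 * musmp) * b.X1
        + p.Cs_r * b.S2
    )
    dSMP = (
        (p.b3 * mu1 + p.kd1 - p.b1 * musmp) * b.X1
        + (p.b4 * mu2 + p.kd2) * b.X2
        + p.Csmp_r * b.SMP
    )
    return np.array([dX1, dX2, dS1, dS2, dSMP, 0.0])
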