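"""Membrane fouling physics: area law, resistances, Darcy flux and the
fouling mass balances.

The model tracks two deposited masses: a cake layer ``mc`` on the
membrane surface and a mass ``mp`` (mostly SMP) blocked inside the
pores.  Both shrink the useful filtering area, add hydraulic
resistances in series, and thereby depress the permeate flux at
constant transmembrane pressure.  During relaxation or backwash the
masses decay exponentially toward an irreversible residual.

All functions here are pure; no file I/O and no integration.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

from .params import CleaningParams, ControlParams, FoulingState, MembraneParams
from .units import flux_si_to_lhm2


def membrane_area(state: FoulingState, p: MembraneParams) -> float:
    """Useful filtering area (m²) as a decreasing function of the
    deposited masses.

    The default form is A = A0 / (1 + sigma*mc + sigma_prime*mp), which
    makes sigma (1/g) dimensionally consistent; the alternative
    ``mass_over_sigma`` form A0 / (1 + mc/sigma + mp/sigma_prime) is kept
    for sensitivity checks.
    """
    if state.mc < 0 or state.mp < 0:
        raise ValueError("deposited masses must be nonnegative")
    if p.area_form == "reciprocal":
        denom = 1.0 + p.sigma * state.mc + p.sigma_prime * state.mp
    else:
        denom = 1.0 + state.mc / p.sigma + state.mp / p.sigma_prime
    return p.A0 / denom


def resistances(
    state: FoulingState, area: float, p: MembraneParams
) -> Tuple[float, float, float]:
    """Cake, pore and total fouling resistances (1/m).

    Rc = alpha*mc/A acts over the whole useful area; Rp =
    alpha_prime*mp/(epsilon*A) acts over the porous fraction only.
    """
    if area <= 0:
        raise ValueError("degenerate membrane: area must be positive")
    rc = p.alpha * state.mc / area
    rp = p.alpha_prime * state.mp / (p.epsilon * area)
    return rc, rp, rc + rp


def flux_and_outflow(
    state: FoulingState, p: MembraneParams, delta_P: Optional[float] = None
) -> Tuple[float, float]:
    """Permeate flux J (L/(h·m²)) and output flow Qout (L/h).

    Darcy resistance-in-series law at constant TMP:
    J = dP / (mu * (R0 + R)) evaluated in SI and converted; Qout = J*A.
    A nonpositive driving pressure (relaxation, backwash) gives zero
    permeate production.
    """
    dp = p.delta_P if delta_P is None else delta_P
    if dp <= 0.0:
        return 0.0, 0.0
    area = membrane_area(state, p)
    _, _, r_foul = resistances(state, area, p)
    j_si = dp / (p.mu_visc * (p.R0 + r_foul))
    j = flux_si_to_lhm2(j_si)
    return j, j * area


def fouling_rhs_filtration(
    state: FoulingState,
    env: dict,
    p: MembraneParams,
    control: Optional[ControlParams] = None,
) -> Tuple[float, float]:
    """Time derivatives (g/h) of (mc, mp) during filtration.

    Attachment is proportional to the mass flow carried toward the
    membrane by the permeate stream:

        dmc/dt = Qout * (Cs*ST + Cx*XT + Csmp*SMP) - f(mc)
        dmp/dt = Qout * (beta1*SMP + beta2*ST)     - g(mp)

    ``env`` carries the bulk concentrations ``ST``, ``XT``, ``SMP``
    (g/L) and the outflow ``Qout`` (L/h).  ``env`` may instead provide
    per-component lists ``S_i``/``X_j`` when per-component weights are
    configured.  The sparging sinks f, g are clipped so they can never
    drive a mass negative within the current state.
    """
    qout = env["Qout"]
    if p.Cs_i is not None and "S_i" in env:
        cake_s = sum(c * s for c, s in zip(p.Cs_i, env["S_i"]))
    else:
        cake_s = p.Cs * env["ST"]
    if p.Cx_j is not None and "X_j" in env:
        cake_x = sum(c * x for c, x in zip(p.Cx_j, env["X_j"]))
    else:
        cake_x = p.Cx * env["XT"]
    dmc = qout * (cake_s + cake_x + p.Csmp * env["SMP"])
    dmp = qout * (p.beta1 * env["SMP"] + p.beta2 * env["ST"])
    if control is not None and control.active:
        dmc -= control.detach_cake(state.mc) if state.mc > 0 else 0.0
        dmp -= control.detach_pore(state.mp) if state.mp > 0 else 0.0
    return dmc, dmp


def fouling_rhs_cleaning(
    state: FoulingState, cp: CleaningParams
) -> Tuple[float, float]:
    """Time derivatives (g/h) of (mc, mp) during relaxation/backwash.

    First-order detachment toward the irreversible residual:
    dm/dt = -omega*m + m_irr, with fixed point m_irr/omega.
    """
    dmc = -cp.omega * state.mc + cp.mc_irr
    dmp = -cp.omega_prime * state.mp + cp.mp_irr
    return dmc, dmp


def cleaning_closed_form(m0: float, omega: float, m_irr: float, t: float) -> float:
    """Analytic solution of dm/dt = -omega*m + m_irr from m(0)=m0."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    fixed = m_irr / omega
    return (m0 - fixed) * math.exp(-omega * t) + fixed


def irreversible_source_from_fraction(
    m_end: float, fraction: float, omega: float, duration: float
) -> float:
    """Constant source m_irr such that a fraction of the end-of-filtration
    mass survives the cleaning segment.

    Solves (m_end - m_irr/omega)*exp(-omega*T) + m_irr/omega =
    fraction*m_end for m_irr, clipped at zero (a fraction below the
    natural decay level needs no source).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    decay = math.exp(-omega * duration)
    m_irr = omega * m_end * (fraction - decay) / (1.0 - decay)
    return max(m_irr, 0.0)


def intrinsic_resistance(j0_lhm2: float, delta_P: float, mu_visc: float) -> float:
    """Clean-membrane resistance R0 (1/m) from the initial flux.

    Inverts the Darcy law at R=0: R0 = dP / (mu * J(0)) with J(0)
    converted from L/(h·m²) to m/s.
    """
    if j0_lhm2 <= 0:
        raise ValueError("J(0) must be positive")
    from .units import flux_lhm2_to_si

    return delta_P / (mu_visc * flux_lhm2_to_si(j0_lhm2))
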