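"""Event-driven integration of the coupled AnMBR model.

A run alternates *filtration* segments (open reactor, Darcy flux,
attachment of matter to the membrane) with *relaxation* or *backwash*
segments (feed stopped, first-order detachment toward an irreversible
residual).  Segments are integrated with an adaptive Runge-Kutta method
and concatenated with state continuity; irreversible fouling carries
over from cycle to cycle.

The full state vector is ``[X1, X2, S1, S2, SMP, V, mc, mp]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import am2b, membrane
from .params import (
    BioState,
    CleaningParams,
    ControlParams,
    FoulingState,
    ModelParams,
)

_STATE_COLS = ["X1", "X2", "S1", "S2", "SMP", "V", "mc", "mp"]
_DERIVED_COLS = ["A", "Rc", "Rp", "R", "J", "Qout"]

FILTRATION = "filtration"
RELAXATION = "relaxation"
BACKWASH = "backwash"
_CLEANING_MODES = (RELAXATION, BACKWASH)


class NoCrossingError(RuntimeError):
    """Raised when the flux never reaches the requested threshold."""

    def __init__(self, js: float, horizon: float):
        super().__init__(
            f"flux never crossed the threshold {js} L/(h·m²) "
            f"within the horizon of {horizon} h"
        )
        self.js = js
        self.horizon = horizon


@dataclass
class StopEvent:
    """Terminate a filtration segment when J drops to the threshold Js."""

    js: float

    def __post_init__(self) -> None:
        if self.js <= 0:
            raise ValueError("threshold flux must be positive")


@dataclass
class PhaseSegment:
    """One operating segment of the filtration/cleaning alternation."""

    mode: str
    duration: Optional[float] = None
    control: Optional[ControlParams] = None
    cleaning: Optional[CleaningParams] = None
    stop: Optional[StopEvent] = None

    def __post_init__(self) -> None:
        if self.mode not in (FILTRATION, RELAXATION, BACKWASH):
            raise ValueError(f"unknown phase mode {self.mode!r}")
        if self.duration is None and self.stop is None:
            raise ValueError("segment needs a duration or a stop event")
        if self.duration is not None and self.duration < 0:
            raise ValueError("duration must be nonnegative")


@dataclass
class PhaseSchedule:
    """Ordered sequence of phase segments."""

    segments: List[PhaseSegment]

    @property
    def period(self) -> float:
        return sum(s.duration or 0.0 for s in self.segments)

    @property
    def n_cycles(self) -> int:
        return sum(1 for s in self.segments if s.mode in _CLEANING_MODES)


@dataclass
class Trajectory:
    """Time-stamped record of all states plus derived quantities.

    ``frame`` has one row per time point with columns t, the eight state
    variables, the derived A, Rc, Rp, R, J, Qout and a phase label.
    """

    frame: pd.DataFrame
    events: List[dict] = field(default_factory=list)

    @property
    def t(self) -> np.ndarray:
        return self.frame["t"].to_numpy()

    @property
    def J(self) -> np.ndarray:
        return self.frame["J"].to_numpy()

    def final_states(self) -> Tuple[BioState, FoulingState]:
        row = self.frame.iloc[-1]
        bio = BioState(*(row[c] for c in _STATE_COLS[:6]))
        foul = FoulingState(max(row["mc"], 0.0), max(row["mp"], 0.0))
        return bio, foul

    def concat(self, other: "Trajectory") -> "Trajectory":
        # keep both boundary samples (pre- and post-switch J), nudged
        # apart by an infinitesimal time so the record stays strictly
        # increasing and the flux discontinuity integrates exactly
        lhs, rhs = self.frame, other.frame
        if len(lhs) and len(rhs) and rhs["t"].iloc[0] <= lhs["t"].iloc[-1]:
            rhs = rhs.copy()
            rhs.iloc[0, rhs.columns.get_loc("t")] = lhs["t"].iloc[-1] + 1e-12
        frame = pd.concat([lhs, rhs], ignore_index=True)
        return Trajectory(frame, self.events + other.events)


# --------------------------------------------------------------------------
# right-hand sides on the packed state vector


def _clipped_states(y: np.ndarray) -> Tuple[BioState, FoulingState]:
    yc = np.maximum(y, 0.0)
    bio = BioState(yc[0], yc[1], yc[2], yc[3], yc[4], max(y[5], 1e-12))
    return bio, FoulingState(yc[6], yc[7])


def _rhs_filtration(t, y, params: ModelParams, control: Optional[ControlParams]):
    bio, foul = _clipped_states(y)
    p = params.membrane
    _, qout = membrane.flux_and_outflow(foul, p)
    st, xt = am2b.totals(bio, include_smp=p.st_includes_smp)
    dbio = am2b.bio_rhs_filtration(
        bio, params.bio, {"Qout": qout, "Cs": p.Cs, "Cx": p.Cx, "Csmp": p.Csmp}
    )
    dmc, dmp = membrane.fouling_rhs_filtration(
        foul, {"ST": st, "XT": xt, "SMP": bio.SMP, "Qout": qout}, p, control
    )
    return np.concatenate([dbio, [dmc, dmp]])


def _rhs_cleaning(t, y, params: ModelParams, cleaning: CleaningParams):
    bio, foul = _clipped_states(y)
    dbio = am2b.bio_rhs_cleaning(bio, params.bio)
    dmc, dmp = membrane.fouling_rhs_cleaning(foul, cleaning)
    return np.concatenate([dbio, [dmc, dmp]])


def _derived(y: np.ndarray, mode: str, params: ModelParams) -> list:
    _, foul = _clipped_states(y)
    p = params.membrane
    area = membrane.membrane_area(foul, p)
    rc, rp, r = membrane.resistances(foul, area, p)
    if mode == FILTRATION:
        j, qout = membrane.flux_and_outflow(foul, p)
    else:
        j, qout = 0.0, 0.0
    return [area, rc, rp, r, j, qout]


def _pack(bio: BioState, foul: FoulingState) -> np.ndarray:
    return np.concatenate([bio.as_array(), [foul.mc, foul.mp]])


def _to_frame(ts, ys, mode, params) -> pd.DataFrame:
    rows = np.asarray(ys)
    derived = np.array([_derived(y, mode, params) for y in rows])
    frame = pd.DataFrame(rows, columns=_STATE_COLS)
    frame.insert(0, "t", ts)
    for i, c in enumerate(_DERIVED_COLS):
        frame[c] = derived[:, i]
    frame["phase"] = mode
    return frame


# --------------------------------------------------------------------------
# segment and schedule integration


def simulate_segment(
    initial: Tuple[BioState, FoulingState],
    seg: PhaseSegment,
    params: ModelParams,
    t0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    n_eval: int = 400,
    max_horizon: float = 48.0,
) -> Trajectory:
    """Integrate one phase segment, returning its trajectory.

    A ``stop`` event on a filtration segment ends the integration when J
    crosses the threshold (located on the dense output); otherwise the
    segment runs for its configured duration.  A zero-length segment
    returns the initial point only.
    """
    bio, foul = initial
    y0 = _pack(bio, foul)

    if seg.duration == 0.0:
        frame = _to_frame([t0], [y0], seg.mode, params)
        return Trajectory(frame)

    if seg.mode == FILTRATION:
        rhs = lambda t, y: _rhs_filtration(t, y, params, seg.control)
    else:
        cleaning = seg.cleaning or params.cleaning
        rhs = lambda t, y: _rhs_cleaning(t, y, params, cleaning)

    t_end = t0 + (seg.duration if seg.duration is not None else max_horizon)
    events = None
    if seg.stop is not None:
        if seg.mode != FILTRATION:
            raise ValueError("stop events only apply to filtration segments")

        def flux_event(t, y):
            _, foul_t = _clipped_states(y)
            j, _ = membrane.flux_and_outflow(foul_t, params.membrane)
            return j - seg.stop.js

        flux_event.terminal = True
        flux_event.direction = -1
        events = flux_event

    sol = solve_ivp(
        rhs,
        (t0, t_end),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=events,
    )
    if not sol.success:
        raise RuntimeError(
            f"solver failed in {seg.mode} segment at t={sol.t[-1]:.6g} h: "
            f"{sol.message}"
        )

    ev_log = []
    if seg.stop is not None:
        if sol.t_events[0].size:
            t_end = float(sol.t_events[0][0])
            ev_log.append(
                {"t": t_end, "event": "flux_threshold", "Js": seg.stop.js}
            )
        elif seg.duration is None:
            raise NoCrossingError(seg.stop.js, max_horizon)

    ts = np.linspace(t0, t_end, n_eval + 1)
    ys = sol.sol(ts).T
    frame = _to_frame(ts, ys, seg.mode, params)
    return Trajectory(frame, ev_log)


def run_schedule(
    initial: Tuple[BioState, FoulingState],
    schedule: PhaseSchedule,
    params: ModelParams,
    t0: float = 0.0,
    **solver_kw,
) -> Trajectory:
    """Integrate an ordered schedule with state carry-over.

    Cleaning segments whose ``irr_fraction`` is set get their
    irreversible sources re-derived from the masses reached at the end
    of the preceding filtration period, so that the configured fraction
    survives the segment.
    """
    bio, foul = initial
    traj: Optional[Trajectory] = None
    t = t0
    for seg in schedule.segments:
        if seg.mode in _CLEANING_MODES:
            cp = seg.cleaning or params.cleaning
            if cp.irr_fraction is not None and seg.duration:
                cp = replace(
                    cp,
                    mc_irr=membrane.irreversible_source_from_fraction(
                        foul.mc, cp.irr_fraction, cp.omega, seg.duration
                    ),
                    mp_irr=membrane.irreversible_source_from_fraction(
                        foul.mp, cp.irr_fraction, cp.omega_prime, seg.duration
                    ),
                    irr_fraction=None,
                )
            seg = replace(seg, cleaning=cp)
        piece = simulate_segment((bio, foul), seg, params, t0=t, **solver_kw)
        piece.events.insert(
            0, {"t": t, "event": "segment_start", "mode": seg.mode}
        )
        traj = piece if traj is None else traj.concat(piece)
        bio, foul = piece.final_states()
        t = float(piece.frame["t"].iloc[-1])
    if traj is None:
        raise ValueError("empty schedule")
    return traj


def make_intermittent_schedule(
    n_cycles: int,
    period: float,
    alpha_t: float,
    control: Optional[ControlParams] = None,
    cleaning: Optional[CleaningParams] = None,
    cleaning_mode: str = RELAXATION,
) -> PhaseSchedule:
    """Equal filtration/relaxation cycles at a fixed time ratio.

    Each of the ``n_cycles`` cycles spans ``period / n_cycles`` hours and
    is split so that Tfiltr / TRelax = ``alpha_t``:
    Tfiltr = (period/n) * alpha_t/(1+alpha_t), TRelax = (period/n)/(1+alpha_t).
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    if period <= 0 or alpha_t <= 0:
        raise ValueError("period and alpha_t must be positive")
    cycle = period / n_cycles
    t_filtr = cycle * alpha_t / (1.0 + alpha_t)
    t_relax = cycle / (1.0 + alpha_t)
    segments: List[PhaseSegment] = []
    for _ in range(n_cycles):
        segments.append(
            PhaseSegment(FILTRATION, duration=t_filtr, control=control)
        )
        segments.append(
            PhaseSegment(cleaning_mode, duration=t_relax, cleaning=cleaning)
        )
    return PhaseSchedule(segments)


def mean_flux(traj: Trajectory, filtration_only: bool = False) -> float:
    """Time-averaged permeate flux over the trajectory, L/(h·m²).

    Cleaning time counts as zero production by default (the flux trace
    is already zero there); ``filtration_only`` restricts the average to
    filtration segments instead.
    """
    frame = traj.frame
    if len(frame) == 0:
        raise ValueError("empty trajectory")
    t = frame["t"].to_numpy()
    j = frame["J"].to_numpy()
    if len(frame) == 1:
        return float(j[0])
    total = np.trapezoid(j, t)
    if filtration_only:
        dt = np.diff(t)
        mask = (frame["phase"].to_numpy()[:-1] == FILTRATION)
        denom = float(np.sum(dt[mask]))
    else:
        denom = float(t[-1] - t[0])
    if denom <= 0:
        raise ValueError("trajectory spans zero time")
    return float(total / denom)


def run_until_threshold(
    initial: Tuple[BioState, FoulingState],
    js: float,
    params: ModelParams,
    control: Optional[ControlParams] = None,
    max_horizon: float = 48.0,
    **solver_kw,
) -> Tuple[Trajectory, float]:
    """Filtration until the flux declines to the threshold ``js``.

    Returns the trajectory up to the crossing and the crossing time.
    Raises ``NoCrossingError`` if the flux stays above ``js`` over the
    whole ``max_horizon``, and ``ValueError`` if it starts below it.
    """
    _, foul = initial
    j0, _ = membrane.flux_and_outflow(foul, params.membrane)
    if j0 <= js:
        raise ValueError(
            f"initial flux {j0:.4g} is not above the threshold {js:.4g}"
        )
    seg = PhaseSegment(
        FILTRATION, duration=None, control=control, stop=StopEvent(js)
    )
    traj = simulate_segment(
        initial, seg, params, max_horizon=max_horizon, **solver_kw
    )
    t_stop = float(traj.frame["t"].iloc[-1])
    return traj, t_stop
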