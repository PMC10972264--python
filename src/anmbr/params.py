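"""Parameter containers, state containers and config-file I/O.

All containers are plain dataclasses with eager validation; invalid
physical values raise ``ValueError`` at construction time.  Parameter sets
round-trip through a YAML config file whose keys follow the customary
symbols of the fouling/AM2b literature (``A0``, ``epsilon``, ``sigma``,
``alpha``, ``beta1`` ...).  Pressure is carried in Pa internally and in
bar in config files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import yaml

from .units import bar_to_pa, pa_to_bar


# --------------------------------------------------------------------------
# membrane / fouling


@dataclass
class MembraneParams:
    """Membrane geometry, resistance and attachment/clogging weights.

    Attributes
    ----------
    A0 : float
        Initial (clean) membrane area, m².
    epsilon : float
        Porous fraction of the useful area, 0 < epsilon < 1.
    sigma, sigma_prime : float
        Area-reduction coefficients for cake and pore mass, 1/g.
    alpha, alpha_prime : float
        Specific cake / pore resistances, scaled so that ``alpha*mc/A``
        is in 1/m when ``mc`` is in g and ``A`` in m².
    R0 : float
        Intrinsic (clean-membrane) resistance, 1/m.
    delta_P : float
        Transmembrane pressure, Pa.  Positive during filtration, zero
        during relaxation, negative during backwash.
    mu_visc : float
        Permeate dynamic viscosity, Pa·s.
    Cs, Cx, Csmp : float
        Cake-attachment weights (g deposited per g carried by the
        permeate flow) for substrates, biomass and SMP.
    beta1, beta2 : float
        Pore-clogging weights for SMP and for the other solutes;
        ``beta2`` defaults to ``beta1 / 15``.
    Cs_i, Cx_j : sequence of float, optional
        Per-component cake weights generalising the lumped Cs/Cx.
    area_form : str
        ``"reciprocal"`` (default) uses A = A0 / (1 + sigma*mc +
        sigma_prime*mp); ``"mass_over_sigma"`` uses the alternative
        A = A0 / (1 + mc/sigma + mp/sigma_prime) for sensitivity checks.
    st_includes_smp : bool
        Whether the soluble total ST driving the fouling terms includes
        SMP (which also appears in its own term).  Default False.
    """

    A0: float = 1.0
    epsilon: float = 0.7
    sigma: float = 10.0
    sigma_prime: float = 10.0
    alpha: float = 4.0e9
    alpha_prime: float = 4.0e9
    R0: float = 6.49e13
    delta_P: float = 1.5e5
    mu_visc: float = 1.0e-3
    Cs: float = 0.1970
    Cx: float = 0.1116
    Csmp: float = 0.9720
    beta1: float = 0.3999
    beta2: Optional[float] = None
    Cs_i: Optional[Sequence[float]] = None
    Cx_j: Optional[Sequence[float]] = None
    area_form: str = "reciprocal"
    st_includes_smp: bool = False

    def __post_init__(self) -> None:
        if self.beta2 is None:
            self.beta2 = self.beta1 / 15.0
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        for name in ("sigma", "sigma_prime", "alpha", "alpha_prime", "R0", "mu_visc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("Cs", "Cx", "Csmp", "beta1", "beta2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.beta2 > self.beta1:
            raise ValueError("beta2 must not exceed beta1")
        if self.area_form not in ("reciprocal", "mass_over_sigma"):
            raise ValueError(f"unknown area_form {self.area_form!r}")


@dataclass
class FoulingState:
    """Deposited masses: cake on the surface (mc) and inside pores (mp), g."""

    mc: float = 0.0
    mp: float = 0.0

    def __post_init__(self) -> None:
        if self.mc < 0 or self.mp < 0:
            raise ValueError("deposited masses must be nonnegative")


@dataclass
class CleaningParams:
    """First-order detachment during relaxation/backwash.

    ``omega``/``omega_prime`` are detachment rates (1/h); ``mc_irr`` /
    ``mp_irr`` are constant irreversible-fouling sources (g/h).  When
    ``irr_fraction`` is set, the sources are re-derived at each cleaning
    segment so that the given fraction of the end-of-filtration mass
    survives the segment.
    """

    omega: float = 120.0
    omega_prime: float = 120.0
    mc_irr: float = 0.0
    mp_irr: float = 0.0
    duration: float = 5.0 / 60.0
    irr_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.omega_prime <= 0:
            raise ValueError("detachment rates must be positive")
        if self.mc_irr < 0 or self.mp_irr < 0:
            raise ValueError("irreversible sources must be nonnegative")
        if self.irr_fraction is not None and not 0.0 <= self.irr_fraction < 1.0:
            raise ValueError("irr_fraction must lie in [0, 1)")


@dataclass
class ControlParams:
    """Gas-sparging detachment control.

    The default detachment laws are linear, f(mc) = km*mc and
    g(mp) = kp*mp; arbitrary positive functions may be supplied through
    ``f`` and ``g`` (they then take precedence over km/kp).
    """

    km: float = 0.0
    kp: float = 0.0
    active: bool = False
    f: Optional[Callable[[float], float]] = None
    g: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.km < 0 or self.kp < 0:
            raise ValueError("km and kp must be nonnegative")

    def detach_cake(self, mc: float) -> float:
        if not self.active:
            return 0.0
        return self.f(mc) if self.f is not None else self.km * mc

    def detach_pore(self, mp: float) -> float:
        if not self.active:
            return 0.0
        return self.g(mp) if self.g is not None else self.kp * mp


# --------------------------------------------------------------------------
# biology (AM2b)


@dataclass
class BioState:
    """AM2b bulk state: biomasses, substrates, SMP (g/L) and volume (L)."""

    X1: float
    X2: float
    S1: float
    S2: float
    SMP: float
    V: float

    def __post_init__(self) -> None:
        for name in ("X1", "X2", "S1", "S2", "SMP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.V <= 0:
            raise ValueError("V must be positive")

    def as_array(self):
        import numpy as np

        return np.array([self.X1, self.X2, self.S1, self.S2, self.SMP, self.V])


@dataclass
class BioParams:
    """AM2b kinetic constants (time unit: hours).

    Acidogenesis is Monod on S1, methanogenesis Haldane on S2, SMP
    degradation Monod on SMP.  ``beta_mem`` is the fraction of SMP small
    enough to pass the membrane; ``Qw`` the sludge withdrawal flow (L/h).
    ``Cs_r``/``Cx_r``/``Csmp_r`` are the relaxation-phase re-injection
    coefficients (zero by default: detached matter is neglected in the
    bulk).
    """

    k1: float = 25.0
    k2: float = 15.0
    k3: float = 16.0
    b1: float = 5.0
    b2: float = 3.0
    b3: float = 0.6
    b4: float = 0.8
    kd1: float = 0.0008
    kd2: float = 0.0008
    beta_mem: float = 0.6
    S1in: float = 10.0
    S2in: float = 1.0
    Qw: float = 0.5
    m1: float = 0.05
    K1: float = 8.85
    m2: float = 0.03
    K2: float = 2.5
    Ki: float = 16.0
    m_smp: float = 0.02
    K_smp: float = 3.0
    Cs_r: float = 0.0
    Cx_r: float = 0.0
    Csmp_r: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "m1", "K1", "m2", "K2", "Ki", "m_smp", "K_smp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("b1", "b2", "b3", "b4", "kd1", "kd2", "S1in", "S2in",
                     "Qw", "Cs_r", "Cx_r", "Csmp_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.beta_mem <= 1.0:
            raise ValueError("beta_mem must lie in [0, 1]")


# --------------------------------------------------------------------------
# bundle + config I/O


@dataclass
class ModelParams:
    """Full parameter bundle for the coupled simulator."""

    membrane: MembraneParams = field(default_factory=MembraneParams)
    bio: BioParams = field(default_factory=BioParams)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    control: ControlParams = field(default_factory=ControlParams)


_MEMBRANE_KEYS = (
    "A0", "epsilon", "sigma", "sigma_prime", "alpha", "alpha_prime", "R0",
    "mu_visc", "Cs", "Cx", "Csmp", "beta1", "beta2", "area_form",
    "st_includes_smp",
)


def to_dict(params: ModelParams) -> dict:
    """Serialize a parameter bundle to a plain dict (pressure in bar)."""
    mem = {k: getattr(params.membrane, k) for k in _MEMBRANE_KEYS}
    mem["deltaP_bar"] = pa_to_bar(params.membrane.delta_P)
    cleaning = {k: v for k, v in asdict(params.cleaning).items()}
    control = {k: getattr(params.control, k) for k in ("km", "kp", "active")}
    return {
        "membrane": mem,
        "am2b": asdict(params.bio),
        "cleaning": cleaning,
        "control": control,
    }


def from_dict(cfg: dict) -> ModelParams:
    """Build a parameter bundle from a config dict (pressure in bar)."""
    mem_cfg = dict(cfg.get("membrane", {}))
    if "deltaP_bar" in mem_cfg:
        mem_cfg["delta_P"] = bar_to_pa(mem_cfg.pop("deltaP_bar"))
    return ModelParams(
        membrane=MembraneParams(**mem_cfg),
        bio=BioParams(**cfg.get("am2b", {})),
        cleaning=CleaningParams(**cfg.get("cleaning", {})),
        control=ControlParams(**cfg.get("control", {})),
    )


def save_config(params: ModelParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(params), fh, sort_keys=False)


def load_config(path: str | Path) -> ModelParams:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))
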