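"""Unit conversions used at the I/O boundary.

Internally the package works in a mixed practical system: time in hours,
volume in litres, mass in grams, area in m², pressure in Pa, viscosity in
Pa·s and hydraulic resistances in 1/m.  Darcy's law is evaluated in SI
(m/s) and converted to the customary permeate-flux unit L/(h·m²) at the
point of use.
"""

#: multiply a flux in m/s by this to get L/(h·m²)
M_PER_S_TO_LHM2 = 3.6e6

#: multiply a pressure in bar by this to get Pa
BAR_TO_PA = 1.0e5

#: hours per minute
MIN_TO_H = 1.0 / 60.0


def flux_si_to_lhm2(j_m_per_s: float) -> float:
    """Convert a permeate flux from m/s to L/(h·m²)."""
    return j_m_per_s * M_PER_S_TO_LHM2


def flux_lhm2_to_si(j_lhm2: float) -> float:
    """Convert a permeate flux from L/(h·m²) to m/s."""
    return j_lhm2 / M_PER_S_TO_LHM2


def bar_to_pa(p_bar: float) -> float:
    return p_bar * BAR_TO_PA


def pa_to_bar(p_pa: float) -> float:
    return p_pa / BAR_TO_PA
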