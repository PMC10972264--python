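# anmbr

Coupled membrane-fouling / anaerobic-digestion simulator for anaerobic
membrane bioreactors (AnMBRs), with parameter calibration and
fouling-control strategy evaluation.

Membrane fouling is the main operational drawback of membrane
bioreactors: matter carried by the permeate stream forms a cake on the
membrane surface and clogs its pores, the flux collapses, and operators
fight back with relaxation/backwash cycles and gas sparging.  This
package implements a deliberately simple, control-oriented model of
that process for people who design operating and control strategies:
process-control and bioprocess engineers, and modelers who need a
fouling model cheap enough to embed in an optimizer.

## The model in brief

Permeation follows a resistance-in-series Darcy law at constant
transmembrane pressure,

    J = ΔP / (μ (R₀ + R)),      R = Rc + Rp,      Qout = J·A,

with two fouling mechanisms: a surface cake of mass m_c
(Rc = α m_c / A) and pore-blocked matter m_p, mostly soluble microbial
products (SMP), acting on the porous fraction ε of the area
(Rp = α′ m_p / (ε A)).  The useful area itself shrinks with both
deposits, A = A₀ / (1 + σ m_c + σ′ m_p).  During filtration the
deposits grow with the mass flow toward the membrane,

    ṁ_c = Qout (Cs·ST + Cx·XT + Csmp·SMP) − km·m_c
    ṁ_p = Qout (β₁·SMP + β₂·ST) − kp·m_p

(km, kp are gas-sparging detachment gains, zero without control);
during relaxation or backwash they decay exponentially toward an
irreversible residual, ṁ = −ω m + m_irr.  The bulk biology is a
two-step anaerobic digestion model (Monod acidogenesis, Haldane
methanogenesis) extended with SMP production and re-consumption; its
concentrations ST, XT, SMP drive the fouling terms, and the membrane's
declining Qout feeds back into the bulk dilution.  See
`docs/methods.md` for the full equations, assumptions and numerical
choices.

## Worked example

Compare intermittent-filtration schedules over a 2 h functioning
period at the packaged control-study operating point:

```python
from anmbr import (control_experiment_config, make_intermittent_schedule,
                   mean_flux, run_schedule)

params, initial = control_experiment_config()
for n in (1, 2, 5, 10):
    schedule = make_intermittent_schedule(n, period=2.0, alpha_t=7.0)
    traj = run_schedule(initial, schedule, params)
    print(f"{n:2d} cycles: Jmean = {mean_flux(traj):5.2f} L/(h*m2)")
```

```
 1 cycles: Jmean = 17.48 L/(h*m2)
 2 cycles: Jmean = 21.03 L/(h*m2)
 5 cycles: Jmean = 27.68 L/(h*m2)
10 cycles: Jmean = 33.94 L/(h*m2)
```

Splitting the same 2 h into more (shorter) filtration/relaxation cycles
at the same 7:1 duty ratio raises the mean produced flux — each
relaxation restores the flux toward its post-irreversible ceiling — but
with diminishing returns, since every cycle pays 12.5% downtime and
leaves an irreversible residue.  The same comparison for control
strategies:

```python
from anmbr import StrategySpec, run_strategy, sweep

specs = [StrategySpec(kind="none", horizon=2.0),
         StrategySpec(kind="gas_sparging", horizon=2.0, km=5.0),
         StrategySpec(kind="combined", horizon=2.0, km=5.0, js=18.0, post_cycles=4)]
table, _ = sweep(specs, initial, params)
print(table[["kind", "Jmean", "terminal_mc", "terminal_mp"]].round(3).to_string(index=False))
```

```
        kind  Jmean  terminal_mc  terminal_mp
        none 18.902        4.751        1.121
gas_sparging 26.293        0.507        2.196
    combined 27.337        0.429        0.226
```

Sparging (km = 5 h⁻¹) strips the cake (terminal m_c drops ninefold) but
routes more solutes into the pores (m_p rises); using it only until the
flux hits the threshold Js = 18 L/(h·m²) and then switching to
relaxation cycles beats either strategy alone.

A command-line interface wraps the same functionality
(`anmbr simulate`, `anmbr calibrate`, `anmbr control`,
`anmbr generate-data`); measurement files are two-column CSVs
(`time_days,value`) and parameter sets are YAML files.

## Calibration

`anmbr.calibration` identifies the fouling weights (Cs, Cx, Csmp, β₁)
from measured flux, total COD and total biomass series, mirroring the
standard pilot procedure: COD is split 85%/15% into substrates and SMP,
the series are interpolated onto a common time base, R₀ is fixed from
the initial flux via R₀ = ΔP/(μ J(0)), and the weights are fitted by
multi-start bound-constrained least squares on the flux.  With SMP
pinned to a fixed COD fraction, Cs and Csmp are only identifiable
through the lump 0.85·Cs + 0.15·Csmp — see `docs/methods.md` for the
identifiability analysis and what the estimator can and cannot recover.
`anmbr.fixtures.generate_dataset` produces synthetic measurement
campaigns (known truth, configurable noise) to exercise the pipeline.

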