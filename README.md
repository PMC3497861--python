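# lungbench

Two-compartment test-lung simulation and expiratory time-constant analysis for
density-dependent (heliox) ventilation studies.

## The problem

In obstructive lung disease, regions of the lung empty at different rates.
The *expiratory time constant* τ quantifies emptying — for a linear
single-compartment lung τ = R·C — and regional differences in τ cause gas
trapping and dynamic hyperinflation. Because the resistance of orifice-like
obstructions (and of ventilator breathing circuits) is inertial,

    ΔP = (k/2) · ρ · Ū²,    Ū = Q/A,

it scales with the gas density ρ: breathing a low-density helium/oxygen
mixture (heliox, 78/22 He/O₂, ρ ≈ 0.42 kg/m³ vs ≈ 1.20 kg/m³ for dry air at
20 °C) lowers these resistances and can speed up regional emptying. But a
ventilator only sees the *total* flow, so its reported time constant (RCexp)
may not reflect what happens in an obstructed compartment.

`lungbench` implements the full modelling toolchain for studying this on a
dual-chamber mechanical test lung:

* **gas_properties** — ideal-gas densities of arbitrary dry mixtures;
* **components** — the quadratic loss law for parabolic resistors
  (Rp5/Rp20/Rp50, k = 3.3/21.5/132.9), entrance-area calibration from the
  published equivalent-resistance table, per-gas polynomial fits
  ΔP = c₁Q + c₂Q² for circuit pressure-flow curves, and an "inertial
  collapse" diagnostic (ΔP vs ρQ² across gases);
* **ventilation** — volume-control breath timing with square inspiratory flow;
* **simulator** — quasi-steady simulation of two compliant chambers venting
  through branch resistors, branch flow sensors and a shared expiratory
  circuit, per the chamber balance
  V_i/C_i = (k_i+k_fs)/2·ρ·(Q_i/A)² + k_cct/2·ρ·((Q_i+Q_j)/A)²,
  with signed flows (pendelluft-capable) and an inspiratory split by common
  Y-piece pressure;
* **time_constants** — breath-summary extraction, the Brunner fixed-point
  iteration for the apparent τ, the ventilator-style RCexp reading, and
  single-compartment closed forms;
* **experiments** — the full study grid (3 obstructions × 3 compliances ×
  2 gases × 2 breathing patterns), resistance-table regeneration, τ-vs-RC
  regressions, and synthetic trace fixtures.

## Worked example

Compare the obstructed (right, Rp50) and healthy (left, Rp5) chamber time
constants for air versus heliox at 1000 ml, 20 breaths/min, C = 0.05 l/cmH₂O:

```python
from lungbench import (VentilatorSettings, apparent_time_constant,
                       build_point_system, simulate, ventilator_rc)

settings = VentilatorSettings(tidal_volume=1.0, rate=20.0, ie_ratio=0.5)
for gas in ("air", "heliox"):
    system = build_point_system(gas, compliance=0.05, right_resistor="Rp50")
    result = simulate(system, settings, n_breaths=10, dt=1e-3, stop_at_steady=True)
    taus = {b: apparent_time_constant(result.breath_summary(b)).tau
            for b in ("right", "left", "whole")}
    rc = ventilator_rc(result.flow_trace("whole"))
    print(f"{gas:7s} tau_right={taus['right']:.2f}s tau_left={taus['left']:.2f}s "
          f"tau_whole={taus['whole']:.2f}s ventilator_RC={rc:.2f}s")
```

prints

```
air     tau_right=2.75s tau_left=0.53s tau_whole=0.82s ventilator_RC=0.64s
heliox  tau_right=1.48s tau_left=0.30s tau_whole=0.46s ventilator_RC=0.40s
```

Heliox roughly halves the obstructed chamber's time constant (2.75 → 1.48 s),
yet the ventilator-style RC moves far less in absolute terms (0.64 → 0.40 s)
and sits much closer to the whole-lung value than to the obstructed
compartment — the obstructed region's behaviour is nearly invisible at the
airway opening.

The same workflow is available from the shell:

```bash
lungbench simulate --config case.yaml --out traces.csv
lungbench taus --trace traces.csv --branch right --method brunner
lungbench calibrate --curve circuit_curve.csv --gas air
lungbench sweep --out results/
```

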