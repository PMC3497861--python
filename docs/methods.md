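# Methods

## Model

The system is a dual-chamber mechanical test lung ventilated in volume
control. Each chamber is a linear compliance C_i (l/cmH₂O) holding a volume
V_i above its relaxed volume, so its recoil pressure is P_i = V_i/C_i. Gas
leaves (or enters) each chamber through a branch consisting of a parabolic
resistor (loss coefficient k_i) and a variable-orifice flow sensor (k_fs),
then both branches merge at a Y-piece into a shared expiratory circuit
(k_cct). Every loss element is inertial:

    ΔP = (k/2) · ρ · (Q/A) · |Q/A|

with a common reference area A and the gas density ρ. The signed form Q|Q|
keeps losses antisymmetric so reverse (pendelluft) flows are representable.
Viscous (density-independent, flow-linear) losses are deliberately absent:
the bench components this model represents are orifice-like, and a circuit
measured to behave otherwise can be supplied as a fitted per-gas polynomial
ΔP = c₁Q + c₂Q² instead of the inertial form.

**Expiration.** With atmospheric pressure as the zero reference, the chamber
balance is

    V_i/C_i = (k_i + k_fs)/2 · ρ (Q_i/A)|Q_i/A|  +  k_cct/2 · ρ ((Q_i+Q_j)/A)|(Q_i+Q_j)/A|,

two coupled equations for the branch flows. For a fixed combined flow
S = Q_L + Q_R the circuit term is known and each branch flow follows by
inverting its signed quadratic, so the system reduces to one monotone scalar
equation g(S) = Q_L(S) + Q_R(S) − S = 0 with a guaranteed bracket
[0, Q_L(0)+Q_R(0)]. A chamber whose recoil falls below the shared circuit
pressure receives *negative* flow — pendelluft from the fast compartment into
the obstructed one. A configuration switch (`clamp_expiratory_inflow`) clamps
branch flows to nonnegative outflow to model strictly independent emptying.

**Inspiration.** The expiratory valve is closed and the ventilator delivers a
constant total flow Q_TOT = V_T/t_I (square wave, I:E fixed, no pause). The
split obeys a common Y-piece pressure: P_aw = V_i/C_i + branch loss(Q_i) on
both sides with Q_L + Q_R = Q_TOT — again one monotone scalar root in P_aw.
Circuit losses upstream of the Y-piece are common to both branches and cannot
affect the split, so they are not modelled during inspiration.

**Time stepping** is quasi-steady explicit Euler: at each step the flows
satisfy the static balance (gas inertia, gas compressibility and the
mechanical inertia/friction of test-lung hardware are neglected), then
V_i ← V_i ± Q_i·dt with a clamp at V = 0. Phase transitions are
instantaneous. The scheme is first order in dt (verified by Richardson
extrapolation); the default dt = 1 ms puts the single-chamber emptying error
at ~0.05% RMS of peak flow. The number of inspiratory steps is
n_I = round(t_I/dt) and the discrete inspiratory flow is V_T/(n_I·dt), so the
inhaled volume per breath equals the set tidal volume exactly (the flow value
differs from V_T/t_I by O(dt/t_I) ≈ 0.02%).

Simulations start from empty chambers (volumes measured above relaxed volume,
recoil zero at V = 0), run a set number of breaths (≥3 recommended), and
report whether a steady cycle was reached: end-expiratory volume change below
0.1 ml per breath. Strongly trapped configurations (high compliance, heavy
obstruction, high minute ventilation, air) need ~8 breaths; everything else
settles by breath 2–3.

## Time-constant estimators

For a linear single-compartment lung, expiratory flow is mono-exponential
with τ = RC. The nonlinear two-compartment system is not mono-exponential, so
an *apparent* τ is computed per compartment (and for the whole lung from the
total flow) by evaluating the mono-exponential volume relation at
end-expiration and iterating the implicit equation:

    τ₀ = V_e,tot/Q_e,p,      τ_{k+1} = τ₀ / (1 − e^{−t_e/τ_k}).

The iterates rise monotonically from τ₀ and converge whenever
V_e,tot < Q_e,p·t_e. The contraction rate is x·e^{−x}/(1−e^{−x}) with
x = t_e/τ, which approaches 1 as τ grows past t_e: for strongly trapped
breaths (τ ≳ 1.5·t_e) the change between iterations 3 and 4 can still exceed
1% even though untrapped breaths converge to <1% in 2–4 iterations. For such
irregular exhalations the estimate is an *index* of compartment emptying, not
a parameter of the flow shape — and, notably, it is not even guaranteed
monotone in the obstruction severity: in the most trapped grid corner
(air, 1000 ml @ 20/min, C = 0.10 l/cmH₂O) the moderately obstructed chamber
scores a *higher* apparent τ than the severely obstructed one, because the
severe obstruction also starves the chamber of tidal volume. At the
moderate compliances (≤0.05 l/cmH₂O) where trapping is mild the index is
monotone in k as expected.

The ventilator-style reading (RCexp) is the ratio of remaining-to-exhale
volume to instantaneous flow at the first instant when 75% of the expiratory
tidal volume remains. The defining phrase "flow at 75% of the tidal volume"
admits several literal readings; this one is the default because it is exact
(returns τ at every instant) for the ideal mono-exponential; the literal
alternatives (tidal volume over flow at 25% or 75% exhaled) are available via
`mode=`. Noisy traces: breath summaries default to the textbook "sample
maximum" peak flow, but `peak_method="initial"` (straight-line intercept over
the first 50 ms) avoids the upward noise bias of a maximum over thousands of
samples; with 2% RMS noise it keeps the mean τ bias below 1%.

Measurement-uncertainty convention for symmetric bench runs: uncertainty is
the maximum |τ_L − τ_R| over configurations with identical resistors in both
branches, where the two should agree exactly.

## Parameters and defaults

| parameter | default | units | status |
|---|---|---|---|
| gas mixtures | air 78/22 N₂/O₂, heliox 78/22 He/O₂ | mole fraction | study condition |
| reference state | 293.15 K, 101 325 Pa | — | assumption (dry room-temperature gas) |
| resistor loss coefficients k | 3.3 / 21.5 / 132.9 | — | published (Rp5/Rp20/Rp50) |
| entrance area A | 8.664×10⁻⁵ (≈10.5 mm bore) | m² | calibrated from the Rp50/air/60 l/min table cell (R = 108.4 cmH₂O·s/l) |
| branch flow-sensor k_fs | 1.2 | — | **assumption**, ~1 cmH₂O at 60 l/min air |
| circuit k_cct | 5.0 | — | **assumption**, ~4 cmH₂O at 60 l/min air |
| compliances | 0.02 / 0.05 / 0.10 | l/cmH₂O | study conditions |
| patterns | 500 ml @ 12/min; 1000 ml @ 20/min; I:E = 1/2 | — | study conditions |
| dt | 0.001 | s | numerical choice (see above) |
| steady tolerance | 0.1 | ml/breath | numerical choice |
| Brunner tol / max_iter | 10⁻⁶ / 50 | — | numerical choice |

A single calibrated area reproduces the full published resistance table: the
high-resolution cells to <0.4%, and all twelve cells to within the larger of
3% and half a unit of the printed one-decimal value (the two smallest heliox
cells, printed 0.3 and 0.9, compute to 0.316 and 0.947 — a 5% relative gap
that is entirely printing resolution, since the heliox/air ratio of every
cell is pinned to the molar-mass ratio 0.3517).

The flow-sensor and circuit coefficients are *not* bench measurements — the
study's fitted circuit polynomials were never published — and the simulated
absolute time constants of obstructed chambers are sensitive to them: for the
heliox/Rp50/C=0.05/1000 ml @ 20/min case the right-chamber apparent τ ranges
from 0.91 s (no sensor or circuit loss at all) through 1.48 s (defaults) to
1.69 s (k_cct = 10, k_fs = 2.4). The quadratic inertial default deliberately
errs on the side of a real, restrictive circuit; a measured pressure-flow
curve (CSV of flow_lpm, dp_cmh2o via `lungbench calibrate`) should replace it
whenever available, because real variable-orifice sensors and expiratory
valves open up with flow and drop less pressure at the >2 l/s flows seen
early in expiration than any fixed-k quadratic.

## Synthetic data

`experiments.make_synthetic_traces` generates the fixtures used by the test
suite: truncated mono-exponentials (known τ), bi-exponentials (known
bracketing components) and simulator-derived expirations, with optional
seeded Gaussian noise scaled to the trace peak. These emulate the *sampled,
noisy* character of bench flow recordings but none of the hardware artifacts
of a real rig — sensor calibration drift, finite valve opening times, or the
mechanical inertia of bellows and top plates that delays phase transitions in
real traces. Passing tests therefore validate the estimators and the
quasi-steady model, not the fidelity of any particular bench.

## Numerical choices

* Scalar root-finds use a damped Newton iteration inside a guaranteed bracket
  with bisection fallback (a Newton step is rejected whenever it would leave
  the bracket or shrink it more slowly than bisection). This matters at the
  pendelluft threshold, where a branch's driving pressure crosses zero and
  the sqrt inversion has unbounded slope; plain Newton oscillates there.
  Convergence is to ~10⁻¹³ relative in flow (pressure residuals far below
  10⁻¹⁰ cmH₂O).
* Zero-volume chambers are handled by flow clamping within the Euler step;
  an empty chamber can still receive pendelluft inflow.
* Degenerate inputs raise typed errors rather than returning NaN: summaries
  with V_e,tot ≥ Q_e,p·t_e (no finite τ), all-zero trace windows, polynomial
  circuit models evaluated for a gas they were not fitted for.
* Exact unit conversion constants (98.0665 Pa/cmH₂O, 10⁻³ m³/l) at the
  interfaces; SI everywhere inside.

## Known limitations

* No gas compressibility, no component inertia or friction: simulated phase
  transitions are instantaneous, and simulated obstructed-chamber time
  constants can exceed idealized model predictions while remaining below
  bench values for rigs with significant moving mass.
* Two compartments only; equal-compliance configurations are the tested
  study conditions (unequal compliance is accepted in configuration but not
  systematically studied).
* The expiratory valve is a fixed loss element: PEEP-dependent valve opening
  is not modelled, and applied PEEP is not supported (volumes are relative to
  the relaxed state at zero end-expiratory pressure).
* Humidified, heated or oxygen-enriched clinical gas properties are out of
  scope; mixtures are dry and ideal.
* Endotracheal tubes and multi-generation airway trees are not modelled.
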