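"""Reproduction of the bench study design as parameter sweeps.

The bench protocol fixed the left-branch resistor at Rp5, varied the
right-branch resistor over {Rp5, Rp20, Rp50}, the (equal) chamber compliances
over {0.02, 0.05, 0.10} l/cmH2O, the gas over {air, heliox 78/22}, and the
breathing pattern over {500 ml @ 12/min, 1000 ml @ 20/min} (I:E = 1/2,
square inspiratory flow). :func:`run_study_grid` simulates every grid point
to a steady cycle and reports, per point, the right/left/whole-lung apparent
time constants (Brunner iteration) and the ventilator-style RC from the
total-flow trace, as a tidy DataFrame ready for plotting or regression.

Synthetic flow traces with known ground truth (mono-exponential,
bi-exponential or simulator-derived) are produced by
:func:`make_synthetic_traces` so that every estimator is testable without any
bench recording.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import units
from .components import RESISTOR_K, CircuitLossModel, make_resistor, reference_area
from .errors import ConfigurationError, FitError, ValidationError
from .gas_properties import AIR, HELIOX, NAMED_MIXTURES, GasMixture, density_ratio
from .simulator import (
    DEFAULT_K_FS,
    Chamber,
    LungSystem,
    default_circuit,
    simulate,
)
from .time_constants import FlowTrace, apparent_time_constant, mono_exponential_trace, ventilator_rc
from .ventilation import VentilatorSettings


@dataclass(frozen=True)
class SweepSpec:
    """The study grid: resistors x compliances x gases x breathing patterns.

    ``patterns`` are (tidal volume l, rate /min) pairs; compliances are equal
    in both chambers; the left resistor is fixed across the grid.
    """

    right_resistors: tuple[str, ...] = ("Rp5", "Rp20", "Rp50")
    left_resistor: str = "Rp5"
    compliances: tuple[float, ...] = (0.02, 0.05, 0.10)
    gases: tuple[str, ...] = ("air", "heliox")
    patterns: tuple[tuple[float, float], ...] = ((0.5, 12.0), (1.0, 20.0))
    ie_ratio: float = 0.5
    sensor_loss_k: float = DEFAULT_K_FS

    def __post_init__(self) -> None:
        if not (self.right_resistors and self.compliances and self.gases and self.patterns):
            raise ValidationError("sweep sets must be nonempty")
        unknown = [r for r in (*self.right_resistors, self.left_resistor) if r not in RESISTOR_K]
        if unknown:
            raise ConfigurationError(f"unknown resistors in sweep: {unknown}")
        for g in self.gases:
            if g not in NAMED_MIXTURES:
                raise ConfigurationError(f"unknown gas {g!r} in sweep")

    def points(self):
        return itertools.product(self.gases, self.patterns, self.compliances, self.right_resistors)


def build_point_system(
    gas: str | GasMixture,
    compliance: float,
    right_resistor: str,
    left_resistor: str = "Rp5",
    circuit: CircuitLossModel | None = None,
    sensor_loss_k: float = DEFAULT_K_FS,
    clamp_expiratory_inflow: bool = False,
) -> LungSystem:
    """LungSystem for one grid point (equal compliances, shared default area)."""
    mixture = NAMED_MIXTURES[gas] if isinstance(gas, str) else gas
    return LungSystem(
        left=Chamber(compliance=compliance, resistor=make_resistor(left_resistor),
                     sensor_loss_k=sensor_loss_k),
        right=Chamber(compliance=compliance, resistor=make_resistor(right_resistor),
                      sensor_loss_k=sensor_loss_k),
        gas=mixture,
        circuit=circuit if circuit is not None else default_circuit(),
        clamp_expiratory_inflow=clamp_expiratory_inflow,
    )


def run_study_grid(
    spec: SweepSpec | None = None,
    circuit: CircuitLossModel | None = None,
    dt: float = 1e-3,
    max_breaths: int = 30,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Simulate every grid point to a steady cycle and summarise it.

    Returns one row per grid point with the three apparent time constants
    (seconds), the ventilator RC from the total-flow trace, peak expiratory
    flows and exhaled volumes, Brunner iteration diagnostics (iteration count
    and the relative change at the fourth iterate), and steady-cycle metadata.
    Per-point simulation or estimation failures are recorded in the ``error``
    column rather than aborting the sweep.
    """
    spec = spec if spec is not None else SweepSpec()
    rows = []
    for gas, (vt, rate), compliance, rp in spec.points():
        row: dict = {
            "gas": gas,
            "tidal_volume_l": vt,
            "rate_bpm": rate,
            "minute_ventilation_lpm": vt * rate,
            "compliance_l_per_cmh2o": compliance,
            "right_resistor": rp,
            "k_right": RESISTOR_K[rp],
            "k_left": RESISTOR_K[spec.left_resistor],
            "error": None,
        }
        try:
            system = build_point_system(
                gas, compliance, rp, spec.left_resistor, circuit,
                sensor_loss_k=spec.sensor_loss_k,
            )
            settings = VentilatorSettings(tidal_volume=vt, rate=rate, ie_ratio=spec.ie_ratio)
            result = simulate(system, settings, n_breaths=max_breaths, dt=dt,
                              stop_at_steady=True)
            row["steady"] = result.steady
            row["breaths_to_steady"] = result.breaths_to_steady
            for branch in ("right", "left", "whole"):
                summary = result.breath_summary(branch)
                est = apparent_time_constant(summary, tol=tol)
                row[f"tau_{branch}_s"] = est.tau
                row[f"iterations_{branch}"] = est.iterations
                row[f"rel_change_iter4_{branch}"] = est.relative_change_at(4)
                row[f"v_exhaled_{branch}_l"] = summary.volume_exhaled
                row[f"q_peak_{branch}_lps"] = summary.peak_flow
            row["rc_ventilator_s"] = ventilator_rc(result.flow_trace("whole"))
        except Exception as exc:  # recorded, not fatal, per sweep contract
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def compare_to_ventilator_rc(result: pd.DataFrame) -> pd.DataFrame:
    """OLS of each compartmental tau series against the ventilator RC.

    Returns one row per branch (right, left, whole) with slope, intercept,
    R^2 and n, mirroring the identity-line comparison of compartment time
    constants with the ventilator's reading. Raises :class:`FitError` for a
    degenerate (constant) series or fewer than 3 points.
    """
    df = result[result["error"].isna()] if "error" in result.columns else result
    if len(df) < 3:
        raise FitError(f"need >= 3 grid points for regression, got {len(df)}")
    x = df["rc_ventilator_s"].to_numpy(float)
    if np.ptp(x) == 0:
        raise FitError("ventilator RC series is constant; regression undefined")
    out = []
    for branch in ("right", "left", "whole"):
        y = df[f"tau_{branch}_s"].to_numpy(float)
        if np.ptp(y) == 0:
            raise FitError(f"tau_{branch} series is constant; regression undefined")
        fit = stats.linregress(x, y)
        out.append(
            {
                "branch": branch,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.rvalue**2,
                "n": len(df),
            }
        )
    return pd.DataFrame(out)


def regenerate_table1(
    gases: tuple[GasMixture, GasMixture] = (AIR, HELIOX),
    flows_lpm: tuple[float, ...] = (20.0, 60.0),
    resistors: dict[str, float] | None = None,
    area: float | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Equivalent-linear-resistance table (both gases x flows x resistors).

    One row per (resistor, flow, gas) with the loss coefficient, the computed
    R in cmH2O s/l, and R rounded to the table's printed precision. The area
    defaults to the shared calibrated entrance area.
    """
    from .components import ParabolicResistor, equivalent_linear_resistance

    resistors = resistors if resistors is not None else dict(RESISTOR_K)
    area = area if area is not None else reference_area()
    rows = []
    for name, k in resistors.items():
        r = ParabolicResistor(k=k, area=area)
        for q_lpm in flows_lpm:
            for gas in gases:
                value = equivalent_linear_resistance(r, gas, units.lpm_to_m3s(q_lpm))
                rows.append(
                    {
                        "resistor": name,
                        "k": k,
                        "flow_lpm": q_lpm,
                        "gas": gas.key,
                        "R_cmh2o_s_per_l": value,
                        "R_rounded": round(value, decimals),
                    }
                )
    return pd.DataFrame(rows)


def make_synthetic_traces(
    kind: str = "mono",
    noise_frac: float = 0.0,
    seed: int | None = 0,
    **params,
) -> tuple[FlowTrace, dict]:
    """Reproducible flow-trace fixtures with known ground truth.

    kinds
    -----
    ``"mono"``: Q(t) = q_p exp(-t/tau); params q_p, tau, t_e, dt. Truth: tau.
    ``"bi"``: sum of two exponentials; params q1, tau1, q2, tau2, t_e, dt.
    ``"simulated"``: right-branch expiration of a study grid point; params
        gas, compliance, right_resistor, tidal_volume, rate, dt, branch.

    ``noise_frac`` adds zero-mean Gaussian noise with standard deviation
    noise_frac * max|Q|, seeded by ``seed``. Returns (trace, truth-dict).
    """
    if kind == "mono":
        q_p = params.get("q_p", 1.0)
        tau = params.get("tau", 0.5)
        t_e = params.get("t_e", 2.0)
        dt = params.get("dt", 1e-3)
        trace = mono_exponential_trace(q_p, tau, t_e, dt)
        truth = {"tau": tau, "q_p": q_p, "t_e": t_e}
    elif kind == "bi":
        q1 = params.get("q1", 1.0)
        tau1 = params.get("tau1", 0.15)
        q2 = params.get("q2", 0.5)
        tau2 = params.get("tau2", 1.2)
        t_e = params.get("t_e", 3.0)
        dt = params.get("dt", 1e-3)
        n = int(round(t_e / dt))
        t = np.arange(n + 1) * dt
        trace = FlowTrace(t, q1 * np.exp(-t / tau1) + q2 * np.exp(-t / tau2))
        truth = {"tau1": tau1, "tau2": tau2, "q1": q1, "q2": q2, "t_e": t_e}
    elif kind == "simulated":
        gas = params.get("gas", "heliox")
        compliance = params.get("compliance", 0.05)
        rp = params.get("right_resistor", "Rp50")
        vt = params.get("tidal_volume", 1.0)
        rate = params.get("rate", 20.0)
        dt = params.get("dt", 1e-3)
        branch = params.get("branch", "right")
        system = build_point_system(gas, compliance, rp)
        settings = VentilatorSettings(tidal_volume=vt, rate=rate)
        result = simulate(system, settings, n_breaths=10, dt=dt, stop_at_steady=True)
        trace = result.flow_trace(branch)
        truth = {
            "gas": gas,
            "compliance": compliance,
            "right_resistor": rp,
            "tidal_volume": vt,
            "rate": rate,
            "branch": branch,
            "tau_brunner": apparent_time_constant(result.breath_summary(branch)).tau,
        }
    else:
        raise ConfigurationError(f"unknown synthetic trace kind {kind!r}")
    if noise_frac > 0.0:
        rng = np.random.default_rng(seed)
        sigma = noise_frac * float(np.max(np.abs(trace.flows)))
        trace = FlowTrace(trace.times, trace.flows + rng.normal(0.0, sigma, trace.flows.shape),
                          trace.phases)
        truth["noise_sigma_lps"] = sigma
    return trace, truth


def heliox_air_resistance_ratio() -> float:
    """Density ratio heliox/air at the shared reference state (~0.352)."""
    return density_ratio(HELIOX, AIR)
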