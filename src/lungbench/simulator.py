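"""Quasi-steady simulation of a two-compartment test lung.

Each compartment is a linear compliance C_i holding volume V_i above its
relaxed volume, vented through its own parabolic resistor (loss coefficient
k_i) and branch flow sensor (k_fs), then through a shared expiratory circuit
(k_cct or a fitted per-gas polynomial). With atmospheric pressure taken as
zero, the governing balance for chamber i during expiration is

    V_i / C_i = (k_i + k_fs)/2 * rho * (Q_i/A) |Q_i/A|
                + k_cct/2 * rho * ((Q_i+Q_j)/A) |(Q_i+Q_j)/A|,

a pair of coupled signed-quadratic equations for the branch flows (Q_j is the
opposite chamber's flow). During inspiration the expiratory valve is closed,
the ventilator delivers a constant total flow, and the split between branches
is set by a common airway (Y-piece) pressure: each chamber's recoil plus its
branch loss must equal that pressure while the branch flows sum to the set
total. Both solves reduce to one monotone scalar root-find (in the combined
expiratory flow, or in the airway pressure) handled by a safeguarded Newton
iteration inside a guaranteed bracket, with bisection as fallback.

Time stepping is quasi-steady explicit Euler: flows satisfy the static
balance at each instant (gas inertia, compressibility and component friction
neglected), volumes are advanced by V_i <- V_i +/- Q_i*dt and clamped at
zero, and phase transitions are instantaneous. Negative (pendelluft) branch
flows during expiration are permitted by default — the shared circuit loss
can drive gas from the fast compartment into the obstructed one — and can be
clamped to nonnegative outflow via ``clamp_expiratory_inflow`` to model
strictly independent emptying.

Internally everything is SI; public interfaces use litres, l/s and cmH2O.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .components import (
    CircuitLossModel,
    ParabolicResistor,
    reference_area,
)
from .errors import DomainError, NumericalError, ValidationError
from .gas_properties import AIR, GasMixture, mixture_density
from .time_constants import BreathSummary, FlowTrace
from .ventilation import VentilatorSettings, breath_timing

#: Assumed loss coefficient of one branch variable-orifice flow sensor
#: (referenced to the shared entrance area). An assumption, not a bench
#: measurement: chosen so the sensor drops ~1 cmH2O at 60 l/min of air.
DEFAULT_K_FS: float = 1.2

#: Assumed loss coefficient of the shared expiratory circuit (tubing,
#: Y-piece, expiratory valve), referenced to the shared entrance area; an
#: assumption giving ~4 cmH2O at 60 l/min of air, comparable to (slightly
#: above) an Rp5, consistent with circuit losses being significant next to
#: low airway resistance.
DEFAULT_K_CCT: float = 5.0


def default_circuit() -> CircuitLossModel:
    """Bundled inertial circuit model with the assumed k_cct."""
    return CircuitLossModel(form="inertial", k=DEFAULT_K_CCT)


@dataclass
class Chamber:
    """One compliant compartment and its branch losses.

    compliance : l/cmH2O (> 0); volume : l above relaxed volume (>= 0);
    resistor : the branch parabolic resistor; sensor_loss_k : dimensionless
    loss coefficient of the branch flow sensor, referenced to the shared area.
    """

    compliance: float
    resistor: ParabolicResistor
    sensor_loss_k: float = DEFAULT_K_FS
    volume: float = 0.0

    def __post_init__(self) -> None:
        if not self.compliance > 0:
            raise ValidationError(f"compliance must be > 0, got {self.compliance}")
        if self.volume < 0:
            raise ValidationError(f"volume must be >= 0, got {self.volume}")
        if self.sensor_loss_k < 0:
            raise ValidationError("sensor loss coefficient must be >= 0")

    @property
    def pressure(self) -> float:
        """Elastic recoil V/C, cmH2O."""
        return self.volume / self.compliance


@dataclass
class LungSystem:
    """Two chambers, a shared circuit, one gas, one reference area.

    ``area`` defaults to the entrance area calibrated from the resistance
    table; ``time`` is the breath clock used by :func:`advance`.
    """

    left: Chamber
    right: Chamber
    gas: GasMixture = AIR
    circuit: CircuitLossModel = field(default_factory=default_circuit)
    area: float | None = None
    clamp_expiratory_inflow: bool = False
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.area is None:
            self.area = reference_area()
        if not self.area > 0:
            raise ValidationError(f"area must be > 0, got {self.area}")


# ---------------------------------------------------------------------------
# scalar root-finding core


def _signed_flow(driving: float, a: float) -> float:
    """Invert dP = a*Q|Q|: Q = sign(dP)*sqrt(|dP|/a)."""
    if driving == 0.0:
        return 0.0
    return math.copysign(math.sqrt(abs(driving) / a), driving)


def _rtsafe(eval_fg, lo: float, hi: float, xtol: float, gtol: float,
            max_iter: int = 100) -> float:
    """Bracketed root of a monotone increasing h with h(lo) < 0 < h(hi).

    Damped Newton with bisection fallback: a Newton step is rejected in favour
    of bisection whenever it would leave the bracket or fail to shrink it as
    fast as bisection would (the sqrt inversion of the signed-quadratic loss
    has an unbounded derivative at zero driving pressure, where plain Newton
    oscillates). ``eval_fg(x)`` returns (h, dh/dx).
    """
    x = 0.5 * (lo + hi)
    dxold = abs(hi - lo)
    dx = dxold
    g, dg = eval_fg(x)
    for _ in range(max_iter):
        if abs(g) <= gtol:
            return x
        if g < 0.0:
            lo = x
        else:
            hi = x
        if hi - lo <= xtol:
            return 0.5 * (lo + hi)
        newton_bad = (
            dg == 0.0
            or ((x - hi) * dg - g) * ((x - lo) * dg - g) > 0.0
            or abs(2.0 * g) > abs(dxold * dg)
        )
        dxold = dx
        if newton_bad:
            dx = 0.5 * (hi - lo)
            x = lo + dx
        else:
            dx = g / dg
            x -= dx
        g, dg = eval_fg(x)
    raise NumericalError("bracketed Newton did not converge")


class _Engine:
    """SI-unit working state and per-step solvers for one system."""

    __slots__ = ("rho", "area", "a_left", "a_right", "c_left", "c_right",
                 "v_left", "v_right", "cc1", "cc2", "clamp")

    def __init__(self, system: LungSystem):
        self.rho = mixture_density(system.gas)
        self.area = float(system.area)
        a2 = self.area * self.area
        self.a_left = (system.left.resistor.k + system.left.sensor_loss_k) * self.rho / (2 * a2)
        self.a_right = (system.right.resistor.k + system.right.sensor_loss_k) * self.rho / (2 * a2)
        self.c_left = units.compliance_to_si(system.left.compliance)
        self.c_right = units.compliance_to_si(system.right.compliance)
        self.v_left = units.l_to_m3(system.left.volume)
        self.v_right = units.l_to_m3(system.right.volume)
        self.cc1, self.cc2 = system.circuit.coefficients_for(system.gas)
        if self.cc1 < 0 or self.cc2 < 0:
            raise ValidationError(
                "circuit loss must be nondecreasing in flow (c1, c2 >= 0)"
            )
        self.clamp = system.clamp_expiratory_inflow

    # -- circuit loss ------------------------------------------------------
    def _lc(self, s: float) -> float:
        return self.cc1 * s + self.cc2 * s * abs(s)

    def _dlc(self, s: float) -> float:
        return self.cc1 + 2.0 * self.cc2 * abs(s)

    # -- expiratory solve ---------------------------------------------------
    def expiratory_flows(self) -> tuple[float, float]:
        """Simultaneous branch flows (m^3/s, out of chamber positive)."""
        p_l = self.v_left / self.c_left
        p_r = self.v_right / self.c_right
        q0_l = _signed_flow(p_l, self.a_left)
        q0_r = _signed_flow(p_r, self.a_right)
        s_hi = q0_l + q0_r
        if s_hi <= 0.0:
            return 0.0, 0.0
        if self.cc1 == 0.0 and self.cc2 == 0.0:
            return q0_l, q0_r  # decoupled chambers
        s = self._solve_combined(p_l, p_r, s_hi)
        lc = self._lc(s)
        q_l = _signed_flow(p_l - lc, self.a_left)
        q_r = _signed_flow(p_r - lc, self.a_right)
        if self.clamp:
            if q_l < 0.0:
                q_l, q_r = 0.0, self._single_branch(p_r, self.a_right)
            elif q_r < 0.0:
                q_r, q_l = 0.0, self._single_branch(p_l, self.a_left)
        return q_l, q_r

    def _solve_combined(self, p_l: float, p_r: float, s_hi: float) -> float:
        """Root of g(S) = Q_l(S) + Q_r(S) - S on [0, s_hi]; g is decreasing."""

        def eval_fg(s: float):  # negated so the function increases with S
            lc = self._lc(s)
            d_l, d_r = p_l - lc, p_r - lc
            g = _signed_flow(d_l, self.a_left) + _signed_flow(d_r, self.a_right) - s
            dq = 0.0
            if d_l != 0.0:
                dq += 0.5 / math.sqrt(self.a_left * abs(d_l))
            if d_r != 0.0:
                dq += 0.5 / math.sqrt(self.a_right * abs(d_r))
            dg = -self._dlc(s) * dq - 1.0
            return -g, -dg

        try:
            return _rtsafe(eval_fg, 0.0, s_hi, xtol=1e-15 * s_hi, gtol=1e-13 * s_hi)
        except NumericalError:
            raise NumericalError(
                f"expiratory flow solve did not converge (p_l={p_l:g} Pa, p_r={p_r:g} Pa)"
            ) from None

    def _single_branch(self, p: float, a: float) -> float:
        """One chamber venting alone: a*Q^2 + cc1*Q + cc2*Q^2 = p, Q >= 0."""
        if p <= 0.0:
            return 0.0
        aa = a + self.cc2
        return (-self.cc1 + math.sqrt(self.cc1 * self.cc1 + 4.0 * aa * p)) / (2.0 * aa)

    # -- inspiratory split --------------------------------------------------
    def inspiratory_split(self, q_tot: float) -> tuple[float, float]:
        """Branch inflows (m^3/s, into chamber positive) summing to q_tot."""
        if q_tot < 0.0:
            raise DomainError(f"inspiratory total flow must be >= 0, got {q_tot}")
        p_l = self.v_left / self.c_left
        p_r = self.v_right / self.c_right
        if q_tot == 0.0 and p_l == p_r:
            return 0.0, 0.0
        lo = min(p_l, p_r)
        hi = max(p_l, p_r) + max(self.a_left, self.a_right) * q_tot * q_tot + 1e-9
        paw = self._solve_airway_pressure(p_l, p_r, q_tot, lo, hi)
        q_l = _signed_flow(paw - p_l, self.a_left)
        return q_l, q_tot - q_l

    def _solve_airway_pressure(
        self, p_l: float, p_r: float, q_tot: float, lo: float, hi: float
    ) -> float:
        """Root of g(P) = Q_l(P) + Q_r(P) - q_tot; g is increasing in P."""
        scale = max(q_tot, _signed_flow(hi - lo, min(self.a_left, self.a_right)), 1e-12)

        def eval_fg(paw: float):
            d_l, d_r = paw - p_l, paw - p_r
            g = _signed_flow(d_l, self.a_left) + _signed_flow(d_r, self.a_right) - q_tot
            dg = 0.0
            if d_l != 0.0:
                dg += 0.5 / math.sqrt(self.a_left * abs(d_l))
            if d_r != 0.0:
                dg += 0.5 / math.sqrt(self.a_right * abs(d_r))
            return g, dg

        try:
            return _rtsafe(eval_fg, lo, hi, xtol=1e-15 * max(hi - lo, 1.0),
                           gtol=1e-13 * scale)
        except NumericalError:
            raise NumericalError("inspiratory split solve did not converge") from None

    # -- state I/O ----------------------------------------------------------
    def write_back(self, system: LungSystem) -> None:
        system.left.volume = units.m3_to_l(self.v_left)
        system.right.volume = units.m3_to_l(self.v_right)


# ---------------------------------------------------------------------------
# public solver wrappers (clinical units)


def solve_inspiratory_split(system: LungSystem, q_tot: float) -> tuple[float, float]:
    """Split a total inspiratory flow (l/s) between the branches, l/s each.

    The branch inflows satisfy a common Y-piece pressure (recoil plus signed
    branch loss equal on both sides) and sum to ``q_tot`` exactly. A branch
    may receive negative flow (pendelluft: one chamber discharging into the
    other) when recoils are sufficiently unequal.
    """
    eng = _Engine(system)
    q_l, q_r = eng.inspiratory_split(units.lps_to_m3s(q_tot))
    return units.m3s_to_lps(q_l), units.m3s_to_lps(q_r)


def solve_expiratory_flows(system: LungSystem) -> tuple[float, float]:
    """Simultaneous expiratory branch flows (l/s, out of chamber positive)."""
    eng = _Engine(system)
    q_l, q_r = eng.expiratory_flows()
    return units.m3s_to_lps(q_l), units.m3s_to_lps(q_r)


# ---------------------------------------------------------------------------
# time stepping


@dataclass(frozen=True)
class StepRecord:
    time: float
    phase: str
    q_left: float  # l/s, out of chamber positive
    q_right: float


def advance(system: LungSystem, settings: VentilatorSettings, dt: float) -> StepRecord:
    """Advance the system state by one explicit Euler step of length ``dt``.

    The phase is read from the system's breath clock: inspiration while
    (time mod period) < t_insp, expiration otherwise. Volumes are updated by
    the quasi-steady flows and clamped at zero; the clock advances by ``dt``.
    Returns the flows used for the step (out-of-chamber positive, so
    inspiratory inflows appear negative).
    """
    if not dt > 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    timing = breath_timing(settings)
    tb = math.fmod(system.time, timing.period)
    eng = _Engine(system)
    if tb < timing.t_insp - 1e-12:
        q_tot = units.lps_to_m3s(settings.tidal_volume / timing.t_insp)
        q_l, q_r = eng.inspiratory_split(q_tot)
        q_l, q_r = _apply_volume_step(eng, -q_l, -q_r, dt)
        phase = "I"
    else:
        q_l, q_r = eng.expiratory_flows()
        q_l, q_r = _apply_volume_step(eng, q_l, q_r, dt)
        phase = "E"
    eng.write_back(system)
    rec = StepRecord(
        time=system.time,
        phase=phase,
        q_left=units.m3s_to_lps(q_l),
        q_right=units.m3s_to_lps(q_r),
    )
    system.time += dt
    return rec


def _apply_volume_step(eng: _Engine, q_out_l: float, q_out_r: float, dt: float):
    """Euler update with zero-volume clamp. Flows are out-of-chamber positive."""
    if q_out_l * dt > eng.v_left:
        q_out_l = eng.v_left / dt
    if q_out_r * dt > eng.v_right:
        q_out_r = eng.v_right / dt
    eng.v_left -= q_out_l * dt
    eng.v_right -= q_out_r * dt
    return q_out_l, q_out_r


@dataclass(frozen=True)
class BreathRecord:
    """Index bounds and per-breath bookkeeping inside a simulation."""

    index: int
    insp_slice: tuple[int, int]
    exp_slice: tuple[int, int]
    t_exp: float
    v_exhaled_left: float
    v_exhaled_right: float
    end_expiratory_left: float
    end_expiratory_right: float


@dataclass
class SimulationResult:
    """Recorded traces and per-breath summaries of one simulation.

    Flows are l/s, out-of-chamber positive (inspiratory samples are negative);
    volumes are litres above relaxed volume; pressures are chamber recoils in
    cmH2O. ``steady`` reports whether the end-expiratory volumes changed by
    less than the steady tolerance between the last two breaths.
    """

    time: np.ndarray
    phase: np.ndarray
    q_left: np.ndarray
    q_right: np.ndarray
    q_total: np.ndarray
    v_left: np.ndarray
    v_right: np.ndarray
    p_left: np.ndarray
    p_right: np.ndarray
    dt: float
    breaths: list[BreathRecord]
    steady: bool
    breaths_to_steady: int | None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "phase": self.phase,
                "q_left_lps": self.q_left,
                "q_right_lps": self.q_right,
                "q_total_lps": self.q_total,
                "v_left_l": self.v_left,
                "v_right_l": self.v_right,
                "p_left_cmh2o": self.p_left,
                "p_right_cmh2o": self.p_right,
            }
        )

    def _branch_flow(self, branch: str) -> np.ndarray:
        try:
            return {"left": self.q_left, "right": self.q_right, "whole": self.q_total}[branch]
        except KeyError:
            raise DomainError(f"branch must be left/right/whole, got {branch!r}") from None

    def flow_trace(self, branch: str = "right", breath: int = -1) -> FlowTrace:
        """Expiratory-phase flow trace of one breath (expiratory-positive)."""
        rec = self.breaths[breath]
        i0, i1 = rec.exp_slice
        q = self._branch_flow(branch)[i0:i1]
        t = self.time[i0:i1]
        return FlowTrace(t - t[0], q, np.full(q.shape, "E"))

    def breath_summary(self, branch: str = "right", breath: int = -1) -> BreathSummary:
        """Expiratory tidal volume, peak flow and duration of one breath.

        Volumes come from the chamber-volume balance (exactly consistent with
        the Euler quadrature of the flows); the peak is the recorded maximum.
        """
        rec = self.breaths[breath]
        i0, i1 = rec.exp_slice
        if branch == "left":
            volume = rec.v_exhaled_left
        elif branch == "right":
            volume = rec.v_exhaled_right
        elif branch == "whole":
            volume = rec.v_exhaled_left + rec.v_exhaled_right
        else:
            raise DomainError(f"branch must be left/right/whole, got {branch!r}")
        peak = float(np.max(self._branch_flow(branch)[i0:i1]))
        return BreathSummary(volume_exhaled=volume, peak_flow=peak, duration=rec.t_exp)


def simulate(
    system: LungSystem,
    settings: VentilatorSettings,
    n_breaths: int = 6,
    dt: float = 1e-3,
    stop_at_steady: bool = False,
    steady_tol: float = 1e-4,
) -> SimulationResult:
    """Run ``n_breaths`` breaths of quasi-steady ventilation.

    The caller's system is not mutated. Step counts per phase are
    n_i = round(t_insp/dt) and n_e = round(t_exp/dt); the discrete inspiratory
    flow is tidal_volume/(n_i*dt) so the inhaled volume per breath equals the
    set tidal volume exactly. ``steady_tol`` (litres) is the per-breath
    end-expiratory volume change below which the cycle is declared steady
    (default 0.1 ml). With ``stop_at_steady`` the run ends at the first steady
    breath.
    """
    if n_breaths < 1:
        raise DomainError("n_breaths must be >= 1")
    if not dt > 0:
        raise DomainError("dt must be > 0")
    system = copy.deepcopy(system)
    eng = _Engine(system)
    timing = breath_timing(settings)
    n_i = max(1, round(timing.t_insp / dt))
    n_e = max(1, round(timing.t_exp / dt))
    q_tot = units.lps_to_m3s(settings.tidal_volume) / (n_i * dt)

    times: list[float] = []
    phases: list[str] = []
    ql: list[float] = []
    qr: list[float] = []
    vl: list[float] = []
    vr: list[float] = []
    breaths: list[BreathRecord] = []
    eev_prev: tuple[float, float] | None = None
    steady = False
    breaths_to_steady: int | None = None
    t0 = system.time

    for b in range(n_breaths):
        base = t0 + b * (n_i + n_e) * dt
        i_start = len(times)
        for s in range(n_i):
            q_out_l, q_out_r = eng.inspiratory_split(q_tot)
            q_out_l, q_out_r = -q_out_l, -q_out_r
            times.append(base + s * dt)
            phases.append("I")
            vl.append(eng.v_left)
            vr.append(eng.v_right)
            q_out_l, q_out_r = _apply_volume_step(eng, q_out_l, q_out_r, dt)
            ql.append(q_out_l)
            qr.append(q_out_r)
        e_start = len(times)
        v_l_start, v_r_start = eng.v_left, eng.v_right
        for s in range(n_e):
            q_out_l, q_out_r = eng.expiratory_flows()
            times.append(base + (n_i + s) * dt)
            phases.append("E")
            vl.append(eng.v_left)
            vr.append(eng.v_right)
            q_out_l, q_out_r = _apply_volume_step(eng, q_out_l, q_out_r, dt)
            ql.append(q_out_l)
            qr.append(q_out_r)
        e_end = len(times)
        eev = (eng.v_left, eng.v_right)
        breaths.append(
            BreathRecord(
                index=b + 1,
                insp_slice=(i_start, e_start),
                exp_slice=(e_start, e_end),
                t_exp=n_e * dt,
                v_exhaled_left=units.m3_to_l(v_l_start - eev[0]),
                v_exhaled_right=units.m3_to_l(v_r_start - eev[1]),
                end_expiratory_left=units.m3_to_l(eev[0]),
                end_expiratory_right=units.m3_to_l(eev[1]),
            )
        )
        if eev_prev is not None and not steady:
            dv = max(abs(eev[0] - eev_prev[0]), abs(eev[1] - eev_prev[1]))
            if units.m3_to_l(dv) < steady_tol:
                steady = True
                breaths_to_steady = b + 1
        eev_prev = eev
        if steady and stop_at_steady:
            break

    eng.write_back(system)
    t = np.asarray(times)
    q_left = np.asarray(ql) / units.LPS_M3S
    q_right = np.asarray(qr) / units.LPS_M3S
    v_left = np.asarray(vl) / units.L_M3
    v_right = np.asarray(vr) / units.L_M3
    return SimulationResult(
        time=t,
        phase=np.asarray(phases),
        q_left=q_left,
        q_right=q_right,
        q_total=q_left + q_right,
        v_left=v_left,
        v_right=v_right,
        p_left=v_left / system.left.compliance,
        p_right=v_right / system.right.compliance,
        dt=dt,
        breaths=breaths,
        steady=steady,
        breaths_to_steady=breaths_to_steady,
    )


def run_expiration(system: LungSystem, duration: float, dt: float = 1e-3) -> SimulationResult:
    """Expire from the system's current volumes for ``duration`` seconds.

    Useful for comparing the stepper against closed-form emptying solutions
    without a preceding inspiration. The caller's system is not mutated.
    """
    if not (duration > 0 and dt > 0):
        raise DomainError("duration and dt must be > 0")
    system = copy.deepcopy(system)
    eng = _Engine(system)
    n = max(1, round(duration / dt))
    times, ql, qr, vl, vr = [], [], [], [], []
    for s in range(n):
        q_out_l, q_out_r = eng.expiratory_flows()
        times.append(s * dt)
        vl.append(eng.v_left)
        vr.append(eng.v_right)
        q_out_l, q_out_r = _apply_volume_step(eng, q_out_l, q_out_r, dt)
        ql.append(q_out_l)
        qr.append(q_out_r)
    v_l0 = system.left.volume
    v_r0 = system.right.volume
    rec = BreathRecord(
        index=1,
        insp_slice=(0, 0),
        exp_slice=(0, n),
        t_exp=n * dt,
        v_exhaled_left=v_l0 - units.m3_to_l(eng.v_left),
        v_exhaled_right=v_r0 - units.m3_to_l(eng.v_right),
        end_expiratory_left=units.m3_to_l(eng.v_left),
        end_expiratory_right=units.m3_to_l(eng.v_right),
    )
    t = np.asarray(times)
    q_left = np.asarray(ql) / units.LPS_M3S
    q_right = np.asarray(qr) / units.LPS_M3S
    v_left = np.asarray(vl) / units.L_M3
    v_right = np.asarray(vr) / units.L_M3
    return SimulationResult(
        time=t,
        phase=np.full(t.shape, "E"),
        q_left=q_left,
        q_right=q_right,
        q_total=q_left + q_right,
        v_left=v_left,
        v_right=v_right,
        p_left=v_left / system.left.compliance,
        p_right=v_right / system.right.compliance,
        dt=dt,
        breaths=[rec],
        steady=False,
        breaths_to_steady=None,
    )


def single_chamber_emptying_closed_form(
    compliance: float,
    k_tot: float,
    area: float,
    gas: GasMixture,
    v0: float,
    dt: float = 1e-3,
) -> tuple[float, FlowTrace]:
    """Analytic emptying of one chamber through a purely quadratic loss.

    With P = V/C = (k_tot/2) rho (Q/A)^2 the volume obeys
    dV/dt = -A sqrt(2 V / (C rho k_tot)), so sqrt(V) decreases linearly,
    the flow decays *linearly* in time, and the chamber empties at

        t_empty = sqrt(2 * V0 * C * rho * k_tot) / A.

    Inputs in clinical units (compliance l/cmH2O, v0 litres); returns
    (t_empty seconds, sampled flow trace in l/s on [0, t_empty]).
    """
    if not (compliance > 0 and k_tot > 0 and area > 0 and v0 > 0 and dt > 0):
        raise DomainError("all closed-form parameters must be positive")
    rho = mixture_density(gas)
    c_si = units.compliance_to_si(compliance)
    v0_si = units.l_to_m3(v0)
    t_empty = math.sqrt(2.0 * v0_si * c_si * rho * k_tot) / area
    q0 = 2.0 * v0_si / t_empty  # == A * sqrt(2 V0 / (C rho k_tot))
    n = int(math.floor(t_empty / dt))
    t = np.arange(n + 1) * dt
    q = np.maximum(q0 * (1.0 - t / t_empty), 0.0)
    return t_empty, FlowTrace(t, q / units.LPS_M3S)
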