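"""Expiratory time constants from flow traces.

For a linear single-compartment lung, expiratory flow is mono-exponential,

    Q_e(t) = Q_ep * exp(-t / tau),     V_e(t) = tau * Q_ep * (1 - exp(-t/tau)),

and tau = R*C. Real (and simulated nonlinear two-compartment) exhalations are
not mono-exponential; an *apparent* time constant is then defined implicitly
by evaluating the volume relation at end-expiration,

    tau = (V_e,tot / Q_ep) * (1 - exp(-t_e/tau))^(-1),

and solving by fixed-point iteration from tau_0 = V_e,tot / Q_ep (the Brunner
method). The iterates are monotone nondecreasing and bounded, so the scheme
converges for any summary with V_e,tot < Q_ep * t_e. For irregular,
non-mono-exponential exhalations the result is best read as an index of
compartment emptying rather than a parameter of the flow shape.

The module also implements the ventilator-style "RCexp" reading: the ratio of
remaining-to-exhale volume to instantaneous flow at the instant when 75% of
the expiratory tidal volume remains to be exhaled. For an ideal
mono-exponential that ratio equals tau at every instant (flow-volume
linearity), so the reading is exact in the single-compartment limit;
alternative literal readings of the defining phrase are available via
``mode``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import DomainError, EstimationError, ExtractionError, ValidationError

_UNIFORM_TOL = 1e-9


@dataclass(frozen=True)
class FlowTrace:
    """A uniformly sampled flow-versus-time signal.

    ``flows`` are in l/s, expiratory-positive within an expiration segment.
    ``phases`` (optional) labels each sample 'I' or 'E'.
    """

    times: np.ndarray
    flows: np.ndarray
    phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flows", q)
        if t.ndim != 1 or t.size < 2 or q.shape != t.shape:
            raise ValidationError("trace needs 1-D times and flows of equal length >= 2")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(q))):
            raise ValidationError("trace contains non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _UNIFORM_TOL:
            raise ValidationError("times must be uniformly spaced within 1e-9 s")
        if self.phases is not None:
            ph = np.asarray(self.phases)
            object.__setattr__(self, "phases", ph)
            if ph.shape != t.shape:
                raise ValidationError("phase labels must match trace length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def window(self, t0: float, t1: float) -> "FlowTrace":
        """Sub-trace with t0 <= t <= t1 (inclusive, sample-aligned)."""
        mask = (self.times >= t0 - 1e-12) & (self.times <= t1 + 1e-12)
        if int(mask.sum()) < 2:
            raise ExtractionError(f"window [{t0}, {t1}] contains fewer than 2 samples")
        ph = self.phases[mask] if self.phases is not None else None
        return FlowTrace(self.times[mask], self.flows[mask], ph)

    def expiration_windows(self, threshold_frac: float = 0.01) -> list[tuple[float, float]]:
        """(t0, t1) spans of expiratory segments.

        Uses phase labels when present; otherwise segments are detected as
        runs of flow above a hysteresis threshold (``threshold_frac`` of the
        trace's absolute peak), which tolerates noise around zero crossings.
        """
        if self.phases is not None:
            exp = np.asarray(self.phases) == "E"
        else:
            peak = float(np.max(np.abs(self.flows)))
            if peak == 0.0:
                raise ExtractionError("all-zero trace; no expiration detectable")
            exp = self.flows > threshold_frac * peak
        edges = np.flatnonzero(np.diff(exp.astype(int)))
        starts = [0] if exp[0] else []
        starts += [int(i) + 1 for i in edges if not exp[i] and exp[i + 1]]
        ends = [int(i) for i in edges if exp[i] and not exp[i + 1]]
        if exp[-1]:
            ends.append(len(exp) - 1)
        return [
            (float(self.times[s]), float(self.times[e]))
            for s, e in zip(starts, ends)
            if e > s
        ]

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        flow_column: str,
        time_column: str = "time_s",
        phase_column: str | None = "phase",
    ) -> "FlowTrace":
        df = pd.read_csv(path, comment="#")
        if flow_column not in df.columns:
            raise ExtractionError(f"no column {flow_column!r} in {path}")
        phases = None
        if phase_column and phase_column in df.columns:
            phases = df[phase_column].to_numpy()
        return cls(df[time_column].to_numpy(float), df[flow_column].to_numpy(float), phases)


@dataclass(frozen=True)
class BreathSummary:
    """Scalars extracted from one expiration.

    volume_exhaled (l), peak_flow (l/s) and duration (s) must be positive and
    satisfy volume_exhaled <= peak_flow * duration (flow bounded by its peak).
    """

    volume_exhaled: float
    peak_flow: float
    duration: float

    def __post_init__(self) -> None:
        if not (self.volume_exhaled > 0 and self.peak_flow > 0 and self.duration > 0):
            raise ValidationError(
                "breath summary requires positive exhaled volume, peak flow and duration"
            )
        if self.volume_exhaled > self.peak_flow * self.duration * (1 + 1e-12):
            raise ValidationError(
                "exhaled volume exceeds peak_flow * duration; flow cannot exceed its peak"
            )


@dataclass(frozen=True)
class TimeConstantEstimate:
    """Apparent time constant with its fixed-point iteration history."""

    tau: float
    iterations: int
    history: tuple[float, ...]
    converged: bool
    relative_changes: tuple[float, ...] = field(default=())

    def relative_change_at(self, k: int) -> float:
        """|tau_k - tau_{k-1}| / tau_{k-1}; if iteration stopped before k, the
        last recorded change (already below tolerance) is returned."""
        if k < 1:
            raise DomainError("iteration index must be >= 1")
        if not self.relative_changes:
            return 0.0
        return self.relative_changes[min(k, len(self.relative_changes)) - 1]


def extract_breath_summary(
    trace: FlowTrace,
    window: tuple[float, float] | None = None,
    peak_method: str = "max",
    peak_fit_window: float = 0.05,
) -> BreathSummary:
    """Expiratory tidal volume, peak flow and duration from a trace window.

    ``window`` is a (t0, t1) span within the trace (default: whole trace).
    Volume is the trapezoidal integral of the (expiratory-positive) flow, the
    duration is the window length, and the peak flow is either the sample
    maximum (``peak_method="max"``, the textbook reading) or, for noisy
    recordings, the intercept of a straight line fitted over the first
    ``peak_fit_window`` seconds (``peak_method="initial"``), which avoids the
    upward bias a sample maximum inherits from noise.
    """
    sub = trace if window is None else trace.window(*window)
    t, q = sub.times, sub.flows
    volume = float(np.trapezoid(q, t))
    duration = float(t[-1] - t[0])
    if peak_method == "max":
        peak = float(np.max(q))
    elif peak_method == "initial":
        mask = t - t[0] <= peak_fit_window + 1e-12
        if int(mask.sum()) < 3:
            raise ExtractionError("peak fit window contains fewer than 3 samples")
        coef = np.polynomial.polynomial.polyfit(t[mask] - t[0], q[mask], 1)
        peak = float(coef[0])
    else:
        raise ExtractionError(f"unknown peak_method {peak_method!r}")
    if volume <= 0 or peak <= 0:
        raise ExtractionError(
            f"window yields non-positive volume ({volume:g} l) or peak ({peak:g} l/s)"
        )
    volume = min(volume, peak * duration)  # guard quadrature round-off at the bound
    return BreathSummary(volume_exhaled=volume, peak_flow=peak, duration=duration)


def apparent_time_constant(
    summary: BreathSummary, tol: float = 1e-6, max_iter: int = 50
) -> TimeConstantEstimate:
    """Apparent expiratory time constant by fixed-point (Brunner) iteration.

    Starting from tau_0 = V_e,tot / Q_ep, iterate

        tau_{k+1} = tau_0 / (1 - exp(-t_e / tau_k))

    until the relative change drops below ``tol`` or ``max_iter`` is reached.
    Raises :class:`DomainError` when V_e,tot >= Q_ep * t_e (the implicit
    equation then has no finite solution: the exhalation would need a mean
    flow at or above its peak).
    """
    v, qp, te = summary.volume_exhaled, summary.peak_flow, summary.duration
    tau0 = v / qp
    if tau0 >= te * (1 - 1e-12):
        raise DomainError(
            f"V_e,tot/Q_ep = {tau0:g} s >= t_e = {te:g} s: no finite time constant"
        )
    history = [tau0]
    changes: list[float] = []
    tau = tau0
    converged = False
    for _ in range(max_iter):
        nxt = tau0 / (1.0 - math.exp(-te / tau))
        changes.append(abs(nxt - tau) / tau)
        history.append(nxt)
        tau = nxt
        if changes[-1] < tol:
            converged = True
            break
    return TimeConstantEstimate(
        tau=tau,
        iterations=len(history) - 1,
        history=tuple(history),
        converged=converged,
        relative_changes=tuple(changes),
    )


def ventilator_rc(
    trace: FlowTrace,
    window: tuple[float, float] | None = None,
    mode: str = "remaining75",
) -> float:
    """Ventilator-style expiratory time constant (RCexp), seconds.

    The defining reading (``mode="remaining75"``) locates the first instant at
    which the remaining-to-exhale volume equals 75% of the expiratory tidal
    volume (i.e. 25% has been exhaled) and returns remaining volume / flow
    there; for an ideal mono-exponential this recovers tau exactly. Literal
    alternatives: ``"tidal_at_25_exhaled"`` returns V_T/flow at the same
    instant; ``"tidal_at_75_exhaled"`` returns V_T/flow at 75% exhaled.
    """
    sub = trace if window is None else trace.window(*window)
    t, q = sub.times, sub.flows
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (q[1:] + q[:-1]) * np.diff(t))])
    v_tot = float(cum[-1])
    if v_tot <= 0:
        raise EstimationError("window exhales no volume; RC undefined")
    if mode in ("remaining75", "tidal_at_25_exhaled"):
        frac = 0.25
    elif mode == "tidal_at_75_exhaled":
        frac = 0.75
    else:
        raise EstimationError(f"unknown RC mode {mode!r}")
    target = frac * v_tot
    idx = int(np.searchsorted(cum, target))
    if idx >= len(cum):
        raise EstimationError("exhaled-volume target never crossed within window")
    if idx == 0:
        t_star, q_star = float(t[0]), float(q[0])
    else:
        # linear interpolation of the crossing between samples idx-1 and idx
        dv = cum[idx] - cum[idx - 1]
        w = 0.0 if dv == 0 else (target - cum[idx - 1]) / dv
        t_star = float(t[idx - 1] + w * (t[idx] - t[idx - 1]))
        q_star = float(q[idx - 1] + w * (q[idx] - q[idx - 1]))
    if q_star <= 0:
        raise EstimationError("non-positive flow at the volume target; RC undefined")
    if mode == "remaining75":
        return 0.75 * v_tot / q_star
    return v_tot / q_star


def mono_exponential_trace(
    q_p: float, tau: float, t_e: float, dt: float = 1e-3
) -> FlowTrace:
    """Sampled single-compartment expiration Q(t) = q_p * exp(-t/tau) on [0, t_e]."""
    if not (q_p > 0 and tau > 0 and t_e > 0 and dt > 0):
        raise DomainError("q_p, tau, t_e and dt must all be positive")
    n = int(round(t_e / dt))
    t = np.arange(n + 1) * dt
    return FlowTrace(t, q_p * np.exp(-t / tau))


def linear_model_time_constant(resistance: float, compliance: float) -> float:
    """tau = R*C of the linear single-compartment model, seconds.

    ``resistance`` in cmH2O s/l and ``compliance`` in l/cmH2O; the units
    cancel to seconds.
    """
    if resistance < 0 or compliance < 0:
        raise DomainError("resistance and compliance must be nonnegative")
    return resistance * compliance
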