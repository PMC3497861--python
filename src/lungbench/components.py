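"""Pressure-loss models for parabolic resistors, flow sensors and the circuit.

A parabolic (orifice-type) resistor obeys the inertial loss law

    dP = (k/2) * rho * U * |U|,       U = Q / A,

where k is a dimensionless loss coefficient fixed by the resistor geometry,
rho the gas density and A the entrance cross-sectional area. The signed
quadratic form (U*|U| rather than U^2) keeps the law antisymmetric so that
reverse (pendelluft) flows are representable.

The bench resistors are characterised by their k values (Rp5: 3.3,
Rp20: 21.5, Rp50: 132.9) and by a table of equivalent linear resistances
R = dP/Q at reference flows, but not by their entrance area. The area is
therefore calibrated once by inverting the loss law against a table cell;
a single shared area reproduces every cell of the table (the table's internal
ratios confirm a common geometry scale), and the same reference area is used
for the flow-sensor and circuit loss coefficients of the simulator.

Circuit losses (flow sensor + tubing + expiratory valve) are represented by a
:class:`CircuitLossModel`, either in *inertial* form (a loss coefficient k
referenced to an area, valid for any gas via its density) or in *polynomial*
form dP = c1*Q + c2*Q^2 fitted per gas from measured pressure-flow curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import units
from .errors import ConfigurationError, DomainError, FitError, ValidationError
from .gas_properties import AIR, GasMixture, mixture_density

#: Loss coefficients of the bench parabolic resistors (dimensionless).
RESISTOR_K: dict[str, float] = {"Rp5": 3.3, "Rp20": 21.5, "Rp50": 132.9}

# Reference table cell used to calibrate the shared entrance area:
# Rp50 with dry air at 60 l/min has an equivalent linear resistance of
# 108.4 cmH2O s/l (the cell printed with the most significant figures).
_CAL_K = RESISTOR_K["Rp50"]
_CAL_FLOW_M3S = units.lpm_to_m3s(60.0)
_CAL_R_CLINICAL = 108.4


@dataclass(frozen=True)
class ParabolicResistor:
    """Orifice-type resistor with loss coefficient ``k`` and entrance ``area`` (m^2)."""

    k: float
    area: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValidationError(f"loss coefficient must be positive, got {self.k}")
        if not self.area > 0:
            raise ValidationError(f"entrance area must be positive, got {self.area}")


def resistor_pressure_drop(r: ParabolicResistor, gas: GasMixture, flow: float) -> float:
    """Signed pressure drop across a parabolic resistor, Pa.

    Parameters
    ----------
    flow : float
        Volumetric flow, m^3/s; any sign. dP = (k/2)*rho*(Q/A)*|Q/A| so the
        drop is positive for forward flow and antisymmetric in Q.
    """
    rho = mixture_density(gas)
    u = flow / r.area
    return 0.5 * r.k * rho * u * abs(u)


def equivalent_linear_resistance(r: ParabolicResistor, gas: GasMixture, flow: float) -> float:
    """Equivalent linear resistance R = dP/Q at a given flow, cmH2O s/l.

    For the quadratic loss law R grows linearly with flow and with gas
    density; it is the flow-specific "resistance" a linear single-compartment
    analysis would attribute to the element.

    Parameters
    ----------
    flow : float
        Volumetric flow, m^3/s; must be positive.
    """
    if not flow > 0:
        raise DomainError(f"equivalent resistance requires flow > 0, got {flow}")
    dp = resistor_pressure_drop(r, gas, flow)
    return units.resistance_to_clinical(dp / flow)


def calibrate_area(k: float, gas: GasMixture, flow: float, resistance: float) -> float:
    """Entrance area (m^2) making the loss law reproduce a resistance table cell.

    Inverts dP = (k/2)*rho*(Q/A)^2 with dP = R*Q:

        A = Q * sqrt(k * rho / (2 * dP))

    Parameters
    ----------
    k : float
        Dimensionless loss coefficient.
    flow : float
        Calibration flow, m^3/s.
    resistance : float
        Equivalent linear resistance at that flow, cmH2O s/l.
    """
    if not (k > 0 and flow > 0 and resistance > 0):
        raise DomainError("calibration requires positive k, flow and resistance")
    rho = mixture_density(gas)
    dp = units.cmh2o_to_pa(resistance / units.L_M3 * flow)  # R*Q in Pa
    return flow * math.sqrt(k * rho / (2.0 * dp))


_REFERENCE_AREA: float | None = None


def reference_area() -> float:
    """Shared entrance area calibrated from the Rp50 / air / 60 l/min cell (m^2)."""
    global _REFERENCE_AREA
    if _REFERENCE_AREA is None:
        _REFERENCE_AREA = calibrate_area(_CAL_K, AIR, _CAL_FLOW_M3S, _CAL_R_CLINICAL)
    return _REFERENCE_AREA


def make_resistor(name_or_k: str | float, area: float | None = None) -> ParabolicResistor:
    """Build a resistor from a bench name ('Rp5', 'Rp20', 'Rp50') or a raw k."""
    if isinstance(name_or_k, str):
        try:
            k = RESISTOR_K[name_or_k]
        except KeyError:
            raise ConfigurationError(
                f"unknown resistor {name_or_k!r}; known: {sorted(RESISTOR_K)}"
            ) from None
    else:
        k = float(name_or_k)
    return ParabolicResistor(k=k, area=reference_area() if area is None else area)


@dataclass(frozen=True)
class PressureFlowCurve:
    """Steady pressure-drop measurements over a range of flows for one gas.

    Flows are stored in m^3/s (nonnegative, strictly increasing) and pressure
    drops in Pa (nonnegative). Use :meth:`from_clinical` / :meth:`from_csv`
    for l/min and cmH2O inputs.
    """

    flows: tuple[float, ...]
    pressure_drops: tuple[float, ...]
    gas: GasMixture

    def __post_init__(self) -> None:
        q = np.asarray(self.flows, dtype=float)
        p = np.asarray(self.pressure_drops, dtype=float)
        if q.size != p.size:
            raise ValidationError("flows and pressure drops must have equal length")
        if q.size == 0:
            raise ValidationError("curve must contain at least one point")
        if np.any(q < 0) or np.any(p < 0):
            raise ValidationError("flows and pressure drops must be nonnegative")
        if np.any(np.diff(q) <= 0):
            raise ValidationError("flows must be strictly increasing")

    @classmethod
    def from_clinical(
        cls, flow_lpm: Sequence[float], dp_cmh2o: Sequence[float], gas: GasMixture
    ) -> "PressureFlowCurve":
        return cls(
            flows=tuple(units.lpm_to_m3s(q) for q in flow_lpm),
            pressure_drops=tuple(units.cmh2o_to_pa(p) for p in dp_cmh2o),
            gas=gas,
        )

    @classmethod
    def from_csv(cls, path: str | Path, gas: GasMixture) -> "PressureFlowCurve":
        """Read a curve from CSV with columns ``flow_lpm, dp_cmh2o`` ('#' comments allowed)."""
        df = pd.read_csv(path, comment="#")
        missing = {"flow_lpm", "dp_cmh2o"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"curve CSV missing columns: {sorted(missing)}")
        df = df.sort_values("flow_lpm")
        return cls.from_clinical(df["flow_lpm"].tolist(), df["dp_cmh2o"].tolist(), gas)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.flows), np.asarray(self.pressure_drops)


@dataclass(frozen=True)
class CircuitLossModel:
    """Loss model for the shared expiratory circuit (or a flow sensor).

    Two forms:

    * ``form="inertial"``: dP = (k/2)*rho*(Q/A)*|Q/A| with loss coefficient
      ``k`` referenced to ``area`` (defaults to the shared reference area at
      evaluation time). Valid for any gas because density enters explicitly.
    * ``form="polynomial"``: dP = c1*Q + c2*Q*|Q| with per-gas coefficients in
      SI units (Pa/(m^3/s) and Pa/(m^3/s)^2), keyed by :attr:`GasMixture.key`.
      The zero-flow intercept is pinned to zero by construction. Using a
      polynomial model with a gas it was not fitted for is an explicit error,
      never a silent density rescaling.
    """

    form: str = "inertial"
    k: float | None = None
    area: float | None = None
    coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)
    diagnostics: dict | None = None

    def __post_init__(self) -> None:
        if self.form == "inertial":
            if self.k is None or not self.k >= 0:
                raise ValidationError("inertial circuit model needs k >= 0")
        elif self.form == "polynomial":
            if not self.coefficients:
                raise ValidationError("polynomial circuit model needs coefficients")
        else:
            raise ValidationError(f"unknown circuit model form {self.form!r}")

    def coefficients_for(self, gas: GasMixture) -> tuple[float, float]:
        """(c1, c2) of the signed polynomial dP = c1*Q + c2*Q|Q| for this gas, SI."""
        if self.form == "inertial":
            area = self.area if self.area is not None else reference_area()
            rho = mixture_density(gas)
            return 0.0, float(self.k) * rho / (2.0 * area * area)
        try:
            return self.coefficients[gas.key]
        except KeyError:
            raise ConfigurationError(
                f"circuit model has no fit for gas {gas.key!r} and no inertial form; "
                "refit with this gas or use an inertial model"
            ) from None


def circuit_pressure_drop(model: CircuitLossModel, gas: GasMixture, flow: float) -> float:
    """Signed circuit pressure drop, Pa, at volumetric flow ``flow`` (m^3/s)."""
    c1, c2 = model.coefficients_for(gas)
    return c1 * flow + c2 * flow * abs(flow)


def fit_pressure_flow_polynomial(curve: PressureFlowCurve) -> CircuitLossModel:
    """Least-squares fit of dP = c1*Q + c2*Q^2 (zero intercept) to one curve.

    Returns a polynomial :class:`CircuitLossModel` keyed by the curve's gas,
    with fit diagnostics (coefficient standard errors, residual RMS). Requires
    at least three distinct flow points; raises :class:`FitError` otherwise or
    if the design is degenerate or the fitted quadratic term is nonpositive.
    """
    q, p = curve.as_arrays()
    if q.size < 3:
        raise FitError(f"need >= 3 flow points to fit, got {q.size}")
    design = np.column_stack([q, q * q])
    coef, _, rank, _ = np.linalg.lstsq(design, p, rcond=None)
    if rank < 2:
        raise FitError("degenerate design matrix (collinear flow points)")
    resid = p - design @ coef
    dof = max(q.size - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    stderr = np.sqrt(np.diag(cov))
    c1, c2 = float(coef[0]), float(coef[1])
    if c2 <= 0:
        raise FitError(f"fitted quadratic coefficient must be positive, got {c2:g}")
    return CircuitLossModel(
        form="polynomial",
        coefficients={curve.gas.key: (c1, c2)},
        diagnostics={
            "gas": curve.gas.key,
            "c1": c1,
            "c2": c2,
            "stderr_c1": float(stderr[0]),
            "stderr_c2": float(stderr[1]),
            "residual_rms_pa": float(np.sqrt(np.mean(resid**2))),
            "n_points": int(q.size),
        },
    )


@dataclass(frozen=True)
class CollapseResult:
    """Outcome of pooling pressure-flow curves against rho*Q^2.

    ``slope`` is the single pooled coefficient beta in dP = beta * rho * Q^2
    (units Pa/(kg/m^3)/(m^3/s)^2; beta = k/(2 A^2) for an orifice of loss
    coefficient k and area A). ``scatter`` is the RMS residual of all points
    about that single line, normalised by the RMS pressure drop: near zero
    when inertial losses dominate, growing as viscous (density-independent)
    contributions appear.
    """

    slope: float
    scatter: float
    n_points: int

    def loss_coefficient(self, area: float) -> float:
        """Convert the pooled slope to a dimensionless k referenced to ``area``."""
        return 2.0 * self.slope * area * area


def inertial_collapse_check(curves: Iterable[PressureFlowCurve]) -> CollapseResult:
    """Regress pooled dP against rho*Q^2 across gases; small scatter = inertial.

    With two or more curves their rho*Q^2 ranges must overlap, otherwise the
    collapse is not testable and a :class:`FitError` is raised. A single curve
    is accepted as the degenerate case (slope and scatter of that curve alone).
    """
    curves = list(curves)
    if not curves:
        raise FitError("no curves supplied")
    xs, ys = [], []
    ranges = []
    for c in curves:
        q, p = c.as_arrays()
        x = mixture_density(c.gas) * q * q
        xs.append(x)
        ys.append(p)
        ranges.append((float(x.min()), float(x.max())))
    if len(curves) >= 2:
        lo = max(r[0] for r in ranges)
        hi = min(r[1] for r in ranges)
        if not lo < hi:
            raise FitError("rho*Q^2 ranges of the supplied curves do not overlap")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    sxx = float(x @ x)
    if sxx == 0.0:
        raise FitError("all points at zero flow; cannot regress")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    y_rms = float(np.sqrt(np.mean(y**2)))
    scatter = float(np.sqrt(np.mean(resid**2))) / y_rms if y_rms > 0 else 0.0
    return CollapseResult(slope=slope, scatter=scatter, n_points=int(x.size))
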