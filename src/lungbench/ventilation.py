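"""Ventilator waveform and breath timing for volume-control ventilation.

Only the mode used on the bench is modelled: volume control with a square
(constant) inspiratory flow, no inspiratory pause, and a fixed I:E ratio.
With those choices the whole cycle is determined by tidal volume, rate and
I:E. Time origin is at the start of inspiration; breaths are indexed from 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .errors import DomainError, ValidationError


class BreathTiming(NamedTuple):
    t_insp: float
    t_exp: float
    period: float


@dataclass(frozen=True)
class VentilatorSettings:
    """Volume-control settings.

    Parameters
    ----------
    tidal_volume : float
        Set tidal volume, litres (> 0).
    rate : float
        Respiratory rate, breaths/min (> 0).
    ie_ratio : float
        Inspiratory:expiratory time ratio (> 0); the bench protocol used 1/2.
    waveform : str
        Only ``"square"`` (constant inspiratory flow) is supported.
    """

    tidal_volume: float
    rate: float
    ie_ratio: float = 0.5
    waveform: str = "square"

    def __post_init__(self) -> None:
        if not self.tidal_volume > 0:
            raise ValidationError(f"tidal volume must be > 0 l, got {self.tidal_volume}")
        if not self.rate > 0:
            raise ValidationError(f"rate must be > 0 /min, got {self.rate}")
        if not self.ie_ratio > 0:
            raise ValidationError(f"I:E ratio must be > 0, got {self.ie_ratio}")
        if self.waveform != "square":
            raise ValidationError("only the square (constant-flow) waveform is supported")

    @property
    def minute_ventilation(self) -> float:
        """Tidal volume x rate, l/min."""
        return self.tidal_volume * self.rate


def breath_timing(s: VentilatorSettings) -> BreathTiming:
    """(t_insp, t_exp, period) in seconds.

    period = 60/rate; t_insp = period * ie/(1+ie); t_exp = period - t_insp.
    """
    period = 60.0 / s.rate
    t_insp = period * s.ie_ratio / (1.0 + s.ie_ratio)
    return BreathTiming(t_insp=t_insp, t_exp=period - t_insp, period=period)


def inspiratory_flow(s: VentilatorSettings, t: float) -> float:
    """Total ventilator flow Q_TOT at time ``t`` within one breath, l/s.

    Constant tidal_volume/t_insp during inspiration, zero during expiration.
    ``t`` must satisfy 0 <= t < period.
    """
    timing = breath_timing(s)
    if not (0.0 <= t < timing.period):
        raise DomainError(f"t={t} outside breath period [0, {timing.period})")
    if t < timing.t_insp:
        return s.tidal_volume / timing.t_insp
    return 0.0
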