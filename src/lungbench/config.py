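"""YAML configuration loading for the command-line interface.

A configuration file describes the gas, the two chambers, the shared circuit
loss model and the ventilator settings::

    gas:
      name: heliox              # or a custom mixture:
      # fractions: {He: 0.78, O2: 0.22}
      # temperature_k: 293.15
      # pressure_pa: 101325
    area_m2: null               # default: area calibrated from the R table
    chambers:
      left:  {compliance: 0.05, resistor: Rp5}
      right: {compliance: 0.05, resistor: Rp50, sensor_loss_k: 1.2}
    circuit:
      form: inertial
      k_cct: 5.0
      # or: form: polynomial
      #     coefficients: {air: {c1_cmh2o_per_lps: 0.5, c2_cmh2o_per_lps2: 2.0}}
    ventilator: {tidal_volume_l: 1.0, rate_bpm: 20, ie_ratio: 0.5}
    simulation: {dt_s: 0.001, breaths: 6, clamp_expiratory_inflow: false}

Compliances are l/cmH2O, tidal volume litres; polynomial circuit
coefficients are given in clinical units (cmH2O per l/s and per (l/s)^2) and
converted exactly to SI on load.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import units
from .components import CircuitLossModel, make_resistor
from .errors import ConfigurationError
from .gas_properties import NAMED_MIXTURES, GasMixture, GasSpecies
from .simulator import DEFAULT_K_FS, Chamber, LungSystem, default_circuit
from .ventilation import VentilatorSettings


def build_gas(cfg: dict | None) -> GasMixture:
    if not cfg:
        return NAMED_MIXTURES["air"]
    name = cfg.get("name")
    if name and "fractions" not in cfg:
        try:
            base = NAMED_MIXTURES[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown named gas {name!r}; provide fractions for custom mixtures"
            ) from None
        return base.at(cfg.get("temperature_k"), cfg.get("pressure_pa"))
    if "fractions" not in cfg:
        raise ConfigurationError("gas config needs a known name or explicit fractions")
    extra = {
        sp: GasSpecies(sp, m)
        for sp, m in (cfg.get("species_molar_masses_g_mol") or {}).items()
    }
    return GasMixture(
        fractions=dict(cfg["fractions"]),
        temperature=cfg.get("temperature_k", 293.15),
        pressure=cfg.get("pressure_pa", 101325.0),
        species=extra,
        name=name,
    )


def build_circuit(cfg: dict | None) -> CircuitLossModel:
    if not cfg:
        return default_circuit()
    form = cfg.get("form", "inertial")
    if form == "inertial":
        return CircuitLossModel(form="inertial", k=cfg.get("k_cct", 5.0),
                                area=cfg.get("area_m2"))
    if form == "polynomial":
        coeffs = {}
        for gas_key, c in (cfg.get("coefficients") or {}).items():
            if isinstance(c, dict):
                c1 = c.get("c1_cmh2o_per_lps", 0.0)
                c2 = c["c2_cmh2o_per_lps2"]
            else:  # bare [c1, c2] pair in clinical units
                c1, c2 = c
            coeffs[gas_key] = (
                c1 * units.CMH2O_PA / units.LPS_M3S,
                c2 * units.CMH2O_PA / units.LPS_M3S**2,
            )
        return CircuitLossModel(form="polynomial", coefficients=coeffs)
    raise ConfigurationError(f"unknown circuit form {form!r}")


def _build_chamber(cfg: dict, area: float | None) -> Chamber:
    resistor = cfg.get("resistor", cfg.get("k"))
    if resistor is None:
        raise ConfigurationError("each chamber needs a 'resistor' name or a 'k' value")
    return Chamber(
        compliance=cfg["compliance"],
        resistor=make_resistor(resistor, area),
        sensor_loss_k=cfg.get("sensor_loss_k", DEFAULT_K_FS),
        volume=cfg.get("volume_l", 0.0),
    )


def build_system(cfg: dict) -> LungSystem:
    gas = build_gas(cfg.get("gas"))
    area = cfg.get("area_m2")
    chambers = cfg.get("chambers") or {}
    if "left" not in chambers or "right" not in chambers:
        raise ConfigurationError("config needs chambers.left and chambers.right")
    sim = cfg.get("simulation") or {}
    return LungSystem(
        left=_build_chamber(chambers["left"], area),
        right=_build_chamber(chambers["right"], area),
        gas=gas,
        circuit=build_circuit(cfg.get("circuit")),
        area=area,
        clamp_expiratory_inflow=bool(sim.get("clamp_expiratory_inflow", False)),
    )


def build_settings(cfg: dict) -> VentilatorSettings:
    v = cfg.get("ventilator") or {}
    try:
        return VentilatorSettings(
            tidal_volume=v["tidal_volume_l"],
            rate=v["rate_bpm"],
            ie_ratio=v.get("ie_ratio", 0.5),
        )
    except KeyError as missing:
        raise ConfigurationError(f"ventilator config missing {missing}") from None


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return cfg
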