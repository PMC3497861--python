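"""Unit conversions between SI (used internally) and clinical units.

Clinical respiratory mechanics is reported in litres, litres per second or per
minute, and centimetres of water; all simulation and pressure-loss algebra is
done in SI (m^3, m^3/s, Pa). Conversions are exact constants applied at the
interface, never inside numerical loops.
"""

#: Pa per cm H2O (conventional water column at 4 degC, standard gravity)
CMH2O_PA: float = 98.0665

#: m^3 per litre
L_M3: float = 1e-3

#: m^3/s per l/min
LPM_M3S: float = L_M3 / 60.0

#: m^3/s per l/s
LPS_M3S: float = L_M3


def lpm_to_m3s(q: float) -> float:
    return q * LPM_M3S


def lps_to_m3s(q: float) -> float:
    return q * LPS_M3S


def m3s_to_lps(q: float) -> float:
    return q / LPS_M3S


def m3s_to_lpm(q: float) -> float:
    return q / LPM_M3S


def cmh2o_to_pa(p: float) -> float:
    return p * CMH2O_PA


def pa_to_cmh2o(p: float) -> float:
    return p / CMH2O_PA


def l_to_m3(v: float) -> float:
    return v * L_M3


def m3_to_l(v: float) -> float:
    return v / L_M3


def compliance_to_si(c_l_per_cmh2o: float) -> float:
    """l/cmH2O -> m^3/Pa."""
    return c_l_per_cmh2o * L_M3 / CMH2O_PA


def resistance_to_clinical(r_pa_s_per_m3: float) -> float:
    """Pa s/m^3 -> cmH2O s/l."""
    return r_pa_s_per_m3 * L_M3 / CMH2O_PA
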