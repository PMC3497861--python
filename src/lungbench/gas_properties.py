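"""Densities of dry breathing-gas mixtures.

The pressure losses of orifice-like airway obstructions and of ventilator
circuit components are inertial: dP = (k/2) * rho * U^2. The only gas property
the rest of the package needs is therefore the mixture mass density rho.

Mixtures are specified by mole fractions and evaluated with the ideal-gas law

    rho = p * M_mix / (R * T),     M_mix = sum_i x_i * M_i,

which for dry, near-ambient gases is accurate to well below the rounding of
any reported resistance value (compressibility factors for He, N2 and O2 at
1 atm differ from unity by < 0.1%). Viscosity is deliberately not modelled:
the loss laws used here are purely inertial.

Two ready-made mixtures are provided: :data:`AIR` (78/22 N2/O2 by mole, the
dry "medical air" convention used on the bench) and :data:`HELIOX`
(78/22 He/O2). The default reference state is 293.15 K and 101325 Pa
(dry, room-temperature gas); both are configurable per mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigurationError, ValidationError

#: Universal gas constant, J/(mol K) (CODATA 2018, exact).
R_UNIVERSAL: float = 8.314462618

#: Default reference temperature, K.
T_REF: float = 293.15

#: Default reference pressure, Pa.
P_REF: float = 101325.0

_FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class GasSpecies:
    """A pure gas species.

    Parameters
    ----------
    name : str
        Species label used as the key in mixture fraction maps.
    molar_mass : float
        Molar mass in g/mol; must be positive.
    """

    name: str
    molar_mass: float

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValidationError(
                f"molar mass of {self.name!r} must be positive, got {self.molar_mass}"
            )


#: Species known out of the box (molar masses in g/mol, CODATA/IUPAC values).
BUILTIN_SPECIES: dict[str, GasSpecies] = {
    s.name: s
    for s in (
        GasSpecies("He", 4.002602),
        GasSpecies("N2", 28.0134),
        GasSpecies("O2", 31.9988),
        GasSpecies("Ar", 39.948),
        GasSpecies("CO2", 44.0095),
        GasSpecies("H2", 2.01588),
        GasSpecies("N2O", 44.0128),
        GasSpecies("Xe", 131.293),
    )
}


@dataclass(frozen=True)
class GasMixture:
    """A dry gas mixture defined by mole fractions at a given state.

    Parameters
    ----------
    fractions : mapping of species name -> mole fraction
        Fractions must lie in [0, 1] and sum to 1 within 1e-9.
    temperature : float
        Absolute temperature, K (> 0). Default 293.15 K.
    pressure : float
        Absolute pressure, Pa (> 0). Default 101325 Pa.
    species : mapping of species name -> GasSpecies, optional
        Additional or overriding species definitions; anything not found here
        is looked up in :data:`BUILTIN_SPECIES`.
    name : str, optional
        Human-readable label (used to key per-gas circuit fits).
    """

    fractions: Mapping[str, float]
    temperature: float = T_REF
    pressure: float = P_REF
    species: Mapping[str, GasSpecies] = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValidationError("mixture must contain at least one species")
        total = 0.0
        for sp, x in self.fractions.items():
            if not (0.0 <= x <= 1.0):
                raise ValidationError(
                    f"mole fraction of {sp!r} must be in [0, 1], got {x}"
                )
            total += x
        if abs(total - 1.0) > _FRACTION_SUM_TOL:
            raise ValidationError(
                f"mole fractions must sum to 1 within {_FRACTION_SUM_TOL}, got {total!r}"
            )
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.pressure > 0:
            raise ValidationError(f"pressure must be > 0 Pa, got {self.pressure}")

    def _species(self, name: str) -> GasSpecies:
        if name in self.species:
            return self.species[name]
        try:
            return BUILTIN_SPECIES[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown gas species {name!r}; declare it via GasMixture(species=...)"
            ) from None

    @property
    def mean_molar_mass(self) -> float:
        """Mole-fraction-weighted molar mass, g/mol."""
        return sum(x * self._species(sp).molar_mass for sp, x in self.fractions.items())

    @property
    def key(self) -> str:
        """Stable label for keying per-gas data (fits, tables)."""
        if self.name:
            return self.name
        return "+".join(f"{sp}{x:g}" for sp, x in sorted(self.fractions.items()))

    def at(self, temperature: float | None = None, pressure: float | None = None) -> "GasMixture":
        """Same composition at a different reference state."""
        return GasMixture(
            fractions=self.fractions,
            temperature=self.temperature if temperature is None else temperature,
            pressure=self.pressure if pressure is None else pressure,
            species=self.species,
            name=self.name,
        )


def mixture_density(mix: GasMixture) -> float:
    """Ideal-gas mass density of a mixture, kg/m^3.

    rho = p * M_mix / (R * T) with M_mix in kg/mol. Strictly positive for any
    valid mixture.
    """
    m_kg = mix.mean_molar_mass * 1e-3
    return mix.pressure * m_kg / (R_UNIVERSAL * mix.temperature)


def density_ratio(a: GasMixture, b: GasMixture) -> float:
    """rho(a) / rho(b).

    At equal temperature and pressure this reduces exactly to the ratio of
    mean molar masses, which is how a heliox-for-air substitution rescales
    every inertial pressure loss in the system.
    """
    return mixture_density(a) / mixture_density(b)


#: Dry medical air, 78/22 N2/O2 by mole.
AIR = GasMixture({"N2": 0.78, "O2": 0.22}, name="air")

#: Heliox, 78/22 He/O2 by mole.
HELIOX = GasMixture({"He": 0.78, "O2": 0.22}, name="heliox")

#: Named mixtures accepted in configuration files.
NAMED_MIXTURES: dict[str, GasMixture] = {"air": AIR, "heliox": HELIOX}
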