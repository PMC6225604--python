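"""Registry of thermodynamic and physical constants, with unit helpers.

All equilibrium constants are 25 degC values for dilute aqueous solution.
Unit conventions used throughout the package:

* concentrations        mol L^-1 (M)
* partial pressures     bar (ideal gas, fugacity = partial pressure)
* gas-exchange fluxes   molecules cm^-2 s^-1
* number densities      molecules cm^-3

Conversions between these happen only through the helpers defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

AVOGADRO = 6.02214076e23  # mol^-1
BOLTZMANN = 1.380649e-23  # J K^-1
GAS_CONSTANT = 8.31446261815324  # J mol^-1 K^-1

#: Atmospheric number density adopted for the 1 bar early-Earth atmosphere,
#: molecules cm^-3.  Kept at the adopted literature value; do not recompute
#: from kT.
N_ATM = 2.4e19


@dataclass(frozen=True)
class EquilibriumConstant:
    """One acid-base (or water autoionization) equilibrium on the pKa scale."""

    label: str
    pKa: float
    reactants: tuple[str, ...]
    products: tuple[str, ...]

    @property
    def Ka(self) -> float:
        return 10.0 ** (-self.pKa)


@dataclass(frozen=True)
class HenryConstant:
    """Henry's-law solubility at the 298.15 K reference, mol L^-1 bar^-1."""

    gas: str
    H: float


@dataclass(frozen=True)
class SolubilityProduct:
    """Solubility product of a 1:1 salt, mol^2 L^-2."""

    mineral: str
    Ksp: float


_EQUILIBRIA: dict[str, EquilibriumConstant] = {
    c.label: c
    for c in (
        EquilibriumConstant("H2S,1", 7.05, ("H2S",), ("HS-", "H+")),
        EquilibriumConstant("H2S,2", 19.0, ("HS-",), ("S-2", "H+")),
        EquilibriumConstant("SO2,1", 1.86, ("SO2",), ("HSO3-", "H+")),
        EquilibriumConstant("SO2,2", 7.2, ("HSO3-",), ("SO3-2", "H+")),
        # adduct formation: HSO3- + SO2 -> HS2O5-  (no proton released)
        EquilibriumConstant("SO2,3", 1.5, ("HSO3-", "SO2"), ("HS2O5-",)),
        EquilibriumConstant("W", 14.0, ("H2O",), ("OH-", "H+")),
        EquilibriumConstant("CO2,1", 6.35, ("CO2",), ("HCO3-", "H+")),
        EquilibriumConstant("CO2,2", 10.33, ("HCO3-",), ("CO3-2", "H+")),
    )
}

_HENRY: dict[str, HenryConstant] = {
    h.gas: h
    for h in (
        HenryConstant("H2S", 0.101),
        HenryConstant("SO2", 1.34),
        HenryConstant("CO2", 3.3e-2),
    )
}

_KSP: dict[str, SolubilityProduct] = {
    s.mineral: s
    for s in (
        SolubilityProduct("CaCO3", 3.36e-9),
        SolubilityProduct("CaSO3", 3.1e-7),
    )
}


class UnknownConstantError(KeyError):
    """Raised when a reaction, gas, or mineral label is not registered."""


def equilibrium(label: str) -> EquilibriumConstant:
    try:
        return _EQUILIBRIA[label]
    except KeyError:
        raise UnknownConstantError(
            f"no equilibrium constant registered under {label!r}; "
            f"known labels: {sorted(_EQUILIBRIA)}"
        ) from None


def pka(label: str) -> float:
    return equilibrium(label).pKa


def ka(label: str) -> float:
    """Equilibrium constant 10^(-pKa) for a registered reaction label."""
    return equilibrium(label).Ka


def henry_constant(gas: str) -> float:
    """Henry's-law constant of ``gas`` in mol L^-1 bar^-1."""
    try:
        return _HENRY[gas].H
    except KeyError:
        raise UnknownConstantError(
            f"no Henry constant registered for gas {gas!r}; "
            f"known gases: {sorted(_HENRY)}"
        ) from None


def solubility_product(mineral: str) -> float:
    try:
        return _KSP[mineral].Ksp
    except KeyError:
        raise UnknownConstantError(
            f"no solubility product registered for {mineral!r}; "
            f"known minerals: {sorted(_KSP)}"
        ) from None


def molar_to_number_density(c: float) -> float:
    """mol L^-1 -> molecules cm^-3 (1 L = 1000 cm^3)."""
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    return c * AVOGADRO / 1000.0


def number_density_to_molar(n: float) -> float:
    """molecules cm^-3 -> mol L^-1."""
    if n < 0:
        raise ValueError(f"number density must be >= 0, got {n}")
    return n * 1000.0 / AVOGADRO


def arrhenius_k17(T: float, Ea: float) -> float:
    """First-order sulfite disproportionation rate coefficient, s^-1.

    k = exp(-Ea / (R T)) with Ea in J mol^-1.  The bracketing activation
    energies 40 and 50 kJ mol^-1 give the fast and slow bounds; at 293 K
    these evaluate to ~7e-8 and ~1e-9 s^-1 (decay timescales of roughly
    half a year to thirty years).
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if Ea < 0:
        raise ValueError(f"activation energy must be >= 0, got {Ea}")
    return math.exp(-Ea / (GAS_CONSTANT * T))


#: Bracketing activation energies for sulfite disproportionation, J mol^-1.
K17_EA_FAST = 40e3
K17_EA_SLOW = 50e3


def constants_table() -> pd.DataFrame:
    """Flat key/value/unit audit table of every registered constant."""
    rows: list[dict[str, object]] = []
    for c in _EQUILIBRIA.values():
        rows.append({"key": f"pKa[{c.label}]", "value": c.pKa, "unit": "log10"})
    for h in _HENRY.values():
        rows.append({"key": f"H[{h.gas}]", "value": h.H, "unit": "mol/L/bar"})
    for s in _KSP.values():
        rows.append({"key": f"Ksp[{s.mineral}]", "value": s.Ksp, "unit": "mol^2/L^2"})
    rows.append({"key": "N_A", "value": AVOGADRO, "unit": "1/mol"})
    rows.append({"key": "k_B", "value": BOLTZMANN, "unit": "J/K"})
    rows.append({"key": "R", "value": GAS_CONSTANT, "unit": "J/mol/K"})
    rows.append({"key": "n_atm", "value": N_ATM, "unit": "molecules/cm^3"})
    return pd.DataFrame(rows, columns=["key", "value", "unit"])


def export_constants(path: str) -> None:
    """Write the audit table as tab-separated text."""
    constants_table().to_csv(path, sep="\t", index=False)
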