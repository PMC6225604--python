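"""Extended Debye-Hueckel activity coefficients and ionic strength.

log10(gamma) = -A z^2 sqrt(I) / (1 + B alpha sqrt(I)) with the 25 degC
water parameters A = 0.5085 M^-1/2, B = 0.3281 M^-1/2 A^-1.  The
ion-size parameters alpha (Angstrom) follow the standard Kielland
compilation; the disulfite adduct HS2O5- has no tabulated alpha and its
coefficient is pinned to 1 at every ionic strength.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import yaml

DEBYE_HUECKEL_A = 0.5085  # M^-1/2, 25 degC water
DEBYE_HUECKEL_B = 0.3281  # M^-1/2 Angstrom^-1

#: Ionic strength above which the Extended Debye-Hueckel form (and the
#: prebiotic-chemistry motivation for dilute waters) is stretched.
IONIC_STRENGTH_SOFT_LIMIT = 0.1


class IonicStrengthWarning(UserWarning):
    """Emitted when gamma is evaluated beyond I = 0.1 M."""


@dataclass(frozen=True)
class IonParameters:
    """Charge and Kielland size parameter of one aqueous species."""

    species: str
    charge: int
    size_angstrom: float | None  # None => gamma pinned to 1 (no alpha known)


_DEFAULT_IONS: tuple[IonParameters, ...] = (
    IonParameters("H+", 1, 9.0),
    IonParameters("OH-", -1, 3.5),
    IonParameters("HS-", -1, 3.5),
    IonParameters("S-2", -2, 5.0),
    IonParameters("HSO3-", -1, 4.0),
    IonParameters("SO3-2", -2, 4.5),
    IonParameters("HS2O5-", -1, None),  # no tabulated alpha; gamma = 1
    IonParameters("Ca+2", 2, 6.0),
    IonParameters("CO3-2", -2, 4.5),
    IonParameters("HCO3-", -1, 4.0),
    IonParameters("Na+", 1, 4.0),
    IonParameters("K+", 1, 3.0),
    IonParameters("Cl-", -1, 3.0),
    # dissolved neutral gases: z = 0, gamma = 1
    IonParameters("H2S", 0, None),
    IonParameters("SO2", 0, None),
    IonParameters("CO2", 0, None),
)

DEFAULT_ION_TABLE: dict[str, IonParameters] = {p.species: p for p in _DEFAULT_IONS}


class UnknownIonError(KeyError):
    pass


def ion_parameters(species: str, table: Mapping[str, IonParameters] | None = None) -> IonParameters:
    table = DEFAULT_ION_TABLE if table is None else table
    try:
        return table[species]
    except KeyError:
        raise UnknownIonError(
            f"no ion parameters for species {species!r}; known: {sorted(table)}"
        ) from None


def load_ion_parameters(path: str) -> dict[str, IonParameters]:
    """Load an alternative ion-size table from YAML.

    Format: a mapping species -> {charge: int, size_angstrom: float|null}.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    table = {}
    for species, rec in raw.items():
        table[species] = IonParameters(
            species=species,
            charge=int(rec["charge"]),
            size_angstrom=None if rec.get("size_angstrom") is None else float(rec["size_angstrom"]),
        )
    return table


def ionic_strength(
    concentrations: Mapping[str, float],
    table: Mapping[str, IonParameters] | None = None,
) -> float:
    """I = 0.5 sum_i c_i z_i^2 in mol L^-1; neutral species contribute 0."""
    total = 0.0
    for species, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {species}: {c}")
        z = ion_parameters(species, table).charge
        total += c * z * z
    return 0.5 * total


def activity_coefficient(
    ion: IonParameters | str,
    I: float,
    table: Mapping[str, IonParameters] | None = None,
) -> float:
    """Extended Debye-Hueckel gamma for one species at ionic strength I."""
    if isinstance(ion, str):
        ion = ion_parameters(ion, table)
    if I < 0:
        raise ValueError(f"ionic strength must be >= 0, got {I}")
    if I > IONIC_STRENGTH_SOFT_LIMIT:
        warnings.warn(
            f"I = {I} M exceeds the 0.1 M dilute-water focus of this model",
            IonicStrengthWarning,
            stacklevel=2,
        )
    if ion.charge == 0 or I == 0.0:
        return 1.0
    if ion.size_angstrom is None:
        # species with no tabulated size parameter (HS2O5-): pinned to ideal
        return 1.0
    sqrt_i = math.sqrt(I)
    log_gamma = (
        -DEBYE_HUECKEL_A
        * ion.charge**2
        * sqrt_i
        / (1.0 + DEBYE_HUECKEL_B * ion.size_angstrom * sqrt_i)
    )
    return 10.0**log_gamma
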