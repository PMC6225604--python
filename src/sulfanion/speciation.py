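"""Equilibrium speciation of dissolved H2S and SO2.

The dissolved-gas activity is fixed by Henry's law (ideal gas, fugacity =
partial pressure).  From there every anion follows by a mass-action
cascade written in activities:

    H2S  -> HS-  + H+        pKa 7.05
    HS-  -> S-2  + H+        pKa 19
    SO2  -> HSO3- + H+       pKa 1.86   (+ H2O)
    HSO3- -> SO3-2 + H+      pKa 7.2
    HSO3- + SO2 -> HS2O5-    pK 1.5     (adduct, second order in S(IV))
    H2O  -> OH- + H+         pKw 14

Two regimes are provided.  *Buffered*: the pH is imposed externally and
the cascade is evaluated in closed form (the buffer absorbs the charge
imbalance).  *Unbuffered*: the proton activity is the unknown; charge
conservation over the solved ions closes the system and is solved by
bracketed root finding on log10 a_H+ over the physical pH range [0, 14],
with the activity coefficients iterated to self-consistency with the
total ionic strength (background electrolyte + solved ions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import brentq

from . import activity as act
from . import constants as const

#: charge of every species that can appear in a SolutionState
SPECIES_CHARGE: dict[str, int] = {
    "H+": 1,
    "OH-": -1,
    "H2S": 0,
    "HS-": -1,
    "S-2": -2,
    "SO2": 0,
    "HSO3-": -1,
    "SO3-2": -2,
    "HS2O5-": -1,
}

_GAS_SPECIES: dict[str, tuple[str, ...]] = {
    "H2S": ("H2S", "HS-", "S-2"),
    "SO2": ("SO2", "HSO3-", "SO3-2", "HS2O5-"),
}

#: species -> parent gas, for threshold queries
SPECIES_GAS: dict[str, str] = {
    s: gas for gas, roster in _GAS_SPECIES.items() for s in roster
}


@dataclass(frozen=True)
class EquilibriumSystem:
    """The reaction set for one or both dissolving gases plus water."""

    gases: tuple[str, ...]

    def __post_init__(self) -> None:
        for gas in self.gases:
            if gas not in _GAS_SPECIES:
                raise const.UnknownConstantError(f"unregistered gas {gas!r}")

    @property
    def species(self) -> tuple[str, ...]:
        roster: list[str] = ["H+", "OH-"]
        for gas in self.gases:
            roster.extend(_GAS_SPECIES[gas])
        return tuple(roster)


def h2s_system() -> EquilibriumSystem:
    return EquilibriumSystem(("H2S",))


def so2_system() -> EquilibriumSystem:
    return EquilibriumSystem(("SO2",))


def joint_system() -> EquilibriumSystem:
    """Both gases dissolving simultaneously (total-outgassing sweeps)."""
    return EquilibriumSystem(("H2S", "SO2"))


@dataclass
class SolutionState:
    """Solver output: pH, total ionic strength, and per-species maps.

    ``activities`` are the thermodynamic activities entering the
    mass-action laws; ``concentrations`` are activities divided by the
    Extended Debye-Hueckel coefficients at ``ionic_strength``.
    """

    pH: float
    ionic_strength: float
    concentrations: dict[str, float]
    activities: dict[str, float]

    def charge_imbalance(self) -> float:
        """Sum z_i c_i over the solved species (excludes inert background)."""
        return sum(SPECIES_CHARGE[s] * c for s, c in self.concentrations.items())


class SpeciationError(RuntimeError):
    pass


class ConvergenceError(SpeciationError):
    pass


class UnreachableTargetError(SpeciationError):
    """Target concentration cannot be reached at any plausible pressure."""


def henry_dissolved(gas: str, p: float) -> float:
    """Dissolved neutral-gas concentration H_gas * p, mol L^-1."""
    if p < 0:
        raise ValueError(f"partial pressure must be >= 0, got {p}")
    return const.henry_constant(gas) * p


def _cascade_activities(
    gases: Mapping[str, float], a_h: float
) -> dict[str, float]:
    """Activities of every species given dissolved-gas activities and a_H+.

    ``gases`` maps gas -> partial pressure (bar).  Works with numpy arrays
    for a_h as well (used by the vectorized test oracle).
    """
    a: dict[str, float] = {"H+": a_h, "OH-": const.ka("W") / a_h}
    if "H2S" in gases:
        a["H2S"] = henry_dissolved("H2S", gases["H2S"])
        a["HS-"] = const.ka("H2S,1") * a["H2S"] / a_h
        a["S-2"] = const.ka("H2S,2") * a["HS-"] / a_h
    if "SO2" in gases:
        a["SO2"] = henry_dissolved("SO2", gases["SO2"])
        a["HSO3-"] = const.ka("SO2,1") * a["SO2"] / a_h
        a["SO3-2"] = const.ka("SO2,2") * a["HSO3-"] / a_h
        a["HS2O5-"] = const.ka("SO2,3") * a["SO2"] * a["HSO3-"]
    return a


def _gammas(species: Iterable[str], I: float) -> dict[str, float]:
    return {s: act.activity_coefficient(s, I) for s in species}


def speciate_buffered(
    system: EquilibriumSystem,
    pressures: Mapping[str, float],
    pH: float,
    I: float = 0.0,
) -> SolutionState:
    """Closed-form speciation at an externally imposed pH.

    The buffer is assumed to absorb any charge imbalance, so no charge
    balance is applied; ``I`` is taken as given (buffer + background).
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {pH}")
    if I < 0:
        raise ValueError(f"ionic strength must be >= 0, got {I}")
    gas_p = {g: float(pressures.get(g, 0.0)) for g in system.gases}
    a = _cascade_activities(gas_p, 10.0 ** (-pH))
    a = {s: a[s] for s in system.species}
    gamma = _gammas(a, I)
    conc = {s: a[s] / gamma[s] for s in a}
    return SolutionState(pH=pH, ionic_strength=I, concentrations=conc, activities=a)


def _charge_residual(
    gases: Mapping[str, float], a_h: float, gamma: Mapping[str, float]
):
    """Sum z_i [C_i] at proton activity a_h with fixed gammas."""
    a = _cascade_activities(gases, a_h)
    total = 0.0
    for s, av in a.items():
        z = SPECIES_CHARGE[s]
        if z:
            total = total + z * av / gamma[s]
    return total


def speciate_unbuffered(
    system: EquilibriumSystem,
    pressures: Mapping[str, float],
    background_I: float = 0.0,
    freeze_ionic_strength: bool = False,
    max_iter: int = 200,
    i_rtol: float = 1e-10,
) -> SolutionState:
    """Solve the fully coupled system: Henry's law, mass action, water
    equilibrium, and charge balance over the solved ions.

    The background electrolyte is inert and charge-symmetric: it adds
    ``background_I`` to the ionic strength but nothing to the charge
    balance.  Unless ``freeze_ionic_strength`` is set, the solved ions'
    own contribution to I is iterated to a fixed point.
    """
    if background_I < 0:
        raise ValueError(f"background ionic strength must be >= 0, got {background_I}")
    gas_p = {g: float(pressures.get(g, 0.0)) for g in system.gases}

    I = background_I
    state: SolutionState | None = None
    for _ in range(max_iter):
        gamma = _gammas(system.species, I)
        f = lambda x: _charge_residual(gas_p, 10.0**x, gamma)  # x = log10 a_H+
        lo, hi = -14.0, 0.0
        f_lo, f_hi = f(lo), f(hi)
        if f_lo == 0.0:
            x_root = lo
        elif f_hi == 0.0:
            x_root = hi
        elif f_lo * f_hi > 0:
            raise SpeciationError(
                "charge balance has no root in pH [0, 14]: "
                f"residual({-lo:.0f})={f_lo:.3e}, residual({-hi:.0f})={f_hi:.3e}"
            )
        else:
            x_root = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
        a_h = 10.0**x_root
        a = _cascade_activities(gas_p, a_h)
        a = {s: a[s] for s in system.species}
        conc = {s: a[s] / gamma[s] for s in a}
        state = SolutionState(
            pH=-x_root, ionic_strength=I, concentrations=conc, activities=a
        )
        if freeze_ionic_strength:
            return state
        I_new = background_I + act.ionic_strength(
            {s: c for s, c in conc.items()}, _ION_TABLE_FOR_SPECIATION
        )
        if abs(I_new - I) <= i_rtol * max(I_new, 1e-300):
            state.ionic_strength = I_new
            return state
        I = I_new
    residual = state.charge_imbalance() if state is not None else float("nan")
    raise ConvergenceError(
        f"ionic-strength fixed point not reached in {max_iter} iterations "
        f"(last charge residual {residual:.3e})"
    )


# ionic_strength needs charges for every speciation species; reuse the
# activity module's table (it covers the full roster).
_ION_TABLE_FOR_SPECIATION = act.DEFAULT_ION_TABLE


@dataclass(frozen=True)
class ThresholdResult:
    """Partial pressure sustaining a target anion concentration."""

    gas: str
    species: str
    target: float  # mol L^-1
    pressure: float  # bar, exact inversion
    decade_pressure: float  # 10^round(log10 p), ties toward -inf


def decade_round(p: float) -> float:
    """Round to the nearest decade; exact half-decades round down."""
    if p <= 0:
        raise ValueError(f"pressure must be positive, got {p}")
    return 10.0 ** math.ceil(math.log10(p) - 0.5)


def threshold_pressure(
    system: EquilibriumSystem,
    species: str,
    target: float,
    pH: float,
    I: float = 0.0,
    p_max: float = 1e2,
) -> ThresholdResult:
    """Invert the buffered cascade: partial pressure giving ``target``.

    Raises :class:`UnreachableTargetError` if no pressure up to ``p_max``
    bar (already far beyond plausible sulfur partial pressures) reaches
    the target -- e.g. millimolar S-2 at any near-neutral pH.
    """
    if species not in SPECIES_GAS:
        raise ValueError(f"{species!r} is not a gas-derived species")
    gas = SPECIES_GAS[species]
    if gas not in system.gases:
        raise ValueError(f"{species!r} does not descend from gases {system.gases}")
    if target <= 0:
        raise ValueError(f"target concentration must be positive, got {target}")

    def conc_at(log_p: float) -> float:
        st = speciate_buffered(system, {gas: 10.0**log_p}, pH, I)
        return st.concentrations[species]

    lo, hi = -30.0, math.log10(p_max)
    f = lambda x: math.log10(conc_at(x)) - math.log10(target)
    if f(hi) < 0:
        raise UnreachableTargetError(
            f"[{species}] = {target} M is not reachable at pH {pH} for any "
            f"p{gas} <= {p_max} bar (max [{species}] = {conc_at(hi):.3e} M)"
        )
    if f(lo) > 0:
        raise UnreachableTargetError(
            f"[{species}] = {target} M is exceeded even at p{gas} = 1e{lo:.0f} bar"
        )
    x = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    p = 10.0**x
    return ThresholdResult(
        gas=gas,
        species=species,
        target=target,
        pressure=p,
        decade_pressure=decade_round(p),
    )


def sweep_table(
    system: EquilibriumSystem,
    pressure_grids: Mapping[str, np.ndarray],
    pH: float | None,
    I: float = 0.0,
    freeze_ionic_strength: bool = False,
):
    """Speciation over a pressure grid -> pandas DataFrame.

    ``pH=None`` selects the unbuffered solver (``I`` is then the inert
    background ionic strength).  Grids for several gases are zipped,
    not crossed; they must share a length.
    """
    import pandas as pd

    gases = list(pressure_grids)
    lengths = {len(v) for v in pressure_grids.values()}
    if len(lengths) > 1:
        raise ValueError("pressure grids must have equal lengths")
    n = lengths.pop() if lengths else 0
    rows = []
    for i in range(n):
        p = {g: float(pressure_grids[g][i]) for g in gases}
        if pH is None:
            st = speciate_unbuffered(
                system, p, background_I=I, freeze_ionic_strength=freeze_ionic_strength
            )
        else:
            st = speciate_buffered(system, p, pH, I)
        row: dict[str, float] = {f"p_{g}_bar": p[g] for g in gases}
        row["pH"] = st.pH
        row["I_M"] = st.ionic_strength
        for s in system.species:
            row[f"{s}_M"] = st.concentrations[s]
        rows.append(row)
    cols = (
        [f"p_{g}_bar" for g in gases]
        + ["pH", "I_M"]
        + [f"{s}_M" for s in system.species]
    )
    return pd.DataFrame(rows, columns=cols)
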