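"""Redox-limited dynamic steady state of a shallow, pH-buffered lake.

Source: dry deposition of atmospheric H2S and SO2 over the catchment.
Sinks: sulfite disproportionation (first order in total S(IV), rate k17)
and hydrosulfide/bisulfite comproportionation (rate law
k18 [HS-][HSO3-]^2).  Per unit lake volume, the steady-state balance is

    F_H2S = (2/3) k18 [HS-][HSO3-]^2
    F_SO2 = (4/3) k18 [HS-][HSO3-]^2 + k17 [S(IV)]

with F_gas = r_gas n_atm v_dep (A_catch/A_lake) / d_lake converted to
mol L^-1 s^-1, and [HSO3-] tied to [S(IV)] by the pKa cascade at the
lake's fixed pH (activity-free).  The first equation gives the
comproportionation rate directly; substituting into the second yields
[S(IV)] in closed form, after which [HS-] follows.  If the implied
[H2S(aq)] exceeds the Henry-equilibrium value the lake would degas, so
[HS-] is capped at the Henry-equilibrium value and [S(IV)] re-solved
with [HS-] held fixed (a quadratic).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import atmosphere as atm
from . import constants as const
from .speciation import henry_dissolved

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LakeConfig:
    """Geometry, deposition, and fixed-pH parameters of the model lake."""

    depth_cm: float = 100.0
    v_dep_h2s: float = 0.015  # cm s^-1
    v_dep_so2: float = 1.0  # cm s^-1
    catchment_ratio: float = 1.0  # A_catch / A_lake
    pH: float = 7.0
    temperature: float = 288.0  # K
    n_atm: float = const.N_ATM  # molecules cm^-3


@dataclass(frozen=True)
class RateModel:
    """Rate coefficients for the two redox sinks.

    k18 was measured at pH 9, I = 0.2 M; it is applied unchanged to the
    (default pH 7) lake, which is logged as a caveat.
    """

    k17: float  # s^-1
    k18: float = 4e3  # M^-2 s^-1 at 293 K

    @classmethod
    def fast(cls, temperature: float = 293.0) -> "RateModel":
        return cls(k17=const.arrhenius_k17(temperature, const.K17_EA_FAST))

    @classmethod
    def slow(cls, temperature: float = 293.0) -> "RateModel":
        return cls(k17=const.arrhenius_k17(temperature, const.K17_EA_SLOW))


@dataclass
class SteadyState:
    """Solved lake steady state (all concentrations mol L^-1)."""

    hs_molar: float
    s4_molar: float
    so2_aq_molar: float
    hso3_molar: float
    so3_molar: float
    solubility_capped: bool
    hs_uncapped_molar: float
    s4_uncapped_molar: float
    degassing_flux_molar_s: float  # H2S return flux when capped, M/s
    so2_exceeds_henry: bool

    @property
    def so2_anion_sum_molar(self) -> float:
        """[HSO3-] + [SO3-2], the prebiotically relevant SO2-derived pool."""
        return self.hso3_molar + self.so3_molar


class LakeSolveError(RuntimeError):
    pass


def s4_fractions(pH: float) -> tuple[float, float, float]:
    """(f_SO2, f_HSO3, f_SO3) of total S(IV) at fixed pH, gamma = 1.

    The disulfite adduct is dropped from the S(IV) budget, consistent
    with its negligible abundance at these concentrations.
    """
    h = 10.0 ** (-pH)
    w1 = const.ka("SO2,1") / h
    w2 = w1 * const.ka("SO2,2") / h
    total = 1.0 + w1 + w2
    return 1.0 / total, w1 / total, w2 / total


def deposition_flux_molar(
    r: float, lake: LakeConfig, v_dep: float
) -> float:
    """Deposition source per unit lake volume, mol L^-1 s^-1."""
    flux_cm2 = r * lake.n_atm * v_dep * lake.catchment_ratio  # molec cm^-2 s^-1
    return const.number_density_to_molar(flux_cm2 / lake.depth_cm)


def steady_state_from_ratios(
    lake: LakeConfig,
    rates: RateModel,
    r_h2s: float,
    r_so2: float,
    total_pressure: float = 1.0,
) -> SteadyState:
    """Solve the two-equation steady state given mixing ratios."""
    if rates.k17 <= 0 or rates.k18 < 0:
        raise ValueError("rate coefficients must be positive (k18 may be 0)")
    f_h2s = deposition_flux_molar(r_h2s, lake, lake.v_dep_h2s)
    f_so2 = deposition_flux_molar(r_so2, lake, lake.v_dep_so2)

    f_so2_frac, f_hso3, f_so3 = s4_fractions(lake.pH)

    if rates.k18 == 0.0:
        # no comproportionation: SO2 balance closes on its own and HS- has
        # no sink (no steady state for the H2S side)
        s4 = f_so2 / rates.k17
        ss = SteadyState(
            hs_molar=float("nan"),
            s4_molar=s4,
            so2_aq_molar=f_so2_frac * s4,
            hso3_molar=f_hso3 * s4,
            so3_molar=f_so3 * s4,
            solubility_capped=False,
            hs_uncapped_molar=float("nan"),
            s4_uncapped_molar=s4,
            degassing_flux_molar_s=0.0,
            so2_exceeds_henry=False,
        )
        return ss

    # Eq for H2S fixes the comproportionation rate; substitute.
    r18 = 1.5 * f_h2s  # = k18 [HS-][HSO3-]^2, M/s
    s4 = (f_so2 - 2.0 * f_h2s) / rates.k17
    if s4 <= 0:
        raise LakeSolveError(
            "negative S(IV) root: H2S deposition consumes more S(IV) than "
            f"SO2 deposition supplies (F_SO2={f_so2:.3e}, F_H2S={f_h2s:.3e} M/s)"
        )
    hso3 = f_hso3 * s4
    hs = r18 / (rates.k18 * hso3**2) if r18 > 0 else 0.0

    # Henry solubility cap on HS-: the [H2S(aq)] in equilibrium with the
    # solved [HS-] at the lake pH must not exceed the Henry value.
    h = 10.0 ** (-lake.pH)
    p_h2s = r_h2s * total_pressure
    hs_cap = const.ka("H2S,1") * henry_dissolved("H2S", p_h2s) / h
    capped = hs > hs_cap
    hs_unc, s4_unc = hs, s4
    degas = 0.0
    so2_flag = False
    if capped:
        # re-solve Eq for SO2 with [HS-] fixed at the cap:
        #   f_so2 = (4/3) k18 hs_cap (f_hso3 s4)^2 + k17 s4
        a = (4.0 / 3.0) * rates.k18 * hs_cap * f_hso3**2
        if a > 0:
            s4 = (-rates.k17 + math.sqrt(rates.k17**2 + 4.0 * a * f_so2)) / (2.0 * a)
        else:
            s4 = f_so2 / rates.k17
        hso3 = f_hso3 * s4
        hs = hs_cap
        # H2S balance now closed by degassing of the excess deposition
        degas = f_h2s - (2.0 / 3.0) * rates.k18 * hs * hso3**2
        log.info(
            "HS- solubility-capped at %.3e M (uncapped %.3e M); "
            "H2S degassing flux %.3e M/s",
            hs_cap,
            hs_unc,
            degas,
        )

    so2_aq = f_so2_frac * s4
    so2_henry = henry_dissolved("SO2", r_so2 * total_pressure)
    if so2_aq > so2_henry:
        so2_flag = True
        warnings.warn(
            f"steady-state [SO2(aq)] = {so2_aq:.3e} M exceeds its Henry "
            f"equilibrium value {so2_henry:.3e} M; the lake would partially "
            "degas SO2 and the reported S(IV) is an upper bound",
            stacklevel=2,
        )
    return SteadyState(
        hs_molar=hs,
        s4_molar=s4,
        so2_aq_molar=so2_aq,
        hso3_molar=hso3,
        so3_molar=f_so3 * s4,
        solubility_capped=capped,
        hs_uncapped_molar=hs_unc,
        s4_uncapped_molar=s4_unc,
        degassing_flux_molar_s=degas,
        so2_exceeds_henry=so2_flag,
    )


def steady_state(
    lake: LakeConfig,
    rates: RateModel,
    atmosphere: atm.AtmosphereModel,
    phi_s: float,
) -> SteadyState:
    """Steady state at sulfur outgassing flux ``phi_s`` (anchor range)."""
    r_h2s, r_so2 = atm.mixing_ratios(atmosphere, phi_s)
    return steady_state_from_ratios(
        lake, rates, r_h2s, r_so2, total_pressure=atmosphere.total_pressure
    )


def sensitivity_sweep(
    lake: LakeConfig,
    atmosphere: atm.AtmosphereModel,
    phi_grid,
    k17_values,
    k18: float = 4e3,
) -> pd.DataFrame:
    """One row per (Phi_S, k17): the data behind the dynamic-lake figure."""
    rows = []
    for phi in phi_grid:
        for k17 in k17_values:
            ss = steady_state(lake, RateModel(k17=k17, k18=k18), atmosphere, phi)
            rows.append(
                {
                    "phi_s": phi,
                    "k17_s": k17,
                    "HS-_M": ss.hs_molar,
                    "S(IV)_M": ss.s4_molar,
                    "SO2_M": ss.so2_aq_molar,
                    "HSO3-_M": ss.hso3_molar,
                    "SO3-2_M": ss.so3_molar,
                    "HS-_uncapped_M": ss.hs_uncapped_molar,
                    "solubility_capped": ss.solubility_capped,
                    "so2_exceeds_henry": ss.so2_exceeds_henry,
                }
            )
    return pd.DataFrame(rows)
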