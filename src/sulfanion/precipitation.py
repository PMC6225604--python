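"""First-order calcium-sulfite precipitation screen.

Chain: pCO2 + pH -> carbonate speciation (Henry + two pKa steps, gamma=1)
-> calcite-equilibrium [Ca2+] = Ksp(CaCO3)/[CO3-2] -> CaSO3 saturation
threshold Ksp(CaSO3)/[Ca2+] on sulfite.  Two precision modes: ``full``
carries every digit; ``paper`` rounds each chained intermediate to one
significant figure, the convention of back-of-envelope geochemical
estimates (0.03 M -> 6e-5 M -> 6e-5 M -> 5e-3 M for 0.9 bar CO2 at
neutral pH).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import constants as const


def round_sig(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` significant figures."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + ndigits - 1)


def _maybe_round(x: float, faithful: bool) -> float:
    return round_sig(x) if faithful else x


@dataclass(frozen=True)
class CarbonateState:
    pco2: float  # bar
    pH: float
    co2_aq_molar: float
    hco3_molar: float
    co3_molar: float


def carbonate_speciation(pco2: float, pH: float, faithful: bool = False) -> CarbonateState:
    """Carbonate system at fixed pH, saturated in CO2 (gamma = 1)."""
    if pco2 < 0:
        raise ValueError(f"pCO2 must be >= 0, got {pco2}")
    co2_aq = _maybe_round(const.henry_constant("CO2") * pco2, faithful)
    hco3 = _maybe_round(co2_aq * 10.0 ** (pH - const.pka("CO2,1")), faithful)
    co3 = _maybe_round(
        co2_aq
        * 10.0 ** (pH - const.pka("CO2,1"))
        * 10.0 ** (pH - const.pka("CO2,2")),
        faithful,
    )
    return CarbonateState(pco2=pco2, pH=pH, co2_aq_molar=co2_aq, hco3_molar=hco3, co3_molar=co3)


def calcium_from_calcite(co3_molar: float, faithful: bool = False) -> float:
    """[Ca2+] in equilibrium with calcite: Ksp(CaCO3)/[CO3-2]."""
    if co3_molar <= 0:
        raise ValueError(
            "carbonate concentration must be positive; unbounded calcium is "
            "unphysical in this screen"
        )
    return _maybe_round(const.solubility_product("CaCO3") / co3_molar, faithful)


def sulfite_saturation_threshold(calcium_molar: float, faithful: bool = False) -> float:
    """[SO3-2] at which CaSO3 begins to precipitate: Ksp(CaSO3)/[Ca2+]."""
    if calcium_molar <= 0:
        raise ValueError("calcium concentration must be positive")
    return _maybe_round(const.solubility_product("CaSO3") / calcium_molar, faithful)


def precipitates(sulfite_molar: float, threshold_molar: float) -> bool:
    """Does CaSO3 form at this sulfite level?  Saturation check."""
    if sulfite_molar < 0:
        raise ValueError("sulfite concentration must be >= 0")
    return sulfite_molar >= threshold_molar


@dataclass(frozen=True)
class PrecipitationReport:
    """Full §-style chain record: inputs, intermediates, threshold, verdict."""

    pco2: float
    pH: float
    mode: str  # "full" | "paper"
    co2_aq_molar: float
    co3_molar: float
    calcium_molar: float
    threshold_molar: float
    sulfite_molar: float | None
    precipitates: bool | None
    acid_regime: bool  # low pH: carbonate solubility exceeds sulfite solubility

    def as_dict(self) -> dict:
        return {
            "pCO2_bar": self.pco2,
            "pH": self.pH,
            "mode": self.mode,
            "CO2_aq_M": self.co2_aq_molar,
            "CO3-2_M": self.co3_molar,
            "Ca+2_M": self.calcium_molar,
            "CaSO3_threshold_M": self.threshold_molar,
            "sulfite_M": self.sulfite_molar,
            "precipitates": self.precipitates,
            "acid_regime": self.acid_regime,
        }


def report(
    pco2: float,
    pH: float,
    mode: str = "full",
    sulfite_molar: float | None = None,
) -> PrecipitationReport:
    """Run the whole screen as one structured record.

    In acidic water (pH below the first carbonate pKa) carbonate is so
    soluble that the calcite control on calcium breaks down and sulfite
    salts may precipitate instead; the record only flags this regime,
    since no first-order closed form exists for it.
    """
    if mode not in ("full", "paper"):
        raise ValueError(f"mode must be 'full' or 'paper', got {mode!r}")
    faithful = mode == "paper"
    carb = carbonate_speciation(pco2, pH, faithful)
    ca = calcium_from_calcite(carb.co3_molar, faithful)
    thr = sulfite_saturation_threshold(ca, faithful)
    return PrecipitationReport(
        pco2=pco2,
        pH=pH,
        mode=mode,
        co2_aq_molar=carb.co2_aq_molar,
        co3_molar=carb.co3_molar,
        calcium_molar=ca,
        threshold_molar=thr,
        sulfite_molar=sulfite_molar,
        precipitates=None if sulfite_molar is None else precipitates(sulfite_molar, thr),
        acid_regime=pH < const.pka("CO2,1"),
    )
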