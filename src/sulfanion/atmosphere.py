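"""Sulfur outgassing flux -> atmospheric H2S / SO2 mixing ratios.

Photochemistry models resolve the full reaction network; this module
only interpolates between their published anchor points (flux,
mixing-ratio pairs).  Interpolation is log-log linear per gas, exact at
the anchors; extrapolation beyond a gas's anchor range fails loudly
unless explicitly enabled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhotochemAnchor:
    """One published (Phi_S, mixing ratio) point from a photochemistry model.

    ``ratio_kind`` records whether the published value is a surface or a
    column-integrated mixing ratio; column-integrated values modestly
    underestimate the surface value and no correction is applied.
    """

    phi_s: float  # molecules cm^-2 s^-1
    r_h2s: float | None
    r_so2: float | None
    model: str = ""
    ratio_kind: str = "column"  # "surface" | "column"


#: Hu et al. high-CO2 case (0.9 bar CO2 + 0.1 bar N2), column-integrated.
HU_HIGH_CO2: tuple[PhotochemAnchor, ...] = (
    PhotochemAnchor(3e9, 4e-10, 3e-10, "hu_high_co2", "column"),
    PhotochemAnchor(1e10, 1e-9, 9e-10, "hu_high_co2", "column"),
    PhotochemAnchor(10**11.5, None, 1e-8, "hu_high_co2", "column"),
)

#: Alternate literature anchor sets (surface mixing ratios), for comparison.
KASTING: tuple[PhotochemAnchor, ...] = (
    PhotochemAnchor(3e9, 2e-10, 2e-9, "kasting", "surface"),
)
CLAIRE: tuple[PhotochemAnchor, ...] = (
    PhotochemAnchor(3e9, 1e-11, 5e-11, "claire", "surface"),
    PhotochemAnchor(1e10, 3e-11, 1e-10, "claire", "surface"),
)

ANCHOR_SETS: dict[str, tuple[PhotochemAnchor, ...]] = {
    "hu_high_co2": HU_HIGH_CO2,
    "kasting": KASTING,
    "claire": CLAIRE,
}


@dataclass(frozen=True)
class AtmosphereModel:
    """Bulk pressure plus the anchor set tying mixing ratios to Phi_S."""

    anchors: tuple[PhotochemAnchor, ...] = HU_HIGH_CO2
    total_pressure: float = 1.0  # bar (0.9 bar CO2 + 0.1 bar N2 default)
    name: str = "hu_high_co2"


def default_model() -> AtmosphereModel:
    return AtmosphereModel()


class AnchorRangeError(ValueError):
    """Requested flux lies outside the anchor range for a gas."""


def _gas_anchors(model: AtmosphereModel, gas: str) -> tuple[np.ndarray, np.ndarray]:
    attr = {"H2S": "r_h2s", "SO2": "r_so2"}[gas]
    pts = [(a.phi_s, getattr(a, attr)) for a in model.anchors if getattr(a, attr) is not None]
    if not pts:
        raise AnchorRangeError(f"anchor set {model.name!r} has no {gas} anchors")
    pts.sort()
    phi, r = map(np.asarray, zip(*pts))
    return phi, r


def mixing_ratio(
    model: AtmosphereModel, gas: str, phi_s: float, extrapolate: bool = False
) -> float:
    """Log-log interpolated mixing ratio of ``gas`` at flux ``phi_s``."""
    phi, r = _gas_anchors(model, gas)
    hit = np.nonzero(phi == phi_s)[0]
    if hit.size:  # anchors are reproduced bit-exactly, no log round trip
        return float(r[hit[0]])
    if not extrapolate and not (phi[0] <= phi_s <= phi[-1]):
        raise AnchorRangeError(
            f"Phi_S = {phi_s:.3g} outside {gas} anchor range "
            f"[{phi[0]:.3g}, {phi[-1]:.3g}] of {model.name!r}; "
            "pass extrapolate=True to force"
        )
    if len(phi) == 1:
        if phi_s != phi[0] and not extrapolate:
            raise AnchorRangeError(
                f"single {gas} anchor at Phi_S = {phi[0]:.3g} in {model.name!r}"
            )
        return float(r[0])
    kinds = {a.ratio_kind for a in model.anchors}
    log.debug("mixing_ratio(%s, %s, %.3g) using %s anchors", model.name, gas, phi_s, kinds)
    logr = np.interp(math.log10(phi_s), np.log10(phi), np.log10(r))
    if extrapolate and not (phi[0] <= phi_s <= phi[-1]):
        # np.interp clamps; extend the end segments instead
        lp = math.log10(phi_s)
        lphi, lr = np.log10(phi), np.log10(r)
        if lp < lphi[0]:
            slope = (lr[1] - lr[0]) / (lphi[1] - lphi[0])
            logr = lr[0] + slope * (lp - lphi[0])
        else:
            slope = (lr[-1] - lr[-2]) / (lphi[-1] - lphi[-2])
            logr = lr[-1] + slope * (lp - lphi[-1])
    return float(10.0**logr)


def mixing_ratios(
    model: AtmosphereModel, phi_s: float, extrapolate: bool = False
) -> tuple[float, float]:
    """(r_H2S, r_SO2) at flux ``phi_s``; fails if either gas lacks anchors."""
    return (
        mixing_ratio(model, "H2S", phi_s, extrapolate),
        mixing_ratio(model, "SO2", phi_s, extrapolate),
    )


def partial_pressure(model: AtmosphereModel, r: float) -> float:
    """Mixing ratio times bulk pressure, bar."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"mixing ratio must lie in [0, 1], got {r}")
    return r * model.total_pressure


def partial_pressures(
    model: AtmosphereModel, phi_s: float, extrapolate: bool = False
) -> dict[str, float]:
    """Partial pressures of both gases at ``phi_s`` (bar)."""
    r_h2s, r_so2 = mixing_ratios(model, phi_s, extrapolate)
    return {
        "H2S": partial_pressure(model, r_h2s),
        "SO2": partial_pressure(model, r_so2),
    }


def gas_anchor_range(model: AtmosphereModel, gas: str) -> tuple[float, float]:
    phi, _ = _gas_anchors(model, gas)
    return float(phi[0]), float(phi[-1])


def load_anchors(path: str, name: str = "custom") -> AtmosphereModel:
    """Load an anchor set from YAML.

    Format::

        total_pressure: 1.0
        anchors:
          - {phi_s: 3.0e9, r_h2s: 4.0e-10, r_so2: 3.0e-10, ratio_kind: column}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    anchors = tuple(
        PhotochemAnchor(
            phi_s=float(rec["phi_s"]),
            r_h2s=None if rec.get("r_h2s") is None else float(rec["r_h2s"]),
            r_so2=None if rec.get("r_so2") is None else float(rec["r_so2"]),
            model=name,
            ratio_kind=rec.get("ratio_kind", "column"),
        )
        for rec in raw["anchors"]
    )
    return AtmosphereModel(
        anchors=anchors,
        total_pressure=float(raw.get("total_pressure", 1.0)),
        name=name,
    )
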