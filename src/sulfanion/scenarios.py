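"""Packaged default scenarios and seeded random scenario generation.

A Scenario bundles everything one model run needs: which gas(es)
dissolve, whether the reservoir is buffered (and to what pH) or
unbuffered, the background ionic strength, per-gas pressure grids or an
outgassing flux, and the lake/rate parameters for dynamic runs.  The
packaged set mirrors the study conditions: three representative buffered
pH values (8.2 modern ocean, 7 near-neutral experiment buffer, 4.25
CO2-rich-atmosphere raindrops), unbuffered reservoirs at I = 0 and
0.1 M, and the published flux anchors for the outgassing sweeps.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import constants as const
from .lake import LakeConfig, RateModel

#: Buffered reservoir pH values spanning ocean, neutral lab buffer, raindrops.
REPRESENTATIVE_PH = (8.2, 7.0, 4.25)

#: Pressure-grid decades spanning the speciation sweeps (bar).
PRESSURE_DECADES = (-12.0, -4.0)

#: Flux anchors with both gases constrained (cm^-2 s^-1).
JOINT_FLUX_ANCHORS = (3e9, 1e10)
#: Flux anchors with at least SO2 constrained.
SO2_FLUX_ANCHORS = (3e9, 1e10, 10**11.5)


@dataclass(frozen=True)
class Scenario:
    """One fully specified model run."""

    name: str
    gases: tuple[str, ...] = ("SO2",)
    mode: str = "buffered"  # "buffered" | "unbuffered"
    pH: float | None = 7.0  # None for unbuffered
    ionic_strength: float = 0.0  # buffered: I as given; unbuffered: background
    #: gas -> pressure grid in bar; grids are zipped row-wise, equal lengths
    pressures: dict[str, tuple[float, ...]] | None = None
    phi_s: float | None = None  # cm^-2 s^-1, for flux-driven runs
    atmosphere: str = "hu_high_co2"
    lake: LakeConfig = field(default_factory=LakeConfig)
    rates: RateModel = field(default_factory=RateModel.fast)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("buffered", "unbuffered"):
            raise ValueError(f"mode must be buffered|unbuffered, got {self.mode!r}")
        if self.mode == "buffered" and self.pH is None:
            raise ValueError("buffered scenarios need a pH")
        if self.pressures is not None:
            lengths = {len(g) for g in self.pressures.values()}
            if len(lengths) > 1:
                raise ValueError("per-gas pressure grids must share a length")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gases"] = list(self.gases)
        if self.pressures is not None:
            d["pressures"] = {g: list(v) for g, v in self.pressures.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        d["gases"] = tuple(d["gases"])
        if d.get("pressures") is not None:
            d["pressures"] = {g: tuple(v) for g, v in d["pressures"].items()}
        d["lake"] = LakeConfig(**d["lake"])
        d["rates"] = RateModel(**d["rates"])
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _log_grid(n: int = 33) -> tuple[float, ...]:
    lo, hi = PRESSURE_DECADES
    return tuple(float(p) for p in np.logspace(lo, hi, n))


def paper_scenarios() -> list[Scenario]:
    """The packaged fixture set behind the four study computations."""
    grid = _log_grid()
    out: list[Scenario] = []
    for gas in ("H2S", "SO2"):
        for ph in REPRESENTATIVE_PH:
            out.append(
                Scenario(
                    name=f"buffered_{gas.lower()}_ph{ph:g}",
                    gases=(gas,),
                    mode="buffered",
                    pH=ph,
                    ionic_strength=0.0,
                    pressures={gas: grid},
                )
            )
        for bg_i in (0.0, 0.1):
            out.append(
                Scenario(
                    name=f"unbuffered_{gas.lower()}_i{bg_i:g}",
                    gases=(gas,),
                    mode="unbuffered",
                    pH=None,
                    ionic_strength=bg_i,
                    pressures={gas: grid},
                )
            )
    for phi in SO2_FLUX_ANCHORS:
        out.append(
            Scenario(
                name=f"flux_equilibrium_phi{phi:.3g}",
                gases=("H2S", "SO2"),
                mode="buffered",
                pH=7.0,
                phi_s=float(phi),
            )
        )
    for phi in JOINT_FLUX_ANCHORS:
        out.append(
            Scenario(
                name=f"flux_dynamic_phi{phi:.3g}",
                gases=("H2S", "SO2"),
                mode="buffered",
                pH=7.0,
                phi_s=float(phi),
            )
        )
    return out


_GAS_CHOICES: tuple[tuple[str, ...], ...] = (("H2S",), ("SO2",), ("H2S", "SO2"))


def random_scenarios(n: int, seed: int) -> list[Scenario]:
    """Deterministic random parameter draws for property testing.

    Pressures log-uniform over [1e-12, 1e-4] bar, pH uniform over
    [2, 10], background I uniform over [0, 0.1] M, k17 log-uniform
    between the slow and fast Arrhenius bounds at the lake temperature.
    The ranges bracket every regime the packaged sweeps cover.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    lake = LakeConfig()
    k_lo = const.arrhenius_k17(lake.temperature, const.K17_EA_SLOW)
    k_hi = const.arrhenius_k17(lake.temperature, const.K17_EA_FAST)
    out = []
    for i in range(n):
        gases = _GAS_CHOICES[int(rng.integers(0, len(_GAS_CHOICES)))]
        mode = "buffered" if rng.integers(0, 2) else "unbuffered"
        ph = float(rng.uniform(2.0, 10.0)) if mode == "buffered" else None
        pressures = {g: (float(10.0 ** rng.uniform(-12.0, -4.0)),) for g in gases}
        k17 = float(10.0 ** rng.uniform(np.log10(k_lo), np.log10(k_hi)))
        out.append(
            Scenario(
                name=f"random_{seed}_{i}",
                gases=gases,
                mode=mode,
                pH=ph,
                ionic_strength=float(rng.uniform(0.0, 0.1)),
                pressures=pressures,
                rates=RateModel(k17=k17),
                seed=seed,
            )
        )
    return out
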