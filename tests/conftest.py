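"""Shared fixtures and independent oracles.

The oracles deliberately avoid the code paths they check: the pH oracle
is a dense grid scan of the charge-balance residual, and the lake oracle
is an explicit ODE relaxation to the fixed point.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sulfanion import activity as act
from sulfanion import lake as lake_mod
from sulfanion import speciation as sp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def brute_force_ph(
    gas_pressures: dict[str, float],
    background_I: float = 0.0,
    step: float = 1e-4,
) -> float:
    """Grid scan of pH in [0, 14] minimizing |charge-balance residual|.

    Gammas are evaluated at the background ionic strength (the frozen-I
    convention), making this a direct independent minimization of the
    same physical residual the root solver zeroes.
    """
    grid = np.arange(0.0, 14.0 + step / 2, step)
    a_h = 10.0 ** (-grid)
    a = sp._cascade_activities(gas_pressures, a_h)
    resid = np.zeros_like(grid)
    for s, av in a.items():
        z = sp.SPECIES_CHARGE[s]
        if z:
            gamma = act.activity_coefficient(s, background_I)
            resid += z * av / gamma
    return float(grid[int(np.argmin(np.abs(resid)))])


def relax_lake_ode(
    lake: lake_mod.LakeConfig,
    rates: lake_mod.RateModel,
    r_h2s: float,
    r_so2: float,
    rtol: float = 1e-10,
) -> tuple[float, float]:
    """Time-step the two lake ODEs to their fixed point.

    Returns (hs, s4) in mol/L.  Integration horizon is set from the
    closed-form no-comproportionation estimate of the relaxation times,
    so it does not peek at the algebraic solution under test.
    """
    from scipy.integrate import solve_ivp

    f_h2s = lake_mod.deposition_flux_molar(r_h2s, lake, lake.v_dep_h2s)
    f_so2 = lake_mod.deposition_flux_molar(r_so2, lake, lake.v_dep_so2)
    _, f_hso3, _ = lake_mod.s4_fractions(lake.pH)

    def rhs(_t, y):
        hs, s4 = y
        hso3 = f_hso3 * s4
        r18 = rates.k18 * hs * hso3**2
        return [f_h2s - (2.0 / 3.0) * r18, f_so2 - (4.0 / 3.0) * r18 - rates.k17 * s4]

    s4_est = f_so2 / rates.k17
    hso3_est = f_hso3 * s4_est
    tau_s4 = 1.0 / rates.k17
    tau_hs = 1.0 / ((2.0 / 3.0) * rates.k18 * hso3_est**2)
    t_final = 300.0 * max(tau_s4, tau_hs)
    sol = solve_ivp(
        rhs,
        (0.0, t_final),
        [0.0, 0.0],
        method="BDF",
        rtol=rtol,
        atol=[1e-20, 1e-20],
    )
    assert sol.success, sol.message
    hs, s4 = sol.y[:, -1]
    # confirm the derivatives have actually relaxed
    dhs, ds4 = rhs(0.0, [hs, s4])
    assert abs(dhs) <= 1e-6 * f_h2s and abs(ds4) <= 1e-6 * f_so2
    return float(hs), float(s4)


@pytest.fixture(scope="session")
def h2s_sys():
    return sp.h2s_system()


@pytest.fixture(scope="session")
def so2_sys():
    return sp.so2_system()


@pytest.fixture(scope="session")
def joint_sys():
    return sp.joint_system()
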