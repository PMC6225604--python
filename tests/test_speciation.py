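"""Equilibrium speciation: buffered cascade, unbuffered root solve,
threshold inversion, and their invariants."""

import math

import numpy as np
import pytest

from sulfanion import activity as act
from sulfanion import constants as const
from sulfanion import scenarios as scn
from sulfanion import speciation as sp

from conftest import brute_force_ph


@pytest.mark.parametrize(
    "gas, p, expected",
    [
        ("SO2", 1.0, 1.34),
        ("H2S", 0.0, 0.0),
        ("H2S", 1e-6, 1.01e-7),
    ],
)
def test_henry_dissolved(gas, p, expected):
    assert sp.henry_dissolved(gas, p) == pytest.approx(expected, rel=1e-12)


def test_henry_rejects_bad_input():
    with pytest.raises(ValueError):
        sp.henry_dissolved("SO2", -1.0)
    with pytest.raises(const.UnknownConstantError):
        sp.henry_dissolved("N2", 1.0)


class TestBuffered:
    def test_bisulfite_at_neutral_ph(self, so2_sys):
        # closed form: 1.34e-8 * 10^(7 - 1.86)
        st = sp.speciate_buffered(so2_sys, {"SO2": 1e-8}, 7.0)
        assert st.concentrations["HSO3-"] == pytest.approx(1.8497e-3, rel=1e-3)

    def test_sulfite_equals_bisulfite_at_its_pka(self, so2_sys):
        st = sp.speciate_buffered(so2_sys, {"SO2": 3e-9}, 7.2)
        assert st.concentrations["SO3-2"] == pytest.approx(
            st.concentrations["HSO3-"], rel=1e-12
        )

    def test_hydrosulfide_at_ocean_ph(self, h2s_sys):
        # closed form: 1.01e-7 * 10^(8.2 - 7.05)
        st = sp.speciate_buffered(h2s_sys, {"H2S": 1e-6}, 8.2)
        assert st.concentrations["HS-"] == pytest.approx(1.4268e-6, rel=1e-3)

    def test_ph_domain_enforced(self, so2_sys):
        with pytest.raises(ValueError):
            sp.speciate_buffered(so2_sys, {"SO2": 1e-8}, -0.5)
        with pytest.raises(ValueError):
            sp.speciate_buffered(so2_sys, {"SO2": 1e-8}, 14.5)

    def test_mass_action_satisfied_in_activities(self, joint_sys):
        """Every modeled equilibrium holds to relative 1e-8 in activities."""
        st = sp.speciate_buffered(joint_sys, {"H2S": 3e-7, "SO2": 2e-9}, 6.3, I=0.05)
        a = st.activities
        h = a["H+"]
        checks = [
            (a["HS-"] * h / a["H2S"], const.ka("H2S,1")),
            (a["S-2"] * h / a["HS-"], const.ka("H2S,2")),
            (a["HSO3-"] * h / a["SO2"], const.ka("SO2,1")),
            (a["SO3-2"] * h / a["HSO3-"], const.ka("SO2,2")),
            (a["HS2O5-"] / (a["SO2"] * a["HSO3-"]), const.ka("SO2,3")),
            (a["OH-"] * h, const.ka("W")),
        ]
        for lhs, k in checks:
            assert lhs == pytest.approx(k, rel=1e-8)

    def test_anions_nondecreasing_in_pressure(self, so2_sys, h2s_sys):
        grid = np.logspace(-12, -4, 17)
        for system, gas in ((so2_sys, "SO2"), (h2s_sys, "H2S")):
            prev = None
            for p in grid:
                st = sp.speciate_buffered(system, {gas: p}, 7.0)
                cur = {s: st.concentrations[s] for s in system.species if s not in ("H+", "OH-")}
                if prev is not None:
                    for s in cur:
                        assert cur[s] >= prev[s]
                prev = cur


class TestUnbuffered:
    def test_pure_water_is_neutral(self, so2_sys):
        st = sp.speciate_unbuffered(so2_sys, {"SO2": 0.0})
        # the tiny self-consistent I (1e-7 M) shifts pH by < 1e-7
        assert st.pH == pytest.approx(7.0, abs=1e-6)

    def test_so2_acidifies(self, so2_sys):
        # brute-force oracle value ~4.87 (x^2 ~ Kw + Ka1 H p)
        st = sp.speciate_unbuffered(so2_sys, {"SO2": 1e-8})
        assert st.pH == pytest.approx(4.87, abs=0.01)
        oracle = brute_force_ph({"SO2": 1e-8})
        assert st.pH == pytest.approx(oracle, abs=2e-4)

    def test_h2s_is_a_weak_acid(self, h2s_sys):
        st = sp.speciate_unbuffered(h2s_sys, {"H2S": 1e-6})
        assert 6.5 < st.pH < 7.0
        oracle = brute_force_ph({"H2S": 1e-6})
        assert st.pH == pytest.approx(oracle, abs=2e-4)

    def test_charge_balance_residual(self, joint_sys):
        st = sp.speciate_unbuffered(joint_sys, {"H2S": 1e-6, "SO2": 1e-9}, 0.05)
        gross = sum(abs(sp.SPECIES_CHARGE[s]) * c for s, c in st.concentrations.items())
        assert abs(st.charge_imbalance()) <= 1e-12 * gross

    def test_oracle_equivalence_on_random_scenarios(self):
        """Root solver matches the dense pH-grid scan on 100+ random draws."""
        draws = [
            s for s in scn.random_scenarios(220, seed=20260927) if s.mode == "unbuffered"
        ]
        assert len(draws) >= 100
        for s in draws[:110]:
            pressures = {g: v[0] for g, v in s.pressures.items()}
            system = sp.EquilibriumSystem(s.gases)
            st = sp.speciate_unbuffered(
                system,
                pressures,
                background_I=s.ionic_strength,
                freeze_ionic_strength=True,
            )
            oracle = brute_force_ph(pressures, background_I=s.ionic_strength)
            assert st.pH == pytest.approx(oracle, abs=2e-4)

    def test_ph_nonincreasing_in_pressure(self, so2_sys, h2s_sys):
        for system, gas in ((so2_sys, "SO2"), (h2s_sys, "H2S")):
            phs = [
                sp.speciate_unbuffered(system, {gas: p}).pH
                for p in np.logspace(-12, -4, 17)
            ]
            assert all(b <= a + 1e-12 for a, b in zip(phs, phs[1:]))

    def test_buffered_reproduces_unbuffered_state(self, so2_sys):
        """Buffered cascade at the solved pH and I returns the same state."""
        u = sp.speciate_unbuffered(so2_sys, {"SO2": 3e-9}, background_I=0.02)
        b = sp.speciate_buffered(so2_sys, {"SO2": 3e-9}, u.pH, I=u.ionic_strength)
        for s in so2_sys.species:
            assert b.concentrations[s] == pytest.approx(
                u.concentrations[s], rel=1e-6
            )

    def test_self_consistent_ionic_strength_fixed_point(self, so2_sys):
        u = sp.speciate_unbuffered(so2_sys, {"SO2": 1e-5}, background_I=0.01)
        solved_i = act.ionic_strength(u.concentrations)
        assert u.ionic_strength == pytest.approx(0.01 + solved_i, rel=1e-8)

    def test_frozen_ionic_strength_knob(self, so2_sys):
        u = sp.speciate_unbuffered(
            so2_sys, {"SO2": 1e-5}, background_I=0.01, freeze_ionic_strength=True
        )
        assert u.ionic_strength == 0.01

    def test_activity_shift_small_between_dilute_and_tenth_molar(self, joint_sys):
        """I = 0 vs I = 0.1 M changes every species activity by < 15%.

        This is the overplotting-curves property: the ionic-strength
        correction barely moves the solution over the dilute range.
        """
        for pressures in ({"H2S": 1e-6, "SO2": 1e-9}, {"H2S": 1e-8, "SO2": 1e-7}):
            lo = sp.speciate_unbuffered(joint_sys, pressures, background_I=0.0)
            hi = sp.speciate_unbuffered(joint_sys, pressures, background_I=0.1)
            for s in joint_sys.species:
                shift = abs(hi.activities[s] - lo.activities[s]) / lo.activities[s]
                assert shift < 0.15, (s, shift)


def test_sulfide_always_negligible(h2s_sys):
    """S-2 stays below nanomolar for pH <= 9 and pH2S <= 1e-4 bar."""
    for ph in (4.0, 7.0, 9.0):
        for p in (1e-12, 1e-8, 1e-4):
            st = sp.speciate_buffered(h2s_sys, {"H2S": p}, ph)
            assert st.concentrations["S-2"] <= 1e-9
    u = sp.speciate_unbuffered(h2s_sys, {"H2S": 1e-4})
    assert u.concentrations["S-2"] <= 1e-9


class TestThreshold:
    @pytest.mark.parametrize(
        "system_name, species, target, ph, decade",
        [
            ("H2S", "HS-", 1e-6, 8.2, 1e-6),
            ("H2S", "HS-", 1e-6, 7.0, 1e-5),
            ("SO2", "HSO3-", 1e-6, 7.0, 1e-11),
            ("SO2", "HSO3-", 1e-3, 7.0, 1e-8),
        ],
    )
    def test_decade_rounded_thresholds(self, system_name, species, target, ph, decade):
        system = sp.EquilibriumSystem((system_name,))
        res = sp.threshold_pressure(system, species, target, ph)
        assert res.decade_pressure == decade

    def test_exact_inversion_round_trips(self, so2_sys):
        res = sp.threshold_pressure(so2_sys, "SO3-2", 1e-6, 7.0)
        st = sp.speciate_buffered(so2_sys, {"SO2": res.pressure}, 7.0)
        assert st.concentrations["SO3-2"] == pytest.approx(1e-6, rel=1e-8)

    def test_millimolar_sulfide_unreachable(self, h2s_sys):
        with pytest.raises(sp.UnreachableTargetError):
            sp.threshold_pressure(h2s_sys, "S-2", 1e-3, 7.0)

    def test_species_must_descend_from_system_gas(self, h2s_sys):
        with pytest.raises(ValueError):
            sp.threshold_pressure(h2s_sys, "HSO3-", 1e-6, 7.0)

    def test_decade_round_ties_go_down(self):
        assert sp.decade_round(10**-6.5) == 1e-7
        assert sp.decade_round(3.17e-7) == 1e-6  # just above the half decade
        assert sp.decade_round(1e-8) == 1e-8
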