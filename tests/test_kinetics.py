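"""Radiolysis kinetics: reaction network, ODE simulation and G(Fe3+)."""

import math

import numpy as np
import pytest

from frickedose import (
    DoseRateProfile,
    PrimaryYields,
    STANDARD_FRICKE_YIELDS,
    fricke_network,
    g_value_closed_form,
    g_value_from_simulation,
    initial_state,
    oxygen_depletion_time,
    simulate,
)
from frickedose.kinetics import Reaction, load_scenario


class TestNetworkConstruction:
    def test_seven_reactions_with_printed_rate_constants(self):
        net = fricke_network()
        assert len(net.reactions) == 7
        np.testing.assert_allclose(
            net.rate_constants,
            [1.12e10, 2.1e10, 1.3e7, 3.4e8, 7.9e5, 2.66e10, 52.0],
        )

    def test_every_reaction_element_and_charge_balanced(self):
        for rxn in fricke_network().reactions:
            assert rxn.balance() == (0, 0, 0, 0)

    def test_unbalanced_reaction_rejected(self):
        from frickedose.kinetics import ReactionNetwork

        with pytest.raises(ValueError, match="balanced"):
            ReactionNetwork([Reaction(("Fe2+", "H"), ("Fe3+", "H2", "OH-"), 1.3e7)])

    def test_rate_override(self):
        net = fricke_network({7: 100.0})
        assert net.rate_constants[6] == 100.0
        with pytest.raises(ValueError):
            fricke_network({8: 1.0})


class TestClosedFormYield:
    def test_aerated_standard_yields(self):
        # 3*3.70 + 2*0.78 + 2.92 = 15.58, reference value 15.5 +/- 0.2
        assert g_value_closed_form(STANDARD_FRICKE_YIELDS, aerated=True) == pytest.approx(
            15.58
        )

    def test_anoxic_standard_yields(self):
        # H atoms oxidize one rather than three Fe2+: 8.18, ref 8.2 +/- 0.3
        assert g_value_closed_form(STANDARD_FRICKE_YIELDS, aerated=False) == pytest.approx(
            8.18
        )

    def test_zero_yields(self):
        z = PrimaryYields(0, 0, 0, 0)
        assert g_value_closed_form(z) == 0.0


GAMMACELL = DoseRateProfile("constant", 0.78 / 60.0)  # 0.78 Gy/min


class TestSimulation:
    def test_no_dose_no_oxidation(self):
        res = simulate(
            fricke_network(),
            STANDARD_FRICKE_YIELDS,
            DoseRateProfile("constant", 0.0),
            duration_s=60.0,
        )
        assert res.final("Fe3+") == pytest.approx(0.0, abs=1e-15)

    def test_aerated_ode_matches_closed_form_within_1pct(self):
        """Low-dose aerated simulation reproduces the stoichiometric yield.

        30 s at 0.78 Gy/min delivers 0.39 Gy, far below O2/Fe2+ depletion;
        a 300 s source-free relaxation lets the slow Fenton step finish.
        """
        res = simulate(
            fricke_network(), STANDARD_FRICKE_YIELDS, GAMMACELL, 30.0, relax_s=300.0
        )
        g_sim = g_value_from_simulation(res)
        g_cf = g_value_closed_form(STANDARD_FRICKE_YIELDS, aerated=True)
        assert g_sim == pytest.approx(g_cf, rel=0.01)

    def test_anoxic_ode_matches_closed_form_within_1pct(self):
        res = simulate(
            fricke_network(),
            STANDARD_FRICKE_YIELDS,
            GAMMACELL,
            30.0,
            relax_s=300.0,
            initial=initial_state(aerated=False),
        )
        g_cf = g_value_closed_form(STANDARD_FRICKE_YIELDS, aerated=False)
        assert g_value_from_simulation(res) == pytest.approx(g_cf, rel=0.01)

    def test_iron_conserved_to_1e9_molar(self):
        res = simulate(
            fricke_network(), STANDARD_FRICKE_YIELDS, GAMMACELL, 30.0, relax_s=300.0
        )
        total = res.concentrations["Fe2+"] + res.concentrations["Fe3+"]
        np.testing.assert_allclose(total, 1e-3, atol=1e-9)

    def test_concentrations_stay_non_negative(self):
        res = simulate(
            fricke_network(), STANDARD_FRICKE_YIELDS, GAMMACELL, 30.0, relax_s=300.0
        )
        assert (res.concentrations.to_numpy() > -1e-12).all()

    def test_decaying_f18_source_tracks_cumulated_dose_curve(self):
        """For a decaying internal source the Fe3+ growth curve has the same
        shape as the cumulative-dose curve (1 - exp(-lambda t))."""
        lam = math.log(2) / (109.77 * 60.0)
        total_dose = 0.17 * 60.0  # 60 MBq vial
        prof = DoseRateProfile("decaying_source", total_dose * lam, lam)
        res = simulate(
            fricke_network(), STANDARD_FRICKE_YIELDS, prof, 4 * 3600.0, n_eval=50
        )
        fe3 = res.concentrations["Fe3+"].to_numpy()
        cum = np.array([prof.cumulative_dose(t) for t in res.times_s])
        np.testing.assert_allclose(fe3[1:] / fe3[-1], cum[1:] / cum[-1], atol=5e-3)


class TestOxygenDepletion:
    def test_zero_dose_rate_never_depletes(self):
        assert oxygen_depletion_time(DoseRateProfile("constant", 0.0)) == math.inf

    def test_depletion_time_decreases_with_dose_rate(self):
        times = [
            oxygen_depletion_time(DoseRateProfile("constant", dr), horizon_s=4000.0)
            for dr in (0.5, 1.0, 2.0)
        ]
        assert all(math.isfinite(t) for t in times)
        assert times[0] > times[1] > times[2]
        # consumption is source-limited: time ~ 1/dose_rate
        assert times[0] / times[2] == pytest.approx(4.0, rel=0.05)

    def test_internal_source_exposure_leaves_o2_intact(self):
        """A <= 12.5 Gy total decaying exposure consumes far less O2 than the
        0.25 mM initially dissolved, so the aerated linear response holds."""
        lam = math.log(2) / (109.77 * 60.0)
        prof = DoseRateProfile("decaying_source", 12.5 * lam, lam)
        assert oxygen_depletion_time(prof, horizon_s=6 * 3600.0) == math.inf
        res = simulate(fricke_network(), STANDARD_FRICKE_YIELDS, prof, 6 * 3600.0)
        consumed = 2.5e-4 - res.final("O2")
        # stoichiometric bound: dose * g(H) in mol/J
        assert consumed <= 12.5 * 3.70 * 1.0364e-7 * 1.01
        assert consumed < 0.02 * 2.5e-4 * 3  # small fraction of initial O2


def test_scenario_loader_round_trip(tmp_path):
    path = tmp_path / "scenario.yaml"
    path.write_text(
        """
network:
  rate_constants: {7: 60.0}
yields: {g_eaq: 2.6, g_h: 0.6, g_oh: 2.9, g_h2o2: 0.7}
dose_profile: {kind: constant, dose_rate_0: 0.013}
initial_concentrations: {O2: 0.0}
"""
    )
    scn = load_scenario(path)
    assert scn["network"].rate_constants[6] == 60.0
    assert scn["yields"].g_reducing == pytest.approx(3.2)
    assert scn["initial"].concentrations["O2"] == 0.0
    assert scn["dose_profile"].rate(0.0) == pytest.approx(0.013)
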