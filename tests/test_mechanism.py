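"""Mechanism simulation: mass-action derivatives, integration, burst analysis."""

import numpy as np
import pytest

import strandsep as ss
from strandsep.mechanism import SPECIES

from conftest import random_rate_sets


class TestDerivatives:
    def test_hand_computed_fluxes(self, wt):
        state = ss.SpeciesState(E=0.1, S=1.0, FS=0.2, GSI=0.05, GSp=0.01, Sp=0.3)
        d = ss.derivatives(state, wt)
        # dS/dt = -k1*E*S + k1r*FS with k1 = 100, k1r = 528
        assert d[SPECIES.index("S")] == pytest.approx(-100 * 0.1 * 1.0 + 528 * 0.2)
        assert d[SPECIES.index("S")] == pytest.approx(95.6)

    def test_zero_state_and_zero_rates_give_zero_flux(self, wt):
        assert np.all(ss.derivatives(ss.SpeciesState(), wt) == 0)
        dead = ss.RateConstants(k1=0, k1r=0, k2=0, k2r=0, k3=0, k3r=0, k4=0,
                                k4r=0, locked=frozenset())
        state = ss.SpeciesState(E=0.3, S=1.0, FS=0.1, GSI=0.1, GSp=0.1, Sp=0.1)
        assert np.all(ss.derivatives(state, dead) == 0)

    def test_fluxes_conserve_totals(self):
        for rates in random_rate_sets(10, seed=1):
            state = ss.SpeciesState(E=0.2, S=1.5, FS=0.3, GSI=0.2, GSp=0.1, Sp=0.4)
            d = ss.derivatives(state, rates)
            assert abs(d[[0, 2, 3, 4]].sum()) < 1e-10       # enzyme species
            assert abs(d[[1, 2, 3, 4, 5]].sum()) < 1e-10    # DNA species

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k2"):
            ss.RateConstants(k2=-1.0)


class TestIntegrate:
    def test_all_rates_zero_is_constant(self):
        dead = ss.RateConstants(k1=0, k1r=0, k2=0, k2r=0, k3=0, k3r=0, k4=0,
                                k4r=0, locked=frozenset())
        traj = ss.integrate(dead, ss.SpeciesState(E=0.5, S=2.5),
                            np.linspace(0.01, 2.0, 20))
        assert np.allclose(traj.species("E"), 0.5, atol=1e-12)
        assert np.allclose(traj.species("S"), 2.5, atol=1e-12)

    def test_two_state_relaxation_closed_form(self):
        k2, k2r = 23.2, 6.7
        rates = ss.RateConstants(k1=0, k1r=0, k2=k2, k2r=k2r, k3=0, k3r=0,
                                 k4=0, k4r=0, locked=frozenset())
        t = np.linspace(1e-4, 1.0, 300)
        traj = ss.integrate(rates, ss.SpeciesState(FS=1.0), t)
        K2 = k2 / k2r
        closed = (K2 / (1 + K2)) * (1 - np.exp(-(k2 + k2r) * t))
        assert np.max(np.abs(traj.species("GSI") - closed)) < 1e-6

    def test_pseudo_first_order_binding_closed_form(self):
        # S0 >> E0 (so substrate depletion by binding is negligible):
        # free-enzyme decay is a single exponential at k1*S0 + k1r
        k1, k1r, E0, S0 = 10.0, 5.0, 1e-5, 10.0
        rates = ss.RateConstants(k1=k1, k1r=k1r, k2=0, k2r=0, k3=0, k3r=0,
                                 k4=0, k4r=0, locked=frozenset())
        t = np.linspace(1e-4, 0.5, 200)
        traj = ss.integrate(rates, ss.SpeciesState(E=E0, S=S0), t)
        kobs = k1 * S0 + k1r
        E_eq = E0 * k1r / kobs
        closed = E_eq + (E0 - E_eq) * np.exp(-kobs * t)
        assert np.max(np.abs(traj.species("E") - closed)) / E0 < 1e-6

    def test_irreversible_scheme_exhausts_substrate(self, wt):
        traj = ss.integrate(wt, ss.SpeciesState(E=0.5, S=2.5),
                            np.linspace(1.0, 200.0, 40))
        assert traj.species("Sp")[-1] == pytest.approx(2.5, abs=1e-3)

    def test_conservation_on_random_parameter_sets(self):
        for rates in random_rate_sets(20, seed=7):
            traj = ss.integrate(rates, ss.SpeciesState(E=0.5, S=2.5),
                                np.geomspace(1e-3, 10.0, 40))
            e_err, s_err = traj.conservation_error()
            assert e_err < 1e-6 and s_err < 1e-6

    def test_product_monotone_when_irreversible(self):
        for rates in random_rate_sets(20, seed=8, irreversible=True):
            traj = ss.integrate(rates, ss.SpeciesState(E=0.5, S=2.5),
                                np.geomspace(1e-3, 10.0, 60))
            p = traj.product_total
            assert np.all(np.diff(p) > -1e-9)

    def test_grid_validation(self, wt):
        with pytest.raises(ValueError):
            ss.integrate(wt, ss.SpeciesState(E=0.1, S=0.1), [])
        with pytest.raises(ValueError):
            ss.integrate(wt, ss.SpeciesState(E=0.1, S=0.1), [0.2, 0.1])


class TestEquilibriumConstants:
    def test_reference_values(self):
        wt = ss.equilibrium_constants(ss.reference_rate_constants("WT"))
        assert wt["K2"] == pytest.approx(3.5, abs=0.05)
        assert wt["K1"] == pytest.approx(1 / 5.28, rel=1e-12)
        r44a = ss.equilibrium_constants(ss.reference_rate_constants("R44A"))
        assert r44a["K2"] == pytest.approx(0.48, abs=0.005)

    def test_symmetric_rates_give_unity(self):
        r = ss.RateConstants(k2=3.3, k2r=3.3, locked=frozenset())
        assert ss.equilibrium_constants(r)["K2"] == 1.0

    def test_zero_denominator_raises(self):
        r = ss.RateConstants(k2r=0.0, locked=frozenset())
        with pytest.raises(ZeroDivisionError):
            ss.equilibrium_constants(r)


class TestBurst:
    FAST_CHEM = dict(k1=100, k1r=100, k2=50, k2r=1, k3=50, k3r=0, k4=0.5, k4r=0)

    def test_no_chemistry_no_product(self):
        rates = ss.RateConstants(**{**self.FAST_CHEM, "k3": 0.0},
                                 locked=frozenset())
        res = ss.simulate_burst(rates, 0.1, 3.0, np.linspace(0.01, 20, 200))
        assert res.amplitude == pytest.approx(0.0, abs=1e-9)

    def test_fast_chemistry_burst_equals_active_sites(self):
        rates = ss.RateConstants(**self.FAST_CHEM, locked=frozenset())
        res = ss.simulate_burst(rates, 0.1, 3.0, np.linspace(0.01, 20, 400))
        assert res.amplitude == pytest.approx(0.1, rel=0.10)

    def test_wild_type_shows_no_burst(self, wt):
        # chemistry (k3) rate-limiting: amplitude under 10% of active sites
        res = ss.simulate_burst(wt, 0.1, 3.0, np.linspace(0.01, 10, 400))
        assert res.amplitude <= 0.01

    def test_amplitude_monotone_in_chemistry_release_ratio(self):
        k4 = 0.5
        amps = []
        for ratio in np.geomspace(1e-2, 1e2, 7):
            rates = ss.RateConstants(**{**self.FAST_CHEM, "k3": ratio * k4},
                                     locked=frozenset())
            res = ss.simulate_burst(rates, 0.1, 3.0, np.linspace(0.01, 30, 400))
            amps.append(res.amplitude)
        assert np.all(np.diff(amps) > 0)
        assert amps[-1] == pytest.approx(0.1, rel=0.15)

    def test_single_turnover_input_rejected(self, wt):
        with pytest.raises(ValueError, match="multiple turnover"):
            ss.simulate_burst(wt, 0.5, 0.1, np.linspace(0.01, 10, 50))
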