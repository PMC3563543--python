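"""Ring-assembly master equation: coefficients, conservation, closed
forms, the stochastic oracle, and rate-fit identifiability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsidyn.ringme import (
    MasterEquationError,
    MEParams,
    METrajectory,
    RingAssemblyME,
    association_rate_conversion,
    association_rate_inverse,
    decay_coefficient,
    fit_me,
    gillespie_ring_network,
    integrate_me,
    me_rhs,
)

NU0 = np.array([60.0, 0, 0, 0, 0, 0])


class TestDecayCoefficients:
    def test_daughter_multiplicity_is_two(self):
        assert decay_coefficient(5, 2, 6) == 2
        for n in range(2, 6):
            for k in range(1, n):
                assert decay_coefficient(n, k, 6) == 2

    def test_total_decay_is_bond_count(self):
        assert decay_coefficient(4, 4, 6) == -3
        for n in range(2, 6):
            assert decay_coefficient(n, n, 6) == -(n - 1)

    def test_completed_ring_has_no_decay_channel(self):
        with pytest.raises(MasterEquationError, match="irreversib"):
            decay_coefficient(6, 3, 6)

    def test_invalid_daughter_size(self):
        with pytest.raises(MasterEquationError):
            decay_coefficient(3, 4, 6)


class TestRHS:
    def test_monomer_only_state(self):
        p = MEParams(a=1e-4, b=1e-3, n_f=6, N=60)
        d = me_rhs(NU0, p)
        # conservation forces the -2:1 ratio between monomer loss and
        # dimer gain of the pure coagulation channel
        assert d[0] == pytest.approx(-p.a * 60**2)
        assert d[1] == pytest.approx(p.a * 60**2 / 2)
        assert np.all(d[2:] == 0)

    def test_absorbing_state(self):
        p = MEParams(a=1e-4, b=1e-3, n_f=6, N=60)
        assert np.all(me_rhs(np.array([0, 0, 0, 0, 0, 10.0]), p) == 0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 30), min_size=6, max_size=6))
    def test_mass_conservation(self, nu):
        p = MEParams(a=2e-4, b=5e-4, n_f=6, N=60)
        d = me_rhs(np.array(nu), p)
        assert abs((np.arange(1, 7) * d).sum()) < 1e-9

    def test_negative_population_rejected(self):
        p = MEParams(a=1e-4, b=1e-3, n_f=6, N=60)
        with pytest.raises(MasterEquationError, match="negative"):
            me_rhs(np.array([-5.0, 0, 0, 0, 0, 0]), p)


class TestIntegration:
    def test_zero_rates_keep_initial_condition(self):
        tr = integrate_me(
            MEParams(a=0.0, b=0.0, n_f=6, N=60), NU0, np.linspace(0, 1e4, 11)
        )
        assert np.allclose(tr.nu, NU0)

    def test_irreversible_dimerisation_closed_form(self):
        # n_f=2, b=0: dnu1/dt = -a nu1^2 has solution N/(1+aNt)
        p = MEParams(a=3e-4, b=0.0, n_f=2, N=50)
        t = np.linspace(0, 2e4, 200)
        tr = integrate_me(p, np.array([50.0, 0.0]), t)
        exact = 50.0 / (1.0 + p.a * 50.0 * t)
        assert np.abs(tr.nu[:, 0] - exact).max() / 50.0 < 1e-6

    def test_long_time_limit_is_all_rings(self):
        # the all-ring state nu_6 = N/6 is the unique absorbing state; the
        # mean-field approach to it is only logarithmically fast, so the
        # horizon must be generous
        t = np.concatenate([[0.0], np.geomspace(1.0, 1e12, 120)])
        tr = integrate_me(MEParams(a=1e-4, b=1e-3, n_f=6, N=60), NU0, t)
        tr.validate()
        assert tr.nu[-1, 5] == pytest.approx(10.0, abs=0.05)

    def test_invariants_along_trajectory(self):
        t = np.linspace(0, 5e4, 60)
        tr = integrate_me(MEParams(a=1e-4, b=1e-3, n_f=6, N=60), NU0, t)
        mass = tr.mass()
        assert np.abs(mass - 60.0).max() < 1e-6
        assert np.all(np.diff(tr.nu[:, 5]) >= -1e-9)

    def test_nonconserving_initial_condition_rejected(self):
        with pytest.raises(MasterEquationError, match="mass"):
            integrate_me(
                MEParams(a=1e-4, b=0, n_f=6, N=60),
                np.array([30.0, 0, 0, 0, 0, 0]),
                np.linspace(0, 10, 5),
            )


class TestGillespie:
    def test_exact_conservation_and_monotone_rings(self):
        p = MEParams(a=1e-4, b=0.0, n_f=6, N=60)
        t = np.linspace(0, 2e4, 40)
        tr = gillespie_ring_network(p, np.random.default_rng(1), t)
        assert np.all(tr.mass() == 60)
        assert np.all(np.diff(tr.nu[:, 5]) >= 0)

    def test_mean_matches_mean_field(self):
        p = MEParams(a=1e-4, b=1e-3, n_f=6, N=60)
        t = np.linspace(0, 5e3, 20)
        runs = np.array(
            [
                gillespie_ring_network(p, np.random.default_rng(300 + i), t).nu
                for i in range(250)
            ]
        )
        mean, se = runs.mean(axis=0), runs.std(axis=0) / np.sqrt(250)
        det = integrate_me(p, NU0, t)
        # mean-field closure error is O(1/N); allow it on top of 3 SE
        dev = np.abs(mean[:, 5] - det.nu[:, 5])
        assert np.all(dev <= 3.0 * se[:, 5] + 0.12)


class TestFit:
    A_ID, A_T3, B = 2.4e-4, 1.2e-4, 9e-4

    def _tables(self, t_max=3e4, n_t=40):
        t = np.linspace(0, t_max, n_t)
        d_id = integrate_me(MEParams(self.A_ID, self.B, 6, 60), NU0, t)
        d_t3 = integrate_me(MEParams(self.A_T3, self.B, 6, 60), NU0, t)
        return d_id, d_t3

    def test_noise_free_recovery_within_one_percent(self):
        res = fit_me(*self._tables())
        assert res.a["identical"] == pytest.approx(self.A_ID, rel=0.01)
        assert res.a["t3like"] == pytest.approx(self.A_T3, rel=0.01)
        assert res.b == pytest.approx(self.B, rel=0.01)
        assert res.a_ratio == pytest.approx(2.0, rel=0.02)
        # multistart cost path is reported best-last
        assert res.cost <= min(res.cost_path)

    def test_summary_renders(self):
        res = fit_me(*self._tables(n_t=15))
        text = res.summary()
        assert "a[identical]" in text and "b" in text

    def test_all_zero_table_rejected(self):
        t = np.linspace(0, 10, 5)
        zero = METrajectory(t_grid=t, nu=np.zeros((5, 6)))
        with pytest.raises(MasterEquationError, match="zero"):
            RingAssemblyME({"x": zero})

    def test_nonconserving_table_rejected(self):
        t = np.linspace(0, 10, 5)
        bad = np.tile(NU0, (5, 1))
        bad[3:, 0] = 10.0
        with pytest.raises(MasterEquationError, match="mass"):
            RingAssemblyME({"x": METrajectory(t_grid=t, nu=bad)})


class TestRateConversion:
    def test_zero_and_linearity(self):
        assert association_rate_conversion(0.0, 1e-3, 60) == 0.0
        k1 = association_rate_conversion(2e-6, 1e-3, 60)
        assert association_rate_conversion(2e-6, 2e-3, 60) == pytest.approx(k1 / 2)

    def test_dimensional_example(self):
        # a = 2.4e-6 ns^-1 at N=60, c=1.198e-3 M: k_a = a N / c, ns->s
        k = association_rate_conversion(2.4e-6, 1.198e-3, 60)
        assert k == pytest.approx(1.202e8, rel=1e-3)

    def test_roundtrip(self):
        a = association_rate_inverse(
            association_rate_conversion(3.3e-6, 4.5e-3, 60), 4.5e-3, 60
        )
        assert a == pytest.approx(3.3e-6)

    def test_invalid_concentration(self):
        with pytest.raises(MasterEquationError):
            association_rate_conversion(1e-6, 0.0, 60)
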