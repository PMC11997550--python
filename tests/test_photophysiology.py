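"""Photon pathway: RuBisCO inactivation, partitioning, RCII dynamics, ROS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coralbleach.params import PhotoParams
from coralbleach.photophysiology import (
    PhotonBudget,
    ReactionCentres,
    partition_photons,
    photon_absorption,
    rc_propagator,
    rc_repair_rate,
    rc_transition_rates,
    ros_detox_rate,
    ros_detox_rate_legacy,
    ros_generation_rate,
    rubisco_activity,
    xanthophyll_switch,
)

THETA = 1.42e-14


class TestRubiscoActivity:
    @pytest.mark.parametrize(
        "delta_t, expected",
        [(1.0, 0.73), (-3.0, 1.0), (0.0, 1.0), (2.0, 0.0), (5.0, 0.0)],
    )
    def test_reference_values(self, delta_t, expected):
        assert rubisco_activity(delta_t) == pytest.approx(expected, abs=5e-3)

    def test_continuous_and_monotone_on_fine_grid(self):
        grid = np.arange(-1.0, 3.0, 1e-3)
        act = rubisco_activity(grid)
        assert np.all(np.diff(act) <= 1e-12)          # monotone non-increasing
        assert np.max(np.abs(np.diff(act))) < 1e-2    # no jumps at the clamps
        assert np.all((act >= 0) & (act <= 1))

    def test_matches_closed_form_inside_the_ramp(self):
        dt = np.linspace(0.01, 1.99, 50)
        expected = (1 - np.exp(-(2 - dt))) / (1 - np.exp(-2))
        np.testing.assert_allclose(rubisco_activity(dt), expected, rtol=1e-12)


class TestAbsorption:
    def test_no_pigment_no_absorption(self):
        b = photon_absorption(500.0, 0.0, 0.0, 0.0, PhotoParams())
        assert b.k_i == 0.0 and b.to_heat == 0.0

    def test_no_diatoxanthin_no_heat(self):
        b = photon_absorption(500.0, 0.2, 0.01, 0.0, PhotoParams())
        assert b.to_heat == 0.0 and b.k_i > 0.0

    @pytest.mark.parametrize("optics", ["competitive", "sequential"])
    def test_linear_in_irradiance(self, optics):
        p = PhotoParams(npq_optics=optics)
        b1 = photon_absorption(300.0, 0.2, 0.01, 0.03, p)
        b2 = photon_absorption(600.0, 0.2, 0.01, 0.03, p)
        assert b2.k_i == pytest.approx(2 * b1.k_i, rel=1e-12)
        assert b2.to_heat == pytest.approx(2 * b1.to_heat, rel=1e-12)

    def test_absorbed_bounded_by_irradiance(self):
        p = PhotoParams()
        e_d = 800.0 * 86400e-6
        b = photon_absorption(800.0, 50.0, 5.0, 5.0, p)
        assert b.k_i + b.to_heat <= e_d + 1e-12

    def test_optical_cap_limits_self_shading(self):
        p = PhotoParams()
        uncapped = photon_absorption(500.0, 10.0, 0.0, 0.0, p)
        capped = photon_absorption(500.0, 10.0, 0.0, 0.0, p, optical_cap=1.0)
        assert capped.k_i < uncapped.k_i

    def test_negative_pigment_rejected(self):
        with pytest.raises(ValueError):
            photon_absorption(100.0, -0.1, 0.0, 0.0, PhotoParams())


class TestPartition:
    def _budget(self, k_i=5.0):
        return PhotonBudget(k_i=k_i, to_heat=1.0)

    def test_inactive_rubisco_routes_everything_to_reduction(self):
        rc = ReactionCentres(1.0, 0.0, 0.0)
        b = partition_photons(self._budget(), rc, activity=0.0, r_c_norm=0.2)
        assert b.to_fixation == 0.0
        assert b.to_reduction == pytest.approx(b.k_i)

    def test_replete_carbon_stops_fixation(self):
        rc = ReactionCentres(1.0, 0.0, 0.0)
        b = partition_photons(self._budget(), rc, activity=1.0, r_c_norm=1.0)
        assert b.to_fixation == 0.0

    def test_pure_inhibited_pool_all_ros(self):
        rc = ReactionCentres(0.0, 0.0, 2.0)
        b = partition_photons(self._budget(), rc, activity=1.0, r_c_norm=0.0)
        assert b.to_ros == pytest.approx(b.k_i)
        assert b.to_fixation == b.to_reduction == b.to_inhibition == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        q=st.tuples(*[st.floats(0.0, 10.0)] * 3).filter(lambda q: sum(q) > 1e-6),
        k_i=st.floats(0.0, 100.0),
        activity=st.floats(0.0, 1.0),
        r_c=st.floats(0.0, 1.0),
    )
    def test_photon_conservation(self, q, k_i, activity, r_c):
        rc = ReactionCentres(*q)
        b = partition_photons(PhotonBudget(k_i=k_i), rc, activity, r_c)
        total = b.to_fixation + b.to_reduction + b.to_inhibition + b.to_ros
        assert total == pytest.approx(k_i, rel=1e-12, abs=1e-15)


class TestReactionCentreDynamics:
    def test_zero_flux_zero_derivatives(self):
        rc = ReactionCentres(1.0, 1.0, 1.0)
        b = PhotonBudget(k_i=0.0)
        assert rc_transition_rates(b, rc, PhotoParams()) == (0.0, 0.0, 0.0)

    def test_unit_flux_formula(self):
        p = PhotoParams(m_rcii=0.002)
        rc = ReactionCentres(1.0, 0.0, 0.0)
        b = PhotonBudget(k_i=0.002, to_reduction=0.002)
        d_ox, d_red, d_in = rc_transition_rates(b, rc, p)
        assert d_red == pytest.approx(1.0)
        assert d_ox == pytest.approx(-1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        to_red=st.floats(0, 10), to_in=st.floats(0, 10), m=st.floats(1e-3, 1e3)
    )
    def test_transitions_conserve_total(self, to_red, to_in, m):
        p = PhotoParams(m_rcii=m)
        rc = ReactionCentres(1.0, 1.0, 1.0)
        d = rc_transition_rates(PhotonBudget(k_i=1, to_reduction=to_red,
                                             to_inhibition=to_in), rc, p)
        assert sum(d) == pytest.approx(0.0, abs=1e-12)

    def test_repair_formula(self):
        p = PhotoParams(m_rcii=0.002)
        assert rc_repair_rate(0.5, p) == pytest.approx(268 * 0.002 * 0.5)
        assert rc_repair_rate(0.0, p) == 0.0

    def test_repair_only_closed_form_half_life(self):
        """Under repair alone Q_in decays exponentially at 268*m_RCII."""
        p = PhotoParams(m_rcii=0.002)
        lam = 268 * p.m_rcii
        rc = ReactionCentres(0.0, 0.3, 1.0)
        dt = 1.0 / 1440.0
        steps = int(round((np.log(2) / lam) / dt))
        for _ in range(steps):
            rc = rc_propagator(rc, 0.0, 1.0, 0.0, p, dt)
        expected = np.exp(-lam * steps * dt)
        assert rc.q_in == pytest.approx(expected, rel=1e-3)
        assert rc.q_red == 0.3                      # untouched in the dark
        assert rc.q_ox + rc.q_in == pytest.approx(1.0, rel=1e-12)

    def test_propagator_conserves_total_under_light(self):
        p = PhotoParams()
        rc = ReactionCentres(1e-7, 2e-8, 5e-8)
        out = rc_propagator(rc, 5.0, 0.5, 0.3, p, 1.0 / 1440.0)
        assert out.q_t == pytest.approx(rc.q_t, rel=1e-12)
        assert min(out.q_ox, out.q_red, out.q_in) >= 0.0

    def test_propagator_matches_generic_ode_solution(self):
        """Cross-check the exact propagator against scipy's stiff integrator."""
        from scipy.integrate import solve_ivp

        p = PhotoParams(m_rcii=50.0)
        k_i, act, r_c = 3.0, 0.4, 0.2
        q0 = np.array([1e-7, 2e-8, 5e-8])
        q_t = q0.sum()
        per = k_i / (p.m_rcii * q_t)
        alpha = per * (1 - act * (1 - r_c))
        beta = per
        gamma = 268.0 * p.m_rcii

        def rhs(_, q):
            return [
                -alpha * q[0] + gamma * q[2],
                alpha * q[0] - beta * q[1],
                beta * q[1] - gamma * q[2],
            ]

        dt = 1.0 / 1440.0
        sol = solve_ivp(rhs, (0, dt), q0, method="Radau",
                        rtol=1e-10, atol=1e-22)
        rc = rc_propagator(ReactionCentres(*q0), k_i, act, r_c, p, dt)
        np.testing.assert_allclose(
            [rc.q_ox, rc.q_red, rc.q_in], sol.y[:, -1], rtol=1e-5
        )


class TestRos:
    def test_generation_formula(self):
        p = PhotoParams(m_rcii=0.002, m_p2r=3500.0)
        rc = ReactionCentres(0.5, 0.0, 0.5)
        b = PhotonBudget(k_i=10.0)
        assert ros_generation_rate(b, rc, p) == pytest.approx(
            10.0 * 0.5 / 0.002 / 3500.0
        )

    def test_no_inhibited_no_generation(self):
        p = PhotoParams()
        assert ros_generation_rate(
            PhotonBudget(k_i=10.0), ReactionCentres(1.0, 0.0, 0.0), p
        ) == 0.0

    def test_halving_m_p2r_doubles_generation(self):
        rc = ReactionCentres(0.2, 0.1, 0.7)
        b = PhotonBudget(k_i=4.0)
        sensitive = ros_generation_rate(b, rc, PhotoParams(m_p2r=3500.0))
        legacy = ros_generation_rate(b, rc, PhotoParams(m_p2r=7000.0))
        assert sensitive == pytest.approx(2 * legacy)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            ros_generation_rate(
                PhotonBudget(k_i=1.0), ReactionCentres(0.0, 0.0, 0.0), PhotoParams()
            )


class TestDetox:
    p = PhotoParams()
    density = 2e9
    mu_max = 0.3

    def rate(self, ros, reserves=(1.0, 1.0, 1.0)):
        return ros_detox_rate(ros, reserves, self.mu_max, self.density, self.p)

    def test_zero_at_and_below_half_threshold(self):
        assert self.rate(0.5 * THETA) == 0.0
        assert self.rate(0.1 * THETA) == 0.0

    def test_continuous_at_both_breakpoints(self):
        cap = self.mu_max * 0.5 * THETA * self.density
        for point in (0.5 * THETA, THETA):
            below = self.rate(point * (1 - 1e-13))
            above = self.rate(point * (1 + 1e-13))
            assert abs(above - below) <= 1e-12 * cap

    def test_cap_value_reached_at_threshold(self):
        expected = self.mu_max * 0.5 * THETA * self.density
        assert self.rate(THETA) == pytest.approx(expected, rel=1e-12)
        assert self.rate(10 * THETA) == pytest.approx(expected, rel=1e-12)

    def test_bounded_by_cap_everywhere(self):
        cap = self.mu_max * 0.5 * THETA * self.density
        ros_grid = THETA * np.linspace(0, 5, 1001)
        assert all(self.rate(r) <= cap + 1e-30 for r in ros_grid)

    def test_any_empty_reserve_disables_detox(self):
        assert self.rate(2 * THETA, reserves=(0.0, 1.0, 1.0)) == 0.0
        assert self.rate(2 * THETA, reserves=(1.0, 0.0, 1.0)) == 0.0

    def test_legacy_proportional_form(self):
        assert ros_detox_rate_legacy(0.0, (1, 1, 1), 0.3) == 0.0
        x = 3e-14
        assert ros_detox_rate_legacy(x, (1, 1, 1), 0.3) == pytest.approx(0.3 * x)
        assert ros_detox_rate_legacy(x, (0.5, 0.5, 0.5), 0.4) == pytest.approx(
            0.4 * 0.125 * x
        )

    def test_legacy_decays_to_zero_revised_floors_at_half(self):
        """0-D per-cell ODE at fixed density: the legacy law lets [ROS] decay
        towards zero; the revised law cannot cross threshold/2."""
        dt = 1e-3
        mu_eff = self.mu_max  # full reserves
        for law in ("legacy", "revised"):
            ros = 0.9 * THETA
            for _ in range(20000):
                if law == "legacy":
                    loss = ros_detox_rate_legacy(ros, (1, 1, 1), self.mu_max)
                else:
                    loss = self.rate(ros) / self.density
                ros -= dt * loss
            if law == "legacy":
                expected = 0.9 * THETA * np.exp(-mu_eff * 20000 * dt)
                assert ros == pytest.approx(expected, rel=1e-2)
                assert ros < 0.5 * THETA
            else:
                assert ros == pytest.approx(0.5 * THETA, rel=1e-6)

    def test_legacy_constant_forcing_closed_form(self):
        """[ROS](t) = [ROS]0 e^-mu t + (gen/mu)(1 - e^-mu t) per cell."""
        gen = 2e-15  # per-cell generation, mg O cell-1 d-1
        mu_eff = self.mu_max * 0.5**3
        ros0 = 1e-14
        dt, n = 1e-4, 50000
        ros = ros0
        for _ in range(n):
            ros += dt * (gen - ros_detox_rate_legacy(ros, (0.5, 0.5, 0.5), self.mu_max))
        t = dt * n
        expected = ros0 * np.exp(-mu_eff * t) + gen / mu_eff * (1 - np.exp(-mu_eff * t))
        assert ros == pytest.approx(expected, rel=1e-3)


class TestXanthophyllSwitch:
    p = PhotoParams(xanth_switch_rate=24.0)

    def test_empty_source_pool(self):
        assert xanthophyll_switch(0.0, 0.0, 0.9, self.p) == (0.0, 0.0)

    def test_relaxation_direction_below_half(self):
        d_p, d_h = xanthophyll_switch(0.1, 0.5, 0.4, self.p)
        assert d_p == pytest.approx(24.0 * 0.5)
        assert d_h == pytest.approx(-24.0 * 0.5)

    def test_protective_direction_above_half(self):
        d_p, d_h = xanthophyll_switch(0.5, 0.1, 0.6, self.p)
        assert d_p == pytest.approx(-24.0 * 0.5)
        assert d_h == pytest.approx(24.0 * 0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        x_p=st.floats(0, 10), x_h=st.floats(0, 10), frac=st.floats(0, 1)
    )
    def test_switch_conserves_total_pool(self, x_p, x_h, frac):
        d_p, d_h = xanthophyll_switch(x_p, x_h, frac, self.p)
        assert d_p + d_h == pytest.approx(0.0, abs=1e-12)
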