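"""Competency/mortality/settlement ODEs against closed-form oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import reefconn as rc
from reefconn.advection import ReleaseSet
from reefconn.larval_fate import ConstantMortality, WeibullMortality


def _params(**kw):
    defaults = dict(
        alpha=0.5,
        t_c=0.0,
        beta=0.05,
        mu_s=0.2,
        mortality=ConstantMortality(0.1),
        rho=1.0,
        t_max=120.0,
        max_events=60,
        n_per_cell=1,
    )
    defaults.update(kw)
    return rc.LarvalParams(**defaults)


def _closed_form(t, alpha, mu, beta, mu_s, fr):
    """Constant-coefficient solution with t_c = 0."""
    a = alpha + mu
    g = beta + mu + mu_s * fr
    l1 = np.exp(-a * t)
    l2 = alpha * (np.exp(-a * t) - np.exp(-g * t)) / (g - a)
    return l1, l2


class TestMortalityRate:
    def test_constant(self):
        p = _params(mortality=ConstantMortality(0.1))
        assert rc.mortality_rate(3.7, p) == 0.1

    def test_weibull_shape_one_is_constant(self):
        p = _params(mortality=WeibullMortality(0.07, 1.0))
        ts = np.linspace(0.0, 100.0, 50)
        assert np.allclose(rc.mortality_rate(ts, p), 0.07)

    def test_weibull_survival_matches_cumulative_hazard(self):
        # survival exp(-(lambda t)^nu) vs numerically integrated hazard
        m = WeibullMortality(0.05, 2.0)
        for t in (1.0, 10.0, 60.0):
            integral, _ = quad(lambda s: m.rate(s), 0.0, t)
            assert integral == pytest.approx((0.05 * t) ** 2, rel=1e-8)

    def test_weibull_singularity_capped(self):
        m = WeibullMortality(0.05, 0.6)
        assert m.rate(0.0) == rc.larval_fate.RATE_CEILING
        assert np.isfinite(m.cumulative_hazard(0.0))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rc.mortality_rate(-1.0, _params())


class TestIntegrateFate:
    def test_inert_when_no_competency_and_no_mortality(self):
        p = _params(alpha=0.0, mortality=ConstantMortality(0.0))
        times = np.linspace(0, 100, 501)
        fate = rc.integrate_fate(times, np.zeros((1, 501)), p)
        assert np.allclose(fate.L1, 1.0) and not fate.L2.any()

    def test_matches_constant_coefficient_closed_form(self):
        # includes the L2(5 d) ~ 0.3382 spot value of this parameter set
        p = _params()
        times = np.linspace(0.0, 120.0, 6001)
        fr = np.full((1, len(times)), 0.5)
        fate = rc.integrate_fate(times, fr, p)
        l1, l2 = _closed_form(times, 0.5, 0.1, 0.05, 0.2, 0.5)
        assert np.abs(fate.L1[0] - l1).max() < 1e-9
        assert np.abs(fate.L2[0] - l2).max() < 1e-9
        k5 = np.searchsorted(times, 5.0)
        assert fate.L2[0, k5] == pytest.approx(0.3382, abs=5e-5)

    def test_degenerate_gamma_limit(self):
        # g - a = 1e-9: solver must agree with L2 = alpha t exp(-(alpha+mu) t)
        alpha, mu = 0.5, 0.1
        beta = alpha + 1e-9  # with F_r = 0: g = beta + mu = alpha + mu + 1e-9
        p = _params(alpha=alpha, beta=beta, mortality=ConstantMortality(mu))
        times = np.linspace(0.0, 60.0, 3001)
        fate = rc.integrate_fate(times, np.zeros((1, len(times))), p)
        limit = alpha * times * np.exp(-(alpha + mu) * times)
        assert np.abs(fate.L2[0] - limit).max() < 1e-9

    def test_competency_zero_before_tc(self):
        p = _params(t_c=3.3)
        times = np.linspace(0.0, 10.0, 501)
        fate = rc.integrate_fate(times, np.full((1, 501), 0.5), p)
        assert not fate.L2[0, times <= 3.3].any()
        assert fate.L2[0, -1] > 0

    @pytest.mark.parametrize(
        "mortality",
        [ConstantMortality(0.08), WeibullMortality(0.055, 0.85), WeibullMortality(0.05, 2.0)],
    )
    def test_mass_balance_near_machine_precision(self, mortality):
        rng = np.random.default_rng(0)
        times = np.linspace(0.0, 120.0, 2001)
        fr = np.where(rng.random((5, 2001)) < 0.3, rng.random((5, 2001)), 0.0)
        p = _params(t_c=3.2, mortality=mortality)
        fate = rc.integrate_fate(times, fr, p)
        assert fate.mass_balance_residual().max() < 1e-12

    def test_higher_mortality_never_settles_more(self):
        times = np.linspace(0.0, 60.0, 1201)
        fr = np.full((1, len(times)), 0.4)
        settled = []
        for mu in (0.02, 0.1, 0.3):
            fate = rc.integrate_fate(times, fr, _params(mortality=ConstantMortality(mu)))
            settled.append(fate.settled[0])
        assert settled[0] > settled[1] > settled[2]

    def test_state_stays_in_simplex(self, mini_sim):
        fate = mini_sim["fate"]
        assert (fate.L1 >= 0).all() and (fate.L2 >= 0).all()
        assert (fate.L1 + fate.L2 <= 1 + 1e-12).all()
        assert (np.diff(fate.L1, axis=1) <= 1e-15).all()  # L1 non-increasing

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            _params(alpha=-0.1)
        with pytest.raises(ValueError):
            _params(t_c=130.0)  # exceeds t_max


def _stationary_sim(fr_value, params, t_max=20.0, dt=0.01):
    """Zero-flow single-cell world: one particle parked over reef."""
    g = rc.GridSpec(0.0, 100.0, 0.0, 100.0, 1, 1)
    field = rc.make_uniform_field(0.0, 0.0, g)
    reef = rc.ReefGrid(
        g.x_edges,
        g.y_edges,
        np.array([[fr_value]]),
        g.cell_area(),
        np.array([[0]]),
    )
    n = params.n_per_cell
    rel = ReleaseSet(
        np.repeat([[0, 0]], n, axis=0),
        np.repeat([[50.0, 50.0]], n, axis=0),
        n,
        pd.Timestamp("2000-11-01"),
    )
    traj = rc.advect(field, rel, dt=dt, t_max=t_max)
    fr = rc.sample_reef_fraction(traj, reef)
    fate = rc.integrate_fate(traj.times, fr, params)
    events = rc.settle_events(traj, fate, reef, params)
    return reef, rel, traj, fate, events


class TestSettleEvents:
    def test_no_reef_after_tc_gives_empty_table(self, grid):
        p = _params(t_c=5.0, t_max=10.0)
        field = rc.make_uniform_field(0.0, 0.0, grid)
        reef = rc.make_reef_grid([(1525.0, 525.0)], 1, grid, seed=0)
        rel = ReleaseSet(np.array([[2, 2]]), np.array([[125.0, 125.0]]), 1,
                         pd.Timestamp("2000-11-01"))
        traj = rc.advect(field, rel, dt=0.02, t_max=10.0)
        fate = rc.integrate_fate(traj.times, rc.sample_reef_fraction(traj, reef), p)
        events = rc.settle_events(traj, fate, reef, p)
        assert len(events) == 0

    def test_single_event_matches_quadrature_oracle(self):
        # S = rho A mu_s F_r * int L2 dt with L2 in closed form
        p = _params(mu_s=0.2)
        fr_val, t_max = 0.5, 20.0
        reef, rel, traj, fate, events = _stationary_sim(fr_val, p, t_max=t_max)
        assert len(events) == 1
        integral, _ = quad(
            lambda t: _closed_form(t, p.alpha, 0.1, p.beta, p.mu_s, fr_val)[1],
            0.0,
            t_max,
            limit=200,
        )
        expected = p.rho * reef.cell_area[0, 0] * p.mu_s * fr_val * integral
        assert events["S"].iloc[0] == pytest.approx(expected, rel=1e-6)
        assert events["tau0"].iloc[0] == 0.0
        assert events["dtau"].iloc[0] == pytest.approx(t_max)

    def test_tau0_respects_competency_period(self):
        p = _params(t_c=3.2)
        _, _, _, _, events = _stationary_sim(0.5, p)
        assert len(events) == 1
        assert events["tau0"].iloc[0] == pytest.approx(3.2)

    def test_linear_in_rho(self):
        p1 = _params(rho=1.0)
        p2 = _params(rho=3.5)
        *_, e1 = _stationary_sim(0.5, p1)
        *_, e2 = _stationary_sim(0.5, p2)
        assert e2["S"].iloc[0] == pytest.approx(3.5 * e1["S"].iloc[0], rel=1e-12)

    def test_doubling_particles_keeps_connectivity(self):
        c = {}
        for n in (1, 2):
            p = _params(n_per_cell=n)
            reef, rel, traj, fate, events = _stationary_sim(0.5, p)
            c[n] = rc.accumulate(events, rel, reef, level="group").values
        assert np.allclose(c[1], c[2], rtol=1e-12)

    def test_event_cap_keeps_earliest_sixty(self):
        # fast flow over a long strip of alternating reef cells: > 60 events
        n_cells = 260
        g = rc.GridSpec(0.0, 100.0 * n_cells, 0.0, 100.0, n_cells, 1)
        field = rc.make_uniform_field(0.5, 90.0, g)  # 43.2 km/day
        fr = np.zeros((1, n_cells))
        fr[0, ::2] = 0.5
        gid = np.where(fr > 0, 0, -1)
        reef = rc.ReefGrid(g.x_edges, g.y_edges, fr, g.cell_area(), gid)
        rel = ReleaseSet(np.array([[0, 0]]), np.array([[50.0, 50.0]]), 1,
                         pd.Timestamp("2000-11-01"))
        p = _params(t_c=0.0, t_max=0.58, max_events=60)
        traj = rc.advect(field, rel, dt=0.0005, t_max=0.58)
        fate = rc.integrate_fate(traj.times, rc.sample_reef_fraction(traj, reef), p)
        events = rc.settle_events(traj, fate, reef, p)
        assert len(events) == 60
        assert list(events["event"]) == list(range(60))
        assert events["tau0"].is_monotonic_increasing

    def test_new_event_on_cell_change(self):
        # two adjacent reef cells: crossing the shared edge splits the event
        g = rc.GridSpec(0.0, 200.0, 0.0, 100.0, 2, 1)
        field = rc.make_uniform_field(0.2, 90.0, g)
        fr = np.array([[0.4, 0.8]])
        gid = np.array([[0, 0]])
        reef = rc.ReefGrid(g.x_edges, g.y_edges, fr, g.cell_area(), gid)
        rel = ReleaseSet(np.array([[0, 0]]), np.array([[10.0, 50.0]]), 1,
                         pd.Timestamp("2000-11-01"))
        p = _params(t_c=0.0, t_max=0.01)
        traj = rc.advect(field, rel, dt=0.0001, t_max=0.01)
        fate = rc.integrate_fate(traj.times, rc.sample_reef_fraction(traj, reef), p)
        events = rc.settle_events(traj, fate, reef, p)
        assert len(events) == 2
        assert list(events["dest_ix"]) == [0, 1]
        assert list(events["fr"]) == [0.4, 0.8]
        assert events["tau0"].iloc[1] == pytest.approx(
            events["tau0"].iloc[0] + events["dtau"].iloc[0]
        )

    def test_mass_balance_on_simulated_run(self, mini_sim):
        assert mini_sim["fate"].mass_balance_residual().max() < 1e-8
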