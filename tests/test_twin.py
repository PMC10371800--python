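import numpy as np
import pytest

from fedflux.twin import (
    SPECIES,
    FeedPolicy,
    ReactorState,
    observed_fluxes,
    rhs,
    simulate,
    simulate_fixed_step,
)

from .oracles import rk4_reference


def make_policy(fin=0.0, fout=0.0, cglc=0.0, t1=400.0, feed=None):
    return FeedPolicy(
        knots=np.array([0.0, t1]),
        F_in=np.full(2, fin),
        F_out=np.full(2, fout),
        C_feed_glc=np.full(2, cglc),
        C_feed_other=feed or {},
    )


def test_zero_cells_zero_feed_is_stationary(params, x0):
    x = ReactorState(t=0.0, V=x0.V, Xv=0.0, Xd=0.0, C=dict(x0.C), P=0.0)
    d = rhs(0.0, x.to_vector(), make_policy(), params)
    assert np.allclose(d, 0.0)


def test_balanced_flows_keep_volume(params, x0):
    pol = make_policy(fin=0.5, fout=0.5)
    d = rhs(0.0, x0.to_vector(), pol, params)
    assert d[0] == pytest.approx(0.0)


def test_rhs_matches_explicit_euler_oracle(params, x0, baseline_policy):
    """One tiny Euler step agrees with the fixed-step integrator."""
    dt = 1e-3
    y0 = x0.to_vector()
    euler = y0 + dt * rhs(0.0, y0, baseline_policy, params)
    traj = simulate_fixed_step(x0, baseline_policy, params, x0.t + dt, dt=dt)
    rk4 = traj.final_state.to_vector()
    # Euler and RK4 agree to O(dt^2); the antibody titre starts at 0 so the
    # comparison there is absolute
    assert np.allclose(euler, rk4, rtol=1e-6, atol=1e-8)


def test_constant_trajectory_without_cells_or_feed(params, x0, no_feed_policy):
    x = ReactorState(t=0.0, V=x0.V, Xv=0.0, Xd=0.0, C=dict(x0.C), P=0.0)
    traj = simulate(x, no_feed_policy, params, 100.0, output_dt=10.0)
    first, last = traj.states[0], traj.states[-1]
    assert last.V == pytest.approx(first.V)
    for s in SPECIES:
        assert last.C[s] == pytest.approx(first.C[s], abs=1e-9)


def test_output_grid_independence(params, x0, baseline_policy):
    a = simulate(x0, baseline_policy, params, 48.0, output_dt=4.0)
    b = simulate(x0, baseline_policy, params, 48.0, output_dt=2.0)
    va = a.final_state.to_vector()
    vb = b.final_state.to_vector()
    assert np.allclose(va, vb, rtol=1e-8)


def test_batch_matches_rk4_oracle(params, x0, no_feed_policy):
    traj = simulate(x0, no_feed_policy, params, 360.0, output_dt=4.0)
    ref = rk4_reference(x0, no_feed_policy, params, 360.0, dt=0.01)
    got = traj.final_state.to_vector()
    assert np.allclose(got, ref, rtol=1e-4, atol=1e-8)
    # growth-then-decline shape
    xv = np.array([s.Xv for s in traj.states])
    peak = int(np.argmax(xv))
    assert 0 < peak < len(xv) - 1
    assert xv[peak] > xv[0] and xv[-1] < xv[peak]


def test_volume_balance_for_random_policies(params, x0):
    rng = np.random.default_rng(0)
    for _ in range(20):
        nk = int(rng.integers(2, 6))
        knots = np.sort(rng.uniform(0.0, 200.0, nk))
        knots[0], knots[-1] = 0.0, 200.0
        if np.any(np.diff(knots) <= 0):
            knots = np.linspace(0.0, 200.0, nk)
        pol = FeedPolicy(
            knots=knots,
            F_in=rng.uniform(0.0, 2.0, nk),
            F_out=rng.uniform(0.0, 1.0, nk),
            C_feed_glc=rng.uniform(0.0, 500.0, nk),
            C_feed_other={},
        )
        traj = simulate(x0, pol, params, 200.0, output_dt=20.0)
        expected = x0.V + np.trapezoid(pol.F_in - pol.F_out, pol.knots)
        assert traj.final_state.V == pytest.approx(expected, rel=1e-6)


def test_positivity(params, x0, baseline_policy):
    traj = simulate(x0, baseline_policy, params, 360.0, output_dt=2.0)
    for s in traj.states:
        assert s.Xv >= -1e-9 and s.Xd >= -1e-9 and s.P >= -1e-9
        assert all(c >= -1e-9 for c in s.C.values())


def test_monotone_response_to_feed_concentration(params, x0, feed_conc):
    lowpol = make_policy(fin=0.3, cglc=100.0, feed=feed_conc)
    highpol = make_policy(fin=0.3, cglc=300.0, feed=feed_conc)
    lo = simulate(x0, lowpol, params, 120.0, output_dt=4.0)
    hi = simulate(x0, highpol, params, 120.0, output_dt=4.0)
    assert np.all(hi.glucose_fed >= lo.glucose_fed - 1e-9)


def test_cumulative_glucose_fed_nondecreasing(params, x0, baseline_policy):
    traj = simulate(x0, baseline_policy, params, 360.0, output_dt=2.0)
    assert np.all(np.diff(traj.glucose_fed) >= -1e-12)


def test_observed_fluxes_schema(params, x0, baseline_policy, stage_targets):
    traj = simulate(x0, baseline_policy, params, 48.0, output_dt=8.0)
    fluxes = observed_fluxes(traj)
    assert set(fluxes.columns) == set(stage_targets.tracked)


def test_observed_glucose_flux_is_minus_uptake(params, x0, baseline_policy):
    from fedflux.kinetics import specific_rates

    traj = simulate(x0, baseline_policy, params, 48.0, output_dt=8.0)
    fluxes = observed_fluxes(traj)
    for state, got in zip(traj.states, fluxes["glc"]):
        assert got == pytest.approx(specific_rates(state.C, params)["glc"], rel=1e-12)


def test_zero_cell_fluxes_are_zero(params, x0, no_feed_policy):
    x = ReactorState(t=0.0, V=x0.V, Xv=0.0, Xd=0.0, C=dict(x0.C), P=0.0)
    traj = simulate(x, no_feed_policy, params, 48.0, output_dt=8.0)
    assert np.allclose(observed_fluxes(traj).to_numpy(), 0.0)


def test_policy_outside_range_raises(params, x0):
    pol = make_policy(t1=100.0)
    with pytest.raises(ValueError, match="span"):
        simulate(x0, pol, params, 200.0)


def test_antibody_mass_is_titre_times_volume(params, x0, baseline_policy):
    traj = simulate(x0, baseline_policy, params, 100.0, output_dt=10.0)
    s = traj.final_state
    assert traj.final_antibody_mass == pytest.approx(s.P * s.V)


def test_policy_concatenation_roundtrip(baseline_policy):
    a = baseline_policy.restricted(0.0, 100.0)
    b = baseline_policy.restricted(100.0, 360.0)
    joined = FeedPolicy.concatenate([a, b])
    ts = np.linspace(0.0, 360.0, 37)
    for t in ts:
        assert joined.at(t) == pytest.approx(baseline_policy.at(t))
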