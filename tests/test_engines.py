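"""Simulation backends: grids, closed-form limits, determinism, SSA behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from withinhost.engines import (
    SimulationError,
    simulate,
    simulate_discrete,
    simulate_ode,
    simulate_stochastic,
    time_grid,
)
from withinhost.models import make_basic_bacteria_model, resolve_parameters
from withinhost.oracles import logistic_closed_form


def test_output_grid_from_default_time_settings(basic, basic_defaults):
    traj = simulate_ode(basic, basic_defaults)
    assert len(traj.times) == 601
    assert traj.times[0] == 0.0
    assert traj.times[-1] == pytest.approx(30.0)
    assert np.allclose(np.diff(traj.times), 0.05)


def test_grid_caps_at_last_multiple_below_tfinal(basic):
    p = resolve_parameters(basic, {"tfinal": 30.03})
    grid = time_grid(p)
    assert grid[-1] == pytest.approx(30.0)
    assert len(grid) == 601


def test_ode_immune_decay_when_no_bacteria(basic):
    """With B0=0, B stays 0 and I decays as a pure exponential."""
    p = resolve_parameters(basic, {"B": 0.0})
    traj = simulate_ode(basic, p)
    assert np.all(traj["B"] == 0)
    expected = np.exp(-p["dI"] * traj.times)
    assert np.allclose(traj["I"], expected, rtol=1e-6)


def test_ode_matches_logistic_closed_form(basic):
    """Switching off death and killing reduces B to pure logistic growth."""
    p = resolve_parameters(basic, {"k": 0.0, "dB": 0.0, "I": 0.0})
    traj = simulate_ode(basic, p)
    expected = np.array(
        [logistic_closed_form(10.0, 1.0, 1e5, t) for t in traj.times]
    )
    rel = np.abs(traj["B"] - expected) / expected
    assert rel.max() < 1e-6


def test_euler_first_step_hand_arithmetic(basic, basic_defaults):
    """x + dt*drift(x) from the printed defaults, checked to 1e-12."""
    traj = simulate_discrete(basic, basic_defaults)
    assert traj["B"][1] == pytest.approx(10.4499495, abs=1e-12)
    assert traj["I"][1] == pytest.approx(0.9505, abs=1e-12)


def test_euler_origin_absorbing(basic):
    p = resolve_parameters(basic, {"B": 0.0, "I": 0.0})
    traj = simulate_discrete(basic, p)
    assert np.all(traj["B"] == 0) and np.all(traj["I"] == 0)


def test_euler_clamps_negative_overshoot_and_logs(basic, caplog):
    """A step overshooting below zero is clamped to 0 with a warning."""
    p = resolve_parameters(basic, {"B": 0.0, "I": 1.0, "dt": 1.5, "tfinal": 3.0})
    with caplog.at_level("WARNING", logger="withinhost.engines"):
        traj = simulate_discrete(basic, p)
    # Euler factor 1 - dt*dI = -0.5 would drive I negative
    assert np.all(traj["I"] >= 0)
    assert traj["I"][1] == 0.0
    assert any("clamped" in rec.message for rec in caplog.records)


def test_euler_halving_dt_roughly_halves_peak_error(basic, basic_defaults):
    """First-order behavior: the peak-outcome error shrinks ~2x with dt/2."""
    errors = []
    for dt in (0.05, 0.025):
        p = basic_defaults.replace(dt=dt)
        ode = simulate_ode(basic, p)
        euler = simulate_discrete(basic, p)
        errors.append(abs(ode["B"].max() - euler["B"].max()))
    assert 1.5 <= errors[0] / errors[1] <= 2.5


def test_euler_raises_on_overflow(basic):
    p = resolve_parameters(basic, {"g": 1e308, "tfinal": 1.0})
    with np.errstate(over="ignore", invalid="ignore"):
        with pytest.raises(SimulationError, match="step"):
            simulate_discrete(basic, p)


def test_stochastic_initial_propensities(basic, basic_defaults):
    """Event rates at the printed initial state (B=10, I=1)."""
    state = {"B": 10.0, "I": 1.0}
    values = [ev(state, basic_defaults) for ev in basic.events]
    assert values == pytest.approx([10.0, 0.001, 1.0, 1e-5, 0.01, 1.0])


def test_stochastic_zero_state_stays_zero(basic):
    p = resolve_parameters(basic, {"B": 0.0, "I": 0.0})
    traj = simulate_stochastic(basic, p, seed=42)
    assert np.all(traj["B"] == 0) and np.all(traj["I"] == 0)
    assert len(traj.times) == 601


def test_stochastic_seed_reproducibility(basic, basic_defaults):
    a = simulate_stochastic(basic, basic_defaults, seed=7)
    b = simulate_stochastic(basic, basic_defaults, seed=7)
    c = simulate_stochastic(basic, basic_defaults, seed=8)
    assert np.array_equal(a["B"], b["B"]) and np.array_equal(a["I"], b["I"])
    assert not (np.array_equal(a["B"], c["B"]) and np.array_equal(a["I"], c["I"]))


def test_stochastic_states_are_nonnegative_integers(basic, basic_defaults):
    traj = simulate_stochastic(basic, basic_defaults, seed=3)
    for name in ("B", "I"):
        assert np.all(traj[name] >= 0)
        assert np.array_equal(traj[name], np.rint(traj[name]))


def test_stochastic_rounds_noninteger_initials_with_warning(basic):
    p = resolve_parameters(basic, {"B": 10.4})
    with pytest.warns(UserWarning, match="rounded"):
        traj = simulate_stochastic(basic, p, seed=1)
    assert traj["B"][0] == 10.0


def test_stochastic_saturated_model_runs(saturated, saturated_defaults):
    traj = simulate_stochastic(saturated, saturated_defaults, seed=11)
    assert len(traj.times) == 601
    assert np.all(traj["I"] >= 0)


def test_stochastic_mean_tracks_ode_at_moderate_population(basic):
    """Quick mean-field sanity check over a short horizon (30 replicates)."""
    p = resolve_parameters(basic, {"B": 1000.0, "I": 100.0, "tfinal": 2.0})
    ode = simulate_ode(basic, p)
    idx = np.searchsorted(ode.times, [1.0, 2.0])
    reps = np.array(
        [simulate_stochastic(basic, p, seed=1000 + i)["B"][idx] for i in range(30)]
    )
    mean = reps.mean(axis=0)
    sem = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
    z = np.abs(mean - ode["B"][idx]) / sem
    assert np.all(z < 4)


def test_dispatch_and_validation(basic, basic_defaults):
    with pytest.raises(ValueError, match="unknown backend"):
        simulate(basic, basic_defaults, backend="leapfrog")
    with pytest.raises(ValueError, match="seed"):
        simulate(basic, basic_defaults, backend="stochastic")
    traj = simulate(basic, basic_defaults, backend="discrete")
    assert traj.meta["backend"] == "discrete"


def test_trajectory_unknown_variable_lookup(basic, basic_defaults):
    traj = simulate_discrete(basic, basic_defaults)
    with pytest.raises(KeyError, match="unknown variable"):
        traj["V"]


@settings(max_examples=20, deadline=None)
@given(
    g=st.floats(0, 5), db=st.floats(0, 2), k=st.floats(0, 1e-4),
    r=st.floats(0, 0.01), di=st.floats(0, 3),
)
def test_deterministic_backends_stay_nonnegative(g, db, k, r, di):
    """No reported value below -1e-9 for random nonnegative parameters."""
    spec = make_basic_bacteria_model()
    p = resolve_parameters(
        spec, {"g": g, "dB": db, "k": k, "r": r, "dI": di, "tfinal": 5.0}
    )
    for backend in (simulate_ode, simulate_discrete):
        traj = backend(spec, p)
        for name in ("B", "I"):
            assert traj[name].min() >= -1e-9
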