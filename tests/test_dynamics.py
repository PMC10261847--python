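import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_states
from supplygame import (
    Singular,
    brackets,
    baseline,
    integrate,
    interior_lattice,
    replicator_field,
    replicator_field_oracle,
    thresholds,
)


def test_field_vanishes_on_faces_and_corners(scenarios, rng):
    for p in scenarios[:10]:
        y, z = rng.uniform(0, 1, 2)
        assert replicator_field(p, (0.0, y, z))[0] == 0.0
        assert replicator_field(p, (1.0, y, z))[0] == 0.0
    for corner in [(0, 1, 0), (1, 1, 1), (0, 0, 0)]:
        assert np.all(replicator_field(baseline(), corner) == 0.0)


def test_baseline_center_field_value(baseline_p):
    """Hand-evaluated brackets (20, 68, 171) times the logistic factor 1/4."""
    expected = np.array([5.0, 17.0, 42.75])
    assert np.allclose(replicator_field(baseline_p, (0.5, 0.5, 0.5)), expected)
    assert np.allclose(
        replicator_field_oracle(baseline_p, (0.5, 0.5, 0.5)), expected
    )


def test_closed_form_matches_payoff_oracle(scenarios, rng):
    states = random_states(rng, 5)
    for p in scenarios[:40]:
        for s in states:
            f = replicator_field(p, s)
            g = replicator_field_oracle(p, s)
            scale = max(np.max(np.abs(f)), 1.0)
            assert np.allclose(f, g, rtol=1e-9, atol=1e-9 * scale)


unit = st.floats(0.0, 1.0, allow_nan=False)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(x=unit, y=unit, z=unit)
def test_field_properties_hold_everywhere(x, y, z):
    """Anywhere in the cube: the closed form equals the payoff-table oracle,
    and each component vanishes on its own faces."""
    p = baseline()
    s = (x, y, z)
    f = replicator_field(p, s)
    g = replicator_field_oracle(p, s)
    scale = max(np.max(np.abs(f)), 1.0)
    assert np.allclose(f, g, rtol=1e-9, atol=1e-9 * scale)
    for i, v in enumerate(s):
        if v in (0.0, 1.0):
            assert f[i] == 0.0


def test_out_of_cube_state_rejected(baseline_p):
    with pytest.raises(ValueError, match="unit cube"):
        replicator_field(baseline_p, (1.2, 0.5, 0.5))
    with pytest.raises(ValueError, match="unit cube"):
        replicator_field_oracle(baseline_p, (0.5, -0.1, 0.5))


def test_field_independent_of_cancelling_parameters(baseline_p, rng):
    """D, E, R1, H1, H3 appear in payoffs but cancel out of the dynamics."""
    states = random_states(rng, 10)
    q = baseline_p.replace(D=999.0, E=1.0, R1=0.0, H1=512.25, H3=77.7)
    for s in states:
        f0 = replicator_field(baseline_p, s)
        f1 = replicator_field(q, s)
        assert np.array_equal(f0, f1)  # bit-identical


def test_threshold_values_at_baseline(baseline_p):
    th = thresholds(baseline_p)
    # the GNPO surface is tangent to the cube at z = A/K2
    assert th.y_star(baseline_p.A / baseline_p.K2) == pytest.approx(1.0)
    assert th.y_star(0.5) == pytest.approx(7.0 / 6.0)       # (-30-30+25)/(-30)
    assert th.y_double_star(0.5) == pytest.approx(1.0)      # -342 / -342
    sing = th.x_star(0.375)  # hospital-surface denominator root 12/32
    assert isinstance(sing, Singular)
    assert sing.argument == pytest.approx(0.375)
    vals = th.x_star_values(np.array([0.0, 0.375, 1.0]))
    assert np.isnan(vals[1]) and np.isfinite(vals[[0, 2]]).all()


def test_thresholds_zero_their_brackets(scenarios):
    """At y = y*(z) the GNPO bracket vanishes, and analogously for the others."""
    for p in scenarios[:25]:
        th = thresholds(p)
        z = 0.2
        ys = th.y_star(z)
        if not isinstance(ys, Singular) and 0.0 <= ys <= 1.0:
            assert brackets(p, (0.5, ys, z))[0] == pytest.approx(0.0, abs=1e-9)
        xs = th.x_star(z)
        if not isinstance(xs, Singular) and 0.0 <= xs <= 1.0:
            assert brackets(p, (xs, 0.5, z))[1] == pytest.approx(0.0, abs=1e-9)
        x = 0.3
        yd = th.y_double_star(x)
        if not isinstance(yd, Singular) and 0.0 <= yd <= 1.0:
            assert brackets(p, (x, yd, 0.5))[2] == pytest.approx(0.0, abs=1e-9)


def test_bracket_monotonicity(scenarios):
    """GNPO bracket decreases in y and government bracket decreases in y
    everywhere (their indifference loci are single-crossing); the hospital
    bracket increases in x on the z=0 face, where its cross term vanishes."""
    for p in scenarios[:25]:
        for z in (0.0, 0.5, 1.0):
            bx_low = brackets(p, (0.5, 0.2, z))[0]
            bx_high = brackets(p, (0.5, 0.8, z))[0]
            assert bx_high <= bx_low + 1e-12
            bz_low = brackets(p, (0.5, 0.2, z))[2]
            bz_high = brackets(p, (0.5, 0.8, z))[2]
            assert bz_high <= bz_low + 1e-12
        by_low = brackets(p, (0.2, 0.5, 0.0))[1]
        by_high = brackets(p, (0.8, 0.5, 0.0))[1]
        assert by_high >= by_low - 1e-12


def test_sign_law_across_gnpo_threshold(scenarios):
    """Below y*(z) the GNPO drifts toward on-demand allocation, above it away."""
    informative = 0
    for p in scenarios:
        th = thresholds(p)
        z = 0.5
        ys = th.y_star(z)
        if isinstance(ys, Singular) or not 0.05 < ys < 0.95:
            continue
        informative += 1
        assert brackets(p, (0.5, ys - 0.04, z))[0] > 0
        assert brackets(p, (0.5, ys + 0.04, z))[0] < 0
    assert informative >= 5


def test_integrate_baseline_reaches_known_ess(baseline_p):
    traj = integrate(baseline_p)
    assert traj.converged
    corner = traj.terminal_corner()
    assert corner in {(0.0, 1.0, 0.0), (1.0, 1.0, 1.0)}
    assert corner == (1.0, 1.0, 1.0)  # recorded outcome at the symmetric start
    assert np.all(np.diff(traj.t) > 0)


def test_integrate_stationary_at_equilibrium(baseline_p):
    traj = integrate(baseline_p, (0.0, 1.0, 0.0), horizon=5.0)
    assert np.allclose(traj.states, [0.0, 1.0, 0.0], atol=1e-12)


def test_cube_forward_invariance(baseline_p):
    for s0 in interior_lattice():
        traj = integrate(baseline_p, s0)
        assert np.all(traj.states >= 0.0) and np.all(traj.states <= 1.0)
        # raw solver overshoot outside the cube is a local-error artifact
        assert traj.max_excursion < 1e-5
    loose = integrate(baseline_p, (0.25, 0.25, 0.25)).max_excursion
    tight = integrate(
        baseline_p, (0.25, 0.25, 0.25), rtol=1e-10, atol=1e-12
    ).max_excursion
    assert tight <= max(loose, 1e-7)  # overshoot shrinks with solver tolerance


def test_result_invariant_under_tolerance_halving(baseline_p):
    t1 = integrate(baseline_p, rtol=1e-8, atol=1e-10)
    t2 = integrate(baseline_p, rtol=5e-9, atol=5e-11)
    assert np.max(np.abs(t1.terminal - t2.terminal)) < 1e-6


def test_trajectory_frame_and_csv(tmp_path, baseline_p):
    traj = integrate(baseline_p, horizon=1.0)
    df = traj.to_frame()
    assert list(df.columns) == ["t", "x", "y", "z"]
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    again = path.read_text()
    traj.to_csv(path)
    assert path.read_text() == again  # deterministic serialization
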