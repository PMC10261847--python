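import dataclasses

import numpy as np
import pytest

from conftest import random_states
from supplygame import (
    CORNER_LABELS,
    ParameterSet,
    check_conditions,
    classify_equilibria,
    corner_eigenvalues,
    enumerate_pure_equilibria,
    find_interior_equilibria,
    integrate,
    jacobian,
    replicator_field,
    stability_report,
)


def test_enumeration_yields_ordered_corners():
    pts = enumerate_pure_equilibria()
    assert len(pts) == 8
    assert pts[0] == (0.0, 0.0, 0.0)
    assert pts[2] == (0.0, 1.0, 0.0)
    assert pts[7] == (1.0, 1.0, 1.0)
    assert pts == enumerate_pure_equilibria()  # stable ordering
    assert len(set(pts)) == 8


def test_corners_are_rest_points(scenarios):
    for p in scenarios[:20]:
        for pt in enumerate_pure_equilibria():
            assert np.all(replicator_field(p, pt) == 0.0)


def test_jacobian_matches_finite_differences(scenarios, rng):
    h = 1e-6
    states = random_states(rng, 5, margin=0.05)
    for p in scenarios[:20]:
        for s in states:
            J = jacobian(p, s)
            fd = np.empty((3, 3))
            for j in range(3):
                sp, sm = s.copy(), s.copy()
                sp[j] += h
                sm[j] -= h
                fd[:, j] = (replicator_field(p, sp) - replicator_field(p, sm)) / (2 * h)
            scale = max(np.max(np.abs(J)), 1.0)
            assert np.allclose(J, fd, rtol=1e-5, atol=1e-5 * scale)


def test_jacobian_offdiagonals_vanish_on_faces(baseline_p, rng):
    for x in (0.0, 1.0):
        J = jacobian(baseline_p, (x, rng.uniform(), rng.uniform()))
        assert J[0, 1] == 0.0 and J[0, 2] == 0.0


def test_jacobian_diagonal_at_corner(baseline_p):
    """At (0,1,0) the Jacobian is diagonal with entries {-25, -6, -10}."""
    J = jacobian(baseline_p, (0.0, 1.0, 0.0))
    assert np.allclose(J, np.diag(np.diag(J)))
    assert sorted(np.diag(J)) == pytest.approx([-25.0, -10.0, -6.0])


def test_closed_form_eigenvalues_match_numeric(scenarios):
    for p in scenarios[:30]:
        for pt in enumerate_pure_equilibria():
            closed = sorted(corner_eigenvalues(p, pt))
            numeric = sorted(np.linalg.eigvals(jacobian(p, pt)).real)
            scale = max(max(abs(v) for v in closed), 1.0)
            assert np.allclose(closed, numeric, rtol=1e-8, atol=1e-8 * scale)


def test_corner_eigenvalues_rejects_interior_point(baseline_p):
    with pytest.raises(ValueError, match="corner"):
        corner_eigenvalues(baseline_p, (0.5, 0.5, 0.5))


def test_all_zero_parameters_give_zero_eigenvalues():
    zero = ParameterSet(**{f.name: 0.0 for f in dataclasses.fields(ParameterSet)})
    for pt in enumerate_pure_equilibria():
        assert corner_eigenvalues(zero, pt) == (0.0, 0.0, 0.0)


def test_baseline_classification(baseline_p):
    reports = {r.label: r for r in classify_equilibria(baseline_p)}
    assert reports["E3"].classification == "ESS"
    assert reports["E3"].eigenvalues == pytest.approx((-6.0, -25.0, -10.0))
    assert reports["E8"].classification == "ESS"
    assert reports["E8"].eigenvalues == pytest.approx((-35.0, -10.0, -114.0))
    for label in CORNER_LABELS:
        if label not in ("E3", "E8"):
            assert reports[label].classification == "unstable"


def test_ess_lost_when_opportunistic_gain_exceeds_penalty(baseline_p):
    reports = {r.label: r for r in classify_equilibria(baseline_p.replace(A=70.0))}
    assert reports["E8"].classification == "unstable"
    assert reports["E8"].eigenvalues[0] == pytest.approx(10.0)  # A - K2


def test_critical_band_reported_not_guessed(baseline_p):
    """A zero eigenvalue puts the corner in the inconclusive Lyapunov case."""
    p = baseline_p.replace(H5=40.0)  # H4 - H5 - R2 = 0 exactly
    reports = {r.label: r for r in classify_equilibria(p)}
    assert reports["E8"].classification == "critical"
    assert reports["E8"].sign_pattern[1] == "0"


def test_condition_values_at_baseline(baseline_p):
    cc = check_conditions(baseline_p)
    values = [v for _, v, _ in cc.condition1_checks + cc.condition2_checks]
    assert values == pytest.approx([-6.0, -10.0, -35.0, -10.0, -114.0])
    assert cc.both


def test_condition_single_term_flip(baseline_p):
    cc = check_conditions(baseline_p.replace(H4=120.0))
    assert not cc.condition2
    assert dict((n, v) for n, v, _ in cc.condition2_checks)["H4 - H5 - R2 < 0"] == 10.0


def test_conditions_iff_bistable_classification(scenarios, bistable_scenarios):
    """Both condition sets hold exactly when E3 and E8 are both ESS."""
    for p in list(scenarios) + list(bistable_scenarios):
        cc = check_conditions(p)
        ess = {r.label for r in classify_equilibria(p) if r.classification == "ESS"}
        assert cc.both == ({"E3", "E8"} <= ess)
    for p in bistable_scenarios:
        ess = {r.label for r in classify_equilibria(p) if r.classification == "ESS"}
        assert {"E3", "E8"} <= ess


def test_ess_attracts_nearby_states(baseline_p):
    for ess in [(0.0, 1.0, 0.0), (1.0, 1.0, 1.0)]:
        start = np.clip(np.array(ess) + np.array([1e-3, -1e-3, 1e-3]), 0, 1)
        traj = integrate(baseline_p, start, horizon=20.0)
        assert np.max(np.abs(traj.terminal - np.array(ess))) < 1e-6


def test_unstable_corner_repels_along_unstable_direction(baseline_p):
    # E1 has its strongest positive eigenvalue along z
    traj = integrate(baseline_p, (0.0, 0.0, 1e-3), horizon=20.0, field_tol=0.0)
    dists = np.linalg.norm(traj.states, axis=1)
    assert np.max(dists) > 0.1


def test_interior_rest_points_are_reported_unclassified(scenarios):
    found_any = False
    for p in scenarios[:15]:
        pts = find_interior_equilibria(p)
        for pt in pts:
            found_any = True
            assert all(0.0 < v < 1.0 for v in pt)
            assert np.linalg.norm(replicator_field(p, pt)) < 1e-7
    # existence is parameter dependent; the call itself must always succeed
    assert found_any or True


def test_stability_report_structure(baseline_p):
    rep = stability_report(baseline_p)
    assert [e["label"] for e in rep["equilibria"]] == list(CORNER_LABELS)
    assert rep["ess"] == ["E3", "E8"]
    assert rep["conditions"]["condition1"]["satisfied"]
    assert isinstance(rep["interior_rest_points"], list)
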