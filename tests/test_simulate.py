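import numpy as np
import pandas as pd
import pytest

import herdsync as hs
from herdsync.scoring import validate_scan_frame
from herdsync.simulate import _BEHAVIOURS, HerdStateSeries


def manual_states(positions, labels, excluded=None,
                  schedule=None):
    """Build a single-step HerdStateSeries from explicit arrays."""
    positions = np.asarray(positions, float)[None, :, :]
    labels = np.asarray(labels, np.int8)[None, :]
    n = positions.shape[1]
    active = np.array([[
        hs.classify_dichotomous(_BEHAVIOURS[i]) is hs.ActivityClass.ACTIVE
        for i in labels[0]
    ]])
    schedule = schedule or hs.ProtocolSchedule(
        n_sessions=1, scans_per_session=1, intersession_gap_scans=0)
    return HerdStateSeries(
        positions=positions, active=active, labels=labels,
        excluded=np.zeros(n, bool) if excluded is None else np.asarray(excluded),
        config=hs.HerdConfig(herd_size=max(n, 6)),
        dynamics=hs.BehaviourDynamics(),
        schedule=schedule,
    )


def test_study_schedule_emits_2250_valid_records():
    records = hs.simulate_study(seed=1)
    assert len(records) == 30 * 15 * 5
    validate_scan_frame(records)  # five roles per scan, consecutive scans
    assert records["session"].nunique() == 30


@pytest.mark.parametrize("n_sessions,n_scans", [(2, 3), (4, 1)])
def test_record_count_arithmetic(n_sessions, n_scans):
    schedule = hs.ProtocolSchedule(
        n_sessions=n_sessions, scans_per_session=n_scans,
        intersession_gap_scans=2)
    records = hs.simulate_study(schedule=schedule, seed=0)
    assert len(records) == n_sessions * n_scans * 5


def test_fixed_seed_reproduces_dataset():
    a = hs.simulate_study(seed=33)
    b = hs.simulate_study(seed=33)
    pd.testing.assert_frame_equal(a, b)
    s1 = hs.simulate_herd(seed=7)
    s2 = hs.simulate_herd(seed=7)
    assert np.array_equal(s1.positions, s2.positions)
    assert np.array_equal(s1.labels, s2.labels)


def test_independent_herd_matches_target_activity_level():
    # lambda = 0: stationary marginal activity = baseline (0.411); with
    # 70 agents x 1350 steps and AR(1) mixing the 4-sigma band is ~0.02
    states = hs.simulate_herd(seed=2)
    assert states.active.mean() == pytest.approx(0.411, abs=0.02)


def test_independent_herd_matches_independence_expectation():
    # lambda = 0: neighbour and control synchrony proportions estimate
    # a**2 + (1 - a)**2 for the realised pooled a
    schedule = hs.ProtocolSchedule(n_sessions=300)
    records = hs.simulate_study(schedule=schedule, seed=6)
    a = hs.pooled_activity_proportion(records)
    expected = hs.expected_independent_sync(a)
    m = hs.score_sessions(records, "dichotomous")
    col_means = m.proportions().mean(axis=0)
    # ~4500 scan pairs per column; autocorrelation inflates the MC error,
    # 0.04 is a conservative band
    assert np.allclose(col_means, expected, atol=0.04)


def test_distance_ties_resolved_by_lowest_id():
    # all agents co-located: neighbours must be the three lowest-id
    # non-focal agents, whatever the focal
    pos = np.zeros((6, 2))
    labels = np.arange(6)  # unique behaviour per agent
    states = manual_states(pos, labels)
    records = hs.sample_protocol(states, seed=0)
    by_role = records.set_index("role")["behaviour"]
    focal_id = _BEHAVIOURS.index(hs.parse_behaviour(by_role["focal"]))
    expect = [i for i in range(6) if i != focal_id][:3]
    got = [
        _BEHAVIOURS.index(hs.parse_behaviour(by_role[f"neighbour{k}"]))
        for k in (1, 2, 3)
    ]
    assert got == expect


def test_excluded_agents_never_recorded():
    rng = np.random.default_rng(0)
    pos = rng.normal(size=(9, 2))
    labels = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8])
    excluded = np.array([True, True, True] + [False] * 6)
    schedule = hs.ProtocolSchedule(n_sessions=4, scans_per_session=1,
                                   intersession_gap_scans=0)
    states = manual_states(pos, labels, excluded=excluded)
    states.positions = np.repeat(states.positions, 4, axis=0)
    states.active = np.repeat(states.active, 4, axis=0)
    states.labels = np.repeat(states.labels, 4, axis=0)
    records = hs.sample_protocol(states, schedule=schedule, seed=1)
    seen = {_BEHAVIOURS.index(hs.parse_behaviour(b))
            for b in records["behaviour"]}
    assert seen.isdisjoint({0, 1, 2})


def test_too_few_eligible_animals_rejected():
    pos = np.zeros((6, 2))
    states = manual_states(pos, np.arange(6),
                           excluded=np.array([True, True] + [False] * 4))
    with pytest.raises(ValueError, match="eligible"):
        hs.sample_protocol(states, seed=0)
    with pytest.raises(ValueError, match="herd_size"):
        hs.HerdConfig(herd_size=6, n_excluded=2)


def test_dynamics_validation():
    with pytest.raises(ValueError):
        hs.BehaviourDynamics(baseline_active=1.2)
    with pytest.raises(ValueError):
        hs.BehaviourDynamics(copy_strength=-1.0)
    with pytest.raises(ValueError):
        hs.BehaviourDynamics(strict_mixture={"Active": {"Resting": 1.0}})
    with pytest.raises(ValueError):
        hs.BehaviourDynamics(strict_mixture={"Active": {"Grazing": 0.7}})


def test_synchrony_increases_with_copy_strength():
    # median nearest-neighbour synchrony is non-decreasing in lambda
    # (3 levels, fixed seed batch)
    schedule = hs.ProtocolSchedule(n_sessions=40)
    medians = []
    for lam in (0.0, 3.0, 49.0):
        vals = []
        for seed in (101, 202, 303):
            dyn = hs.BehaviourDynamics(copy_strength=lam)
            rec = hs.simulate_study(dynamics=dyn, schedule=schedule,
                                    seed=seed)
            m = hs.score_sessions(rec, "dichotomous")
            vals.append(m.median_proportions()["neighbour1"])
        medians.append(np.mean(vals))
    assert medians[0] <= medians[1] <= medians[2]
    assert medians[2] > medians[0]  # coupling has a visible effect


def test_strong_copy_dataset_shows_proximity_gradient(
        strong_copy_records_30):
    m = hs.score_sessions(strong_copy_records_30, "dichotomous")
    med = m.median_proportions()
    assert med["neighbour1"] > med["control"]
    assert hs.friedman_test(m).p_value < 0.05


def test_positions_stay_inside_arena():
    config = hs.HerdConfig(arena=(30.0, 20.0), home_range_scale=10.0,
                           movement_step=2.0)
    states = hs.simulate_herd(config=config, seed=3)
    assert states.positions[:, :, 0].min() >= 0
    assert states.positions[:, :, 0].max() <= 30
    assert states.positions[:, :, 1].min() >= 0
    assert states.positions[:, :, 1].max() <= 20


def test_positions_frame_layout():
    schedule = hs.ProtocolSchedule(n_sessions=1, scans_per_session=2,
                                   intersession_gap_scans=0)
    states = hs.simulate_herd(schedule=schedule, seed=0)
    frame = states.positions_frame()
    assert list(frame.columns) == ["t", "id", "x", "y", "class"]
    assert len(frame) == states.n_steps * states.herd_size
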