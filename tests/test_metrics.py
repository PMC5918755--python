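import math

import numpy as np
import pytest

from trustsim import ModelConfig, Population, run_simulation
from trustsim.metrics import (
    RunSummary,
    Trajectory,
    aggregate_replications,
    convergence_time,
    decline_recovery_ratio,
    mean_willingness,
    read_trajectories,
    summary_from_trajectory,
    unrecovered_trust,
    write_summaries,
    write_trajectories,
    years_equivalent,
)
from trustsim.core_model import Group


def make_traj(times, dom, sub, rep=0):
    times = np.asarray(times)
    dom = np.asarray(dom, dtype=float)
    sub = np.asarray(sub, dtype=float)
    zeros = np.zeros_like(dom)
    return Trajectory(times, dom, sub, zeros, zeros, replication=rep)


# ---------------------------------------------------------------------------
# mean willingness
# ---------------------------------------------------------------------------
def test_mean_willingness_simple_cases():
    beliefs = np.array([[0.9, 0.4], [0.8, 0.4], [0.2, 0.1], [0.6, 0.3]])
    pop = Population(beliefs, 2, 2)
    assert mean_willingness(pop, Group.DOMINANT, Group.SUBORDINATE) == pytest.approx(0.4)
    assert mean_willingness(pop, Group.SUBORDINATE, Group.DOMINANT) == pytest.approx(0.4)
    two = Population(np.array([[0.0, 0.2], [0.0, 0.6], [0.5, 0.5]]), 2, 1)
    assert mean_willingness(two, Group.DOMINANT, Group.SUBORDINATE) == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# convergence time
# ---------------------------------------------------------------------------
def test_convergence_time_examples():
    t = [0, 10, 100, 1000]
    same = make_traj(t, [0.3] * 4, [0.3] * 4)
    assert convergence_time(same, 1e-4) == 0
    gap = make_traj(t, [0.5, 0.31, 0.30005, 0.3], [0.25, 0.3, 0.3, 0.3])
    assert convergence_time(gap, 1e-4) == 100
    never = make_traj(t, [0.5] * 4, [0.25] * 4)
    assert convergence_time(never, 1e-4) is None
    with pytest.raises(ValueError):
        convergence_time(same, 0.0)


def test_convergence_time_monotone_in_threshold(rng):
    times = np.arange(0, 50)
    dom = 0.3 + 0.2 * np.exp(-times / 7.0) + 0.01 * rng.random(50)
    sub = np.full(50, 0.3)
    tr = make_traj(times, dom, sub)
    thresholds = [1e-3, 3e-3, 1e-2, 3e-2, 1e-1, 0.5]
    found = [convergence_time(tr, thr) for thr in thresholds]
    as_inf = [math.inf if v is None else v for v in found]
    assert all(a >= b for a, b in zip(as_inf, as_inf[1:]))


# ---------------------------------------------------------------------------
# unrecovered trust and decline/recovery ratio
# ---------------------------------------------------------------------------
def test_unrecovered_trust_examples():
    t = [0, 10_000, 10_010_000]
    equal = make_traj(t, [0.5, 0.4, 0.45], [0.5, 0.3, 0.45])
    assert unrecovered_trust(equal, 10_000, 10_000_000) == pytest.approx(0.0)
    gap = make_traj(t, [0.5, 0.4, 0.7], [0.5, 0.3, 0.4])
    assert unrecovered_trust(gap, 10_000, 10_000_000) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        unrecovered_trust(gap, 10_000, 20_000_000)  # horizon too short


def test_decline_recovery_ratio_examples():
    # decline 0.2 over 1e4, recovery 0.1 over 1e7 -> (0.2/1e4)/(0.1/1e7) = 2000
    tr = make_traj([0, 10_000, 10_010_000], [0.3, 0.3, 0.3], [0.5, 0.3, 0.4])
    assert decline_recovery_ratio(tr, 10_000) == pytest.approx(2000.0)
    symmetric = make_traj([0, 100, 200], [0.3] * 3, [0.5, 0.3, 0.5])
    assert decline_recovery_ratio(symmetric, 100) == pytest.approx(1.0)
    flat = make_traj([0, 100, 200], [0.3] * 3, [0.5, 0.3, 0.3])
    assert math.isnan(decline_recovery_ratio(flat, 100))
    with pytest.raises(ValueError):
        decline_recovery_ratio(symmetric, 500)


# ---------------------------------------------------------------------------
# model time to years
# ---------------------------------------------------------------------------
def test_years_equivalent():
    long_run = years_equivalent(10_000_000, 50)
    assert long_run == pytest.approx(10_000_000 / (50 * 365))
    assert long_run > 500
    assert years_equivalent(365 * 7.3, 7.3) == pytest.approx(1.0)
    assert years_equivalent(10_000, 100) == pytest.approx(years_equivalent(10_000, 50) / 2)
    with pytest.raises(ValueError):
        years_equivalent(100, 0)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------
def _summary(term_dom, term_sub, rep=0, conv=None):
    return RunSummary(
        convergence_time=conv,
        convergence_value=None,
        terminal_mean_dominant_toward_subordinate=term_dom,
        terminal_mean_subordinate_toward_dominant=term_sub,
        unrecovered_trust=None,
        decline_recovery_ratio=None,
        replication=rep,
    )


def test_aggregate_single_replication_is_identity():
    tr = make_traj([0, 10], [0.4, 0.35], [0.5, 0.45])
    agg_tr, agg = aggregate_replications([_summary(0.35, 0.45)], [tr])
    assert np.array_equal(agg_tr.mean_dominant_toward_subordinate, tr.mean_dominant_toward_subordinate)
    assert agg["terminal_mean_dominant_toward_subordinate"]["mean"] == 0.35
    assert agg["unrecovered_trust"]["mean"] is None


def test_aggregate_two_replications_pointwise_mean_and_permutation_invariance():
    tr_a = make_traj([0, 10], [0.4, 0.4], [0.6, 0.6], rep=0)
    tr_b = make_traj([0, 10], [0.2, 0.2], [0.4, 0.4], rep=1)
    s_a, s_b = _summary(0.4, 0.6, 0), _summary(0.2, 0.4, 1)
    agg_tr, agg = aggregate_replications([s_a, s_b], [tr_a, tr_b])
    assert np.allclose(agg_tr.mean_dominant_toward_subordinate, [0.3, 0.3])
    agg_tr2, agg2 = aggregate_replications([s_b, s_a], [tr_b, tr_a])
    assert np.array_equal(agg_tr.mean_dominant_toward_subordinate, agg_tr2.mean_dominant_toward_subordinate)
    assert agg["terminal_mean_dominant_toward_subordinate"] == agg2["terminal_mean_dominant_toward_subordinate"]


def test_aggregate_rejects_mismatched_grids():
    tr_a = make_traj([0, 10], [0.4, 0.4], [0.6, 0.6])
    tr_b = make_traj([0, 20], [0.2, 0.2], [0.4, 0.4])
    with pytest.raises(ValueError):
        aggregate_replications([_summary(0.4, 0.6), _summary(0.2, 0.4)], [tr_a, tr_b])


# ---------------------------------------------------------------------------
# CSV round trips: summaries are pure functions of saved trajectories
# ---------------------------------------------------------------------------
def test_csv_round_trip_preserves_trajectories_and_statistics(tmp_path):
    cfg = ModelConfig(
        alpha_mode="constant", alpha_constant=0.25, horizon=5000,
        n_replications=2, checkpoints=40, seed=5,
    )
    result = run_simulation(cfg)
    path = tmp_path / "trajectories.csv"
    write_trajectories(path, result.trajectories, config=cfg)
    back = read_trajectories(path)
    assert len(back) == 2
    for orig, loaded in zip(result.trajectories, back):
        assert np.array_equal(orig.times, loaded.times)
        assert np.array_equal(
            orig.mean_dominant_toward_subordinate, loaded.mean_dominant_toward_subordinate
        )
        s_orig = summary_from_trajectory(orig, threshold=0.01)
        s_loaded = summary_from_trajectory(loaded, threshold=0.01)
        assert s_orig == s_loaded
    spath = tmp_path / "summaries.csv"
    write_summaries(spath, result.summaries, aggregate=result.aggregate_summary, config=cfg)
    assert spath.read_text().startswith("# ")
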