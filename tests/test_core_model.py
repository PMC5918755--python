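import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from trustsim import (
    Action,
    Group,
    ModelConfig,
    Population,
    RngBundle,
    choose_action,
    init_population,
    sample_dyad,
    sample_dyads,
    step,
    update_belief,
)
from trustsim.core_model import checkpoint_grid, replication_bundles


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------
def test_initial_prior_means_match_uniform_expectations():
    # dominant out-group prior U(0, 0.5) -> mean 0.25; subordinate U(0, 1) -> 0.5
    cfg = ModelConfig(theta=0.5)
    dom, sub = [], []
    for bundle in replication_bundles(seed=7, n_replications=300):
        pop = init_population(cfg, bundle)
        dom.append(pop.group_beliefs(Group.DOMINANT, Group.SUBORDINATE))
        sub.append(pop.group_beliefs(Group.SUBORDINATE, Group.DOMINANT))
    dom, sub = np.concatenate(dom), np.concatenate(sub)
    assert dom.mean() == pytest.approx(0.25, abs=0.005)  # ~5 sigma Monte-Carlo band
    assert sub.mean() == pytest.approx(0.50, abs=0.016)


def test_unbiased_theta_one_groups_are_exchangeable():
    cfg = ModelConfig(theta=1.0)
    dom, sub = [], []
    for bundle in replication_bundles(seed=11, n_replications=100):
        pop = init_population(cfg, bundle)
        dom.append(pop.group_beliefs(Group.DOMINANT, Group.SUBORDINATE))
        sub.append(pop.group_beliefs(Group.SUBORDINATE, Group.DOMINANT))
    result = sps.ks_2samp(np.concatenate(dom), np.concatenate(sub))
    assert result.pvalue > 0.001


def test_truncated_normal_priors_stay_inside_unit_interval():
    cfg = ModelConfig(
        prior_family="truncated_normal",
        prior_dominant=(0.25, 0.2),
        prior_subordinate=(0.5, 0.2),
    )
    for bundle in replication_bundles(seed=3, n_replications=50):
        pop = init_population(cfg, bundle)
        cross = np.concatenate(
            [
                pop.group_beliefs(Group.DOMINANT, Group.SUBORDINATE),
                pop.group_beliefs(Group.SUBORDINATE, Group.DOMINANT),
            ]
        )
        assert np.all(cross > 0.0) and np.all(cross < 1.0)


# ---------------------------------------------------------------------------
# dyad sampling
# ---------------------------------------------------------------------------
def test_dyad_sampling_frequencies_match_combinatorics(rng):
    # 80/20: cross pairs 80*20 = 1600 of C(100,2) = 4950; J-J pairs C(20,2) = 190
    a, b = sample_dyads(100, rng, 1_000_000)
    assert np.all(a != b)
    cross = np.mean((a < 80) != (b < 80))
    both_sub = np.mean((a >= 80) & (b >= 80))
    assert cross == pytest.approx(1600 / 4950, abs=0.002)
    assert both_sub == pytest.approx(190 / 4950, abs=0.0008)


def test_dyad_sampling_uniform_over_pairs(rng):
    # every unordered pair of a 6-agent society equally likely
    a, b = sample_dyads(6, rng, 150_000)
    pairs = np.minimum(a, b) * 6 + np.maximum(a, b)
    _, counts = np.unique(pairs, return_counts=True)
    assert counts.size == 15
    chi2 = ((counts - 10_000.0) ** 2 / 10_000.0).sum()
    assert chi2 < sps.chi2.ppf(0.999, df=14)


def test_sample_dyad_requires_two_agents(rng):
    pop = Population(np.full((1, 2), 0.5), 1, 0)
    with pytest.raises(ValueError):
        sample_dyad(pop, rng)
    pop2 = Population(np.full((3, 2), 0.5), 2, 1)
    a, b = sample_dyad(pop2, rng)
    assert a != b


# ---------------------------------------------------------------------------
# actions and belief updates
# ---------------------------------------------------------------------------
def test_choose_action_degenerate_beliefs(rng):
    assert all(choose_action(1.0, rng) is Action.COLLABORATE for _ in range(50))
    assert all(choose_action(0.0, rng) is Action.DEFECT for _ in range(50))
    with pytest.raises(ValueError):
        choose_action(1.2, rng)


def test_choose_action_matches_belief_probability(rng):
    draws = [int(choose_action(0.5, rng)) for _ in range(100_000)]
    assert np.mean(draws) == pytest.approx(0.5, abs=0.005)  # ~3 sigma binomial


def test_choose_action_threshold_rule(rng):
    assert choose_action(0.49, rng, rule="threshold") is Action.DEFECT
    assert choose_action(0.5, rng, rule="threshold") is Action.COLLABORATE


def test_update_belief_exact_values():
    assert update_belief(0.5, Action.COLLABORATE, 0.25) == 0.625
    assert update_belief(0.37, Action.DEFECT, 0.0) == 0.37  # alpha=0: no learning
    assert update_belief(0.2, Action.COLLABORATE, 1.0) == 1.0
    with pytest.raises(ValueError):
        update_belief(0.5, Action.COLLABORATE, 1.5)


@given(st.floats(0, 1), st.integers(0, 1), st.floats(0, 1))
def test_update_belief_is_bounded_and_monotone(belief, action, alpha):
    new = update_belief(belief, action, alpha)
    assert 0.0 <= new <= 1.0
    if action == 1:
        assert new >= belief - 1e-15  # collaboration never lowers trust
    else:
        assert new <= belief + 1e-15


# ---------------------------------------------------------------------------
# single step
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "cfg",
    [
        ModelConfig(alpha_mode="constant", alpha_constant=0.3, horizon=1),
        ModelConfig(horizon=1),  # conformity
    ],
    ids=["constant", "conformity"],
)
def test_step_changes_at_most_two_directed_beliefs(cfg):
    bundle = RngBundle.from_seed(21)
    pop = init_population(cfg, bundle)
    for _ in range(60):
        before = pop.beliefs.copy()
        count_before = pop.interaction_count
        step(pop, cfg, bundle)
        changed = np.argwhere(pop.beliefs != before)
        assert len(changed) <= 2
        assert pop.interaction_count == count_before + 1
        assert np.all(pop.beliefs >= 0) and np.all(pop.beliefs <= 1)
        if len(changed) == 2:
            (r1, c1), (r2, c2) = changed
            assert r1 != r2  # two distinct participants
            # each participant updated its belief toward the partner's group
            assert c1 == int(pop.group_of(r2)) and c2 == int(pop.group_of(r1))


# ---------------------------------------------------------------------------
# checkpoint grid
# ---------------------------------------------------------------------------
def test_checkpoint_grid_covers_endpoints_log_spaced():
    grid = checkpoint_grid(10_000_000, 200)
    assert grid[0] == 0 and grid[-1] == 10_000_000
    assert np.all(np.diff(grid) > 0)
    assert 150 <= grid.size <= 200
    assert np.array_equal(checkpoint_grid(0, 200), [0])
    small = checkpoint_grid(10, 200)
    assert np.array_equal(small, np.arange(11))
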