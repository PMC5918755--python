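"""Agent state, population initialization, dyad sampling, action choice, the
belief-update step, and the full simulation driver.

The society is two groups — I (dominant) and J (subordinate) — whose members
hold directed beliefs ("willingness to collaborate") toward each group.  Each
period one dyad is drawn uniformly from all unordered pairs; both participants
simultaneously choose collaborate/defect from their pre-interaction belief
toward the partner's group, then each updates that same directed belief by
exponential smoothing toward the partner's observed action:

    rho_new = alpha * s_partner + (1 - alpha) * rho_old

with alpha either constant or, under conformity, equal to the agent's absolute
deviation from its group's distance-weighted norm (see :mod:`trustsim.conformity`).

``run_simulation`` executes this loop through a compiled kernel in fixed-size
chunks of pre-drawn random numbers; all randomness flows from a master seed
through named substreams (initialization of cross-group and in-group beliefs,
dyad sampling, per-group action draws, interventions), which makes cross-group
trajectories exactly reproducible and exactly independent of in-group priors.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Union

import numpy as np

from . import conformity as _conf
from . import _kernel
from .config import ConfigurationError, ModelConfig
from .metrics import (
    RunSummary,
    Trajectory,
    aggregate_replications,
    decline_recovery_ratio,
    unrecovered_trust,
)

__all__ = [
    "Group",
    "Action",
    "AgentState",
    "Population",
    "RngBundle",
    "init_population",
    "sample_dyad",
    "sample_dyads",
    "choose_action",
    "update_belief",
    "step",
    "run_simulation",
    "checkpoint_grid",
    "ReplicationResult",
    "SimulationResult",
    "CHUNK_SIZE",
]

#: Fixed RNG chunk size; part of the reproducibility contract (changing it
#: would re-order the random stream).
CHUNK_SIZE = 1 << 20
_REDRAW_CHUNK = 1 << 16


class Group(enum.IntEnum):
    """Group membership; also indexes the belief-target axis."""

    DOMINANT = 0      # I
    SUBORDINATE = 1   # J


class Action(enum.IntEnum):
    """Binary strategy in the coordination game."""

    DEFECT = 0
    COLLABORATE = 1


@dataclass(frozen=True)
class AgentState:
    """Snapshot of one agent: membership and directed beliefs."""

    group: Group
    belief_toward_I: float
    belief_toward_J: float


class Population:
    """All agents: an (n, 2) belief matrix plus group bookkeeping.

    Agents ``0 .. n_dominant-1`` form group I, the rest group J.  Column 0 of
    ``beliefs`` is the belief toward group I, column 1 toward group J.
    """

    __slots__ = ("beliefs", "n_dominant", "n_subordinate", "interaction_count", "frozen")

    def __init__(self, beliefs: np.ndarray, n_dominant: int, n_subordinate: int):
        beliefs = np.asarray(beliefs, dtype=np.float64)
        if beliefs.shape != (n_dominant + n_subordinate, 2):
            raise ValueError("beliefs must have shape (n_agents, 2)")
        if np.any(beliefs < 0) or np.any(beliefs > 1):
            raise ValueError("beliefs must lie in [0, 1]")
        self.beliefs = beliefs
        self.n_dominant = int(n_dominant)
        self.n_subordinate = int(n_subordinate)
        self.interaction_count = 0
        self.frozen = np.zeros(beliefs.shape[0], dtype=np.uint8)

    # -- group structure ----------------------------------------------------
    @property
    def n_agents(self) -> int:
        return self.n_dominant + self.n_subordinate

    @property
    def dominant_indices(self) -> np.ndarray:
        return np.arange(self.n_dominant)

    @property
    def subordinate_indices(self) -> np.ndarray:
        return np.arange(self.n_dominant, self.n_agents)

    def group_of(self, k: int) -> Group:
        return Group.DOMINANT if k < self.n_dominant else Group.SUBORDINATE

    def agent(self, k: int) -> AgentState:
        return AgentState(
            group=self.group_of(k),
            belief_toward_I=float(self.beliefs[k, 0]),
            belief_toward_J=float(self.beliefs[k, 1]),
        )

    def __len__(self) -> int:
        return self.n_agents

    def group_beliefs(self, observer: Group, target: Group) -> np.ndarray:
        """View of the observer group's beliefs toward the target group."""
        sl = slice(0, self.n_dominant) if observer == Group.DOMINANT else slice(self.n_dominant, None)
        return self.beliefs[sl, int(target)]

    def copy(self) -> "Population":
        out = Population(self.beliefs.copy(), self.n_dominant, self.n_subordinate)
        out.interaction_count = self.interaction_count
        out.frozen = self.frozen.copy()
        return out


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------
@dataclass
class RngBundle:
    """Named independent substreams spawned from one seed.

    Separate streams for cross-group vs in-group initialization, dyad
    sampling, each group's action draws, and interventions guarantee that
    cross-group dynamics are bit-identical under any change of in-group
    priors (the decoupling property).
    """

    init_cross: np.random.Generator
    init_ingroup: np.random.Generator
    dyad: np.random.Generator
    action_dominant: np.random.Generator
    action_subordinate: np.random.Generator
    intervention: np.random.Generator

    @classmethod
    def from_seedseq(cls, ss: np.random.SeedSequence) -> "RngBundle":
        return cls(*(np.random.default_rng(c) for c in ss.spawn(6)))

    @classmethod
    def from_seed(cls, seed: int) -> "RngBundle":
        return cls.from_seedseq(np.random.SeedSequence(seed))


def replication_bundles(seed: int, n_replications: int) -> list[RngBundle]:
    """Independent substream bundles, one per replication."""
    master = np.random.SeedSequence(seed)
    return [RngBundle.from_seedseq(child) for child in master.spawn(n_replications)]


def _as_bundle(rng) -> RngBundle:
    if isinstance(rng, RngBundle):
        return rng
    if isinstance(rng, np.random.SeedSequence):
        return RngBundle.from_seedseq(rng)
    if isinstance(rng, (int, np.integer)):
        return RngBundle.from_seed(int(rng))
    if isinstance(rng, np.random.Generator):
        # one generator serves every role (fine for interactive use; the
        # decoupling guarantee needs distinct streams)
        return RngBundle(rng, rng, rng, rng, rng, rng)
    raise TypeError(f"cannot interpret {type(rng).__name__} as an RNG source")


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------
def _draw_truncated_normal(gen: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Rejection-sample N(mean, sd) into the open interval (0, 1)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draws = gen.normal(mean, sd, size - filled)
        good = draws[(draws > 0.0) & (draws < 1.0)]
        out[filled:filled + good.size] = good
        filled += good.size
    return out


def _draw_prior(gen: np.random.Generator, family: str, params: tuple[float, float], size: int) -> np.ndarray:
    if family == "uniform":
        lo, hi = params
        return lo + (hi - lo) * gen.random(size)
    return _draw_truncated_normal(gen, params[0], params[1], size)


def init_population(config: ModelConfig, rng) -> Population:
    """Draw an initial population from the configured prior distributions.

    Dominant agents' beliefs toward J come from the prejudiced prior
    (default U(0, theta)); subordinate agents' beliefs toward I from U(0, 1);
    in-group beliefs from the (neutral, configurable) in-group prior.
    """
    config.validate()
    bundle = _as_bundle(rng)
    n_I, n_J = config.n_dominant, config.n_subordinate
    beliefs = np.empty((n_I + n_J, 2))
    # cross-group priors first, from their own stream
    beliefs[:n_I, 1] = _draw_prior(
        bundle.init_cross, config.prior_family, config.resolved_prior_dominant(), n_I
    )
    beliefs[n_I:, 0] = _draw_prior(
        bundle.init_cross, config.prior_family, config.resolved_prior_subordinate(), n_J
    )
    # in-group priors (always uniform), from a separate stream
    lo, hi = config.prior_ingroup
    beliefs[:n_I, 0] = lo + (hi - lo) * bundle.init_ingroup.random(n_I)
    beliefs[n_I:, 1] = lo + (hi - lo) * bundle.init_ingroup.random(n_J)
    return Population(beliefs, n_I, n_J)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------
def sample_dyad(population: Population, rng) -> tuple[int, int]:
    """Draw one interaction pair, uniform over all unordered pairs of agents."""
    n = population.n_agents
    if n < 2:
        raise ValueError("need at least two agents to form a dyad")
    gen = _as_bundle(rng).dyad if not isinstance(rng, np.random.Generator) else rng
    a = int(gen.integers(0, n))
    b = int(gen.integers(0, n - 1))
    if b >= a:
        b += 1
    return a, b


def sample_dyads(n_agents: int, gen: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized dyad sampling; the exact scheme the simulation driver uses."""
    if n_agents < 2:
        raise ValueError("need at least two agents to form a dyad")
    a = gen.integers(0, n_agents, size)
    b = gen.integers(0, n_agents - 1, size)
    b = b + (b >= a)
    return a, b


def choose_action(belief: float, rng, rule: str = "bernoulli") -> Action:
    """Choose collaborate/defect from a belief.

    Bernoulli rule: collaborate with probability exactly ``belief``.
    Threshold rule: collaborate iff ``belief >= 0.5``.
    """
    if not (0.0 <= belief <= 1.0):
        raise ValueError(f"belief must lie in [0, 1], got {belief}")
    if rule == "bernoulli":
        gen = rng if isinstance(rng, np.random.Generator) else _as_bundle(rng).action_dominant
        return Action.COLLABORATE if gen.random() < belief else Action.DEFECT
    if rule == "threshold":
        return Action.COLLABORATE if belief >= 0.5 else Action.DEFECT
    raise ValueError(f"unknown action rule {rule!r}")


def update_belief(belief: float, partner_action: Union[Action, int], alpha: float) -> float:
    """Exponential-smoothing belief update: alpha*s + (1-alpha)*belief."""
    s = float(int(partner_action))
    if s not in (0.0, 1.0):
        raise ValueError("partner_action must be 0 or 1")
    if not (0.0 <= belief <= 1.0):
        raise ValueError("belief must lie in [0, 1]")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * s + (1.0 - alpha) * belief


def _learning_rate_for(population: Population, agent: int, target: Group, config: ModelConfig) -> float:
    if config.alpha_mode == "constant":
        return float(config.alpha_constant)
    beliefs = population.group_beliefs(population.group_of(agent), target)
    norm = _conf.group_norm(beliefs, config.norm_variant)
    return abs(float(population.beliefs[agent, int(target)]) - norm)


def step(population: Population, config: ModelConfig, rng) -> Population:
    """Advance the population by one dyadic interaction, in place.

    Both participants act simultaneously from pre-interaction beliefs and then
    update the directed belief toward the partner's group; learning rates (in
    conformity mode) are evaluated on the pre-interaction belief configuration.
    Exactly two belief values change; ``interaction_count`` increments by one.
    """
    bundle = _as_bundle(rng)
    n = population.n_agents
    a = int(bundle.dyad.integers(0, n))
    b = int(bundle.dyad.integers(0, n - 1))
    if b >= a:
        b += 1
    # fixed per-period consumption: two uniforms from each group's stream
    u_dom = bundle.action_dominant.random(2)
    u_sub = bundle.action_subordinate.random(2)
    ga, gb = population.group_of(a), population.group_of(b)
    ba = float(population.beliefs[a, int(gb)])
    bb = float(population.beliefs[b, int(ga)])
    ua = u_dom[0] if ga == Group.DOMINANT else u_sub[0]
    ub = u_dom[1] if gb == Group.DOMINANT else u_sub[1]
    if config.action_rule == "bernoulli":
        sa = Action.COLLABORATE if ua < ba else Action.DEFECT
        sb = Action.COLLABORATE if ub < bb else Action.DEFECT
    else:
        sa = Action.COLLABORATE if ba >= 0.5 else Action.DEFECT
        sb = Action.COLLABORATE if bb >= 0.5 else Action.DEFECT
    al_a = _learning_rate_for(population, a, gb, config)
    al_b = _learning_rate_for(population, b, ga, config)
    new_a = al_a * float(sb) + (1.0 - al_a) * ba
    new_b = al_b * float(sa) + (1.0 - al_b) * bb
    if not population.frozen[a]:
        population.beliefs[a, int(gb)] = new_a
    if not population.frozen[b]:
        population.beliefs[b, int(ga)] = new_b
    population.interaction_count += 1
    return population


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------
def checkpoint_grid(horizon: int, checkpoints: int) -> np.ndarray:
    """~`checkpoints` log-spaced recording times in [0, horizon], incl. both ends."""
    if horizon == 0:
        return np.array([0], dtype=np.int64)
    pts = np.unique(np.round(np.geomspace(1.0, float(horizon), checkpoints - 1)).astype(np.int64))
    return np.concatenate(([np.int64(0)], pts))


@dataclass
class ReplicationResult:
    """One replication: its trajectory, summary, and final belief matrix."""

    trajectory: Trajectory
    summary: RunSummary
    final_beliefs: np.ndarray


@dataclass
class SimulationResult:
    """All replications of one configuration plus cross-replication aggregates."""

    config: ModelConfig
    replications: list[ReplicationResult]
    aggregate_trajectory: Trajectory
    aggregate_summary: dict

    @property
    def trajectories(self) -> list[Trajectory]:
        return [r.trajectory for r in self.replications]

    @property
    def summaries(self) -> list[RunSummary]:
        return [r.summary for r in self.replications]


_ALPHA_MODE_CODE = {"constant": 0, "conformity": 1}
_NORM_CODE = {"inverse_pairwise_distance": 0, "distance_from_mean": 1, "distance_from_median": 2}
_ACTION_CODE = {"bernoulli": 0, "threshold": 1}
_INTERV_CODE = {"none": 0, "instant_enlightenment": 1, "gradual_replacement": 2}
_BASELINE_CODE = {"frozen": 0, "redraw": 1}


def _gradual_event_count(horizon: int, interval: int, T_e: int) -> int:
    first = max(T_e, 1)
    first_mult = ((first + interval - 1) // interval) * interval
    if first_mult > horizon:
        return 0
    return (horizon - first_mult) // interval + 1


def _run_one_replication(config: ModelConfig, bundle: RngBundle, replication: int) -> ReplicationResult:
    n_I, n_J = config.n_dominant, config.n_subordinate
    n = n_I + n_J
    pop = init_population(config, bundle)
    bel = pop.beliefs

    times = checkpoint_grid(config.horizon, config.checkpoints)
    kernel_times = times[times > 0]
    traj_arr = np.empty((kernel_times.size, 4))

    s_II = np.sort(bel[:n_I, 0])
    s_IJ = np.sort(bel[:n_I, 1])
    s_JI = np.sort(bel[n_I:, 0])
    s_JJ = np.sort(bel[n_I:, 1])

    # t = 0 checkpoint, recorded with the kernel's own summation order
    row0 = np.empty(4)
    sum_IJ0, sum_JI0 = _kernel.record_checkpoint(
        bel, n_I,
        s_IJ, s_JI,
        _ALPHA_MODE_CODE[config.alpha_mode],
        float(config.alpha_constant) if config.alpha_constant is not None else 0.0,
        _NORM_CODE[config.norm_variant],
        row0,
    )
    sums = np.array([sum_IJ0, sum_JI0])

    conv_state = np.zeros(3)
    if abs(row0[0] - row0[1]) < config.convergence_threshold:
        conv_state[:] = (1.0, 0.0, 0.5 * (row0[0] + row0[1]))

    interv_code = _INTERV_CODE[config.intervention_mode]
    baseline_code = _BASELINE_CODE[config.baseline_mode]
    redraw = interv_code == 1 and baseline_code == 1
    if interv_code == 1 and not redraw:
        baselines = bundle.intervention.random(n_I)
    else:
        baselines = np.zeros(n_I)
    if interv_code == 2:
        n_events = _gradual_event_count(config.horizon, config.replacement_interval, config.enlightenment_time)
        repl_agents = bundle.intervention.integers(0, n_I, n_events)
        repl_values = bundle.intervention.random(n_events)
    else:
        repl_agents = np.zeros(0, dtype=np.int64)
        repl_values = np.zeros(0)

    ck_state = np.zeros(1, dtype=np.int64)
    enl_state = np.zeros(1, dtype=np.int64)
    repl_state = np.zeros(1, dtype=np.int64)
    redraw_state = np.zeros(1, dtype=np.int64)

    chunk = _REDRAW_CHUNK if redraw else CHUNK_SIZE
    t_done = 0
    while t_done < config.horizon:
        K = int(min(chunk, config.horizon - t_done))
        dyad_a = bundle.dyad.integers(0, n, K)
        dyad_b = bundle.dyad.integers(0, n - 1, K)
        dyad_b = dyad_b + (dyad_b >= dyad_a)
        u_dom = bundle.action_dominant.random((K, 2))
        u_sub = bundle.action_subordinate.random((K, 2))
        if redraw:
            first_active = max(config.enlightenment_time, 1)
            lo, hi = t_done + 1, t_done + K
            n_active = 0 if hi < first_active else hi - max(lo, first_active) + 1
            redraw_vals = bundle.intervention.random((n_active, n_I))
        else:
            redraw_vals = np.zeros((0, n_I))
        redraw_state[0] = 0
        status = _kernel.simulate_chunk(
            bel, n_I, s_II, s_IJ, s_JI, s_JJ, sums, pop.frozen,
            dyad_a, dyad_b, u_dom, u_sub,
            _ALPHA_MODE_CODE[config.alpha_mode],
            float(config.alpha_constant) if config.alpha_constant is not None else 0.0,
            _NORM_CODE[config.norm_variant],
            _ACTION_CODE[config.action_rule],
            t_done, kernel_times, traj_arr, ck_state,
            interv_code, config.enlightenment_time, baseline_code,
            baselines, redraw_vals, redraw_state,
            config.replacement_interval, repl_agents, repl_values, repl_state,
            1 if config.replacement_learns else 0,
            config.convergence_threshold, conv_state, enl_state,
            config.audit_interval,
        )
        if status != 0:
            raise _conf.NormStateError(
                "incremental norm state failed the from-scratch audit"
            )
        t_done += K
    pop.interaction_count = config.horizon

    full = np.vstack([row0, traj_arr]) if kernel_times.size else row0[None, :]
    trajectory = Trajectory(
        times=times,
        mean_dominant_toward_subordinate=full[:, 0],
        mean_subordinate_toward_dominant=full[:, 1],
        mean_alpha_dominant=full[:, 2],
        mean_alpha_subordinate=full[:, 3],
        replication=replication,
    )

    converged = conv_state[0] == 1.0
    intervened = config.intervention_mode != "none" and config.enlightenment_time <= config.horizon
    T_e = config.enlightenment_time
    unrec = ratio = None
    if intervened:
        unrec = unrecovered_trust(trajectory, T_e, config.horizon - T_e)
        if 0 < T_e < config.horizon:
            ratio = decline_recovery_ratio(trajectory, T_e)
    summary = RunSummary(
        convergence_time=int(conv_state[1]) if converged else None,
        convergence_value=float(conv_state[2]) if converged else None,
        terminal_mean_dominant_toward_subordinate=float(full[-1, 0]),
        terminal_mean_subordinate_toward_dominant=float(full[-1, 1]),
        unrecovered_trust=unrec,
        decline_recovery_ratio=ratio,
        replication=replication,
        seed=config.seed,
    )
    return ReplicationResult(trajectory=trajectory, summary=summary, final_beliefs=bel.copy())


def run_simulation(config: ModelConfig) -> SimulationResult:
    """Run every replication of ``config`` and aggregate the results.

    Each replication draws its own named RNG substreams from the master seed,
    so runs are reproducible bit-for-bit and replications are independent.
    """
    config.validate()
    bundles = replication_bundles(config.seed, config.n_replications)
    reps = [
        _run_one_replication(config, bundle, r)
        for r, bundle in enumerate(bundles)
    ]
    agg_traj, agg_summary = aggregate_replications(
        [r.summary for r in reps], [r.trajectory for r in reps]
    )
    return SimulationResult(
        config=config,
        replications=reps,
        aggregate_trajectory=agg_traj,
        aggregate_summary=agg_summary,
    )
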