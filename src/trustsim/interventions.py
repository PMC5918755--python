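"""Enlightenment interventions on the dominant group.

Two schedules are supported:

* ``instant_enlightenment`` — from period ``T_e`` onward, every dominant agent
  is (re)placed by a "perfectly enlightened" individual holding one baseline
  willingness value toward both groups.  In ``frozen`` mode the baselines are
  drawn once at the first application and re-imposed every period, so the
  enlightened generation never drifts (equivalently: enlightened dominant
  agents do not learn).  In ``redraw`` mode a fresh enlightened generation is
  drawn every period.
* ``gradual_replacement`` — one uniformly chosen dominant agent is replaced
  every ``replacement_interval`` periods by an enlightened individual with
  equal beliefs toward both groups; by default replacements learn normally
  afterwards (they are new society members, subject to the same conformity).

Subordinate agents are never touched, and group sizes are conserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import ConfigurationError, ModelConfig

__all__ = [
    "InterventionSchedule",
    "apply_instant_enlightenment",
    "apply_gradual_replacement",
    "apply_intervention",
]


@dataclass
class InterventionSchedule:
    """When and how the dominant group is enlightened.

    ``baselines`` holds the frozen enlightened values once drawn; it is
    run-state, populated at the first application.
    """

    mode: str = "none"
    enlightenment_time: int = 0
    replacement_interval: int = 100
    baseline_mode: str = "frozen"
    replacement_learns: bool = True
    baselines: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if self.mode not in ("none", "instant_enlightenment", "gradual_replacement"):
            raise ConfigurationError(f"unknown intervention mode {self.mode!r}")
        if self.enlightenment_time < 0:
            raise ConfigurationError("enlightenment_time must be >= 0")
        if self.replacement_interval < 1:
            raise ConfigurationError("replacement_interval must be >= 1")

    @classmethod
    def from_config(cls, config: ModelConfig) -> "InterventionSchedule":
        return cls(
            mode=config.intervention_mode,
            enlightenment_time=config.enlightenment_time,
            replacement_interval=config.replacement_interval,
            baseline_mode=config.baseline_mode,
            replacement_learns=config.replacement_learns,
        )


def apply_instant_enlightenment(population, t: int, schedule: InterventionSchedule, rng) -> None:
    """Reset every dominant agent to its enlightened baseline, in place.

    After application each dominant agent holds exactly equal beliefs toward
    both groups; re-applying with unchanged dominant beliefs is a no-op.
    """
    if schedule.mode != "instant_enlightenment":
        raise ValueError("schedule mode is not instant_enlightenment")
    if t < schedule.enlightenment_time:
        raise ValueError(f"t={t} is before the enlightenment time {schedule.enlightenment_time}")
    n_I = population.n_dominant
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if schedule.baseline_mode == "redraw" or schedule.baselines is None:
        schedule.baselines = gen.random(n_I)
    population.beliefs[:n_I, 0] = schedule.baselines
    population.beliefs[:n_I, 1] = schedule.baselines


def apply_gradual_replacement(population, t: int, schedule: InterventionSchedule, rng) -> int:
    """Replace one uniformly chosen dominant agent with an enlightened one.

    Returns the replaced agent's index.  The new agent's beliefs toward both
    groups are drawn equal from U(0, 1); unless ``replacement_learns`` it is
    frozen thereafter.
    """
    if schedule.mode != "gradual_replacement":
        raise ValueError("schedule mode is not gradual_replacement")
    if t < schedule.enlightenment_time or t % schedule.replacement_interval != 0:
        raise ValueError(
            f"t={t} is not a scheduled replacement period "
            f"(interval {schedule.replacement_interval}, from {schedule.enlightenment_time})"
        )
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    agent = int(gen.integers(0, population.n_dominant))
    value = float(gen.random())
    population.beliefs[agent, 0] = value
    population.beliefs[agent, 1] = value
    population.frozen[agent] = 0 if schedule.replacement_learns else 1
    return agent


def apply_intervention(population, t: int, schedule: InterventionSchedule, rng) -> None:
    """Apply whatever the schedule prescribes at interaction count ``t``.

    Checked after the learning step of each period; a ``none`` schedule (or a
    period that matches no trigger) leaves the population untouched.
    """
    if schedule.mode == "none":
        return
    if schedule.mode == "instant_enlightenment":
        if t >= schedule.enlightenment_time:
            apply_instant_enlightenment(population, t, schedule, rng)
    else:
        if (
            t >= schedule.enlightenment_time
            and t >= 1
            and t % schedule.replacement_interval == 0
        ):
            apply_gradual_replacement(population, t, schedule, rng)
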