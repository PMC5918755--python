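"""Trajectory records and summary statistics.

Statistics mirror the quantities the simulator is judged on: group-mean
willingness to collaborate, time to belief convergence, unrecovered trust
after an enlightenment intervention, the decline/recovery rate ratio, a
model-time-to-years conversion, and multi-replication aggregation.

Except for the exact first-passage convergence time (tracked inside the
simulation kernel), every statistic here is a pure function of a recorded
trajectory: recomputing from a saved CSV reproduces it exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "RunSummary",
    "mean_willingness",
    "convergence_time",
    "unrecovered_trust",
    "decline_recovery_ratio",
    "years_equivalent",
    "aggregate_replications",
    "summary_from_trajectory",
    "write_trajectories",
    "read_trajectories",
    "write_summaries",
    "read_summaries",
    "TRAJECTORY_COLUMNS",
    "SUMMARY_COLUMNS",
]

TRAJECTORY_COLUMNS = [
    "replication",
    "checkpoint_time",
    "mean_dominant_toward_subordinate",
    "mean_subordinate_toward_dominant",
    "mean_alpha_dominant",
    "mean_alpha_subordinate",
]

SUMMARY_COLUMNS = [
    "replication",
    "seed",
    "convergence_time",
    "convergence_value",
    "terminal_mean_dominant_toward_subordinate",
    "terminal_mean_subordinate_toward_dominant",
    "unrecovered_trust",
    "decline_recovery_ratio",
]


@dataclass
class Trajectory:
    """Group-level state at log-spaced checkpoint times.

    ``times`` is strictly increasing and includes 0 and the horizon; the mean
    willingness series are the observer group's average belief toward the
    other group; the mean-alpha series are group averages of the (constant or
    conformity) learning rate.
    """

    times: np.ndarray
    mean_dominant_toward_subordinate: np.ndarray
    mean_subordinate_toward_dominant: np.ndarray
    mean_alpha_dominant: np.ndarray
    mean_alpha_subordinate: np.ndarray
    replication: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.int64)
        for name in (
            "mean_dominant_toward_subordinate",
            "mean_subordinate_toward_dominant",
            "mean_alpha_dominant",
            "mean_alpha_subordinate",
        ):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must align with times")
        if self.times.size == 0:
            raise ValueError("trajectory must contain at least one checkpoint")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("checkpoint times must be strictly increasing")
        for name in ("mean_dominant_toward_subordinate", "mean_subordinate_toward_dominant"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def gap(self) -> np.ndarray:
        """Dominant-minus-subordinate gap in mean out-group willingness."""
        return self.mean_dominant_toward_subordinate - self.mean_subordinate_toward_dominant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replication": self.replication,
                "checkpoint_time": self.times,
                "mean_dominant_toward_subordinate": self.mean_dominant_toward_subordinate,
                "mean_subordinate_toward_dominant": self.mean_subordinate_toward_dominant,
                "mean_alpha_dominant": self.mean_alpha_dominant,
                "mean_alpha_subordinate": self.mean_alpha_subordinate,
            }
        )


@dataclass
class RunSummary:
    """Per-replication summary statistics.

    ``convergence_time`` is the exact first interaction at which the absolute
    group-mean gap fell below the configured threshold (None if it never did);
    ``convergence_value`` is the common mean willingness at that moment.
    ``unrecovered_trust`` and ``decline_recovery_ratio`` are defined only when
    an intervention ran (None otherwise); the ratio is NaN when the
    post-enlightenment accrual is zero or negative.
    """

    convergence_time: Optional[int]
    convergence_value: Optional[float]
    terminal_mean_dominant_toward_subordinate: float
    terminal_mean_subordinate_toward_dominant: float
    unrecovered_trust: Optional[float]
    decline_recovery_ratio: Optional[float]
    replication: int = 0
    seed: int = 0


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------
def mean_willingness(population, observer_group, target_group) -> float:
    """Arithmetic mean of the observer group's beliefs toward the target group."""
    beliefs = population.group_beliefs(observer_group, target_group)
    if beliefs.size == 0:
        raise ValueError("observer group is empty")
    return float(np.mean(beliefs))


def convergence_time(trajectory: Trajectory, threshold: float) -> Optional[int]:
    """First checkpoint time with |mean gap| < threshold; None if never.

    Note: the checkpoint grid is coarse, so this underestimates how often the
    gap dips below a small threshold between checkpoints; run summaries carry
    the exact first-passage time tracked inside the simulation loop.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    hits = np.nonzero(np.abs(trajectory.gap) < threshold)[0]
    if hits.size == 0:
        return None
    return int(trajectory.times[hits[0]])


def unrecovered_trust(trajectory: Trajectory, T_e: int, delta: int) -> float:
    """Dominant-minus-subordinate willingness gap ``delta`` periods after
    enlightenment, read at the checkpoint nearest ``T_e + delta``."""
    target = T_e + delta
    if trajectory.times[-1] < target:
        raise ValueError(
            f"trajectory ends at t={trajectory.times[-1]}, before T_e + delta = {target}"
        )
    k = int(np.argmin(np.abs(trajectory.times - target)))
    return float(trajectory.gap[k])


def decline_recovery_ratio(trajectory: Trajectory, T_e: int) -> float:
    """Ratio of the subordinate group's mean per-period decline rate before
    enlightenment to its mean recovery rate afterwards.

    Rates are endpoint differences over elapsed periods:
    ``[(w(0) - w(T_e)) / T_e] / [(w(end) - w(T_e)) / (end - T_e)]`` with w the
    subordinate group's mean willingness toward the dominant group, evaluated
    at the checkpoint nearest T_e.  NaN when the post-enlightenment accrual is
    zero or negative.
    """
    times = trajectory.times
    if times[-1] <= T_e:
        raise ValueError("trajectory does not extend beyond the enlightenment time")
    k = int(np.argmin(np.abs(times - T_e)))
    t_e = float(times[k])
    if t_e <= 0 or t_e >= times[-1]:
        return math.nan
    w = trajectory.mean_subordinate_toward_dominant
    decline_rate = (w[0] - w[k]) / t_e
    recovery = w[-1] - w[k]
    if recovery <= 0:
        return math.nan
    recovery_rate = recovery / (times[-1] - t_e)
    return float(decline_rate / recovery_rate)


def years_equivalent(n_interactions: int, interactions_per_day: float) -> float:
    """Convert an interaction count to years at a given population-wide daily
    interaction frequency."""
    if interactions_per_day <= 0:
        raise ValueError("interactions_per_day must be > 0")
    return n_interactions / (interactions_per_day * 365.0)


def summary_from_trajectory(
    trajectory: Trajectory,
    threshold: float = 1e-4,
    T_e: Optional[int] = None,
    seed: int = 0,
) -> RunSummary:
    """Recompute every trajectory-derivable summary statistic from a trajectory."""
    t_conv = convergence_time(trajectory, threshold)
    value = None
    if t_conv is not None:
        k = int(np.nonzero(trajectory.times == t_conv)[0][0])
        value = float(
            0.5
            * (
                trajectory.mean_dominant_toward_subordinate[k]
                + trajectory.mean_subordinate_toward_dominant[k]
            )
        )
    unrec = ratio = None
    if T_e is not None:
        horizon = int(trajectory.times[-1])
        unrec = unrecovered_trust(trajectory, T_e, horizon - T_e)
        if 0 < T_e < horizon:
            ratio = decline_recovery_ratio(trajectory, T_e)
    return RunSummary(
        convergence_time=t_conv,
        convergence_value=value,
        terminal_mean_dominant_toward_subordinate=float(
            trajectory.mean_dominant_toward_subordinate[-1]
        ),
        terminal_mean_subordinate_toward_dominant=float(
            trajectory.mean_subordinate_toward_dominant[-1]
        ),
        unrecovered_trust=unrec,
        decline_recovery_ratio=ratio,
        replication=trajectory.replication,
        seed=seed,
    )


_AGG_FIELDS = [
    "convergence_time",
    "convergence_value",
    "terminal_mean_dominant_toward_subordinate",
    "terminal_mean_subordinate_toward_dominant",
    "unrecovered_trust",
    "decline_recovery_ratio",
]


def aggregate_replications(
    summaries: Sequence[RunSummary], trajectories: Sequence[Trajectory]
) -> tuple[Trajectory, dict]:
    """Pointwise-mean trajectory plus mean/sd of each summary statistic.

    Statistics that are None (not applicable) or NaN (undefined) in a
    replication are excluded from that statistic's aggregate; the aggregate
    dict records how many replications contributed to each.
    """
    if len(summaries) == 0 or len(summaries) != len(trajectories):
        raise ValueError("need matching, non-empty summaries and trajectories")
    base = trajectories[0].times
    for tr in trajectories[1:]:
        if not np.array_equal(tr.times, base):
            raise ValueError("all trajectories must share one checkpoint grid")
    mean_traj = Trajectory(
        times=base.copy(),
        mean_dominant_toward_subordinate=np.mean(
            [tr.mean_dominant_toward_subordinate for tr in trajectories], axis=0
        ),
        mean_subordinate_toward_dominant=np.mean(
            [tr.mean_subordinate_toward_dominant for tr in trajectories], axis=0
        ),
        mean_alpha_dominant=np.mean([tr.mean_alpha_dominant for tr in trajectories], axis=0),
        mean_alpha_subordinate=np.mean(
            [tr.mean_alpha_subordinate for tr in trajectories], axis=0
        ),
        replication=-1,
    )
    agg: dict = {"n_replications": len(summaries)}
    for name in _AGG_FIELDS:
        vals = [
            float(getattr(s, name))
            for s in summaries
            if getattr(s, name) is not None and not math.isnan(float(getattr(s, name)))
        ]
        agg[name] = {
            "mean": float(np.mean(vals)) if vals else None,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else (0.0 if vals else None),
            "n": len(vals),
        }
    return mean_traj, agg


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
def _config_header(config) -> str:
    if config is None:
        return ""
    lines = [f"# {key} = {value}" for key, value in sorted(config.to_dict().items())]
    return "\n".join(lines) + "\n"


def write_trajectories(path, trajectories: Sequence[Trajectory], config=None) -> None:
    """Write trajectories as CSV, with the resolved config embedded as header
    comments for provenance."""
    frame = pd.concat([tr.to_frame() for tr in trajectories], ignore_index=True)
    with open(path, "w", newline="") as fh:
        fh.write(_config_header(config))
        frame.to_csv(fh, index=False, columns=TRAJECTORY_COLUMNS)


def read_trajectories(path) -> list[Trajectory]:
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = []
    for rep, grp in frame.groupby("replication", sort=True):
        out.append(
            Trajectory(
                times=grp["checkpoint_time"].to_numpy(),
                mean_dominant_toward_subordinate=grp[
                    "mean_dominant_toward_subordinate"
                ].to_numpy(),
                mean_subordinate_toward_dominant=grp[
                    "mean_subordinate_toward_dominant"
                ].to_numpy(),
                mean_alpha_dominant=grp["mean_alpha_dominant"].to_numpy(),
                mean_alpha_subordinate=grp["mean_alpha_subordinate"].to_numpy(),
                replication=int(rep),
            )
        )
    return out


def _summary_row(s: RunSummary, replication) -> dict:
    return {
        "replication": replication,
        "seed": s.seed,
        "convergence_time": s.convergence_time,
        "convergence_value": s.convergence_value,
        "terminal_mean_dominant_toward_subordinate": s.terminal_mean_dominant_toward_subordinate,
        "terminal_mean_subordinate_toward_dominant": s.terminal_mean_subordinate_toward_dominant,
        "unrecovered_trust": s.unrecovered_trust,
        "decline_recovery_ratio": s.decline_recovery_ratio,
    }


def write_summaries(path, summaries: Sequence[RunSummary], aggregate: Optional[dict] = None, config=None) -> None:
    """Write one row per replication plus an aggregate (mean-over-reps) row."""
    rows = [_summary_row(s, s.replication) for s in summaries]
    if aggregate is not None:
        agg_row = {"replication": "aggregate", "seed": summaries[0].seed if summaries else ""}
        for name in _AGG_FIELDS:
            agg_row[name] = aggregate[name]["mean"]
        rows.append(agg_row)
    frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    with open(path, "w", newline="") as fh:
        fh.write(_config_header(config))
        frame.to_csv(fh, index=False)


def read_summaries(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
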