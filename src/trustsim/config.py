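"""Run configuration: every knob of a simulation in one flat, serializable record.

The configuration is deliberately flat so that it round-trips losslessly through
a plain key-value YAML file and can be embedded verbatim in output CSV headers.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = [
    "ModelConfig",
    "ConfigurationError",
    "ALPHA_MODES",
    "NORM_VARIANTS",
    "INTERVENTION_MODES",
    "PRIOR_FAMILIES",
    "ACTION_RULES",
]

ALPHA_MODES = ("constant", "conformity")
NORM_VARIANTS = ("inverse_pairwise_distance", "distance_from_mean", "distance_from_median")
INTERVENTION_MODES = ("none", "instant_enlightenment", "gradual_replacement")
PRIOR_FAMILIES = ("uniform", "truncated_normal")
ACTION_RULES = ("bernoulli", "threshold")
BASELINE_MODES = ("frozen", "redraw")


class ConfigurationError(ValueError):
    """Raised when a configuration violates a model constraint."""


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterization of one simulation experiment.

    Parameters
    ----------
    n_dominant, n_subordinate
        Group sizes |I| (dominant) and |J| (subordinate).
    theta
        Upper bound of the dominant group's prejudiced uniform prior toward the
        subordinate group, U(0, theta).  Ignored when ``prior_dominant`` is set
        explicitly.
    prior_family
        ``uniform`` (params are (low, high)) or ``truncated_normal`` (params are
        (mean, sd), rejection-sampled into the open interval (0, 1)).
    prior_dominant, prior_subordinate
        Out-group prior parameters for each group.  ``None`` selects the
        defaults: dominant U(0, theta), subordinate U(0, 1) (uniform family;
        the truncated-normal family requires explicit parameters).
    prior_ingroup
        Uniform (low, high) bounds for every agent's in-group prior.  In-group
        beliefs are dynamically decoupled from cross-group outcomes, so this
        choice is cosmetic for the headline statistics.
    alpha_mode
        ``constant`` (fixed learning rate ``alpha_constant``) or ``conformity``
        (per-agent rate equal to the absolute deviation from the group norm).
    norm_variant
        How the group norm is computed in conformity mode.
    action_rule
        ``bernoulli`` (collaborate with probability equal to the belief) or
        ``threshold`` (collaborate iff belief >= 0.5).
    intervention_mode, enlightenment_time, replacement_interval,
    baseline_mode, replacement_learns
        Enlightenment schedule.  ``instant_enlightenment`` replaces every
        dominant agent from ``enlightenment_time`` onward with an enlightened
        individual holding equal beliefs toward both groups; ``frozen`` keeps
        one per-agent baseline value, ``redraw`` draws fresh enlightened agents
        every period.  ``gradual_replacement`` replaces one random dominant
        agent every ``replacement_interval`` interactions.
    horizon
        Number of dyadic interactions to simulate (one period == one
        interaction).
    n_replications
        Independent replications; each gets its own RNG substreams spawned
        from ``seed``.
    checkpoints
        Number of log-spaced recording times (t=0 and t=horizon always
        included).
    convergence_threshold
        Gap threshold for the exact first-passage convergence time.
    audit_interval
        If > 0, every ``audit_interval`` interactions the kernel re-derives its
        incremental norm state from scratch and verifies consistency.
    """

    n_dominant: int = 80
    n_subordinate: int = 20
    theta: float = 0.5
    prior_family: str = "uniform"
    prior_dominant: Optional[tuple[float, float]] = None
    prior_subordinate: Optional[tuple[float, float]] = None
    prior_ingroup: tuple[float, float] = (0.0, 1.0)
    alpha_mode: str = "conformity"
    alpha_constant: Optional[float] = None
    norm_variant: str = "inverse_pairwise_distance"
    action_rule: str = "bernoulli"
    intervention_mode: str = "none"
    enlightenment_time: int = 0
    replacement_interval: int = 100
    baseline_mode: str = "frozen"
    replacement_learns: bool = True
    horizon: int = 10_000_000
    n_replications: int = 10
    checkpoints: int = 200
    convergence_threshold: float = 1e-4
    audit_interval: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_dominant < 1 or self.n_subordinate < 1:
            raise ConfigurationError("group sizes must be positive")
        if self.n_dominant + self.n_subordinate < 2:
            raise ConfigurationError("population must contain at least two agents")
        if not (0.0 < self.theta <= 1.0):
            raise ConfigurationError(f"theta must lie in (0, 1], got {self.theta}")
        if self.prior_family not in PRIOR_FAMILIES:
            raise ConfigurationError(f"unknown prior_family {self.prior_family!r}")
        if self.alpha_mode not in ALPHA_MODES:
            raise ConfigurationError(f"unknown alpha_mode {self.alpha_mode!r}")
        if self.alpha_mode == "constant":
            if self.alpha_constant is None:
                raise ConfigurationError("alpha_constant is required when alpha_mode='constant'")
            if not (0.0 <= self.alpha_constant <= 1.0):
                raise ConfigurationError("alpha_constant must lie in [0, 1]")
        elif self.alpha_constant is not None:
            raise ConfigurationError("alpha_constant is only meaningful when alpha_mode='constant'")
        if self.norm_variant not in NORM_VARIANTS:
            raise ConfigurationError(f"unknown norm_variant {self.norm_variant!r}")
        if self.action_rule not in ACTION_RULES:
            raise ConfigurationError(f"unknown action_rule {self.action_rule!r}")
        if self.intervention_mode not in INTERVENTION_MODES:
            raise ConfigurationError(f"unknown intervention_mode {self.intervention_mode!r}")
        if self.baseline_mode not in BASELINE_MODES:
            raise ConfigurationError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.enlightenment_time < 0:
            raise ConfigurationError("enlightenment_time must be >= 0")
        if self.replacement_interval < 1:
            raise ConfigurationError("replacement_interval must be >= 1")
        if self.horizon < 0:
            raise ConfigurationError("horizon must be >= 0")
        if self.n_replications < 1:
            raise ConfigurationError("n_replications must be >= 1")
        if self.checkpoints < 2:
            raise ConfigurationError("checkpoints must be >= 2")
        if self.convergence_threshold <= 0:
            raise ConfigurationError("convergence_threshold must be > 0")
        if self.audit_interval < 0:
            raise ConfigurationError("audit_interval must be >= 0")
        for name, params in (
            ("prior_dominant", self.resolved_prior_dominant()),
            ("prior_subordinate", self.resolved_prior_subordinate()),
        ):
            self._check_prior(name, params, self.prior_family)
        self._check_prior("prior_ingroup", self.prior_ingroup, "uniform")

    @staticmethod
    def _check_prior(name: str, params: tuple[float, float], family: str) -> None:
        if len(params) != 2:
            raise ConfigurationError(f"{name} must have exactly two parameters")
        a, b = params
        if family == "uniform":
            if not (0.0 <= a < b <= 1.0):
                raise ConfigurationError(
                    f"{name}: uniform bounds must satisfy 0 <= low < high <= 1, got ({a}, {b})"
                )
        else:  # truncated_normal: (mean, sd)
            if b <= 0:
                raise ConfigurationError(f"{name}: truncated-normal sd must be > 0, got {b}")

    # -- derived priors -----------------------------------------------------
    def resolved_prior_dominant(self) -> tuple[float, float]:
        """Out-group prior parameters for dominant agents (toward J)."""
        if self.prior_dominant is not None:
            return tuple(self.prior_dominant)  # type: ignore[return-value]
        if self.prior_family == "truncated_normal":
            raise ConfigurationError("truncated_normal family requires explicit prior_dominant")
        return (0.0, self.theta)

    def resolved_prior_subordinate(self) -> tuple[float, float]:
        """Out-group prior parameters for subordinate agents (toward I)."""
        if self.prior_subordinate is not None:
            return tuple(self.prior_subordinate)  # type: ignore[return-value]
        if self.prior_family == "truncated_normal":
            raise ConfigurationError("truncated_normal family requires explicit prior_subordinate")
        return (0.0, 1.0)

    @property
    def n_agents(self) -> int:
        return self.n_dominant + self.n_subordinate

    def replace(self, **changes) -> "ModelConfig":
        """Return a validated copy with ``changes`` applied."""
        return dataclasses.replace(self, **changes)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("prior_dominant", "prior_subordinate", "prior_ingroup"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("prior_dominant", "prior_subordinate", "prior_ingroup"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(float(x) for x in kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=None)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelConfig":
        """Load from a YAML path or string."""
        import os

        if isinstance(source, str) and not os.path.exists(source) and "\n" not in source:
            raise ConfigurationError(f"config file not found: {source}")
        if isinstance(source, str) and os.path.exists(source):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(data)
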