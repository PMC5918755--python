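"""Scenario presets: the named experiment configurations the simulator ships.

Each preset is a complete :class:`~trustsim.config.ModelConfig`.  The base
society has 80 dominant and 20 subordinate members, prejudiced dominant priors
U(0, 0.5) against neutral subordinate priors U(0, 1), and a 10^7-interaction
horizon; variants change the stigma magnitude, group sizes and scale, prior
family and trust climate, and the enlightenment schedule.  Default replication
counts are desk-scale (10); raise ``n_replications`` for smoother aggregates.
"""
from __future__ import annotations

from dataclasses import dataclass

from .config import ModelConfig

__all__ = ["ScenarioPreset", "PRESETS", "load_preset", "list_presets"]


@dataclass(frozen=True)
class ScenarioPreset:
    """A named configuration plus a one-line description of what it probes."""

    name: str
    config: ModelConfig
    note: str


_BASE = ModelConfig()  # 80/20, theta=0.5, conformity, horizon 1e7


def _preset(name: str, note: str, **overrides) -> ScenarioPreset:
    return ScenarioPreset(name=name, config=_BASE.replace(**overrides), note=note)


_PRESET_LIST = [
    _preset(
        "base_constant_alpha",
        "self-fulfilling prophecy baseline: constant learning rate 0.25, 80/20, theta=0.5",
        alpha_mode="constant",
        alpha_constant=0.25,
    ),
    _preset(
        "base_conformity",
        "persistence of stigma: conformity-modulated learning, 80/20, theta=0.5",
    ),
    _preset(
        "stigma_magnitude_01",
        "strong initial prejudice: dominant out-group prior U(0, 0.1)",
        theta=0.1,
    ),
    _preset(
        "stigma_magnitude_09",
        "weak initial prejudice: dominant out-group prior U(0, 0.9)",
        theta=0.9,
    ),
    _preset(
        "stigma_magnitude_099",
        "near-vanishing initial prejudice: dominant out-group prior U(0, 0.99)",
        theta=0.99,
    ),
    _preset(
        "large_population",
        "base conformity case scaled to 1000 agents (800/200)",
        n_dominant=800,
        n_subordinate=200,
    ),
    _preset(
        "enlightenment",
        "instant enlightenment of the dominant group from t = 10^4 onward",
        intervention_mode="instant_enlightenment",
        enlightenment_time=10_000,
        horizon=10_000 + 10_000_000,
    ),
    _preset(
        "delayed_enlightenment_1e3",
        "enlightenment delayed to t = 10^3 (unrecovered-trust sweep point)",
        intervention_mode="instant_enlightenment",
        enlightenment_time=1_000,
        horizon=1_000 + 10_000_000,
    ),
    _preset(
        "delayed_enlightenment_1e4",
        "enlightenment delayed to t = 10^4 (unrecovered-trust sweep point)",
        intervention_mode="instant_enlightenment",
        enlightenment_time=10_000,
        horizon=10_000 + 10_000_000,
    ),
    _preset(
        "delayed_enlightenment_1e5",
        "enlightenment delayed to t = 10^5 (unrecovered-trust sweep point)",
        intervention_mode="instant_enlightenment",
        enlightenment_time=100_000,
        horizon=100_000 + 10_000_000,
    ),
    _preset(
        "gradual_replacement",
        "generational change: one random dominant member replaced every 100 periods",
        intervention_mode="gradual_replacement",
        replacement_interval=100,
        enlightenment_time=0,
    ),
    _preset(
        "inverted_sizes",
        "subordinate majority: |I| = 20 dominant vs |J| = 80 subordinate",
        n_dominant=20,
        n_subordinate=80,
    ),
    _preset(
        "inverted_sizes_large",
        "subordinate majority at scale: 200 dominant vs 800 subordinate",
        n_dominant=200,
        n_subordinate=800,
    ),
    _preset(
        "collaborative",
        "high-trust climate: priors U(0.5, 1) subordinate and U(0.5, 0.75) dominant",
        prior_dominant=(0.5, 0.75),
        prior_subordinate=(0.5, 1.0),
    ),
    _preset(
        "collaborative_large",
        "high-trust climate at scale (800/200)",
        n_dominant=800,
        n_subordinate=200,
        prior_dominant=(0.5, 0.75),
        prior_subordinate=(0.5, 1.0),
    ),
    _preset(
        "distrustful",
        "low-trust climate: priors U(0, 0.5) subordinate and U(0, 0.25) dominant",
        prior_dominant=(0.0, 0.25),
        prior_subordinate=(0.0, 0.5),
    ),
    _preset(
        "distrustful_large",
        "low-trust climate at scale (800/200)",
        n_dominant=800,
        n_subordinate=200,
        prior_dominant=(0.0, 0.25),
        prior_subordinate=(0.0, 0.5),
    ),
    _preset(
        "truncated_normal_sd01",
        "truncated-normal priors: N(0.25, 0.1) dominant, N(0.5, 0.1) subordinate, on (0, 1)",
        prior_family="truncated_normal",
        prior_dominant=(0.25, 0.1),
        prior_subordinate=(0.5, 0.1),
    ),
    _preset(
        "truncated_normal_sd02",
        "truncated-normal priors: N(0.25, 0.2) dominant, N(0.5, 0.2) subordinate, on (0, 1)",
        prior_family="truncated_normal",
        prior_dominant=(0.25, 0.2),
        prior_subordinate=(0.5, 0.2),
    ),
    _preset(
        "truncated_normal_sd03",
        "truncated-normal priors: N(0.25, 0.3) dominant, N(0.5, 0.3) subordinate, on (0, 1)",
        prior_family="truncated_normal",
        prior_dominant=(0.25, 0.3),
        prior_subordinate=(0.5, 0.3),
    ),
    _preset(
        "truncated_normal_sd04",
        "truncated-normal priors: N(0.25, 0.4) dominant, N(0.5, 0.4) subordinate, on (0, 1)",
        prior_family="truncated_normal",
        prior_dominant=(0.25, 0.4),
        prior_subordinate=(0.5, 0.4),
    ),
    _preset(
        "truncated_normal_large",
        "truncated-normal priors (sd 0.2) at scale (800/200)",
        n_dominant=800,
        n_subordinate=200,
        prior_family="truncated_normal",
        prior_dominant=(0.25, 0.2),
        prior_subordinate=(0.5, 0.2),
    ),
    _preset(
        "large_enlightenment",
        "instant enlightenment at t = 10^5 in the 1000-agent society "
        "(same accumulated interactions per individual as the small-society case)",
        n_dominant=800,
        n_subordinate=200,
        intervention_mode="instant_enlightenment",
        enlightenment_time=100_000,
        horizon=100_000 + 10_000_000,
    ),
]

PRESETS: dict[str, ScenarioPreset] = {p.name: p for p in _PRESET_LIST}


def load_preset(name: str, **overrides) -> ModelConfig:
    """Return the named preset's configuration, optionally with overrides."""
    if name not in PRESETS:
        known = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; available presets: {known}")
    config = PRESETS[name].config
    return config.replace(**overrides) if overrides else config


def list_presets() -> list[ScenarioPreset]:
    """All registered presets, in registry order."""
    return list(_PRESET_LIST)
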