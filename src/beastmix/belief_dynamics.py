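"""Agent-based belief dynamics in stylized social environments.

One-shot simulations of 1000 agents who each observe ten peer estimates
concentrated at a Low and a High grid position and adjust their first
estimate once, using strategy parameters drawn from the population-level
distribution of the cognitive model.  Five scenario compositions probe
how confirmation-based weighting shapes belief change:

* ``majority_agree`` / ``half_agree`` / ``minority_agree`` — the agent
  starts at Low and is confirmed by 8, 5 or 2 of the 10 peers;
* ``strong_conf_split`` / ``weak_conf_split`` — peers split 5/5, the
  agent starts between the clusters but closer to Low, and only agents
  in the upper (resp. lower) half of the confirmation-weighting
  distribution are simulated.

The filter-bubble reading: confirmatory peers both trigger the keep
heuristic and dominate the compromise weighting, so even heavily
outnumbered agents barely move — and strongly confirmation-weighting
agents between two camps drift towards the nearer, more extreme one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .task_design import DEFAULT_SLIDER
from .cognitive_model import (
    GroupParams,
    IndividualParams,
    ModelSpec,
    default_group_params,
    simulate_adjustment,
)

__all__ = [
    "SCENARIO_NAMES",
    "ScenarioSpec",
    "build_scenario",
    "run_scenario",
    "ScenarioResult",
    "summarize_adjustments",
    "AdjustmentSummary",
]

SCENARIO_NAMES = (
    "majority_agree",
    "half_agree",
    "minority_agree",
    "strong_conf_split",
    "weak_conf_split",
)

#: Default grid geometry: peer clusters at Low/High on the 1-200 slider;
#: in split scenarios the agent sits between the clusters, closer to Low.
_DEFAULT_GEOMETRY = dict(low_value=50, high_value=150, split_agent_E1=75)

_COMPOSITIONS = {
    "majority_agree": dict(n_low=8, n_high=2, agent_at="low", agent_subset="all"),
    "half_agree": dict(n_low=5, n_high=5, agent_at="low", agent_subset="all"),
    "minority_agree": dict(n_low=2, n_high=8, agent_at="low", agent_subset="all"),
    "strong_conf_split": dict(n_low=5, n_high=5, agent_at="split",
                              agent_subset="upper_conf"),
    "weak_conf_split": dict(n_low=5, n_high=5, agent_at="split",
                            agent_subset="lower_conf"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Composition of one simulated social environment (10 peers total)."""

    name: str
    low_value: int
    high_value: int
    n_low: int
    n_high: int
    agent_E1: int
    agent_subset: str  # all | upper_conf | lower_conf

    def __post_init__(self) -> None:
        if self.n_low + self.n_high != 10:
            raise ValueError("scenarios present exactly 10 peers")
        if self.agent_subset not in ("all", "upper_conf", "lower_conf"):
            raise ValueError(f"unknown agent subset {self.agent_subset!r}")

    @property
    def peers(self) -> tuple[int, ...]:
        return (self.low_value,) * self.n_low + (self.high_value,) * self.n_high


def build_scenario(name: str, geometry: Optional[dict] = None) -> ScenarioSpec:
    """Return one of the five canonical scenario compositions."""
    if name not in _COMPOSITIONS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    geo = dict(_DEFAULT_GEOMETRY)
    if geometry:
        geo.update(geometry)
    comp = _COMPOSITIONS[name]
    agent_E1 = geo["low_value"] if comp["agent_at"] == "low" else geo["split_agent_E1"]
    return ScenarioSpec(
        name=name, low_value=geo["low_value"], high_value=geo["high_value"],
        n_low=comp["n_low"], n_high=comp["n_high"], agent_E1=agent_E1,
        agent_subset=comp["agent_subset"],
    )


@dataclass(frozen=True)
class AdjustmentSummary:
    """Box-plot summary of an adjustment distribution."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    keep_fraction: float
    n: int


@dataclass(frozen=True)
class ScenarioResult:
    scenario: ScenarioSpec
    E2: np.ndarray
    adjustments: np.ndarray
    summary: AdjustmentSummary


def _sample_agents(
    group: GroupParams, spec: ModelSpec, n: int, subset: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw agent parameter vectors, honouring the confirmation subset rule.

    Subset filtering keeps draws in the upper or lower half of the
    confirmation-weighting (var_conf) distribution; under the normal
    population model the halves split at the group mean, so rejection
    sampling against it partitions the candidate pool exactly in two.
    """
    if subset == "all":
        return group.sample_individuals(n, spec, rng)
    cut = group.mean["var_conf"]
    keep_upper = subset == "upper_conf"
    out = np.empty((0, 9))
    while out.shape[0] < n:
        cand = group.sample_individuals(2 * (n - out.shape[0]), spec, rng)
        sel = cand[:, 6] > cut if keep_upper else cand[:, 6] <= cut
        out = np.vstack([out, cand[sel]])
    return out[:n]


def run_scenario(
    scenario: ScenarioSpec | str,
    population,
    n_agents: int = 1000,
    seed: int = 0,
    spec: ModelSpec = ModelSpec(use_adopt=False),
    slider: tuple[int, int] = DEFAULT_SLIDER,
) -> ScenarioResult:
    """Simulate one adjustment per agent under a scenario.

    ``population`` supplies the parameter distribution: a GroupParams
    object, a PosteriorFit (its posterior-mean group distribution is
    used), or None for the packaged calibrated fixture.
    """
    if isinstance(scenario, str):
        scenario = build_scenario(scenario)
    if population is None:
        group = default_group_params()
    elif isinstance(population, GroupParams):
        group = population
    else:  # a PosteriorFit
        group = population.group_params()
        spec = population.spec
    rng = np.random.default_rng(seed)
    theta = _sample_agents(group, spec, n_agents, scenario.agent_subset, rng)
    peers = scenario.peers
    E2 = np.empty(n_agents, dtype=int)
    for a in range(n_agents):
        E2[a] = simulate_adjustment(
            scenario.agent_E1, peers, IndividualParams.from_array(theta[a]),
            spec, rng, slider,
        )
    adjustments = E2.astype(float) - scenario.agent_E1
    return ScenarioResult(
        scenario=scenario, E2=E2, adjustments=adjustments,
        summary=summarize_adjustments(E2, scenario),
    )


def summarize_adjustments(E2: Sequence[int], scenario: ScenarioSpec) -> AdjustmentSummary:
    """Median, quartiles, 1.5-IQR whiskers and keep fraction of adjustments."""
    E2 = np.asarray(E2, dtype=float)
    if E2.size == 0:
        raise ValueError("no adjustments to summarize")
    adj = E2 - scenario.agent_E1
    q1, med, q3 = np.quantile(adj, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    return AdjustmentSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_lo=float(q1 - 1.5 * iqr), whisker_hi=float(q3 + 1.5 * iqr),
        keep_fraction=float(np.mean(adj == 0)), n=int(E2.size),
    )
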