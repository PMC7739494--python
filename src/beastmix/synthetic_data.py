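"""Synthetic study generator.

Emulates the full design of the estimate-adjustment experiment so every
downstream stage (classification, model fitting, model comparison,
recovery) can run without any behavioural data release:

* a cohort of participants whose strategy parameters are drawn from a
  population-level (hierarchical) distribution,
* 30 main rounds — five of each of the four social-information
  conditions plus ten filler rounds — in one random order shared by all
  participants, followed by a five-round control block with four peers
  and no stimulus,
* a pre-recorded pool of 100 independent first estimates per stimulus,
  from which filler (and optionally condition) social information is
  drawn,
* a multiplicative log-normal first-estimate error model standing in for
  the perceptual front end (count estimation errors scale with the
  count; a configurable bias reproduces the usual underestimation of
  large groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .task_design import (
    CONDITIONS,
    DEFAULT_MEAN_OFFSET_FRACTION,
    DEFAULT_SLIDER,
    Trial,
    make_condition_layout,
    realize_social_info,
)
from .cognitive_model import (
    PARAM_NAMES,
    GroupParams,
    IndividualParams,
    ModelSpec,
    default_group_params,
    simulate_response,
)

__all__ = [
    "EstimatorNoise",
    "SessionDesign",
    "PeerPool",
    "default_truths",
    "simulate_first_estimate",
    "build_peer_pool",
    "assemble_trial",
    "simulate_population",
]


@dataclass(frozen=True)
class EstimatorNoise:
    """Multiplicative log-normal error of a first estimate.

    An estimate is ``round(truth * exp(eps))`` with
    ``eps ~ Normal(bias, sd)``.  The default negative bias reproduces the
    systematic underestimation of large groups typical of numerosity
    judgements; sd = 0.25 gives a realistic coefficient of variation of
    roughly 25%.
    """

    bias: float = -0.1
    sd: float = 0.25


def default_truths(n: int = 35, slider: tuple[int, int] = DEFAULT_SLIDER) -> tuple[int, ...]:
    """Deterministic stimulus counts spread over the central slider range.

    Kept away from the slider edges so peers at the largest layout offset
    (2 M above the estimate) usually still fit on the grid.
    """
    lo, hi = slider
    lo_t = lo + int(0.17 * (hi - lo))
    hi_t = lo + int(0.60 * (hi - lo))
    return tuple(int(round(v)) for v in np.linspace(lo_t, hi_t, n))


@dataclass(frozen=True)
class SessionDesign:
    """Layout of one experimental session.

    30 main rounds (five per condition plus ``n_filler`` fillers) in a
    random order fixed by ``order_seed`` and shared by every participant,
    then a control block of ``n_control`` rounds with four peers each
    (one emulating each condition layout, plus one filler-style round).
    """

    n_condition_rounds: int = 5
    n_filler: int = 10
    n_control: int = 5
    slider: tuple[int, int] = DEFAULT_SLIDER
    mean_offset_fraction: float = DEFAULT_MEAN_OFFSET_FRACTION
    truths: tuple[int, ...] = field(default_factory=default_truths)
    order_seed: int = 20201125

    @property
    def n_main(self) -> int:
        return self.n_condition_rounds * len(CONDITIONS) + self.n_filler

    @property
    def n_rounds(self) -> int:
        return self.n_main + self.n_control

    def __post_init__(self) -> None:
        if len(self.truths) < self.n_rounds:
            raise ValueError(
                f"need at least {self.n_rounds} stimulus truths, got {len(self.truths)}"
            )

    def schedule(self) -> list[str]:
        """Condition label per round (main block shuffled, control appended)."""
        labels = [c for c in CONDITIONS for _ in range(self.n_condition_rounds)]
        labels += ["FILLER"] * self.n_filler
        order = np.random.default_rng(self.order_seed).permutation(len(labels))
        main = [labels[i] for i in order]
        return main + ["CONTROL"] * self.n_control


@dataclass(frozen=True)
class PeerPool:
    """Pre-recorded first estimates, one list per stimulus index."""

    estimates: tuple[tuple[int, ...], ...]

    def __getitem__(self, stimulus: int) -> tuple[int, ...]:
        return self.estimates[stimulus]

    def __len__(self) -> int:
        return len(self.estimates)


def simulate_first_estimate(
    truth: int,
    noise: EstimatorNoise = EstimatorNoise(),
    rng: np.random.Generator | None = None,
    slider: tuple[int, int] = DEFAULT_SLIDER,
) -> int:
    """One noisy count estimate: round(truth * exp(eps)), clipped to the slider."""
    if truth < 1:
        raise ValueError("truth must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    eps = noise.bias if noise.sd == 0 else rng.normal(noise.bias, noise.sd)
    lo, hi = slider
    return int(np.clip(round(truth * np.exp(eps)), lo, hi))


def build_peer_pool(
    truths: Sequence[int],
    n_estimators: int = 100,
    noise: EstimatorNoise = EstimatorNoise(),
    seed: int = 0,
    slider: tuple[int, int] = DEFAULT_SLIDER,
) -> PeerPool:
    """Simulate the pre-recorded estimate pool: n_estimators per stimulus."""
    rng = np.random.default_rng(seed)
    pool = []
    for t in truths:
        pool.append(
            tuple(
                simulate_first_estimate(t, noise, rng, slider)
                for _ in range(n_estimators)
            )
        )
    return PeerPool(estimates=tuple(pool))


def _match_from_pool(
    targets: Sequence[int],
    candidates: Sequence[int],
) -> Optional[list[int]]:
    """Pick len(targets) distinct pool entries minimizing summed distance.

    Exact assignment via the Hungarian algorithm; None when the pool has
    too few candidates.
    """
    if len(candidates) < len(targets):
        return None
    cost = np.abs(
        np.asarray(targets, float)[:, None] - np.asarray(candidates, float)[None, :]
    )
    rows, cols = linear_sum_assignment(cost)
    return [int(candidates[j]) for _, j in sorted(zip(rows, cols))]


def assemble_trial(
    participant_id: str,
    round_index: int,
    condition: str,
    truth: int,
    E1: Optional[int],
    pool_entries: Sequence[int],
    rng: np.random.Generator,
    *,
    mean_offset_fraction: float = DEFAULT_MEAN_OFFSET_FRACTION,
    slider: tuple[int, int] = DEFAULT_SLIDER,
    pool_matching: bool = False,
    jitter: int = 2,
    control_peers: Optional[Sequence[int]] = None,
) -> Trial:
    """Build one trial skeleton (no second estimate yet).

    Condition rounds place three peers by the condition layout on the
    truth side of ``E1`` — either synthetically jittered, or, in
    pool-matching mode, as the three same-side pool entries closest to the
    layout targets (falling back to the synthetic placement when the pool
    is too thin on that side).  Filler rounds draw three pool entries
    uniformly without replacement, which may bracket ``E1``.  Control
    rounds take their four pre-built peers from ``control_peers``.
    """
    lo, hi = slider
    if condition == "CONTROL":
        if control_peers is None or len(control_peers) != 4:
            raise ValueError("CONTROL rounds require 4 pre-built peers")
        return Trial(participant_id, round_index, "CONTROL", truth, None,
                     tuple(int(x) for x in control_peers))
    if E1 is None:
        raise ValueError("non-control rounds require E1")
    if condition == "FILLER":
        if len(pool_entries) < 3:
            raise ValueError("pool exhausted: need 3 filler estimates")
        idx = rng.choice(len(pool_entries), size=3, replace=False)
        X = tuple(int(pool_entries[i]) for i in idx)
        return Trial(participant_id, round_index, "FILLER", truth, E1, X)

    layout = make_condition_layout(condition, mean_offset_fraction=mean_offset_fraction)
    direction = 1 if truth >= E1 else -1
    if direction > 0 and E1 >= hi:
        direction = -1
    elif direction < 0 and E1 <= lo:
        direction = 1
    if pool_matching:
        targets = [
            round(E1 * (1.0 + direction * mean_offset_fraction * off))
            for off in layout.relative_offsets
        ]
        side = [x for x in pool_entries if (x - E1) * direction > 0]
        matched = _match_from_pool(targets, side)
        if matched is not None:
            X = tuple(int(np.clip(x, lo, hi)) for x in matched)
            return Trial(participant_id, round_index, condition, truth, E1, X)
    X = realize_social_info(E1, layout, direction, rng, jitter=jitter, slider=slider)
    return Trial(participant_id, round_index, condition, truth, E1, X)


def _build_control_peers(
    design: SessionDesign, pool: PeerPool, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Four-peer layouts for the control block, shared by all participants.

    The first four control rounds emulate the four condition layouts
    centred on the cohort-typical estimate for that stimulus (the pool
    median plays the role the personal estimate plays in main rounds);
    the remaining rounds are filler-style draws of four pool estimates.
    """
    lo, hi = design.slider
    peers: list[tuple[int, ...]] = []
    for j in range(design.n_control):
        stim = design.n_main + j
        entries = pool[stim]
        if j < len(CONDITIONS):
            layout = make_condition_layout(
                CONDITIONS[j], mean_offset_fraction=design.mean_offset_fraction
            )
            C = int(np.median(entries))
            direction = 1 if C <= (lo + hi) // 2 else -1
            three = realize_social_info(
                C, layout, direction, rng, jitter=2, slider=design.slider
            )
            peers.append((C,) + three)
        else:
            idx = rng.choice(len(entries), size=4, replace=False)
            peers.append(tuple(int(entries[i]) for i in idx))
    return peers


def simulate_population(
    group: GroupParams | None = None,
    design: SessionDesign = SessionDesign(),
    n_participants: int = 95,
    spec: ModelSpec = ModelSpec(use_adopt=False),
    seed: int = 0,
    *,
    noise: EstimatorNoise = EstimatorNoise(),
    pool_matching: bool = False,
    include_control: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial table, true-parameter table).

    Every participant runs the same round schedule; first estimates come
    from the log-normal error model, second estimates from the cognitive
    model at the participant's own parameters, drawn from ``group``
    (defaults to the calibrated population fixture).  The trial table
    follows the package CSV schema; the parameter table has one row per
    participant with the generating values.
    """
    if group is None:
        group = default_group_params()
    ss = np.random.SeedSequence(seed)
    rng_params, rng_pool, rng_sess = [np.random.default_rng(s) for s in ss.spawn(3)]

    theta = group.sample_individuals(n_participants, spec, rng_params)
    pool = build_peer_pool(
        design.truths, 100, noise, seed=int(rng_pool.integers(2**31)),
        slider=design.slider,
    )
    schedule = design.schedule()
    control_peers = _build_control_peers(design, pool, rng_sess)

    rows = []
    for p in range(n_participants):
        pid = f"P{p + 1:03d}"
        params = IndividualParams.from_array(theta[p])
        for r, condition in enumerate(schedule):
            if condition == "CONTROL" and not include_control:
                continue
            truth = design.truths[r]
            if condition == "CONTROL":
                trial = assemble_trial(
                    pid, r + 1, condition, truth, None, pool[r], rng_sess,
                    mean_offset_fraction=design.mean_offset_fraction,
                    slider=design.slider,
                    control_peers=control_peers[r - design.n_main],
                )
            else:
                E1 = simulate_first_estimate(truth, noise, rng_sess, design.slider)
                trial = assemble_trial(
                    pid, r + 1, condition, truth, E1, pool[r], rng_sess,
                    mean_offset_fraction=design.mean_offset_fraction,
                    slider=design.slider, pool_matching=pool_matching,
                )
            E2 = simulate_response(trial, params, spec, rng_sess, design.slider)
            X = list(trial.X) + [None] * (4 - len(trial.X))
            rows.append(
                dict(participant_id=pid, round_index=trial.round_index,
                     condition=condition, truth=truth, E1=trial.E1,
                     X1=X[0], X2=X[1], X3=X[2], X4=X[3], E2=E2)
            )
    trials = pd.DataFrame(rows)
    for col in ("E1", "X1", "X2", "X3", "X4", "E2"):
        trials[col] = trials[col].astype("Int64")
    truth_table = pd.DataFrame(theta, columns=list(PARAM_NAMES))
    truth_table.insert(0, "participant_id", [f"P{p + 1:03d}" for p in range(n_participants)])
    return trials, truth_table
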