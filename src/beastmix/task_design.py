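"""Experimental structure of the estimate-adjustment task.

Participants first estimate the number of animals in an image (first
estimate ``E1``), then observe the estimates of three peers and give a
second estimate ``E2``.  The social information is laid out relative to
``E1`` in one of four conditions that vary the variance and skewness of
the peer distribution while holding the mean peer offset fixed:

========  =================================================
LN        low variance, no skew
HN        high variance, no skew
HF        high variance, two-peer cluster far from ``E1``
HC        high variance, two-peer cluster close to ``E1``
========  =================================================

This module defines the canonical condition layouts, realizes integer
peer estimates from them, computes the relative-adjustment metric ``s``
and classifies observed adjustments into keep / adopt / compromise
(plus overshoot / contrary) strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CONDITIONS",
    "ALL_ROUND_TYPES",
    "DEFAULT_LAYOUT_OFFSETS",
    "DEFAULT_MEAN_OFFSET_FRACTION",
    "DEFAULT_SLIDER",
    "Trial",
    "ConditionLayout",
    "StrategyLabel",
    "make_condition_layout",
    "realize_social_info",
    "compute_s",
    "classify_strategy",
]

#: Experimental conditions with a structured peer layout.
CONDITIONS = ("LN", "HN", "HF", "HC")

#: All round types appearing in a session.
ALL_ROUND_TYPES = CONDITIONS + ("FILLER", "CONTROL")

#: Canonical per-peer offsets, as multiples of the mean peer offset M.
#: Each triple averages to 1 so the mean peer offset is identical across
#: conditions; only variance and skewness differ.
DEFAULT_LAYOUT_OFFSETS = {
    "LN": (0.8, 1.0, 1.2),
    "HN": (0.3, 1.0, 1.7),
    "HF": (0.30, 1.35, 1.35),
    "HC": (0.50, 0.50, 2.00),
}

#: Mean peer offset M as a fraction of the first estimate.
DEFAULT_MEAN_OFFSET_FRACTION = 0.4

#: Inclusive integer slider range for all estimates.
DEFAULT_SLIDER = (1, 200)


@dataclass(frozen=True)
class ConditionLayout:
    """Peer positions for one condition, relative to the first estimate.

    ``relative_offsets[i]`` is peer i's distance from ``E1`` expressed as a
    multiple of the mean peer offset ``M``; ``mean_offset_fraction`` is
    ``M`` itself, as a fraction of ``E1``.
    """

    condition: str
    relative_offsets: tuple[float, ...]
    mean_offset_fraction: float = DEFAULT_MEAN_OFFSET_FRACTION

    def __post_init__(self) -> None:
        if not np.isclose(float(np.mean(self.relative_offsets)), 1.0, atol=1e-12):
            raise ValueError(
                f"layout offsets for {self.condition} must average to 1, "
                f"got {self.relative_offsets}"
            )
        if self.mean_offset_fraction <= 0:
            raise ValueError("mean_offset_fraction must be positive")


@dataclass(frozen=True)
class Trial:
    """One judgement round.

    ``E1`` is absent (None) in CONTROL rounds, where the participant never
    sees the stimulus and observes four peer estimates instead of three.
    ``E2`` may be None for a trial skeleton awaiting a simulated response.
    """

    participant_id: str
    round_index: int
    condition: str
    truth: int
    E1: Optional[int]
    X: tuple[int, ...]
    E2: Optional[int] = None

    def __post_init__(self) -> None:
        if self.condition not in ALL_ROUND_TYPES:
            raise ValueError(f"unknown condition {self.condition!r}")
        if (self.condition == "CONTROL") != (self.E1 is None):
            raise ValueError("E1 must be absent exactly for CONTROL rounds")
        if (self.condition == "CONTROL") != (len(self.X) == 4):
            raise ValueError("CONTROL rounds have 4 peers, all others 3")
        if self.condition in CONDITIONS:
            side = np.sign(np.asarray(self.X) - self.E1)
            if len(set(side)) != 1 or 0 in side:
                raise ValueError(
                    f"{self.condition} peers must lie strictly on one side of E1"
                )


@dataclass(frozen=True)
class StrategyLabel:
    """Classification of one observed adjustment.

    ``adopt_target`` is the 0-based index of the adopted peer and is
    present exactly when ``label == "ADOPT"``.
    """

    label: str
    adopt_target: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label not in ("KEEP", "ADOPT", "COMPROMISE", "OVERSHOOT", "CONTRARY"):
            raise ValueError(f"unknown strategy label {self.label!r}")
        if (self.label == "ADOPT") != (self.adopt_target is not None):
            raise ValueError("adopt_target present iff label == ADOPT")


def make_condition_layout(
    condition: str,
    offsets: dict[str, tuple[float, ...]] | None = None,
    mean_offset_fraction: float = DEFAULT_MEAN_OFFSET_FRACTION,
) -> ConditionLayout:
    """Return the canonical peer layout for an experimental condition.

    Raises ``ValueError`` for FILLER/CONTROL or unknown labels: only the
    four structured conditions have a layout.
    """
    table = DEFAULT_LAYOUT_OFFSETS if offsets is None else offsets
    if condition not in CONDITIONS or condition not in table:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    return ConditionLayout(
        condition=condition,
        relative_offsets=tuple(table[condition]),
        mean_offset_fraction=mean_offset_fraction,
    )


def realize_social_info(
    E1: int,
    layout: ConditionLayout,
    direction: int,
    rng: np.random.Generator | None = None,
    *,
    jitter: int = 0,
    slider: tuple[int, int] = DEFAULT_SLIDER,
) -> tuple[int, ...]:
    """Place integer peer estimates around ``E1`` according to a layout.

    Peer i sits at ``round(E1 * (1 + direction * M * offset_i))`` plus an
    optional uniform integer jitter of magnitude ``jitter`` that emulates
    nearest-match selection from a finite pre-recorded pool.  All peers are
    forced strictly onto the ``direction`` side of ``E1`` and clipped to the
    slider range.
    """
    lo, hi = slider
    if not (lo <= E1 <= hi):
        raise ValueError(f"E1={E1} outside slider range {slider}")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    M = layout.mean_offset_fraction
    peers = []
    for off in layout.relative_offsets:
        x = round(E1 * (1.0 + direction * M * off))
        if jitter > 0:
            if rng is None:
                raise ValueError("jitter > 0 requires an rng")
            x += int(rng.integers(-jitter, jitter + 1))
        # keep strictly on the correct side, then inside the slider
        if direction > 0:
            x = max(x, E1 + 1)
        else:
            x = min(x, E1 - 1)
        x = int(np.clip(x, lo, hi))
        if (x - E1) * direction <= 0:
            # slider clipping collapsed the peer onto/over E1 (E1 at an
            # extreme); nudge to the last grid point on the correct side
            raise ValueError(
                f"cannot place peers on side {direction:+d} of E1={E1} "
                f"within slider {slider}"
            )
        peers.append(x)
    return tuple(peers)


def compute_s(
    E1: float,
    E2: float,
    X: Sequence[float],
    *,
    tol: float = 0.5,
) -> Optional[float]:
    """Relative adjustment ``s = (E2 - E1) / (mean(X) - E1)``.

    ``s = 0`` means the first estimate was kept, ``s = 1`` a full shift to
    the mean of the social information.  Returns None (undefined) when the
    mean peer estimate is within ``tol`` grid units of ``E1`` — the
    denominator is degenerate, as in filler rounds whose random peers
    bracket the first estimate.
    """
    xbar = float(np.mean(X))
    denom = xbar - E1
    if abs(denom) < tol:
        return None
    return (E2 - E1) / denom


def classify_strategy(trial: Trial, tol: int = 0) -> StrategyLabel:
    """Classify an adjustment as KEEP / ADOPT / COMPROMISE / OVERSHOOT / CONTRARY.

    KEEP if the second estimate stays within ``tol`` of the first; else
    ADOPT(i) if it lands within ``tol`` of peer i (nearest peer wins, lower
    index breaks exact ties); else the label depends on where ``E2`` lies
    relative to the peers on the side it moved towards: COMPROMISE strictly
    between ``E1`` and the farthest such peer, OVERSHOOT beyond it, CONTRARY
    when the adjustment moved away from every peer.
    """
    if trial.E1 is None or trial.E2 is None:
        raise ValueError("classification requires both E1 and E2")
    E1, E2 = trial.E1, trial.E2
    X = np.asarray(trial.X, dtype=float)

    if abs(E2 - E1) <= tol:
        return StrategyLabel("KEEP")

    dists = np.abs(X - E2)
    if dists.min() <= tol:
        return StrategyLabel("ADOPT", adopt_target=int(dists.argmin()))

    move = np.sign(E2 - E1)
    on_side = X[(X - E1) * move > 0]
    if on_side.size == 0:
        return StrategyLabel("CONTRARY")
    farthest = on_side[np.abs(on_side - E1).argmax()]
    if abs(E2 - E1) < abs(farthest - E1):
        return StrategyLabel("COMPROMISE")
    return StrategyLabel("OVERSHOOT")
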