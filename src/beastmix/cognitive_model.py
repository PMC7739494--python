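"""Mixture cognitive model of social-information integration.

On each round an individual either *keeps* the first estimate, *adopts*
the nearest peer estimate, or *compromises* via Bayesian updating.  The
probabilities of the two heuristics are logistic functions of the
relative distance between the first estimate and the nearest peer; the
compromise is a precision-weighted average of the personal estimate and
the peer estimates, where the subjective variance assigned to peer i
grows log-linearly with

* its relative distance to the first estimate (confirmation-based
  weighting: agreeing peers are trusted more), and
* its mean relative distance to the other peers (proximity-based
  weighting: peers that agree with each other are trusted more).

All distances are expressed relative to the first estimate, making the
parameters comparable across stimuli of different magnitudes.  Responses
live on an integer slider grid, so the model's response distribution is a
mixture of two point masses (keep, adopt) and a discretized normal for
the compromise branch — a proper probability mass function over the grid.

Sixteen model variants arise from switching each of the four features
(keep, adopt, confirmation, proximity) on or off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, ndtr

from .task_design import DEFAULT_SLIDER, Trial

__all__ = [
    "PARAM_NAMES",
    "IndividualParams",
    "ModelSpec",
    "GroupParams",
    "default_group_params",
    "nearest_peer_distance",
    "keep_probability",
    "adopt_probability",
    "branch_probabilities",
    "peer_variance",
    "compromise_posterior",
    "control_posterior",
    "trial_loglik",
    "response_distribution",
    "simulate_response",
    "simulate_adjustment",
]

#: Canonical parameter order used throughout the package.
PARAM_NAMES = (
    "keep_intercept",
    "keep_slope",
    "adopt_intercept",
    "adopt_slope",
    "log_sigma_E",
    "var_base",
    "var_conf",
    "var_prox",
    "log_sigma_resp",
)

_KEEP_PARAMS = ("keep_intercept", "keep_slope")
_ADOPT_PARAMS = ("adopt_intercept", "adopt_slope")


@dataclass(frozen=True)
class ModelSpec:
    """Feature flags selecting one of the 16 model variants."""

    use_keep: bool = True
    use_adopt: bool = True
    use_confirmation: bool = True
    use_proximity: bool = True

    def active_params(self) -> tuple[str, ...]:
        """Names of the parameters that are free under this spec.

        Switching a feature off fixes its parameters: the heuristic's
        probability is 0, or the variance coefficient is 0.
        """
        names = []
        for name in PARAM_NAMES:
            if name in _KEEP_PARAMS and not self.use_keep:
                continue
            if name in _ADOPT_PARAMS and not self.use_adopt:
                continue
            if name == "var_conf" and not self.use_confirmation:
                continue
            if name == "var_prox" and not self.use_proximity:
                continue
            names.append(name)
        return tuple(names)

    @property
    def label(self) -> str:
        bits = []
        for flag, tag in [
            (self.use_keep, "keep"),
            (self.use_adopt, "adopt"),
            (self.use_confirmation, "conf"),
            (self.use_proximity, "prox"),
        ]:
            if flag:
                bits.append(tag)
        return "+".join(bits) if bits else "null"


@dataclass(frozen=True)
class IndividualParams:
    """One agent's strategy parameters (all on the unconstrained scale).

    keep_intercept / keep_slope
        log-odds of keeping at zero distance, and its change per unit
        relative distance to the nearest peer (negative slope: keeping is
        more likely when the nearest peer closely agrees).
    adopt_intercept / adopt_slope
        same construction for adopting the nearest peer, conditional on
        not keeping.
    log_sigma_E
        log of the standard deviation of the personal estimate, in
        relative-distance units.
    var_base / var_conf / var_prox
        baseline log-variance of a peer estimate and the log-variance
        increments per unit confirmation distance (|Xi - E1| / E1) and
        proximity distance (mean distance of Xi to the other peers,
        relative units).
    log_sigma_resp
        log standard deviation of the response noise added around the
        compromise mean (slider/motor noise, relative units).
    """

    keep_intercept: float = 0.0
    keep_slope: float = 0.0
    adopt_intercept: float = 0.0
    adopt_slope: float = 0.0
    log_sigma_E: float = math.log(0.15)
    var_base: float = -3.5
    var_conf: float = 0.0
    var_prox: float = 0.0
    log_sigma_resp: float = math.log(0.05)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "IndividualParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))


@dataclass(frozen=True)
class GroupParams:
    """Population means and spreads from which individuals are drawn.

    Individual parameters are Normal(mean, sd) on the unconstrained scale,
    independently per parameter.
    """

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        for n in PARAM_NAMES:
            if n not in self.mean or n not in self.sd:
                raise ValueError(f"missing group parameter {n!r}")
            if self.sd[n] <= 0:
                raise ValueError(f"group sd for {n!r} must be positive")

    def sample_individuals(
        self, n: int, spec: ModelSpec, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw an (n, 9) array of individual parameters.

        Inactive parameters under ``spec`` are set to 0 rather than
        sampled (their features contribute nothing to the likelihood).
        """
        active = set(spec.active_params())
        out = np.zeros((n, len(PARAM_NAMES)))
        for k, name in enumerate(PARAM_NAMES):
            if name in active:
                out[:, k] = rng.normal(self.mean[name], self.sd[name], size=n)
        return out


def default_group_params() -> GroupParams:
    """Calibrated population defaults for the synthetic cohort.

    Chosen so a simulated cohort shows the qualitative behavioural
    signatures of the task: strongest adjustment under low-variance social
    information, more keeping when a single peer closely agrees, stronger
    confirmation than proximity weighting, and marked egocentric
    discounting (self weighted above any single peer).
    """
    mean = {
        "keep_intercept": 1.0,
        "keep_slope": -8.0,
        "adopt_intercept": -1.5,
        "adopt_slope": -4.0,
        "log_sigma_E": math.log(0.15),
        "var_base": -3.5,
        "var_conf": 3.0,
        "var_prox": 0.5,
        "log_sigma_resp": math.log(0.11),
    }
    sd = {
        "keep_intercept": 0.8,
        "keep_slope": 5.0,
        "adopt_intercept": 0.8,
        "adopt_slope": 1.5,
        "log_sigma_E": 0.3,
        "var_base": 0.6,
        "var_conf": 2.2,
        "var_prox": 1.6,
        "log_sigma_resp": 0.2,
    }
    return GroupParams(mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# elementary model quantities (scalar API)
# ---------------------------------------------------------------------------

def nearest_peer_distance(E1: float, X: Sequence[float]) -> tuple[float, int]:
    """Relative distance to the nearest peer and its 0-based index.

    Distance is ``min_i |Xi - E1| / E1``; the lower index wins ties.
    """
    if E1 <= 0:
        raise ValueError("E1 must be positive")
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("peer list must be nonempty")
    d = np.abs(X - E1) / E1
    i = int(d.argmin())  # argmin returns the first minimum: lower index on ties
    return float(d[i]), i


def keep_probability(d_min: float, params: IndividualParams) -> float:
    """Probability of keeping the first estimate at nearest-peer distance d_min."""
    return float(expit(params.keep_intercept + params.keep_slope * d_min))


def adopt_probability(
    d_min: float, params: IndividualParams, spec: ModelSpec = ModelSpec()
) -> float:
    """Probability of adopting the nearest peer estimate.

    Composed after keep so the three branch probabilities always form a
    simplex: P(adopt) = (1 - P(keep)) * logistic(adopt linear predictor).
    """
    pk, pa, _ = branch_probabilities(d_min, params, spec)
    return pa


def branch_probabilities(
    d_min: float, params: IndividualParams, spec: ModelSpec
) -> tuple[float, float, float]:
    """(P(keep), P(adopt), P(compromise)) at nearest-peer distance d_min."""
    pk = keep_probability(d_min, params) if spec.use_keep else 0.0
    if spec.use_adopt:
        pa = (1.0 - pk) * float(
            expit(params.adopt_intercept + params.adopt_slope * d_min)
        )
    else:
        pa = 0.0
    return pk, pa, 1.0 - pk - pa


def peer_variance(
    i: int,
    E1: float,
    X: Sequence[float],
    params: IndividualParams,
    spec: ModelSpec = ModelSpec(),
) -> float:
    """Subjective variance assigned to peer i (relative-distance units).

    sigma_i^2 = exp(var_base + var_conf * |Xi - E1|/E1
                             + var_prox * mean_{j != i} |Xi - Xj|/E1),
    with each term present only when its feature is active.
    """
    X = np.asarray(X, dtype=float)
    if not (0 <= i < X.size):
        raise ValueError(f"peer index {i} out of range")
    logvar = params.var_base
    if spec.use_confirmation:
        logvar += params.var_conf * abs(X[i] - E1) / E1
    if spec.use_proximity and X.size > 1:
        others = np.delete(X, i)
        logvar += params.var_prox * float(np.mean(np.abs(X[i] - others))) / E1
    return float(np.exp(logvar))


def compromise_posterior(
    E1: float,
    X: Sequence[float],
    params: IndividualParams,
    spec: ModelSpec = ModelSpec(),
) -> tuple[float, float]:
    """Precision-weighted combination of the personal and peer estimates.

    Returns the posterior mean and variance on the estimate scale.  The
    computation runs in relative units (everything divided by ``E1``) and
    is scaled back, so the variance parameters keep their relative-unit
    interpretation for stimuli of any magnitude.
    """
    X = np.asarray(X, dtype=float)
    prec_E = math.exp(-2.0 * params.log_sigma_E)
    prec_X = np.array(
        [1.0 / peer_variance(i, E1, X, params, spec) for i in range(X.size)]
    )
    v = X / E1
    total = prec_E + prec_X.sum()
    mu_rel = (prec_E * 1.0 + float(prec_X @ v)) / total
    var_rel = 1.0 / total
    return mu_rel * E1, var_rel * E1 * E1


def control_posterior(
    X: Sequence[float],
    params: IndividualParams,
    spec: ModelSpec = ModelSpec(),
) -> tuple[float, float]:
    """Posterior for control rounds: four peers, no personal estimate.

    Without a first estimate the confirmation term has no anchor and is
    omitted; proximity-based weighting is retained.  The mean peer
    estimate serves as the reference scale for the relative units.
    """
    X = np.asarray(X, dtype=float)
    if X.size != 4:
        raise ValueError(f"control rounds have 4 peers, got {X.size}")
    R = float(np.mean(X))
    logvar = np.full(X.size, params.var_base)
    if spec.use_proximity:
        for i in range(X.size):
            others = np.delete(X, i)
            logvar[i] += params.var_prox * float(np.mean(np.abs(X[i] - others))) / R
    prec = np.exp(-logvar)
    v = X / R
    mu_rel = float(prec @ v) / prec.sum()
    var_rel = 1.0 / prec.sum()
    return mu_rel * R, var_rel * R * R


# ---------------------------------------------------------------------------
# response distribution on the slider grid
# ---------------------------------------------------------------------------

def _discretized_normal_logpmf(
    e2: np.ndarray, mu: float, sd: float, slider: tuple[int, int]
) -> np.ndarray:
    """log pmf of a normal discretized to the integer grid and renormalized."""
    lo, hi = slider
    z = ndtr((hi + 0.5 - mu) / sd) - ndtr((lo - 0.5 - mu) / sd)
    cell = ndtr((e2 + 0.5 - mu) / sd) - ndtr((e2 - 0.5 - mu) / sd)
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(cell, 0.0)) - np.log(max(z, 1e-300))


def _forward(
    E1: Optional[float],
    X: Sequence[float],
    params: IndividualParams,
    spec: ModelSpec,
) -> tuple[float, float, float, Optional[int], float, float]:
    """Shared forward pass: branch probabilities and compromise distribution.

    Returns (p_keep, p_adopt, p_compromise, nearest_peer, mu, sd_total)
    where mu/sd_total describe the compromise response distribution before
    discretization.  ``E1 is None`` marks a control round: no heuristics,
    p_compromise = 1, peers-only posterior.
    """
    if E1 is None:
        mu, var = control_posterior(X, params, spec)
        R = float(np.mean(X))
        sd = math.sqrt(var + math.exp(2.0 * params.log_sigma_resp) * R * R)
        return 0.0, 0.0, 1.0, None, mu, sd
    d_min, i_near = nearest_peer_distance(E1, X)
    pk, pa, pc = branch_probabilities(d_min, params, spec)
    mu, var = compromise_posterior(E1, X, params, spec)
    sd = math.sqrt(var + math.exp(2.0 * params.log_sigma_resp) * E1 * E1)
    return pk, pa, pc, X[i_near], mu, sd


def _trial_forward(
    trial: Trial, params: IndividualParams, spec: ModelSpec
) -> tuple[float, float, float, Optional[int], float, float]:
    return _forward(trial.E1, trial.X, params, spec)


def response_distribution(
    trial: Trial,
    params: IndividualParams,
    spec: ModelSpec = ModelSpec(),
    slider: tuple[int, int] = DEFAULT_SLIDER,
) -> np.ndarray:
    """Probability of every grid value as the second estimate.

    A proper pmf over the slider grid: point masses at the first estimate
    (keep) and the nearest peer (adopt) plus a discretized normal around
    the compromise mean.
    """
    lo, hi = slider
    grid = np.arange(lo, hi + 1)
    pk, pa, pc, x_near, mu, sd = _trial_forward(trial, params, spec)
    pmf = pc * np.exp(_discretized_normal_logpmf(grid, mu, sd, slider))
    if pk > 0:
        pmf[trial.E1 - lo] += pk
    if pa > 0:
        pmf[x_near - lo] += pa
    return pmf


def trial_loglik(
    trial: Trial,
    params: IndividualParams,
    spec: ModelSpec = ModelSpec(),
    slider: tuple[int, int] = DEFAULT_SLIDER,
) -> float:
    """Log-probability of the observed second estimate under the mixture."""
    lo, hi = slider
    if trial.E2 is None or not (lo <= trial.E2 <= hi) or trial.E2 != int(trial.E2):
        raise ValueError(f"E2={trial.E2} is not on the slider grid {slider}")
    pk, pa, pc, x_near, mu, sd = _trial_forward(trial, params, spec)
    p = pc * math.exp(
        float(_discretized_normal_logpmf(np.asarray(trial.E2, float), mu, sd, slider))
    )
    if pk > 0 and trial.E2 == trial.E1:
        p += pk
    if pa > 0 and trial.E2 == x_near:
        p += pa
    return math.log(max(p, 1e-300))


def simulate_response(
    trial: Trial,
    params: IndividualParams,
    spec: ModelSpec = ModelSpec(),
    rng: np.random.Generator | None = None,
    slider: tuple[int, int] = DEFAULT_SLIDER,
) -> int:
    """Sample a second estimate from the same distribution trial_loglik scores.

    Samples the branch (keep / adopt / compromise), then, for compromise,
    an integer from the discretized normal via inverse-cdf sampling on the
    grid — the exact pmf, so simulation and likelihood share one code path.
    """
    return simulate_adjustment(trial.E1, trial.X, params, spec, rng, slider)


def simulate_adjustment(
    E1: Optional[int],
    X: Sequence[int],
    params: IndividualParams,
    spec: ModelSpec = ModelSpec(),
    rng: np.random.Generator | None = None,
    slider: tuple[int, int] = DEFAULT_SLIDER,
) -> int:
    """Sample a second estimate given a first estimate and any peer set.

    Same forward pass as the trial likelihood but free of the session's
    3/4-peer trial structure, so agent-based simulations can present an
    arbitrary number of peers (``E1 is None`` gives the peers-only control
    behaviour).
    """
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = slider
    pk, pa, pc, x_near, mu, sd = _forward(E1, X, params, spec)
    u = rng.random()
    if u < pk:
        return int(E1)
    if u < pk + pa:
        return int(x_near)
    grid = np.arange(lo, hi + 1)
    pmf = np.exp(_discretized_normal_logpmf(grid, mu, sd, slider))
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    return int(grid[np.searchsorted(cdf, rng.random())])
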