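"""Type-1 and type-2 signal-detection analysis of the 2AFC metacognitive tasks.

The visual (dot-numerosity) and memory (word recognition) tasks yield, per
trial, a binary choice and a 1-6 confidence rating; task difficulty in the
visual task is controlled online by a one-up two-down staircase that
converges on ~70.7% correct.  From the confidence-by-outcome counts we
estimate:

* ``d'`` - first-order sensitivity, z(hit rate) - z(false-alarm rate);
* ``meta-d'`` - the first-order sensitivity an ideal (SDT) observer would
  need in order to produce the observed response-conditional confidence
  distributions, fitted by maximum likelihood with the type-1 relative
  criterion c' = c/d' held at its observed value;
* metacognitive efficiency ``meta-d' - d'``, which is ~0 for an observer
  whose confidence carries full access to the first-order evidence and
  approaches ``-d'`` as confidence becomes uninformative.

The meta-d' model follows the standard equal-variance formulation: evidence
x ~ N(-meta_d'/2, 1) under stimulus A and N(+meta_d'/2, 1) under stimulus B,
a type-1 criterion at c' * meta_d', and 2*(n_ratings-1) monotone type-2
criteria partitioning each response side into rating bins.  The fit
maximises the multinomial likelihood of the response-conditional rating
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .errors import (
    EmptyInputError,
    InvalidInputError,
    InvalidParameterError,
    NotConvergedError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Trials and count tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetacogTrial:
    """One 2AFC trial: stimulus class, response class and a 1..n_ratings confidence."""

    stimulus_class: str  # "A" | "B"
    response_class: str
    confidence_rating: int

    def __post_init__(self) -> None:
        for f in (self.stimulus_class, self.response_class):
            if f not in ("A", "B"):
                raise InvalidInputError(f"stimulus/response class must be 'A' or 'B', got {f!r}")
        if self.confidence_rating < 1:
            raise InvalidInputError("confidence rating must be >= 1")

    @property
    def correct(self) -> bool:
        return self.response_class == self.stimulus_class


@dataclass(frozen=True)
class ConfidenceCountTable:
    """Counts indexed [stimulus (A,B)] x [response (A,B)] x [rating 1..K].

    The sufficient statistic for both d' and meta-d'.
    """

    counts: np.ndarray  # shape (2, 2, K)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3 or c.shape[:2] != (2, 2) or c.shape[2] < 2:
            raise InvalidInputError(f"counts must have shape (2, 2, K>=2), got {c.shape}")
        if (c < 0).any():
            raise InvalidInputError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(float))

    @property
    def n_ratings(self) -> int:
        return self.counts.shape[2]

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_trials(cls, trials: Sequence[MetacogTrial], n_ratings: int = 6) -> "ConfidenceCountTable":
        if not trials:
            raise EmptyInputError("no metacognitive trials")
        counts = np.zeros((2, 2, n_ratings))
        idx = {"A": 0, "B": 1}
        for t in trials:
            if t.confidence_rating > n_ratings:
                raise InvalidInputError(
                    f"rating {t.confidence_rating} exceeds n_ratings={n_ratings}"
                )
            counts[idx[t.stimulus_class], idx[t.response_class], t.confidence_rating - 1] += 1
        return cls(counts)


# ---------------------------------------------------------------------------
# One-up two-down staircase
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StaircaseState:
    """State of the one-up two-down difficulty staircase.

    ``current_level`` is the stimulus difference (e.g. dots added/subtracted);
    a *larger* level is an *easier* trial.  One incorrect response eases the
    task by one step immediately; two consecutive correct responses harden
    it by one step.  The long-run convergence point of this rule is the
    level at which P(correct) = 2^(-1/2) ~ 0.707.
    """

    current_level: float = 40.0
    step_size: float = 2.0
    consecutive_correct: int = 0
    floor: float = 1.0
    ceiling: float = 99.0
    history: tuple = field(default_factory=tuple)  # ((level, correct), ...)

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise InvalidParameterError("step_size must be positive")
        if not self.floor <= self.current_level <= self.ceiling:
            raise InvalidParameterError("current_level outside [floor, ceiling]")


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one trial; pure function of (state, correct)."""
    history = state.history + ((state.current_level, bool(correct)),)
    if not correct:
        level = min(state.current_level + state.step_size, state.ceiling)
        counter = 0
    elif state.consecutive_correct + 1 >= 2:
        level = max(state.current_level - state.step_size, state.floor)
        counter = 0
    else:
        level = state.current_level
        counter = state.consecutive_correct + 1
    return replace(state, current_level=level, consecutive_correct=counter, history=history)


def difficulty_threshold(history: Sequence[tuple], burn_in: int = 0) -> float:
    """Mean presented level over the staircase run (after an optional burn-in)."""
    levels = [h[0] for h in history][burn_in:]
    if not levels:
        raise EmptyInputError("empty staircase history")
    return float(np.mean(levels))


def run_staircase(
    p_correct_at_level, n_trials: int, rng: np.random.Generator, state: StaircaseState | None = None
) -> StaircaseState:
    """Drive the staircase against a simulated observer.

    ``p_correct_at_level(level)`` gives the observer's accuracy at a given
    stimulus level (monotone increasing in level).
    """
    state = state or StaircaseState()
    for _ in range(n_trials):
        correct = rng.random() < p_correct_at_level(state.current_level)
        state = staircase_update(state, correct)
    return state


# ---------------------------------------------------------------------------
# Type-1 sensitivity
# ---------------------------------------------------------------------------


def type1_dprime(table: ConfidenceCountTable) -> tuple[float, float]:
    """Equal-variance d' and criterion c from the 2x2 response counts.

    Treats stimulus/response "B" as signal: HR = P(respond B | B),
    FAR = P(respond B | A).  If any of the four response cells is zero,
    0.5 is added to all four (log-linear correction) to keep the normal
    quantiles finite.
    """
    resp = table.counts.sum(axis=2)  # (stimulus, response)
    if resp[0].sum() == 0 or resp[1].sum() == 0:
        raise InvalidInputError("both stimulus classes must be present")
    if (resp == 0).any():
        resp = resp + 0.5
    hr = resp[1, 1] / resp[1].sum()
    far = resp[0, 1] / resp[0].sum()
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return float(zh - zf), float(-0.5 * (zh + zf))


# ---------------------------------------------------------------------------
# meta-d' maximum-likelihood fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetacogFit:
    """Result of the meta-d' fit (plus the type-1 quantities it conditions on)."""

    d_prime: float
    criterion_c: float
    meta_d_prime: float
    type2_criteria: np.ndarray  # 2*(K-1) values: response-A side ascending, then response-B side
    log_likelihood: float
    efficiency: float
    converged: bool
    diagnostics: str = ""


def _rating_probs(meta_d: float, c_meta: float, t2_a: np.ndarray, t2_b: np.ndarray) -> np.ndarray:
    """Model P(response, rating | stimulus) under the equal-variance observer.

    Returns an array (2 stimuli, 2 responses, K ratings).  ``t2_a`` are the
    ascending type-2 criteria below c_meta (response A side), ``t2_b`` the
    ascending criteria above it (response B side).
    """
    K = len(t2_b) + 1
    means = np.array([-meta_d / 2.0, meta_d / 2.0])
    out = np.empty((2, 2, K))
    # response A: evidence in (-inf, c_meta); confidence K at the far left
    edges_a = np.concatenate(([-np.inf], t2_a, [c_meta]))
    # response B: evidence in (c_meta, inf); confidence K at the far right
    edges_b = np.concatenate(([c_meta], t2_b, [np.inf]))
    for s, m in enumerate(means):
        cdf_a = norm.cdf(edges_a - m)
        cdf_b = norm.cdf(edges_b - m)
        out[s, 0, :] = np.diff(cdf_a)[::-1]  # leftmost interval -> highest rating
        out[s, 1, :] = np.diff(cdf_b)
    return out


def _conditional_loglik(
    meta_d: float,
    c_prime: float,
    t2_a: np.ndarray,
    t2_b: np.ndarray,
    padded_counts: np.ndarray,
) -> float:
    """Multinomial log-likelihood of response-conditional rating counts."""
    c_meta = c_prime * meta_d
    joint = _rating_probs(meta_d, c_meta, t2_a, t2_b)
    p_resp = joint.sum(axis=2, keepdims=True)  # P(response | stimulus)
    cond = joint / np.clip(p_resp, 1e-300, None)
    cond = np.clip(cond, 1e-300, None)
    return float((padded_counts * np.log(cond)).sum())


def _unpack(theta: np.ndarray, c_prime: float, K: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Map unconstrained parameters to (meta_d, t2_a ascending, t2_b ascending).

    Criteria are parameterised as cumulative exp-spaced offsets from the
    type-1 criterion, which enforces the monotone ordering by construction.
    """
    meta_d = theta[0]
    c_meta = c_prime * meta_d
    off_b = np.cumsum(np.exp(theta[1:K]))
    off_a = np.cumsum(np.exp(theta[K : 2 * K - 1]))
    t2_b = c_meta + off_b
    t2_a = (c_meta - off_a)[::-1]
    return meta_d, t2_a, t2_b


def fit_meta_dprime(
    table: ConfidenceCountTable,
    response_conditional: bool = True,
    n_starts: int = 4,
) -> MetacogFit:
    """Maximum-likelihood meta-d' from a confidence count table.

    Fits a single meta-d' (shared across response sides) with free type-2
    criteria on each side, holding c' = c/d' at its observed type-1 value.
    Rating cells are padded by 1/(2K) before likelihood evaluation so
    sparse tables cannot produce an infinite deviance.

    When ``response_conditional`` is False the two stimulus classes are
    collapsed into correct/incorrect before fitting (pooled type-2 fit);
    the default matches the response-conditional convention.
    """
    d_prime, criterion_c = type1_dprime(table)
    K = table.n_ratings
    c_prime = criterion_c / d_prime if abs(d_prime) > 1e-8 else 0.0

    counts = table.counts
    if not response_conditional:
        # pool stimuli: fold incorrect responses of each class together by
        # symmetrising the table, preserving correct/incorrect x rating counts
        pooled = np.empty_like(counts)
        pooled[0] = (counts[0] + counts[1, ::-1, :]) / 2.0
        pooled[1] = pooled[0, ::-1, :]
        counts = pooled
    padded = counts + 1.0 / (2.0 * K)

    def neg_ll(theta: np.ndarray) -> float:
        meta_d, t2_a, t2_b = _unpack(theta, c_prime, K)
        return -_conditional_loglik(meta_d, c_prime, t2_a, t2_b, padded)

    # multi-start quasi-Newton; starts bracket the plausible meta-d' range
    starts = []
    base_spacing = np.full(K - 1, np.log(0.5))
    for md0 in (d_prime, 0.5 * d_prime, 0.1, max(d_prime, 0.5) * 1.5)[:n_starts]:
        starts.append(np.concatenate(([md0], base_spacing, base_spacing)))

    best = None
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    converged = bool(best.success) and np.isfinite(best.fun)
    meta_d, t2_a, t2_b = _unpack(best.x, c_prime, K)
    fit = MetacogFit(
        d_prime=d_prime,
        criterion_c=criterion_c,
        meta_d_prime=float(meta_d),
        type2_criteria=np.concatenate([t2_a, t2_b]),
        log_likelihood=float(-best.fun),
        efficiency=float(meta_d - d_prime),
        converged=converged,
        diagnostics="" if converged else str(best.message),
    )
    if not converged:
        logger.warning("meta-d' fit did not converge: %s", best.message)
    return fit


def metacog_efficiency(fit: MetacogFit) -> float:
    """Metacognitive efficiency, meta-d' - d'."""
    if not fit.converged:
        raise NotConvergedError(f"meta-d' fit unconverged: {fit.diagnostics}")
    return fit.meta_d_prime - fit.d_prime


def saturated_loglik(table: ConfidenceCountTable) -> float:
    """Log-likelihood of the saturated response-conditional multinomial model.

    Upper bound for any meta-d' fit evaluated on the same (padded) counts.
    """
    padded = table.counts + 1.0 / (2.0 * table.n_ratings)
    totals = padded.sum(axis=2, keepdims=True)
    p = padded / totals
    return float((padded * np.log(p)).sum())
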