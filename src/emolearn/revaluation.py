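"""Discrete-trial simulation of implicit UCS revaluation.

The emotional response elicited by an unconditioned stimulus (UCS) is modelled
as the sum of an *active* component ``x`` (sustained by the energy flux of the
stimulus) and a *reactive* component ``i_R`` (self-induced, triggered by the
mere perception of the stimulus).  The reactive component equals a fraction
``alpha`` of the expected response, and the expectation is revised trial by
trial through prediction errors.  With a last-outcome expectation the
recursion is simply

    y[n] = x[n] + alpha * y[n-1]

which for a constant input converges to ``x / (1 - alpha)``.  The module also
implements emotional contrast (an overshoot/undershoot proportional to the
same-trial *actual* error, coefficient ``K``), a weighted-history expectation
(a moving-average low-pass filter over the last ``L`` outcomes), and a
top-down periodic-pattern expectation blended in with a per-trial belief
weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, StabilityError

__all__ = [
    "RevaluationParams",
    "StimulusSchedule",
    "TrialTrace",
    "simulate_revaluation",
    "asymptotic_response",
    "devaluation_trajectory",
    "unexpected_elicitation",
    "predicted_response",
    "actual_error",
    "exponential_weights",
    "ramp_belief",
]


def _check_alpha(alpha: float) -> None:
    if not np.isfinite(alpha) or abs(alpha) >= 1.0:
        raise StabilityError(
            f"reactive gain alpha={alpha!r} violates the stability condition |alpha| < 1"
        )


def exponential_weights(L: int = 5, decay: float = 0.5) -> np.ndarray:
    """Normalized exponential history weights ``h_k ∝ (1-decay)*decay**(k-1)``.

    ``k = 1`` is the most recent trial.  The weights are renormalized to sum
    to one over the finite window so that the steady state of the filtered
    expectation coincides with the last-outcome expectation (and hence the
    closed-form asymptote ``x / (1 - alpha)`` is preserved).
    """
    if L < 1:
        raise ConfigError("filter length L must be >= 1")
    if not 0.0 < decay < 1.0:
        raise ConfigError("decay must lie in (0, 1)")
    w = (1.0 - decay) * decay ** np.arange(L)
    return w / w.sum()


def ramp_belief(
    n_trials: int, period: int, learned_after: int = 3, plateau: float = 1.0
) -> np.ndarray:
    """Convenience pattern-belief profile: linear rise to ``plateau``.

    Belief is zero during the first ``learned_after`` pattern repetitions and
    then ramps linearly over one further repetition.  This is a modelling
    convenience, not a fitted update law.
    """
    if period < 1:
        raise ConfigError("pattern period must be positive")
    if not 0.0 <= plateau <= 1.0:
        raise ConfigError("plateau belief must lie in [0, 1]")
    trials = np.arange(1, n_trials + 1)
    start = learned_after * period
    ramp = (trials - start) / float(period)
    return np.clip(ramp, 0.0, 1.0) * plateau


@dataclass(frozen=True)
class RevaluationParams:
    """Parameters of the discrete revaluation model.

    Parameters
    ----------
    alpha:
        Reactive gain (emotional learning rate), ``|alpha| < 1`` for a stable
        emotional system.
    K:
        Contrast coefficient in ``[0, 1)``; scales the same-trial actual
        error into a response overshoot/undershoot.
    filter_weights:
        Nonnegative history weights ``h_1..h_L`` (most recent first) used to
        form the expected response.  The default single weight reproduces the
        last-outcome expectation.
    pattern_period:
        Period ``N0`` (in trials) of a recognized stimulation pattern, if any.
    pattern_belief:
        Per-trial belief ``omega_P(n)`` in ``[0, 1]`` that the pattern is
        driving the stimulation; the bottom-up weight is ``1 - omega_P(n)``.
    contrast_updates_expectation:
        If True (default) the full response, contrast term included, feeds
        the stored expectation — the behaviour implied by the collapsed
        recursion ``y[n] = (1+K)x[n] + (alpha+K*alpha-K)y[n-1]``.  If False
        the contrast contribution is excluded from the stored expectation
        (a one-shot overshoot).
    enforce_stability:
        When False the |alpha| < 1 check is skipped, which permits numeric
        exploration of the unstable regime.
    """

    alpha: float
    K: float = 0.0
    filter_weights: Sequence[float] = (1.0,)
    pattern_period: Optional[int] = None
    pattern_belief: Optional[Sequence[float]] = None
    contrast_updates_expectation: bool = True
    enforce_stability: bool = True

    def __post_init__(self) -> None:
        if self.enforce_stability:
            _check_alpha(self.alpha)
        if not 0.0 <= self.K < 1.0:
            raise ConfigError(f"contrast coefficient K={self.K!r} must lie in [0, 1)")
        w = np.asarray(self.filter_weights, dtype=float)
        if w.ndim != 1 or w.size < 1 or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ConfigError("filter_weights must be a nonempty sequence of nonnegative finite numbers")
        object.__setattr__(self, "filter_weights", tuple(float(v) for v in w))
        if self.pattern_period is not None and self.pattern_period < 1:
            raise ConfigError(f"pattern_period={self.pattern_period!r} must be a positive integer")
        if self.pattern_belief is not None:
            b = np.asarray(self.pattern_belief, dtype=float)
            if np.any(b < 0) or np.any(b > 1):
                raise ConfigError("pattern_belief values must lie in [0, 1]")
            if np.any(b > 0) and self.pattern_period is None:
                raise ConfigError("pattern_belief > 0 requires a configured pattern_period")
            object.__setattr__(self, "pattern_belief", tuple(float(v) for v in b))

    @property
    def L(self) -> int:
        return len(self.filter_weights)

    def belief_at(self, trial: int) -> float:
        """Pattern belief ``omega_P`` at a 1-based trial index (0 if unset)."""
        if self.pattern_belief is None:
            return 0.0
        idx = min(trial - 1, len(self.pattern_belief) - 1)
        return self.pattern_belief[idx] if idx >= 0 else 0.0


@dataclass(frozen=True)
class StimulusSchedule:
    """Per-trial active intensities plus elicitation flags (1-based trials).

    ``expected[n]`` is False on trials where the UCS elicitation is neither
    signalled nor preceded by perception of the stimulus: no reactive
    response is triggered and the contrast overshoot applies to the full
    active intensity.  ``perceived`` marks whether the UCS is perceived
    before elicitation; in every scenario modelled here it coincides with
    ``expected`` and is carried as metadata.
    """

    x: Sequence[float]
    expected: Optional[Sequence[bool]] = None
    perceived: Optional[Sequence[bool]] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1 or x.size < 1:
            raise ConfigError("schedule must contain at least one trial")
        object.__setattr__(self, "x", tuple(float(v) for v in x))
        n = x.size
        for name in ("expected", "perceived"):
            flags = getattr(self, name)
            if flags is None:
                flags = (True,) * n
            else:
                flags = tuple(bool(v) for v in flags)
                if len(flags) != n:
                    raise ConfigError(f"{name} flags must match the number of trials")
            object.__setattr__(self, name, flags)

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def constant(cls, x: float, n_trials: int) -> "StimulusSchedule":
        if n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        return cls(x=(float(x),) * n_trials)


@dataclass
class TrialTrace:
    """Per-trial record of a discrete revaluation run (1-based trials)."""

    trial: np.ndarray
    x: np.ndarray
    y: np.ndarray
    i_R: np.ndarray
    e: np.ndarray
    e_A: np.ndarray
    y_expected: np.ndarray

    def __len__(self) -> int:
        return self.trial.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "x": self.x,
                "y": self.y,
                "i_R": self.i_R,
                "e": self.e,
                "e_A": self.e_A,
                "y_expected": self.y_expected,
            }
        )


def asymptotic_response(x: float, alpha: float) -> float:
    """Closed-form asymptote ``x / (1 - alpha)`` of the constant-input recursion."""
    _check_alpha(alpha)
    return x / (1.0 - alpha)


def devaluation_trajectory(y0: float, alpha: float, n: int) -> np.ndarray:
    """Geometric devaluation ``y0 * alpha**k`` for ``k = 0..n``.

    ``y0`` is the expected response at the start of the devaluation (zero
    active input thereafter); for ``0 < alpha < 1`` the sequence decays
    monotonically to zero.
    """
    _check_alpha(alpha)
    if n < 0:
        raise ConfigError("trial count n must be >= 0")
    return y0 * alpha ** np.arange(n + 1, dtype=float)


def unexpected_elicitation(
    x: float, K: float, prior_expected: Optional[float] = None
) -> tuple[float, float]:
    """Response and prediction error of an unsignalled UCS elicitation.

    The response is ``x + K*x`` (active intensity plus contrast overshoot on
    the full, unanticipated intensity).  A prediction error is computed only
    when the stored expectation differs from that response — hence a series
    of unexpected elicitations yields an error on the first one only.  Pass
    ``prior_expected`` to obtain that first-trial error (for an expectation
    ``x + alpha*x`` it equals ``x*(K - alpha)``); omit it for the steady
    repeated-elicitation case, which returns error zero.
    """
    if x < 0:
        raise ConfigError("active intensity x must be nonnegative")
    if not 0.0 <= K < 1.0:
        raise ConfigError(f"contrast coefficient K={K!r} must lie in [0, 1)")
    response = x + K * x
    error = 0.0 if prior_expected is None else response - float(prior_expected)
    return response, error


def predicted_response(
    history: Sequence[float],
    params: RevaluationParams,
    trial: Optional[int] = None,
    pattern_value: Optional[float] = None,
) -> float:
    """Expected response before a trial: filtered history blended with pattern.

    ``history`` lists past responses oldest-first (``history[-1]`` is the
    previous trial).  The bottom-up term is the weighted sum
    ``sum_k h_k * y[n-k]``; the top-down term is the stored pattern value
    ``y_P`` with weight ``omega_P``, the two weights summing to one.  When the
    pattern value is needed and not supplied it is read from the history one
    period back.
    """
    hist = np.asarray(history, dtype=float)
    if hist.ndim != 1 or hist.size < 1:
        raise ConfigError("history must contain at least one response")
    n = trial if trial is not None else hist.size + 1
    omega_p = params.belief_at(n)
    w = np.asarray(params.filter_weights, dtype=float)
    # h_1 pairs with the most recent outcome; truncate to available history.
    L = min(w.size, hist.size)
    bottom_up = float(np.dot(w[:L], hist[::-1][:L]))
    if omega_p == 0.0:
        return bottom_up
    if pattern_value is None:
        if params.pattern_period is None:
            raise ConfigError("pattern belief > 0 but no pattern configured")
        k = hist.size - params.pattern_period
        pattern_value = float(hist[k]) if k >= 0 else 0.0
    return (1.0 - omega_p) * bottom_up + omega_p * float(pattern_value)


def actual_error(x_n: float, params: RevaluationParams, predicted: float) -> float:
    """Same-trial (actual) error ``x_n + predicted * (alpha - 1)``.

    This is the discrepancy between the incoming outcome — active intensity
    plus the reactive contribution ``alpha * predicted`` — and the expected
    response; it drives the contrast overshoot in the same trial.
    """
    return x_n + predicted * (params.alpha - 1.0)


def simulate_revaluation(
    schedule: StimulusSchedule,
    params: RevaluationParams,
    initial_expected: float = 0.0,
) -> TrialTrace:
    """Trial-by-trial simulation of implicit UCS revaluation.

    On signalled (expected) trials the update is

        predicted = (1 - omega_P) * sum_k h_k y[n-k] + omega_P * y[n-N0]
        e_A[n]    = x[n] + predicted * (alpha - 1)
        y[n]      = x[n] + alpha * predicted + K * e_A[n]
        e[n]      = y[n] - predicted

    which collapses to ``y[n] = (1+K)x[n] + (alpha+K*alpha-K)y[n-1]`` for a
    last-outcome expectation.  Unexpected trials elicit ``x + K*x`` with no
    reactive component; the stored expectation is brought to that value so a
    repeated unexpected elicitation produces no further prediction error.

    ``initial_expected`` seeds the pre-run expectation (the virtual history),
    e.g. to start a devaluation from an already-learned response level.
    """
    if params.enforce_stability:
        _check_alpha(params.alpha)
    n_trials = len(schedule)
    alpha, K = params.alpha, params.K
    w = np.asarray(params.filter_weights, dtype=float)
    L = w.size

    x_arr = np.asarray(schedule.x, dtype=float)
    y = np.empty(n_trials)
    y_stored = np.empty(n_trials)  # values fed to the expectation history
    i_R = np.empty(n_trials)
    e = np.empty(n_trials)
    e_A = np.empty(n_trials)
    y_exp = np.empty(n_trials)

    def stored(idx: int) -> float:
        """Stored response of 0-based trial idx; pre-run trials hold the seed."""
        return y_stored[idx] if idx >= 0 else initial_expected

    for i in range(n_trials):
        xn = x_arr[i]
        filt = float(np.dot(w, [stored(i - 1 - k) for k in range(L)]))
        omega_p = params.belief_at(i + 1)
        if omega_p > 0.0 and params.pattern_period is None:
            raise ConfigError("pattern belief > 0 but no pattern configured")
        if omega_p > 0.0:
            pat = stored(i - params.pattern_period)
            predicted = (1.0 - omega_p) * filt + omega_p * pat
        else:
            predicted = filt
        y_exp[i] = predicted

        if schedule.expected[i]:
            e_A[i] = xn + predicted * (alpha - 1.0)
            i_R[i] = alpha * predicted
            y[i] = xn + i_R[i] + K * e_A[i]
            e[i] = y[i] - predicted
            y_stored[i] = y[i] if params.contrast_updates_expectation else y[i] - K * e_A[i]
        else:
            # Unsignalled elicitation: no reactive trigger, contrast on the
            # full intensity, expectation snaps to the experienced response.
            e_A[i] = xn
            i_R[i] = 0.0
            y[i] = xn + K * xn
            e[i] = y[i] - predicted
            y_stored[i] = y[i]

    return TrialTrace(
        trial=np.arange(1, n_trials + 1),
        x=x_arr,
        y=y,
        i_R=i_R,
        e=e,
        e_A=e_A,
        y_expected=y_exp,
    )
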