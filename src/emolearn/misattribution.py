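"""Reactive-source misattribution (evaluative conditioning) dynamics.

When a purely reactive response of intensity ``i_U`` — elicited by an
unrevealed or confusable source — is attributed to a neutral stimulus, that
stimulus becomes an independent reactive source.  On each further exposure
the stimulus triggers the attributed expectation, the still-present
unattributed response adds on top, and the resulting prediction error
inflates the attribution.  With full attribution per trial the response after
``n`` exposures is the geometric sum

    y[n] = i_U * (1 + alpha + alpha**2 + ... + alpha**(n-1))

which converges to ``i_U / (1 - alpha)``.  At that point the expected
response is purely reactive and coincides with the elicited one, so the
prediction error vanishes and the acquired response is resistant to
extinction: there is no active component whose removal could drive it down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, StabilityError, TraceError

__all__ = [
    "MisattributionConfig",
    "MisattributionTrace",
    "simulate_misattribution",
    "misattribution_asymptote",
    "inextinguishability_check",
]


@dataclass(frozen=True)
class MisattributionConfig:
    """Unattributed intensity, gain, per-trial attributed fraction, length.

    ``attribution_fraction`` (p) is the portion of each trial's prediction
    error that is credited to the misattributed stimulus; p = 1 reproduces
    the full-attribution geometric sum, smaller p slows convergence to the
    same ``i_U / (1 - alpha)`` ceiling.  The linear fractional law is the
    minimal choice consistent with partial statistical attribution.
    """

    i_U: float
    alpha: float
    attribution_fraction: float = 1.0
    n_trials: int = 100
    initial_expected: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.alpha) >= 1.0:
            raise StabilityError(f"alpha={self.alpha!r} violates |alpha| < 1")
        if not 0.0 <= self.attribution_fraction <= 1.0:
            raise ConfigError("attribution_fraction must lie in [0, 1]")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.i_U < 0:
            raise ConfigError("i_U must be nonnegative")


@dataclass
class MisattributionTrace:
    """Per-trial record; the response is purely reactive (x is always zero)."""

    trial: np.ndarray
    x: np.ndarray
    y: np.ndarray
    i_R: np.ndarray
    e: np.ndarray
    attributed_expectation: np.ndarray

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
                "attributed_expectation": self.attributed_expectation,
            }
        )


def misattribution_asymptote(i_U: float, alpha: float) -> float:
    """Ceiling ``i_U / (1 - alpha)`` of the cumulative misattribution."""
    if abs(alpha) >= 1.0:
        raise StabilityError(f"alpha={alpha!r} violates |alpha| < 1")
    return i_U / (1.0 - alpha)


def simulate_misattribution(config: MisattributionConfig) -> MisattributionTrace:
    """Accumulation of a purely reactive response onto a misattributed stimulus.

    Per trial, with attributed expectation ``E`` (seeded by
    ``initial_expected``):

        y = i_U + alpha * E          elicited response (all reactive)
        e = y - E                    prediction error
        E <- E + p * e               partial attribution of the error

    With p = 1 this is exactly the geometric-sum recursion
    ``y[n] = i_U + alpha * y[n-1]``; responses are non-decreasing and bounded
    by ``i_U / (1 - alpha)`` for any p.
    """
    n = config.n_trials
    alpha, i_U, p = config.alpha, config.i_U, config.attribution_fraction
    y = np.empty(n)
    e = np.empty(n)
    E_arr = np.empty(n)
    E = float(config.initial_expected)
    for i in range(n):
        E_arr[i] = E
        y[i] = i_U + alpha * E
        e[i] = y[i] - E
        E = E + p * e[i]
    return MisattributionTrace(
        trial=np.arange(1, n + 1),
        x=np.zeros(n),
        y=y,
        i_R=y.copy(),
        e=e,
        attributed_expectation=E_arr,
    )


def inextinguishability_check(trace, window: int = 50, tol: float = 1e-6) -> bool:
    """Certify a resistant-to-extinction state over the final ``window`` trials.

    True iff, over the last ``window`` entries, the prediction error and the
    active input are both below ``tol`` in magnitude while the reactive
    response stays above ``tol``.  Accepts any trace exposing ``x``, ``i_R``
    and ``e`` arrays (or a DataFrame with those columns).
    """
    if hasattr(trace, "to_frame") and not isinstance(trace, pd.DataFrame):
        frame = trace.to_frame()
    elif isinstance(trace, pd.DataFrame):
        frame = trace
    else:
        frame = pd.DataFrame({"x": trace.x, "i_R": trace.i_R, "e": trace.e})
    for col in ("x", "i_R", "e"):
        if col not in frame.columns:
            raise TraceError(f"trace lacks required field {col!r}")
    if len(frame) == 0:
        raise TraceError("empty trace")
    tail = frame.iloc[-min(window, len(frame)):]
    return bool(
        np.max(np.abs(tail["e"].to_numpy())) < tol
        and np.max(np.abs(tail["x"].to_numpy())) < tol
        and np.min(tail["i_R"].to_numpy()) > tol
    )
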