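"""Composite protocols built on the core models.

*Iterative climbing* alternates two unconditioned stimuli; while one is
actively delivered, the reactive response of the other is co-elicited (e.g.
by optical stimulation of its engram) and the whole response is misattributed
to the stimulated one.  Each phase therefore re-converges to

    y_phase = (x_target + i_R_partner) / (1 - alpha)

and hands the inflated reactive response ``alpha * y_phase`` to the next
phase.  With ``alpha = 0.5`` and equal intensities the phase-2 asymptote is
``6 x``; without a saturation cap the sequence ratchets upward without bound
for ``alpha >= 1/2``, while a cap on the expected response freezes both
reactive responses at ``alpha * sat_threshold`` and leaves a zero-error,
zero-input triggered response — the resistant-to-extinction certificate.

The *inextinguishable-input search* asks the complementary continuous-time
question: is there a stimulation waveform ``x(t)`` that leaves a nonzero
response with near-zero prediction error once the input has returned to
zero?  The search minimizes a weighted terminal-window objective over
piecewise-constant inputs; in the stable linear regime no such input exists
(the terminal response decays with the input), which the optimizer is built
to document rather than presume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, StabilityError
from .misattribution import inextinguishability_check
from .revaluation import RevaluationParams, StimulusSchedule, simulate_revaluation
from . import continuous as cont

__all__ = [
    "ClimbingConfig",
    "ClimbingResult",
    "iterative_climbing",
    "probe_extinction",
    "SearchConfig",
    "SearchResult",
    "search_inextinguishable_input",
]


@dataclass(frozen=True)
class ClimbingConfig:
    """Two UCS intensities, gain, number of alternating phases, optional cap.

    ``trials_per_phase=None`` runs each phase to its asymptote (per-trial
    change below ``convergence_tol`` or 10_000 trials, whichever first).
    ``sat_threshold`` caps the stored expected response of either UCS.
    """

    x1: float
    x2: float
    alpha: float
    phases: int = 2
    trials_per_phase: Optional[int] = None
    sat_threshold: Optional[float] = None
    convergence_tol: float = 1e-8
    max_trials: int = 10_000

    def __post_init__(self) -> None:
        if abs(self.alpha) >= 1.0:
            raise StabilityError(f"alpha={self.alpha!r} violates |alpha| < 1")
        if self.phases < 1:
            raise ConfigError("phases must be >= 1")
        if self.trials_per_phase is not None and self.trials_per_phase < 1:
            raise ConfigError("trials_per_phase must be >= 1")
        if self.sat_threshold is not None and self.sat_threshold <= 0:
            raise ConfigError("sat_threshold must be positive")


@dataclass
class ClimbingResult:
    """Per-phase asymptotes and the reactive responses they leave behind."""

    phase: np.ndarray
    target: np.ndarray  # 1 or 2: which UCS is actively stimulated
    asymptote: np.ndarray
    i_R1: np.ndarray  # after the phase
    i_R2: np.ndarray
    saturated: np.ndarray
    config: ClimbingConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phase": self.phase,
                "target": self.target,
                "asymptote": self.asymptote,
                "i_R1": self.i_R1,
                "i_R2": self.i_R2,
                "saturated": self.saturated,
            }
        )


def _phase_asymptote_closed_form(
    x_t: float, i_R_partner: float, alpha: float, sat: Optional[float]
) -> tuple[float, float, bool]:
    """(asymptote, new target i_R, saturated?) for one phase."""
    inp = x_t + i_R_partner
    expected = inp / (1.0 - alpha)
    saturated = sat is not None and expected >= sat
    if saturated:
        expected = sat
    i_R_new = alpha * expected
    return inp + i_R_new, i_R_new, saturated


def _phase_asymptote_simulated(
    x_t: float, i_R_partner: float, i_R_target: float, cfg: ClimbingConfig
) -> tuple[float, float, bool]:
    """Trial-level phase run via the revaluation recursion.

    The partner's reactive response is injected (and misattributed) on every
    trial, so the constant per-trial input is ``x_t + i_R_partner`` and the
    starting expectation is the target's pre-phase expected response
    ``i_R_target / alpha``.
    """
    alpha, sat = cfg.alpha, cfg.sat_threshold
    inp = x_t + i_R_partner
    E = i_R_target / alpha if alpha != 0 else 0.0
    n_max = cfg.trials_per_phase or cfg.max_trials
    y_prev = None
    saturated = False
    if sat is None:
        # Pure revaluation recursion: delegate to the discrete module.
        params = RevaluationParams(alpha=alpha)
        n = cfg.trials_per_phase or cfg.max_trials
        trace = simulate_revaluation(
            StimulusSchedule.constant(inp, n), params, initial_expected=E
        )
        if cfg.trials_per_phase is None:
            dy = np.abs(np.diff(trace.y))
            small = np.nonzero(dy < cfg.convergence_tol)[0]
            idx = int(small[0]) + 1 if small.size else n - 1
            y_final = float(trace.y[idx])
        else:
            y_final = float(trace.y[-1])
        E_final = y_final  # last-outcome expectation
        return y_final, alpha * E_final, False
    for _ in range(n_max):
        E_eff = min(E, sat)
        y = inp + alpha * E_eff
        if E < sat:
            E = y  # expectation tracks the outcome (stored value capped below)
        saturated = saturated or E >= sat
        E = min(E, sat)
        if y_prev is not None and abs(y - y_prev) < cfg.convergence_tol and cfg.trials_per_phase is None:
            y_prev = y
            break
        y_prev = y
    return float(y_prev), alpha * min(E, sat), saturated


def iterative_climbing(
    config: ClimbingConfig, method: str = "closed_form"
) -> ClimbingResult:
    """Run the alternating misattribution protocol phase by phase.

    Reactive responses start at the single-UCS asymptotic values
    ``alpha * x_i / (1 - alpha)``.  Odd phases stimulate UCS1 (injecting
    ``i_R2``), even phases UCS2.  ``method`` selects the closed-form phase
    asymptote or the trial-level co-simulation; the two agree to the
    convergence tolerance.
    """
    if method not in ("closed_form", "simulate"):
        raise ConfigError(f"unknown method {method!r}")
    cfg = config
    a = cfg.alpha
    i_R = {1: a * cfg.x1 / (1.0 - a), 2: a * cfg.x2 / (1.0 - a)}
    x = {1: cfg.x1, 2: cfg.x2}

    rows = []
    for j in range(1, cfg.phases + 1):
        target = 1 if j % 2 == 1 else 2
        partner = 2 if target == 1 else 1
        if method == "closed_form":
            y_inf, i_R_new, saturated = _phase_asymptote_closed_form(
                x[target], i_R[partner], a, cfg.sat_threshold
            )
        else:
            y_inf, i_R_new, saturated = _phase_asymptote_simulated(
                x[target], i_R[partner], i_R[target], cfg
            )
        i_R[target] = i_R_new
        rows.append((j, target, y_inf, i_R[1], i_R[2], saturated))

    arr = np.array(rows, dtype=float)
    return ClimbingResult(
        phase=arr[:, 0].astype(int),
        target=arr[:, 1].astype(int),
        asymptote=arr[:, 2],
        i_R1=arr[:, 3],
        i_R2=arr[:, 4],
        saturated=arr[:, 5].astype(bool),
        config=cfg,
    )


def probe_extinction(
    result: ClimbingResult, n_probes: int = 50, tol: float = 1e-6
) -> bool:
    """Zero-active-input probe trials after a climbing run.

    The last stimulated UCS is presented without any active stimulation.  If
    its expected response sits at the saturation cap, the prediction error is
    clamped to zero and every probe elicits the undiminished reactive
    response; otherwise the probes devalue the expectation geometrically.
    Returns the resistant-to-extinction certificate over ``n_probes`` trials.
    """
    cfg = result.config
    a = cfg.alpha
    target = int(result.target[-1]) if len(result.phase) else 1
    i_R_final = float((result.i_R1 if target == 1 else result.i_R2)[-1])
    E = i_R_final / a if a != 0 else 0.0
    sat = cfg.sat_threshold

    x = np.zeros(n_probes)
    i_R = np.empty(n_probes)
    e = np.empty(n_probes)
    for i in range(n_probes):
        at_cap = sat is not None and E >= sat
        y = a * (min(E, sat) if sat is not None else E)
        i_R[i] = y
        if at_cap:
            e[i] = 0.0  # expected response coincides with the triggered one
        else:
            e[i] = y - E
            E = y
    frame = pd.DataFrame({"x": x, "i_R": i_R, "e": e})
    return inextinguishability_check(frame, window=n_probes, tol=tol)


@dataclass(frozen=True)
class SearchConfig:
    """Setup of the resistant-to-extinction input search.

    The input is piecewise constant over ``n_segments`` equal segments of
    ``[0, horizon]``; the objective is evaluated over the trailing
    ``terminal_window`` seconds:

        J = -w_response * mean(y) + w_error * mean(|e|) + w_input * mean(|x|)

    i.e. reward a surviving response, penalize residual prediction error and
    residual input.
    """

    horizon: float = 30.0
    terminal_window: float = 6.0
    n_segments: int = 40
    input_bounds: tuple[float, float] = (0.0, 5.0)
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    max_iterations: int = 40
    popsize: int = 12

    def __post_init__(self) -> None:
        if not self.horizon > self.terminal_window > 0:
            raise ConfigError("need horizon > terminal_window > 0")
        if self.n_segments < 1:
            raise ConfigError("n_segments must be >= 1")
        lo, hi = self.input_bounds
        if hi < lo:
            raise ConfigError("input_bounds must be (low, high) with high >= low")


@dataclass
class SearchResult:
    """Optimized input, objective value and terminal-window diagnostics."""

    segment_times: np.ndarray
    segment_values: np.ndarray
    objective: float
    response_term: float
    error_term: float
    input_term: float
    converged: bool
    inextinguishable: bool
    trace: "cont.ContinuousTrace"


def _segments_to_waveform(values: np.ndarray, horizon: float):
    edges = np.linspace(0.0, horizon, len(values) + 1)

    def wave(t: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(edges, np.atleast_1d(t), side="right") - 1,
                      0, len(values) - 1)
        out = np.asarray(values, dtype=float)[idx]
        return out

    return wave


def search_inextinguishable_input(
    search: SearchConfig, model: "cont.ContinuousConfig"
) -> SearchResult:
    """Numerically search for an input pattern leaving a self-sustained response.

    Derivative-free global search (differential evolution, seeded and hence
    reproducible) over piecewise-constant inputs; non-convergence is reported
    through ``converged`` with the best candidate still returned.  Any
    returned solution is additionally screened with the
    resistant-to-extinction certificate on its terminal window.
    """
    from scipy.optimize import differential_evolution

    cfg = model if model.sat_threshold is not None else cont.ContinuousConfig(
        alpha=model.alpha, K=model.K, tau1=model.tau1, tau2=model.tau2,
        T=model.T, sat_threshold=np.inf, dt=model.dt, sat_kind=model.sat_kind,
    )
    w0, w1, w2 = search.weights

    def run(values: np.ndarray) -> "cont.ContinuousTrace":
        wave = _segments_to_waveform(values, search.horizon)
        return cont.simulate_saturating(None, wave, cfg, horizon=search.horizon)

    def terms(trace: "cont.ContinuousTrace") -> tuple[float, float, float]:
        mask = trace.t >= search.horizon - search.terminal_window
        return (
            float(np.mean(trace.y[mask])),
            float(np.mean(np.abs(trace.e[mask]))),
            float(np.mean(np.abs(trace.x[mask]))),
        )

    def objective(values: np.ndarray) -> float:
        yt, et, xt = terms(run(values))
        return -w0 * yt + w1 * et + w2 * xt

    lo, hi = search.input_bounds
    bounds = [(lo, hi)] * search.n_segments
    if hi == lo:
        values = np.full(search.n_segments, lo)
        converged = True
    else:
        res = differential_evolution(
            objective, bounds, seed=search.seed, maxiter=search.max_iterations,
            popsize=search.popsize, polish=False, tol=1e-8, init="sobol",
        )
        values, converged = np.asarray(res.x), bool(res.success)
    trace = run(values)
    yt, et, xt = terms(trace)
    mask = trace.t >= search.horizon - search.terminal_window
    tail = pd.DataFrame({"x": trace.x[mask], "i_R": trace.i_R[mask], "e": trace.e[mask]})
    flag = inextinguishability_check(tail, window=int(mask.sum()), tol=1e-3)
    edges = np.linspace(0.0, search.horizon, search.n_segments + 1)[:-1]
    return SearchResult(
        segment_times=edges,
        segment_values=values,
        objective=-w0 * yt + w1 * et + w2 * xt,
        response_term=yt,
        error_term=et,
        input_term=xt,
        converged=converged,
        inextinguishable=flag,
        trace=trace,
    )
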