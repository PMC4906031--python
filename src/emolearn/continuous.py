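"""Continuous-time emotional tracking dynamics with amygdala saturation.

The discrete revaluation recursion, sampled at the sensory time-discrimination
threshold ``T`` and mapped to continuous time through the bilinear transform,
yields the second-order transfer function

    H(s) = Y(s)/X(s)
         = (K*tau2*s**2 + (K+tau2)*s + 1)
           / (tau1*(tau2+K-K*alpha)*s**2
              + (tau2+K-K*alpha+tau1-alpha*tau1)*s + (1-alpha))

whose DC gain ``1/(1-alpha)`` reproduces the discrete asymptote.  ``tau1`` is
the low-pass time constant of the stimulated population, ``tau2`` that of the
evaluation (moving-average) filter.

Saturation cannot live inside a linear transfer function, so the nonlinear
simulator uses an explicit state realization:

    x1:  input low-pass            tau1 * dx1/dt = x - x1
    y2:  evaluation low-pass       tau2 * dy2/dt = y - y2
    P:   amygdala expected response, driven by the tracking prediction error
         (y2 - P)/T while P is below the saturation threshold T_S, plus any
         injected error spikes (inferred prediction errors arrive as short
         pulses; a sustained signal into this integrating node grows without
         bound, which is why spike-form transmission matters)

    i_R = alpha * sat(P)           sat = hard clip at T_S (tanh optional)
    y   = x1 + i_R + K * e_A,      e_A = (x1 + i_R) - y2

Above threshold the expected response delivered downstream is the saturated
value, which coincides with the triggered reactive response: the tracking
error is no longer computed there, so moderate negative (safe-context) spikes
lower ``P`` without touching the output until ``P`` re-enters the linear zone.
This is what makes a saturated trauma acquisition resistant to extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigError, FitError, StabilityError, TraceError
from .revaluation import TrialTrace

__all__ = [
    "ContinuousConfig",
    "ErrorSpikeTrain",
    "ContinuousTrace",
    "transfer_function",
    "simulate_lti",
    "bilinear_discretize",
    "inverse_bilinear",
    "simulate_saturating",
    "scenario_figure6",
    "error_path_analysis",
    "ErrorPathReport",
    "fit_parameters",
    "FitResult",
]

WaveformLike = Union[Callable[[np.ndarray], np.ndarray], tuple, float]


@dataclass(frozen=True)
class ContinuousConfig:
    """Parameters of the continuous-time model.

    ``T`` is the sensory time-discrimination threshold used as the sampling
    interval of the underlying discrete model and as the gain of the
    error-integrating accumulator; ``sat_threshold`` (T_S) caps the amygdala
    expected response; ``dt`` is the fixed integration step (defaults to
    ``min(tau1, tau2, T)/20``).
    """

    alpha: float
    K: float = 0.0
    tau1: float = 1.0
    tau2: float = 1.0
    T: float = 0.1
    sat_threshold: Optional[float] = None
    dt: Optional[float] = None
    sat_kind: str = "hard"

    def __post_init__(self) -> None:
        if abs(self.alpha) >= 1.0:
            raise StabilityError(f"alpha={self.alpha!r} violates |alpha| < 1")
        for name in ("tau1", "tau2", "T"):
            v = getattr(self, name)
            if v <= 0:
                raise ConfigError(f"{name}={v!r} must be positive")
        if self.dt is not None:
            if self.dt <= 0:
                raise ConfigError("dt must be positive")
            if self.dt > min(self.tau1, self.tau2) / 20.0:
                raise ConfigError("dt too large: must be <= min(tau1, tau2)/20")
        if self.sat_threshold is not None and self.sat_threshold <= 0:
            raise ConfigError("sat_threshold must be positive")
        if self.sat_kind not in ("hard", "tanh"):
            raise ConfigError(f"unknown sat_kind {self.sat_kind!r}")

    def step(self) -> float:
        return self.dt if self.dt is not None else min(self.tau1, self.tau2, self.T) / 20.0


@dataclass(frozen=True)
class ErrorSpikeTrain:
    """Timed rectangular error pulses injected at the prediction-error node.

    Each event is ``(time, amplitude, width)``; the injected mass (increment
    of the amygdala expected response) is ``amplitude * width``.  Negative
    amplitudes model inhibitory (deflationary) errors, e.g. from a safe
    context.
    """

    events: Sequence[tuple[float, float, float]] = ()

    def __post_init__(self) -> None:
        ev = tuple((float(t), float(a), float(w)) for t, a, w in self.events)
        if any(w <= 0 for _, _, w in ev):
            raise ConfigError("spike widths must be positive")
        if list(t for t, _, _ in ev) != sorted(t for t, _, _ in ev):
            raise ConfigError("spike events must be time-sorted")
        object.__setattr__(self, "events", ev)

    def min_width(self) -> Optional[float]:
        return min((w for _, _, w in self.events), default=None)

    def rate(self, t: float) -> float:
        """Injection rate at time t (sum of active pulse amplitudes)."""
        total = 0.0
        for t0, a, w in self.events:
            if t0 <= t < t0 + w:
                total += a
        return total

    def total_mass(self) -> float:
        return sum(a * w for _, a, w in self.events)


@dataclass
class ContinuousTrace:
    """Time-gridded record of a continuous-time run."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    i_R: np.ndarray
    e: np.ndarray
    P: np.ndarray
    P_ofc: np.ndarray

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.t,
                "x": self.x,
                "y": self.y,
                "i_R": self.i_R,
                "e": self.e,
                "P": self.P,
                "P_ofc": self.P_ofc,
            }
        )


def _as_callable(x_waveform: WaveformLike) -> Callable[[np.ndarray], np.ndarray]:
    if callable(x_waveform):
        return x_waveform
    if isinstance(x_waveform, tuple) and len(x_waveform) == 2:
        tt = np.asarray(x_waveform[0], dtype=float)
        xx = np.asarray(x_waveform[1], dtype=float)
        return lambda t: np.interp(t, tt, xx, left=xx[0], right=xx[-1])
    if np.isscalar(x_waveform):
        val = float(x_waveform)
        return lambda t: np.full_like(np.asarray(t, dtype=float), val)
    raise ConfigError("x_waveform must be a callable, a (t, x) pair or a scalar")


def transfer_function(config: ContinuousConfig) -> tuple[np.ndarray, np.ndarray]:
    """Numerator/denominator of H(s) in descending powers of s."""
    a, K, t1, t2 = config.alpha, config.K, config.tau1, config.tau2
    num = np.array([K * t2, K + t2, 1.0])
    den = np.array([t1 * (t2 + K - K * a), t2 + K - K * a + t1 - a * t1, 1.0 - a])
    if abs(den[-1]) < 1e-15:
        raise ConfigError("degenerate denominator: alpha = 1")
    return num, den


def simulate_lti(
    x_waveform: WaveformLike,
    config: ContinuousConfig,
    horizon: float = 60.0,
) -> ContinuousTrace:
    """Linear response of the transfer-function model from rest.

    A step input of amplitude ``x`` converges to ``x / (1 - alpha)`` (final
    value theorem), matching the discrete asymptote.  Fields without a
    meaning in the linear run (``i_R``, ``e``, ``P``, ``P_ofc``) are NaN.
    """
    num, den = transfer_function(config)
    num = np.trim_zeros(num, "f")  # K = 0 zeroes the leading coefficient
    dt = config.step()
    t = np.arange(0.0, horizon + dt / 2, dt)
    x = np.asarray(_as_callable(x_waveform)(t), dtype=float)
    _, y, _ = signal.lsim((num, den), U=x, T=t)
    nan = np.full_like(t, np.nan)
    return ContinuousTrace(t=t, x=x, y=np.asarray(y), i_R=nan.copy(), e=nan.copy(),
                           P=nan.copy(), P_ofc=nan.copy())


def _mobius_substitute(
    coeffs: np.ndarray, total_degree: int, a: float, b: float, c: float, d: float
) -> np.ndarray:
    """Coefficients of ``p((a*u+b)/(c*u+d)) * (c*u+d)**total_degree``.

    ``coeffs`` are descending; ``total_degree >= deg(p)`` controls the common
    clearing factor so numerator and denominator stay consistent.
    """
    deg = len(coeffs) - 1
    out = np.zeros(1)
    for i, ci in enumerate(coeffs):
        p = np.array([1.0])
        for _ in range(deg - i):
            p = np.polymul(p, [a, b])
        for _ in range(total_degree - (deg - i)):
            p = np.polymul(p, [c, d])
        out = np.polyadd(out, float(ci) * p)
    return out


def bilinear_discretize(
    tf: tuple[np.ndarray, np.ndarray], T: float
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete filter H(z) from H(s) via ``s = (2/T)(z-1)/(z+1)``.

    The map sends s = 0 to z = 1, so the DC gain is preserved exactly.
    Coefficients are descending in z, normalized to a unit leading
    denominator coefficient.
    """
    if T <= 0:
        raise ConfigError("sampling interval T must be positive")
    num, den = (np.asarray(v, dtype=float) for v in tf)
    D = max(len(num), len(den)) - 1
    a, b, c, d = 2.0 / T, -2.0 / T, 1.0, 1.0
    num_z = _mobius_substitute(num, D, a, b, c, d)
    den_z = _mobius_substitute(den, D, a, b, c, d)
    if abs(den_z[0]) < 1e-300:
        raise ConfigError("bilinear mapping produced a degenerate denominator")
    return num_z / den_z[0], den_z / den_z[0]


def inverse_bilinear(
    tf_z: tuple[np.ndarray, np.ndarray], T: float
) -> tuple[np.ndarray, np.ndarray]:
    """Recover H(s) from H(z) via ``z = (1 + s*T/2)/(1 - s*T/2)``."""
    if T <= 0:
        raise ConfigError("sampling interval T must be positive")
    num, den = (np.asarray(v, dtype=float) for v in tf_z)
    D = max(len(num), len(den)) - 1
    a, b, c, d = T / 2.0, 1.0, -T / 2.0, 1.0
    num_s = _mobius_substitute(num, D, a, b, c, d)
    den_s = _mobius_substitute(den, D, a, b, c, d)
    if abs(den_s[0]) < 1e-300:
        raise ConfigError("inverse bilinear mapping is singular for this filter")
    return num_s / den_s[0], den_s / den_s[0]


def simulate_saturating(
    error_train: Optional[ErrorSpikeTrain],
    x_waveform: WaveformLike,
    config: ContinuousConfig,
    horizon: float = 60.0,
    loop_tracking: bool = True,
    initial_P: float = 0.0,
    p_ofc: Optional[Callable[[float], float]] = None,
) -> ContinuousTrace:
    """Nonlinear simulation with error-spike injection and amygdala saturation.

    Fixed-step 4th-order Runge–Kutta over the states ``(x1, y2, P)``; the
    step resolves the narrowest spike.  ``loop_tracking=False`` disconnects
    the internal tracking error, leaving ``P`` a raw accumulator of injected
    spikes.  ``p_ofc`` optionally records the conscious (OFC) expectation
    trajectory alongside the states; it does not enter the dynamics.

    Behaviour at the threshold: while ``P >= T_S`` the output is clamped at
    ``alpha * T_S`` and the tracking error is not computed, so negative
    injected spikes lower ``P`` (possibly back into the linear zone) without
    reducing the output until they exceed the accumulated degree of
    saturation.  ``P`` is kept nonnegative.
    """
    if config.sat_threshold is None:
        raise ConfigError("simulate_saturating requires sat_threshold (use inf for none)")
    train = error_train if error_train is not None else ErrorSpikeTrain()
    xfun = _as_callable(x_waveform)
    alpha, K, t1, t2, T = config.alpha, config.K, config.tau1, config.tau2, config.T
    Ts = float(config.sat_threshold)

    dt = config.step()
    wmin = train.min_width()
    if wmin is not None:
        dt = min(dt, wmin / 10.0)
    n_steps = int(np.ceil(horizon / dt))
    t_grid = np.arange(n_steps + 1) * dt

    if config.sat_kind == "hard":
        def sat(P: float) -> float:
            return P if P < Ts else Ts
    else:
        def sat(P: float) -> float:
            return Ts * np.tanh(P / Ts) if np.isfinite(Ts) else P

    # Input and injection rate are sampled once on the half-step grid so the
    # RK4 stages run on plain scalars.
    half_t = np.arange(2 * n_steps + 1) * (dt / 2.0)
    x_half = np.asarray(xfun(half_t), dtype=float)
    rate_half = np.array([train.rate(float(tv)) for tv in half_t])

    def deriv(j: int, x1: float, y2: float, P: float):
        i_R = alpha * sat(P)
        y = (1.0 + K) * (x1 + i_R) - K * y2
        dx1 = (x_half[j] - x1) / t1
        dy2 = (y - y2) / t2
        dP = rate_half[j]
        if loop_tracking and P <= Ts:
            dP += (y2 - P) / T
        return dx1, dy2, dP

    states = np.empty((n_steps + 1, 3))
    states[0] = [0.0, 0.0, initial_P]
    x1, y2, P = 0.0, 0.0, float(initial_P)
    h2, h6 = dt / 2.0, dt / 6.0
    for i in range(n_steps):
        j = 2 * i
        a1, b1, c1 = deriv(j, x1, y2, P)
        a2, b2, c2 = deriv(j + 1, x1 + h2 * a1, y2 + h2 * b1, P + h2 * c1)
        a3, b3, c3 = deriv(j + 1, x1 + h2 * a2, y2 + h2 * b2, P + h2 * c2)
        a4, b4, c4 = deriv(j + 2, x1 + dt * a3, y2 + dt * b3, P + dt * c3)
        x1 += h6 * (a1 + 2 * a2 + 2 * a3 + a4)
        y2 += h6 * (b1 + 2 * b2 + 2 * b3 + b4)
        P += h6 * (c1 + 2 * c2 + 2 * c3 + c4)
        if P < 0.0:
            P = 0.0
        states[i + 1] = (x1, y2, P)

    x1_a, y2_a, P_a = states[:, 0], states[:, 1], states[:, 2]
    sat_P = np.minimum(P_a, Ts) if config.sat_kind == "hard" else (
        Ts * np.tanh(P_a / Ts) if np.isfinite(Ts) else P_a
    )
    i_R = alpha * sat_P
    y = (1.0 + K) * (x1_a + i_R) - K * y2_a
    e = np.where(P_a <= Ts, y2_a - P_a, 0.0)
    x_in = np.asarray(xfun(t_grid), dtype=float)
    ofc = (
        np.array([float(p_ofc(tv)) for tv in t_grid])
        if p_ofc is not None
        else np.full_like(t_grid, np.nan)
    )
    return ContinuousTrace(t=t_grid, x=x_in, y=y, i_R=i_R, e=e, P=P_a, P_ofc=ofc)


# -- worked trauma/stress scenarios ------------------------------------------

_FIG6_PANELS = ("A1", "A2", "B1", "B2")


def _inference_train(
    prior: float,
    inferred: float,
    start: float = 1.0,
    spacing: float = 0.5,
    n_spikes: int = 10,
    gain: float = 12.0,
    ofc_rate: float = 0.4,
    width: float = 0.05,
) -> tuple[ErrorSpikeTrain, Callable[[float], float]]:
    """Positive error-spike train closing an inferred-vs-expected gap.

    Each presentation sends a pulse whose mass is ``gain`` times the current
    gap between the inferred outcome and the conscious (OFC) expectation;
    the expectation is revised toward the inferred outcome by a fraction
    ``ofc_rate`` per presentation, so the masses shrink geometrically.  The
    gain reflects the integrating action of the error pathway (repeated
    inferred errors accumulate far beyond the nominal gap).
    """
    events = []
    ofc_times = [0.0]
    ofc_vals = [prior]
    expectation = prior
    for k in range(n_spikes):
        t0 = start + k * spacing
        gap = inferred - expectation
        events.append((t0, gain * gap / width, width))
        expectation += ofc_rate * gap
        ofc_times.append(t0 + width)
        ofc_vals.append(expectation)

    def ofc(tv: float) -> float:
        return float(np.interp(tv, ofc_times, ofc_vals))

    return ErrorSpikeTrain(events=events), ofc


def _safe_context_train(
    start: float, spacing: float = 0.5, n_spikes: int = 10,
    mass: float = 5.0, width: float = 0.05,
) -> ErrorSpikeTrain:
    """Inhibitory spikes from re-exposure in a safe context (deflation)."""
    return ErrorSpikeTrain(
        events=[(start + k * spacing, -mass / width, width) for k in range(n_spikes)]
    )


def scenario_figure6(
    panel: str, config: Optional[ContinuousConfig] = None
) -> ContinuousTrace:
    """Four canonical regimes of inference-driven emotional (de)valuation.

    A1: stressful acquisition — the subject consciously expects a negative
        outcome of 8 and infers 10; the small inferred errors never saturate
        the amygdala.
    A2: A1 followed by safe-context re-exposure; the inhibitory errors
        devalue the response toward zero.
    B1: traumatic acquisition — conscious expectation 1 against an inferred
        outcome of 10; the accumulated errors drive the expected response
        past the saturation threshold, clamping the reactive response at
        ``alpha * T_S`` (60 with the default parameters).
    B2: B1 followed by the same safe-context exposure; the inhibition is
        smaller than the accumulated degree of saturation, so the clamped
        response does not move.

    Default parameters: ``alpha=0.4``, ``K=0.5``, ``tau1=tau2=T=2 s`` (a
    single time constant governs filtering and sampling), saturation of the
    amygdala expected response at 150, no active stimulation (the drive is
    purely inferential).
    """
    if panel not in _FIG6_PANELS:
        raise ConfigError(f"unknown panel {panel!r}; choose one of {_FIG6_PANELS}")
    cfg = config or ContinuousConfig(
        alpha=0.4, K=0.5, tau1=2.0, tau2=2.0, T=2.0, sat_threshold=150.0
    )
    traumatic = panel.startswith("B")
    prior = 1.0 if traumatic else 8.0
    acq_train, ofc = _inference_train(prior=prior, inferred=10.0)
    if panel in ("A1", "B1"):
        return simulate_saturating(
            acq_train, 0.0, cfg, horizon=12.0, initial_P=prior, p_ofc=ofc
        )
    safe = _safe_context_train(start=13.0)
    events = list(acq_train.events) + list(safe.events)
    return simulate_saturating(
        ErrorSpikeTrain(events=events), 0.0, cfg, horizon=24.0,
        initial_P=prior, p_ofc=ofc,
    )


@dataclass
class ErrorPathReport:
    """Poles and boundedness of the error-injection-to-output path."""

    poles_full_loop: np.ndarray
    bounded_full_loop: bool
    poles_raw_accumulator: np.ndarray
    bounded_raw_accumulator: bool
    final_output_full_loop: float
    final_output_raw_accumulator: float
    horizon: float


def error_path_analysis(
    config: ContinuousConfig, horizon: float = 100.0
) -> ErrorPathReport:
    """Poles and boundedness of the path from injected error to output.

    The raw accumulator (tracking loop disconnected) is a pure integrator:
    a pole at the origin, so a sustained error input grows without bound —
    the reason inferred errors are transmitted as short spikes.  In this
    realization the closed tracking loop relocates that pole into the left
    half plane for ``|alpha| < 1``, so the full-loop path is bounded; the
    numerical verdicts for both modes are reported alongside the poles.
    """
    a, K, t2, T = config.alpha, config.K, config.tau2, config.T
    A_full = np.array([[-(1.0 + K) / t2, (1.0 + K) * a / t2], [1.0 / T, -1.0 / T]])
    poles_full = np.linalg.eigvals(A_full)
    poles_raw = np.array([-(1.0 + K) / t2, 0.0])

    cfg = config if config.sat_threshold is not None else ContinuousConfig(
        alpha=a, K=K, tau1=config.tau1, tau2=t2, T=T,
        sat_threshold=np.inf, dt=config.dt, sat_kind=config.sat_kind,
    )
    sustained = ErrorSpikeTrain(events=[(0.0, 1.0, horizon)])
    tr_full = simulate_saturating(sustained, 0.0, cfg, horizon=horizon)
    tr_raw = simulate_saturating(
        sustained, 0.0, cfg, horizon=horizon, loop_tracking=False
    )
    # Bounded if the trajectory has stopped growing over the final quarter.
    def settled(tr: ContinuousTrace) -> bool:
        q = len(tr) // 4
        tail, prev = np.abs(tr.y[-q:]), np.abs(tr.y[-2 * q:-q])
        return float(tail.max()) <= float(prev.max()) * 1.01 + 1e-12

    return ErrorPathReport(
        poles_full_loop=poles_full,
        bounded_full_loop=settled(tr_full),
        poles_raw_accumulator=poles_raw,
        bounded_raw_accumulator=settled(tr_raw),
        final_output_full_loop=float(tr_full.y[-1]),
        final_output_raw_accumulator=float(tr_raw.y[-1]),
        horizon=horizon,
    )


@dataclass
class FitResult:
    """Least-squares parameter estimates from a known-input trace."""

    alpha: float
    K: float
    tau2: Optional[float]
    residual_rms: float


def fit_parameters(
    trace: Union[ContinuousTrace, TrialTrace],
    tau1: Optional[float] = None,
) -> FitResult:
    """Recover ``(alpha, K, tau2)`` from a self-generated known-input trace.

    For a continuous trace the transfer-function response is fitted by
    nonlinear least squares (``tau1`` must be supplied; it is tied to the
    sensory threshold and assumed known).  For a discrete trial trace the
    collapsed recursion ``y[n] = (1+K)x[n] + (alpha+K*alpha-K)y[n-1]`` is a
    linear regression, solved in closed form; ``tau2`` is not identifiable
    there and is returned as None.
    """
    if isinstance(trace, TrialTrace):
        x, y = np.asarray(trace.x, float), np.asarray(trace.y, float)
        if len(y) < 3 or np.max(np.abs(x)) < 1e-12:
            raise FitError("insufficient excitation in trial trace")
        A = np.column_stack([x[1:], y[:-1]])
        if np.linalg.matrix_rank(A) < 2:
            raise FitError("ill-posed fit: degenerate regressors")
        coef, res, *_ = np.linalg.lstsq(A, y[1:], rcond=None)
        a_hat, b_hat = coef
        K_est = a_hat - 1.0
        alpha_est = (b_hat + K_est) / (1.0 + K_est)
        pred = A @ coef
        rms = float(np.sqrt(np.mean((pred - y[1:]) ** 2)))
        return FitResult(alpha=float(alpha_est), K=float(K_est), tau2=None,
                         residual_rms=rms)

    if tau1 is None:
        raise ConfigError("fitting a continuous trace requires the known tau1")
    t = np.asarray(trace.t, float)
    x = np.asarray(trace.x, float)
    y = np.asarray(trace.y, float)
    if np.max(np.abs(x)) < 1e-12:
        raise FitError("insufficient excitation: input is identically zero")

    from scipy.optimize import least_squares

    def model(theta: np.ndarray) -> np.ndarray:
        alpha, K, tau2 = theta
        cfg = ContinuousConfig(alpha=alpha, K=K, tau1=tau1, tau2=tau2,
                               dt=min(tau1, tau2) / 20.0)
        num, den = transfer_function(cfg)
        _, ym, _ = signal.lsim((np.trim_zeros(num, "f"), den), U=x, T=t)
        return np.asarray(ym)

    tail = max(len(y) // 10, 1)
    x_end, y_end = np.mean(x[-tail:]), np.mean(y[-tail:])
    alpha0 = 1.0 - x_end / y_end if abs(y_end) > 1e-9 else 0.5
    alpha0 = float(np.clip(alpha0, 0.05, 0.9))
    theta0 = np.array([alpha0, 0.25, max((t[-1] - t[0]) / 10.0, 0.1)])
    sol = least_squares(
        lambda th: model(th) - y,
        theta0,
        bounds=([1e-3, 0.0, 1e-3], [0.99, 0.99, 1e3]),
        xtol=1e-12, ftol=1e-12,
    )
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return FitResult(alpha=float(sol.x[0]), K=float(sol.x[1]),
                     tau2=float(sol.x[2]), residual_rms=rms)
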