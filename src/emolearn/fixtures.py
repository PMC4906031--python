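"""Deterministic schedule and waveform generators.

Every module in the package is testable without external data: the
generators here emit the canonical stimulation scenarios — constant and
staircase intensities, periodic Gaussian-bump patterns, expected-reward
omission probes, acquisition/extinction phase blocks, and the inference
error-spike trains of the trauma/stress scenarios.  All outputs are pure
functions of ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from .conditioning import ConditioningSchedule
from .continuous import ErrorSpikeTrain, _inference_train, _safe_context_train
from .errors import ConfigError
from .revaluation import StimulusSchedule

__all__ = ["GeneratorSpec", "Waveform", "make_schedule", "make_waveform"]

_SCHEDULE_KINDS = (
    "constant",
    "staircase",
    "periodic_gaussian_pattern",
    "omission",
    "acquisition_extinction",
)
_WAVEFORM_KINDS = ("zero", "step", "ramp", "pulse", "sine", "composite", "spike_train")


@dataclass(frozen=True)
class GeneratorSpec:
    """Kind + keyword parameters + seed; fixed seed gives identical output."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class Waveform:
    """Piecewise analytic waveform, callable on any time array."""

    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, t) -> np.ndarray:
        return np.asarray(self.fn(np.asarray(t, dtype=float)), dtype=float)


def make_schedule(spec: GeneratorSpec):
    """Build a stimulation schedule from a generator spec.

    Kinds: ``constant`` (x, n_trials); ``staircase`` (levels,
    trials_per_level); ``periodic_gaussian_pattern`` (period, amplitude,
    sigma, n_trials) — a Gaussian intensity bump repeating every ``period``
    trials, so ``x[n] = x[n - period]``; ``omission`` (x, n_trials,
    omit_trial) — a constant run with one signalled trial of zero intensity,
    the negative-contrast probe; ``acquisition_extinction`` (phases) — a
    conditioning phase-block schedule.
    """
    p: dict[str, Any] = dict(spec.params)
    if spec.kind == "constant":
        return StimulusSchedule.constant(p.get("x", 1.0), p.get("n_trials", 10))
    if spec.kind == "staircase":
        levels = p.get("levels", (1.0, 2.0, 4.0))
        per = int(p.get("trials_per_level", 10))
        if per < 1:
            raise ConfigError("trials_per_level must be >= 1")
        x = [float(v) for v in levels for _ in range(per)]
        return StimulusSchedule(x=x)
    if spec.kind == "periodic_gaussian_pattern":
        period = int(p.get("period", 8))
        if period < 1:
            raise ConfigError("period must be >= 1")
        amp = float(p.get("amplitude", 1.0))
        sigma = float(p.get("sigma", period / 4.0))
        n = int(p.get("n_trials", 5 * period))
        phase = np.arange(n) % period
        x = amp * np.exp(-0.5 * ((phase - (period - 1) / 2.0) / sigma) ** 2)
        return StimulusSchedule(x=x)
    if spec.kind == "omission":
        n = int(p.get("n_trials", 20))
        omit = int(p.get("omit_trial", n))
        if not 1 <= omit <= n:
            raise ConfigError("omit_trial must lie within the schedule")
        x = np.full(n, float(p.get("x", 1.0)))
        x[omit - 1] = 0.0
        return StimulusSchedule(x=x)
    if spec.kind == "acquisition_extinction":
        phases = p.get("phases", [("acquisition", 20), ("extinction", 20)])
        return ConditioningSchedule.from_phases([(k, int(n)) for k, n in phases])
    raise ConfigError(f"unknown schedule kind {spec.kind!r}")


def make_waveform(spec: GeneratorSpec):
    """Build a continuous-time input waveform or error-spike train.

    Waveform kinds: ``zero``; ``step`` (t0, amplitude); ``ramp`` (t0, t1,
    amplitude); ``pulse`` (t0, width, amplitude); ``sine`` (amplitude,
    frequency, phase); ``composite`` (parts: list of specs, summed).  The
    kind ``spike_train`` returns an :class:`ErrorSpikeTrain` instead:
    either explicit ``events`` or an inference train closing a
    prior-vs-inferred expectation gap (``prior``, ``inferred``, ...), with
    an optional safe-context deflation block appended.
    """
    p: dict[str, Any] = dict(spec.params)
    if spec.kind == "zero":
        return Waveform(lambda t: np.zeros_like(t))
    if spec.kind == "step":
        t0, amp = float(p.get("t0", 0.0)), float(p.get("amplitude", 1.0))
        return Waveform(lambda t: np.where(t >= t0, amp, 0.0))
    if spec.kind == "ramp":
        t0, t1 = float(p.get("t0", 0.0)), float(p.get("t1", 1.0))
        amp = float(p.get("amplitude", 1.0))
        if t1 <= t0:
            raise ConfigError("ramp requires t1 > t0")
        return Waveform(lambda t: amp * np.clip((t - t0) / (t1 - t0), 0.0, 1.0))
    if spec.kind == "pulse":
        t0, w = float(p.get("t0", 0.0)), float(p.get("width", 1.0))
        amp = float(p.get("amplitude", 1.0))
        if w <= 0:
            raise ConfigError("pulse width must be positive")
        return Waveform(lambda t: np.where((t >= t0) & (t < t0 + w), amp, 0.0))
    if spec.kind == "sine":
        amp = float(p.get("amplitude", 1.0))
        f = float(p.get("frequency", 1.0))
        ph = float(p.get("phase", 0.0))
        return Waveform(lambda t: amp * np.sin(2.0 * np.pi * f * t + ph))
    if spec.kind == "composite":
        parts = [make_waveform(GeneratorSpec(kind=q["kind"], params=q.get("params", {})))
                 for q in p.get("parts", [])]
        return Waveform(lambda t: sum((w(t) for w in parts), np.zeros_like(t)))
    if spec.kind == "spike_train":
        if "events" in p:
            return ErrorSpikeTrain(events=[tuple(ev) for ev in p["events"]])
        train, _ = _inference_train(
            prior=float(p.get("prior", 1.0)),
            inferred=float(p.get("inferred", 10.0)),
            start=float(p.get("start", 1.0)),
            spacing=float(p.get("spacing", 0.5)),
            n_spikes=int(p.get("n_spikes", 10)),
            gain=float(p.get("gain", 12.0)),
            ofc_rate=float(p.get("ofc_rate", 0.4)),
            width=float(p.get("width", 0.05)),
        )
        events = list(train.events)
        if p.get("safe_context", False):
            safe = _safe_context_train(
                start=float(p.get("safe_start", events[-1][0] + 2.0)),
                mass=float(p.get("safe_mass", 5.0)),
            )
            events += list(safe.events)
        return ErrorSpikeTrain(events=events)
    raise ConfigError(f"unknown waveform kind {spec.kind!r}")
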