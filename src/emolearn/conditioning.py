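"""Classical conditioning with implicit UCS revaluation.

A conditioned stimulus (CS) acquires the ability to trigger the reactive
response attached to an unconditioned stimulus (UCS) through the synaptic
strength ``omega`` of the CS→UCS connection, modelled as the potentiated
fraction of a population of binary (stochastic Hebbian) synapses:

    reinforced      omega[n] = omega[n-1] + pot_rate * (1 - omega[n-1])
    non-reinforced  omega[n] = omega[n-1] - dep_rate * omega[n-1]

Neglecting UCS revaluation this is exactly the Rescorla–Wagner acquisition
curve ``1 - (1 - pot_rate)**(n-1)``.  The extension tracked here is that the
conditioned response is misattributed forward onto the UCS, inflating its
reactive response ``i_R`` during acquisition:

    i_R[n]  = alpha * (X + i_R[n-1] * omega[n])
    y_CS[n] = omega[n] * i_R[n-1]

with initial conditions ``omega(1)=0``, ``i_R(1)=alpha*X``, ``y_CS(1)=0`` and
``y_UCS(1)=X``.  Under sustained reinforcement ``i_R`` rises from ``alpha*X``
to ``alpha*X/(1-alpha)``, so the asymptotic conditioned response depends on
UCS intensity — a feature absent from the plain Rescorla–Wagner model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, StabilityError, StateError

__all__ = [
    "ConditioningParams",
    "ConditioningSchedule",
    "ConditioningTrace",
    "update_synapse",
    "simulate_conditioning",
    "rescorla_wagner_closed_form",
    "stochastic_synapse_update",
]


@dataclass(frozen=True)
class ConditioningParams:
    """Gains and rates of the conditioning model.

    ``pot_rate`` / ``dep_rate`` are the per-trial probabilities for a plastic
    synapse to switch to the potentiated / depressed state; ``X`` is the
    active UCS intensity in response units; ``n_synapses`` sizes the synapse
    population for the stochastic update mode.
    """

    alpha: float
    pot_rate: float = 0.3
    dep_rate: float = 0.3
    X: float = 1.0
    n_synapses: Optional[int] = None

    def __post_init__(self) -> None:
        if abs(self.alpha) >= 1.0:
            raise StabilityError(
                f"reactive gain alpha={self.alpha!r} violates |alpha| < 1"
            )
        for name in ("pot_rate", "dep_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name}={r!r} must lie in [0, 1]")
        if self.n_synapses is not None and self.n_synapses <= 0:
            raise ConfigError("n_synapses must be a positive integer")


@dataclass(frozen=True)
class ConditioningSchedule:
    """Ordered list of trials; each flagged reinforced (CS–UCS) or CS-alone."""

    reinforced: Sequence[bool]

    def __post_init__(self) -> None:
        flags = tuple(bool(v) for v in self.reinforced)
        if len(flags) < 1:
            raise ConfigError("schedule must contain at least one trial")
        object.__setattr__(self, "reinforced", flags)

    def __len__(self) -> int:
        return len(self.reinforced)

    @classmethod
    def from_phases(cls, phases: Sequence[tuple[str, int]]) -> "ConditioningSchedule":
        """Build from blocks like ``[("acquisition", 20), ("extinction", 30)]``."""
        flags: list[bool] = []
        for kind, n in phases:
            if kind not in ("acquisition", "extinction"):
                raise ConfigError(f"unknown phase type {kind!r}")
            if n < 0:
                raise ConfigError("phase trial count must be nonnegative")
            flags.extend([kind == "acquisition"] * n)
        return cls(reinforced=flags)


@dataclass
class ConditioningTrace:
    """Per-trial synaptic strength, reactive response, CR and UCR."""

    trial: np.ndarray
    omega: np.ndarray
    i_R: np.ndarray
    y_CS: np.ndarray
    y_UCS: np.ndarray
    reinforced: np.ndarray

    def __len__(self) -> int:
        return self.trial.size

    def to_frame(self) -> pd.DataFrame:
        phase = np.where(self.reinforced, "acquisition", "extinction")
        return pd.DataFrame(
            {
                "trial": self.trial,
                "omega": self.omega,
                "i_R": self.i_R,
                "y_CS": self.y_CS,
                "y_UCS": self.y_UCS,
                "phase": phase,
            }
        )


def update_synapse(omega: float, reinforced: bool, params: ConditioningParams) -> float:
    """One mean-field synaptic update; preserves ``omega`` in [0, 1]."""
    if not 0.0 <= omega <= 1.0:
        raise StateError(f"synaptic strength omega={omega!r} outside [0, 1]")
    if reinforced:
        return omega + params.pot_rate * (1.0 - omega)
    return omega - params.dep_rate * omega


def rescorla_wagner_closed_form(n: int, pot_rate: float) -> float:
    """Rescorla–Wagner acquisition curve ``1 - (1 - pot_rate)**(n-1)``.

    Serves as the independent closed form for ``omega`` under uninterrupted
    reinforcement (trial index 1-based, ``omega(1) = 0``).
    """
    if n < 1:
        raise ConfigError("trial index n must be >= 1")
    return 1.0 - (1.0 - pot_rate) ** (n - 1)


def stochastic_synapse_update(
    omega: float,
    reinforced: bool,
    params: ConditioningParams,
    rng: Union[int, np.random.Generator],
) -> float:
    """Binomial synapse-population update; expectation equals the mean-field rule.

    Of ``M = n_synapses`` binary synapses, ``round(M*omega)`` are potentiated.
    On a reinforced trial each depressed synapse switches with probability
    ``pot_rate``; on a non-reinforced trial each potentiated synapse switches
    with probability ``dep_rate``.
    """
    if params.n_synapses is None:
        raise ConfigError("stochastic update requires n_synapses to be configured")
    if not 0.0 <= omega <= 1.0:
        raise StateError(f"synaptic strength omega={omega!r} outside [0, 1]")
    gen = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    M = params.n_synapses
    pot = int(round(M * omega))
    if reinforced:
        switched = gen.binomial(M - pot, params.pot_rate)
        return (pot + switched) / M
    switched = gen.binomial(pot, params.dep_rate)
    return (pot - switched) / M


def simulate_conditioning(
    schedule: ConditioningSchedule,
    params: ConditioningParams,
    devalue_on_extinction: bool = False,
    rng: Union[int, np.random.Generator, None] = None,
) -> ConditioningTrace:
    """Coupled trial-by-trial dynamics of synapse, reactive response, CR and UCR.

    Within a trial the synapse is updated first, then ``i_R`` from the new
    ``omega`` and the previous ``i_R``, then the conditioned response from the
    new ``omega`` and the previous ``i_R`` — the literal index pattern of the
    recursions.  On extinction trials (CS alone) the UCS is not perceived, so
    ``i_R`` is frozen by default; set ``devalue_on_extinction`` to let the CS
    presentation devalue it (``i_R[n] = alpha * i_R[n-1] * omega[n]``), the
    case of a UCS perceived without elicitation.  The UCR column reports
    ``X + i_R[n-1]`` on reinforced trials and zero when no UCS is delivered.

    Pass ``rng`` (seed or Generator) to replace the mean-field synapse update
    with the binomial population update.
    """
    n_trials = len(schedule)
    alpha, X = params.alpha, params.X
    gen: Optional[np.random.Generator] = None
    if rng is not None:
        gen = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    omega = np.empty(n_trials)
    i_R = np.empty(n_trials)
    y_CS = np.empty(n_trials)
    y_UCS = np.empty(n_trials)

    omega[0] = 0.0
    i_R[0] = alpha * X
    y_CS[0] = 0.0
    y_UCS[0] = X if schedule.reinforced[0] else 0.0

    for i in range(1, n_trials):
        r = schedule.reinforced[i]
        if gen is None:
            omega[i] = update_synapse(omega[i - 1], r, params)
        else:
            omega[i] = stochastic_synapse_update(omega[i - 1], r, params, gen)
        if r:
            i_R[i] = alpha * (X + i_R[i - 1] * omega[i])
            y_UCS[i] = X + i_R[i - 1]
        else:
            i_R[i] = alpha * i_R[i - 1] * omega[i] if devalue_on_extinction else i_R[i - 1]
            y_UCS[i] = 0.0
        y_CS[i] = omega[i] * i_R[i - 1]

    return ConditioningTrace(
        trial=np.arange(1, n_trials + 1),
        omega=omega,
        i_R=i_R,
        y_CS=y_CS,
        y_UCS=y_UCS,
        reinforced=np.asarray(schedule.reinforced, dtype=bool),
    )
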