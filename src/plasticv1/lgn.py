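"""Poisson LGN front end: rate maps to spikes plus presynaptic traces.

288 LGN units (144 ON + 144 OFF for a 12x12 patch) emit Bernoulli spikes at
1 ms resolution, thinning a Poisson process at the pixel's rate.  Each unit
carries a presynaptic spike trace x̄ that jumps by 1 on a spike and decays
exponentially with τ_x = 15 ms; the trace is what the excitatory learning
rule reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stimuli import OnOffRates

__all__ = ["LgnState", "lgn_step", "TAU_X"]

#: presynaptic spike-trace time constant (ms)
TAU_X = 15.0


@dataclass
class LgnState:
    """Dynamical state of the LGN population.

    ``x_trace`` is the presynaptic trace x̄ per unit; ``last_spikes`` holds
    the 0/1 spike indicators of the most recent step (the binary membrane
    bookkeeping of the Poisson unit).
    """

    n: int
    x_trace: np.ndarray = field(default=None)
    last_spikes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.x_trace is None:
            self.x_trace = np.zeros(self.n)
        if self.last_spikes is None:
            self.last_spikes = np.zeros(self.n, dtype=np.uint8)


def lgn_step(
    state: LgnState,
    rates: OnOffRates | np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the LGN population by one step; returns the spike indicators.

    Each unit spikes with probability rate*dt (probability clipped at 1,
    with a warning, if rate*dt exceeds 1).  On a spike the trace jumps by
    1; otherwise it decays by exp(-dt/τ_x).  State is updated in place.
    """
    r = rates.flat() if isinstance(rates, OnOffRates) else np.asarray(rates, dtype=float).ravel()
    if r.shape[0] != state.n:
        raise ValueError(f"rate vector length {r.shape[0]} != population size {state.n}")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    p = r * dt * 1e-3  # Hz * ms
    if np.any(p > 1.0):
        warnings.warn("rate*dt exceeds 1; spike probability clipped", stacklevel=2)
        p = np.minimum(p, 1.0)
    spikes = (rng.random(state.n) < p).astype(np.uint8)
    state.x_trace *= np.exp(-dt / TAU_X)
    state.x_trace += spikes
    state.last_spikes = spikes
    return spikes
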