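"""Adaptive exponential integrate-and-fire (AdEx) dynamics for V1 units.

The membrane potential u follows leaky integration plus an exponential
spike-initiation term, and is coupled to three slower variables: an
adaptive threshold V_T (raised after every spike, relaxing to rest with
τ_VT), a hyperpolarizing adaptation current w_ad (subthreshold drive
a(u - E_L) plus a jump b per spike), and a depolarizing afterpotential z
(reset to I_sp after a spike).  Current-based synapses feed u with I_exc
(τ = 1 ms) and I_inh (τ = 10 ms, entering with negative sign).

Spike handling follows the clamp treatment: when u crosses V_T it is held
at +29 mV for exactly 2 ms (visible to the plasticity voltage traces, which
is what makes the LTP term fire), then reset to E_L.  All integration is
forward Euler at dt = 1 ms, matching the clock-driven simulator the rest of
the package builds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AdexParams", "AdexState", "adex_step", "SPIKE_CLAMP_MV", "SPIKE_CLAMP_MS"]

#: membrane value during the after-spike clamp (mV) and its duration (ms)
SPIKE_CLAMP_MV = 29.0
SPIKE_CLAMP_MS = 2

#: cap on the exponential-term argument; keeps the Euler step finite when u
#: overshoots far above V_T within one step (the value is then discarded by
#: the spike reset anyway)
_EXP_ARG_MAX = 30.0


@dataclass
class AdexParams:
    """AdEx neuron constants; defaults are the standard parameter set."""

    C: float = 281.0          # membrane capacitance, pF
    g_L: float = 30.0         # leak conductance, nS
    E_L: float = -70.6        # resting potential, mV
    Delta_T: float = 2.0      # slope factor, mV
    VT_rest: float = -50.4    # spike threshold at rest, mV
    VT_max: float = 30.4      # spike threshold right after a spike, mV
    tau_VT: float = 50.0      # threshold relaxation, ms
    tau_z: float = 40.0       # afterpotential decay, ms
    tau_wad: float = 144.0    # adaptation decay, ms
    I_sp: float = 400.0       # afterpotential reset value, pA
    a: float = 4.0            # subthreshold adaptation, nS
    b: float = 0.805          # spike-triggered adaptation, pA
    tau_Iexc: float = 1.0     # excitatory synaptic time constant, ms
    tau_Iinh: float = 10.0    # inhibitory synaptic time constant, ms

    def __post_init__(self) -> None:
        for name in ("tau_VT", "tau_z", "tau_wad", "tau_Iexc", "tau_Iinh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AdexState:
    """Population state; every field is an array of length n."""

    n: int
    params: AdexParams = field(default_factory=AdexParams)
    u: np.ndarray = None
    V_T: np.ndarray = None
    w_ad: np.ndarray = None
    z: np.ndarray = None
    I_exc: np.ndarray = None
    I_inh: np.ndarray = None
    clamp_timer: np.ndarray = None

    def __post_init__(self) -> None:
        if self.u is None:
            self.u = np.full(self.n, self.params.E_L)
        if self.V_T is None:
            self.V_T = np.full(self.n, self.params.VT_rest)
        for name in ("w_ad", "z", "I_exc", "I_inh"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.n))
        if self.clamp_timer is None:
            self.clamp_timer = np.zeros(self.n, dtype=np.int64)


def adex_step(
    state: AdexState,
    exc_input: np.ndarray | float,
    inh_input: np.ndarray | float = 0.0,
    dt: float = 1.0,
) -> np.ndarray:
    """Advance the population by one step; returns the spike indicators.

    ``exc_input`` / ``inh_input`` are the summed synaptic weights of the
    afferents that spiked on the previous step (the one-step transmission
    delay lives in the caller).  Update order within the step: synaptic
    currents, membrane integration (or clamp countdown), spike detection,
    adaptation-variable relaxation, spike resets.  State is modified in
    place.
    """
    p = state.params
    if not (np.all(np.isfinite(state.u)) and np.all(np.isfinite(state.w_ad))):
        raise FloatingPointError("non-finite AdEx state; dynamics diverged")

    state.I_exc *= 1.0 - dt / p.tau_Iexc
    state.I_exc += exc_input
    state.I_inh *= 1.0 - dt / p.tau_Iinh
    state.I_inh += inh_input

    clamped = state.clamp_timer > 0
    # clamp countdown: u stays at +29 mV while the timer is positive, and
    # drops to E_L on the step the timer expires
    state.clamp_timer[clamped] -= 1
    state.u[clamped] = np.where(
        state.clamp_timer[clamped] > 0, SPIKE_CLAMP_MV, p.E_L
    )

    free = ~clamped
    uf = state.u[free]
    exp_arg = np.minimum((uf - state.V_T[free]) / p.Delta_T, _EXP_ARG_MAX)
    dudt = (
        -p.g_L * (uf - p.E_L)
        + p.g_L * p.Delta_T * np.exp(exp_arg)
        - state.w_ad[free]
        + state.z[free]
        + state.I_exc[free]
        - state.I_inh[free]
    ) / p.C
    state.u[free] = uf + dt * dudt

    spiked = free & (state.u > state.V_T)
    state.u[spiked] = SPIKE_CLAMP_MV
    state.clamp_timer[spiked] = SPIKE_CLAMP_MS

    state.V_T += dt / p.tau_VT * (p.VT_rest - state.V_T)
    state.z *= 1.0 - dt / p.tau_z
    state.w_ad += dt / p.tau_wad * (p.a * (state.u - p.E_L) - state.w_ad)

    state.V_T[spiked] = p.VT_max
    state.z[spiked] = p.I_sp
    state.w_ad[spiked] += p.b
    return spiked.astype(np.uint8)
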