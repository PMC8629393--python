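"""Synaptic learning rules: voltage-based excitatory STDP and homeostatic iSTDP.

Excitatory synapses (LGN→E, LGN→I, E→I) follow the voltage-based triplet
STDP rule: potentiation requires a presynaptic trace x̄ together with
strong instantaneous depolarization (u above θ+) and a recently depolarized
low-pass voltage ū+; depression fires on each presynaptic spike when the
slower trace ū- is above rest, scaled homeostatically by ū̄/u_ref where ū̄
is a slow average of squared depolarization.  The rule produces BCM-like
dynamics: the ū̄ term acts as a sliding threshold between depression and
potentiation.

Inhibitory synapses (I→E, I→I) follow the symmetric homeostatic iSTDP
rule: near-coincident pre/post spiking potentiates regardless of order,
isolated presynaptic spikes depress by η·ρ, and the fixed point pins the
postsynaptic trace average — hence the postsynaptic rate — at a target
set by ρ.

Step conventions (shared with the fused simulation kernel): spike traces
decay by exp(-dt/τ) and jump by 1, and are updated with the current step's
spikes *before* the weight update reads them; voltage traces are forward
Euler; the depression term reads the pre-update value of ū̄.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClopathParams",
    "ClopathTraces",
    "IstdpParams",
    "clopath_update",
    "istdp_update",
    "decay_trace",
    "equalize_on_off",
    "EXC_PROJECTION_PARAMS",
    "INH_PROJECTION_PARAMS",
]


@dataclass
class ClopathParams:
    """Voltage-based STDP constants.

    Learning rates, the homeostatic reference u_ref, and the weight bounds
    are projection-specific (see ``EXC_PROJECTION_PARAMS``); thresholds and
    time constants are global.
    """

    A_LTP: float              # potentiation rate, (mV^-2) ms^-1
    A_LTD: float              # depression rate, mV^-1
    u_ref: float              # homeostatic reference depolarization, mV^2
    w_max: float
    w_min: float = 0.0
    theta_plus: float = -45.3   # instantaneous-voltage LTP threshold, mV
    theta_minus: float = -70.6  # voltage-trace threshold, mV
    tau_plus: float = 7.0       # ū+ time constant, ms
    tau_minus: float = 10.0     # ū- time constant, ms
    tau_ubarbar: float = 750.0  # ū̄ time constant, ms
    tau_x: float = 15.0         # presynaptic trace time constant, ms
    E_L: float = -70.6          # rest reference for ū̄'s rectified drive, mV
    w_init: tuple = (0.0, 1.0)  # bounds of the uniform init distribution

    def __post_init__(self) -> None:
        if self.u_ref <= 0:
            raise ValueError("u_ref must be positive")
        if self.A_LTP < 0 or self.A_LTD < 0:
            raise ValueError("learning rates must be nonnegative")


@dataclass
class ClopathTraces:
    """Per-projection state: presynaptic traces and postsynaptic voltage traces."""

    n_pre: int
    n_post: int
    x_bar: np.ndarray = None        # presynaptic spike traces
    u_bar_plus: np.ndarray = None   # fast low-pass membrane, mV
    u_bar_minus: np.ndarray = None  # slower low-pass membrane, mV
    u_bar_bar: np.ndarray = None    # slow mean squared depolarization, mV^2

    def __post_init__(self) -> None:
        if self.x_bar is None:
            self.x_bar = np.zeros(self.n_pre)
        rest = -70.6
        if self.u_bar_plus is None:
            self.u_bar_plus = np.full(self.n_post, rest)
        if self.u_bar_minus is None:
            self.u_bar_minus = np.full(self.n_post, rest)
        if self.u_bar_bar is None:
            self.u_bar_bar = np.zeros(self.n_post)


@dataclass
class IstdpParams:
    """Symmetric homeostatic iSTDP constants (projection-specific ρ, w_max)."""

    eta: float = 1e-5    # learning rate
    rho: float = 0.4     # target constant; sets the homeostatic rate ρ/τ_post
    tau_pre: float = 10.0
    tau_post: float = 10.0
    w_min: float = 0.0
    w_max: float = 0.7


#: Table of per-projection excitatory-rule parameters.  The noInh variant
#: uses reduced LGN→E learning rates to compensate for the higher firing
#: rates reached without inhibition.
EXC_PROJECTION_PARAMS: dict[str, ClopathParams] = {
    "lgn_e": ClopathParams(
        A_LTP=1.35e-4, A_LTD=1.05e-4, u_ref=60.0, w_max=5.0, w_init=(0.015, 2.0)
    ),
    "lgn_e_noinh": ClopathParams(
        A_LTP=7.2e-5, A_LTD=5.6e-5, u_ref=60.0, w_max=5.0, w_init=(0.015, 2.0)
    ),
    "lgn_i": ClopathParams(
        A_LTP=5.4e-5, A_LTD=4.2e-5, u_ref=55.0, w_max=3.0, w_init=(0.0175, 2.15)
    ),
    "e_i": ClopathParams(
        A_LTP=1.2e-5, A_LTD=1.4e-5, u_ref=55.0, w_max=1.0, w_init=(0.0175, 0.25)
    ),
}

#: Per-projection inhibitory-rule parameters; ρ at I→E is the variant's
#: excitation/inhibition knob (0.4 for EI2/1, 0.7 for EI3/1).
INH_PROJECTION_PARAMS: dict[str, IstdpParams] = {
    "i_e": IstdpParams(eta=1e-5, rho=0.4, w_max=0.7),
    "i_e_ei31": IstdpParams(eta=1e-5, rho=0.7, w_max=0.7),
    "i_i": IstdpParams(eta=1e-5, rho=0.6, w_max=0.5),
}


def decay_trace(trace: np.ndarray, spikes: np.ndarray, tau: float, dt: float = 1.0) -> np.ndarray:
    """Exponential-decay/unit-jump spike trace update (in place)."""
    trace *= np.exp(-dt / tau)
    trace += spikes
    return trace


def clopath_update(
    weights: np.ndarray,
    traces: ClopathTraces,
    pre_spikes: np.ndarray,
    u_post: np.ndarray,
    params: ClopathParams,
    dt: float = 1.0,
) -> np.ndarray:
    """One step of the voltage-based STDP rule (weights and traces in place).

    dw_ij = A_LTP x̄_i (u_j-θ+)+ (ū+_j-θ-)+  -  A_LTD (ū̄_j/u_ref) X_i (ū-_j-θ-)+
    integrated over dt, then clipped to [w_min, w_max].
    """
    pre_spikes = np.asarray(pre_spikes, dtype=float)
    u_post = np.asarray(u_post, dtype=float)

    # presynaptic trace: exact impulse response of τ_x dx̄/dt = -x̄ + X for
    # unit-area spike impulses, i.e. a jump of 1/τ_x per spike; this scale
    # is what balances the printed A_LTP against A_LTD
    decay_trace(traces.x_bar, pre_spikes / params.tau_x, params.tau_x, dt)
    traces.u_bar_plus += dt / params.tau_plus * (u_post - traces.u_bar_plus)
    traces.u_bar_minus += dt / params.tau_minus * (u_post - traces.u_bar_minus)
    ubarbar_old = traces.u_bar_bar.copy()
    drive = np.maximum(u_post - params.E_L, 0.0) ** 2
    traces.u_bar_bar += dt / params.tau_ubarbar * (drive - traces.u_bar_bar)

    ltp_post = np.maximum(u_post - params.theta_plus, 0.0) * np.maximum(
        traces.u_bar_plus - params.theta_minus, 0.0
    )
    ltd_post = (ubarbar_old / params.u_ref) * np.maximum(
        traces.u_bar_minus - params.theta_minus, 0.0
    )
    weights += dt * (
        params.A_LTP * np.outer(traces.x_bar, ltp_post)
        - params.A_LTD * np.outer(pre_spikes, ltd_post)
    )
    np.clip(weights, params.w_min, params.w_max, out=weights)
    return weights


def istdp_update(
    weights: np.ndarray,
    x_pre: np.ndarray,
    x_post: np.ndarray,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    params: IstdpParams,
) -> np.ndarray:
    """One step of the symmetric iSTDP rule (weights in place).

    On each presynaptic spike w_ij += η(x̄post_j - ρ); on each postsynaptic
    spike w_ij += η x̄pre_i; clip to [w_min, w_max].  Trace maintenance
    (τ = 10 ms, unit jump, current step's spikes already applied) is the
    caller's responsibility via :func:`decay_trace`.
    """
    pre_spikes = np.asarray(pre_spikes, dtype=float)
    post_spikes = np.asarray(post_spikes, dtype=float)
    weights += params.eta * np.outer(pre_spikes, x_post - params.rho)
    weights += params.eta * np.outer(x_pre, post_spikes)
    np.clip(weights, params.w_min, params.w_max, out=weights)
    return weights


def equalize_on_off(weights_lgn: np.ndarray) -> np.ndarray:
    """Rescale the OFF half so its Euclidean norm matches the ON half.

    ``weights_lgn`` has shape (2*n_pix, n_post) with the ON afferents in the
    first half of the rows; the rescaling is per postsynaptic neuron and
    leaves the ON half untouched.  Columns with zero OFF norm but nonzero
    ON norm are skipped with a warning.  Applied every 20 s of simulated
    time during training to keep the two input channels balanced.
    """
    n_pre = weights_lgn.shape[0]
    if n_pre % 2:
        raise ValueError("LGN weight matrix must have an even number of rows")
    half = n_pre // 2
    on_norm = np.linalg.norm(weights_lgn[:half], axis=0)
    off_norm = np.linalg.norm(weights_lgn[half:], axis=0)
    degenerate = (off_norm == 0) & (on_norm > 0)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} neuron(s) with zero OFF norm; skipped",
            stacklevel=2,
        )
    ok = off_norm > 0
    weights_lgn[half:, ok] *= on_norm[ok] / off_norm[ok]
    return weights_lgn
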