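"""Network assembly, stimulus presentation, training, variants, checkpoints.

The circuit: 288 Poisson LGN units (144 ON + 144 OFF) project all-to-all
onto an excitatory (144) and an inhibitory (36, a 4:1 ratio) population of
AdEx neurons; the V1 populations are mutually connected and the inhibitory
population inhibits itself (no self-connections).  Excitatory synapses
learn with the voltage-based STDP rule, inhibitory synapses with the
homeostatic iSTDP rule.

Model variants
--------------
``EI2/1``     all synapses plastic, ρ(I→E) = 0.4 (≈2:1 E/I current ratio)
``EI3/1``     all synapses plastic, ρ(I→E) = 0.7 (weaker inhibition)
``noInh``     no inhibitory population at all; reduced LGN→E learning rates
``blockInh``  an EI2/1 network whose inhibitory transmission is zeroed
              after training (see :meth:`Network.with_blocked_inhibition`)
``fix_fb_inh``  I→E frozen at a shuffled reference weight set
``fix_ff_inh``  LGN→I and E→I frozen at a shuffled reference weight set

The fix_* variants start every projection from value-shuffled weights of a
previously trained EI2/1 run (preserving the weight distribution, hence the
overall E/I balance), except LGN→E which is re-drawn from its uniform init
distribution and is plastic in every variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .adex import AdexParams
from .plasticity import (
    EXC_PROJECTION_PARAMS,
    INH_PROJECTION_PARAMS,
    ClopathParams,
    IstdpParams,
    equalize_on_off,
)
from .stimuli import (
    NATURAL_R_MAX,
    OnOffRates,
    WhitenedScene,
    on_off_split,
    sample_patch,
)

__all__ = [
    "NetworkConfig",
    "Network",
    "SpikeRecord",
    "TrainingLog",
    "build_network",
    "present_stimulus",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("EI2/1", "EI3/1", "noInh", "blockInh", "fix_fb_inh", "fix_ff_inh")

#: interval between ON/OFF norm equalizations (simulated ms)
EQUALIZE_INTERVAL_MS = 20_000.0


@dataclass
class NetworkConfig:
    """Sizes, variant and run parameters of one network instance.

    ``scale_factor`` shrinks both V1 populations (keeping the 4:1
    excitatory:inhibitory ratio) for desk-scale runs; the LGN stays at
    288 units because the input patch stays 12x12x2.
    """

    variant: str = "EI2/1"
    seed: int = 0
    n_lgn: int = 288
    n_exc: int = 144
    n_inh: int = 36
    dt: float = 1.0
    presentation_ms: int = 125
    n_stimuli: int = 400_000
    scale_factor: float | None = None
    #: iSTDP learning-rate multiplier for shortened training runs.  The
    #: printed η is calibrated to 400k-stimulus training; an n-fold shorter
    #: run uses eta_scale = n so the inhibitory weights reach the same
    #: ρ-determined operating point within the run.  The fixed point itself
    #: (set by ρ) is unaffected.
    eta_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if self.scale_factor is not None:
            self.n_exc = int(round(144 * self.scale_factor))
            self.n_inh = int(round(36 * self.scale_factor))
        if self.variant == "noInh":
            self.n_inh = 0
        elif self.n_inh > 0 and abs(self.n_exc / self.n_inh - 4.0) > 1e-9:
            raise ValueError("excitatory:inhibitory ratio must be 4:1")


@dataclass
class SpikeRecord:
    """Spike events of one simulation window, at 1 ms resolution.

    ``population`` codes are 0 = LGN, 1 = excitatory, 2 = inhibitory.
    """

    population: np.ndarray
    neuron: np.ndarray
    time_ms: np.ndarray
    window: tuple[float, float]

    def counts(self, population: int, n: int) -> np.ndarray:
        """Spike count per neuron of one population over the window."""
        mask = self.population == population
        return np.bincount(self.neuron[mask], minlength=n)


@dataclass
class TrainingLog:
    """Per-block training observables."""

    block_end: list = field(default_factory=list)          # stimuli presented
    mean_abs_dw: list = field(default_factory=list)        # mean |ΔW(LGN→E)| per block
    mean_pairwise_corr: list = field(default_factory=list)  # probe-set response corr


class Network:
    """All dynamical state plus the five projections of one model instance."""

    def __init__(self, config: NetworkConfig, adex_params: AdexParams | None = None):
        self.config = config
        self.params = adex_params or AdexParams()
        nL, nE, nI = config.n_lgn, config.n_exc, config.n_inh

        lgn_e_key = "lgn_e_noinh" if config.variant == "noInh" else "lgn_e"
        i_e_key = "i_e_ei31" if config.variant == "EI3/1" else "i_e"
        self.clopath_params: dict[str, ClopathParams] = {
            "lgn_e": EXC_PROJECTION_PARAMS[lgn_e_key],
            "lgn_i": EXC_PROJECTION_PARAMS["lgn_i"],
            "e_i": EXC_PROJECTION_PARAMS["e_i"],
        }
        # population-downscaling compensation: projections from a scaled V1
        # population keep the total input current of the full-size circuit
        # by scaling per-synapse strength (bounds, init, learning rate) by
        # the inverse population ratio; LGN projections are untouched (the
        # LGN always has 288 units)
        comp = 144 / nE if nE else 1.0
        if comp != 1.0:
            ei = self.clopath_params["e_i"]
            self.clopath_params["e_i"] = replace(
                ei, A_LTP=ei.A_LTP * comp, A_LTD=ei.A_LTD * comp,
                w_max=ei.w_max * comp,
                w_init=(ei.w_init[0] * comp, ei.w_init[1] * comp),
            )
        self.istdp_params: dict[str, IstdpParams] = {}
        for key, base_key in (("i_e", i_e_key), ("i_i", "i_i")):
            ip = INH_PROJECTION_PARAMS[base_key]
            self.istdp_params[key] = replace(
                ip, eta=ip.eta * config.eta_scale * comp, w_max=ip.w_max * comp
            )

        self.weights: dict[str, np.ndarray] = {
            "lgn_e": np.zeros((nL, nE)),
            "lgn_i": np.zeros((nL, nI)),
            "e_i": np.zeros((nE, nI)),
            "i_e": np.zeros((nI, nE)),
            "i_i": np.zeros((nI, nI)),
        }
        if config.variant == "noInh":
            self.plastic = {"lgn_e": True, "lgn_i": False, "e_i": False,
                            "i_e": False, "i_i": False}
        elif config.variant == "fix_fb_inh":
            self.plastic = {"lgn_e": True, "lgn_i": True, "e_i": True,
                            "i_e": False, "i_i": True}
        elif config.variant == "fix_ff_inh":
            self.plastic = {"lgn_e": True, "lgn_i": False, "e_i": False,
                            "i_e": True, "i_i": True}
        else:
            self.plastic = {k: True for k in self.weights}
        self.inh_enabled = config.variant != "noInh"

        # dynamical state (kernel layout)
        EL, VTrest = self.params.E_L, self.params.VT_rest
        self.xL = np.zeros(nL)
        self.sL_prev = np.zeros(nL, dtype=np.uint8)
        self.uE = np.full(nE, EL)
        self.VTE = np.full(nE, VTrest)
        self.wadE = np.zeros(nE)
        self.zE = np.zeros(nE)
        self.IexcE = np.zeros(nE)
        self.IinhE = np.zeros(nE)
        self.clampE = np.zeros(nE, dtype=np.int64)
        self.ubpE = np.full(nE, EL)
        self.ubmE = np.full(nE, EL)
        self.ubbE = np.zeros(nE)
        self.xcE = np.zeros(nE)
        self.xiE = np.zeros(nE)
        self.sE_prev = np.zeros(nE, dtype=np.uint8)
        self.uI = np.full(nI, EL)
        self.VTI = np.full(nI, VTrest)
        self.wadI = np.zeros(nI)
        self.zI = np.zeros(nI)
        self.IexcI = np.zeros(nI)
        self.IinhI = np.zeros(nI)
        self.clampI = np.zeros(nI, dtype=np.int64)
        self.ubpI = np.full(nI, EL)
        self.ubmI = np.full(nI, EL)
        self.ubbI = np.zeros(nI)
        self.xiI = np.zeros(nI)
        self.sI_prev = np.zeros(nI, dtype=np.uint8)

        # named random substreams so variants can share stimulus sequences
        ss = np.random.SeedSequence(config.seed)
        keys = ("init", "patches", "poisson", "shuffle")
        self.rng = {k: np.random.Generator(np.random.PCG64(s))
                    for k, s in zip(keys, ss.spawn(len(keys)))}

        self.t_ms = 0.0
        self.next_equalize_ms = EQUALIZE_INTERVAL_MS
        self.n_presented = 0

    # -- parameter packing for the kernel ---------------------------------
    def _packed(self):
        p = self.params
        NP = np.zeros(K.NP_SIZE)
        NP[K.NP_C] = p.C
        NP[K.NP_GL] = p.g_L
        NP[K.NP_EL] = p.E_L
        NP[K.NP_DELTAT] = p.Delta_T
        NP[K.NP_VTREST] = p.VT_rest
        NP[K.NP_VTMAX] = p.VT_max
        NP[K.NP_TAUVT] = p.tau_VT
        NP[K.NP_TAUZ] = p.tau_z
        NP[K.NP_TAUWAD] = p.tau_wad
        NP[K.NP_ISP] = p.I_sp
        NP[K.NP_A] = p.a
        NP[K.NP_B] = p.b
        NP[K.NP_TAUIEXC] = p.tau_Iexc
        NP[K.NP_TAUIINH] = p.tau_Iinh
        cp0 = self.clopath_params["lgn_e"]
        NP[K.NP_THETAP] = cp0.theta_plus
        NP[K.NP_THETAM] = cp0.theta_minus
        NP[K.NP_TAUP] = cp0.tau_plus
        NP[K.NP_TAUM] = cp0.tau_minus
        NP[K.NP_TAUUBB] = cp0.tau_ubarbar
        NP[K.NP_TAUX] = cp0.tau_x
        NP[K.NP_TAUISTDP] = self.istdp_params["i_e"].tau_post
        NP[K.NP_CLAMPMV] = 29.0
        NP[K.NP_CLAMPSTEPS] = 2.0
        CP = np.zeros((3, 5))
        for r, key in enumerate(("lgn_e", "lgn_i", "e_i")):
            cp = self.clopath_params[key]
            CP[r] = (cp.A_LTP, cp.A_LTD, cp.u_ref, cp.w_min, cp.w_max)
        IP = np.zeros((2, 4))
        for r, key in enumerate(("i_e", "i_i")):
            ip = self.istdp_params[key]
            IP[r] = (ip.eta, ip.rho, ip.w_min, ip.w_max)
        return NP, CP, IP

    def _flags(self, plastic: bool) -> np.ndarray:
        fl = np.zeros(K.FL_SIZE, dtype=np.int64)
        if plastic:
            fl[K.FL_PLASTIC_LE] = self.plastic["lgn_e"]
            fl[K.FL_PLASTIC_LI] = self.plastic["lgn_i"]
            fl[K.FL_PLASTIC_EI] = self.plastic["e_i"]
            fl[K.FL_PLASTIC_IE] = self.plastic["i_e"]
            fl[K.FL_PLASTIC_II] = self.plastic["i_i"]
        fl[K.FL_INH_ON] = self.inh_enabled
        return fl

    # -- variant transforms ------------------------------------------------
    def with_blocked_inhibition(self) -> "Network":
        """Copy of this network with inhibitory transmission zeroed.

        The LGN→E weights are shared by construction (same arrays copied),
        matching the blockInh protocol: train EI2/1, then silence both
        inhibitory projections while keeping everything else intact.
        """
        import copy

        blocked = copy.deepcopy(self)
        blocked.inh_enabled = False
        blocked.IinhE[:] = 0.0
        blocked.IinhI[:] = 0.0
        blocked.config = replace(self.config, variant="blockInh")
        return blocked

    def firing_rates(self, record: "SpikeRecord", population: int = 1) -> np.ndarray:
        """Mean rate (Hz) per neuron of one population over a record."""
        n = {0: self.config.n_lgn, 1: self.config.n_exc, 2: self.config.n_inh}[population]
        dur_s = (record.window[1] - record.window[0]) * 1e-3
        return record.counts(population, n) / dur_s


def _shuffled(values: np.ndarray, rng: np.random.Generator, no_diag: bool = False) -> np.ndarray:
    """Value-shuffled copy of a weight matrix (multiset preserved)."""
    out = values.copy()
    if no_diag and out.shape[0] == out.shape[1] and out.shape[0] > 0:
        off = ~np.eye(out.shape[0], dtype=bool)
        vals = out[off]
        rng.shuffle(vals)
        out[off] = vals
        np.fill_diagonal(out, 0.0)
    else:
        flat = out.ravel()
        rng.shuffle(flat)
    return out


def build_network(
    config: NetworkConfig,
    reference_weights: dict[str, np.ndarray] | None = None,
    adex_params: AdexParams | None = None,
) -> Network:
    """Create a network with variant-appropriate initial weights.

    Excitatory projections start from per-projection uniform distributions;
    inhibitory weights start at zero (the iSTDP rule grows them against
    activity).  fix_* variants additionally require ``reference_weights``
    (a trained EI2/1 weight dict) which is value-shuffled per projection.
    """
    net = Network(config, adex_params)
    rng = net.rng["init"]
    for key in ("lgn_e", "lgn_i", "e_i"):
        lo, hi = net.clopath_params[key].w_init
        W = net.weights[key]
        W[:] = rng.uniform(lo, hi, size=W.shape)
    # inhibitory weights start at zero; no self-inhibition
    np.fill_diagonal(net.weights["i_i"], 0.0)

    if config.variant in ("fix_fb_inh", "fix_ff_inh"):
        if reference_weights is None:
            raise ValueError(f"variant {config.variant} requires reference_weights")
        sh = net.rng["shuffle"]
        for key in ("lgn_i", "e_i", "i_e", "i_i"):
            ref = np.asarray(reference_weights[key], dtype=float)
            if ref.shape != net.weights[key].shape:
                raise ValueError(f"reference weights for {key} have shape "
                                 f"{ref.shape}, expected {net.weights[key].shape}")
            net.weights[key][:] = _shuffled(ref, sh, no_diag=(key == "i_i"))
        # LGN→E is re-drawn from its init distribution (done above) and
        # remains plastic in every variant
    return net


def present_stimulus(
    net: Network,
    rates: OnOffRates | np.ndarray,
    duration: float | None = None,
    plastic: bool = False,
    record: bool = True,
) -> tuple[SpikeRecord, dict]:
    """Run one stimulus presentation through the clock-driven kernel.

    Returns the spike record and a dict of 1 ms-resolution observables
    (excitatory-population spikes ``spikes_e``, input currents ``i_exc`` /
    ``i_inh``, membrane potential ``u``; LGN and inhibitory spike rasters).
    Network state persists across calls — there is no reset between
    stimuli, during training or measurement.
    """
    cfg = net.config
    duration = cfg.presentation_ms if duration is None else duration
    T = int(round(duration / cfg.dt))
    if abs(T * cfg.dt - duration) > 1e-9:
        raise ValueError("duration must be a multiple of dt")
    r = rates.flat() if isinstance(rates, OnOffRates) else np.asarray(rates, dtype=float).ravel()
    if r.shape[0] != cfg.n_lgn:
        raise ValueError(f"rate vector length {r.shape[0]} != n_lgn {cfg.n_lgn}")

    uniforms = net.rng["poisson"].random((T, cfg.n_lgn))
    NP, CP, IP = net._packed()
    flags = net._flags(plastic)
    recL = np.zeros((T, cfg.n_lgn), dtype=np.uint8)
    recE = np.zeros((T, cfg.n_exc), dtype=np.uint8)
    recI = np.zeros((T, cfg.n_inh), dtype=np.uint8)
    recIexcE = np.zeros((T, cfg.n_exc))
    recIinhE = np.zeros((T, cfg.n_exc))
    recUE = np.zeros((T, cfg.n_exc))

    K.simulate_presentation(
        T, cfg.dt, r, uniforms, NP, CP, IP, flags,
        net.weights["lgn_e"], net.weights["lgn_i"], net.weights["e_i"],
        net.weights["i_e"], net.weights["i_i"],
        net.xL, net.sL_prev,
        net.uE, net.VTE, net.wadE, net.zE, net.IexcE, net.IinhE, net.clampE,
        net.ubpE, net.ubmE, net.ubbE, net.xcE, net.xiE, net.sE_prev,
        net.uI, net.VTI, net.wadI, net.zI, net.IexcI, net.IinhI, net.clampI,
        net.ubpI, net.ubmI, net.ubbI, net.xiI, net.sI_prev,
        recL, recE, recI, recIexcE, recIinhE, recUE,
    )

    t0 = net.t_ms
    net.t_ms += T * cfg.dt
    net.n_presented += 1

    traces = {
        "spikes_e": recE, "spikes_i": recI, "spikes_lgn": recL,
        "i_exc": recIexcE, "i_inh": recIinhE, "u": recUE,
    }
    if record:
        pops, neurons, times = [], [], []
        for code, rec in ((0, recL), (1, recE), (2, recI)):
            tt, nn = np.nonzero(rec)
            pops.append(np.full(tt.shape[0], code, dtype=np.int8))
            neurons.append(nn.astype(np.int32))
            times.append(t0 + (tt + 1) * cfg.dt)
        spike_record = SpikeRecord(
            population=np.concatenate(pops),
            neuron=np.concatenate(neurons),
            time_ms=np.concatenate(times),
            window=(t0, net.t_ms),
        )
    else:
        spike_record = SpikeRecord(
            population=np.zeros(0, dtype=np.int8),
            neuron=np.zeros(0, dtype=np.int32),
            time_ms=np.zeros(0),
            window=(t0, net.t_ms),
        )
    return spike_record, traces


def train(
    net: Network,
    scenes: list[WhitenedScene],
    n_stimuli: int | None = None,
    r_max: float = NATURAL_R_MAX,
    log_every: int = 1000,
    probe_patches: np.ndarray | None = None,
    checkpoint_every: int | None = None,
    checkpoint_path: str | None = None,
) -> TrainingLog:
    """Train on random patches from ``scenes`` with plasticity enabled.

    Each patch is presented for 125 ms; ON/OFF norms of the LGN efferents
    are equalized every 20 s of simulated time.  The log records, per block
    of ``log_every`` stimuli, the mean absolute LGN→E weight change and
    (when ``probe_patches`` is given, an array of flattened ON/OFF rate
    vectors) the mean pairwise response correlation on that held-out probe
    set, measured with plasticity off.

    Raises ``RuntimeError`` when >99% of the LGN→E weights saturate at
    w_max — the runaway-weight failure mode of unstable configurations.
    """
    from .metrics import mean_pairwise_correlation

    if n_stimuli is None:
        n_stimuli = net.config.n_stimuli
    log = TrainingLog()
    w_ref = net.weights["lgn_e"].copy()
    w_max = net.clopath_params["lgn_e"].w_max
    rng_patches = net.rng["patches"]

    for k in range(n_stimuli):
        scene = scenes[int(rng_patches.integers(len(scenes)))]
        patch = sample_patch(scene, rng_patches)
        rates = on_off_split(patch, r_max)
        present_stimulus(net, rates, plastic=True, record=False)

        if net.t_ms >= net.next_equalize_ms:
            equalize_on_off(net.weights["lgn_e"])
            if net.config.n_inh:
                equalize_on_off(net.weights["lgn_i"])
            net.next_equalize_ms += EQUALIZE_INTERVAL_MS

        if (k + 1) % log_every == 0 or k + 1 == n_stimuli:
            W = net.weights["lgn_e"]
            if np.mean(W >= w_max * (1 - 1e-12)) > 0.99:
                raise RuntimeError("runaway weights: LGN→E saturated at w_max")
            log.block_end.append(net.n_presented)
            log.mean_abs_dw.append(float(np.mean(np.abs(W - w_ref))))
            w_ref = W.copy()
            if probe_patches is not None:
                counts = np.zeros((len(probe_patches), net.config.n_exc))
                for s, pr in enumerate(probe_patches):
                    _, tr = present_stimulus(net, pr, plastic=False, record=False)
                    counts[s] = tr["spikes_e"].sum(axis=0)
                log.mean_pairwise_corr.append(mean_pairwise_correlation(counts)[0])
        if checkpoint_every and checkpoint_path and (k + 1) % checkpoint_every == 0:
            save_checkpoint(net, checkpoint_path)
    return log


# -- checkpointing ---------------------------------------------------------

_STATE_ARRAYS = (
    "xL", "sL_prev",
    "uE", "VTE", "wadE", "zE", "IexcE", "IinhE", "clampE",
    "ubpE", "ubmE", "ubbE", "xcE", "xiE", "sE_prev",
    "uI", "VTI", "wadI", "zI", "IexcI", "IinhI", "clampI",
    "ubpI", "ubmI", "ubbI", "xiI", "sI_prev",
)


def save_checkpoint(net: Network, path: str) -> None:
    """Serialize weights, dynamical state, counters and RNG substreams."""
    from dataclasses import asdict

    meta = {
        "config": asdict(net.config),
        "adex": asdict(net.params),
        "plastic": net.plastic,
        "inh_enabled": net.inh_enabled,
        "t_ms": net.t_ms,
        "next_equalize_ms": net.next_equalize_ms,
        "n_presented": net.n_presented,
        "rng": {k: g.bit_generator.state for k, g in net.rng.items()},
    }
    arrays = {f"W_{k}": v for k, v in net.weights.items()}
    arrays.update({f"S_{name}": getattr(net, name) for name in _STATE_ARRAYS})
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str) -> Network:
    """Restore a network bit-identically from :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg_dict = meta["config"]
        cfg_dict.pop("scale_factor", None)
        config = NetworkConfig(**cfg_dict, scale_factor=None)
        net = Network(config, AdexParams(**meta["adex"]))
        net.plastic = {k: bool(v) for k, v in meta["plastic"].items()}
        net.inh_enabled = bool(meta["inh_enabled"])
        net.t_ms = float(meta["t_ms"])
        net.next_equalize_ms = float(meta["next_equalize_ms"])
        net.n_presented = int(meta["n_presented"])
        for k in net.weights:
            net.weights[k][:] = data[f"W_{k}"]
        for name in _STATE_ARRAYS:
            arr = getattr(net, name)
            arr[:] = data[f"S_{name}"]
        for k, g in net.rng.items():
            g.bit_generator.state = meta["rng"][k]
    return net
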