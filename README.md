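# plasticv1

A fully plastic spiking-network model of primary visual cortex (V1)
layer 4, with the complete measurement suite needed to study how
orientation tuning, excitation/inhibition balance, contrast-invariant
tuning, sparseness and coding efficiency emerge from synaptic plasticity.

The package is for computational neuroscientists who want a desk-scale,
dependency-light reimplementation of this class of model: every synapse
in the circuit learns, and every headline analysis (receptive fields,
tuning curves, information per spike, reconstruction error, …) is a
plain function over recorded spikes.

## The model

Whitened image patches (12×12) drive 288 Poisson LGN units — positive
pixels as ON rates, magnitudes of negative pixels as OFF rates, the unit
pixel magnitude mapped to 125 Hz. The LGN projects all-to-all onto an
excitatory (144) and an inhibitory (36) population of adaptive
exponential integrate-and-fire neurons,

C du/dt = −g_L(u−E_L) + g_L Δ_T e^{(u−V_T)/Δ_T} − w_ad + z + I_exc − I_inh,

which are mutually connected and recurrently inhibited (no
self-connections). Excitatory synapses follow the voltage-based triplet
STDP rule

dw_i/dt = A_LTP x̄_i (u−θ₊)₊ (ū₊−θ₋)₊ − A_LTD (ū̄/u_ref) X_i (ū₋−θ₋)₊,

whose slow depolarization average ū̄ acts as a BCM-style sliding
threshold; inhibitory synapses follow the symmetric homeostatic iSTDP
rule (w += η(x̄_post − ρ) on presynaptic spikes, w += η x̄_pre on
postsynaptic spikes), whose ρ parameter sets the postsynaptic target
rate and thereby the circuit's excitation/inhibition ratio. Model
variants: `EI2/1` (ρ=0.4), `EI3/1` (ρ=0.7), `noInh`, `blockInh`,
`fix_fb_inh`, `fix_ff_inh`. Everything runs on a 1 ms clock (forward
Euler) through a numba kernel that is cross-checked against the plain
numpy operations.

A synthetic-data module generates whitened natural-scene surrogates
(dead-leaves images, spectrally whitened), Gabor receptive-field
fixtures, and linear-nonlinear-Poisson (LNP) surrogate neurons with
known ground truth, so the full pipeline runs and is tested without any
download. See `docs/methods.md` for conventions, parameters and
limitations.

## Quick start

```python
import numpy as np
from plasticv1 import NetworkConfig, build_network, present_stimulus, train
from plasticv1.metrics import population_sparseness
from plasticv1.stimuli import on_off_split, sample_patch
from plasticv1.synthetic import generate_scene_set

scenes = generate_scene_set(10, np.random.default_rng(42))
config = NetworkConfig(variant="EI2/1", seed=0, scale_factor=0.25,
                       n_stimuli=5_000, eta_scale=8.0)
net = build_network(config)
log = train(net, scenes, log_every=1000)
print(f"trained {config.n_exc} excitatory / {config.n_inh} inhibitory neurons "
      f"on {config.n_stimuli} patches")
print("per-block mean |dW(LGN->E)|:", np.round(log.mean_abs_dw, 3))

rng = np.random.default_rng(7)
sparseness, rates = [], []
for _ in range(200):
    patch = sample_patch(scenes[int(rng.integers(10))], rng)
    _, tr = present_stimulus(net, on_off_split(patch, 125.0))
    counts = tr["spikes_e"].sum(axis=0)
    rates.append(counts.mean() / 0.125)
    if counts.any():
        sparseness.append(population_sparseness(counts))
print(f"mean excitatory rate on natural patches: {np.mean(rates):.1f} Hz")
print(f"population sparseness: {np.mean(sparseness):.2f}")
```

prints

```
trained 36 excitatory / 9 inhibitory neurons on 5000 patches
per-block mean |dW(LGN->E)|: [2.03  1.413 1.296 1.214 1.245]
mean excitatory rate on natural patches: 25.8 Hz
population sparseness: 0.06
```

The falling per-block weight change shows the feed-forward weights
settling; the mean rate sits near the homeostatic operating point set by
ρ. Population sparseness after only 5,000 patches is low — selectivity
(and with it sparseness) develops over the full training run, and
desk-scale runs stay well below the sharply tuned full-scale regime (see
`docs/methods.md`, "Known limitations").

A thin CLI wraps the same functions:

```
plasticv1 synth --n-scenes 10 --size 128 --seed 0 --out scenes.npz
plasticv1 train --variant EI2/1 --n-stimuli 50000 --scale 0.25 --seed 0 --out ckpt.npz
plasticv1 measure --checkpoint ckpt.npz --metric sparseness --metric odi
plasticv1 sweep --config experiment.yaml
plasticv1 report --results results/metrics.csv
```

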