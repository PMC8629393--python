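# Methods

## Model

The circuit is a spiking model of V1 layer 4. A 12×12 patch of whitened
luminance drives 288 LGN units (144 ON + 144 OFF): positive pixels map to
the ON plane, magnitudes of negative pixels to the OFF plane, and each
plane value scales a Poisson rate with the unit pixel magnitude mapped to
`r_max` (125 Hz for natural-scene input; the per-scene normalization by the
maximum absolute pixel makes that rate rare). LGN spikes are Bernoulli
thinnings at 1 ms resolution.

The V1 populations — 144 excitatory and 36 inhibitory neurons at full
size, all-to-all connected (no inhibitory self-connections) — are adaptive
exponential integrate-and-fire (AdEx) neurons:

    C du/dt = −g_L (u − E_L) + g_L Δ_T exp((u − V_T)/Δ_T) − w_ad + z + I_exc − I_inh

with an adaptive threshold V_T (reset to VT_max after a spike, relaxing to
VT_rest with τ_VT = 50 ms), an adaptation current w_ad (subthreshold drive
a(u−E_L), jump b per spike, τ = 144 ms) and a depolarizing afterpotential
z (reset to I_sp = 400 pA, τ = 40 ms). On a threshold crossing the
membrane is held at +29 mV for exactly 2 ms and then reset to E_L; the
clamped voltage is visible to the plasticity traces, which is what lets
the potentiation term fire. Integration is forward Euler at dt = 1 ms.

Synapses are current-based with τ_exc = 1 ms and τ_inh = 10 ms, a
deliberate stand-in for voltage pulses: with the 1 ms Euler step the
excitatory current equals the summed weights of the afferents that spiked
on the previous step, i.e. a presynaptic spike of weight w depolarizes the
target by roughly w mV. Synaptic drive therefore enters the membrane
equation at voltage scale; intrinsic currents (leak, exponential,
adaptation, afterpotential) are in pA and divided by C. The standalone
AdEx operation (`plasticv1.adex.adex_step`) takes inputs in pA — the two
conventions are related by the factor C, and the network kernel is
cross-checked against the composed public operations in the test suite.

### Excitatory plasticity (voltage-based STDP)

All excitatory projections (LGN→E, LGN→I, E→I) evolve by

    dw_i/dt = A_LTP x̄_i (u − θ+)₊ (ū+ − θ−)₊ − A_LTD (ū̄/u_ref) X_i (ū− − θ−)₊

where x̄_i is the presynaptic spike trace, ū± are low-pass filtered
membrane potentials (τ+ = 7 ms, τ− = 10 ms), θ+ = −45.3 mV, θ− = −70.6 mV,
and ū̄ is a slow average of the squared suprathreshold-of-rest
depolarization ((u−E_L)₊² filtered at τ = 750 ms) that scales depression
homeostatically against the reference u_ref. Hard bounds [w_min, w_max]
clip after every step; both terms accumulate before the single clip.

Trace conventions, chosen once and used identically in the fused kernel,
the public operations and the test oracles:

* The excitatory rule's presynaptic trace is the exact impulse response of
  its defining ODE: a jump of 1/τ_x (τ_x = 15 ms) per spike with
  exponential decay. This scale is what balances the printed A_LTP
  against A_LTD — with unit jumps, potentiation outweighs depression
  ~15-fold at any rate and the feed-forward weights saturate within
  seconds of simulated time. It also reproduces classic pairing-protocol
  magnitudes (fractions of a percent to a few percent per pairing).
* Traces are updated with the current step's spikes and voltage *before*
  the weight update reads them; the depression term reads the pre-update
  value of ū̄ (an O(dt/τ) convention).
* Per global step the order is: LGN spikes → synaptic currents from the
  previous step's spikes (one-step delay everywhere) → AdEx integration
  and spike detection → plasticity → clipping.

Every 20 s of simulated time the OFF half of each neuron's LGN afferents is
rescaled so its Euclidean norm matches the ON half (both LGN→E and LGN→I),
preventing one input channel from outcompeting the other.

### Inhibitory plasticity (homeostatic symmetric iSTDP)

Inhibitory projections (I→E, I→I) use the symmetric rule: on a
presynaptic spike w += η(x̄_post − ρ), on a postsynaptic spike
w += η x̄_pre, with unit-jump traces at τ = 10 ms and hard bounds. The
fixed point pins the postsynaptic rate near ρ/(2τ) (20 Hz at ρ = 0.4); the
measured operating point sits ~15% above that because each presynaptic
spike causally suppresses the postsynaptic neuron exactly when its trace
is sampled — the toy-circuit acceptance value (23.7 Hz at ρ = 0.4) comes
from an independent long-run scalar simulation. The unit-jump convention
is retained here (unlike the excitatory trace) because ρ of order 0.4–0.7
is only meaningful against the unit-jump trace scale r·τ.

### Variants

`EI2/1` (ρ_I→E = 0.4), `EI3/1` (ρ_I→E = 0.7), `noInh` (no inhibitory
population; reduced LGN→E learning rates), `blockInh` (a trained EI2/1
network with inhibitory transmission zeroed afterwards, sharing its
feed-forward weights), `fix_fb_inh` (I→E frozen) and `fix_ff_inh` (LGN→I
and E→I frozen). The fix_* variants start every projection from
value-shuffled weights of a trained EI2/1 run — preserving each weight
distribution, hence the overall E/I balance — except LGN→E, which is
re-drawn from its uniform init distribution and is plastic in every
variant.

## Synthetic whitened scenes

The generator emulates whitened natural scenes with no download: a
dead-leaves image (occluding disks, radii from an r⁻³ power law — the
standard natural-image surrogate with realistic edge statistics) is
spectrally whitened by dividing out its own radial amplitude profile and
applying the smooth roll-off exp(−(f/f₀)⁴) with f₀ = 200·(size/512)
cycles/image, then a whitened Gaussian texture floor is added at 0.25
relative amplitude, the DC component is removed and the scene is
normalized so max |pixel| = 1. The result is zero-mean, spatially
decorrelated (flat passband amplitude within a factor 2, lag-3
autocorrelation ≪ 0.3) and mildly heavy-tailed, with oriented contours —
the feature of natural input that drives oriented receptive-field
development. A phase-free Gaussian field with the identical spectrum is
available as a control (`structure="gaussian"`); it cannot produce
oriented receptive fields, since whitening leaves it with no higher-order
structure, and training on it yields unstructured ON≈OFF weights. What
the surrogate does **not** emulate: the full kurtosis of natural scenes
(its pixel excess kurtosis is ~2 rather than ~10), occlusion textures,
and long-range contour curvature statistics; passing emergence tests on
it therefore show that the mechanism works on edge-bearing decorrelated
input, not that the quantitative full-scale results of natural images are
reproduced.

## Desk-scale study conditions

The full study (144 E / 36 I, 400,000 stimuli × 125 ms ≈ 14 h simulated
time per run, 20 repetitions) is available by configuration but is not the
default. The desk preset (`plasticv1.study`) uses:

* populations scaled to 36 E / 9 I (4:1 preserved). Projections *from*
  scaled populations (E→I, I→E, I→I) have per-synapse strength — bounds,
  init range and learning rate — multiplied by the inverse population
  ratio so each neuron receives the full-size total input current;
  LGN projections are untouched (the LGN stays at 288 units).
* 50,000 training stimuli, with the iSTDP learning rate scaled by the
  training-length ratio (×8) so the inhibitory weights reach their
  ρ-determined operating point within the shortened run; ρ itself — the
  fixed point — is unchanged.
* measurement ensembles of a few hundred stimuli with 3–5 repetitions
  where the full protocol uses thousands and 50–100 repetitions.

## Measurement choices

* Tuning gratings are sampled directly on the 8° grid over [0°, 180°)
  (23 orientations); since grating responses are 180°-periodic, the full
  0–360° sweep is redundant, and folding it would interleave two grids
  4° apart (180 is not a multiple of 8). Responses are repetition means,
  maximized over 3–5 phases in [0, π] and spatial frequencies in
  [0.05, 0.15] cycles/pixel.
* OBW is the mean half-width at peak/√2 found by linear interpolation on
  both flanks of the (circularly extended) tuning curve. A curve that
  never crosses the level has no measurable bandwidth; population
  summaries count such neurons as maximally broad (90°, half the
  orientation domain). Note the 8° grid's circular wrap gap is 4°, a
  small discretization asymmetry for peaks at the domain edge.
* ODI uses the 23 8°-wide orientation bins and natural logarithms;
  empty bins contribute zero to the divergence.
* The STA is the plain spike-weighted stimulus average. The noise
  ensemble (N(15, 20) Hz clipped at zero, presented on the ON plane) has
  a large mean component that the raw STA retains; filter-recovery
  checks compare the mean-corrected STA (STA minus the ensemble mean
  stimulus) with the ground-truth filter.
* d′ follows the printed definition with *variances* (not standard
  deviations) in the denominator; because both response clouds are
  projected onto the difference of their means, the statistic is
  symmetric and nonnegative in expectation (swapping conditions flips the
  projection axis along with the labels). A conventional
  standard-deviation denominator is available as a toggle.
* The E/I ratio is mean(I_exc)/mean(I_inh) over natural patches, with
  per-neuron currents averaged over the 125 ms window and repetitions;
  it is scale-free, so the voltage-scale current convention does not
  affect it.
* Network state (voltages, traces, currents) persists across stimuli with
  no reset, during training and measurement alike.
* Pairwise response correlations are Pearson correlations of per-stimulus
  spike counts over the 125 ms window; the training log probes them on a
  fixed held-out patch set.

## Numerical and engineering notes

* All randomness flows through named substreams (weight init, patch
  sampling, Poisson draws, reference shuffling) derived from the config
  seed, so variants can share stimulus sequences and checkpoints can
  restore mid-run bit-identically (generator states are serialized).
* The per-presentation simulation kernel (numba) is verified against the
  step-by-step composition of the public operations; the exponential term
  argument is capped at 30 (the value is discarded by the spike reset).
* Training aborts with a "runaway weights" error when >99% of the LGN→E
  weights saturate at w_max — the known instability of the excitatory
  rule under unsuitable conditions.

## Known limitations

* At desk scale the feed-forward weights do not reach the strongly
  bimodal min/max distribution of the full-scale study; individual
  weights keep fluctuating under the (deliberately fast) learning rates,
  and orientation tuning is correspondingly broad and shallow. Contrasts
  *between* variants (baseline activity, bandwidth, correlation,
  contrast-invariance) are robust; absolute tuning sharpness is not.
* Orientation diversity at 36 neurons materializes as a few orientation
  clusters per run; the ODI is accordingly noisy, and for unselective
  populations (the desk-scale noInh model at any contrast) the
  argmax-preferred orientation is close to arbitrary, which inflates
  apparent diversity — the cross-variant ODI ordering of the full-scale
  study is therefore not reliably reproduced at desk scale.
* The desk-scale blockInh and noInh tuning curves never cross the
  bandwidth level at any contrast, so their OBW summaries peg at the
  maximal width and contrast-dependent broadening is not measurable for
  them (their measurable spread degenerates to zero; circular variance
  degenerates the same way, pinned near 1).
* VT_max is implemented as printed (+30.4 mV) and exposed as a parameter;
  with the alternative sign (−30.4 mV) the threshold recovers faster and
  burst statistics change.
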