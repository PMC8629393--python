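"""Desk-scale study preset: scaled populations, shortened training, and the
measurement panel used to compare model variants.

The full-size study (144 E / 36 I, 400,000 stimuli, ~14 h simulated time
per run, 20 repetitions) is a configuration choice; the preset here scales
the V1 populations to 36 E / 9 I (keeping 4:1), trains on 50,000 patches
from surrogate whitened scenes, and compensates the shortened run by
scaling the iSTDP learning rate with the training-length ratio (the
ρ-determined operating points are unchanged).  Projections from the scaled
populations keep the full-size total input current (see
:class:`~plasticv1.network.Network`).
"""

from __future__ import annotations

import numpy as np

from .metrics import (
    TuningResult,
    UndefinedMetric,
    measure_tuning,
    mutual_information_per_spike,
    population_obw,
    population_sparseness,
)
from .network import Network, NetworkConfig, build_network, present_stimulus, train
from .stimuli import NATURAL_R_MAX, on_off_split, sample_patch
from .synthetic import generate_scene_set

__all__ = [
    "DESK_SCALE",
    "DESK_N_STIMULI",
    "DESK_ETA_SCALE",
    "CONTRAST_LEVELS",
    "desk_config",
    "training_scenes",
    "train_desk_variant",
    "natural_patch_counts",
    "repeated_patch_counts",
    "tuning_panel",
    "mean_obw",
    "obw_contrast_spread",
    "width_contrast_spread",
    "summarize_sparseness",
    "summarize_information",
]

#: desk-scale study conditions
DESK_SCALE = 0.25          # 36 excitatory / 9 inhibitory neurons
DESK_N_STIMULI = 50_000    # training patches (full study: 400,000)
DESK_ETA_SCALE = 8.0       # iSTDP speed-up = 400,000 / 50,000
#: grating peak-rate sweep for contrast analyses (Hz)
CONTRAST_LEVELS = (14.25, 40.0, 100.0)
#: a tuning curve that never drops below peak/sqrt(2) has no measurable
#: bandwidth; summaries count it as maximally broad (half the 180° domain)
OBW_UNDEFINED_DEG = 90.0


def desk_config(variant: str, seed: int) -> NetworkConfig:
    return NetworkConfig(
        variant=variant, seed=seed, scale_factor=DESK_SCALE,
        n_stimuli=DESK_N_STIMULI, eta_scale=DESK_ETA_SCALE,
    )


def training_scenes(seed: int, n_scenes: int = 10, size: int = 128):
    """The surrogate whitened-scene set for one study repetition."""
    return generate_scene_set(n_scenes, np.random.default_rng(seed + 7_000_000), size=size)


def train_desk_variant(
    variant: str,
    seed: int,
    scenes,
    n_stimuli: int = DESK_N_STIMULI,
    reference_weights: dict | None = None,
    log_every: int = 2500,
):
    """Build and train one variant under the desk-scale study conditions."""
    net = build_network(desk_config(variant, seed), reference_weights=reference_weights)
    log = train(net, scenes, n_stimuli=n_stimuli, log_every=log_every)
    return net, log


def natural_patch_counts(net: Network, scenes, n_stimuli: int, seed: int) -> np.ndarray:
    """Spike counts (n_stimuli, n_exc) on random natural patches,
    plasticity off; the probe ensemble for sparseness/correlation."""
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_stimuli, net.config.n_exc))
    for s in range(n_stimuli):
        scene = scenes[int(rng.integers(len(scenes)))]
        rates = on_off_split(sample_patch(scene, rng), NATURAL_R_MAX)
        _, tr = present_stimulus(net, rates, plastic=False, record=False)
        counts[s] = tr["spikes_e"].sum(axis=0)
    return counts


def repeated_patch_counts(
    net: Network, scenes, n_stimuli: int, n_reps: int, seed: int
) -> np.ndarray:
    """Counts (n_stimuli, n_reps, n_exc) on a fixed repeated stimulus set;
    the ensemble for information and discriminability measures."""
    rng = np.random.default_rng(seed)
    stim = []
    for _ in range(n_stimuli):
        scene = scenes[int(rng.integers(len(scenes)))]
        stim.append(on_off_split(sample_patch(scene, rng), NATURAL_R_MAX))
    counts = np.zeros((n_stimuli, n_reps, net.config.n_exc))
    for k, rates in enumerate(stim):
        for i in range(n_reps):
            _, tr = present_stimulus(net, rates, plastic=False, record=False)
            counts[k, i] = tr["spikes_e"].sum(axis=0)
    return counts


def tuning_panel(
    net: Network,
    contrasts=CONTRAST_LEVELS,
    n_reps: int = 5,
    n_phases: int = 4,
    n_freqs: int = 3,
) -> dict[float, TuningResult]:
    """Grating tuning at each contrast (desk-scale sampling)."""
    return {
        c: measure_tuning(net, r_max=c, n_reps=n_reps, n_phases=n_phases,
                          n_freqs=n_freqs)
        for c in contrasts
    }


def mean_obw(tuning: TuningResult, undefined: float = OBW_UNDEFINED_DEG) -> float:
    """Population-mean OBW with undefined bandwidths counted as maximally
    broad."""
    obw = population_obw(tuning)
    return float(np.where(np.isnan(obw), undefined, obw).mean())


def obw_contrast_spread(panel: dict[float, TuningResult]) -> float:
    """Max minus min of the population-mean OBW across contrast levels —
    zero for perfectly contrast-invariant tuning width."""
    means = [mean_obw(t) for t in panel.values()]
    return float(max(means) - min(means))


def width_contrast_spread(panel: dict[float, TuningResult]) -> float:
    """Contrast spread of tuning width measured by circular variance.

    Unlike the OBW, the circular variance is defined for arbitrarily
    broad curves, so this spread stays meaningful for variants whose
    curves never cross the bandwidth level (where the OBW summary pegs at
    the maximal width and its spread degenerates to zero).
    """
    from .metrics import circular_variance

    means = []
    for tun in panel.values():
        cvs = []
        for j in range(tun.response.shape[0]):
            try:
                cvs.append(circular_variance(tun.response[j], tun.orientations))
            except UndefinedMetric:
                pass
        means.append(float(np.mean(cvs)) if cvs else np.nan)
    return float(np.nanmax(means) - np.nanmin(means))


def summarize_sparseness(counts: np.ndarray) -> float:
    """Mean population sparseness over a probe ensemble (silent stimuli,
    for which sparseness is undefined, are skipped)."""
    vals = []
    for row in counts:
        try:
            vals.append(population_sparseness(row))
        except UndefinedMetric:
            pass
    return float(np.mean(vals)) if vals else float("nan")


def summarize_information(counts3: np.ndarray) -> float:
    """Mean bits/spike over neurons (neurons with no spikes skipped)."""
    vals = []
    for j in range(counts3.shape[2]):
        try:
            vals.append(mutual_information_per_spike(counts3[:, :, j]))
        except UndefinedMetric:
            pass
    return float(np.mean(vals)) if vals else float("nan")
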