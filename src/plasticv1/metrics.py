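"""Quantitative analyses: receptive fields, tuning, balance, sparseness,
reconstruction, information, discriminability, correlation structure.

All metrics are deterministic given recorded responses; randomness lives
only in the simulation protocols (functions taking a ``Network``), which
draw from the network's own Poisson substream.  Undefined cases (zero
spikes, all-zero response vectors, a tuning curve that never crosses the
bandwidth level) raise :class:`UndefinedMetric`, which protocol wrappers
convert to NaN where a population summary is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import (
    GRATING_R_MAX,
    NATURAL_R_MAX,
    GratingSpec,
    OnOffRates,
    WhitenedScene,
    make_grating,
    make_noise_patch,
    on_off_split,
    sample_patch,
)

__all__ = [
    "UndefinedMetric",
    "ReceptiveField",
    "TuningResult",
    "rf_from_weights",
    "receptive_field_maps",
    "spike_triggered_average",
    "measure_sta",
    "rf_similarity",
    "measure_tuning",
    "orientation_bandwidth",
    "population_obw",
    "circular_variance",
    "orientation_diversity_index",
    "gain_curve",
    "ei_ratio",
    "population_sparseness",
    "reconstruction_error",
    "image_reconstruction_error",
    "mutual_information_per_spike",
    "discriminability",
    "correlation_vs_similarity",
    "mean_pairwise_correlation",
    "DEFAULT_ORIENTATIONS",
]

#: orientation grid for tuning measurements: 8° steps over [0°, 180°)
DEFAULT_ORIENTATIONS = np.arange(0.0, 180.0, 8.0)


class UndefinedMetric(ValueError):
    """Raised when a metric has no defined value for the given input."""


@dataclass
class ReceptiveField:
    """Signed 12x12 spatial weighting of visual input for one neuron."""

    map: np.ndarray
    neuron: int = 0


@dataclass
class TuningResult:
    """Orientation tuning of a population at one contrast.

    ``response[j, k]`` is neuron j's mean spike count per presentation at
    orientation k, maximized over the probed phases and spatial
    frequencies; ``i_exc[j, k]`` is the matching mean excitatory input
    current (taken at the response-maximizing phase/frequency).
    """

    orientations: np.ndarray
    response: np.ndarray
    i_exc: np.ndarray
    contrast: float

    @property
    def preferred(self) -> np.ndarray:
        return self.orientations[np.argmax(self.response, axis=1)]


# -- receptive fields ------------------------------------------------------

def rf_from_weights(weights_lgn: np.ndarray, neuron: int, patch_size: int = 12) -> ReceptiveField:
    """ON-minus-OFF feed-forward weight map of one neuron.

    Reverts the ON/OFF input mapping: since at most one of the two planes
    is driven per pixel, the difference of the learned weight halves
    recovers the neuron's signed receptive field.
    """
    half = weights_lgn.shape[0] // 2
    col = weights_lgn[:, neuron]
    rf = (col[:half] - col[half:]).reshape(patch_size, patch_size)
    return ReceptiveField(map=rf, neuron=neuron)


def receptive_field_maps(weights_lgn: np.ndarray, patch_size: int = 12) -> np.ndarray:
    """All receptive fields as an array of shape (n_neurons, p, p)."""
    half = weights_lgn.shape[0] // 2
    diff = weights_lgn[:half] - weights_lgn[half:]
    return diff.T.reshape(-1, patch_size, patch_size)


def spike_triggered_average(stimuli: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Spike-count-weighted stimulus average: STA = (1/N) Σ_spikes s.

    ``stimuli`` has one stimulus per row (any trailing shape); ``counts``
    are the spikes each stimulus elicited.  With zero total spikes the STA
    is undefined.  Note the plain average retains the ensemble-mean
    stimulus; subtract ``stimuli.mean(axis=0)`` to recover a zero-mean
    filter estimate from a biased ensemble.
    """
    counts = np.asarray(counts, dtype=float)
    stimuli = np.asarray(stimuli, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise UndefinedMetric("STA undefined: neuron emitted no spikes")
    return np.tensordot(counts, stimuli, axes=1) / total


def measure_sta(
    net,
    n_stimuli: int = 2000,
    noise_mean: float = 15.0,
    noise_sd: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-patch mapping protocol: returns (stimuli, counts).

    Presents clipped-Gaussian noise patches for 125 ms each and records the
    excitatory population's spike counts; feed the columns of ``counts``
    to :func:`spike_triggered_average`.
    """
    from .network import present_stimulus

    size = int(np.sqrt(net.config.n_lgn // 2))
    stimuli = np.zeros((n_stimuli, size, size))
    counts = np.zeros((n_stimuli, net.config.n_exc))
    rng = net.rng["poisson"]
    for k in range(n_stimuli):
        patch = make_noise_patch(rng, size=size, mean=noise_mean, sd=noise_sd)
        stimuli[k] = patch.signed()
        _, tr = present_stimulus(net, patch, plastic=False, record=False)
        counts[k] = tr["spikes_e"].sum(axis=0)
    return stimuli, counts


def rf_similarity(rf_a: np.ndarray | ReceptiveField, rf_b: np.ndarray | ReceptiveField) -> float:
    """Cosine of the angle between two receptive-field (weight) vectors."""
    a = (rf_a.map if isinstance(rf_a, ReceptiveField) else np.asarray(rf_a, dtype=float)).ravel()
    b = (rf_b.map if isinstance(rf_b, ReceptiveField) else np.asarray(rf_b, dtype=float)).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedMetric("similarity undefined for zero vector")
    return float(np.dot(a, b) / (na * nb))


# -- tuning ----------------------------------------------------------------

def measure_tuning(
    net,
    r_max: float = GRATING_R_MAX,
    orientations: np.ndarray = DEFAULT_ORIENTATIONS,
    n_phases: int = 5,
    n_freqs: int = 5,
    n_reps: int = 50,
) -> TuningResult:
    """Grating tuning protocol at one contrast (peak input rate ``r_max``).

    Each (orientation, phase, frequency) combination is presented
    ``n_reps`` times for 125 ms with plasticity off; the per-orientation
    response is the repetition-mean spike count, maximized over phase and
    spatial frequency.
    """
    from .network import present_stimulus

    phases = np.linspace(0.0, np.pi, n_phases)
    freqs = np.linspace(0.05, 0.15, n_freqs)
    nE = net.config.n_exc
    response = np.zeros((nE, len(orientations)))
    i_exc = np.zeros((nE, len(orientations)))
    for k, theta in enumerate(orientations):
        best = np.zeros(nE)
        best_i = np.zeros(nE)
        for phi in phases:
            for f in freqs:
                rates = make_grating(GratingSpec(
                    orientation=float(theta) % 360.0, phase=float(phi),
                    spatial_frequency=float(f), r_max=r_max,
                ))
                mean_count = np.zeros(nE)
                mean_iexc = np.zeros(nE)
                for _ in range(n_reps):
                    _, tr = present_stimulus(net, rates, plastic=False, record=False)
                    mean_count += tr["spikes_e"].sum(axis=0)
                    mean_iexc += tr["i_exc"].mean(axis=0)
                mean_count /= n_reps
                mean_iexc /= n_reps
                better = mean_count > best
                best[better] = mean_count[better]
                best_i[better] = mean_iexc[better]
        response[:, k] = best
        i_exc[:, k] = best_i
    return TuningResult(orientations=np.asarray(orientations, dtype=float),
                        response=response, i_exc=i_exc, contrast=r_max)


def orientation_bandwidth(
    response: np.ndarray,
    orientations: np.ndarray = DEFAULT_ORIENTATIONS,
    period: float = 180.0,
) -> float:
    """Half-width of a tuning curve at peak/sqrt(2), in degrees.

    The curve is treated as periodic in orientation; each flank's crossing
    of the 1/sqrt(2) level is located by linear interpolation and the OBW
    is the mean of the two half-widths.  A curve that never crosses the
    level (e.g. flat) has no defined bandwidth.
    """
    r = np.asarray(response, dtype=float)
    orientations = np.asarray(orientations, dtype=float)
    n = r.size
    if n < 3:
        raise UndefinedMetric("too few orientations for a bandwidth")
    gap = float(orientations[1] - orientations[0])  # uniform grid
    peak = int(np.argmax(r))
    level = r[peak] / np.sqrt(2.0)
    half_widths = []
    for direction in (+1, -1):
        width = None
        for s in range(1, n):
            i_prev = (peak + direction * (s - 1)) % n
            i_cur = (peak + direction * s) % n
            if r[i_cur] < level:
                # linear interpolation between the bracketing samples
                frac = (r[i_prev] - level) / (r[i_prev] - r[i_cur])
                width = (s - 1 + frac) * gap
                break
        if width is None:
            raise UndefinedMetric("tuning curve never crosses the 1/sqrt(2) level")
        half_widths.append(width)
    return float(np.mean(half_widths))


def population_obw(tuning: TuningResult) -> np.ndarray:
    """Per-neuron OBW; NaN where the bandwidth is undefined."""
    out = np.full(tuning.response.shape[0], np.nan)
    for j in range(out.size):
        try:
            out[j] = orientation_bandwidth(tuning.response[j], tuning.orientations)
        except UndefinedMetric:
            pass
    return out


def circular_variance(
    response: np.ndarray,
    orientations: np.ndarray = DEFAULT_ORIENTATIONS,
) -> float:
    """Orientation circular variance: 1 - |Σ R exp(2iθ)| / Σ R.

    0 for a perfectly selective curve, 1 for a flat one.  Unlike the OBW
    it is defined for arbitrarily broad curves, which makes it the width
    proxy of choice when a curve never crosses the bandwidth level.
    """
    r = np.asarray(response, dtype=float)
    total = r.sum()
    if total <= 0:
        raise UndefinedMetric("circular variance undefined for zero response")
    theta = np.deg2rad(np.asarray(orientations, dtype=float))
    vector = np.sum(r * np.exp(2j * theta))
    return float(1.0 - np.abs(vector) / total)


def orientation_diversity_index(
    preferred: np.ndarray,
    n_bins: int = len(DEFAULT_ORIENTATIONS),
    domain: float = 180.0,
) -> float:
    """exp(-KL divergence) between the preferred-orientation histogram and
    a uniform distribution; 1 means maximally diverse, 1/K means all mass
    in one of the K bins.  Empty bins contribute zero to the divergence.
    """
    preferred = np.asarray(preferred, dtype=float)
    if preferred.size == 0:
        raise UndefinedMetric("ODI undefined for an empty population")
    hist, _ = np.histogram(preferred % domain, bins=n_bins, range=(0.0, domain))
    P = hist / hist.sum()
    Q = 1.0 / n_bins
    nz = P > 0
    dkl = float(np.sum(P[nz] * np.log(P[nz] / Q)))
    return float(np.exp(-dkl))


def gain_curve(
    net,
    contrasts: tuple = (14.25, 100.0),
    n_bins: int = 20,
    **tuning_kwargs,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Population response gain: spike count vs excitatory input current.

    For each contrast (peak input rate, Hz) the grating protocol is run
    over orientations from orthogonal to preferred for every neuron; the
    (mean I_exc, mean count) pairs of all neurons and orientations are
    pooled, sorted by current in ascending order and binned.  Returns
    {contrast: (bin-mean current, bin-mean count)}.
    """
    out = {}
    for c in contrasts:
        tun = measure_tuning(net, r_max=c, **tuning_kwargs)
        x = tun.i_exc.ravel()
        y = tun.response.ravel()
        order = np.argsort(x)
        x, y = x[order], y[order]
        edges = np.array_split(np.arange(x.size), n_bins)
        xb = np.array([x[idx].mean() for idx in edges if idx.size])
        yb = np.array([y[idx].mean() for idx in edges if idx.size])
        out[c] = (xb, yb)
    return out


# -- currents --------------------------------------------------------------

def ei_ratio(
    net,
    scenes: list[WhitenedScene],
    n_scenes: int = 1000,
    n_reps: int = 100,
    n_bins: int = 20,
    r_max: float = NATURAL_R_MAX,
) -> dict:
    """Excitation/inhibition balance at the excitatory population.

    Presents random natural-scene patches, averages each neuron's incoming
    currents over the 125 ms window and the repetitions, sorts the
    (I_exc, I_inh) pairs by excitatory current and bins them.  The summary
    ratio is mean(I_exc)/mean(I_inh); with no inhibitory transmission the
    ratio is reported as infinite.
    """
    from .network import present_stimulus

    rng = net.rng["patches"]
    nE = net.config.n_exc
    iexc = np.zeros((n_scenes, nE))
    iinh = np.zeros((n_scenes, nE))
    for s in range(n_scenes):
        scene = scenes[int(rng.integers(len(scenes)))]
        rates = on_off_split(sample_patch(scene, rng), r_max)
        for _ in range(n_reps):
            _, tr = present_stimulus(net, rates, plastic=False, record=False)
            iexc[s] += tr["i_exc"].mean(axis=0)
            iinh[s] += tr["i_inh"].mean(axis=0)
    iexc /= n_reps
    iinh /= n_reps
    x, y = iexc.ravel(), iinh.ravel()
    order = np.argsort(x)
    x, y = x[order], y[order]
    chunks = np.array_split(np.arange(x.size), n_bins)
    curve = (
        np.array([x[idx].mean() for idx in chunks if idx.size]),
        np.array([y[idx].mean() for idx in chunks if idx.size]),
    )
    mean_inh = float(np.mean(iinh))
    ratio = np.inf if mean_inh == 0 else float(np.mean(iexc) / mean_inh)
    return {"ratio": ratio, "curve": curve, "i_exc": iexc, "i_inh": iinh,
            "zero_inhibition": mean_inh == 0}


# -- population codes ------------------------------------------------------

def population_sparseness(responses: np.ndarray) -> float:
    """Vinje-Gallant population sparseness of one stimulus's response.

    S = (1 - (Σr/n)²/Σ(r²/n)) / (1 - 1/n): 1 for a one-hot response, 0 for
    a uniform one.
    """
    r = np.asarray(responses, dtype=float)
    n = r.size
    if n < 2:
        raise UndefinedMetric("sparseness needs at least two neurons")
    denom = np.sum(r**2) / n
    if denom == 0:
        raise UndefinedMetric("sparseness undefined for all-zero response")
    return float((1.0 - (np.sum(r) / n) ** 2 / denom) / (1.0 - 1.0 / n))


def reconstruction_error(original: np.ndarray, reconstruction: np.ndarray) -> float:
    """RMS pixel difference after z-normalizing both images.

    Normalization to zero mean and unit variance makes the error invariant
    to affine rescaling of the reconstruction.
    """
    def znorm(img):
        img = np.asarray(img, dtype=float)
        sd = img.std()
        return (img - img.mean()) / sd if sd > 0 else img - img.mean()

    a, b = znorm(original), znorm(reconstruction)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def image_reconstruction_error(
    net,
    scene: WhitenedScene,
    stride: int = 3,
    n_reps: int = 50,
    r_max: float = NATURAL_R_MAX,
    patch_size: int = 12,
) -> float:
    """Linear-decoding reconstruction error of a whole scene.

    The scene is tiled into overlapping patches (stride 3); each patch is
    presented ``n_reps`` times and the repetition-mean spike counts weight
    the neurons' feed-forward receptive fields to form a linear patch
    reconstruction; overlapping reconstructions are averaged and the
    z-normalized RMS error against the original scene is returned.
    """
    from .network import present_stimulus

    img = scene.pixels
    h, w = img.shape
    if h < patch_size or w < patch_size:
        raise ValueError("scene smaller than patch")
    rfs = receptive_field_maps(net.weights["lgn_e"], patch_size)
    divisor = scene.norm_divisor or 1.0
    recon = np.zeros_like(img)
    weight = np.zeros_like(img)
    for r0 in range(0, h - patch_size + 1, stride):
        for c0 in range(0, w - patch_size + 1, stride):
            patch = img[r0:r0 + patch_size, c0:c0 + patch_size] / divisor
            rates = on_off_split(patch, r_max)
            mean_count = np.zeros(net.config.n_exc)
            for _ in range(n_reps):
                _, tr = present_stimulus(net, rates, plastic=False, record=False)
                mean_count += tr["spikes_e"].sum(axis=0)
            mean_count /= n_reps
            patch_recon = np.tensordot(mean_count, rfs, axes=1)
            recon[r0:r0 + patch_size, c0:c0 + patch_size] += patch_recon
            weight[r0:r0 + patch_size, c0:c0 + patch_size] += 1.0
    covered = weight > 0
    recon[covered] /= weight[covered]
    return reconstruction_error(img[covered], recon[covered])


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a spike-count sample."""
    _, freq = np.unique(counts, return_counts=True)
    p = freq / freq.sum()
    return float(-np.sum(p * np.log2(p)))


def mutual_information_per_spike(counts: np.ndarray) -> float:
    """Stimulus information per spike (bits/spike) for one neuron.

    ``counts[k, i]`` is the spike count on repetition i of stimulus k.
    I(s,r) = H(r) - H(r|s) with H(r) from the pooled count distribution
    and H(r|s) the repetition-wise entropy averaged over stimuli; the
    result is divided by the mean spikes per stimulus bin.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise UndefinedMetric("need >= 2 stimuli with repetitions")
    mean_spikes = counts.mean()
    if mean_spikes == 0:
        raise UndefinedMetric("information per spike undefined with no spikes")
    h_total = _entropy(counts.ravel())
    h_noise = float(np.mean([_entropy(row) for row in counts]))
    return (h_total - h_noise) / mean_spikes


def discriminability(
    responses_a: np.ndarray,
    responses_b: np.ndarray,
    variance_denominator: bool = True,
) -> float:
    """d' between two stimulus-conditioned population response clouds.

    Each repetition (row) is projected onto the difference of the two mean
    responses; d' is the separation of the projected means over the mean
    of the projected variances (the printed convention; set
    ``variance_denominator=False`` for the usual standard-deviation form).
    """
    a = np.atleast_2d(np.asarray(responses_a, dtype=float))
    b = np.atleast_2d(np.asarray(responses_b, dtype=float))
    diff = a.mean(axis=0) - b.mean(axis=0)
    alpha_a = a @ diff
    alpha_b = b @ diff
    var_a, var_b = alpha_a.var(), alpha_b.var()
    denom = 0.5 * (var_a + var_b)
    if not variance_denominator:
        denom = np.sqrt(denom)
    if denom == 0:
        if alpha_a.mean() == alpha_b.mean():
            return 0.0
        raise UndefinedMetric("zero projected variance in both conditions")
    return float((alpha_a.mean() - alpha_b.mean()) / denom)


def mean_pairwise_correlation(counts: np.ndarray) -> tuple[float, int]:
    """Mean Pearson correlation between neurons' per-stimulus responses.

    ``counts[s, j]`` is neuron j's spike count on stimulus s.  Neurons
    with constant response are excluded; returns (mean correlation over
    the remaining pairs, number of neurons excluded).
    """
    counts = np.asarray(counts, dtype=float)
    sd = counts.std(axis=0)
    keep = sd > 0
    n_excluded = int(np.sum(~keep))
    kept = counts[:, keep]
    if kept.shape[1] < 2:
        raise UndefinedMetric("fewer than two non-constant neurons")
    corr = np.corrcoef(kept.T)
    iu = np.triu_indices(corr.shape[0], k=1)
    return float(np.mean(corr[iu])), n_excluded


def correlation_vs_similarity(
    responses: np.ndarray,
    rfs: np.ndarray,
    n_bins: int = 30,
) -> dict:
    """Pairwise response correlation as a function of RF similarity.

    ``responses[j, s]`` are per-stimulus rates (or counts) of neuron j;
    ``rfs[j]`` the matching receptive-field maps/weight vectors.  Pairs
    are binned by cosine similarity into equal-width bins spanning [-1, 1];
    pairs involving a constant-rate neuron are excluded (count reported).
    """
    responses = np.asarray(responses, dtype=float)
    n = responses.shape[0]
    if n < 2 or responses.shape[1] < 2:
        raise UndefinedMetric("need >= 2 neurons and >= 2 stimuli")
    rf_flat = np.asarray(rfs, dtype=float).reshape(n, -1)
    sd = responses.std(axis=1)
    keep = sd > 0
    n_excluded = int(np.sum(~keep))

    sims, corrs = [], []
    corr_mat = np.corrcoef(responses[keep])
    idx = np.flatnonzero(keep)
    for ai in range(idx.size):
        for bi in range(ai + 1, idx.size):
            sims.append(rf_similarity(rf_flat[idx[ai]], rf_flat[idx[bi]]))
            corrs.append(corr_mat[ai, bi])
    sims = np.asarray(sims)
    corrs = np.asarray(corrs)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(sims, edges) - 1, 0, n_bins - 1)
    bin_mean = np.full(n_bins, np.nan)
    bin_count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        m = which == b
        bin_count[b] = m.sum()
        if bin_count[b]:
            bin_mean[b] = corrs[m].mean()
    return {
        "bin_centers": 0.5 * (edges[:-1] + edges[1:]),
        "bin_mean_correlation": bin_mean,
        "bin_count": bin_count,
        "mean_correlation": float(corrs.mean()),
        "n_neurons_excluded": n_excluded,
    }
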