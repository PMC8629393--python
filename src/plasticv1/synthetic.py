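"""Synthetic inputs and ground-truth fixtures: whitened scenes, Gabors, LNP.

Everything the pipeline consumes can be generated here without any
download: surrogate whitened natural scenes (zero-mean, spatially
decorrelated Gaussian random fields with the classic sparse-coding
whitening profile), Gabor receptive-field fixtures that can be installed
as frozen feed-forward weights, and linear-nonlinear-Poisson (LNP)
surrogate neurons that serve as analytically known targets for the
receptive-field and tuning estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import OnOffRates, WhitenedScene

__all__ = [
    "SyntheticSceneParams",
    "GaborFixture",
    "LnpNeuron",
    "generate_whitened_scene",
    "generate_scene_set",
    "gabor_map",
    "make_gabor_population",
    "install_gabor_weights",
    "lnp_surrogate",
]


@dataclass
class SyntheticSceneParams:
    """Size, structure and whitening roll-off of a surrogate scene.

    ``structure`` selects the pre-whitening image model: ``"leaves"``
    (default) paints occluding disks with power-law radii — the classic
    dead-leaves surrogate whose edge statistics match natural photographs,
    so oriented contours survive whitening — and superimposes a dense
    decorrelated texture floor (``texture_mix`` sets its amplitude
    relative to the edge component), reproducing the two components of a
    whitened natural scene: sparse oriented structure over broadband
    texture.  ``"gaussian"`` gives the pure phase-free field (spectrally
    identical but without higher-order structure).
    """

    size: int = 128
    cutoff_frequency: float | None = None  # cycles/image; default 200*(size/512)
    structure: str = "leaves"
    n_leaves: int = 400
    min_radius: float = 3.0
    texture_mix: float = 0.25
    #: degrees of freedom of the Student-t leaf-shade distribution; small
    #: values give rare very-dark/bright leaves, so the per-scene
    #: normalizing maximum is rare and typical pixels are small relative
    #: to it; None uses uniform shades
    shade_df: float | None = None

    def __post_init__(self) -> None:
        if self.size < 12:
            raise ValueError("scene must be at least 12 pixels")
        if self.structure not in ("leaves", "gaussian"):
            raise ValueError("structure must be 'leaves' or 'gaussian'")
        if self.cutoff_frequency is None:
            # the classic whitening ramp f*exp(-(f/f0)^4) uses f0 = 200
            # cycles/image on 512-pixel images; scale f0 with image size
            self.cutoff_frequency = 200.0 * self.size / 512.0


def generate_whitened_scene(
    params: SyntheticSceneParams,
    rng: np.random.Generator,
    scene_id: str = "synthetic",
) -> WhitenedScene:
    """Surrogate whitened natural scene.

    A Gaussian random field with 1/f amplitude is whitened by the ramp
    f*exp(-(f/f0)^4), leaving a flat amplitude spectrum with a smooth
    high-frequency cutoff; the field is zero-mean (DC removed) and
    normalized so the maximum absolute pixel value is 1, matching the
    per-scene normalization applied to real whitened scenes.
    """
    n = params.size
    f0 = params.cutoff_frequency

    if params.structure == "leaves":
        raw = _dead_leaves(n, params.n_leaves, params.min_radius, rng,
                           params.shade_df)
        img = _whiten(raw, f0)
        if params.texture_mix > 0:
            texture = _whiten(rng.standard_normal((n, n)), f0)
            img = img / img.std() + params.texture_mix * texture / texture.std()
            img -= img.mean()
    else:
        img = _whiten(rng.standard_normal((n, n)), f0)

    img /= np.max(np.abs(img))
    return WhitenedScene(pixels=img, scene_id=scene_id)


def _whiten(raw: np.ndarray, f0: float) -> np.ndarray:
    """Flatten the radial amplitude spectrum, then roll off high
    frequencies with exp(-(f/f0)^4); removes the DC component."""
    n = raw.shape[0]
    fx = np.fft.fftfreq(n) * n  # cycles/image
    f = np.hypot(*np.meshgrid(fx, fx))
    spectrum = np.fft.fft2(raw)
    fi = np.clip(np.round(f).astype(np.int64), 0, n)
    power = np.abs(spectrum) ** 2
    radial = np.bincount(fi.ravel(), weights=power.ravel(), minlength=n + 1)
    counts = np.bincount(fi.ravel(), minlength=n + 1)
    mean_amp = np.sqrt(radial / np.maximum(counts, 1))
    mean_amp[mean_amp == 0] = 1.0
    flat = spectrum / mean_amp[fi]
    flat *= np.exp(-((f / f0) ** 4))
    flat[0, 0] = 0.0  # zero mean by construction
    return np.real(np.fft.ifft2(flat))


def _dead_leaves(
    n: int,
    n_leaves: int,
    min_radius: float,
    rng: np.random.Generator,
    shade_df: float | None = None,
) -> np.ndarray:
    """Occluding disks with ~r^-3 radius law; gray levels uniform or heavy-tailed."""
    img = np.zeros((n, n))
    rows, cols = np.mgrid[0:n, 0:n]
    r_max = n / 2.0
    # stratified inverse-CDF sampling of p(r) ~ r^-3 on [min_radius, r_max]:
    # one draw per quantile stratum, so every scene carries the same radius
    # mix (iid draws make scene statistics vary too much between sets)
    u = (np.arange(n_leaves) + rng.random(n_leaves)) / n_leaves
    a, b = min_radius ** -2, r_max ** -2
    radii = (a - u * (a - b)) ** -0.5
    rng.shuffle(radii)  # decouple radius from painting (occlusion) order
    cy = rng.uniform(0, n, n_leaves)
    cx = rng.uniform(0, n, n_leaves)
    if shade_df is None:
        shade = rng.uniform(-1.0, 1.0, n_leaves)
    else:
        shade = rng.standard_t(shade_df, n_leaves)
    for k in range(n_leaves):  # painter's order: later leaves occlude
        mask = (rows - cy[k]) ** 2 + (cols - cx[k]) ** 2 <= radii[k] ** 2
        img[mask] = shade[k]
    return img


def generate_scene_set(
    n_scenes: int,
    rng: np.random.Generator,
    size: int = 128,
) -> list[WhitenedScene]:
    """A batch of surrogate scenes, e.g. as a training scene source."""
    params = SyntheticSceneParams(size=size)
    return [
        generate_whitened_scene(params, rng, scene_id=f"synthetic-{k}")
        for k in range(n_scenes)
    ]


@dataclass
class GaborFixture:
    """A rendered Gabor receptive field with its ON/OFF weight split."""

    orientation: float       # degrees in [0, 180)
    phase: float             # radians
    wavelength: float        # pixels/cycle
    envelope_sd: float       # Gaussian envelope, pixels
    map: np.ndarray = None   # unit-norm signed 12x12 map
    size: int = 12

    def __post_init__(self) -> None:
        if self.map is None:
            self.map = gabor_map(
                self.orientation, self.phase, self.wavelength,
                self.envelope_sd, self.size,
            )

    def on_off_weights(self, scale: float = 1.0) -> np.ndarray:
        """Flat (2*size², ) weight vector: ON half then OFF half."""
        on = np.maximum(self.map, 0.0).ravel()
        off = np.maximum(-self.map, 0.0).ravel()
        return scale * np.concatenate([on, off])


def gabor_map(
    orientation: float,
    phase: float,
    wavelength: float,
    envelope_sd: float,
    size: int = 12,
) -> np.ndarray:
    """Unit-norm Gabor: oriented sinusoid under a Gaussian envelope.

    Uses the same carrier convention as the grating generator, so a
    grating at the Gabor's orientation maximally overlaps it.
    """
    theta = np.deg2rad(orientation)
    c = (size - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(size) - c, np.arange(size) - c)
    carrier = np.cos(
        2.0 * np.pi / wavelength * (cols * np.cos(theta) + rows * np.sin(theta))
        + phase
    )
    envelope = np.exp(-(cols**2 + rows**2) / (2.0 * envelope_sd**2))
    g = carrier * envelope
    g -= g.mean()  # zero net luminance, like a whitened simple-cell RF
    return g / np.linalg.norm(g)


def make_gabor_population(
    n: int,
    rng: np.random.Generator,
    wavelength: float = 8.0,
    envelope_sd: float = 3.0,
    size: int = 12,
) -> list[GaborFixture]:
    """Gabor fixtures with orientations tiling [0°, 180°) uniformly.

    Phases are drawn uniformly from [0, π); orientations are the exact
    uniform grid i*180/n, so the constructed-orientation histogram (hence
    the population's ODI ground truth) is known by construction.
    """
    if n < 1:
        raise ValueError("need at least one fixture")
    return [
        GaborFixture(
            orientation=180.0 * k / n,
            phase=float(rng.uniform(0.0, np.pi)),
            wavelength=wavelength,
            envelope_sd=envelope_sd,
            size=size,
        )
        for k in range(n)
    ]


def install_gabor_weights(net, fixtures: list[GaborFixture], scale: float = 1.0) -> None:
    """Install fixtures as frozen LGN→E weights of a network (in place)."""
    W = net.weights["lgn_e"]
    if len(fixtures) != W.shape[1]:
        raise ValueError("one fixture per excitatory neuron required")
    for j, fx in enumerate(fixtures):
        W[:, j] = fx.on_off_weights(scale)
    net.plastic["lgn_e"] = False


@dataclass
class LnpNeuron:
    """Linear-nonlinear-Poisson responder: rate = gain*(<k,s>)_+ + offset.

    The stimulus may be a signed pixel array or an :class:`OnOffRates`
    (whose ON-OFF signed map is used).  Counts are Poisson over the
    presentation duration.
    """

    fixture: GaborFixture
    gain: float
    offset: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def rate(self, stimulus) -> float:
        """Instantaneous firing rate in Hz for one stimulus."""
        s = stimulus.signed() if isinstance(stimulus, OnOffRates) else np.asarray(stimulus, dtype=float)
        drive = float(np.sum(self.fixture.map * s))
        return self.gain * max(drive, 0.0) + self.offset

    def counts(self, stimulus, duration_ms: float = 125.0, n_reps: int = 1) -> np.ndarray:
        """Poisson spike counts over ``n_reps`` presentations."""
        lam = self.rate(stimulus) * duration_ms * 1e-3
        return self.rng.poisson(lam, size=n_reps)


def lnp_surrogate(
    fixture: GaborFixture,
    gain: float,
    offset: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LnpNeuron:
    """Construct an LNP surrogate neuron around a Gabor fixture."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return LnpNeuron(fixture=fixture, gain=gain, offset=offset,
                     rng=rng or np.random.default_rng())
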