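"""Visual stimuli for the model: natural-scene patches, gratings, noise.

The network sees the world through 12x12 patches of whitened luminance.
Signed pixel values are split into an ON plane (positive part) and an OFF
plane (magnitude of the negative part), each expressed as a Poisson firing
rate in Hz, with the unit pixel magnitude mapped to ``r_max`` (125 Hz for
natural-scene training input).

Three stimulus classes are produced here:

* random patches cut from whitened scenes (training input),
* sinusoidal gratings (orientation-tuning and gain measurements),
* clipped Gaussian noise patches (spike-triggered-average mapping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WhitenedScene",
    "WhitenedPatch",
    "OnOffRates",
    "GratingSpec",
    "load_scene",
    "sample_patch",
    "on_off_split",
    "make_grating",
    "make_noise_patch",
    "DEFAULT_PATCH_SIZE",
    "NATURAL_R_MAX",
    "GRATING_R_MAX",
]

DEFAULT_PATCH_SIZE = 12
#: peak LGN rate assigned to the (rare) unit pixel magnitude during training
NATURAL_R_MAX = 125.0
#: peak LGN rate used for grating (tuning-curve) measurements
GRATING_R_MAX = 85.7


@dataclass
class WhitenedScene:
    """A whitened luminance image, in arbitrary signed units."""

    pixels: np.ndarray
    scene_id: str = "scene"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("scene must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("scene contains non-finite values")

    @property
    def norm_divisor(self) -> float:
        """Per-scene normalization divisor: the maximum absolute pixel."""
        return float(np.max(np.abs(self.pixels)))


@dataclass
class WhitenedPatch:
    """A 12x12 patch cut from a scene, normalized to [-1, 1]."""

    pixels: np.ndarray
    source: tuple = ("", (0, 0))
    flips: tuple = (False, False)  # (horizontal-axis flip, vertical-axis flip)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)


@dataclass
class OnOffRates:
    """Nonnegative ON/OFF firing-rate map in Hz, shape (h, w, 2).

    Plane 0 carries positive pixel values, plane 1 the magnitude of
    negative values; at most one plane is nonzero per pixel.
    """

    rates: np.ndarray
    r_max: float

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)

    def flat(self) -> np.ndarray:
        """Rates flattened to one vector: all ON pixels then all OFF pixels."""
        return np.concatenate(
            [self.rates[..., 0].ravel(), self.rates[..., 1].ravel()]
        )

    def signed(self) -> np.ndarray:
        """ON - OFF map; recovers r_max * pixels of the source patch."""
        return self.rates[..., 0] - self.rates[..., 1]


@dataclass
class GratingSpec:
    """Parameters of a sinusoidal grating probe stimulus.

    Contrast is manipulated solely through ``r_max`` (peak input rate),
    spanning 14.25-100 Hz in the gain-curve protocol.
    """

    orientation: float  # degrees in [0, 180)
    phase: float = 0.0  # radians in [0, pi]
    spatial_frequency: float = 0.10  # cycles/pixel in [0.05, 0.15]
    r_max: float = GRATING_R_MAX

    def __post_init__(self) -> None:
        if not 0.0 <= self.orientation < 360.0:
            raise ValueError(f"orientation {self.orientation} out of range")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be positive")


def load_scene(path, scene_id: str | None = None) -> WhitenedScene:
    """Read a whitened scene from a raster image (PNG/TIFF, converted to
    grayscale and centred) or an array container (.npy / single-array .npz).
    """
    import os

    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".npy":
        pixels = np.load(path)
    elif ext == ".npz":
        with np.load(path) as data:
            if len(data.files) != 1:
                raise ValueError("expected a single array in the container")
            pixels = data[data.files[0]]
    else:
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path), dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)  # collapse color channels
        pixels = img - img.mean()  # raster formats store nonnegative values
    return WhitenedScene(
        pixels=pixels, scene_id=scene_id or os.path.basename(str(path))
    )


def sample_patch(
    scene: WhitenedScene,
    rng: np.random.Generator,
    patch_size: int = DEFAULT_PATCH_SIZE,
    flip: bool = True,
    offset: tuple[int, int] | None = None,
) -> WhitenedPatch:
    """Cut a random patch from a scene and normalize it to [-1, 1].

    The patch is taken at a uniformly random offset, divided by the scene's
    maximum absolute pixel value, then flipped about the horizontal and
    vertical axes independently, each with probability 0.5 (removes any
    orientation bias in the scene ensemble).
    """
    h, w = scene.pixels.shape
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"scene {h}x{w} smaller than patch size {patch_size}"
        )
    if offset is None:
        r0 = int(rng.integers(0, h - patch_size + 1))
        c0 = int(rng.integers(0, w - patch_size + 1))
    else:
        r0, c0 = offset
    patch = scene.pixels[r0 : r0 + patch_size, c0 : c0 + patch_size]
    divisor = scene.norm_divisor
    if divisor > 0:
        patch = patch / divisor
    flip_h = flip_v = False
    if flip:
        flip_h = bool(rng.random() < 0.5)
        flip_v = bool(rng.random() < 0.5)
        if flip_h:  # flip about the horizontal axis: reverse rows
            patch = patch[::-1, :]
        if flip_v:  # flip about the vertical axis: reverse columns
            patch = patch[:, ::-1]
    return WhitenedPatch(
        pixels=np.ascontiguousarray(patch),
        source=(scene.scene_id, (r0, c0)),
        flips=(flip_h, flip_v),
    )


def on_off_split(patch, r_max: float) -> OnOffRates:
    """Map a signed patch onto nonnegative ON/OFF rates.

    ON(i,j) = max(p, 0) * r_max and OFF(i,j) = max(-p, 0) * r_max, so that
    ON - OFF = r_max * p exactly and no rate is ever negative.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    pixels = patch.pixels if isinstance(patch, WhitenedPatch) else np.asarray(patch, dtype=float)
    rates = np.stack(
        [np.maximum(pixels, 0.0) * r_max, np.maximum(-pixels, 0.0) * r_max],
        axis=-1,
    )
    return OnOffRates(rates=rates, r_max=float(r_max))


def grating_pattern(spec: GratingSpec, size: int = DEFAULT_PATCH_SIZE) -> np.ndarray:
    """Signed sinusoid centred on the patch, scaled to unit peak amplitude."""
    theta = np.deg2rad(spec.orientation)
    c = (size - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(size) - c, np.arange(size) - c)
    arg = (
        2.0 * np.pi * spec.spatial_frequency * (cols * np.cos(theta) + rows * np.sin(theta))
        + spec.phase
    )
    pattern = np.cos(arg)
    peak = np.max(np.abs(pattern))
    return pattern / peak


def make_grating(spec: GratingSpec, size: int = DEFAULT_PATCH_SIZE) -> OnOffRates:
    """Render a grating and split it into ON/OFF rates at the spec's r_max."""
    return on_off_split(grating_pattern(spec, size), spec.r_max)


def make_noise_patch(
    rng: np.random.Generator,
    size: int = DEFAULT_PATCH_SIZE,
    mean: float = 15.0,
    sd: float = 20.0,
) -> OnOffRates:
    """Gaussian noise patch for spike-triggered-average mapping.

    Pixels are drawn from Normal(mean, sd) in Hz; negative draws are set to
    zero and the result is interpreted directly as ON-plane rates (the OFF
    plane is zero, since nothing is negative after clipping).
    """
    draws = rng.normal(mean, sd, size=(size, size))
    on = np.maximum(draws, 0.0)
    rates = np.stack([on, np.zeros_like(on)], axis=-1)
    return OnOffRates(rates=rates, r_max=float(max(on.max(), 1.0)))
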