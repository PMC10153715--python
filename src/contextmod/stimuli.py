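"""Image-domain stimulus operators.

Grating-scene synthesis for the contrast-detection task (target gratings in a
surround context), plus the face-image preprocessing primitives used when
preparing eye-matching stimuli: luminance/RMS normalization, pixelwise
similarity, iterative phase scrambling for noise masks, and similarity-based
morph-pair preselection.

All images are grayscale luminance arrays on a 0..1 scale.  RMS contrast is
the standard deviation of the luminance values on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LuminanceImage:
    """Grayscale image with luminance in [0, 1] and a spatial calibration."""

    pixels: np.ndarray
    pixels_per_degree: float = 16.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("pixels must be a 2-D array with both dims >= 2")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("luminance values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class GratingScene:
    """Parameters of one contrast-detection stimulus.

    A horizontal target grating of ``target_contrast`` appears in one of four
    circular regions (3 deg diameter, 5 deg eccentric, at 45/135/225/315 deg)
    inside a 20-deg context disc carrying a horizontal ("Same"), vertical
    ("Different") or no ("none", Isolated) grating at ``context_contrast``.
    All gratings share spatial frequency and phase; contrast ramps to zero at
    region edges through a raised-cosine envelope.
    """

    context_orientation: str = "horizontal"   # "horizontal" | "vertical" | "none"
    context_contrast: float = 0.25
    target_contrast: float = 0.05
    target_quadrant: int = 0                  # index into target_angles
    context_diameter: float = 20.0            # deg
    target_diameter: float = 3.0              # deg
    target_eccentricity: float = 5.0          # deg
    target_angles: tuple[float, ...] = (45.0, 135.0, 225.0, 315.0)
    spatial_frequency: float = 1.0            # cycles/deg
    phase: float = 0.0                        # radians, cosine phase at center
    ramp_width: float = 0.5                   # deg, raised-cosine edge

    def __post_init__(self) -> None:
        if self.context_orientation not in ("horizontal", "vertical", "none"):
            raise ValueError(f"unknown context orientation "
                             f"{self.context_orientation!r}")
        if not 0 < self.target_contrast <= 1:
            raise ValueError("target contrast must be in (0, 1] "
                             "(targets have variable, non-zero contrast)")
        if self.context_orientation != "none" and not 0 < self.context_contrast <= 1:
            raise ValueError("context contrast must be in (0, 1]")
        if not 0 <= self.target_quadrant < len(self.target_angles):
            raise ValueError("target_quadrant out of range")


def _raised_cosine_disc(r: np.ndarray, radius: float, ramp: float) -> np.ndarray:
    """Envelope: 1 inside, cosine half-cycle ramp to 0 over the outer ``ramp``."""
    w = np.zeros_like(r)
    inner = radius - ramp
    w[r <= inner] = 1.0
    edge = (r > inner) & (r < radius)
    w[edge] = 0.5 * (1 + np.cos(np.pi * (r[edge] - inner) / ramp))
    return w


def render_grating_scene(scene: GratingScene,
                         pixels_per_degree: float = 16.0) -> LuminanceImage:
    """Render a scene to luminance with mean background 0.5.

    A grating of Michelson contrast C around mean 0.5 is 0.5*(1 + C*cos(...)),
    so measured Michelson contrast in a fully-modulated region equals C.
    Within the target disc the context pattern cross-fades into the target
    grating through the target's raised-cosine envelope.
    """
    if pixels_per_degree < 8 * scene.spatial_frequency:
        raise ValueError("need >= 8 pixels per grating cycle")
    half = scene.context_diameter / 2 + 1.0  # deg, with margin
    n = int(round(2 * half * pixels_per_degree))
    coords = (np.arange(n) - (n - 1) / 2) / pixels_per_degree
    x, y = np.meshgrid(coords, coords)
    r = np.hypot(x, y)

    carrier_h = np.cos(2 * np.pi * scene.spatial_frequency * y + scene.phase)
    carrier_v = np.cos(2 * np.pi * scene.spatial_frequency * x + scene.phase)

    if scene.context_orientation == "none":
        ctx_mod = np.zeros_like(r)
    else:
        carrier = carrier_h if scene.context_orientation == "horizontal" else carrier_v
        w_ctx = _raised_cosine_disc(r, scene.context_diameter / 2,
                                    scene.ramp_width)
        ctx_mod = scene.context_contrast * carrier * w_ctx

    theta = np.deg2rad(scene.target_angles[scene.target_quadrant])
    cx, cy = (scene.target_eccentricity * np.cos(theta),
              scene.target_eccentricity * np.sin(theta))
    rt = np.hypot(x - cx, y - cy)
    w_t = _raised_cosine_disc(rt, scene.target_diameter / 2, scene.ramp_width)
    target_mod = scene.target_contrast * carrier_h

    mod = (1 - w_t) * ctx_mod + w_t * target_mod
    return LuminanceImage(0.5 * (1 + mod), pixels_per_degree)


def normalize_image(img: LuminanceImage, target_mean: float = 0.52,
                    target_rms: float = 0.12) -> LuminanceImage:
    """Affinely rescale an image to a given mean luminance and RMS contrast.

    RMS contrast is the pixel standard deviation on the 0..1 luminance scale.
    Raises on constant images (RMS cannot be set) and on images whose
    standardized range would leave [0, 1].
    """
    p = img.pixels
    sd = p.std()
    if sd < 1e-12:
        raise ValueError("constant image: RMS contrast cannot be adjusted")
    out = (p - p.mean()) / sd * target_rms + target_mean
    return LuminanceImage(out, img.pixels_per_degree)


def pixelwise_similarity(a: LuminanceImage, b: LuminanceImage) -> float:
    """Pearson correlation of the flattened pixel vectors (MATLAB ``corr2``)."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    pa, pb = a.pixels.ravel(), b.pixels.ravel()
    if pa.std() < 1e-12 or pb.std() < 1e-12:
        raise ValueError("correlation undefined for constant images")
    return float(np.corrcoef(pa, pb)[0, 1])


def phase_scramble(img: LuminanceImage, iterations: int = 500,
                   seed: int = 0) -> LuminanceImage:
    """Iterative Fourier phase scrambling, preserving the amplitude spectrum.

    Each iteration perturbs the current phase spectrum with a fresh random
    (Hermitian-antisymmetric) phase field, re-imposes the original amplitude
    spectrum, inverts, and clips to [0, 1].  Iterating keeps the clipped
    image's spectrum close to the original's, which is what makes the result
    usable as a spectrally-matched noise mask: a single scramble-and-clip of
    an image on a uniform background would leak background structure.
    """
    if iterations < 1:
        raise ValueError("need at least one iteration")
    rng = np.random.default_rng(seed)
    amplitude = np.abs(np.fft.fft2(img.pixels))
    x = img.pixels
    for _ in range(iterations):
        # angle(fft(real noise)) is antisymmetric, so the spectrum built below
        # stays Hermitian and the inverse transform real
        rand_phase = np.angle(np.fft.fft2(rng.standard_normal(img.shape)))
        rand_phase[0, 0] = 0.0   # keep the DC (mean-luminance) term intact
        phase = np.angle(np.fft.fft2(x)) + rand_phase
        x = np.real(np.fft.ifft2(amplitude * np.exp(1j * phase)))
        x = np.clip(x, 0.0, 1.0)
    return LuminanceImage(x, img.pixels_per_degree)


def save_image(img: LuminanceImage, path) -> None:
    """Write as 8-bit grayscale PNG (or any PIL-supported format)."""
    from PIL import Image

    data = np.round(np.clip(img.pixels, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def load_image(path, pixels_per_degree: float = 16.0) -> LuminanceImage:
    """Read a grayscale image file onto the 0..1 luminance scale."""
    from PIL import Image

    with Image.open(path) as im:
        data = np.asarray(im.convert("L"), dtype=float) / 255.0
    return LuminanceImage(data, pixels_per_degree)


def select_morph_pairs(similarities) -> np.ndarray:
    """Indices of pairs within two sample SDs of the mean pixelwise similarity.

    Used to keep only face pairs of typical similarity for morphing; with all
    values equal (SD 0) every pair is retained.
    """
    s = np.asarray(similarities, dtype=float)
    if s.ndim != 1 or s.size < 3:
        raise ValueError("need at least three similarity values")
    sd = s.std(ddof=1)
    keep = np.abs(s - s.mean()) <= 2 * sd
    return np.flatnonzero(keep)
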