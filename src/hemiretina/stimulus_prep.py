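"""Spatial-frequency stimulus preparation.

Face-like grayscale stimuli are prepared in three spatial-frequency (SF)
conditions: broadband (BSF, unfiltered), low-pass (LSF, < 8 cycles/image)
and high-pass (HSF, > 32 cycles/image), using a radial Butterworth filter
of order 2 applied in the 2-D frequency domain. Filtered sets are then
contrast/luminance equated (linear mean/SD matching) and cropped to a
vertical ellipse so only the inner face region remains visible.

Cycles-per-image (cpi) are defined on the square 512x512 pre-crop frame:
a frequency of f cpi completes f full luminance cycles across the image
width. Conversions to cycles/degree depend on viewing geometry and are not
used computationally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "StimulusImage",
    "FilterSpec",
    "EquateStats",
    "LOWPASS_CUTOFF_CPI",
    "HIGHPASS_CUTOFF_CPI",
    "ELLIPSE_HEIGHT_PX",
    "ELLIPSE_WIDTH_PX",
    "generate_synthetic_face",
    "stimulus_inventory",
    "butterworth_radial_gain",
    "butterworth_radial_filter",
    "equate_luminance_contrast",
    "elliptical_crop",
    "radial_power_spectrum",
    "save_png",
    "load_png",
    "prepare_stimulus_set",
]

#: Default cut-offs, in cycles per image on the 512x512 frame.
LOWPASS_CUTOFF_CPI = 8.0
HIGHPASS_CUTOFF_CPI = 32.0

#: Elliptical crop axes (vertical ellipse), in pixels.
ELLIPSE_HEIGHT_PX = 337.0
ELLIPSE_WIDTH_PX = 256.12

IMAGE_SIZE = 512


@dataclass
class StimulusImage:
    """A grayscale stimulus with an optional opacity mask.

    Parameters
    ----------
    pixels
        Luminance grid (rows x cols), nominally in [0, 1]. Intermediate
        processing (filtering, equating) may leave values outside [0, 1];
        they are clipped only on PNG export.
    alpha
        Optional opacity mask of the same shape; after elliptical cropping
        the mask is binary (1 inside the ellipse, 0 outside).
    """

    pixels: np.ndarray
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D luminance grid")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
            if self.alpha.shape != self.pixels.shape:
                raise ValueError("alpha mask must match pixel shape")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    def visible_pixels(self) -> np.ndarray:
        """Luminance values where the stimulus is opaque (alpha > 0)."""
        if self.alpha is None:
            return self.pixels.ravel()
        return self.pixels[self.alpha > 0]


@dataclass(frozen=True)
class FilterSpec:
    """Radial Butterworth filter specification (cut-off in cycles/image)."""

    band: Literal["none", "lowpass", "highpass"]
    cutoff_cpi: float
    order: int = 2

    def __post_init__(self) -> None:
        if self.band not in ("none", "lowpass", "highpass"):
            raise ValueError(f"unknown band {self.band!r}")
        if self.band != "none" and self.cutoff_cpi <= 0:
            raise ValueError("cutoff_cpi must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class EquateStats:
    """Target luminance mean/SD for contrast equating."""

    target_mean: float
    target_sd: float

    def __post_init__(self) -> None:
        if self.target_sd < 0:
            raise ValueError("target_sd must be >= 0")


def _soft_edge(d: np.ndarray, width: float) -> np.ndarray:
    """Smooth 1->0 transition of a signed distance, of the given width."""
    return 1.0 / (1.0 + np.exp(d / width))


def generate_synthetic_face(
    seed: int, expression: Literal["neutral", "fearful"] = "neutral", size: int = IMAGE_SIZE
) -> StimulusImage:
    """Procedurally generate a face-like grayscale image.

    The image combines a smooth head/face blob (low-SF structure) with
    hard-edged eye, brow and mouth features plus fine skin texture (high-SF
    structure), so that low-pass and high-pass filtering produce measurably
    different stimuli. ``expression`` widens the eye and mouth apertures
    ("fearful") without changing the global feature layout; per-seed jitter
    varies feature geometry so seeds act like face identities.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = size / 2 + rng.uniform(-6, 6)
    cy = size / 2 + rng.uniform(-6, 6)

    # Head: smooth vertical ellipse, bright on a dark background.
    a = size * (0.30 + rng.uniform(-0.02, 0.02))  # semi-axis x
    b = size * (0.40 + rng.uniform(-0.02, 0.02))  # semi-axis y
    d_head = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2) - 1.0
    img = 0.15 + 0.55 * _soft_edge(d_head * min(a, b), 6.0)

    # Shading gradient across the face (more low-SF content).
    img += 0.06 * np.sin(2 * np.pi * (yy - cy) / size) * _soft_edge(d_head * min(a, b), 10.0)

    wide = 1.0 if expression == "neutral" else 1.45  # aperture scaling
    eye_dx = size * (0.13 + rng.uniform(-0.01, 0.01))
    eye_y = cy - size * 0.10
    eye_rx = size * 0.055
    eye_ry = size * 0.028 * wide
    for sx in (-1.0, 1.0):
        ex = cx + sx * eye_dx
        # Sclera: hard-edged bright ellipse (high-SF edges).
        sclera = ((xx - ex) / eye_rx) ** 2 + ((yy - eye_y) / eye_ry) ** 2 <= 1.0
        img[sclera] = 0.92
        # Pupil: hard dark disc.
        pupil = (xx - ex) ** 2 + (yy - eye_y) ** 2 <= (size * 0.016) ** 2
        img[pupil] = 0.05
        # Brow: thin dark bar, raised when fearful.
        brow_y = eye_y - size * (0.055 + 0.02 * (wide - 1.0))
        brow = (np.abs(yy - brow_y) <= size * 0.008) & (np.abs(xx - ex) <= eye_rx * 1.3)
        img[brow] = 0.12

    # Nose: faint vertical ridge.
    nose = (np.abs(xx - cx) <= size * 0.012) & (np.abs(yy - cy - size * 0.02) <= size * 0.09)
    img[nose] += 0.08

    # Mouth: hard-edged ellipse, opened when fearful.
    mouth_y = cy + size * 0.20
    mouth_rx = size * 0.09
    mouth_ry = size * 0.02 * wide
    mouth = ((xx - cx) / mouth_rx) ** 2 + ((yy - mouth_y) / mouth_ry) ** 2 <= 1.0
    img[mouth] = 0.10 if expression == "fearful" else 0.25

    # Fine skin texture: broadband speckle confined to the face, guarantees
    # energy above the high-pass cut-off.
    texture = rng.normal(0.0, 0.02, size=(size, size))
    img += texture * _soft_edge(d_head * min(a, b), 6.0)

    return StimulusImage(pixels=np.clip(img, 0.0, 1.0))


def stimulus_inventory(
    n_identities: int = 20,
    expressions: Sequence[str] = ("neutral", "fearful"),
    sf_conditions: Sequence[str] = ("BSF", "LSF", "HSF"),
) -> list[dict]:
    """Enumerate the full stimulus set (identity x expression x SF).

    With the defaults this is the 20 x 2 x 3 = 120-stimulus design.
    """
    return [
        {"identity": i, "expression": e, "sf": s}
        for i in range(1, n_identities + 1)
        for e in expressions
        for s in sf_conditions
    ]


def _radial_frequency_grid(n: int) -> np.ndarray:
    """Radial frequency sqrt(u^2+v^2) in cycles/image for an n x n image."""
    f1 = np.fft.fftfreq(n) * n  # cycles per image along one axis
    fx, fy = np.meshgrid(f1, f1)
    return np.sqrt(fx**2 + fy**2)


def butterworth_radial_gain(f: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Amplitude gain G(f) of the radial Butterworth filter.

    Lowpass: G(f) = 1/sqrt(1 + (f/fc)^(2n)), so G(0) = 1 and G(fc) = 1/sqrt(2).
    Highpass: G(f) = 1/sqrt(1 + (fc/f)^(2n)) with G(0) = 0 exactly.
    """
    f = np.asarray(f, dtype=float)
    fc, n = spec.cutoff_cpi, spec.order
    if spec.band == "lowpass":
        return 1.0 / np.sqrt(1.0 + (f / fc) ** (2 * n))
    if spec.band == "highpass":
        out = np.zeros_like(f)
        nz = f > 0
        out[nz] = 1.0 / np.sqrt(1.0 + (fc / f[nz]) ** (2 * n))
        return out
    return np.ones_like(f)


def butterworth_radial_filter(img: StimulusImage, spec: FilterSpec) -> StimulusImage:
    """Filter an image with a radial Butterworth amplitude gain in 2-D frequency space.

    The output is the inverse FFT of the input spectrum multiplied by G(f),
    f being radial frequency in cycles/image. Values are *not* clipped to
    [0, 1] here — the subsequent equating step restores the luminance range;
    clipping happens only at PNG export.
    """
    if img.height_px != img.width_px:
        raise ValueError("radial filtering requires a square image")
    if spec.band == "none":
        return StimulusImage(pixels=img.pixels.copy(), alpha=None if img.alpha is None else img.alpha.copy())
    f = _radial_frequency_grid(img.height_px)
    gain = butterworth_radial_gain(f, spec)
    spectrum = np.fft.fft2(img.pixels)
    out = np.real(np.fft.ifft2(spectrum * gain))
    return StimulusImage(pixels=out, alpha=None if img.alpha is None else img.alpha.copy())


def equate_luminance_contrast(
    images: Sequence[StimulusImage], stats: EquateStats | None = None
) -> list[StimulusImage]:
    """Linearly rescale every image to a common luminance mean and SD.

    Each image is transformed as ``x' = (x - mean)/sd * target_sd + target_mean``
    where mean/SD are computed over opaque pixels when an alpha mask exists.
    If ``stats`` is None, the grand mean/SD over the whole set is used, so the
    set as prepared is equated to its own average statistics.
    """
    if not images:
        return []
    shapes = {im.pixels.shape for im in images}
    if len(shapes) > 1:
        raise ValueError("all images must share a shape for joint equating")
    if stats is None:
        pooled = np.concatenate([im.visible_pixels() for im in images])
        stats = EquateStats(target_mean=float(pooled.mean()), target_sd=float(pooled.std()))
    out = []
    for im in images:
        vis = im.visible_pixels()
        sd = float(vis.std())
        if sd == 0.0:
            raise ValueError("degenerate image: zero luminance SD, cannot equate contrast")
        scaled = (im.pixels - vis.mean()) / sd * stats.target_sd + stats.target_mean
        out.append(StimulusImage(pixels=scaled, alpha=None if im.alpha is None else im.alpha.copy()))
    return out


def elliptical_crop(
    img: StimulusImage,
    height_px: float = ELLIPSE_HEIGHT_PX,
    width_px: float = ELLIPSE_WIDTH_PX,
) -> StimulusImage:
    """Set alpha to 1 inside the centred axis-aligned ellipse, 0 outside.

    The ellipse is vertical (``height_px`` along rows, ``width_px`` along
    columns), centred on the image centre; pixel luminance is untouched.
    """
    if height_px > img.height_px or width_px > img.width_px:
        raise ValueError("ellipse does not fit inside the image")
    h, w = img.pixels.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    inside = ((yy - cy) / (height_px / 2.0)) ** 2 + ((xx - cx) / (width_px / 2.0)) ** 2 <= 1.0
    return StimulusImage(pixels=img.pixels.copy(), alpha=inside.astype(float))


def radial_power_spectrum(img: StimulusImage, n_bins: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Rotationally averaged power spectrum, binned by radial frequency (cpi).

    Returns (bin centre frequencies, mean power per bin); the DC component is
    excluded so the spectrum reflects structure, not mean luminance.
    """
    if img.height_px != img.width_px:
        raise ValueError("radial spectrum requires a square image")
    f = _radial_frequency_grid(img.height_px)
    power = np.abs(np.fft.fft2(img.pixels)) ** 2
    fmax = img.height_px / 2.0
    edges = np.linspace(0, fmax, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = f > 0
    idx = np.clip(np.digitize(f[mask], edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=power[mask], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_power = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return centers, mean_power


def save_png(img: StimulusImage, path: str | Path) -> None:
    """Export as 8-bit grayscale PNG (grayscale+alpha when a mask exists)."""
    lum = np.clip(img.pixels, 0.0, 1.0)
    l8 = np.round(lum * 255).astype(np.uint8)
    if img.alpha is None:
        Image.fromarray(l8, mode="L").save(path)
    else:
        a8 = np.round(np.clip(img.alpha, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(np.stack([l8, a8], axis=-1), mode="LA").save(path)


def load_png(path: str | Path) -> StimulusImage:
    im = Image.open(path)
    if im.mode == "LA":
        arr = np.asarray(im, dtype=float) / 255.0
        return StimulusImage(pixels=arr[..., 0], alpha=arr[..., 1])
    arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return StimulusImage(pixels=arr)


def prepare_stimulus_set(
    n_identities: int = 20,
    seed: int = 0,
    low_cutoff: float = LOWPASS_CUTOFF_CPI,
    high_cutoff: float = HIGHPASS_CUTOFF_CPI,
    order: int = 2,
    equate: bool = True,
    out_dir: str | Path | None = None,
) -> dict[tuple[int, str, str], StimulusImage]:
    """Build the full BSF/LSF/HSF stimulus set from procedural faces.

    Filenames (when ``out_dir`` is given) follow
    ``id{NN}_{neutral|fear}_{bsf|lsf|hsf}.png``.
    """
    lp = FilterSpec("lowpass", low_cutoff, order)
    hp = FilterSpec("highpass", high_cutoff, order)
    filtered: dict[tuple[int, str, str], StimulusImage] = {}
    for ident in range(1, n_identities + 1):
        for expr in ("neutral", "fearful"):
            base = generate_synthetic_face(seed * 1000 + ident, expr)
            filtered[(ident, expr, "BSF")] = base
            filtered[(ident, expr, "LSF")] = butterworth_radial_filter(base, lp)
            filtered[(ident, expr, "HSF")] = butterworth_radial_filter(base, hp)
    if equate:
        keys = list(filtered)
        equated = equate_luminance_contrast([filtered[k] for k in keys])
        filtered = dict(zip(keys, equated))
    cropped = {k: elliptical_crop(v) for k, v in filtered.items()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        short = {"neutral": "neutral", "fearful": "fear"}
        for (ident, expr, sf), im in cropped.items():
            save_png(im, out / f"id{ident:02d}_{short[expr]}_{sf.lower()}.png")
    return cropped
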