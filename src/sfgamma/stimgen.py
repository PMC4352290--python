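"""Stimulus synthesis: spatial-frequency filtering, phase scrambling and
luminance/contrast equalisation of grayscale object photographs.

The six stimulus classes of the 2 (objecthood) x 3 (spatial frequency)
design are built from broadband (BB) source images:

* BB / HSF / LSF object images — the source either unfiltered or passed
  through a radially symmetric Gaussian gain in the 2-D frequency plane
  (high-pass at ~4.7 cpd for HSF, low-pass at ~0.9 cpd for LSF);
* their non-object counterparts — Fourier phase-scrambled versions with
  the identical amplitude spectrum, hence identical spatial-frequency
  content and second-order statistics.

All images are finally matched to the mean luminance and RMS contrast
(pixel standard deviation) of the full BB set.

The "cut-off" of the Gaussian gain follows the half-amplitude convention:
gain(cutoff) = 0.5, i.e. ``g(f) = 2**(-(f/fc)**2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import ViewingGeometry, pixels_per_degree

__all__ = [
    "GrayImage",
    "SFFilterSpec",
    "make_sf_filter",
    "apply_sf_filter",
    "phase_scramble",
    "match_luminance_contrast",
    "build_stimulus_set",
    "StimulusSet",
    "make_toy_objects",
    "save_png",
    "load_gray",
    "CONDITIONS",
]

#: the six design cells, (objecthood, spatial frequency)
CONDITIONS = [
    (obj, sf) for obj in ("object", "nonobject") for sf in ("HSF", "BB", "LSF")
]


@dataclass
class GrayImage:
    """A 2-D grayscale intensity array with its pixels-per-degree scale."""

    intensities: np.ndarray
    ppd: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("image must be 2-D")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("image contains non-finite values")
        if self.ppd <= 0:
            raise ValueError("pixels per degree must be positive")

    @property
    def mean(self) -> float:
        return float(self.intensities.mean())

    @property
    def sd(self) -> float:
        return float(self.intensities.std())


@dataclass(frozen=True)
class SFFilterSpec:
    """Gaussian spatial-frequency filter under the half-amplitude convention.

    ``kind='low-pass'`` passes DC with unit gain and has gain 0.5 at
    ``cutoff_cpd``; ``kind='high-pass'`` is its complement (gain rising to
    ~1 towards Nyquist).  ``preserve_mean`` keeps the DC bin at unit gain
    for high-pass filters so the global mean survives filtering.
    """

    kind: Literal["low-pass", "high-pass"]
    cutoff_cpd: float
    preserve_mean: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("low-pass", "high-pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.cutoff_cpd <= 0:
            raise ValueError("cutoff must be positive")

    def gain_at(self, f_cpd: np.ndarray | float) -> np.ndarray | float:
        """Closed-form radial gain at frequency ``f_cpd`` (half-amplitude Gaussian)."""
        g = 2.0 ** (-((np.asarray(f_cpd, dtype=float) / self.cutoff_cpd) ** 2))
        return g if self.kind == "low-pass" else 1.0 - g


def _radial_freq_cpd(shape: tuple[int, int], ppd: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0]) * ppd
    fx = np.fft.fftfreq(shape[1]) * ppd
    return np.hypot(fy[:, None], fx[None, :])


def make_sf_filter(spec: SFFilterSpec, shape: tuple[int, int], ppd: float) -> np.ndarray:
    """Build the 2-D frequency-plane gain matrix (unshifted FFT layout, DC at [0, 0])."""
    if ppd <= 0:
        raise ValueError("pixels per degree must be positive")
    nyquist = 0.5 * ppd
    if spec.cutoff_cpd >= nyquist:
        warnings.warn(
            f"cutoff {spec.cutoff_cpd:.2f} cpd is at or beyond Nyquist ({nyquist:.2f} cpd)",
            stacklevel=2,
        )
    gain = np.asarray(spec.gain_at(_radial_freq_cpd(shape, ppd)), dtype=float)
    if spec.kind == "high-pass" and spec.preserve_mean:
        gain[0, 0] = 1.0
    return gain


def apply_sf_filter(img: GrayImage, gain: np.ndarray) -> GrayImage:
    """Multiply the image's amplitude spectrum by ``gain`` and invert."""
    if gain.shape != img.intensities.shape:
        raise ValueError(
            f"gain shape {gain.shape} does not match image {img.intensities.shape}"
        )
    spectrum = np.fft.fft2(img.intensities)
    out = np.fft.ifft2(spectrum * gain)
    signal_norm = np.linalg.norm(out)
    if signal_norm > 0 and np.linalg.norm(out.imag) > 1e-8 * signal_norm:
        raise RuntimeError("unexpected imaginary residue after filtering")
    return GrayImage(out.real, img.ppd)


def phase_scramble(img: GrayImage, seed: int | np.random.Generator) -> GrayImage:
    """Randomise Fourier phases while keeping the amplitude spectrum.

    Random phases are drawn as the phases of the FFT of white noise, which
    are i.i.d. uniform and automatically Hermitian-symmetric, so the
    inverse transform is real.  The DC bin keeps its original (zero-phase)
    value so the global mean is preserved exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spectrum = np.fft.fft2(img.intensities)
    noise_phase = np.angle(np.fft.fft2(rng.standard_normal(img.intensities.shape)))
    scrambled = np.abs(spectrum) * np.exp(1j * noise_phase)
    scrambled[0, 0] = spectrum[0, 0]
    return GrayImage(np.fft.ifft2(scrambled).real, img.ppd)


def match_luminance_contrast(
    img: GrayImage, target_mean: float, target_sd: float
) -> GrayImage:
    """Affinely rescale so pixel mean/sd equal the targets exactly."""
    if target_sd < 0:
        raise ValueError("target sd must be non-negative")
    sd = img.sd
    if target_sd > 0 and sd < 1e-12 * max(1.0, abs(img.mean)):
        raise ValueError("cannot impose nonzero contrast on a zero-variance image")
    if target_sd == 0:
        out = np.full_like(img.intensities, target_mean)
    else:
        out = (img.intensities - img.mean) * (target_sd / sd) + target_mean
    return GrayImage(out, img.ppd)


@dataclass
class StimulusSet:
    """The six stimulus classes for every source image, plus a manifest."""

    images: dict[tuple[str, str], list[GrayImage]]
    manifest: pd.DataFrame
    target_mean: float
    target_sd: float
    cutoffs_cpd: dict[str, float] = field(default_factory=dict)


def build_stimulus_set(
    sources: Sequence[GrayImage],
    geom: ViewingGeometry | None = None,
    *,
    ppd: float | None = None,
    hsf_cutoff_cpd: float = 4.7,
    lsf_cutoff_cpd: float = 0.9,
    seed: int = 0,
    swap_filter_assignment: bool = False,
    out_dir: str | Path | None = None,
    clip: bool = False,
) -> StimulusSet:
    """Build BB/HSF/LSF object images and their phase-scrambled non-objects.

    The conventional mapping filters HSF images with a *high*-pass at
    ``hsf_cutoff_cpd`` and LSF images with a *low*-pass at
    ``lsf_cutoff_cpd``.  ``swap_filter_assignment=True`` swaps the filter
    kinds (low-pass for HSF, high-pass for LSF) for users who want the
    alternative reading of the filtering description.

    Every output is matched to the grand mean luminance and RMS contrast
    of the broadband source set.  When ``out_dir`` is given, 16-bit PNGs
    are written and the manifest records their paths.
    """
    if len(sources) == 0:
        raise ValueError("at least one source image is required")
    if ppd is None:
        if geom is None:
            ppd = sources[0].ppd
        else:
            ppd = pixels_per_degree(geom)

    if swap_filter_assignment:
        hsf_kind, lsf_kind = "low-pass", "high-pass"
    else:
        hsf_kind, lsf_kind = "high-pass", "low-pass"
    specs = {
        "BB": None,
        "HSF": SFFilterSpec(hsf_kind, hsf_cutoff_cpd),
        "LSF": SFFilterSpec(lsf_kind, lsf_cutoff_cpd),
    }
    shape = sources[0].intensities.shape
    gains = {
        sf: make_sf_filter(spec, shape, ppd) if spec is not None else None
        for sf, spec in specs.items()
    }

    bb_stack = np.stack([s.intensities for s in sources])
    target_mean = float(bb_stack.mean())
    target_sd = float(bb_stack.std())

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    images: dict[tuple[str, str], list[GrayImage]] = {c: [] for c in CONDITIONS}
    rows = []
    for i, src in enumerate(sources):
        if src.intensities.shape != shape:
            raise ValueError("all source images must share one shape")
        for sf in ("HSF", "BB", "LSF"):
            filtered = src if gains[sf] is None else apply_sf_filter(src, gains[sf])
            scramble_seed = int(rng.integers(0, 2**31))
            scrambled = phase_scramble(filtered, scramble_seed)
            for objecthood, im, used_seed in (
                ("object", filtered, -1),
                ("nonobject", scrambled, scramble_seed),
            ):
                matched = match_luminance_contrast(im, target_mean, target_sd)
                images[(objecthood, sf)].append(matched)
                path = ""
                if out_dir is not None:
                    path = str(out_dir / f"src{i:03d}_{objecthood}_{sf}.png")
                    save_png(matched, path, clip=clip)
                rows.append(
                    {
                        "source_id": i,
                        "condition": f"{objecthood}/{sf}",
                        "path": path,
                        "mean": matched.mean,
                        "sd": matched.sd,
                        "cutoff": specs[sf].cutoff_cpd if specs[sf] else np.nan,
                        "seed": used_seed,
                    }
                )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return StimulusSet(
        images=images,
        manifest=manifest,
        target_mean=target_mean,
        target_sd=target_sd,
        cutoffs_cpd={"HSF": hsf_cutoff_cpd, "LSF": lsf_cutoff_cpd},
    )


def make_toy_objects(
    n: int,
    *,
    size: int = 400,
    ppd: float = 41.4,
    seed: int = 0,
) -> list[GrayImage]:
    """Generate synthetic 'object photographs': simple shapes on a grey field.

    Stand-ins for real object photographs (none ship with the package):
    even indices get angular, man-made-like shapes (bars, crosses,
    rectangles), odd indices rounded, natural-like blobs (ellipse unions).
    Intensities live in [0, 1] with a 0.5 background.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    out = []
    for i in range(n):
        img = np.full((size, size), 0.5)
        n_parts = rng.integers(2, 5)
        for _ in range(n_parts):
            py = cy + rng.uniform(-0.2, 0.2) * size
            px = cx + rng.uniform(-0.2, 0.2) * size
            level = rng.uniform(0.15, 0.85)
            if i % 2 == 0:  # angular
                h = rng.uniform(0.04, 0.25) * size
                w = rng.uniform(0.04, 0.25) * size
                mask = (np.abs(yy - py) < h) & (np.abs(xx - px) < w)
            else:  # rounded
                a = rng.uniform(0.05, 0.2) * size
                b = rng.uniform(0.05, 0.2) * size
                mask = ((yy - py) / a) ** 2 + ((xx - px) / b) ** 2 < 1.0
            img[mask] = level
        out.append(GrayImage(img, ppd))
    return out


def save_png(img: GrayImage, path: str | Path, *, bit_depth: int = 16, clip: bool = False) -> None:
    """Write as 8- or 16-bit grayscale PNG, mapping intensity [0, 1] to full range.

    Out-of-range values are clipped; when ``clip`` is False a warning is
    raised if any clipping actually occurred.
    """
    import imageio.v3 as iio

    if bit_depth not in (8, 16):
        raise ValueError("bit depth must be 8 or 16")
    vals = img.intensities
    lo, hi = float(vals.min()), float(vals.max())
    if (lo < 0 or hi > 1) and not clip:
        warnings.warn(
            f"intensities outside [0, 1] ({lo:.3f}..{hi:.3f}) clipped on save", stacklevel=2
        )
    scale = 2**bit_depth - 1
    arr = np.clip(vals, 0.0, 1.0) * scale
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), arr.round().astype(dtype))


def load_gray(path: str | Path, ppd: float) -> GrayImage:
    """Read an 8- or 16-bit grayscale PNG/TIFF into intensity units [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)), dtype=float)
    if arr.ndim == 3:  # collapse identical channels
        arr = arr.mean(axis=2)
    scale = 255.0 if arr.max() <= 255 else 65535.0
    return GrayImage(arr / scale, ppd)
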