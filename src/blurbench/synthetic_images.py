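"""Isotropic natural-image surrogates, grayscale image I/O and window sampling.

Natural photographs share a characteristic second-order statistic: their
amplitude spectrum falls off roughly as 1/f with spatial frequency.  The
surrogate generator here synthesises grayscale fields with exactly that
radially symmetric power-law spectrum and uniformly random phases, which
preserves the statistic that makes "natural images" the relevant input class
for a centre-surround / cortical filter bank while being fully reproducible
from a seed.  By construction the surrogates have no preferred orientation.

Coordinate convention used throughout the package: row-major, 0-based
``(row, col)`` indexing; windows are half-open ``[top, top + size)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .exceptions import ConfigError, DataError, GeometryError

__all__ = [
    "GrayImage",
    "WindowSample",
    "generate_surrogate_image",
    "read_image",
    "write_image",
    "sample_windows",
    "save_window_set",
    "load_window_set",
]

#: ITU-R BT.601 luma weights used to collapse colour inputs to grayscale.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_MIN_SURROGATE_SIDE = 32


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of pixel intensities in the closed interval [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise DataError(f"expected a 2-D pixel grid, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise DataError(f"degenerate image shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise DataError("image contains non-finite intensities")
        lo, hi = float(arr.min()), float(arr.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise DataError(
                f"intensities must lie in [0, 1]; found range [{lo:.6g}, {hi:.6g}]"
            )
        arr = np.clip(arr, 0.0, 1.0)
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class WindowSample:
    """A square window cut from a source image, carrying a safety margin.

    ``core`` is the analysis window proper; ``margin_field`` is the larger
    field around it from which the core can be recomputed after filtering,
    so that no padded (invented) pixel ever enters the core.  ``top_left``
    is the position of the *core* in source-image coordinates.
    """

    core: GrayImage
    margin_field: GrayImage
    source_id: str
    top_left: tuple[int, int]
    margin: int = field(default=0)

    def __post_init__(self) -> None:
        w = self.core.width
        if self.core.height != w:
            raise GeometryError("window core must be square")
        m = self.margin
        if self.margin_field.height != w + 2 * m or self.margin_field.width != w + 2 * m:
            raise GeometryError(
                f"margin field shape {self.margin_field.pixels.shape} inconsistent "
                f"with core size {w} and margin {m}"
            )
        inner = self.margin_field.pixels[m : m + w, m : m + w]
        if not np.array_equal(inner, self.core.pixels):
            raise GeometryError("core is not the central region of the margin field")

    @property
    def window_size(self) -> int:
        return self.core.width


def generate_surrogate_image(
    width: int,
    height: int,
    spectral_exponent: float = 1.0,
    seed: int = 0,
) -> GrayImage:
    """Generate an isotropic random field with a 1/f**exponent amplitude spectrum.

    The field is produced by spectrally shaping Gaussian white noise: the DC
    component is removed, every other Fourier amplitude is scaled by
    ``f ** -spectral_exponent`` with ``f`` the radial frequency in cycles per
    pixel, and the result is affinely rescaled so its minimum is exactly 0 and
    its maximum exactly 1.  ``spectral_exponent=0`` therefore yields white
    noise; ``1`` yields the pink, scale-invariant statistics typical of
    natural scenes.  The same ``seed`` gives a bit-identical image.
    """
    if width < _MIN_SURROGATE_SIDE or height < _MIN_SURROGATE_SIDE:
        raise ConfigError(
            f"surrogate dimensions must be at least {_MIN_SURROGATE_SIDE} px, "
            f"got {width}x{height}"
        )
    if spectral_exponent < 0:
        raise ConfigError("spectral_exponent must be >= 0")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((height, width))
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-spectral_exponent)
    shaped = np.fft.ifft2(np.fft.fft2(noise) * amp).real
    lo, hi = shaped.min(), shaped.max()
    if hi <= lo:  # pragma: no cover - cannot happen for continuous noise
        raise ConfigError("degenerate surrogate field (constant)")
    return GrayImage((shaped - lo) / (hi - lo))


def read_image(path: str | Path) -> GrayImage:
    """Read a PNG or PGM image as a GrayImage in [0, 1].

    Colour inputs are collapsed with the BT.601 luma transform
    ``0.299 R + 0.587 G + 0.114 B``; 8-bit values map to [0, 1] by
    division by 255.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"image file not found: {path}")
    if path.suffix.lower() not in {".png", ".pgm"}:
        raise DataError(f"unsupported image format: {path.suffix!r} (use PNG or PGM)")
    try:
        with Image.open(path) as img:
            arr = np.asarray(img, dtype=np.float64)
    except Exception as exc:  # pillow raises a zoo of errors
        raise DataError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        rgb = arr[..., :3]
        arr = rgb @ np.asarray(LUMA_WEIGHTS)
    return GrayImage(np.clip(arr / 255.0, 0.0, 1.0))


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write a GrayImage as an 8-bit PNG or PGM file."""
    path = Path(path)
    if path.suffix.lower() not in {".png", ".pgm"}:
        raise DataError(f"unsupported image format: {path.suffix!r} (use PNG or PGM)")
    data = np.round(image.pixels * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def sample_windows(
    images: Sequence[GrayImage],
    n: int,
    window_size: int,
    margin: int = 0,
    seed: int = 0,
) -> list[WindowSample]:
    """Draw ``n`` square windows uniformly over images and valid positions.

    Positions are uniform over placements where the margin field (core plus
    ``margin`` on every side) lies fully inside the source image; the source
    image index is uniform as well, with replacement.  Reproducible under
    ``seed``.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if window_size < 1 or margin < 0:
        raise ConfigError("window_size must be >= 1 and margin >= 0")
    if not images:
        raise ConfigError("no source images given")
    side = window_size + 2 * margin
    for i, img in enumerate(images):
        if img.height < side or img.width < side:
            raise GeometryError(
                f"image {i} ({img.height}x{img.width}) too small for "
                f"window {window_size} with margin {margin} (needs {side})"
            )
    rng = np.random.default_rng(seed)
    samples: list[WindowSample] = []
    for _ in range(n):
        idx = int(rng.integers(len(images)))
        img = images[idx]
        top = margin + int(rng.integers(img.height - side + 1))
        left = margin + int(rng.integers(img.width - side + 1))
        field_px = img.pixels[top - margin : top - margin + side,
                              left - margin : left - margin + side]
        core_px = field_px[margin : margin + window_size, margin : margin + window_size]
        samples.append(
            WindowSample(
                core=GrayImage(core_px),
                margin_field=GrayImage(field_px),
                source_id=str(idx),
                top_left=(top, left),
                margin=margin,
            )
        )
    return samples


def save_window_set(samples: Sequence[WindowSample], out_dir: str | Path) -> Path:
    """Serialize windows as PNG cores plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "windows.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["index", "file", "source_id", "top_left_row", "top_left_col",
             "window_size", "margin"]
        )
        for i, s in enumerate(samples):
            name = f"window_{i:05d}.png"
            write_image(s.core, out_dir / name)
            writer.writerow(
                [i, name, s.source_id, s.top_left[0], s.top_left[1],
                 s.window_size, s.margin]
            )
    return manifest


def load_window_set(manifest: str | Path) -> list[WindowSample]:
    """Load windows written by :func:`save_window_set`.

    The margin field cannot be reconstructed from the serialized cores, so
    loaded samples carry margin 0 (sufficient for representation stages;
    blurring requires re-sampling from the sources).
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise DataError(f"manifest not found: {manifest}")
    samples = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            core = read_image(manifest.parent / row["file"])
            samples.append(
                WindowSample(
                    core=core,
                    margin_field=core,
                    source_id=row["source_id"],
                    top_left=(int(row["top_left_row"]), int(row["top_left_col"])),
                    margin=0,
                )
            )
    return samples
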