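"""Thalamic (LGN) representation: DoG receptive fields on a hexagonal mosaic.

The lateral geniculate nucleus is modelled as a bank of centre-surround
units.  Each unit's receptive-field profile is a difference of two
unit-mass Gaussians,

    RF(D) = exp(-D^2 / 2 sigma_c^2) / (2 pi sigma_c^2)
          - exp(-D^2 / 2 sigma_s^2) / (2 pi sigma_s^2),

with D the Euclidean distance (pixels) from the field centre,
sigma_c = 0.833 px and sigma_s = 3 sigma_c by default; this places the
radial zero crossing at ~1.85 px, i.e. a positive centre about 4 px wide,
with the whole field spanning ~16 px.  91 ON-centre and 91 OFF-centre
units share identical centres laid out as a centred hexagonal lattice
(rings=5) over the analysis window.  For a window with intensities
PI in [0, 1], each centre computes the filtered drive
s = sum_xy RF_xy PI_xy and emits the rectified pair

    ON  = max(0, 0.1 + s),      OFF = max(0, 0.1 - s),

so ON + OFF = 0.2 wherever both are positive.  The RF support is clipped
at the window border: out-of-window pixels are simply omitted from the sum
(no padding), which leaves edge units with a small nonzero drive even for
uniform input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .exceptions import ConfigError, GeometryError
from .synthetic_images import GrayImage

__all__ = [
    "RFProfile",
    "LgnMosaic",
    "LgnVector",
    "dog_profile",
    "center_diameter_px",
    "hex_mosaic",
    "lgn_response",
    "lgn_weight_matrix",
    "lgn_represent",
]

DEFAULT_SIGMA_CENTER = 0.833
DEFAULT_SURROUND_RATIO = 3.0
BASELINE = 0.1  # resting activity added to +/- the filtered drive


def _dog_value(d2: np.ndarray | float, sigma_c: float, sigma_s: float):
    """Difference-of-Gaussians profile evaluated at squared distance d2."""
    gc = np.exp(-np.asarray(d2) / (2.0 * sigma_c**2)) / (2.0 * np.pi * sigma_c**2)
    gs = np.exp(-np.asarray(d2) / (2.0 * sigma_s**2)) / (2.0 * np.pi * sigma_s**2)
    return gc - gs


@dataclass(frozen=True)
class RFProfile:
    """Discretized DoG receptive-field kernel with its two space constants."""

    sigma_center: float
    sigma_surround: float
    kernel: np.ndarray  # (2*support+1, 2*support+1), value at centre positive
    support: int  # half-width of the kernel in pixels

    def __post_init__(self) -> None:
        if not (self.sigma_surround > self.sigma_center > 0):
            raise ConfigError("need sigma_surround > sigma_center > 0")

    def __call__(self, d2):
        """Profile value at squared distance ``d2`` from the field centre."""
        return _dog_value(d2, self.sigma_center, self.sigma_surround)


def dog_profile(
    sigma_center: float = DEFAULT_SIGMA_CENTER,
    surround_ratio: float = DEFAULT_SURROUND_RATIO,
    support: int | None = None,
) -> RFProfile:
    """Build the DoG profile; ``support`` defaults to ceil(3*sigma_surround).

    With the defaults (sigma_center=0.833, ratio 3) the support half-width is
    8 px, i.e. a 17x17 kernel covering the ~16 px receptive field.
    """
    if sigma_center <= 0:
        raise ConfigError("sigma_center must be positive")
    if surround_ratio <= 1:
        raise ConfigError("surround_ratio must exceed 1")
    sigma_surround = surround_ratio * sigma_center
    if support is None:
        support = int(np.ceil(3.0 * sigma_surround))
    offsets = np.arange(-support, support + 1, dtype=np.float64)
    d2 = offsets[:, None] ** 2 + offsets[None, :] ** 2
    kernel = _dog_value(d2, sigma_center, sigma_surround)
    return RFProfile(sigma_center, sigma_surround, kernel, support)


def center_diameter_px(profile: RFProfile) -> float:
    """Diameter of the positive central lobe, from the radial zero crossing.

    Found by 1-D root bracketing of the radial profile between 0 and the
    support radius.
    """
    f = lambda r: float(profile(r * r))
    radius = brentq(f, 1e-9, float(profile.support))
    return 2.0 * radius


@dataclass(frozen=True)
class LgnMosaic:
    """Centred hexagonal lattice of receptive-field centres over a window."""

    centers: np.ndarray  # (n, 2) float (row, col) in window coordinates
    rings: int
    spacing: float
    window_size: int

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]


def hex_mosaic(
    rings: int = 5,
    spacing: float = 2.4,
    window_size: int = 25,
) -> LgnMosaic:
    """Centred hexagonal lattice with 3*rings*(rings+1)+1 points.

    rings=5 gives the 91-centre mosaic; spacing 2.4 px makes the lattice
    diameter 24 px, tiling a 25x25 window.  Centres are ordered
    deterministically by axial coordinates.  A warning (not an error) is
    issued if the lattice overhangs the window by more than spacing/2;
    receptive-field support clipped at the border is always allowed.
    """
    if rings < 0:
        raise ConfigError("rings must be >= 0")
    if spacing <= 0:
        raise ConfigError("spacing must be positive")
    pts = []
    for r in range(-rings, rings + 1):
        for q in range(-rings, rings + 1):
            if abs(q + r) <= rings:
                row = spacing * (np.sqrt(3.0) / 2.0) * r
                col = spacing * (q + r / 2.0)
                pts.append((row, col))
    centers = np.asarray(pts, dtype=np.float64)
    mid = (window_size - 1) / 2.0
    centers += mid
    over = max(
        float(-centers.min()),
        float(centers.max() - (window_size - 1)),
        0.0,
    )
    if over > spacing / 2.0:
        warnings.warn(
            f"hexagonal mosaic overhangs the {window_size}px window by {over:.2f}px",
            stacklevel=2,
        )
    return LgnMosaic(centers, rings, spacing, window_size)


@dataclass(frozen=True)
class LgnVector:
    """Rectified ON/OFF activities at each mosaic centre (all ON, then all OFF)."""

    on: np.ndarray
    off: np.ndarray

    def __post_init__(self) -> None:
        if self.on.shape != self.off.shape or self.on.ndim != 1:
            raise ConfigError("ON and OFF channels must be 1-D and equal length")
        if (self.on < 0).any() or (self.off < 0).any():
            raise ConfigError("LGN activities are rectified and must be >= 0")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.on, self.off])

    def __len__(self) -> int:
        return self.on.size + self.off.size


def lgn_weight_matrix(mosaic: LgnMosaic, profile: RFProfile) -> np.ndarray:
    """Per-centre DoG weights over the window pixels: shape (n_centers, size*size).

    The profile is evaluated at the exact Euclidean distance between each
    (possibly fractional) mosaic centre and each pixel, zeroed beyond the
    support radius; pixels outside the window are implicitly omitted
    (border clipping).
    """
    w = mosaic.window_size
    rows = np.arange(w, dtype=np.float64)
    rr, cc = np.meshgrid(rows, rows, indexing="ij")
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1)  # (w*w, 2)
    diff = mosaic.centers[:, None, :] - pix[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    weights = profile(d2)
    weights[d2 > profile.support**2] = 0.0
    return weights


def _lgn_drive(windows: np.ndarray, weights: np.ndarray) -> np.ndarray:
    flat = windows.reshape(windows.shape[0], -1)
    return flat @ weights.T


def lgn_response(window: GrayImage, mosaic: LgnMosaic, profile: RFProfile) -> LgnVector:
    """ON/OFF activities of the mosaic for one window (Eqs. of the model above)."""
    if window.height != mosaic.window_size or window.width != mosaic.window_size:
        raise GeometryError(
            f"window shape {window.pixels.shape} does not match mosaic "
            f"window size {mosaic.window_size}"
        )
    s = _lgn_drive(window.pixels[None], lgn_weight_matrix(mosaic, profile))[0]
    return LgnVector(on=np.maximum(0.0, BASELINE + s), off=np.maximum(0.0, BASELINE - s))


def lgn_represent(
    windows: Sequence[GrayImage] | np.ndarray,
    mosaic: LgnMosaic,
    profile: RFProfile,
) -> np.ndarray:
    """Stacked LGN vectors for many windows: shape (n, 2 * n_centers).

    Column order is all ON activities in mosaic order, then all OFF.
    """
    if isinstance(windows, np.ndarray):
        arr = windows
    else:
        arr = np.stack([w.pixels for w in windows])
    if arr.shape[1] != mosaic.window_size or arr.shape[2] != mosaic.window_size:
        raise GeometryError("window stack does not match the mosaic window size")
    s = _lgn_drive(arr, lgn_weight_matrix(mosaic, profile))
    return np.concatenate(
        [np.maximum(0.0, BASELINE + s), np.maximum(0.0, BASELINE - s)], axis=1
    )
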