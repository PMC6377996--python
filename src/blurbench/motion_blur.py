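"""Linear motion blur and the two-class (horizontal vs vertical) dataset.

Linear motion during exposure smears the image along the motion axis; for
uniform velocity the point-spread function is a uniform (box) line segment.
A horizontal box kernel of length ``size`` averages ``size`` neighbouring
pixels along rows, attenuating vertical detail while leaving structure that
is constant along the motion axis untouched; the vertical kernel is its
exact transpose.  Blur is always applied to the margin field of a window
sample and the core re-cropped, so no padded pixel ever enters the core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import ConfigError, GeometryError
from .synthetic_images import GrayImage, WindowSample

__all__ = [
    "BlurSpec",
    "LabelledSample",
    "make_blur_kernel",
    "apply_blur",
    "build_dataset",
    "HORIZONTAL",
    "VERTICAL",
]

HORIZONTAL = "horizontal"
VERTICAL = "vertical"

#: Class labels: 0 = horizontal motion, 1 = vertical motion.
LABEL_OF_ORIENTATION = {HORIZONTAL: 0, VERTICAL: 1}


@dataclass(frozen=True)
class BlurSpec:
    """Orientation and extent (pixels) of a linear motion blur; size 1 is identity."""

    orientation: Literal["horizontal", "vertical"]
    size: int

    def __post_init__(self) -> None:
        if self.orientation not in (HORIZONTAL, VERTICAL):
            raise ConfigError(f"unknown blur orientation {self.orientation!r}")
        if int(self.size) != self.size or self.size < 1:
            raise ConfigError(f"blur size must be an integer >= 1, got {self.size!r}")

    @property
    def label(self) -> int:
        return LABEL_OF_ORIENTATION[self.orientation]

    @property
    def min_margin(self) -> int:
        """Margin needed so the blurred core uses only real pixels."""
        return self.size // 2


@dataclass(frozen=True)
class LabelledSample:
    """A blurred window with its class label (0 horizontal, 1 vertical)."""

    window: GrayImage
    label: int
    blur: BlurSpec
    source_ref: str

    def __post_init__(self) -> None:
        if self.label != self.blur.label:
            raise ConfigError("label inconsistent with blur orientation")


def make_blur_kernel(spec: BlurSpec) -> np.ndarray:
    """Uniform line kernel for the given blur: shape (1, size) or (size, 1).

    Weights are 1/size each and sum to 1, so convolution preserves the mean
    of a constant field.
    """
    line = np.full(spec.size, 1.0 / spec.size)
    return line[None, :] if spec.orientation == HORIZONTAL else line[:, None]


def _blur_crop(fields: np.ndarray, orientation: str, size: int,
               margin: int, core: int) -> np.ndarray:
    """Box-blur a batch of margin fields and crop the cores.

    ``fields`` has shape (..., S, S) with S = core + 2*margin.  The kernel
    anchor is floor(size/2) from the left/top of the kernel, so the crop for
    core pixel j covers field pixels [m + j - size//2, ...) of length size.
    The accumulation order over kernel taps is fixed, which makes the
    horizontal blur of a field and the vertical blur of its transpose
    bit-identical transposes of one another.
    """
    a = size // 2
    if margin < a:
        raise GeometryError(
            f"margin {margin} insufficient for blur size {size} (needs >= {a})"
        )
    m = margin
    acc = np.zeros(fields.shape[:-2] + (core, core), dtype=np.float64)
    for t in range(size):
        off = m - a + t
        if orientation == HORIZONTAL:
            acc += fields[..., m : m + core, off : off + core]
        else:
            acc += fields[..., off : off + core, m : m + core]
    return acc / size


def apply_blur(sample: WindowSample, spec: BlurSpec) -> GrayImage:
    """Blur a window's margin field and return the re-cropped core.

    Requires ``sample.margin >= spec.size // 2``; raises GeometryError
    otherwise.  Output intensities stay in [0, 1] (a box average of values
    in [0, 1]).
    """
    out = _blur_crop(
        sample.margin_field.pixels, spec.orientation, spec.size,
        sample.margin, sample.window_size,
    )
    return GrayImage(out)


def build_dataset(
    samples: Sequence[WindowSample],
    size: int,
    assignment_seed: int = 0,
) -> list[LabelledSample]:
    """Split windows into two disjoint halves and blur one per orientation.

    Each physical window contributes exactly one labelled sample (either
    horizontal, label 0, or vertical, label 1 — never both), which rules out
    twin-image leakage between later train/test splits.  Class sizes differ
    by at most 1; the assignment is a seeded uniform permutation.  Samples
    are returned in their original order.
    """
    n = len(samples)
    if n < 2:
        raise ConfigError("need at least 2 windows to build a two-class dataset")
    rng = np.random.default_rng(assignment_seed)
    perm = rng.permutation(n)
    horizontal_idx = set(perm[: n // 2].tolist())
    out: list[LabelledSample] = []
    for i, s in enumerate(samples):
        orient = HORIZONTAL if i in horizontal_idx else VERTICAL
        spec = BlurSpec(orient, size)
        out.append(
            LabelledSample(
                window=apply_blur(s, spec),
                label=spec.label,
                blur=spec,
                source_ref=f"{s.source_id}@{s.top_left[0]},{s.top_left[1]}",
            )
        )
    return out
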