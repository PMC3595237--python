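"""Eight-bin quantization of MIP maps, false-color rendering, ratio statistics.

Masked pixels of the 8-bit MIP are tallied into eight equal-width gray-value
bins on the fixed 0-255 scale (edges 0, 32, ..., 256; intervals half-open,
the last closed at 255).  The two response variables of the analysis are the
pixel-count ratios of the top and second-highest bins to all masked pixels:
size-corrected proxies for how much of the articular surface is loaded at
the highest radiodensity levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinHistogram",
    "SpecimenRecord",
    "bin_counts",
    "ratio_statistics",
    "false_color_map",
    "DEFAULT_PALETTE",
]

#: blue -> red false-color palette, low to high radiodensity (RGB, 0-255)
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (0, 0, 143),
    (0, 64, 255),
    (0, 191, 255),
    (64, 255, 191),
    (191, 255, 64),
    (255, 191, 0),
    (255, 64, 0),
    (143, 0, 0),
)

BACKGROUND_RGB = (0, 0, 0)


class EmptyMaskError(ValueError):
    """Raised when a histogram or ratio is requested over an empty mask."""


@dataclass
class BinHistogram:
    """Counts of masked pixels in gray-value bins.

    counts : per-bin pixel counts ordered low -> high gray value
    total : number of masked pixels (== sum of counts)
    edges : bin boundaries on the 0-255 scale; [e_i, e_{i+1}) with the last
        bin closed at 255
    """

    counts: np.ndarray
    total: int
    edges: np.ndarray


def bin_counts(mip8: np.ndarray, mask: np.ndarray, n_bins: int = 8) -> BinHistogram:
    """Tally masked 8-bit pixels into equal-width bins spanning [0, 256).

    With the default 8 bins, edges are 0, 32, ..., 256 and the bin index of a
    pixel value v is v // 32 (value 31 -> bin 0, 32 -> bin 1, 255 -> bin 7).
    """
    mip8 = np.asarray(mip8)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != mip8.shape:
        raise ValueError("mask and image shapes differ")
    if not mask.any():
        raise EmptyMaskError("empty mask: bin ratios are undefined")
    vals = mip8[mask].astype(int)
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("image is not 8-bit (values outside 0-255)")
    width = 256 // n_bins
    idx = np.minimum(vals // width, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * width
    return BinHistogram(counts=counts, total=int(counts.sum()), edges=edges)


def ratio_statistics(hist: BinHistogram) -> tuple[float, float]:
    """Return (max_ratio, second_ratio): top and second-bin counts over total."""
    if hist.total <= 0:
        raise EmptyMaskError("histogram has zero total")
    return (
        float(hist.counts[-1]) / hist.total,
        float(hist.counts[-2]) / hist.total,
    )


@dataclass
class SpecimenRecord:
    """One specimen's response variables: the two bin ratios plus metadata."""

    specimen_id: str
    species: str
    gait: str
    max_ratio: float
    second_ratio: float

    def __post_init__(self) -> None:
        for r in (self.max_ratio, self.second_ratio):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"ratio out of [0,1]: {r}")
        if self.max_ratio + self.second_ratio > 1.0 + 1e-12:
            raise ValueError("top two bin ratios exceed 1")


def false_color_map(
    mip8: np.ndarray,
    mask: np.ndarray,
    palette8: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE,
) -> np.ndarray:
    """Render each masked pixel with its bin's palette color.

    Returns an (nx, ny, 3) uint8 RGB image; unmasked pixels take the neutral
    background color.  Bin assignment is identical to :func:`bin_counts`.
    """
    if len(palette8) != 8:
        raise ValueError("palette must have 8 entries")
    mip8 = np.asarray(mip8)
    mask = np.asarray(mask, dtype=bool)
    lut = np.array(palette8, dtype=np.uint8)
    idx = np.minimum(np.asarray(mip8, dtype=int) // 32, 7)
    rgb = lut[idx]
    rgb[~mask] = np.array(BACKGROUND_RGB, dtype=np.uint8)
    return rgb
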