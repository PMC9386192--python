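"""Per-ROI temperature features: mean, quantized-histogram Shannon entropy,
and gray-level co-occurrence texture.

The entropy path follows the quantization procedure used for exercise
thermograms: temperatures are rounded to 0.1 °C precision, the ROI minimum
is subtracted, and the result is expressed as non-negative integer levels,
so that the Shannon entropy

    H = -sum_k p(x_k) * log2 p(x_k)

of the level histogram measures how heterogeneous the ROI's temperature
texture is, independently of its absolute temperature.  The mean
temperature is computed on the raw (unrounded) values; rounding applies
only to the texture path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ROIMask, ThermalFrame

__all__ = [
    "QuantizedROI",
    "ROIFeatures",
    "extract_roi",
    "quantize",
    "shannon_entropy",
    "mean_temperature",
    "glcm_texture",
    "frame_features",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_GLCM_OFFSETS",
]

#: Temperature bin width (°C) separating adjacent quantized levels.
DEFAULT_BIN_WIDTH = 0.1

#: The four unit displacements of a symmetric co-occurrence analysis.
DEFAULT_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class QuantizedROI:
    """An ROI's temperatures as non-negative integer levels.

    ``levels[i] * bin_width + t_min`` recovers the rounded temperature of
    pixel *i*.  ``min(levels) == 0`` by construction.
    """

    levels: np.ndarray
    bin_width: float
    t_min: float

    @property
    def n_pixels(self) -> int:
        return int(self.levels.size)

    @property
    def n_levels(self) -> int:
        return int(np.unique(self.levels).size)


@dataclass(frozen=True)
class ROIFeatures:
    """Feature record for one ROI in one frame."""

    label: str
    mean_temp: float
    entropy: float
    n_pixels: int
    n_levels: int
    contrast: float | None = None
    homogeneity: float | None = None


def extract_roi(frame: ThermalFrame, mask: ROIMask) -> np.ndarray:
    """Temperatures at the mask's true pixels (row-major order, multiplicity kept)."""
    if mask.mask.shape != frame.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match frame shape {frame.shape}"
        )
    return frame.temperatures[mask.mask]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round uses banker's rounding; the documented tie rule is half away
    # from zero.  Pre-rounding to 9 decimals absorbs float representation
    # error in quotients like 30.05 / 0.1 = 300.49999...
    x = np.round(x, 9)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize(temps: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH) -> QuantizedROI:
    """Round to ``bin_width`` precision (ties half away from zero), subtract
    the rounded ROI minimum, and express the result as integer levels."""
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("cannot quantize an empty set of temperatures")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    units = _round_half_away(temps / bin_width).astype(np.int64)
    t_min_units = units.min()
    return QuantizedROI(
        levels=units - t_min_units,
        bin_width=float(bin_width),
        t_min=float(t_min_units * bin_width),
    )


def shannon_entropy(q: QuantizedROI) -> float:
    """Shannon entropy (bits) of the quantized level histogram.

    ``p(x_k)`` is the relative frequency of level ``x_k`` among the ROI's
    pixels; the sum runs over observed levels only, with ``0 log 0 = 0``.
    """
    if q.n_pixels == 0:
        raise ValueError("cannot compute entropy of an empty ROI")
    _, counts = np.unique(q.levels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def mean_temperature(temps: Sequence[float]) -> float:
    """Arithmetic mean of the raw (unrounded) ROI temperatures, in °C."""
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("cannot average an empty set of temperatures")
    return float(temps.mean())


def glcm_texture(
    q: QuantizedROI,
    mask: ROIMask,
    offsets: Sequence[tuple[int, int]] = DEFAULT_GLCM_OFFSETS,
) -> dict[str, float]:
    """Contrast and homogeneity from a symmetric, normalized co-occurrence
    matrix of quantized levels, restricted to pixel pairs fully inside the
    mask.

    contrast    = sum_ij P(i,j) (i-j)^2
    homogeneity = sum_ij P(i,j) / (1 + |i-j|)
    """
    level_img = np.full(mask.mask.shape, -1, dtype=np.int64)
    level_img[mask.mask] = q.levels
    n_levels = int(q.levels.max()) + 1
    glcm = np.zeros((n_levels, n_levels), dtype=float)
    rows, cols = mask.mask.shape
    for dr, dc in offsets:
        r0a, r1a = max(0, -dr), min(rows, rows - dr)
        c0a, c1a = max(0, -dc), min(cols, cols - dc)
        a = level_img[r0a:r1a, c0a:c1a]
        b = level_img[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
        valid = (a >= 0) & (b >= 0)
        if not valid.any():
            continue
        np.add.at(glcm, (a[valid], b[valid]), 1.0)
        np.add.at(glcm, (b[valid], a[valid]), 1.0)
    total = glcm.sum()
    if total == 0:
        raise ValueError("no co-occurring pixel pair lies fully inside the mask")
    p = glcm / total
    i, j = np.indices(p.shape)
    return {
        "contrast": float(np.sum(p * (i - j) ** 2)),
        "homogeneity": float(np.sum(p / (1.0 + np.abs(i - j)))),
    }


def frame_features(
    frame: ThermalFrame,
    masks: Sequence[ROIMask],
    bin_width: float = DEFAULT_BIN_WIDTH,
    with_glcm: bool = False,
) -> list[ROIFeatures]:
    """Mean temperature and entropy (optionally GLCM texture) per ROI."""
    out = []
    for mask in masks:
        temps = extract_roi(frame, mask)
        q = quantize(temps, bin_width)
        tex: dict[str, float | None] = {"contrast": None, "homogeneity": None}
        if with_glcm:
            tex = dict(glcm_texture(q, mask))
        out.append(
            ROIFeatures(
                label=mask.label,
                mean_temp=mean_temperature(temps),
                entropy=shannon_entropy(q),
                n_pixels=q.n_pixels,
                n_levels=q.n_levels,
                contrast=tex["contrast"],
                homogeneity=tex["homogeneity"],
            )
        )
    return out
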