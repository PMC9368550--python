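"""Ecological criticality surfaces and threshold-based ECA extraction.

Per cell, the multiple-ecosystem-services landscape index (MESLI) is the sum
of min-max normalised ecosystem-service values,

    MESLI_i = sum_s (x_si - min_s) / (max_s - min_s)   in [0, n_services],

and the ecological critical index is the product with the landscape
structure security index, ECI_i = MESLI_i x LESSI_i.  Ecologically critical
areas (ECA) are the cells whose ECI exceeds a threshold T extracted from the
ECI frequency distribution: the histogram counts are smoothed with a
centred moving average and T is the centre of the bin holding the last
(highest-ECI) strict local maximum of the smoothed curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdResult",
    "mesli",
    "eci",
    "extract_threshold",
    "identify_eca",
]

logger = logging.getLogger(__name__)


def mesli(services: np.ndarray) -> np.ndarray:
    """Sum of per-layer min-max normalised service values.

    ``services`` is an ``(n_services, rows, cols)`` stack.  Normalisation
    bounds are taken over the finite cells of each layer for the period at
    hand.  NaN cells propagate.  A constant layer has no contrast to
    normalise and raises ``ValueError`` naming the layer.
    """
    stack = np.asarray(services, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected a (n_services, rows, cols) stack, got {stack.shape}")
    out = np.zeros(stack.shape[1:], dtype=float)
    for i, layer in enumerate(stack):
        lo = np.nanmin(layer)
        hi = np.nanmax(layer)
        if not np.isfinite(lo) or hi == lo:
            raise ValueError(f"service layer {i} is constant (min == max == {lo}); cannot normalise")
        out = out + (layer - lo) / (hi - lo)
    return out


def eci(mesli_raster: np.ndarray, lessi_raster: np.ndarray) -> np.ndarray:
    """Cell-wise product MESLI x LESSI; NaN propagates."""
    m = np.asarray(mesli_raster, dtype=float)
    l = np.asarray(lessi_raster, dtype=float)
    if m.shape != l.shape:
        raise ValueError(f"grid mismatch: MESLI {m.shape} vs LESSI {l.shape}")
    return m * l


@dataclass
class ThresholdResult:
    """Threshold plus the diagnostic curve used to find it."""

    threshold: float
    bin_centers: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    peak_bins: list[int]
    fallback: bool = False


def _moving_average(counts: np.ndarray, window: int) -> np.ndarray:
    # centred moving average; the window is truncated (renormalised) at the
    # ends so boundary bins average only over existing neighbours
    kernel = np.ones(window)
    num = np.convolve(counts, kernel, mode="same")
    den = np.convolve(np.ones_like(counts), kernel, mode="same")
    return num / den


def _strict_peaks(smoothed: np.ndarray) -> list[int]:
    """Interior strict local maxima; plateaus collapse to their centre bin."""
    peaks = []
    n = len(smoothed)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and smoothed[j + 1] == smoothed[i]:
            j += 1
        if smoothed[i] > smoothed[i - 1] and j < n - 1 and smoothed[j] > smoothed[j + 1]:
            peaks.append((i + j) // 2)
        i = j + 1
    return peaks


def extract_threshold(
    values: np.ndarray,
    n_bins: int = 100,
    smooth_window: int = 5,
) -> ThresholdResult:
    """Extract the ECA threshold from an ECI sample.

    The histogram spans [min, max] with ``n_bins`` equal-width bins; counts
    are smoothed by a centred moving average of ``smooth_window`` bins and T
    is the centre of the bin holding the last strict local maximum.  When
    the smoothed curve has no interior local maximum the global maximum bin
    is used instead and a warning is logged.
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 1000:
        raise ValueError(f"need at least 1000 finite values to fit a frequency curve, got {vals.size}")
    if n_bins < 10:
        raise ValueError(f"n_bins must be >= 10, got {n_bins}")
    counts, edges = np.histogram(vals, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = _moving_average(counts.astype(float), smooth_window)
    peaks = _strict_peaks(smoothed)
    if peaks:
        t_bin = peaks[-1]
        fallback = False
    else:
        t_bin = int(np.argmax(smoothed))
        fallback = True
        logger.warning(
            "no interior local maximum in the smoothed ECI histogram; "
            "falling back to the global maximum bin"
        )
    return ThresholdResult(
        threshold=float(centers[t_bin]),
        bin_centers=centers,
        counts=counts,
        smoothed=smoothed,
        peak_bins=peaks,
        fallback=fallback,
    )


def identify_eca(
    eci_raster: np.ndarray, threshold: float
) -> tuple[np.ndarray, int, float]:
    """Boolean ECA mask (strict ``ECI > T``), grid count and valid share.

    NaN cells are excluded from the mask and from the share denominator.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    arr = np.asarray(eci_raster, dtype=float)
    valid = np.isfinite(arr)
    mask = valid & (arr > threshold)
    count = int(mask.sum())
    n_valid = int(valid.sum())
    share = count / n_valid if n_valid else 0.0
    return mask, count, share
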