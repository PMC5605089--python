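"""Automatic histogram thresholding: Otsu, Intermodes and Percentile.

These are the three classic 8-bit histogram algorithms the segmentation
pipelines rely on, implemented from their published definitions:

* Otsu — exhaustive search for the cut maximising the between-class
  variance ``w0*w1*(mu0 - mu1)**2`` with foreground strictly above the cut.
* Intermodes (Prewitt & Mendelsohn) — repeatedly smooth the histogram with
  a centred 3-bin running mean until exactly two local maxima remain;
  the threshold is the floor of the midpoint of the two peak bins.
* Percentile (Doyle) — the cut placing a target fraction of pixels at or
  below threshold, i.e. minimising ``|F(t) - p|`` over the cumulative
  fraction F.

All three operate on a 256-bin histogram of the image linearly rescaled to
[0, 255] (their original 8-bit GUI context).  The foreground convention is
strictly-greater-than everywhere.  Ties break to the smallest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, Image2D

__all__ = [
    "IntensityHistogram",
    "ThresholdResult",
    "quantize_image",
    "otsu_threshold",
    "intermode_threshold",
    "percentile_threshold",
    "apply_threshold",
    "threshold_mask",
]

N_BINS_DEFAULT = 256


@dataclass(frozen=True)
class IntensityHistogram:
    """Binned intensity distribution (non-negative counts, monotone edges)."""

    counts: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        edges = np.asarray(self.bin_edges, dtype=float)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "bin_edges", edges)
        if counts.ndim != 1 or edges.ndim != 1 or len(edges) != len(counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("histogram is empty")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @classmethod
    def from_counts(cls, counts) -> "IntensityHistogram":
        counts = np.asarray(counts)
        return cls(counts, np.arange(len(counts) + 1, dtype=float))


@dataclass(frozen=True)
class ThresholdResult:
    """Threshold in intensity units plus the bin index it came from."""

    threshold: float
    bin_index: int
    method: str
    converged: bool = True
    iterations: int = 0


def quantize_image(
    image: Image2D,
    mask: np.ndarray | None = None,
    n_bins: int = N_BINS_DEFAULT,
) -> tuple[np.ndarray, IntensityHistogram]:
    """Linearly rescale to [0, n_bins-1] integers and histogram the pixels.

    Scaling uses the maximum over ``mask`` (or the whole image), so results
    are invariant to multiplying the image by any positive constant.  Returns
    the quantised integer image (full frame) and the histogram of the masked
    pixels.
    """
    data = image.data
    sel = data[mask] if mask is not None else data.ravel()
    if sel.size == 0:
        raise ValueError("empty mask")
    vmax = float(sel.max())
    if vmax <= 0:
        q = np.zeros(data.shape, dtype=np.int64)
    else:
        q = np.clip((data / vmax * n_bins).astype(np.int64), 0, n_bins - 1)
    counts = np.bincount(
        (q[mask] if mask is not None else q.ravel()), minlength=n_bins
    )[:n_bins]
    return q, IntensityHistogram.from_counts(counts)


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

def otsu_threshold(hist: IntensityHistogram) -> ThresholdResult:
    """Cut maximising between-class variance; foreground strictly above."""
    counts = hist.counts.astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise ValueError("Otsu needs at least two non-empty bins")
    total = counts.sum()
    centers = np.arange(hist.n_bins, dtype=np.float64)
    w0 = np.cumsum(counts)
    m0 = np.cumsum(counts * centers)
    mean_all = m0[-1]
    # candidate cuts t = 0 .. n-2; background = bins <= t, foreground above
    w0c = w0[:-1]
    w1c = total - w0c
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0[:-1] / w0c
        mu1 = (mean_all - m0[:-1]) / w1c
        sigma_b = w0c * w1c * (mu0 - mu1) ** 2
    sigma_b[(w0c == 0) | (w1c == 0)] = -np.inf
    t = int(np.argmax(sigma_b))  # argmax returns the smallest maximiser
    return ThresholdResult(float(hist.bin_edges[t]), t, "otsu")


# ---------------------------------------------------------------------------
# Intermodes
# ---------------------------------------------------------------------------

def _peak_bins(h: np.ndarray) -> np.ndarray:
    """Local maxima with plateaus collapsed to their leftmost bin.

    After collapsing runs of equal values, a bin is a peak when it is
    strictly greater than both distinct neighbours; the histogram ends
    count as open boundaries (a fall from bin 0 makes bin 0 a peak).
    """
    idx = np.concatenate(([0], np.nonzero(np.diff(h) != 0)[0] + 1))
    v = h[idx]
    peaks = []
    for j in range(len(v)):
        lrise = j == 0 or v[j - 1] < v[j]
        rfall = j == len(v) - 1 or v[j + 1] < v[j]
        if lrise and rfall:
            peaks.append(idx[j])
    return np.asarray(peaks, dtype=int)


def _smooth3(h: np.ndarray) -> np.ndarray:
    """Centred 3-bin running mean, edge values replicated at the ends."""
    padded = np.pad(h, 1, mode="edge")
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def intermode_threshold(
    hist: IntensityHistogram, max_iter: int = 10000
) -> ThresholdResult:
    """Iterative smoothing to bimodality; threshold = floor of peak midpoint.

    If the histogram collapses to a single peak before ever being bimodal,
    or ``max_iter`` is reached, the result falls back to Otsu with
    ``converged=False``.
    """
    if np.count_nonzero(hist.counts) < 2:
        raise ValueError("Intermodes needs at least two non-empty bins")
    h = hist.counts.astype(np.float64)
    iterations = 0
    while iterations <= max_iter:
        peaks = _peak_bins(h)
        if len(peaks) == 2:
            t = int(np.floor((peaks[0] + peaks[1]) / 2.0))
            return ThresholdResult(
                float(hist.bin_edges[t]), t, "intermodes", True, iterations
            )
        if len(peaks) < 2:
            break
        h = _smooth3(h)
        iterations += 1
    fallback = otsu_threshold(hist)
    return ThresholdResult(
        fallback.threshold, fallback.bin_index, "intermodes", False, iterations
    )


# ---------------------------------------------------------------------------
# Percentile
# ---------------------------------------------------------------------------

def percentile_threshold(hist: IntensityHistogram, p: float = 0.5) -> ThresholdResult:
    """Cut minimising |F(t) - p|, F = cumulative fraction of pixels <= t."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    frac = np.cumsum(hist.counts) / hist.counts.sum()
    t = int(np.argmin(np.abs(frac - p)))  # smallest on ties
    return ThresholdResult(float(hist.bin_edges[t]), t, "percentile")


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def apply_threshold(image: Image2D, t: float) -> BinaryMask:
    """Foreground mask: pixels strictly greater than ``t``."""
    return BinaryMask(image.data > t, image.calibration)


def threshold_mask(
    q: np.ndarray,
    result: ThresholdResult,
    within: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of quantised pixels above a threshold result's bin."""
    fg = q > result.bin_index
    if within is not None:
        fg &= within
    return fg
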