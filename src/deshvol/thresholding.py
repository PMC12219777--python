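"""Subject-specific global CSF threshold from the intensity histogram.

On a T1-weighted image CSF is dark and gray matter bright, so the intensity
histogram of the voxels inside the combined search volumes (Sylvian
fissures, high convexities and lateral ventricle) is bimodal. The global
threshold is the signal intensity midway between the CSF mode and the gray
matter mode; everything strictly below it is classified as CSF.

Peak identification works on a moving-average smoothed histogram and ranks
local maxima by topographic prominence (peak height minus the highest
separating minimum), which ignores counting-noise wiggles while keeping the
two tissue modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal import peak_prominences

from .imaging_io import BinaryMask, ImageVolume

__all__ = [
    "IntensityHistogram",
    "ThresholdResult",
    "build_histogram",
    "find_peaks",
    "compute_threshold",
    "DEFAULT_N_BINS",
    "DEFAULT_WINDOW_BINS",
]

# Defaults chosen to resolve the CSF and GM modes at a typical T1 dynamic
# range; both are configurable and echoed into the result JSON.
DEFAULT_N_BINS = 256
DEFAULT_WINDOW_BINS = 5


@dataclass
class IntensityHistogram:
    """Histogram of masked intensities plus its moving-average smoothing."""

    bin_edges: np.ndarray  # length n_bins + 1, intensity units
    counts: np.ndarray  # voxel counts, length n_bins
    smoothed: np.ndarray  # moving-average filtered counts, same length
    window_bins: int  # odd, >= 1

    def __post_init__(self):
        if self.window_bins < 1 or self.window_bins % 2 == 0:
            raise ValueError("smoothing window must be an odd integer >= 1")
        if len(self.smoothed) != len(self.counts):
            raise ValueError("smoothed histogram length mismatch")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_voxels(self) -> int:
        return int(self.counts.sum())


@dataclass
class ThresholdResult:
    """CSF/GM peak intensities and the midway global threshold."""

    csf_peak: float
    gm_peak: float
    threshold: float
    histogram: IntensityHistogram
    n_bins: int
    window_bins: int

    def __post_init__(self):
        if not (self.csf_peak < self.threshold < self.gm_peak):
            raise ValueError(
                f"threshold {self.threshold} not strictly between peaks "
                f"({self.csf_peak}, {self.gm_peak})"
            )

    def to_dict(self) -> dict:
        return {
            "csf_peak": float(self.csf_peak),
            "gm_peak": float(self.gm_peak),
            "threshold": float(self.threshold),
            "n_bins": int(self.n_bins),
            "window_bins": int(self.window_bins),
        }


def _moving_average(counts: np.ndarray, window_bins: int) -> np.ndarray:
    if window_bins == 1:
        return counts.astype(float)
    kernel = np.ones(window_bins) / window_bins
    # 'same' with implicit zero padding: fine for interior tissue modes,
    # and edge modes remain local maxima after padding in _two_main_peaks.
    return np.convolve(counts.astype(float), kernel, mode="same")


def build_histogram(
    image: ImageVolume,
    union_mask: BinaryMask,
    n_bins: int = DEFAULT_N_BINS,
    window_bins: int = DEFAULT_WINDOW_BINS,
) -> IntensityHistogram:
    """Equal-width histogram of the intensities inside ``union_mask``.

    Bins span [min, max] of the masked intensities; counts are exact voxel
    tallies (they sum to the mask's voxel count).
    """
    if n_bins < 8:
        raise ValueError("need at least 8 histogram bins")
    union_mask.check_compatible(
        BinaryMask(np.zeros(image.shape, dtype=bool), image.spacing)
    )
    values = np.asarray(image.data)[union_mask.data]
    if values.size == 0:
        raise ValueError("empty union mask — nothing to histogram")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("constant intensity inside mask — histogram degenerate")
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    smoothed = _moving_average(counts, window_bins)
    return IntensityHistogram(edges, counts, smoothed, window_bins)


def _two_main_peaks(smoothed: np.ndarray) -> tuple[int, int]:
    """Indices of the two most prominent local maxima of ``smoothed``.

    The array is padded with a value below its minimum so that modes sitting
    on the first/last bin still register as peaks. Prominence ties are broken
    toward the more extreme intensity (distance from the histogram middle).
    """
    pad_value = smoothed.min() - 1.0
    padded = np.concatenate(([pad_value], smoothed, [pad_value]))
    idx, _ = _scipy_find_peaks(padded)
    if len(idx) < 2:
        raise ValueError(
            "unimodal histogram — cannot separate CSF from GM"
        )
    prom = peak_prominences(padded, idx)[0]
    mid = (len(smoothed) - 1) / 2.0
    extremity = np.abs((idx - 1) - mid)
    order = sorted(
        range(len(idx)), key=lambda i: (prom[i], extremity[i]), reverse=True
    )
    first, second = idx[order[0]] - 1, idx[order[1]] - 1
    return (first, second) if first < second else (second, first)


def find_peaks(hist: IntensityHistogram) -> tuple[float, float]:
    """CSF and GM mode intensities from the smoothed histogram.

    Returns bin-center intensities of the two most prominent local maxima;
    the lower one is the CSF peak, the higher the GM peak.
    """
    lo_idx, hi_idx = _two_main_peaks(hist.smoothed)
    centers = hist.bin_centers
    return float(centers[lo_idx]), float(centers[hi_idx])


def compute_threshold(
    image: ImageVolume,
    union_mask: BinaryMask,
    n_bins: int = DEFAULT_N_BINS,
    window_bins: int = DEFAULT_WINDOW_BINS,
) -> ThresholdResult:
    """Global CSF threshold: arithmetic mean of the CSF and GM peak intensities.

    Downstream segmentation classifies a voxel as CSF iff its intensity is
    strictly below this threshold.
    """
    hist = build_histogram(image, union_mask, n_bins=n_bins, window_bins=window_bins)
    csf_peak, gm_peak = find_peaks(hist)
    threshold = 0.5 * (csf_peak + gm_peak)
    return ThresholdResult(csf_peak, gm_peak, threshold, hist, n_bins, window_bins)
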