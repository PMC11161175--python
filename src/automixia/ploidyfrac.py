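"""Mixoploidy quantification from cell counts and DNA-content histograms.

Two estimators of the haploid-cell burden in a blood sample: direct class
counts from stained smears (diploid / smaller haploid / binucleated), and
peak detection on flow-cytometry DNA-content intensities, where a haploid
subpopulation appears as an extra peak at half the diploid (2n) position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d


@dataclass(frozen=True)
class CellSample:
    """Erythrocyte class counts, optionally with raw DNA-content intensities."""

    n_diploid: int
    n_haploid: int
    n_binucleated: int
    dna_content_events: np.ndarray | None = None

    def __post_init__(self):
        if min(self.n_diploid, self.n_haploid, self.n_binucleated) < 0:
            raise ValueError("cell counts must be >= 0")
        if self.dna_content_events is not None and np.any(
            np.asarray(self.dna_content_events) <= 0
        ):
            raise ValueError("DNA-content intensities must be > 0")

    @property
    def n_total(self) -> int:
        return self.n_diploid + self.n_haploid + self.n_binucleated


@dataclass(frozen=True)
class PloidyFractions:
    percent_diploid: float
    percent_haploid: float
    percent_binucleated: float
    n_total: int

    def __post_init__(self):
        total = self.percent_diploid + self.percent_haploid + self.percent_binucleated
        if abs(total - 100.0) > 1e-9:
            raise ValueError("class percentages must sum to 100")


@dataclass(frozen=True)
class DnaContentPeaks:
    """Detected DNA-content peaks and the haploid-subpopulation call."""

    positions: np.ndarray
    proportions: np.ndarray
    reference_2n: float
    haploid_call: bool
    haploid_peak: float | None
    haploid_proportion: float | None


def count_fractions(sample: CellSample) -> PloidyFractions:
    """Convert erythrocyte class counts to percentages of the scored cells."""
    total = sample.n_total
    if total == 0:
        raise ValueError("cannot compute fractions of an empty cell sample")
    return PloidyFractions(
        percent_diploid=100.0 * sample.n_diploid / total,
        percent_haploid=100.0 * sample.n_haploid / total,
        percent_binucleated=100.0 * sample.n_binucleated / total,
        n_total=total,
    )


def detect_ploidy_peaks(
    events: np.ndarray,
    reference_2n: float,
    min_fraction: float = 0.01,
    *,
    haploid_window: float = 0.15,
    min_separation_frac: float = 0.2,
    smooth_bins: int = 5,
) -> DnaContentPeaks:
    """Find DNA-content peaks and test for a haploid subpopulation.

    Events are histogrammed with Freedman-Diaconis bins; local maxima of the
    lightly smoothed histogram become candidate peaks, peaks closer than
    ``min_separation_frac * reference_2n`` are merged into the taller one,
    events are assigned to the nearest surviving peak, and peaks holding
    fewer than ``min_fraction`` of events are dropped. The haploid call is
    positive when a peak sits within ``haploid_window`` (relative) of half
    the 2n reference.
    """
    events = np.asarray(events, dtype=float)
    if len(events) < 1000:
        raise ValueError("need at least 1000 events for peak detection")
    if reference_2n <= 0:
        raise ValueError("reference_2n must be > 0")

    counts, edges = np.histogram(events, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]
    w = max(1, int(smooth_bins) | 1)  # odd window
    kernel = np.ones(w) / w
    smooth = np.convolve(counts, kernel, mode="same")

    # non-maximum suppression: a peak must dominate its neighbourhood of
    # width min_separation, which kills shoulder artifacts of a single mode
    min_sep = min_separation_frac * reference_2n
    w_sup = max(3, int(round(min_sep / bin_width)) | 1)
    local_max = (smooth == maximum_filter1d(smooth, size=w_sup)) & (smooth > 0)
    peak_idx = np.nonzero(local_max)[0]
    if len(peak_idx) == 0:
        peak_idx = np.array([int(np.argmax(smooth))])
    # greedy separation check, tallest first (plateaus yield adjacent indices)
    order = peak_idx[np.argsort(smooth[peak_idx])[::-1]]
    kept: list[float] = []
    for i in order:
        if all(abs(centers[i] - p) >= min_sep for p in kept):
            kept.append(float(centers[i]))
    positions = np.array(sorted(kept))

    # assign events to nearest peak; drop minor peaks and re-assign
    while True:
        assign = np.argmin(np.abs(events[:, None] - positions[None, :]), axis=1)
        props = np.bincount(assign, minlength=len(positions)) / len(events)
        weak = props < min_fraction
        if not weak.any() or len(positions) == 1:
            break
        positions = positions[~weak]
    # refine positions as the median of assigned events
    positions = np.array(
        [float(np.median(events[assign == j])) for j in range(len(positions))]
    )

    half = 0.5 * reference_2n
    rel = np.abs(positions - half) / half
    hap_candidates = np.where(rel <= haploid_window)[0]
    if len(hap_candidates):
        j = hap_candidates[np.argmin(rel[hap_candidates])]
        haploid_call = True
        haploid_peak = float(positions[j])
        haploid_proportion = float(props[j])
    else:
        haploid_call = False
        haploid_peak = None
        haploid_proportion = None
    return DnaContentPeaks(
        positions=positions,
        proportions=props,
        reference_2n=float(reference_2n),
        haploid_call=haploid_call,
        haploid_peak=haploid_peak,
        haploid_proportion=haploid_proportion,
    )
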