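"""Genome-size estimation from propidium-iodide flow-cytometry events.

The estimator follows standard internal-reference practice: a run contains
nuclei of both the sample and a reference species of known DNA content, the
fluorescence histogram shows one G1 peak per species, and the sample's 1C
value (pg) is the reference 1C multiplied by the ratio of peak means.  A
run passes quality control only when both peaks' coefficients of variation
(100*sd/mean) fall below a threshold, 10% by default.

Peak detection: build a histogram (512 bins by default), smooth it with a
short moving average, take the requested number of highest well-separated
local maxima, seed each peak's spread from its full width at half maximum,
then re-estimate mean and sd from the raw events within +-2.5 sd of the
peak position.  Which peak is the reference is an explicit caller
declaration — reference species may sit either below or above the sample
peak, so positional guessing would be ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import DetectionError, UsageError

_FWHM_TO_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class FlowPeak:
    """One fluorescence peak: mean and sd in channel units, CV in percent."""

    mean: float
    sd: float
    cv: float
    n_events: int

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise UsageError("peak mean must be positive")


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """Internal-reference genome-size result for one run."""

    sample_1C: float
    reference_name: str
    reference_1C: float
    ratio: float
    qc_pass: bool
    sample_cv: float
    reference_cv: float


def read_events(path: str | Path) -> np.ndarray:
    """Read a one-column text/CSV event list (optional header line)."""
    try:
        return np.loadtxt(path, dtype=float)
    except ValueError:
        return np.loadtxt(path, dtype=float, skiprows=1)


def _initial_sd(hist: np.ndarray, centers: np.ndarray, peak_idx: int) -> float:
    """Seed sd from the full width at half maximum around a histogram peak."""
    half = hist[peak_idx] / 2.0
    left = peak_idx
    while left > 0 and hist[left] > half:
        left -= 1
    right = peak_idx
    while right < len(hist) - 1 and hist[right] > half:
        right += 1
    width = centers[right] - centers[left]
    bin_width = centers[1] - centers[0] if len(centers) > 1 else 1.0
    return max(width, bin_width) / _FWHM_TO_SD


def detect_peaks(
    events: Sequence[float] | np.ndarray,
    n_peaks: int = 2,
    bins: int = 512,
    smooth_window: int = 5,
    min_separation: int = 10,
) -> list[FlowPeak]:
    """Find the ``n_peaks`` dominant fluorescence peaks in an event list.

    Peaks are returned sorted by mean ascending.  Raises DetectionError if
    fewer than ``n_peaks`` well-separated local maxima exist.
    """
    events = np.asarray(events, dtype=float)
    if events.size < 1000:
        raise UsageError(f"need >=1000 events, got {events.size}")
    if n_peaks not in (1, 2):
        raise UsageError("n_peaks must be 1 or 2")

    hist, edges = np.histogram(events, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(hist, kernel, mode="same")
    else:
        smoothed = hist.astype(float)

    # pad so maxima in the first/last bin (degenerate spikes) are found
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    maxima, _ = find_peaks(padded, distance=min_separation)
    maxima = maxima - 1
    if len(maxima) < n_peaks:
        raise DetectionError(
            f"found {len(maxima)} local maxima, need {n_peaks}"
        )
    # n_peaks highest maxima
    top = maxima[np.argsort(smoothed[maxima])[::-1][:n_peaks]]

    peaks: list[FlowPeak] = []
    for idx in sorted(top):
        mean0 = centers[idx]
        sd0 = _initial_sd(smoothed, centers, idx)
        mean, sd = mean0, sd0
        for _ in range(2):  # refine on raw events
            window = events[np.abs(events - mean) <= 2.5 * max(sd, 1e-12)]
            if window.size == 0:
                break
            mean = float(window.mean())
            sd = float(window.std(ddof=0))
        n = int((np.abs(events - mean) <= 2.5 * max(sd, 1e-12)).sum())
        cv = 100.0 * sd / mean if mean > 0 else math.inf
        peaks.append(FlowPeak(mean, sd, cv, n))
    return sorted(peaks, key=lambda p: p.mean)


def estimate_genome_size(
    sample_peak: FlowPeak,
    ref_peak: FlowPeak,
    reference_1C: float,
    cv_threshold: float = 10.0,
    reference_name: str = "reference",
) -> GenomeSizeEstimate:
    """Scale the reference 1C by the sample/reference peak-mean ratio.

    QC passes only when both peak CVs are strictly below ``cv_threshold``
    (percent).
    """
    if sample_peak.mean <= 0 or ref_peak.mean <= 0:
        raise UsageError("peak means must be positive")
    ratio = sample_peak.mean / ref_peak.mean
    qc = sample_peak.cv < cv_threshold and ref_peak.cv < cv_threshold
    return GenomeSizeEstimate(
        sample_1C=reference_1C * ratio,
        reference_name=reference_name,
        reference_1C=reference_1C,
        ratio=ratio,
        qc_pass=qc,
        sample_cv=sample_peak.cv,
        reference_cv=ref_peak.cv,
    )


def estimate_from_events(
    events: np.ndarray,
    reference_1C: float,
    reference_is: Literal["smaller", "larger"],
    cv_threshold: float = 10.0,
    reference_name: str = "reference",
    **peak_kwargs,
) -> GenomeSizeEstimate:
    """Detect two peaks and estimate 1C, with the reference peak declared
    explicitly as the smaller- or larger-mean of the two."""
    if reference_is not in ("smaller", "larger"):
        raise UsageError("reference_is must be 'smaller' or 'larger'")
    low, high = detect_peaks(events, n_peaks=2, **peak_kwargs)
    ref, sample = (low, high) if reference_is == "smaller" else (high, low)
    return estimate_genome_size(sample, ref, reference_1C, cv_threshold, reference_name)


def replicate_report(
    estimates: dict[str, GenomeSizeEstimate | None],
) -> pd.DataFrame:
    """Per-replicate table plus detection failures (None entries)."""
    rows = []
    for name, est in estimates.items():
        if est is None:
            rows.append((name, math.nan, math.nan, math.nan, math.nan, False, "detection failed"))
        else:
            rows.append((name, est.ratio, est.sample_1C, est.sample_cv,
                         est.reference_cv, est.qc_pass, ""))
    return pd.DataFrame(
        rows,
        columns=["replicate", "ratio", "sample_1C_pg", "sample_cv_pct",
                 "reference_cv_pct", "qc_pass", "note"],
    )


def aggregate_1c(estimates: Sequence[GenomeSizeEstimate]) -> float:
    """Mean 1C over replicate estimates (detection failures excluded)."""
    values = [e.sample_1C for e in estimates]
    if not values:
        raise UsageError("no successful estimates to aggregate")
    return float(np.mean(values))
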