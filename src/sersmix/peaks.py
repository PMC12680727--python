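"""Band-maximum detection and peak matching.

Noise is estimated with the scaled median absolute deviation (MAD) of
the detrended signal; band maxima are found as local maxima of a
smoothed signal whose height exceeds ``snr_threshold`` times the noise,
with the reported position refined to the raw-grid argmax near the
smoothed maximum (so the smoother cannot bias positions, which matters
when measuring few-cm^-1 isotopologue shifts).

Two smoothers are provided, both exactly preserving straight lines:

``fixed``
    local linear regression in a centered window of ``span`` grid
    points (truncated at the edges);
``supersmoother``
    adaptive-span local linear regression: candidate spans are compared
    point-by-point through smoothed leave-one-out absolute residuals
    and the locally best span wins.  Candidate spans are expressed in
    grid points (default 5/11/23) rather than fractions of the record
    length, which would be far wider than a SERS band on a
    1401-point axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal
from scipy.signal import argrelmax

from .core_io import Spectrum

__all__ = [
    "PeakList",
    "PeakMatch",
    "estimate_noise_mad",
    "smooth",
    "detect_peaks",
    "match_peaks",
]

MAD_SCALE = 1.4826  # makes the MAD consistent for Gaussian noise

_SMOOTH_METHODS = ("supersmoother", "fixed")
DEFAULT_SPANS = (5, 11, 23)


def _local_linear(y: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Running local-linear fit with uniform weights.

    Returns ``(smoothed, loo_abs_resid)`` where the second array holds
    leave-one-out absolute residuals.  Windows are truncated at the
    edges; a truncated local-linear fit still reproduces straight lines
    exactly.
    """
    n = y.size
    x = np.arange(n, dtype=float)
    # prefix sums for O(n) windowed moments
    def windowed_sum(v: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(v)])
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half, n - 1)
        return c[hi + 1] - c[lo]

    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    m = (hi - lo + 1).astype(float)
    sx = windowed_sum(x)
    sy = windowed_sum(y)
    sxx = windowed_sum(x * x)
    sxy = windowed_sum(x * y)
    xbar = sx / m
    ybar = sy / m
    ssx = sxx - sx * xbar
    ssxy = sxy - sx * ybar
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(ssx > 0, ssxy / np.where(ssx > 0, ssx, 1.0), 0.0)
    smoothed = ybar + slope * (x - xbar)
    # leverage of the centre point of each window
    with np.errstate(invalid="ignore", divide="ignore"):
        lever = 1.0 / m + np.where(ssx > 0, (x - xbar) ** 2 / np.where(ssx > 0, ssx, 1.0), 0.0)
    resid = y - smoothed
    denom = np.clip(1.0 - lever, 1e-10, None)
    return smoothed, np.abs(resid / denom)


def smooth(
    spectrum: Spectrum,
    method: str = "supersmoother",
    span: int | None = None,
    spans: tuple[int, ...] = DEFAULT_SPANS,
) -> Spectrum:
    """Smooth a spectrum with a line-preserving local-linear smoother.

    ``method='fixed'`` uses a single window of ``span`` points (odd,
    default 11); ``method='supersmoother'`` selects the locally best of
    the candidate ``spans`` by cross-validation.
    """
    if method not in _SMOOTH_METHODS:
        raise ValueError(
            f"unknown smoothing method {method!r}; available: {list(_SMOOTH_METHODS)}"
        )
    y = spectrum.intensity
    if method == "fixed":
        w = 11 if span is None else int(span)
        if w < 3:
            raise ValueError(f"span must be >= 3 points, got {w}")
        smoothed, _ = _local_linear(y, w // 2)
        return spectrum.with_intensity(smoothed)

    spans = tuple(sorted(int(s) for s in spans))
    if any(s < 3 for s in spans) or not spans:
        raise ValueError(f"spans must all be >= 3 points, got {spans}")
    fits = []
    residuals = []
    mid_half = spans[len(spans) // 2] // 2
    for s in spans:
        f, r = _local_linear(y, s // 2)
        # compare spans through smoothed CV residuals (stabilizes choice)
        r_smooth, _ = _local_linear(r, mid_half)
        fits.append(f)
        residuals.append(r_smooth)
    choice = np.argmin(np.vstack(residuals), axis=0)
    selected = np.choose(choice, np.vstack(fits))
    # final light pass with the smallest span removes selection seams
    final, _ = _local_linear(selected, spans[0] // 2)
    return spectrum.with_intensity(final)


def estimate_noise_mad(
    intensity: np.ndarray,
    detrend_span: int = 51,
) -> float:
    """Scaled-MAD noise estimate of a signal.

    The signal is detrended by subtracting a running-median smooth
    (robust, so gross outliers do not leak into the trend), then the
    noise scale is ``1.4826 * median(|d - median(d)|)`` of the
    residual.  All-identical input returns 0.
    """
    y = np.asarray(intensity, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points for a noise estimate")
    span = min(detrend_span | 1, y.size if y.size % 2 else y.size - 1)
    trend = scipy.signal.medfilt(y, kernel_size=span)
    d = y - trend
    return MAD_SCALE * float(np.median(np.abs(d - np.median(d))))


@dataclass
class PeakList:
    """Detected band maxima: positions (cm^-1), heights, SNR."""

    positions: np.ndarray
    heights: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (self.positions.size == self.heights.size == self.snr.size):
            raise ValueError("positions, heights and snr must have equal length")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("peak positions must be strictly increasing")

    def __len__(self) -> int:
        return self.positions.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "height": self.heights, "snr": self.snr}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def nearest(self, position: float) -> int:
        if len(self) == 0:
            raise ValueError("empty peak list")
        return int(np.argmin(np.abs(self.positions - position)))


def detect_peaks(
    spectrum: Spectrum,
    snr_threshold: float = 3.0,
    method: str = "supersmoother",
    span: int | None = None,
    spans: tuple[int, ...] = DEFAULT_SPANS,
) -> PeakList:
    """Detect band maxima whose smoothed height exceeds ``snr_threshold``
    times the MAD noise.

    Candidate maxima are local maxima of the smoothed signal; each is
    refined to the raw-grid argmax within +-half the smoother span, and
    the reported height is the raw intensity at the refined position.
    May return an empty list.
    """
    y = spectrum.intensity
    smoothed = smooth(spectrum, method=method, span=span, spans=spans).intensity
    noise = estimate_noise_mad(y)
    candidates = argrelmax(smoothed, order=2)[0]
    half = (max(spans) if method == "supersmoother" else (span or 11)) // 2

    refined: list[int] = []
    for idx in candidates:
        if noise > 0 and smoothed[idx] / noise < snr_threshold:
            continue
        if noise == 0 and smoothed[idx] <= 0:
            continue
        lo = max(idx - half, 0)
        hi = min(idx + half + 1, y.size)
        refined.append(lo + int(np.argmax(y[lo:hi])))
    if not refined:
        return PeakList(np.empty(0), np.empty(0), np.empty(0))
    idxs = np.unique(refined)
    heights = y[idxs]
    snr = heights / noise if noise > 0 else np.full(idxs.size, np.inf)
    keep = snr >= snr_threshold if noise > 0 else heights > 0
    idxs, heights, snr = idxs[keep], heights[keep], snr[keep]
    return PeakList(spectrum.axis.values[idxs], heights, snr)


@dataclass
class PeakMatch:
    """Greedy nearest-neighbour assignment of peaks to reference centers."""

    pairs: pd.DataFrame  # columns: reference, position, offset
    unmatched_peaks: np.ndarray
    unmatched_references: np.ndarray

    def offset_for(self, reference: float) -> float:
        row = self.pairs[self.pairs["reference"] == reference]
        if row.empty:
            raise KeyError(f"reference {reference} unmatched")
        return float(row["offset"].iloc[0])


def match_peaks(
    peaks: PeakList, reference_centers: np.ndarray, tol: float
) -> PeakMatch:
    """Match detected peaks to reference band centers within ``tol`` cm^-1.

    Greedy: candidate (peak, reference) pairs are taken in order of
    increasing |offset|; each peak and each reference is used at most
    once.  Unmatched peaks and references are reported.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    refs = np.asarray(reference_centers, dtype=float)
    cand = [
        (abs(p - r), i, j)
        for i, p in enumerate(peaks.positions)
        for j, r in enumerate(refs)
        if abs(p - r) <= tol
    ]
    cand.sort()
    used_p: set[int] = set()
    used_r: set[int] = set()
    rows = []
    for dist, i, j in cand:
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        rows.append(
            {
                "reference": refs[j],
                "position": peaks.positions[i],
                "offset": peaks.positions[i] - refs[j],
            }
        )
    pairs = pd.DataFrame(rows, columns=["reference", "position", "offset"]).sort_values(
        "reference", ignore_index=True
    )
    unmatched_p = np.asarray(
        [p for i, p in enumerate(peaks.positions) if i not in used_p]
    )
    unmatched_r = np.asarray([r for j, r in enumerate(refs) if j not in used_r])
    return PeakMatch(pairs, unmatched_p, unmatched_r)
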