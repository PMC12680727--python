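"""Preprocessing chain for serum SERS spectra.

The chain is crop (400-1800 cm^-1) -> iterative modified-polynomial
baseline subtraction (degree 4) -> vector normalization, applied in that
order.  Modified polynomial fitting ("modpoly") estimates a slowly
varying fluorescence/background baseline by refitting a least-squares
polynomial after clamping the signal to the current fit, so positive
peaks lose their influence on the estimate.

Baseline subtraction may leave small negative values; they are retained
(no clipping) so band-height statistics stay unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import Spectrum, SpectrumSet, WavenumberAxis

logger = logging.getLogger(__name__)

__all__ = ["BaselineResult", "crop", "modpoly_baseline", "vector_normalize", "preprocess_set"]


@dataclass
class BaselineResult:
    """Outcome of an iterative baseline estimate."""

    baseline: np.ndarray
    corrected: np.ndarray
    iterations: int
    converged: bool


def crop(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Restrict a spectrum to the closed interval [lo, hi] cm^-1."""
    if not lo < hi:
        raise ValueError(f"invalid crop interval: lo={lo} >= hi={hi}")
    mask = (spectrum.axis.values >= lo) & (spectrum.axis.values <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"crop to [{lo}, {hi}] leaves {int(mask.sum())} point(s) of axis "
            f"[{spectrum.axis.lo}, {spectrum.axis.hi}]"
        )
    axis = WavenumberAxis(spectrum.axis.values[mask])
    return Spectrum(axis, spectrum.intensity[mask], dict(spectrum.meta))


def modpoly_baseline(
    spectrum: Spectrum,
    degree: int = 4,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> BaselineResult:
    """Modified-polynomial (modpoly) baseline estimation.

    Iteratively fits a least-squares polynomial of the given degree,
    clamps the working signal to the fit wherever it exceeds it, and
    refits, until the relative L2 change of the baseline drops below
    ``tol`` or ``max_iter`` is reached.  Non-convergence sets
    ``converged=False`` (logged), it is not an error.
    """
    y = spectrum.intensity
    n = y.size
    if n <= degree + 1:
        raise ValueError(f"axis length {n} must exceed degree+1 = {degree + 1}")
    # scale abscissa to [-1, 1] for numerical conditioning
    x = np.linspace(-1.0, 1.0, n)
    vander = np.polynomial.polynomial.polyvander(x, degree)
    # precompute the hat projection via QR for repeated fits
    q, _ = np.linalg.qr(vander)

    work = y.copy()
    baseline = q @ (q.T @ work)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        work = np.minimum(work, baseline)
        new_baseline = q @ (q.T @ work)
        denom = np.linalg.norm(baseline)
        change = np.linalg.norm(new_baseline - baseline) / denom if denom > 0 else 0.0
        baseline = new_baseline
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "modpoly did not converge in %d iterations (spectrum %r)",
            max_iter,
            spectrum.meta.get("sample"),
        )
    return BaselineResult(baseline, y - baseline, iterations, converged)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Divide a spectrum by its Euclidean norm sqrt(sum(x_i^2)).

    The factor used is stored in the output metadata under
    ``norm_factor`` so absolute intensities can be recovered.
    """
    norm = spectrum.norm
    if norm == 0.0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return spectrum.with_intensity(spectrum.intensity / norm, norm_factor=norm)


def preprocess_set(
    sset: SpectrumSet,
    crop_lo: float = 400.0,
    crop_hi: float = 1800.0,
    degree: int = 4,
    tol: float = 1e-3,
    max_iter: int = 100,
    normalize: bool = True,
) -> SpectrumSet:
    """Apply crop -> modpoly baseline subtraction -> vector normalization.

    Per-spectrum baseline convergence is recorded in the metadata
    (``baseline_converged``, ``baseline_iterations``); member failures
    are re-raised with the spectrum id attached.  An empty set maps to
    an empty set.
    """
    if len(sset) == 0:
        return sset
    out: list[Spectrum] = []
    for i, s in enumerate(sset):
        sid = s.meta.get("sample", i)
        try:
            c = crop(s, crop_lo, crop_hi)
            res = modpoly_baseline(c, degree=degree, tol=tol, max_iter=max_iter)
            corrected = c.with_intensity(
                res.corrected,
                baseline_converged=res.converged,
                baseline_iterations=res.iterations,
            )
            out.append(vector_normalize(corrected) if normalize else corrected)
        except ValueError as exc:
            raise ValueError(f"spectrum {sid!r}: {exc}") from exc
    return SpectrumSet(out, out[0].axis)
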