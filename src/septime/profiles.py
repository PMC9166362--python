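"""Profile-level preprocessing: background subtraction, modal background
estimation and 1-D registration of fluorescence against phase-contrast
profiles.
"""

from __future__ import annotations

import numpy as np

from .errors import AlignmentError, InsufficientDataError
from .records import DEFAULT_PIXEL_PITCH


def subtract_background(profile: np.ndarray, background: float) -> np.ndarray:
    """Subtract a scalar (modal) background from every sample.

    Negative results are preserved, not clipped: clipping would bias the
    midcell surplus upward for dim cells.
    """
    if background < 0:
        raise ValueError(f"background must be >= 0, got {background}")
    return np.asarray(profile, dtype=float) - background


def estimate_modal(values: np.ndarray, min_bin_width: float = 1.0) -> float:
    """Estimate the modal intensity of a sample of camera pixel values.

    The mode is taken as the center of the tallest histogram bin, with the
    bin width the larger of ``min_bin_width`` (one intensity unit for
    integer camera counts) and the Freedman-Diaconis width.  Ties go to the
    lowest bin, the conservative choice for a background estimate.

    Requires at least 10 samples.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 10:
        raise InsufficientDataError(
            f"modal estimation needs >= 10 samples, got {values.size}"
        )
    q75, q25 = np.percentile(values, [75, 25])
    fd_width = 2.0 * (q75 - q25) / values.size ** (1.0 / 3.0)
    width = max(min_bin_width, fd_width)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return float(lo)
    n_bins = max(1, int(np.ceil((hi - lo) / width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, lo + n_bins * width))
    best = int(np.argmax(counts))  # argmax takes the first, i.e. lowest, bin on ties
    return float(0.5 * (edges[best] + edges[best + 1]))


def _parabolic_refine(c_m: float, c_0: float, c_p: float) -> float:
    """Sub-sample offset of a correlation peak from its 3-point neighborhood."""
    denom = c_m - 2.0 * c_0 + c_p
    if denom == 0.0:
        return 0.0
    delta = 0.5 * (c_m - c_p) / denom
    return float(np.clip(delta, -0.5, 0.5))


def _shift_with_edge_padding(signal: np.ndarray, shift_samples: float) -> np.ndarray:
    """Translate ``signal`` by ``shift_samples`` (linear interpolation),
    padding beyond the ends with the end values."""
    n = len(signal)
    coords = np.arange(n, dtype=float) + shift_samples
    return np.interp(coords, np.arange(n, dtype=float), signal)


def align_profile(
    reference: np.ndarray,
    signal: np.ndarray,
    max_shift: float,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> tuple[float, np.ndarray]:
    """Register a fluorescence profile against its phase-contrast reference.

    Finds the translation of ``signal`` relative to ``reference`` that
    maximizes their cross-correlation within ``+/- max_shift`` μm, refined
    to sub-sample precision by parabolic interpolation of the correlation
    peak.  Returns ``(shift, aligned)`` where ``shift`` is in μm and
    ``aligned`` is the signal translated by ``-shift`` (edge-padded), i.e.
    brought into register with the reference.

    Raises
    ------
    AlignmentError
        If the signal (or reference) has zero variance — a flat trace
        carries no registration information.
    """
    reference = np.asarray(reference, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(reference) != len(signal):
        raise AlignmentError(
            f"profiles must share a sampling grid ({len(reference)} vs {len(signal)})"
        )
    if np.ptp(signal) == 0.0 or np.ptp(reference) == 0.0:
        raise AlignmentError("flat (zero-variance) profile cannot be aligned")

    max_lag = int(np.floor(max_shift * pixel_pitch))
    ref0 = reference - reference.mean()
    sig0 = signal - signal.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    for j, k in enumerate(lags):
        # c(k) = sum_i ref[i] * sig[i + k], sig edge-padded
        shifted = _shift_with_edge_padding(sig0, float(k))
        corr[j] = float(ref0 @ shifted)
    best = int(np.argmax(corr))
    k_best = float(lags[best])
    if 0 < best < lags.size - 1:
        k_best += _parabolic_refine(corr[best - 1], corr[best], corr[best + 1])
    shift_um = k_best / pixel_pitch
    aligned = _shift_with_edge_padding(signal, k_best)
    return shift_um, aligned
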