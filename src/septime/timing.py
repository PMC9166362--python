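"""Divisome arrival timing from binned FCPlus curves.

Two timepoints characterize when a protein arrives at midcell during the
division cycle:

* ``t0`` — the age at which the binned midcell surplus first turns (and
  stays) positive: more fluorescence at midcell than in the rest of the
  cell.
* ``t_half`` — the age at which the curve first reaches half of its
  maximum.  The half-maximum is used instead of the maximum because the
  curve usually plateaus before declining at the end of the cycle, making
  the maximum itself poorly localized in age.

Replicate-level timing estimates for two strains are compared with a
two-sided unpaired Welch t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, NoOnsetError
from .stats import BinnedCurve

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimingResult:
    """Arrival timing of one protein in one replicate."""

    protein: str
    strain: str
    replicate_id: str
    t0: float
    t_half: float
    fc_max: float
    n_cells: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.t0 <= self.t_half <= 1.0:
            raise ValueError(
                f"need 0 <= t0 <= t_half <= 1, got t0={self.t0}, t_half={self.t_half}"
            )


@dataclass(frozen=True)
class StrainComparison:
    """Welch-t comparison of a timing statistic between two strains."""

    protein: str
    statistic_name: str
    mean_difference: float  # parental - mutant, in cycle-age fraction
    p_value: float
    n_parental: int
    n_mutant: int

    @property
    def mean_difference_percent(self) -> float:
        """Difference expressed as percent of the division cycle."""
        return 100.0 * self.mean_difference

    @property
    def stars(self) -> str:
        """Significance label: *** for P <= 0.0001, ** for P <= 0.001,
        * for P <= 0.05, ns otherwise."""
        if self.p_value <= 0.0001:
            return "***"
        if self.p_value <= 0.001:
            return "**"
        if self.p_value <= 0.05:
            return "*"
        return "ns"


def _occupied(curve: BinnedCurve) -> tuple[np.ndarray, np.ndarray]:
    """Centers and means of occupied bins; warn when interpolating across
    missing bins."""
    occ = curve.occupied
    if occ.sum() < curve.counts.size and not occ.all():
        gaps = np.flatnonzero(~occ)
        interior = gaps[(gaps > np.argmax(occ)) & (gaps < len(occ) - np.argmax(occ[::-1]) - 1)]
        if interior.size:
            logger.warning(
                "curve has %d empty interior bins; timing interpolates across them",
                interior.size,
            )
    return curve.bin_centers[occ], curve.means[occ]


def estimate_t0(curve: BinnedCurve, persistence: int = 2) -> float:
    """Onset age: where the binned midcell surplus turns durably positive.

    Scans the occupied bins for the first bin whose mean is positive and is
    followed by at least ``persistence - 1`` further positive bins (the
    persistence rule suppresses single-bin noise).  The crossing age is
    linearly interpolated between the last non-positive and the first
    positive bin center; a curve that starts positive yields 0.

    Raises
    ------
    NoOnsetError
        If the curve never turns durably positive — the protein shows no
        midcell localization.
    """
    centers, means = _occupied(curve)
    if centers.size < 4:
        raise InsufficientDataError(
            f"t0 estimation needs >= 4 occupied bins, got {centers.size}"
        )
    positive = means > 0.0
    run = 0
    first = None
    for i in range(positive.size - 1, -1, -1):
        run = run + 1 if positive[i] else 0
        if run >= persistence:
            first = i
    if first is None:
        raise NoOnsetError("midcell surplus never durably positive; no onset")
    if first == 0:
        return 0.0
    c0, m0 = centers[first - 1], means[first - 1]
    c1, m1 = centers[first], means[first]
    # linear interpolation of the zero crossing between bin centers
    return float(c0 + (0.0 - m0) / (m1 - m0) * (c1 - c0))


def estimate_thalf(
    curve: BinnedCurve, t0: float | None = None, persistence: int = 2
) -> tuple[float, float]:
    """Half-maximum age and curve maximum.

    ``fc_max`` is the maximum of the binned means (no smoothing); scanning
    upward in age from ``t0``, ``t_half`` is the first age at which the
    curve reaches ``fc_max / 2``, linearly interpolated between the
    bracketing bin centers.  A curve whose maximum sits in the very first
    occupied bin is flagged with a warning but still yields a result.
    """
    if t0 is None:
        t0 = estimate_t0(curve, persistence=persistence)
    centers, means = _occupied(curve)
    i_max = int(np.argmax(means))
    fc_max = float(means[i_max])
    if i_max == 0:
        warnings.warn(
            "curve maximum at the first occupied bin; t_half is ill-constrained",
            stacklevel=2,
        )
    target = fc_max / 2.0
    for i in range(centers.size):
        if centers[i] < t0 and means[i] < target:
            continue
        if means[i] >= target:
            if i == 0 or means[i - 1] >= target:
                return float(min(max(centers[i], t0), 1.0)), fc_max
            c0, m0 = centers[i - 1], means[i - 1]
            c1, m1 = centers[i], means[i]
            t_half = c0 + (target - m0) / (m1 - m0) * (c1 - c0)
            return float(min(max(t_half, t0), 1.0)), fc_max
    # curve reaches fc_max somewhere, so this is unreachable for finite data
    return float(centers[i_max]), fc_max


def timing_from_curve(
    curve: BinnedCurve,
    protein: str = "",
    strain: str = "",
    replicate_id: str = "",
    persistence: int = 2,
) -> TimingResult:
    """Convenience: t0 + t_half + fc_max for one replicate curve."""
    t0 = estimate_t0(curve, persistence=persistence)
    t_half, fc_max = estimate_thalf(curve, t0=t0, persistence=persistence)
    return TimingResult(
        protein=protein,
        strain=strain,
        replicate_id=replicate_id,
        t0=t0,
        t_half=t_half,
        fc_max=fc_max,
        n_cells=curve.n_cells(),
    )


def compare_strains(
    parental: list[TimingResult],
    mutant: list[TimingResult],
    statistic: str = "t0",
) -> StrainComparison:
    """Compare a timing statistic between strains across replicates.

    Uses the two-sided unpaired Welch (unequal-variance) t-test — replicate
    counts routinely differ between strains.  The reported difference is
    mean(parental) - mean(mutant): positive means the mutant localizes
    earlier.
    """
    if statistic not in ("t0", "t_half"):
        raise ValueError(f"statistic must be 't0' or 't_half', got {statistic!r}")
    if len(parental) < 2 or len(mutant) < 2:
        raise InsufficientDataError(
            f"need >= 2 replicates per strain, got {len(parental)} and {len(mutant)}"
        )
    a = np.array([getattr(r, statistic) for r in parental])
    b = np.array([getattr(r, statistic) for r in mutant])
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        p = 1.0  # identical constant samples: no evidence of difference
    else:
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    proteins = {r.protein for r in parental + mutant}
    return StrainComparison(
        protein=proteins.pop() if len(proteins) == 1 else "/".join(sorted(proteins)),
        statistic_name=statistic,
        mean_difference=float(a.mean() - b.mean()),
        p_value=p,
        n_parental=len(a),
        n_mutant=len(b),
    )
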