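"""Cell-cycle localization statistics.

This is the quantitative heart of the package: converting a length-sorted
steady-state population into division-cycle ages, computing the midcell
fluorescence surplus (FCPlus) per cell, binning values into 5% age classes
with confidence intervals, normalizing and averaging replicate curves, and
calibrating fluorescence into molecule numbers.

FCPlus is defined on the central 0.8 μm of the cell axis: the fluorophore
concentration there minus the concentration in the rest of the cell, times
the midcell volume — i.e. the fluorescence at midcell in excess of what a
spatially uniform distribution would place there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateCurveError,
    GeometryError,
    InsufficientDataError,
    ShortCellError,
)
from .records import DEFAULT_PIXEL_PITCH, CellRecord

logger = logging.getLogger(__name__)

#: Axial extent of the midcell window, μm.
DEFAULT_MIDCELL_WIDTH = 0.8
#: Age-class width for binned curves (5% classes).
DEFAULT_BIN_WIDTH = 0.05
#: Confidence level for binned-curve error bars.
DEFAULT_CI_LEVEL = 0.95
#: Ribosome-profiling calibration: average PBP4 molecules per cell.
DEFAULT_MOLECULES_PER_CELL = 133.0


@dataclass(frozen=True)
class AgeAssignment:
    """Length rank and inferred division-cycle age of one cell."""

    cell_id: str
    rank: int
    age: float


@dataclass(frozen=True)
class FCPlusResult:
    """Per-cell midcell fluorescence surplus and its ingredients."""

    cell_id: str
    F_mid: float
    F_rest: float
    V_mid: float
    V_rest: float
    C_mid: float
    C_rest: float
    fcplus: float

    @property
    def total_F(self) -> float:
        return self.F_mid + self.F_rest


@dataclass
class BinnedCurve:
    """Per-age-bin means with confidence intervals.

    Bins partition [0, 1] into classes of ``bin_width``; the last bin is
    closed so age exactly 1 (the longest cell) is counted.  Empty bins hold
    NaN means, never zero.
    """

    bin_centers: np.ndarray
    means: np.ndarray
    ci_halfwidths: np.ndarray
    counts: np.ndarray
    value_kind: str = "fcplus"

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.ci_halfwidths = np.asarray(self.ci_halfwidths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def n_cells(self) -> int:
        return int(self.counts.sum())


def assign_ages(
    lengths: np.ndarray, cell_ids: list[str] | None = None
) -> list[AgeAssignment]:
    """Assign division-cycle ages from length rank in a steady-state sample.

    Lengths are ranked ascending (stable sort, so tied cells keep their
    input order and distinct integer ranks) and mapped through

        age = ln(1 - 0.5 * rank / (nCells - 1)) / ln(0.5)

    which inverts the steady-state age CDF: the shortest cell gets age 0,
    the longest exactly age 1.  Output order matches input order.
    """
    lengths = np.asarray(lengths, dtype=float)
    n = lengths.size
    if n < 2:
        raise InsufficientDataError(f"age assignment needs >= 2 cells, got {n}")
    if np.any(lengths <= 0):
        raise GeometryError("all lengths must be positive")
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n)]
    order = np.argsort(lengths, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    ages = np.log(1.0 - 0.5 * ranks / (n - 1)) / math.log(0.5)
    return [
        AgeAssignment(cell_id=cell_ids[i], rank=int(ranks[i]), age=float(ages[i]))
        for i in range(n)
    ]


def cell_volume(length: float, diameter: float, geometry: str = "spherocylinder") -> float:
    """Cell volume in μm³.

    Default is the sphero-cylinder (cylinder with hemispherical caps):
    ``π r² (L - 2r) + (4/3) π r³``; ``geometry="cylinder"`` gives the plain
    cylinder ``π r² L`` for comparison.
    """
    if diameter <= 0 or length < diameter:
        raise GeometryError(
            f"need length >= diameter > 0, got L={length}, d={diameter}"
        )
    r = diameter / 2.0
    if geometry == "cylinder":
        return math.pi * r * r * length
    if geometry != "spherocylinder":
        raise ValueError(f"unknown geometry {geometry!r}")
    return math.pi * r * r * (length - 2.0 * r) + (4.0 / 3.0) * math.pi * r**3


def cell_surface_area(length: float, diameter: float) -> float:
    """Sphero-cylinder envelope area in μm²: ``π d (L - d) + π d²``."""
    if diameter <= 0 or length < diameter:
        raise GeometryError(
            f"need length >= diameter > 0, got L={length}, d={diameter}"
        )
    return math.pi * diameter * (length - diameter) + math.pi * diameter**2


def _window_weights(n_px: int, center: float, half_width_px: float) -> np.ndarray:
    """Per-pixel overlap of pixels ``[i-0.5, i+0.5]`` with the window
    ``[center - hw, center + hw]`` (linear fractional-edge weighting)."""
    i = np.arange(n_px, dtype=float)
    lo = np.maximum(i - 0.5, center - half_width_px)
    hi = np.minimum(i + 0.5, center + half_width_px)
    return np.clip(hi - lo, 0.0, 1.0)


def fcplus(
    cell: CellRecord,
    midcell_width: float = DEFAULT_MIDCELL_WIDTH,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> FCPlusResult:
    """Midcell fluorescence surplus of one cell.

    The midcell window is the central ``midcell_width`` of the axis,
    treated as a pure cylinder slab — the cell must therefore be longer
    than ``midcell_width + diameter`` so the hemispherical caps stay out of
    the window.  ``F_mid`` integrates the profile over the window with
    linear weighting of the fractional edge pixels (the window is not an
    integer number of pixels); concentrations are fluorescence per μm³ on
    each side, and

        fcplus = (C_mid - C_rest) * V_mid.

    Raises
    ------
    ShortCellError
        If the cell is too short for a cylindrical window; callers exclude
        and count such cells.
    """
    if cell.length <= midcell_width + cell.diameter:
        raise ShortCellError(
            f"cell {cell.cell_id!r}: length {cell.length:.3f} μm too short for a "
            f"{midcell_width} μm cylindrical midcell window at diameter "
            f"{cell.diameter:.3f} μm"
        )
    n_px = len(cell.profile)
    center = (n_px - 1) / 2.0
    half_width_px = midcell_width * pixel_pitch / 2.0
    w = _window_weights(n_px, center, half_width_px)
    F_mid = float(w @ cell.profile)
    F_rest = float(cell.profile.sum()) - F_mid
    r = cell.diameter / 2.0
    V_mid = math.pi * r * r * midcell_width
    V_rest = cell_volume(cell.length, cell.diameter) - V_mid
    C_mid = F_mid / V_mid
    C_rest = F_rest / V_rest
    return FCPlusResult(
        cell_id=cell.cell_id,
        F_mid=F_mid,
        F_rest=F_rest,
        V_mid=V_mid,
        V_rest=V_rest,
        C_mid=C_mid,
        C_rest=C_rest,
        fcplus=(C_mid - C_rest) * V_mid,
    )


def bin_by_age(
    values: np.ndarray,
    ages: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    ci_level: float = DEFAULT_CI_LEVEL,
    value_kind: str = "fcplus",
) -> BinnedCurve:
    """Bin per-cell values into age classes with Student-t CIs.

    Bins are ``[k w, (k+1) w)`` with the last bin closed at 1.  The CI
    half-width is ``t_{(1+ci)/2, n-1} * s / sqrt(n)`` per bin (0 for a
    single cell); empty bins carry NaN.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape:
        raise ValueError(
            f"values and ages must match in length ({values.size} vs {ages.size})"
        )
    if np.any((ages < 0) | (ages > 1)):
        raise ValueError("ages must lie in [0, 1]")
    n_bins = int(round(1.0 / bin_width))
    idx = np.minimum((ages / bin_width).astype(int), n_bins - 1)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    means = np.full(n_bins, np.nan)
    ci = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        vals = values[idx == b]
        counts[b] = vals.size
        if vals.size == 0:
            continue
        means[b] = vals.mean()
        if vals.size == 1:
            ci[b] = 0.0
        else:
            s = vals.std(ddof=1)
            t = sps.t.ppf(0.5 + ci_level / 2.0, vals.size - 1)
            ci[b] = t * s / math.sqrt(vals.size)
    return BinnedCurve(centers, means, ci, counts, value_kind=value_kind)


def minmax_normalize(curve: BinnedCurve) -> BinnedCurve:
    """Map the occupied-bin means affinely onto [0, 1].

    Puts curves with different molecule numbers and antibody affinities on
    a common scale so their timing can be compared.  CI half-widths are
    scaled by the same factor.  Idempotent; raises on a constant curve.
    """
    occ = curve.occupied
    if occ.sum() < 2:
        raise DegenerateCurveError("normalization needs >= 2 occupied bins")
    lo = np.nanmin(curve.means[occ])
    hi = np.nanmax(curve.means[occ])
    if hi == lo:
        raise DegenerateCurveError("constant curve cannot be min-max normalized")
    scale = 1.0 / (hi - lo)
    return replace(
        curve,
        means=(curve.means - lo) * scale,
        ci_halfwidths=curve.ci_halfwidths * scale,
        value_kind="normalized",
    )


def average_replicates(curves: list[BinnedCurve]) -> BinnedCurve:
    """Unweighted per-bin mean over replicate curves on a shared bin grid.

    A bin contributes wherever at least one replicate occupies it; the CI
    half-width comes from the between-replicate scatter (Student-t over the
    replicates present in that bin).  The returned counts are replicate
    counts per bin, not cell counts.
    """
    if len(curves) < 2:
        raise ValueError("need >= 2 replicate curves to average")
    grid = curves[0].bin_centers
    kind = curves[0].value_kind
    for c in curves[1:]:
        if not np.allclose(c.bin_centers, grid):
            raise ValueError("replicate curves must share the same bin grid")
        if c.value_kind != kind:
            raise ValueError(
                f"replicate curves must share value_kind ({c.value_kind!r} != {kind!r})"
            )
    stacked = np.vstack([c.means for c in curves])
    present = np.vstack([c.occupied for c in curves])
    n_rep = present.sum(axis=0)
    means = np.full(grid.size, np.nan)
    ci = np.full(grid.size, np.nan)
    for b in range(grid.size):
        vals = stacked[present[:, b], b]
        if vals.size == 0:
            continue
        means[b] = vals.mean()
        if vals.size == 1:
            ci[b] = 0.0
        else:
            s = vals.std(ddof=1)
            t = sps.t.ppf(0.975, vals.size - 1)
            ci[b] = t * s / math.sqrt(vals.size)
    return BinnedCurve(grid, means, ci, n_rep, value_kind=kind)


def molecules_at_midcell(
    curve: BinnedCurve,
    mean_total_F: float,
    n_total: float = DEFAULT_MOLECULES_PER_CELL,
) -> BinnedCurve:
    """Convert an FCPlus curve into molecule numbers.

    Calibrated by the average number of molecules per cell in the culture
    (133 for PBP4, from ribosome profiling): a bin whose FCPlus equals the
    mean total fluorescence per cell corresponds to ``n_total`` molecules
    at midcell; the mapping is linear.
    """
    if mean_total_F <= 0:
        raise ValueError(f"mean_total_F must be positive, got {mean_total_F}")
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    scale = n_total / mean_total_F
    return replace(
        curve,
        means=curve.means * scale,
        ci_halfwidths=curve.ci_halfwidths * scale,
        value_kind="molecules",
    )


def midcell_density_per_circumference(result: FCPlusResult, diameter: float) -> float:
    """Midcell fluorescence surplus per μm of cell circumference."""
    if diameter <= 0:
        raise GeometryError(f"diameter must be positive, got {diameter}")
    return result.fcplus / (math.pi * diameter)


def concentration_per_volume(cell: CellRecord) -> float:
    """Total fluorescence divided by sphero-cylinder cell volume (per μm³)."""
    return cell.total_fluorescence / cell_volume(cell.length, cell.diameter)


def concentration_per_surface(cell: CellRecord) -> float:
    """Total fluorescence per μm² of envelope — the natural normalization
    for a cell-wall-bound enzyme."""
    return cell.total_fluorescence / cell_surface_area(cell.length, cell.diameter)
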