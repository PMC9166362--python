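"""End-to-end analysis of one population: ages, FCPlus, binned curve.

This is the glue the CLI and the validation harness share: it takes a
:class:`~septime.records.Population`, assigns division-cycle ages from
length rank, computes the per-cell midcell surplus (excluding and counting
cells too short for the window), and bins the surplus into age classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import EmptyInputError, ShortCellError
from .records import Population
from .stats import (
    BinnedCurve,
    assign_ages,
    bin_by_age,
    concentration_per_volume,
    fcplus,
    midcell_density_per_circumference,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Per-cell table plus the binned FCPlus curve for one replicate."""

    per_cell: pd.DataFrame
    curve: BinnedCurve
    n_short_excluded: int
    mean_total_F: float


def analyze_population(pop: Population, config: RunConfig | None = None) -> AnalysisResult:
    """Run the per-cell localization analysis on one replicate.

    The per-cell table carries, for every cell that admits a cylindrical
    midcell window: rank, age, total fluorescence, FCPlus and its
    ingredients, concentration per volume and midcell density per μm of
    circumference.  Short cells are excluded from FCPlus but still counted
    in the age ranking (their length is information about the age
    distribution) and in the log.
    """
    config = config or RunConfig()
    if len(pop) < 2:
        raise EmptyInputError(f"analysis needs >= 2 cells, got {len(pop)}")
    assignments = assign_ages(pop.lengths, [c.cell_id for c in pop.cells])
    rows = []
    n_short = 0
    for cell, assignment in zip(pop.cells, assignments):
        try:
            res = fcplus(cell, config.midcell_width, pop.pixel_pitch)
        except ShortCellError:
            n_short += 1
            continue
        rows.append(
            {
                "cell_id": cell.cell_id,
                "length_um": cell.length,
                "diameter_um": cell.diameter,
                "rank": assignment.rank,
                "age": assignment.age,
                "constricting": cell.constricting,
                "total_F": res.total_F,
                "F_mid": res.F_mid,
                "F_rest": res.F_rest,
                "C_mid": res.C_mid,
                "C_rest": res.C_rest,
                "fcplus": res.fcplus,
                "concentration": concentration_per_volume(cell),
                "midcell_density": midcell_density_per_circumference(
                    res, cell.diameter
                ),
            }
        )
    if n_short:
        logger.warning("excluded %d cells too short for the midcell window", n_short)
    if not rows:
        raise EmptyInputError("no cell long enough for the midcell window")
    per_cell = pd.DataFrame(rows)
    curve = bin_by_age(
        per_cell["fcplus"].to_numpy(),
        per_cell["age"].to_numpy(),
        bin_width=config.bin_width,
        ci_level=config.ci_level,
    )
    return AnalysisResult(
        per_cell=per_cell,
        curve=curve,
        n_short_excluded=n_short,
        mean_total_F=float(per_cell["total_F"].mean()),
    )


def curve_to_frame(curve: BinnedCurve) -> pd.DataFrame:
    """Tabular form of a binned curve (bin_center, mean, ci, n)."""
    return pd.DataFrame(
        {
            "bin_center": curve.bin_centers,
            "mean": curve.means,
            "ci_halfwidth": curve.ci_halfwidths,
            "n": curve.counts,
            "value_kind": curve.value_kind,
        }
    )


def frame_to_curve(frame: pd.DataFrame) -> BinnedCurve:
    """Inverse of :func:`curve_to_frame`."""
    kind = str(frame["value_kind"].iloc[0]) if "value_kind" in frame else "fcplus"
    return BinnedCurve(
        frame["bin_center"].to_numpy(float),
        frame["mean"].to_numpy(float),
        frame["ci_halfwidth"].to_numpy(float),
        frame["n"].to_numpy(int),
        value_kind=kind,
    )


def constricting_percentage(pop: Population) -> float:
    """Percentage of cells flagged as constricting."""
    if len(pop) == 0:
        raise EmptyInputError("empty population")
    return 100.0 * float(np.mean([c.constricting for c in pop.cells]))
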