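"""Demographs: length-sorted maps of axial fluorescence.

A demograph stacks the axial profile of every cell as one raster row,
cells sorted by length ascending and profiles anchored at the cell center
(the future division plane), so midcell recruitment appears as a central
column of intensity that switches on partway down the image.  Samples
outside a cell's outline are absent (NaN), not zero, and the per-row cell
outline is kept for overlay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import Population

#: Value written for absent (outside-outline) samples in CSV export.
ABSENT_SENTINEL = "NA"


@dataclass
class Demograph:
    """Length-sorted fluorescence map.

    ``matrix`` rows are cells in non-decreasing length order, columns a
    common axial grid centered on the cell midpoint; ``outline`` holds each
    row's half-length in grid units.
    """

    matrix: np.ndarray  # float, NaN outside the outline
    outline: np.ndarray  # per-row half-length, grid units
    lengths: np.ndarray  # per-row cell length, μm
    pixel_pitch: float

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def center_col(self) -> float:
        return (self.matrix.shape[1] - 1) / 2.0


def build_demograph(pop: Population, normalize_per_cell: bool = False) -> Demograph:
    """Assemble a demograph from a population.

    Profiles keep their native pixel pitch (no per-cell resampling) and are
    placed center-aligned on a grid wide enough for the longest cell; with
    ``normalize_per_cell`` each profile is divided by its own peak so
    localization pattern, not brightness, is displayed.
    """
    if len(pop) < 2:
        raise ValueError(f"demograph needs >= 2 cells, got {len(pop)}")
    order = np.argsort(pop.lengths, kind="stable")
    cells = [pop.cells[i] for i in order]
    width = max(len(c.profile) for c in cells)
    matrix = np.full((len(cells), width), np.nan)
    outline = np.empty(len(cells))
    for row, cell in enumerate(cells):
        profile = cell.profile.astype(float)
        if normalize_per_cell:
            peak = np.max(np.abs(profile))
            if peak > 0:
                profile = profile / peak
        n = len(profile)
        start = (width - n) // 2
        matrix[row, start : start + n] = profile
        outline[row] = n / 2.0
    return Demograph(
        matrix=matrix,
        outline=outline,
        lengths=np.array([c.length for c in cells]),
        pixel_pitch=pop.pixel_pitch,
    )


def render_demograph(
    d: Demograph, shared_scale: tuple[float, float] | None = None
) -> np.ndarray:
    """Render a demograph to a 16-bit grayscale raster with the outline
    overlaid at full intensity.

    Intensities map affinely from ``shared_scale = (lo, hi)`` onto
    0..65534 (clipped); passing the same ``shared_scale`` to several
    conditions renders them directly comparable.  Absent samples render as
    0, the outline as 65535.
    """
    if shared_scale is None:
        finite = d.matrix[np.isfinite(d.matrix)]
        lo, hi = float(finite.min()), float(finite.max())
        if hi == lo:
            hi = lo + 1.0
    else:
        lo, hi = shared_scale
        if lo >= hi:
            raise ValueError(f"need lo < hi in shared_scale, got ({lo}, {hi})")
    scaled = (d.matrix - lo) / (hi - lo) * 65534.0
    img = np.where(np.isfinite(scaled), np.clip(scaled, 0.0, 65534.0), 0.0)
    img = np.rint(img).astype(np.uint16)
    center = d.center_col
    for row in range(d.n_cells):
        for edge in (center - d.outline[row], center + d.outline[row] - 1):
            col = int(round(np.clip(edge, 0, img.shape[1] - 1)))
            img[row, col] = 65535
    return img


def export_matrix_csv(d: Demograph, path: str | Path) -> Path:
    """Write the demograph matrix as CSV with ``NA`` for absent samples."""
    path = Path(path)
    pd.DataFrame(d.matrix).to_csv(path, index=False, na_rep=ABSENT_SENTINEL)
    return path


def export_tiff(d: Demograph, path: str | Path, shared_scale=None) -> Path:
    """Render and write a 16-bit grayscale TIFF."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, render_demograph(d, shared_scale))
    return path


def export_png(d: Demograph, path: str | Path, shared_scale=None) -> Path:
    """Render and write a 16-bit grayscale PNG."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, render_demograph(d, shared_scale))
    return path
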