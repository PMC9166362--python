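"""Core data model: one measured cell and a replicate population.

A :class:`CellRecord` holds what a single-cell fluorescence export provides:
the cell length and diameter (μm) and the background-subtracted axial
fluorescence profile, sampled pole-to-pole at a fixed pixel pitch.  A
:class:`Population` bundles the cells of one immunolabeling replicate with
its acquisition metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

#: Default microscope scaling, pixels per μm.
DEFAULT_PIXEL_PITCH = 15.28


@dataclass
class CellRecord:
    """A single measured cell.

    Parameters
    ----------
    cell_id
        Opaque identifier, preserved verbatim through the pipeline.
    length
        Cell axis length in μm; must be positive and >= ``diameter``
        (cells are rods or spheres, never oblate).
    diameter
        Cell diameter in μm, positive.
    profile
        Axial fluorescence values from one pole (index 0) to the other,
        one sample per pixel.  Values may be negative after background
        subtraction; they must all be finite.
    constricting
        Whether the cell shows a visible constriction.
    """

    cell_id: str
    length: float
    diameter: float
    profile: np.ndarray
    constricting: bool = False

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if not (self.length > 0 and self.diameter > 0):
            raise GeometryError(
                f"cell {self.cell_id!r}: length and diameter must be positive "
                f"(got {self.length}, {self.diameter})"
            )
        if self.length < self.diameter:
            raise GeometryError(
                f"cell {self.cell_id!r}: length {self.length} < diameter "
                f"{self.diameter} (oblate cells are not valid rods)"
            )
        if self.profile.ndim != 1:
            raise ValueError(f"cell {self.cell_id!r}: profile must be 1-D")
        if not np.all(np.isfinite(self.profile)):
            raise ValueError(f"cell {self.cell_id!r}: non-finite profile values")

    @property
    def total_fluorescence(self) -> float:
        """Integrated fluorescence over the whole axis (sum of samples)."""
        return float(self.profile.sum())

    def matches_pitch(self, pixel_pitch: float, slack: int = 1) -> bool:
        """True if the profile length is consistent with ``length`` at the
        given pitch, within ``slack`` samples."""
        expected = round(self.length * pixel_pitch)
        return abs(len(self.profile) - expected) <= slack


@dataclass
class Population:
    """All cells of one replicate plus acquisition metadata."""

    cells: list[CellRecord] = field(default_factory=list)
    strain: str = ""
    replicate_id: str = ""
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    growth_condition: str = ""
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.cells])

    @property
    def diameters(self) -> np.ndarray:
        return np.array([c.diameter for c in self.cells])
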