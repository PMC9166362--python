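"""Readers and writers for per-cell measurement tables.

The on-disk shape mirrors typical single-cell fluorescence exports: one row
per cell with columns ``cell_id``, ``length_um``, ``diameter_um``,
``constricting`` and the axial profile either as wide columns
(``p0``, ``p1``, ...) or as a single ``profile`` column packing the samples
into one ``;``-delimited string.  CSV, TSV and xlsx dialects are supported
on read; CSV and TSV on write.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, GeometryError
from .records import DEFAULT_PIXEL_PITCH, CellRecord, Population

logger = logging.getLogger(__name__)

_PROFILE_SEP = ";"
_WIDE_RE = re.compile(r"^p(\d+)$")

_READERS = {
    "csv": lambda p: pd.read_csv(p, float_precision="round_trip"),
    "tsv": lambda p: pd.read_csv(p, sep="\t", float_precision="round_trip"),
    "xlsx": lambda p: pd.read_excel(p),
}


def _pack_profile(profile: np.ndarray) -> str:
    # repr() of a Python float is shortest-round-trip, hence lossless
    return _PROFILE_SEP.join(repr(float(v)) for v in profile)


def _unpack_profile(packed: str) -> np.ndarray:
    packed = packed.strip()
    if not packed:
        return np.empty(0)
    return np.array([float(tok) for tok in packed.split(_PROFILE_SEP)])


def _extract_profiles(frame: pd.DataFrame) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Pull the profile block out of the table, wide or packed."""
    wide = sorted(
        (c for c in frame.columns if _WIDE_RE.match(str(c))),
        key=lambda c: int(_WIDE_RE.match(str(c)).group(1)),
    )
    if "profile" in frame.columns:
        profiles = [
            _unpack_profile(v) if isinstance(v, str) else np.empty(0)
            for v in frame["profile"]
        ]
        return profiles, frame.drop(columns=["profile"])
    if wide:
        block = frame[wide].to_numpy(dtype=float)
        # wide rows are NaN-padded to the longest cell; strip trailing NaNs
        profiles = []
        for row in block:
            valid = np.flatnonzero(np.isfinite(row))
            profiles.append(row[: valid[-1] + 1] if valid.size else np.empty(0))
        return profiles, frame.drop(columns=wide)
    raise FormatError(
        "no profile data: expected a packed 'profile' column or wide 'p0..pN' columns"
    )


def read_population(
    path: str | Path,
    dialect: str | None = None,
    *,
    strain: str = "",
    replicate_id: str = "",
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    growth_condition: str = "",
) -> Population:
    """Read a per-cell table into a :class:`Population`.

    Rows failing validation (non-positive or non-finite length/diameter,
    length < diameter, non-finite profile values) are dropped and counted in
    a log message.  Missing diameters are imputed with the population median
    diameter, also logged.

    Raises
    ------
    FormatError
        If a mandatory column is absent (names the column).
    EmptyInputError
        If no valid rows remain.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower().lstrip(".")
        dialect = {"csv": "csv", "tsv": "tsv", "tab": "tsv", "xlsx": "xlsx"}.get(
            suffix, "csv"
        )
    if dialect not in _READERS:
        raise FormatError(f"unknown dialect {dialect!r}")
    frame = _READERS[dialect](path)

    for col in ("cell_id", "length_um"):
        if col not in frame.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")

    profiles, meta = _extract_profiles(frame)

    if "diameter_um" not in meta.columns:
        meta = meta.assign(diameter_um=np.nan)
    diam = pd.to_numeric(meta["diameter_um"], errors="coerce")
    n_missing_diam = int(diam.isna().sum())
    if n_missing_diam:
        median = float(diam.median())
        if not np.isfinite(median):
            raise FormatError(
                "column 'diameter_um' has no usable values to impute from"
            )
        diam = diam.fillna(median)
        logger.warning(
            "%s: imputed median diameter %.4g um for %d rows", path, median, n_missing_diam
        )

    lengths = pd.to_numeric(meta["length_um"], errors="coerce")
    constricting = (
        meta["constricting"].astype(bool)
        if "constricting" in meta.columns
        else pd.Series(False, index=meta.index)
    )

    cells: list[CellRecord] = []
    n_dropped = 0
    for i in range(len(meta)):
        try:
            cells.append(
                CellRecord(
                    cell_id=str(meta["cell_id"].iloc[i]),
                    length=float(lengths.iloc[i]),
                    diameter=float(diam.iloc[i]),
                    profile=profiles[i],
                    constricting=bool(constricting.iloc[i]),
                )
            )
        except (GeometryError, ValueError):
            n_dropped += 1
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows", path, n_dropped)
    if not cells:
        raise EmptyInputError(f"{path}: no valid cell rows")
    pop = Population(
        cells=cells,
        strain=strain,
        replicate_id=replicate_id,
        pixel_pitch=pixel_pitch,
        growth_condition=growth_condition,
    )
    logger.info("%s: read %d cells (%d dropped)", path, len(cells), n_dropped)
    return pop


def write_population(pop: Population, path: str | Path, dialect: str = "csv") -> Path:
    """Write a :class:`Population` as a delimited table with a packed
    ``profile`` column.  Floats are written shortest-round-trip so that
    ``read_population`` recovers them bit-exactly."""
    if dialect not in ("csv", "tsv"):
        raise FormatError(f"write dialect must be csv or tsv, got {dialect!r}")
    path = Path(path)
    frame = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in pop.cells],
            "length_um": [repr(c.length) for c in pop.cells],
            "diameter_um": [repr(c.diameter) for c in pop.cells],
            "constricting": [c.constricting for c in pop.cells],
            "profile": [_pack_profile(c.profile) for c in pop.cells],
        }
    )
    frame.to_csv(path, index=False, sep="\t" if dialect == "tsv" else ",")
    return path
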