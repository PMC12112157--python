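"""Synthetic lattice datasets with known planted structure.

Regular grids of unit squares with Gaussian background noise and three
pattern primitives that emulate phenomena seen in real longitudinal areal
data: a persistent elevated block (a stable hot region), a linear-trend
block (a gradually emerging cluster), and a single-cell, single-time spike
(a transient anomaly).  Effects are expressed in multiples of the noise sd
so the fixtures are scale-free — the statistics consume z-scores only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import box

from .errors import DataFormatError
from .geodata import AreaGeometry, SpatioTemporalDataset


@dataclass(frozen=True)
class LatticeSpec:
    """Regular rows x cols lattice of unit squares."""

    rows: int = 12
    cols: int = 12
    cell_size: float = 1.0
    times: int = 10
    noise_sd: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.rows * self.cols < 4:
            raise DataFormatError("lattice needs at least 4 cells")
        if self.times < 1:
            raise DataFormatError("need at least 1 time point")

    def cell_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise DataFormatError(f"cell ({row}, {col}) outside {self.rows}x{self.cols} grid")
        return row * self.cols + col


@dataclass(frozen=True)
class StaticBlock:
    """Constant additive effect on a set of cells at every time point."""

    cells: tuple  # of (row, col)
    effect: float


@dataclass(frozen=True)
class TrendBlock:
    """Effect interpolated linearly from start_effect to end_effect over time."""

    cells: tuple
    start_effect: float
    end_effect: float


@dataclass(frozen=True)
class Spike:
    """Single-cell additive effect at one time index."""

    cell: tuple  # (row, col)
    time_index: int
    effect: float


def block_cells(row0: int, row1: int, col0: int, col1: int) -> tuple:
    """Inclusive rectangle of (row, col) cells."""
    return tuple((r, c) for r in range(row0, row1 + 1) for c in range(col0, col1 + 1))


def grid_lattice(spec: LatticeSpec) -> list[AreaGeometry]:
    """rows x cols unit squares, ids ``r{i}c{j}``, row-major order."""
    s = spec.cell_size
    geoms = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            geoms.append(
                AreaGeometry(
                    area_id=f"r{r}c{c}",
                    geometry=box(c * s, (spec.rows - 1 - r) * s, (c + 1) * s, (spec.rows - r) * s),
                )
            )
    return geoms


def _time_labels(times: int) -> list[str]:
    return [str(2000 + t) for t in range(times)]


def checkerboard_dataset(rows: int, cols: int) -> SpatioTemporalDataset:
    """Single-time +1/-1 checkerboard: every neighbor pair has opposite sign."""
    spec = LatticeSpec(rows=rows, cols=cols, times=1)
    vals = np.array(
        [[1.0 if (r + c) % 2 == 0 else -1.0] for r in range(rows) for c in range(cols)]
    )
    return SpatioTemporalDataset(areas=grid_lattice(spec), times=["2000"], values=vals)


def plant_patterns(spec: LatticeSpec, patterns=()) -> SpatioTemporalDataset:
    """Gaussian background noise plus the additive pattern effects.

    Overlapping patterns sum.  Reproducible from ``spec.seed``.
    """
    n = spec.rows * spec.cols
    rng = np.random.default_rng(spec.seed)
    values = rng.normal(0.0, spec.noise_sd, size=(n, spec.times))
    tspan = max(spec.times - 1, 1)
    for pat in patterns:
        if isinstance(pat, StaticBlock):
            for (r, c) in pat.cells:
                values[spec.cell_index(r, c), :] += pat.effect
        elif isinstance(pat, TrendBlock):
            ramp = pat.start_effect + (pat.end_effect - pat.start_effect) * (
                np.arange(spec.times) / tspan
            )
            for (r, c) in pat.cells:
                values[spec.cell_index(r, c), :] += ramp
        elif isinstance(pat, Spike):
            if not 0 <= pat.time_index < spec.times:
                raise DataFormatError(f"spike time index {pat.time_index} out of range")
            r, c = pat.cell
            values[spec.cell_index(r, c), pat.time_index] += pat.effect
        else:
            raise DataFormatError(f"unknown pattern type {type(pat).__name__}")
    return SpatioTemporalDataset(
        areas=grid_lattice(spec), times=_time_labels(spec.times), values=values
    )


def default_patterns(spec: LatticeSpec) -> list:
    """The stock pattern set, scaled to the grid.

    A gradually emerging low block (NW), a persistent high block (SE), and a
    single-cell spike at the final time (NE).  On the default 12x12 grid the
    blocks are 3x3 at rows/cols 1-3 and 7-9 with the spike at (2, 9).
    """
    s = spec.noise_sd
    qr = max(1, min(spec.rows // 4, spec.rows - 1))
    qc = max(1, min(spec.cols // 4, spec.cols - 1))
    lo_r0, lo_c0 = min(1, spec.rows - qr), min(1, spec.cols - qc)
    hi_r0 = max(0, spec.rows - 2 - qr)
    hi_c0 = max(0, spec.cols - 2 - qc)
    spike_cell = (min(spec.rows - 1, max(0, spec.rows // 6)), max(0, spec.cols - 3))
    return [
        TrendBlock(
            cells=block_cells(lo_r0, lo_r0 + qr - 1, lo_c0, lo_c0 + qc - 1),
            start_effect=0.0,
            end_effect=-3.0 * s,
        ),
        StaticBlock(
            cells=block_cells(hi_r0, hi_r0 + qr - 1, hi_c0, hi_c0 + qc - 1),
            effect=3.0 * s,
        ),
        Spike(cell=spike_cell, time_index=spec.times - 1, effect=6.0 * s),
    ]


def default_fixture(seed: int = 42) -> SpatioTemporalDataset:
    """12x12 lattice, 10 time points, unit noise, all three pattern types."""
    spec = LatticeSpec(seed=seed)
    return plant_patterns(spec, default_patterns(spec))
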