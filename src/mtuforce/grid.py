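"""Electrode-array geometry for high-density surface EMG.

An HD-sEMG montage is a regular 2-D grid of electrodes over one muscle.
Grid coordinates are millimetres, origin at electrode (row 0, col 0),
x running along columns and y along rows.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ElectrodeGrid:
    """Regular 2-D electrode grid.

    Parameters
    ----------
    rows, cols : int
        Grid dimensions; the recording has ``rows * cols`` channels in
        row-major channel order (channel ``r*cols + c`` sits at row r, col c).
    pitch_mm : float
        Centre-to-centre electrode spacing in millimetres. The pitch is the
        natural unit of localization error.
    """

    rows: int
    cols: int
    pitch_mm: float

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.rows}x{self.cols}")
        if not self.pitch_mm > 0:
            raise ValueError(f"pitch must be positive, got {self.pitch_mm}")

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    def positions(self) -> np.ndarray:
        """(n_electrodes, 2) array of (x, y) positions in mm, row-major order.

        Electrode at (row r, col c) sits at x = c*pitch, y = r*pitch.
        """
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        xy = np.stack([cc.ravel() * self.pitch_mm, rr.ravel() * self.pitch_mm], axis=1)
        return xy.astype(float)

    def electrode_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"electrode ({row},{col}) outside {self.rows}x{self.cols} grid")
        return row * self.cols + col

    def index_to_rowcol(self, index: int) -> tuple[int, int]:
        if not 0 <= index < self.n_electrodes:
            raise IndexError(f"electrode index {index} outside grid of {self.n_electrodes}")
        return divmod(index, self.cols)
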