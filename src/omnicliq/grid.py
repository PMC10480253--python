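"""Electrode-grid geometry and the unipolar-recording container.

A mapping array is a regular ``rows x cols`` grid of unipolar electrodes
with fixed pitch.  Rows are lettered A, B, C, ... from top to bottom and
columns numbered 1, 2, ... from left to right, so an electrode label reads
like ``"B3"``.  Physical coordinates follow the convention used throughout
this package: x grows with the column number, y grows *upwards* (row A has
the greatest y), and the origin sits at the bottom-left electrode.  Under
this convention the vertical bipole ``u_A1 - u_B1`` points from B to A,
i.e. along +y.

Recordings are stored on disk as a two-file container: a CSV matrix
(samples x channels, header row of electrode labels in row-major order
A1..A<cols>, B1..) next to a JSON sidecar carrying the sampling rate, grid
shape, pitch, amplitude units and free-form metadata.  Internal units are
fixed to microvolts and millimetres; declared units are converted on read.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "ElectrodeGrid",
    "UnipolarRecording",
    "GridError",
    "RecordingFormatError",
    "make_grid",
    "read_recording",
    "write_recording",
]

_ROW_LETTERS = string.ascii_uppercase

#: amplitude units accepted in the sidecar, with conversion factor to uV
_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6}


class GridError(ValueError):
    """Invalid electrode-grid geometry."""


class RecordingFormatError(ValueError):
    """Malformed on-disk recording container; the message names the field."""


@dataclass(frozen=True)
class ElectrodeGrid:
    """Regular planar electrode array.

    Parameters
    ----------
    rows, cols : int
        Grid shape; both must be >= 2 so at least one 2x2 clique exists.
    pitch : float
        Nearest-neighbour electrode spacing in mm.
    """

    rows: int
    cols: int
    pitch: float

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise GridError(
                f"grid must be at least 2x2 (got {self.rows}x{self.cols}); "
                "no clique exists otherwise"
            )
        if self.rows > len(_ROW_LETTERS):
            raise GridError(f"at most {len(_ROW_LETTERS)} lettered rows supported")
        if not self.pitch > 0:
            raise GridError(f"pitch must be positive (got {self.pitch})")

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    def label(self, i: int, j: int) -> str:
        """Label of the electrode in row ``i`` (0 = A), column ``j`` (0 = 1)."""
        if not (0 <= i < self.rows and 0 <= j < self.cols):
            raise GridError(f"electrode index ({i}, {j}) outside {self.rows}x{self.cols} grid")
        return f"{_ROW_LETTERS[i]}{j + 1}"

    def index(self, label: str) -> tuple[int, int]:
        """Inverse of :meth:`label`."""
        i = _ROW_LETTERS.find(label[0])
        try:
            j = int(label[1:]) - 1
        except ValueError as exc:
            raise GridError(f"malformed electrode label {label!r}") from exc
        if i < 0 or not (0 <= i < self.rows and 0 <= j < self.cols):
            raise GridError(f"label {label!r} outside {self.rows}x{self.cols} grid")
        return i, j

    def labels(self) -> list[str]:
        """All labels in row-major order A1..A<cols>, B1.. (the channel order)."""
        return [self.label(i, j) for i in range(self.rows) for j in range(self.cols)]

    def position(self, label: str) -> tuple[float, float]:
        """Planar coordinates (x, y) in mm; origin at the bottom-left electrode."""
        i, j = self.index(label)
        return j * self.pitch, (self.rows - 1 - i) * self.pitch

    def positions(self) -> dict[str, tuple[float, float]]:
        return {lab: self.position(lab) for lab in self.labels()}

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels())


def make_grid(rows: int, cols: int, pitch: float = 1.0) -> ElectrodeGrid:
    """Build an :class:`ElectrodeGrid`; raises :class:`GridError` if degenerate."""
    return ElectrodeGrid(rows=rows, cols=cols, pitch=pitch)


@dataclass
class UnipolarRecording:
    """Multichannel unipolar electrogram recording on a grid.

    ``data`` is a ``(n_electrodes, n_samples)`` float array in uV, channel
    order matching ``grid.labels()``.  ``meta`` is free-form, JSON-native
    provenance (pacing rate, generator parameters, seed, ...).
    """

    grid: ElectrodeGrid
    fs: float
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise RecordingFormatError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.grid.n_electrodes:
            raise RecordingFormatError(
                f"channel count {self.data.shape[0]} does not match grid "
                f"{self.grid.rows}x{self.grid.cols} = {self.grid.n_electrodes} electrodes"
            )
        if not self.fs > 0:
            raise RecordingFormatError(f"fs must be positive (got {self.fs})")
        if not np.all(np.isfinite(self.data)):
            raise RecordingFormatError("amplitudes must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms from recording start."""
        return np.arange(self.n_samples) * (1000.0 / self.fs)

    def channel(self, label: str) -> np.ndarray:
        """Time series of one electrode (view, uV)."""
        i, j = self.grid.index(label)
        return self.data[i * self.grid.cols + j]


def write_recording(rec: UnipolarRecording, path: str | Path) -> None:
    """Write the CSV matrix plus JSON sidecar (same stem, ``.json``)."""
    path = Path(path)
    header = ",".join(rec.grid.labels())
    np.savetxt(path, rec.data.T, delimiter=",", header=header, comments="", fmt="%.17g")
    sidecar = {
        "fs": rec.fs,
        "rows": rec.grid.rows,
        "cols": rec.grid.cols,
        "pitch_mm": rec.grid.pitch,
        "units": "uV",
        "meta": rec.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=float))


def read_recording(path: str | Path) -> UnipolarRecording:
    """Read a recording container written by :func:`write_recording`.

    Declared amplitude units are converted to uV on ingest.  Raises
    :class:`RecordingFormatError` naming the offending field on mismatch.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not path.exists():
        raise RecordingFormatError(f"recording matrix {path} does not exist")
    if not sidecar_path.exists():
        raise RecordingFormatError(f"sidecar {sidecar_path} does not exist")
    side = json.loads(sidecar_path.read_text())
    for key in ("fs", "rows", "cols", "pitch_mm"):
        if key not in side:
            raise RecordingFormatError(f"sidecar missing required field {key!r}")
    units = side.get("units", "uV")
    if units not in _UNIT_TO_UV:
        raise RecordingFormatError(f"unknown units {units!r} in sidecar")
    grid = make_grid(int(side["rows"]), int(side["cols"]), float(side["pitch_mm"]))

    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if header != grid.labels():
        raise RecordingFormatError(
            f"CSV header channels do not match grid labels: expected "
            f"{len(grid.labels())} row-major labels, got {len(header)} "
            f"starting {header[:3]}"
        )
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2).T
    if data.shape[0] != grid.n_electrodes:
        raise RecordingFormatError(
            f"channel count {data.shape[0]} != rows*cols = {grid.n_electrodes}"
        )
    return UnipolarRecording(
        grid=grid,
        fs=float(side["fs"]),
        data=data * _UNIT_TO_UV[units],
        meta=side.get("meta", {}),
    )
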