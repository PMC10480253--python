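"""2x2 electrode cliques and their orthogonal bipole pairs.

A clique is a square cell of four electrodes from which one pair of
orthogonal bipolar electrograms is formed.  Four triangular configurations
use two adjacent edges of the cell; the cross configuration uses the two
diagonals, followed by a +pi/4 counterclockwise rotation that realigns the
diagonal frame with the Cartesian axes.  Larger interelectrode distances
are realised by taking cell corners k grid steps apart on the same array.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .grid import ElectrodeGrid, UnipolarRecording

__all__ = [
    "CliqueConfig",
    "Clique",
    "BipolePair",
    "enumerate_cliques",
    "clique_bipoles",
    "bipole_separation_mm",
    "TRIANGLE_CONFIGS",
    "COMPLEMENTARY_PAIRS",
]

_SQ2_INV = np.sqrt(2.0) / 2.0
# +pi/4 counterclockwise: maps the diagonal bipole frame onto (x, y)
ROT45 = np.array([[_SQ2_INV, -_SQ2_INV], [_SQ2_INV, _SQ2_INV]])


class CliqueConfig(str, Enum):
    """The five clique configurations."""

    T_LL = "t_ll"  # lower-left triangle
    T_LR = "t_lr"  # lower-right triangle
    T_UL = "t_ul"  # upper-left triangle
    T_UR = "t_ur"  # upper-right triangle
    X = "x"        # cross (diagonals)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


TRIANGLE_CONFIGS = (CliqueConfig.T_LL, CliqueConfig.T_LR, CliqueConfig.T_UL, CliqueConfig.T_UR)

#: triangle pairs occupying opposite corners of the cell; they share
#: parallel bipole directions and behave alike under planar propagation
COMPLEMENTARY_PAIRS = (
    (CliqueConfig.T_LL, CliqueConfig.T_UR),
    (CliqueConfig.T_LR, CliqueConfig.T_UL),
)


@dataclass(frozen=True)
class Clique:
    """Corner labels of one square cell.

    The A/B (row) and 1/2 (column) roles are the cell's own: ``a1`` is the
    top-left corner, ``a2`` top-right, ``b1`` bottom-left, ``b2``
    bottom-right — regardless of the corners' global grid labels.
    """

    a1: str
    a2: str
    b1: str
    b2: str
    spacing_k: int
    spacing_mm: float

    @property
    def corners(self) -> tuple[str, str, str, str]:
        return (self.a1, self.a2, self.b1, self.b2)

    @property
    def id(self) -> str:
        return f"{self.a1}+{self.spacing_k}"


@dataclass
class BipolePair:
    """Cartesian bipole pair b(t) = [b_x(t), b_y(t)] of one clique (uV).

    For the cross configuration ``raw_diagonals`` keeps (b_1, b_2) before
    the +pi/4 rotation; the rotation preserves the per-sample norm, so the
    pair's energy equals the diagonals' energy.
    """

    b_x: np.ndarray
    b_y: np.ndarray
    clique: Clique
    config: CliqueConfig
    fs: float
    raw_diagonals: tuple[np.ndarray, np.ndarray] | None = None

    def as_matrix(self) -> np.ndarray:
        """Stack to shape (2, n_samples)."""
        return np.vstack([self.b_x, self.b_y])


def enumerate_cliques(grid: ElectrodeGrid, spacing_k: int = 1) -> list[Clique]:
    """Every axis-aligned square cell with corners ``spacing_k`` steps apart.

    Returned in row-major order of the top-left corner; count is
    ``(rows - k) * (cols - k)``.  A spacing exceeding the grid yields an
    empty list, not an error.
    """
    if spacing_k < 1:
        raise ValueError(f"spacing_k must be >= 1 (got {spacing_k})")
    out: list[Clique] = []
    for i in range(grid.rows - spacing_k):
        for j in range(grid.cols - spacing_k):
            out.append(
                Clique(
                    a1=grid.label(i, j),
                    a2=grid.label(i, j + spacing_k),
                    b1=grid.label(i + spacing_k, j),
                    b2=grid.label(i + spacing_k, j + spacing_k),
                    spacing_k=spacing_k,
                    spacing_mm=spacing_k * grid.pitch,
                )
            )
    return out


def clique_bipoles(
    rec: UnipolarRecording, clique: Clique, config: CliqueConfig
) -> BipolePair:
    """Compute the Cartesian bipole pair of one clique configuration.

    Triangular configurations subtract along two adjacent cell edges; the
    cross configuration subtracts along the diagonals,

        b_1 = u_A2 - u_B1,   b_2 = u_A1 - u_B2,

    then rotates (b_1, b_2) by +pi/4 counterclockwise to obtain (b_x, b_y).
    """
    u = {c: rec.channel(c) for c in clique.corners}
    a1, a2, b1, b2 = (u[clique.a1], u[clique.a2], u[clique.b1], u[clique.b2])

    raw = None
    if config == CliqueConfig.T_LL:
        bx, by = b2 - b1, a1 - b1
    elif config == CliqueConfig.T_LR:
        bx, by = b2 - b1, a2 - b2
    elif config == CliqueConfig.T_UL:
        bx, by = a2 - a1, a1 - b1
    elif config == CliqueConfig.T_UR:
        bx, by = a2 - a1, a2 - b2
    elif config == CliqueConfig.X:
        d1, d2 = a2 - b1, a1 - b2
        bx, by = ROT45 @ np.vstack([d1, d2])
        raw = (d1, d2)
    else:  # pragma: no cover - closed enumeration
        raise ValueError(f"unknown configuration {config!r}")

    return BipolePair(b_x=bx, b_y=by, clique=clique, config=config, fs=rec.fs,
                      raw_diagonals=raw)


def bipole_separation_mm(
    grid: ElectrodeGrid, clique: Clique, config: CliqueConfig
) -> float:
    """Physical electrode separation of the clique's bipoles in mm.

    Both bipoles of a configuration have equal separation: the cell side
    for triangles, the diagonal (side * sqrt(2)) for the cross — the
    cross's effective interelectrode distance is scaled by sqrt(2).
    Computed from electrode coordinates, not assumed.
    """
    if config == CliqueConfig.X:
        p, q = grid.position(clique.a2), grid.position(clique.b1)
    else:
        p, q = grid.position(clique.b2), grid.position(clique.b1)
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))
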