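"""Model/Results frontend over the clique-omnipole pipeline.

`OmnipolarModel` is constructed from a recording (or a file) and holds the
analysis design: which clique configurations, which interelectrode
spacings, the activation-window policy.  `fit()` runs the sweep and
returns an `OmnipolarResults` carrying the per-clique estimates (tidy
DataFrame), the aggregated summary, direction estimates with circular
spread, and a `summary()` text table, in the spirit of statsmodels'
model/results split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cliques import CliqueConfig, clique_bipoles, enumerate_cliques
from .grid import UnipolarRecording, read_recording
from .pipeline import (
    ALL_CONFIGS,
    METRIC_COLUMNS,
    aggregate,
    evaluate,
    segment_activations,
    summary_text,
)

__all__ = ["OmnipolarModel", "OmnipolarResults"]


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    z = np.exp(1j * np.deg2rad(angles_deg))
    return float(np.rad2deg(np.angle(z.mean())) % 360.0)


def _circular_std_deg(angles_deg: np.ndarray) -> float:
    r = np.abs(np.exp(1j * np.deg2rad(angles_deg)).mean())
    r = min(max(r, 1e-12), 1.0)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))


class OmnipolarModel:
    """Omnipolar estimation design for one or more recordings.

    Parameters
    ----------
    recording : UnipolarRecording or sequence thereof
    configs : clique configurations to evaluate (default: all five)
    spacings : interelectrode spacings in grid steps (default 1-4)
    max_cliques : deterministic even subsample cap per spacing (None = all)
    half_width_ms : activation-window half width
    window_policy : "auto" | "meta" | "detect"
    """

    def __init__(
        self,
        recording: UnipolarRecording | Sequence[UnipolarRecording],
        configs: Sequence[CliqueConfig] = ALL_CONFIGS,
        spacings: Sequence[int] = (1, 2, 3, 4),
        max_cliques: int | None = None,
        half_width_ms: float = 60.0,
        window_policy: str = "auto",
    ) -> None:
        if isinstance(recording, UnipolarRecording):
            recording = [recording]
        self.recordings = list(recording)
        self.configs = tuple(configs)
        self.spacings = tuple(spacings)
        self.max_cliques = max_cliques
        self.half_width_ms = half_width_ms
        self.window_policy = window_policy

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "OmnipolarModel":
        """Build a model from an on-disk recording container."""
        return cls(read_recording(path), **kwargs)

    def fit(self) -> "OmnipolarResults":
        """Run the sweep and return the results object."""
        records = evaluate(
            self.recordings,
            configs=self.configs,
            spacings=self.spacings,
            max_cliques=self.max_cliques,
            half_width_ms=self.half_width_ms,
            window_policy=self.window_policy,
        )
        return OmnipolarResults(model=self, records=records)


@dataclass
class OmnipolarResults:
    """Fitted per-clique omnipole estimates and their reliability metrics."""

    model: OmnipolarModel
    records: pd.DataFrame
    _aggregate: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def aggregate_(self) -> pd.DataFrame:
        """Mean/SD/median/IQR/n per (config, spacing, metric)."""
        if self._aggregate is None:
            self._aggregate = aggregate(self.records)
        return self._aggregate

    def wavefront_direction(
        self, config: CliqueConfig = CliqueConfig.X, spacing_k: int | None = None
    ) -> dict[str, float]:
        """Circular mean and spread of recovered propagation directions.

        Uses the given configuration (cross by default) at the smallest
        fitted spacing unless ``spacing_k`` is given.
        """
        if spacing_k is None:
            spacing_k = min(self.model.spacings)
        sel = self.records[
            (self.records["config"] == config.value)
            & (self.records["spacing_k"] == spacing_k)
        ]
        angles = sel["direction_deg"].dropna().to_numpy()
        if len(angles) == 0:
            raise ValueError("no direction estimates for the requested cell")
        return {
            "direction_deg": _circular_mean_deg(angles),
            "circ_std_deg": _circular_std_deg(angles),
            "n": int(len(angles)),
        }

    def summary(self) -> str:
        """Text summary: run design header plus per-spacing metric table."""
        n_rec = len(self.model.recordings)
        n_rows = len(self.records)
        n_flagged = int((self.records["flags"] != "").sum()) if n_rows else 0
        head = [
            "Omnipolar electrogram estimation summary",
            "=" * 44,
            f"recordings: {n_rec}   rows: {n_rows}   flagged: {n_flagged}",
            f"configs: {', '.join(c.value for c in self.model.configs)}"
            f"   spacings (steps): {list(self.model.spacings)}",
            "",
        ]
        return "\n".join(head) + summary_text(self.aggregate_)

    def plot_loop(self, clique_id: str, config: CliqueConfig, beat: int = 0, ax=None):
        """Debug plot of one clique's bipole loop in the b_x-b_y plane."""
        import matplotlib.pyplot as plt

        rec = next(
            r for r in self.model.recordings
            for k in self.model.spacings
            for c in enumerate_cliques(r.grid, k)
            if c.id == clique_id
        )
        spacing_k = int(clique_id.rsplit("+", 1)[1])
        clique = next(c for c in enumerate_cliques(rec.grid, spacing_k) if c.id == clique_id)
        windows = segment_activations(rec, policy=self.model.window_policy,
                                      half_width_ms=self.model.half_width_ms)
        w = windows[beat].slice
        pair = clique_bipoles(rec, clique, config)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(pair.b_x[w], pair.b_y[w], "k-", lw=0.8)
        ax.set_xlabel("$b_x$ [uV]")
        ax.set_ylabel("$b_y$ [uV]")
        ax.set_title(f"{clique_id} {config.value}")
        ax.set_aspect("equal")
        return ax
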