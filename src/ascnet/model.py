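"""Model/Results interface over the two-state connectivity analysis.

`AscModel` holds paired multichannel time series (one per state); `fit`
runs the full pipeline — covariance summaries with effective degrees of
freedom, Fisher-z change tests with FDR control, Monte-Carlo class tests —
and returns an `AscResults` carrying per-edge estimates, null intervals,
categories and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bounds import CorrInterval, additive_bounds, common_signal_bounds, \
    uncorrelated_predicted_correlation
from .covariance import StateSeries, read_series_csv
from .inference import McConfig
from .network import NetworkResult, analyze_network, export_results

__all__ = ["AscModel", "AscResults"]


class AscModel:
    """Two-state functional-connectivity change model.

    Parameters
    ----------
    series_a, series_b
        Node time series of the two states (same node set).

    Examples
    --------
    >>> model = AscModel.from_dataframes(frame_a, frame_b)
    >>> res = model.fit(n_iterations=500, seed=7)
    >>> print(res.summary())
    """

    def __init__(self, series_a: StateSeries, series_b: StateSeries):
        if set(series_a.node_labels) != set(series_b.node_labels):
            raise ValueError("states must share the same node set")
        self.series_a = series_a
        self.series_b = series_b

    @classmethod
    def from_dataframes(cls, frame_a: pd.DataFrame, frame_b: pd.DataFrame,
                        state_labels: tuple[str, str] = ("A", "B")) -> "AscModel":
        def mk(frame, lab):
            return StateSeries(values=frame.to_numpy(dtype=float),
                               node_labels=tuple(str(c) for c in frame.columns),
                               state_label=lab)
        return cls(mk(frame_a, state_labels[0]), mk(frame_b, state_labels[1]))

    @classmethod
    def from_csv(cls, path_a: str | Path, path_b: str | Path,
                 transpose: bool = False) -> "AscModel":
        return cls(read_series_csv(path_a, state_label="A", transpose=transpose),
                   read_series_csv(path_b, state_label="B", transpose=transpose))

    def fit(self, n_iterations: int = 2000, interval_level: float = 0.95,
            seed: int = 0, fdr_level: float = 0.2,
            dof_override: float | None = None) -> "AscResults":
        cfg = McConfig(n_iterations=n_iterations, interval_level=interval_level,
                       seed=seed, dof_override=dof_override)
        net = analyze_network(self.series_a, self.series_b, cfg, fdr_level)
        return AscResults(self, net)


@dataclass
class AscResults:
    """Fitted two-state connectivity-change results."""

    model: AscModel
    network: NetworkResult

    @property
    def edges(self) -> pd.DataFrame:
        from .network import _edge_row
        return pd.DataFrame([_edge_row(e) for e in self.network.edges])

    def category_counts(self) -> dict[str, int]:
        return self.network.category_counts()

    def deterministic_bounds(self, node_x: str, node_y: str) -> dict[str, object]:
        """Class intervals for one edge at the point estimates (no MC)."""
        for e in self.network.edges:
            if set(e.pair) == {node_x, node_y}:
                break
        else:
            raise KeyError(f"unknown edge ({node_x}, {node_y})")
        va_x = self.network.var_a[e.pair[0]]
        va_y = self.network.var_a[e.pair[1]]
        vb_x = self.network.var_b[e.pair[0]]
        vb_y = self.network.var_b[e.pair[1]]
        return dict(
            uncorrelated=uncorrelated_predicted_correlation(
                e.rho_a, np.sqrt(vb_x / va_x), np.sqrt(vb_y / va_y)),
            common=common_signal_bounds(e.rho_a, va_x, va_y, vb_x, vb_y),
            additive=additive_bounds(e.rho_a, va_x, va_y, vb_x, vb_y),
        )

    def save(self, path: str | Path, plot: bool = False) -> dict[str, Path]:
        return export_results(self.network, path, plot=plot)

    def summary(self) -> str:
        net = self.network
        counts = net.category_counts()
        n_sig = len(net.significant_edges())
        lines = [
            "Additive Signal Change analysis",
            "=" * 46,
            f"nodes:                {len(net.node_labels)}",
            f"edges:                {len(net.edges)}",
            f"significant (FDR {net.fdr_level:g}): {n_sig}",
            f"MC iterations:        {net.config.n_iterations}",
            f"seed:                 {net.config.seed}",
            "",
            "category counts (significant edges)",
            "-" * 46,
        ]
        for cat in ("uncorrelated", "common", "other_additive", "non_additive"):
            lines.append(f"  {cat:<16s} {counts[cat]:>4d}")
        n_skip = sum(e.skipped_low_correlation for e in net.edges)
        if n_skip:
            lines.append(f"  (skipped, negligible correlation) {n_skip}")
        lines.append("")
        lines.append("significant edges")
        lines.append("-" * 46)
        lines.append(f"{'edge':<10s}{'rho_A':>8s}{'rho_B':>8s}{'q':>9s}  category")
        for e in net.significant_edges():
            cat = e.category or "(skipped)"
            lines.append(f"{e.pair[0]}-{e.pair[1]:<8s}{e.rho_a:>8.3f}"
                         f"{e.rho_b:>8.3f}{e.q_value:>9.4f}  {cat}")
        return "\n".join(lines)
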