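"""Network-level classification of functional-connectivity changes.

Applies the per-edge Monte-Carlo class tests across all node pairs of a
two-state dataset, controls the false discovery rate over the
correlation-change p-values (Benjamini-Hochberg), and labels each
significantly changing edge with the most specific class of additive
signal change that can still explain it:

``uncorrelated`` -> ``common`` -> ``other_additive`` -> ``non_additive``

Edges explained by a subclass are deliberately not counted under the more
general classes, so the four categories partition the significant edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .covariance import (
    StateSeries,
    TwoStateSummary,
    correlation,
    estimate_state_covariance,
)
from .inference import CLASS_IDS, ClassTestResult, McConfig, class_test, correlation_change_test

__all__ = [
    "EdgeClassification",
    "NetworkResult",
    "analyze_network",
    "classify_edge",
    "export_results",
    "load_results",
    "CATEGORIES",
]

CATEGORIES = ("uncorrelated", "common", "other_additive", "non_additive")

#: Edges whose correlation is negligible in both states carry no class
#: information (class effects require some initial correlation).
MIN_CLASSIFIABLE_CORR = 0.05


@dataclass(frozen=True)
class EdgeClassification:
    """Per-edge outcome: change statistics, significance and ASC category."""

    pair: tuple[str, str]
    rho_a: float
    rho_b: float
    delta_rho: float
    delta_var_x: float
    delta_var_y: float
    p_change: float
    q_value: float
    significant: bool
    category: str | None = None
    class_results: tuple[ClassTestResult, ...] = ()
    subclass_annotation: str | None = None
    skipped_low_correlation: bool = False


@dataclass(frozen=True)
class NetworkResult:
    """All edges of a two-state network analysis."""

    node_labels: tuple[str, ...]
    var_a: dict[str, float]
    var_b: dict[str, float]
    edges: tuple[EdgeClassification, ...]
    fdr_level: float
    config: McConfig

    def significant_edges(self) -> list[EdgeClassification]:
        return [e for e in self.edges if e.significant]

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for e in self.significant_edges():
            if e.category is not None:
                counts[e.category] += 1
        return counts


def classify_edge(results: Sequence[ClassTestResult], delta_rho: float) -> str:
    """Most-specific surviving class for one edge.

    Precedence: uncorrelated, then common, then the general additive class;
    an edge rejected by all three cannot be explained by additive change.
    """
    by_class = {r.class_id: r for r in results}
    missing = [c for c in CLASS_IDS if c not in by_class]
    if missing:
        raise ValueError(f"missing class results: {missing}")
    if not by_class["uncorrelated"].rejected:
        return "uncorrelated"
    if not by_class["common"].rejected:
        return "common"
    if not by_class["additive"].rejected:
        return "other_additive"
    return "non_additive"


def _subclass_annotation(results: Sequence[ClassTestResult], delta_rho: float,
                         delta_var_x: float, delta_var_y: float) -> str | None:
    """Secondary hint when both subclasses survive.

    Variance and absolute correlation moving together suggests a common
    signal; moving oppositely suggests uncorrelated signal. The primary
    label always follows the fixed precedence order.
    """
    by_class = {r.class_id: r for r in results}
    if by_class["uncorrelated"].rejected or by_class["common"].rejected:
        return None
    dvar = delta_var_x + delta_var_y
    moved_together = (dvar > 0) == (delta_rho > 0)
    return "common" if moved_together else "uncorrelated"


def _edge_seed(cfg: McConfig, index: int) -> McConfig:
    """Per-edge child configuration with a derived, order-independent seed."""
    child = np.random.SeedSequence([cfg.seed, 7919, index]).generate_state(1)[0]
    return McConfig(n_iterations=cfg.n_iterations,
                    interval_level=cfg.interval_level,
                    seed=int(child % (2 ** 31)),
                    dof_override=cfg.dof_override)


def analyze_network(series_a: StateSeries, series_b: StateSeries,
                    cfg: McConfig | None = None,
                    fdr_level: float = 0.2) -> NetworkResult:
    """Full two-state analysis of every node pair.

    For each unordered pair: covariance summaries and effective dof per
    state, a Fisher-z correlation-change test, Benjamini-Hochberg FDR
    across all pairs, then the three class tests on surviving pairs and
    category assignment by precedence.
    """
    cfg = cfg or McConfig()
    if set(series_a.node_labels) != set(series_b.node_labels):
        raise ValueError("the two states must share the same node set")
    labels = series_a.node_labels
    pairs = [(labels[i], labels[j])
             for i in range(len(labels)) for j in range(i + 1, len(labels))]

    summaries: list[TwoStateSummary] = []
    p_change = []
    for pair in pairs:
        sa = estimate_state_covariance(series_a, pair)
        sb = estimate_state_covariance(series_b, pair)
        summary = TwoStateSummary(state_a=sa, state_b=sb, pair_labels=pair)
        summaries.append(summary)
        p_change.append(correlation_change_test(summary, cfg))
    p_change = np.asarray(p_change)
    significant, q_values, _, _ = multipletests(p_change, alpha=fdr_level,
                                                method="fdr_bh")[:4]

    edges = []
    for idx, (pair, summary) in enumerate(zip(pairs, summaries)):
        rho_a = correlation(summary.state_a)
        rho_b = correlation(summary.state_b)
        dvx = summary.state_b.var_x - summary.state_a.var_x
        dvy = summary.state_b.var_y - summary.state_a.var_y
        sig = bool(significant[idx])
        low_corr = (abs(rho_a) < MIN_CLASSIFIABLE_CORR
                    and abs(rho_b) < MIN_CLASSIFIABLE_CORR)
        category = None
        class_results: tuple[ClassTestResult, ...] = ()
        annotation = None
        if sig and not low_corr:
            ecfg = _edge_seed(cfg, idx)
            class_results = tuple(class_test(summary, cid, ecfg)
                                  for cid in CLASS_IDS)
            category = classify_edge(class_results, rho_b - rho_a)
            annotation = _subclass_annotation(class_results, rho_b - rho_a, dvx, dvy)
        edges.append(EdgeClassification(
            pair=pair, rho_a=rho_a, rho_b=rho_b, delta_rho=rho_b - rho_a,
            delta_var_x=dvx, delta_var_y=dvy,
            p_change=float(p_change[idx]), q_value=float(q_values[idx]),
            significant=sig, category=category, class_results=class_results,
            subclass_annotation=annotation,
            skipped_low_correlation=sig and low_corr,
        ))

    var_a = {}
    var_b = {}
    for lab in labels:
        col_a = series_a.column(lab)
        col_b = series_b.column(lab)
        var_a[lab] = float(np.var(col_a - col_a.mean(), ddof=1))
        var_b[lab] = float(np.var(col_b - col_b.mean(), ddof=1))
    return NetworkResult(node_labels=labels, var_a=var_a, var_b=var_b,
                         edges=tuple(edges), fdr_level=fdr_level, config=cfg)


# ---------------------------------------------------------------------------
# export / import


def _edge_row(e: EdgeClassification) -> dict:
    row = dict(
        node_x=e.pair[0], node_y=e.pair[1], rho_a=e.rho_a, rho_b=e.rho_b,
        delta_rho=e.delta_rho, delta_var_x=e.delta_var_x, delta_var_y=e.delta_var_y,
        p_change=e.p_change, q_value=e.q_value, significant=e.significant,
        category=e.category if e.category is not None else "",
        subclass_annotation=e.subclass_annotation or "",
        skipped_low_correlation=e.skipped_low_correlation,
    )
    for r in e.class_results:
        row[f"{r.class_id}_null_lo"] = r.null_lo_interval[0]
        row[f"{r.class_id}_null_hi"] = r.null_hi_interval[1]
        row[f"{r.class_id}_p_below"] = r.p_below
        row[f"{r.class_id}_p_above"] = r.p_above
        row[f"{r.class_id}_rejected"] = r.rejected
    return row


def export_results(net: NetworkResult, path: str | Path,
                   plot: bool = False) -> dict[str, Path]:
    """Write the edge table, run metadata and (optionally) a category plot.

    Produces ``edges.csv`` and ``run.json`` under ``path``; with
    ``plot=True`` also a simple four-panel graph rendering
    (``categories.png``).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([_edge_row(e) for e in net.edges])
    edges_path = path / "edges.csv"
    frame.to_csv(edges_path, index=False)

    from . import __version__

    meta = dict(
        node_labels=list(net.node_labels),
        var_a=net.var_a, var_b=net.var_b,
        fdr_level=net.fdr_level,
        config=dict(n_iterations=net.config.n_iterations,
                    interval_level=net.config.interval_level,
                    seed=net.config.seed,
                    dof_override=net.config.dof_override),
        category_counts=net.category_counts(),
        version=__version__,
    )
    run_path = path / "run.json"
    run_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    out = {"edges": edges_path, "run": run_path}
    if plot:
        out["plot"] = _plot_categories(net, path / "categories.png")
    return out


def _plot_categories(net: NetworkResult, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = net.node_labels
    n = len(labels)
    angles = {lab: 2 * np.pi * i / n for i, lab in enumerate(labels)}
    fig, axes = plt.subplots(1, 4, figsize=(16, 4.2), subplot_kw=dict(aspect="equal"))
    for ax, cat in zip(axes, CATEGORIES):
        ax.set_title(cat)
        for lab, ang in angles.items():
            ax.plot(np.cos(ang), np.sin(ang), "o", color="grey", ms=6)
            ax.annotate(lab, (1.12 * np.cos(ang), 1.12 * np.sin(ang)),
                        ha="center", va="center", fontsize=7)
        for e in net.significant_edges():
            if e.category != cat:
                continue
            a1, a2 = angles[e.pair[0]], angles[e.pair[1]]
            color = "red" if e.delta_rho > 0 else "blue"
            ax.plot([np.cos(a1), np.cos(a2)], [np.sin(a1), np.sin(a2)],
                    color=color, lw=1.5, alpha=0.8)
        ax.set_xlim(-1.3, 1.3)
        ax.set_ylim(-1.3, 1.3)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def load_results(path: str | Path) -> pd.DataFrame:
    """Read back an exported edge table."""
    frame = pd.read_csv(Path(path) / "edges.csv",
                        dtype={"node_x": str, "node_y": str},
                        keep_default_na=False)
    return frame
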