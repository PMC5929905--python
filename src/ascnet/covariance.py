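"""Per-state covariance summaries and effective degrees of freedom.

Functional-connectivity inference starts from the sample covariance of a
pair of node time series within each state. Because neural recordings are
autocorrelated, the nominal number of time points overstates the amount of
independent information behind a covariance estimate; every downstream test
therefore consumes an *effective* degrees of freedom computed from fitted
autoregressive models of the two channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StateSeries",
    "StateCovariance",
    "TwoStateSummary",
    "estimate_state_covariance",
    "correlation",
    "estimate_effective_dof",
    "summaries_to_frame",
    "frame_to_summaries",
    "read_series_csv",
]

#: Below this many time points the AR-based dof estimator is unreliable and
#: we fall back to n - 1 with a warning.
MIN_TIMEPOINTS_FOR_AR = 30

#: Maximum autoregressive order considered by AIC selection.
MAX_AR_ORDER = 10


@dataclass(frozen=True)
class StateSeries:
    """Multichannel time series recorded in one experimental state.

    Rows are time points, columns are nodes. Signals are assumed zero-mean
    stationary; channels are demeaned before covariance estimation.
    """

    values: np.ndarray
    node_labels: tuple[str, ...]
    state_label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", tuple(str(l) for l in self.node_labels))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (time x nodes) array")
        if values.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if values.shape[1] < 2:
            raise ValueError("need at least 2 nodes")
        if values.shape[1] != len(self.node_labels):
            raise ValueError("number of labels must match number of columns")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("all values must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None
        return self.values[:, j]


@dataclass(frozen=True)
class StateCovariance:
    """Observed 2x2 covariance of a node pair in one state.

    ``dof_eff`` is the effective number of independent samples behind the
    estimate (<= n_timepoints, >= 2); for white noise it is close to n.
    """

    var_x: float
    var_y: float
    cov_xy: float
    n_timepoints: int
    dof_eff: float

    def __post_init__(self) -> None:
        if not (self.var_x > 0 and self.var_y > 0):
            raise ValueError("variances must be positive")
        bound = np.sqrt(self.var_x * self.var_y)
        if abs(self.cov_xy) > bound * (1 + 1e-12):
            raise ValueError("|cov_xy| may not exceed sqrt(var_x*var_y)")
        if self.dof_eff < 2:
            raise ValueError("dof_eff must be >= 2")
        if self.dof_eff > self.n_timepoints:
            raise ValueError("dof_eff may not exceed n_timepoints")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.var_x, self.cov_xy], [self.cov_xy, self.var_y]])


@dataclass(frozen=True)
class TwoStateSummary:
    """Covariance summaries of one node pair in the two states."""

    state_a: StateCovariance
    state_b: StateCovariance
    pair_labels: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair_labels", tuple(self.pair_labels))
        if len(self.pair_labels) != 2:
            raise ValueError("pair_labels must name exactly two nodes")


def correlation(sc: StateCovariance) -> float:
    """Pearson correlation implied by a covariance summary."""
    r = sc.cov_xy / np.sqrt(sc.var_x * sc.var_y)
    return float(np.clip(r, -1.0, 1.0))


def _ar_autocorr_sum(x: np.ndarray, max_order: int = MAX_AR_ORDER) -> float:
    """Sum over all lags of the squared autocorrelation implied by an AR fit.

    Returns ``sum_{k=-inf}^{inf} rho_k^2`` (>= 1), the variance-inflation
    factor for second-moment estimates from this channel. AR order is chosen
    by AIC up to ``max_order``; an explosive or failed fit falls back to 1
    (white noise) and the caller decides how to warn.
    """
    from statsmodels.tsa.ar_model import AutoReg, ar_select_order

    n = x.shape[0]
    x = x - x.mean()
    max_order = int(min(max_order, n // 5))
    try:
        sel = ar_select_order(x, maxlag=max_order, ic="aic", trend="n", old_names=False)
        lags = sel.ar_lags or []
        if not lags:
            return 1.0
        res = AutoReg(x, lags=lags, trend="n", old_names=False).fit()
        order = max(lags)
        phi = np.zeros(order)
        for lag, coef in zip(lags, res.params):
            phi[lag - 1] = coef
    except Exception:
        return np.nan
    # stationarity: companion-matrix spectral radius < 1
    comp = np.zeros((order, order))
    comp[0, :] = phi
    if order > 1:
        comp[1:, :-1] = np.eye(order - 1)
    if np.max(np.abs(np.linalg.eigvals(comp))) >= 0.999:
        return np.nan
    # autocorrelation function of the fitted AR process: Yule-Walker for the
    # first `order` lags (rho_i = sum_j phi_j rho_|i-j|, rho_0 = 1), then the
    # AR recursion for higher lags.
    n_lags = min(10 * order + 50, 5 * n)
    rho = np.zeros(n_lags + 1)
    rho[0] = 1.0
    M = np.eye(order)
    rhs = phi.copy()  # the j == i term contributes phi_i * rho_0
    for i in range(1, order + 1):
        for j in range(1, order + 1):
            k = abs(i - j)
            if k == 0:
                continue
            M[i - 1, k - 1] -= phi[j - 1]
    try:
        rho[1 : order + 1] = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return np.nan
    for k in range(order + 1, n_lags + 1):
        rho[k] = np.dot(phi, rho[k - order : k][::-1])
    vif = 1.0 + 2.0 * float(np.sum(rho[1:] ** 2))
    if not np.isfinite(vif) or vif < 1.0:
        return np.nan
    return vif


def estimate_effective_dof(series: StateSeries) -> float:
    """Effective number of independent samples for covariance estimation.

    Fits an AR(p) model (AIC order selection, p <= 10) to each channel and
    converts the implied autocorrelation function to a variance-inflation
    factor ``1 + 2*sum_k rho_k^2`` for second-moment estimates. The series'
    effective dof is ``n / VIF``, combined across channels by harmonic mean.
    For white noise the result is close to n.

    Below 30 time points (or when an AR fit is explosive/non-stationary) the
    estimator falls back to ``n - 1`` with a warning.
    """
    n = series.n_timepoints
    if n < MIN_TIMEPOINTS_FOR_AR:
        warnings.warn(
            f"only {n} time points: falling back to dof = n - 1", UserWarning, stacklevel=2
        )
        return float(n - 1)
    dofs = []
    for j in range(series.values.shape[1]):
        vif = _ar_autocorr_sum(series.values[:, j])
        if not np.isfinite(vif):
            warnings.warn(
                "non-stationary AR fit: falling back to dof = n - 1", UserWarning, stacklevel=2
            )
            return float(n - 1)
        dofs.append(n / vif)
    dofs = np.asarray(dofs)
    dof = len(dofs) / np.sum(1.0 / dofs)  # harmonic mean
    return float(np.clip(dof, 2.0, n))


def estimate_state_covariance(
    series: StateSeries,
    pair: Sequence[str],
    detrend: bool = False,
    dof_eff: float | None = None,
) -> StateCovariance:
    """Unbiased sample covariance summary of a labelled node pair.

    Channels are demeaned (optionally linearly detrended) before the (n-1)-
    normalized covariance is computed. ``dof_eff`` defaults to the AR-based
    estimate from :func:`estimate_effective_dof` applied to the pair.
    """
    if len(pair) != 2:
        raise ValueError("pair must name exactly two nodes")
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 time points for covariance estimation")
    cols = np.column_stack([series.column(pair[0]), series.column(pair[1])])
    if detrend:
        t = np.arange(cols.shape[0], dtype=float)
        t = (t - t.mean()) / t.std()
        for j in range(2):
            beta = np.dot(t, cols[:, j]) / np.dot(t, t)
            cols[:, j] = cols[:, j] - beta * t
    cols = cols - cols.mean(axis=0)
    if np.allclose(cols[:, 0], 0) or np.allclose(cols[:, 1], 0):
        raise ValueError("zero-variance channel: covariance undefined")
    q = cols.T @ cols / (cols.shape[0] - 1)
    if dof_eff is None:
        pair_series = StateSeries(cols, node_labels=tuple(pair), state_label=series.state_label)
        dof_eff = estimate_effective_dof(pair_series)
    return StateCovariance(
        var_x=float(q[0, 0]),
        var_y=float(q[1, 1]),
        cov_xy=float(q[0, 1]),
        n_timepoints=series.n_timepoints,
        dof_eff=float(dof_eff),
    )


# ---------------------------------------------------------------------------
# flat-table round trips

_COLUMNS = ["node_x", "node_y", "state", "var_x", "var_y", "cov_xy", "n", "dof_eff"]


def summaries_to_frame(summaries: Sequence[TwoStateSummary],
                       state_labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Flatten TwoStateSummary records into the canonical CSV layout."""
    rows = []
    for s in summaries:
        for sc, state in ((s.state_a, state_labels[0]), (s.state_b, state_labels[1])):
            rows.append(
                dict(
                    node_x=s.pair_labels[0],
                    node_y=s.pair_labels[1],
                    state=state,
                    var_x=sc.var_x,
                    var_y=sc.var_y,
                    cov_xy=sc.cov_xy,
                    n=sc.n_timepoints,
                    dof_eff=sc.dof_eff,
                )
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_summaries(frame: pd.DataFrame,
                       state_labels: tuple[str, str] = ("A", "B")) -> list[TwoStateSummary]:
    """Inverse of :func:`summaries_to_frame`."""
    out = []
    for (nx, ny), grp in frame.groupby(["node_x", "node_y"], sort=False):
        by_state = {}
        for _, row in grp.iterrows():
            by_state[row["state"]] = StateCovariance(
                var_x=float(row["var_x"]),
                var_y=float(row["var_y"]),
                cov_xy=float(row["cov_xy"]),
                n_timepoints=int(row["n"]),
                dof_eff=float(row["dof_eff"]),
            )
        out.append(
            TwoStateSummary(
                state_a=by_state[state_labels[0]],
                state_b=by_state[state_labels[1]],
                pair_labels=(str(nx), str(ny)),
            )
        )
    return out


def read_series_csv(path: str | Path, state_label: str = "",
                    transpose: bool = False, sep: str | None = None) -> StateSeries:
    """Read a delimited time-series table (header row of node labels).

    Comma- and tab-delimited files are auto-detected unless ``sep`` is given.
    Missing values are an error.
    """
    frame = pd.read_csv(path, sep=sep, engine="python")
    if transpose:
        frame = frame.set_index(frame.columns[0]).T.reset_index(drop=True)
    if frame.isna().any().any():
        raise ValueError(f"{path}: missing values are not allowed")
    return StateSeries(
        values=frame.to_numpy(dtype=float),
        node_labels=tuple(str(c) for c in frame.columns),
        state_label=state_label,
    )
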