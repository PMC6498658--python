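"""Temporal bipolarisation of a policy debate.

Bipolarisation of a discourse network is the maximum modularity attainable
by any two-cluster partition, estimated as the best of a k = 2 clustering
ensemble.  High values mean two segregated coalitions with few
intermediaries; a network of many brokers scores low.  The temporal curve
slides a fixed-size window (default 200 statements) over the date-ordered
statement stream one statement at a time, rebuilds the thresholded network
inside each window, and records the window's bipolarisation at the date of
its median statement.  A LOESS smoother fitted over window index exposes
the trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .coalitions import cluster_k2_ensemble
from .errors import ParameterError
from .network import ActorNetwork
from .statements import StatementSet
from .transform import DEFAULT_THRESHOLD, build_network

DEFAULT_WINDOW = 200
DEFAULT_SPAN = 0.3


@dataclass
class PolarisationSeries:
    """Windowed bipolarisation values and (optionally) their smoothed curve.

    ``points`` is a list of (window_index, centre_date, value); degenerate
    windows (no clusterable network) carry value NaN and are retained as
    gaps.  ``smoothed`` aligns with ``points`` after fitting.
    """

    points: list = field(default_factory=list)
    window_size: int = DEFAULT_WINDOW
    smoothed: list = field(default_factory=list)
    loess_span: float | None = None

    def values(self) -> np.ndarray:
        return np.array([v for (_i, _d, v) in self.points], dtype=float)

    def dates(self) -> list:
        return [d for (_i, d, _v) in self.points]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["window_index", "centre_date", "bipolarisation"])
        if self.smoothed:
            df["smoothed"] = [v for (_d, v) in self.smoothed]
        return df


def bipolarisation(n: ActorNetwork, methods=None, seed: int | None = None) -> float:
    """Max modularity over the k = 2 clustering ensemble.

    Returns NaN for degenerate networks (fewer than 2 non-isolates, or no
    ensemble member produced a partition).
    """
    if len(n.non_isolates()) < 2:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parts = cluster_k2_ensemble(n, methods=methods, seed=seed)
    if not parts:
        return float("nan")
    return max(p.modularity for p in parts)


def polarisation_series(
    s: StatementSet,
    window: int = DEFAULT_WINDOW,
    tau: float = DEFAULT_THRESHOLD,
    methods=None,
    seed: int | None = None,
) -> PolarisationSeries:
    """Sliding-window bipolarisation over a date-ordered statement stream.

    Each consecutive ``window``-statement block (step: one statement) is
    rebuilt into a thresholded network and scored; the point is dated at the
    window's median statement.  Requires at least ``window`` statements.
    """
    if window < 2:
        raise ParameterError("window must cover at least 2 statements")
    n_stmt = len(s)
    if n_stmt < window:
        raise ParameterError(
            f"{n_stmt} statements < window {window}; use a smaller window"
        )
    stmts = list(s)  # already ordered by (date, article_id, input order)
    rng = np.random.default_rng(seed)
    points = []
    for start in range(n_stmt - window + 1):
        block = stmts[start : start + window]
        centre = block[(window - 1) // 2].date
        sub = StatementSet(statements=block)
        win_seed = int(rng.integers(2**31 - 1))
        try:
            net = build_network(sub, tau=tau)
            value = bipolarisation(net, methods=methods, seed=win_seed)
        except Exception:
            value = float("nan")
        points.append((start, centre, value))
    return PolarisationSeries(points=points, window_size=window)


def loess_smooth(
    series: PolarisationSeries, span: float = DEFAULT_SPAN
) -> PolarisationSeries:
    """Fit a LOESS (locally weighted linear regression) curve over window
    index; NaN points are excluded from the fit and remain gaps.

    ``span`` is the fraction of points entering each local regression.
    """
    if not 0 < span <= 1:
        raise ParameterError(f"span {span} outside (0, 1]")
    x = np.array([i for (i, _d, _v) in series.points], dtype=float)
    y = series.values()
    ok = ~np.isnan(y)
    if ok.sum() < 5:
        raise ParameterError("need at least 5 non-missing points to smooth")
    if span * ok.sum() < 2:
        raise ParameterError(f"span {span} covers fewer than 2 points per local fit")
    fitted = lowess(y[ok], x[ok], frac=span, return_sorted=False)
    smoothed = []
    pos = 0
    for (i, d, v), keep in zip(series.points, ok):
        if keep:
            smoothed.append((d, float(fitted[pos])))
            pos += 1
        else:
            smoothed.append((d, float("nan")))
    return PolarisationSeries(
        points=list(series.points),
        window_size=series.window_size,
        smoothed=smoothed,
        loess_span=span,
    )


def plot_series(series: PolarisationSeries, path=None, ax=None):
    """Bipolarisation-over-time curve (raw points + LOESS trend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(8, 4))
    dates = series.dates()
    ax.plot(dates, series.values(), lw=0.6, color="0.6", label="windowed bipolarisation")
    if series.smoothed:
        ax.plot(dates, [v for (_d, v) in series.smoothed], lw=2, color="C0", label="LOESS")
    ax.set_xlabel("window centre date")
    ax.set_ylabel("bipolarisation (max k=2 modularity)")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
    return ax
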