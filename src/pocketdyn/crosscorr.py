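"""Normalized time-lagged cross-correlation of structural time series.

For two mean-subtracted series x(t), y(t) sampled at a common timestep,

    r_xy(tau) = <x(t + tau) y(t)> / sqrt(<x^2> <y^2>)

where <x(t+tau) y(t)> is the time average over the trajectory and the
normalization uses the full-series mean squares of the centered series
(the two autocorrelations at tau = 0), so r_xy lies in [-1, 1].

Lag-sign convention: x is the first-named series; a peak at *negative* lag
means y lags behind x (y follows x in time).  For H-bond-distance versus
cavity-volume reports, x is the H-bond distance and y the volume, so a
maximum at -65 fs reads "the volume lags the distance by 65 fs".

Estimator details (boundary handling at nonzero lag is a genuine choice,
documented in docs/methods.md): the numerator at lag tau = k·dt sums
x(t_i + tau)·y(t_i) over the overlap region only and divides by the
overlap count N - |k| (lag-wise unbiased), while the denominator is
tau-independent.  A consequence is that |r| can marginally exceed 1 at
extreme lags; values are clipped to [-1, 1] and the overlap count is
reported per lag.  Each directed lag is computed with the identical BLAS
dot product in both argument orders, so r_xy(tau) == r_yx(-tau) holds
bit-exactly.

Significance is by the retention rule |r_xy| > 0.45 (strict): correlation
functions whose extrema never exceed it are kept in the report but flagged
as not retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trajectory import TimeSeries

__all__ = [
    "CrossCorrelation",
    "CorrelationExtremum",
    "CorrelationEntry",
    "CorrelationReport",
    "CorrelationError",
    "RETENTION_THRESHOLD",
    "cross_correlation",
    "find_extrema",
    "filter_significant",
    "correlation_matrix",
]

#: Default retention rule: keep correlation functions with max |r| > 0.45.
RETENTION_THRESHOLD = 0.45

#: Default cap on the lag range as a fraction of the series duration.
MAX_LAG_FRACTION = 0.7

#: Overlap below which a low-overlap warning is emitted.
MIN_OVERLAP_WARN = 30


class CorrelationError(ValueError):
    """Invalid inputs to the cross-correlation estimator."""


@dataclass(frozen=True)
class CrossCorrelation:
    """r_xy on a symmetric lag grid (integer multiples of dt, in fs)."""

    x_name: str
    y_name: str
    lags: np.ndarray     # fs, symmetric about 0
    r: np.ndarray        # clipped to [-1, 1]
    overlap: np.ndarray  # samples per lag, N - |k|
    dt: float

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class CorrelationExtremum:
    """A local extremum of r(tau): the paper-style 'value (delay)' pair."""

    r_value: float
    lag: float  # fs
    sign: str   # "max" | "min"

    def __str__(self) -> str:
        return f"{self.r_value:.2f} ({self.lag:g})"


@dataclass(frozen=True)
class CorrelationEntry:
    """One analysed pair with its extrema and retention flag."""

    pair: tuple
    extrema: tuple
    retained: bool
    self_pair: bool = False


@dataclass(frozen=True)
class CorrelationReport:
    """All analysed pairs; ``retained`` ⇔ some extremum exceeds the threshold."""

    entries: tuple
    threshold: float = RETENTION_THRESHOLD

    def retained_pairs(self) -> list[tuple]:
        return [e.pair for e in self.entries if e.retained]

    def to_records(self) -> list[dict]:
        rows = []
        for entry in self.entries:
            if not entry.extrema:
                rows.append({"x": entry.pair[0], "y": entry.pair[1],
                             "r": np.nan, "lag_fs": np.nan, "sign": "",
                             "retained": entry.retained})
            for ext in entry.extrema:
                rows.append({"x": entry.pair[0], "y": entry.pair[1],
                             "r": ext.r_value, "lag_fs": ext.lag,
                             "sign": ext.sign, "retained": entry.retained})
        return rows

    def format_table(self, significant_only: bool = True) -> str:
        """Render 'r (lag)' cells, one row per pair — the tabular layout
        used for H-bond/volume and H-bond/H-bond reports."""
        lines = [f"{'pair':<50s}  r (lag fs)"]
        for entry in self.entries:
            exts = [e for e in entry.extrema
                    if (not significant_only) or abs(e.r_value) > self.threshold]
            cell = "  ".join(str(e) for e in exts) if exts else "-"
            mark = "" if entry.retained else "   [not retained]"
            pair_label = f"{entry.pair[0]} / {entry.pair[1]}"
            lines.append(f"{pair_label:<50s}  {cell}{mark}")
        return "\n".join(lines)


def cross_correlation(x: TimeSeries, y: TimeSeries,
                      max_lag: float | None = None,
                      max_lag_fraction: float = MAX_LAG_FRACTION,
                      ) -> CrossCorrelation:
    """Normalized cross-correlation r_xy(tau) on the symmetric lag grid.

    Parameters
    ----------
    x, y : TimeSeries
        Must share dt and length (N >= 2) and be non-constant.
    max_lag : float, optional
        Largest |tau| in fs; defaults to ``max_lag_fraction`` of the
        series duration.  Must not exceed that cap.

    Returns
    -------
    CrossCorrelation
        With lags k·dt for k in [-K, K] and r clipped to [-1, 1].
    """
    if x.dt != y.dt:
        raise CorrelationError(f"dt mismatch: {x.dt} vs {y.dt}")
    n = len(x)
    if len(y) != n:
        raise CorrelationError(f"length mismatch: {n} vs {len(y)}")
    if n < 2:
        raise CorrelationError("need at least 2 samples")
    dt = x.dt
    duration = (n - 1) * dt
    cap = max_lag_fraction * duration
    if max_lag is None:
        max_lag = cap
    elif max_lag > cap + 1e-9:
        raise CorrelationError(
            f"max_lag {max_lag} fs exceeds the cap {cap:.6g} fs "
            f"({max_lag_fraction:.0%} of the duration)")
    k_max = int(np.floor(max_lag / dt + 1e-9))
    k_max = min(k_max, n - 1)

    xc = x.values - x.values.mean()
    yc = y.values - y.values.mean()
    mx2 = float(np.dot(xc, xc)) / n
    my2 = float(np.dot(yc, yc)) / n
    if mx2 == 0.0 or my2 == 0.0:
        which = x.name if mx2 == 0.0 else y.name
        raise CorrelationError(f"series {which!r} is constant (zero variance)")
    denom = np.sqrt(mx2 * my2)

    r = np.empty(2 * k_max + 1)
    overlap = np.empty(2 * k_max + 1, dtype=int)
    # k >= 0: sum_i x[i+k] y[i]; k < 0: sum_i y[i+|k|] x[i].  Both branches
    # run np.dot(shifted, base) so swapping (x, y) mirrors the computation
    # bit-exactly.
    for k in range(0, k_max + 1):
        m = n - k
        c_plus = float(np.dot(xc[k:], yc[:m]))
        c_minus = float(np.dot(yc[k:], xc[:m]))
        r[k_max + k] = (c_plus / m) / denom
        r[k_max - k] = (c_minus / m) / denom
        overlap[k_max + k] = overlap[k_max - k] = m
    np.clip(r, -1.0, 1.0, out=r)

    if overlap.min() < MIN_OVERLAP_WARN:
        warnings.warn(
            f"cross_correlation({x.name!r}, {y.name!r}): overlap falls to "
            f"{int(overlap.min())} samples at extreme lags", stacklevel=2)

    lags = dt * np.arange(-k_max, k_max + 1)
    return CrossCorrelation(x_name=x.name, y_name=y.name, lags=lags, r=r,
                            overlap=overlap, dt=dt)


def find_extrema(cc: CrossCorrelation, min_separation: float = 50.0,
                 threshold: float = RETENTION_THRESHOLD,
                 ) -> list[CorrelationExtremum]:
    """Interior local maxima/minima of r(tau), reported as value-(delay) pairs.

    The global |r| extremum (if any interior extremum exists) is always
    reported first, even below the threshold, so every analysed pair has a
    headline value; further extrema must exceed the retention threshold.
    Extrema closer than ``min_separation`` fs keep only the larger |r|.
    Endpoints are never extrema: a monotone r(tau) yields an empty list.
    """
    r, lags = cc.r, cc.lags
    if len(r) < 3:
        return []
    interior = np.arange(1, len(r) - 1)
    is_max = (r[interior] > r[interior - 1]) & (r[interior] > r[interior + 1])
    is_min = (r[interior] < r[interior - 1]) & (r[interior] < r[interior + 1])
    cands = [CorrelationExtremum(float(r[i]), float(lags[i]),
                                 "max" if mx else "min")
             for i, mx, mn in zip(interior, is_max, is_min) if mx or mn]
    if not cands:
        return []
    cands.sort(key=lambda e: abs(e.r_value), reverse=True)
    kept: list[CorrelationExtremum] = [cands[0]]  # global extremum
    for cand in cands[1:]:
        if abs(cand.r_value) <= threshold:
            continue
        if all(abs(cand.lag - k.lag) >= min_separation for k in kept):
            kept.append(cand)
    return kept


def filter_significant(report: CorrelationReport,
                       threshold: float = RETENTION_THRESHOLD,
                       ) -> CorrelationReport:
    """Re-flag entries by the retention rule max |r| > threshold (strict).

    All entries are kept in the report; only the ``retained`` flags (and
    the report threshold) change.
    """
    if not 0.0 < threshold < 1.0:
        raise CorrelationError(f"threshold must be in (0, 1), got {threshold}")
    entries = tuple(
        replace(e, retained=any(abs(x.r_value) > threshold for x in e.extrema))
        for e in report.entries)
    return CorrelationReport(entries=entries, threshold=threshold)


def correlation_matrix(series: Sequence[TimeSeries],
                       pairs: Sequence[tuple],
                       max_lag: float | None = None,
                       max_lag_fraction: float = MAX_LAG_FRACTION,
                       threshold: float = RETENTION_THRESHOLD,
                       min_separation: float = 50.0) -> CorrelationReport:
    """Cross-correlation report over a roster of named series pairs.

    ``pairs`` is a list of (x_name, y_name).  A pair with x == y is
    computed (r(0) = 1, trivially retained) and flagged as a self-pair.
    """
    by_name = {ts.name: ts for ts in series}
    entries = []
    for x_name, y_name in pairs:
        for name in (x_name, y_name):
            if name not in by_name:
                raise CorrelationError(f"unknown series name {name!r}")
        self_pair = x_name == y_name
        cc = cross_correlation(by_name[x_name], by_name[y_name],
                               max_lag=max_lag,
                               max_lag_fraction=max_lag_fraction)
        extrema = tuple(find_extrema(cc, min_separation=min_separation,
                                     threshold=threshold))
        retained = any(abs(e.r_value) > threshold for e in extrema)
        entries.append(CorrelationEntry(pair=(x_name, y_name), extrema=extrema,
                                        retained=retained, self_pair=self_pair))
    return CorrelationReport(entries=tuple(entries), threshold=threshold)
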