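"""Time-delayed correlations and asymmetry-based causality detection.

For an ordered site pair (i, j) the lagged correlation

    C_ij(tau) = < dR_i(t) . dR_j(t + tau) >_t

is estimated over the truncated overlap (only frames with both endpoints in
range; the denominator is the count of valid pairs).  Asymmetry between
C_ij(tau) and C_ji(tau) at a positive lag indicates that i's fluctuations
carry information about j's future (i "drives" j); at tau = 0 the two
directions are identical by construction.

Two estimators are provided.  The default ``direct`` estimator is the plain
lagged-product average.  The ``binned`` estimator makes the conditional
construction explicit: per spatial component, values of dR_i(t) are split
into equal-count bins, the conditional mean of dR_j(t + tau) given the bin
is formed, and the correlation is recombined as
sum_bins p(bin) * <dR_i>_bin * <dR_j|bin>, summed over components.  By the
law of total expectation both estimate the same quantity; their agreement is
a fidelity check, tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import BinningError
from .trajectory_io import FluctuationSeries, SiteLabel

__all__ = [
    "DelayedCorrelationCurve",
    "CausalityEdge",
    "connectivity_fluctuation",
    "delayed_autocorrelation",
    "decay_time",
    "delayed_cross_correlation",
    "causality_scan",
    "edges_to_graph",
    "DEFAULT_MIN_STRENGTH",
    "DEFAULT_MIN_ASYMMETRY",
    "DEFAULT_N_BINS",
]

DEFAULT_MIN_STRENGTH = 0.2
DEFAULT_MIN_ASYMMETRY = 0.1
DEFAULT_N_BINS = 20
_MIN_SAMPLES_PER_BIN = 10


@dataclass(frozen=True)
class DelayedCorrelationCurve:
    """C(tau) over an ascending lag grid for one ordered pair (or self)."""

    lags: np.ndarray
    values: np.ndarray
    pair: tuple
    normalized: bool
    estimator: str = "direct"
    normalization: str = "c0"

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        if lags.shape != values.shape or lags.ndim != 1:
            raise ValueError("lags and values must be matching 1-D arrays")
        if lags.size and (np.diff(lags) <= 0).any():
            raise ValueError("lags must be strictly increasing")
        if self.normalized:
            if lags.size == 0 or lags[0] != 0:
                raise ValueError("a normalized curve must start at lag 0")
            if abs(values[0] - 1.0) > 1e-12:
                raise ValueError("normalized curve must have value 1 at lag 0")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class CausalityEdge:
    """Directed influence: `driver`'s fluctuations correlate with `follower`'s future."""

    driver: int
    follower: int
    lag: float
    c_forward: float
    c_backward: float
    driver_label: SiteLabel | None = None
    follower_label: SiteLabel | None = None

    def __post_init__(self) -> None:
        if self.lag <= 0:
            raise ValueError("lag must be positive")
        if not self.c_forward > self.c_backward:
            raise ValueError("driver direction must have the larger correlation")

    @property
    def asymmetry(self) -> float:
        return self.c_forward - self.c_backward

    @property
    def strength(self) -> float:
        return max(abs(self.c_forward), abs(self.c_backward))


# ---------------------------------------------------------------------------
# building blocks


def connectivity_fluctuation(fluct: FluctuationSeries, i, j) -> np.ndarray:
    """Per-frame difference vector v(t) = dR_i(t) - dR_j(t), shape (frames, 3).

    The sign convention is fixed (i minus j); autocorrelations are invariant
    to it.
    """
    ii, jj = fluct.site_index(i), fluct.site_index(j)
    if ii == jj:
        raise ValueError("i and j must be distinct sites")
    return fluct.deltas[:, ii] - fluct.deltas[:, jj]


def _lag_to_frames(lag: float, dt: float) -> int:
    n = lag / dt
    n_round = round(n)
    if abs(n - n_round) > 1e-6:
        raise ValueError(f"lag {lag} ps is not a multiple of dt = {dt} ps")
    return int(n_round)


def _raw_lagged(x: np.ndarray, y: np.ndarray, lag_frames: int) -> float:
    """mean_t x(t).y(t+lag) over the truncated overlap; x, y are (F, 3)."""
    n = x.shape[0] - lag_frames
    if n <= 0:
        raise ValueError("lag exceeds series length")
    return float(np.einsum("tc,tc->", x[:n], y[lag_frames:]) / n)


def _binned_lagged(
    x: np.ndarray, y: np.ndarray, lag_frames: int, n_bins: int
) -> float:
    """Conditional-average estimator of mean_t x(t).y(t+lag).

    Per component: equal-count bins on x(t); within each bin the conditional
    mean of y(t+lag) is paired with the bin mean of x; recombined weighted by
    the bin probability.
    """
    n = x.shape[0] - lag_frames
    if n <= 0:
        raise ValueError("lag exceeds series length")
    if n // n_bins < _MIN_SAMPLES_PER_BIN:
        raise BinningError(
            f"{n} samples over {n_bins} bins gives < {_MIN_SAMPLES_PER_BIN} per bin; "
            f"use at most {max(1, n // _MIN_SAMPLES_PER_BIN)} bins"
        )
    total = 0.0
    bounds = np.linspace(0, n, n_bins + 1).astype(int)
    for c in range(x.shape[1]):
        xc = x[:n, c]
        yc = y[lag_frames:, c]
        order = np.argsort(xc, kind="stable")
        for b in range(n_bins):
            sel = order[bounds[b] : bounds[b + 1]]
            p = sel.size / n
            total += p * xc[sel].mean() * yc[sel].mean()
    return total


def delayed_autocorrelation(
    series: np.ndarray,
    dt: float,
    max_lag: float,
    lag_stride: float | None = None,
) -> DelayedCorrelationCurve:
    """Normalized time-delayed autocorrelation of a 3-D vector series.

    C(tau) = <v(t).v(t+tau)>_t / <|v(t)|^2>, computed on the truncated
    overlap.  ``max_lag`` and ``lag_stride`` in ps; the stride must be a
    multiple of dt (default: dt itself).
    """
    v = np.asarray(series, dtype=np.float64)
    if v.ndim == 1:
        v = v[:, None]
    duration = (v.shape[0] - 1) * dt
    if max_lag >= duration:
        raise ValueError(f"max_lag {max_lag} ps >= series duration {duration} ps")
    stride_frames = _lag_to_frames(lag_stride if lag_stride is not None else dt, dt)
    if stride_frames < 1:
        raise ValueError("lag_stride must be at least dt")
    max_frames = int(math.floor(max_lag / dt + 1e-9))
    lag_frames = np.arange(0, max_frames + 1, stride_frames)
    raw = np.array([_raw_lagged(v, v, L) for L in lag_frames])
    if raw[0] <= 0:
        raise ValueError("zero-variance series: autocorrelation undefined")
    return DelayedCorrelationCurve(
        lags=lag_frames * dt,
        values=raw / raw[0],
        pair=("self", "self"),
        normalized=True,
        estimator="direct",
        normalization="c0",
    )


def decay_time(curve: DelayedCorrelationCurve, level: float = 1.0 / math.e) -> float | None:
    """First downward crossing of `level`, linearly interpolated; None if the
    curve never drops below the level within its lag range."""
    if not curve.normalized:
        raise ValueError("decay_time requires a normalized curve")
    vals, lags = curve.values, curve.lags
    below = vals < level
    if not below.any():
        return None
    k = int(np.argmax(below))
    if k == 0:  # normalized curves start at 1 > 1/e, defensive only
        return float(lags[0])
    v0, v1 = vals[k - 1], vals[k]
    frac = (v0 - level) / (v0 - v1)
    return float(lags[k - 1] + frac * (lags[k] - lags[k - 1]))


def delayed_cross_correlation(
    fluct: FluctuationSeries,
    i,
    j,
    lags: Sequence[float],
    estimator: str = "direct",
    normalization: str = "c0",
    n_bins: int = DEFAULT_N_BINS,
) -> DelayedCorrelationCurve:
    """C_ij(tau) on a lag grid (ps) for the ordered pair source i -> target j.

    normalization:
      * ``"c0"`` (default, the figure convention): divide by C_ij(0);
      * ``"pearson"``: divide by sqrt(C_ii(0) * C_jj(0)) — robust when the
        equal-time cross-correlation is near zero;
      * ``"none"``: raw lagged products (A^2).
    """
    ii, jj = fluct.site_index(i), fluct.site_index(j)
    if estimator not in ("direct", "binned"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if normalization not in ("c0", "pearson", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    lag_arr = np.asarray(lags, dtype=np.float64)
    if lag_arr.ndim != 1 or lag_arr.size == 0:
        raise ValueError("lags must be a non-empty 1-D grid")
    if (lag_arr < 0).any() or (np.diff(lag_arr) <= 0).any():
        raise ValueError("lags must be non-negative and strictly increasing")
    if lag_arr[-1] >= fluct.duration:
        raise ValueError(f"max lag {lag_arr[-1]} ps >= duration {fluct.duration} ps")
    if normalization == "c0" and lag_arr[0] != 0:
        raise ValueError("c0 normalization requires the grid to start at 0")

    x = fluct.deltas[:, ii]
    y = fluct.deltas[:, jj]
    frames = [_lag_to_frames(l, fluct.dt) for l in lag_arr]
    if estimator == "direct":
        raw = np.array([_raw_lagged(x, y, L) for L in frames])
    else:
        raw = np.array([_binned_lagged(x, y, L, n_bins) for L in frames])

    if normalization == "none":
        values, normalized = raw, False
    elif normalization == "c0":
        if estimator == "direct":
            c0 = _raw_lagged(x, y, 0)
        else:
            c0 = _binned_lagged(x, y, 0, n_bins)
        if c0 == 0:
            raise ValueError("C(0) is zero for this pair; use pearson or none")
        values, normalized = raw / c0, True
    else:
        denom = math.sqrt(_raw_lagged(x, x, 0) * _raw_lagged(y, y, 0))
        if denom == 0:
            raise ValueError("zero-variance site; pearson normalization undefined")
        values, normalized = raw / denom, False

    return DelayedCorrelationCurve(
        lags=lag_arr,
        values=values,
        pair=(fluct.site_labels[ii], fluct.site_labels[jj]) if ii != jj else ("self", "self"),
        normalized=normalized,
        estimator=estimator,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# causality scan


def causality_scan(
    fluct: FluctuationSeries,
    lag: float,
    min_strength: float = DEFAULT_MIN_STRENGTH,
    min_asymmetry: float = DEFAULT_MIN_ASYMMETRY,
    pairs: Iterable[tuple] | None = None,
) -> list[CausalityEdge]:
    """Scan site pairs for asymmetric lagged correlation at one lag (ps).

    For each unordered pair, both C_ij(lag) and C_ji(lag) are estimated with
    the direct estimator and Pearson-normalized (by sqrt(C_ii(0) C_jj(0)), a
    shared symmetric denominator, so the asymmetry is exactly the normalized
    raw difference).  An edge is emitted with the larger-valued direction as
    driver when strength >= min_strength and the asymmetry >=
    min_asymmetry; pairs below either threshold yield no edge — never an
    arbitrary direction.  Output is sorted by asymmetry descending, ties
    broken by site indices, so results are deterministic.
    """
    if lag <= 0:
        raise ValueError("lag must be positive")
    if lag >= fluct.duration:
        raise ValueError(f"lag {lag} ps >= duration {fluct.duration} ps")
    if not (0 <= min_strength <= 1 and 0 <= min_asymmetry <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    L = _lag_to_frames(lag, fluct.dt)
    d = fluct.deltas
    n_t = d.shape[0] - L

    if pairs is None:
        iu, ju = np.triu_indices(fluct.n_sites, k=1)
        pair_list = list(zip(iu.tolist(), ju.tolist()))
    else:
        pair_list = []
        for a, b in pairs:
            ia, ib = fluct.site_index(a), fluct.site_index(b)
            if ia == ib:
                raise ValueError("pairs must consist of distinct sites")
            pair_list.append((min(ia, ib), max(ia, ib)))

    sites = sorted({s for p in pair_list for s in p})
    # lagged gram over needed sites: fwd[a, b] = <dR_a(t) . dR_b(t+L)>
    sub = {s: k for k, s in enumerate(sites)}
    X = d[:n_t][:, sites]
    Y = d[L:][:, sites]
    fwd = np.einsum("tic,tjc->ij", X, Y) / n_t
    var0 = np.einsum("tic,tic->i", d[:, sites], d[:, sites]) / d.shape[0]

    edges: list[CausalityEdge] = []
    for a, b in pair_list:
        ka, kb = sub[a], sub[b]
        denom = math.sqrt(var0[ka] * var0[kb])
        if denom == 0:
            continue
        c_ab = fwd[ka, kb] / denom
        c_ba = fwd[kb, ka] / denom
        if c_ab >= c_ba:
            drv, fol, c_f, c_b = a, b, c_ab, c_ba
        else:
            drv, fol, c_f, c_b = b, a, c_ba, c_ab
        if max(abs(c_f), abs(c_b)) < min_strength:
            continue
        if c_f - c_b < min_asymmetry:
            continue
        edges.append(
            CausalityEdge(
                driver=drv,
                follower=fol,
                lag=lag,
                c_forward=c_f,
                c_backward=c_b,
                driver_label=fluct.site_labels[drv],
                follower_label=fluct.site_labels[fol],
            )
        )
    edges.sort(key=lambda e: (-e.asymmetry, e.driver, e.follower))
    return edges


def edges_to_graph(edges: Sequence[CausalityEdge]):
    """Directed networkx graph with edge attributes (for GraphML export)."""
    import networkx as nx

    g = nx.DiGraph()
    for e in edges:
        drv = str(e.driver_label) if e.driver_label is not None else str(e.driver)
        fol = str(e.follower_label) if e.follower_label is not None else str(e.follower)
        g.add_edge(
            drv,
            fol,
            lag=float(e.lag),
            c_forward=float(e.c_forward),
            c_backward=float(e.c_backward),
            asymmetry=float(e.asymmetry),
            strength=float(e.strength),
        )
    return g
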