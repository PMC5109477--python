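"""Equal-time cross-correlation maps and residue-pair distance distributions.

The map entry is the normalized dot-product correlation

    C_ij = <dR_i . dR_j> / sqrt(<|dR_i|^2> <|dR_j|^2>),

bounded in [-1, 1] with C_ii = 1.  Zero-variance (frozen) sites yield NaN
entries plus a warning rather than an exception so full-protein maps survive
frozen atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import CoordinateEnsemble, FluctuationSeries, SiteLabel

__all__ = [
    "CorrelationMap",
    "DistanceDistribution",
    "cross_correlation_map",
    "threshold_map",
    "pair_distance_series",
    "distance_distribution",
    "DEFAULT_POS_MIN",
    "DEFAULT_NEG_MAX",
]

#: display-threshold defaults for :func:`threshold_map`
DEFAULT_POS_MIN = 0.6
DEFAULT_NEG_MAX = -0.45


@dataclass(frozen=True)
class CorrelationMap:
    """Symmetric dimensionless site x site correlation matrix."""

    C: np.ndarray
    site_labels: tuple[SiteLabel, ...]

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=np.float64)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        finite = np.isfinite(C)
        if not np.array_equal(np.where(finite, C, 0.0), np.where(finite.T, C.T, 0.0)):
            raise ValueError("C must be symmetric")
        if finite.any() and (np.abs(C[finite]) > 1 + 1e-9).any():
            raise ValueError("correlation entries must lie in [-1, 1]")
        diag = np.diag(C)
        ok = np.isfinite(diag)
        if ok.any() and np.abs(diag[ok] - 1).max() > 1e-12:
            raise ValueError("diagonal must equal 1")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "site_labels", tuple(SiteLabel(*l) for l in self.site_labels))
        if len(self.site_labels) != C.shape[0]:
            raise ValueError("one label per site required")

    @property
    def n_sites(self) -> int:
        return self.C.shape[0]

    def to_frame(self) -> pd.DataFrame:
        names = [str(lab) for lab in self.site_labels]
        return pd.DataFrame(self.C, index=names, columns=names)


def cross_correlation_map(fluct: FluctuationSeries) -> CorrelationMap:
    """Normalized equal-time dot-product correlation for every site pair."""
    flat = fluct.deltas.transpose(1, 0, 2).reshape(fluct.n_sites, -1)
    gram = (flat @ flat.T) / fluct.n_frames
    sq = np.diag(gram).copy()
    zero_var = sq <= 0
    if zero_var.any():
        idx = [str(fluct.site_labels[i]) for i in np.flatnonzero(zero_var)]
        warnings.warn(
            f"zero-variance site(s) {idx}: correlation entries undefined", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        C = gram / np.sqrt(np.outer(sq, sq))
    C[zero_var, :] = np.nan
    C[:, zero_var] = np.nan
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, np.where(zero_var, np.nan, 1.0))
    C = np.where(np.isfinite(C), (C + np.where(np.isfinite(C.T), C.T, C)) / 2.0, np.nan)
    return CorrelationMap(C=C, site_labels=fluct.site_labels)


def threshold_map(
    C: CorrelationMap,
    pos_min: float = DEFAULT_POS_MIN,
    neg_max: float = DEFAULT_NEG_MAX,
) -> np.ndarray:
    """Tri-valued display mask: +1 where C >= pos_min, -1 where C <= neg_max,
    0 elsewhere (both boundaries inclusive).  NaN entries map to 0."""
    if not (-1 <= neg_max < pos_min <= 1):
        raise ValueError(
            f"need -1 <= neg_max < pos_min <= 1, got neg_max={neg_max}, pos_min={pos_min}"
        )
    mask = np.zeros_like(C.C, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        mask[C.C >= pos_min] = 1
        mask[C.C <= neg_max] = -1
    return mask


def pair_distance_series(ensemble: CoordinateEnsemble, i, j) -> np.ndarray:
    """Per-frame Euclidean distance R_ij(t) between two sites, in Angstrom."""
    labels = ensemble.site_labels
    def resolve(s):
        if isinstance(s, (int, np.integer)):
            return int(s) % len(labels)
        return labels.index(SiteLabel(*s))
    ii, jj = resolve(i), resolve(j)
    if ii == jj:
        raise ValueError("i and j must be distinct sites")
    return np.linalg.norm(ensemble.coords[:, ii] - ensemble.coords[:, jj], axis=1)


@dataclass(frozen=True)
class DistanceDistribution:
    """Normalized (unit-integral) histogram of a pair-distance series."""

    bin_edges: np.ndarray
    density: np.ndarray
    pair: tuple
    n_samples: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        dens = np.asarray(self.density, dtype=np.float64)
        if edges.ndim != 1 or dens.shape != (edges.size - 1,):
            raise ValueError("bin_edges must be 1-D with len(density) + 1 entries")
        if (dens < 0).any():
            raise ValueError("density must be non-negative")
        mass = float(np.sum(dens * np.diff(edges)))
        if abs(mass - 1.0) > 1e-9:
            raise ValueError(f"density must integrate to 1, got {mass}")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "density", dens)

    @property
    def peak(self) -> float:
        """Centre of the highest-density bin."""
        b = int(np.argmax(self.density))
        return float((self.bin_edges[b] + self.bin_edges[b + 1]) / 2.0)

    @property
    def bin_width(self) -> np.ndarray:
        return np.diff(self.bin_edges)


def distance_distribution(
    series: np.ndarray, bins: int | float = 100, pair: tuple = (0, 1)
) -> DistanceDistribution:
    """Histogram a distance series over its observed [min, max] range.

    ``bins`` is a bin count if integral, otherwise a bin width in Angstrom.
    The result is a density (unit integral).  A constant series produces a
    single narrow bin carrying all the mass.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 1:
        raise ValueError("series must be a non-empty 1-D array")
    lo, hi = float(series.min()), float(series.max())
    if hi == lo:
        width = 2.0**-20  # power of two: density * width is exactly 1
        edges = np.array([lo - width / 2, lo + width / 2])
        density = np.array([1.0 / width])
        return DistanceDistribution(edges, density, tuple(pair), series.size)
    if isinstance(bins, (int, np.integer)):
        n_bins = int(bins)
    else:
        n_bins = max(1, int(np.ceil((hi - lo) / float(bins))))
    if n_bins < 1:
        raise ValueError("bin spec must be positive")
    density, edges = np.histogram(series, bins=n_bins, range=(lo, hi), density=True)
    return DistanceDistribution(edges, density, tuple(pair), series.size)
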