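"""Pairwise spring constants from fluctuation covariances.

An effective harmonic spring between sites i and j has constant

    k_ij = kB * T / ( <|dR_i|^2> - 2 <dR_i . dR_j> + <|dR_j|^2> )

i.e. kB*T divided by the mean squared fluctuation of the pair separation,
<|dR_i - dR_j|^2>.  Averages are time averages over frames; squared terms
are 3-D squared norms and the cross term the 3-D dot product.  Units:
kcal/(mol A^2), convertible to pN/nm with :func:`convert_stiffness_units`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .trajectory_io import FluctuationSeries, SiteLabel

__all__ = [
    "KB_KCAL_MOL_K",
    "PN_NM_PER_KCAL_MOL_A2",
    "DEFAULT_TEMPERATURE_K",
    "SpringConstantMatrix",
    "StabilityReport",
    "OverallMethod",
    "pairwise_spring_constants",
    "mean_spring_constant",
    "overall_spring_constant",
    "stiffness_difference",
    "convert_stiffness_units",
    "stability_report",
]

#: Boltzmann constant in kcal/(mol K) (CODATA, molar form)
KB_KCAL_MOL_K = 1.98720425864e-3

#: 1 kcal/(mol A^2) in pN/nm: 4184 J/kcal / N_A / 1e-20 m^2 -> N/m, x1e3
PN_NM_PER_KCAL_MOL_A2 = 4184.0 / 6.02214076e23 / 1e-20 * 1e3

#: physiological default temperature
DEFAULT_TEMPERATURE_K = 310.0


class OverallMethod(str, Enum):
    """Aggregation used by :func:`overall_spring_constant`."""

    PAIR_MEAN = "pair-mean"
    SITE_MEAN = "site-mean"


@dataclass(frozen=True)
class SpringConstantMatrix:
    """Symmetric site x site spring-constant matrix.

    The diagonal is undefined by construction (the denominator is zero for
    i == j) and is stored as NaN; rigidly co-moving pairs (zero denominator
    off the diagonal) are flagged +inf.  Both are excluded from every
    aggregate in this module.
    """

    k: np.ndarray
    temperature: float
    site_labels: tuple[SiteLabel, ...]

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=np.float64)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("k must be square")
        off = ~np.eye(k.shape[0], dtype=bool)
        if not np.array_equal(k[off], k.T[off]):
            raise ValueError("k must be exactly symmetric")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "site_labels", tuple(SiteLabel(*l) for l in self.site_labels))
        if len(self.site_labels) != k.shape[0]:
            raise ValueError("one label per site required")

    @property
    def n_sites(self) -> int:
        return self.k.shape[0]

    def valid_mask(self) -> np.ndarray:
        """Off-diagonal entries that are finite (not flagged, not diagonal)."""
        return np.isfinite(self.k) & ~np.eye(self.n_sites, dtype=bool)

    def flagged_pairs(self) -> list[tuple[int, int]]:
        """Unordered (i, j), i < j, flagged infinite-stiffness."""
        iu, ju = np.triu_indices(self.n_sites, k=1)
        flag = np.isinf(self.k[iu, ju])
        return list(zip(iu[flag].tolist(), ju[flag].tolist()))

    def to_frame(self) -> pd.DataFrame:
        names = [str(lab) for lab in self.site_labels]
        return pd.DataFrame(self.k, index=names, columns=names)


def pairwise_spring_constants(
    fluct: FluctuationSeries, temperature: float = DEFAULT_TEMPERATURE_K
) -> SpringConstantMatrix:
    """Estimate k_ij for every site pair from a fluctuation series.

    The denominator <|dR_i - dR_j|^2> is computed from the time-averaged
    second moments; it is non-negative by construction.  Zero denominators
    off the diagonal mark rigidly co-moving pairs and yield +inf entries.
    """
    if fluct.n_sites < 2:
        raise ValueError("need >= 2 sites")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    d = fluct.deltas  # (F, S, 3)
    # gram[i, j] = <dR_i . dR_j> over frames
    flat = d.transpose(1, 0, 2).reshape(fluct.n_sites, -1)
    gram = (flat @ flat.T) / fluct.n_frames
    sq = np.diag(gram)
    denom = sq[:, None] + sq[None, :] - 2.0 * gram
    denom = np.where(denom < 0, 0.0, denom)  # guard rounding
    with np.errstate(divide="ignore"):
        k = KB_KCAL_MOL_K * temperature / denom
    np.fill_diagonal(k, np.nan)
    k = (k + k.T) / 2.0  # enforce exact symmetry against rounding
    return SpringConstantMatrix(k=k, temperature=temperature, site_labels=fluct.site_labels)


def mean_spring_constant(K: SpringConstantMatrix) -> np.ndarray:
    """Per-site mean of k_ij over the N-1 partners, skipping flagged entries.

    Sites whose partners are all flagged get NaN.
    """
    if K.n_sites < 2:
        raise ValueError("need >= 2 sites")
    valid = K.valid_mask()
    counts = valid.sum(axis=1)
    sums = np.where(valid, K.k, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means


def overall_spring_constant(
    K: SpringConstantMatrix, method: OverallMethod | str = OverallMethod.PAIR_MEAN
) -> float:
    """Scalar stiffness of the whole system.

    ``pair-mean`` (default) averages k_ij over all distinct unordered pairs;
    ``site-mean`` averages the per-site means.  Both agree for uniform
    matrices; both skip flagged entries.
    """
    method = OverallMethod(method)
    if method is OverallMethod.PAIR_MEAN:
        iu, ju = np.triu_indices(K.n_sites, k=1)
        vals = K.k[iu, ju]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")
    means = mean_spring_constant(K)
    means = means[np.isfinite(means)]
    return float(means.mean()) if means.size else float("nan")


def stiffness_difference(
    K_a: SpringConstantMatrix, K_b: SpringConstantMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Delta k_ij = k_a - k_b and the per-site mean differences.

    Entries flagged (inf) or undefined (diagonal NaN) in either input
    propagate as NaN in the difference.  Inputs must share labels and
    temperature.
    """
    if K_a.site_labels != K_b.site_labels:
        only_a = set(K_a.site_labels) - set(K_b.site_labels)
        only_b = set(K_b.site_labels) - set(K_a.site_labels)
        raise AlignmentError(
            f"site labels differ (only in A: {sorted(map(str, only_a))}, "
            f"only in B: {sorted(map(str, only_b))})"
        )
    if K_a.temperature != K_b.temperature:
        raise AlignmentError(
            f"temperatures differ: {K_a.temperature} K vs {K_b.temperature} K"
        )
    both_valid = K_a.valid_mask() & K_b.valid_mask()
    diff = np.where(both_valid, K_a.k - K_b.k, np.nan)
    mean_diff = mean_spring_constant(K_a) - mean_spring_constant(K_b)
    return diff, mean_diff


def convert_stiffness_units(value, direction: str = "to_pn_per_nm"):
    """Convert stiffness between kcal/(mol A^2) and pN/nm.

    direction: ``"to_pn_per_nm"`` multiplies by ~694.77, ``"to_kcal_mol_A2"``
    divides.  Accepts scalars or arrays.
    """
    value = np.asarray(value, dtype=np.float64)
    if direction == "to_pn_per_nm":
        out = value * PN_NM_PER_KCAL_MOL_A2
    elif direction == "to_kcal_mol_A2":
        out = value / PN_NM_PER_KCAL_MOL_A2
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StabilityReport:
    """Per-site joint RMSF/stiffness comparison between two states.

    classification per site:
      * ``more-stable-in-A``: RMSF_A < RMSF_B and mean_k_A > mean_k_B
      * ``more-stable-in-B``: RMSF_B < RMSF_A and mean_k_B > mean_k_A
      * ``unchanged``: both quantities within rel_tolerance
      * ``mixed``: anything else (the two indicators disagree)
    """

    table: pd.DataFrame
    rel_tolerance: float

    def counts(self) -> dict[str, int]:
        return self.table["classification"].value_counts().to_dict()


def stability_report(
    rmsf_a: np.ndarray,
    rmsf_b: np.ndarray,
    meank_a: np.ndarray,
    meank_b: np.ndarray,
    site_labels: Sequence[SiteLabel] | None = None,
    rel_tolerance: float = 1e-6,
) -> StabilityReport:
    """Classify each site by the joint (reduced RMSF, increased stiffness) rule."""
    arrs = [np.asarray(a, dtype=np.float64) for a in (rmsf_a, rmsf_b, meank_a, meank_b)]
    n = arrs[0].shape[0]
    if any(a.shape != (n,) for a in arrs):
        raise AlignmentError("rmsf/mean-k inputs must be equal-length 1-D arrays")
    if site_labels is not None and len(site_labels) != n:
        raise AlignmentError(f"{len(site_labels)} labels for {n} sites")
    rmsf_a, rmsf_b, meank_a, meank_b = arrs

    def sig(x, y):
        scale = np.maximum(np.abs(x), np.abs(y))
        return np.abs(x - y) > rel_tolerance * np.maximum(scale, 1e-300)

    rmsf_sig = sig(rmsf_a, rmsf_b)
    k_sig = sig(meank_a, meank_b)
    cls = np.full(n, "mixed", dtype=object)
    cls[~rmsf_sig & ~k_sig] = "unchanged"
    cls[rmsf_sig & k_sig & (rmsf_a < rmsf_b) & (meank_a > meank_b)] = "more-stable-in-A"
    cls[rmsf_sig & k_sig & (rmsf_b < rmsf_a) & (meank_b > meank_a)] = "more-stable-in-B"

    table = pd.DataFrame(
        {
            "site": [str(l) for l in site_labels] if site_labels is not None else np.arange(n),
            "rmsf_A": rmsf_a,
            "rmsf_B": rmsf_b,
            "mean_k_A": meank_a,
            "mean_k_B": meank_b,
            "classification": cls,
        }
    )
    return StabilityReport(table=table, rel_tolerance=rel_tolerance)
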