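"""Synthetic fluctuation generators with analytic oracles.

Two generator families make every estimator in the package testable without
MD data:

* i.i.d. Gaussian ensembles with a prescribed per-component site covariance
  (:func:`sample_gaussian_ensemble`) — the structure consumed by the
  stiffness and equal-time correlation estimators;
* coupled Ornstein-Uhlenbeck networks with asymmetric lagged coupling
  (:func:`simulate_ou_network`), whose exact stationary and lagged
  covariances follow from a Lyapunov equation
  (:func:`analytic_lagged_covariance`) — ground truth for the time-delayed
  estimators and the causality scan.

Each spatial component evolves independently (isotropy), matching the
dot-product estimators' assumptions and keeping the oracles closed-form.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov

from .errors import SpecError
from .trajectory_io import FluctuationSeries, SiteLabel

__all__ = [
    "GaussianEnsembleSpec",
    "OUNetworkSpec",
    "sample_gaussian_ensemble",
    "simulate_ou_network",
    "analytic_lagged_covariance",
    "make_driver_follower_chain",
    "brute_force_lagged_correlation",
    "synthetic_labels",
]

#: burn-in discarded by simulate_ou_network, in units of the slowest
#: relaxation time (10 / min Re eigenvalue of A); fixed, not configurable,
#: so downstream statistics are stable.
BURN_IN_RELAXATION_TIMES = 10.0


def synthetic_labels(n_sites: int) -> list[SiteLabel]:
    """Placeholder residue labels S1..Sn for generated series."""
    return [SiteLabel(k + 1, "SYN", "CA", "A") for k in range(n_sites)]


def _center(deltas: np.ndarray) -> np.ndarray:
    return deltas - deltas.mean(axis=0)


@dataclass(frozen=True)
class GaussianEnsembleSpec:
    """i.i.d. frames; each spatial component drawn from N(0, S)."""

    n_sites: int
    S: np.ndarray  # per-component site covariance, A^2
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=np.float64)
        if S.shape != (self.n_sites, self.n_sites):
            raise SpecError(f"S must be {self.n_sites} x {self.n_sites}, got {S.shape}")
        if not np.allclose(S, S.T, atol=1e-12):
            raise SpecError("S must be symmetric")
        eigvals = np.linalg.eigvalsh(S)
        if eigvals.min() < -1e-10 * max(abs(eigvals.max()), 1.0):
            raise SpecError(f"S is not positive semi-definite (eigenvalue {eigvals.min():.3g})")
        if self.n_frames < 2:
            raise SpecError("n_frames must be >= 2")
        if self.seed is None:
            raise SpecError("seed is mandatory")
        object.__setattr__(self, "S", S)


def sample_gaussian_ensemble(spec: GaussianEnsembleSpec) -> FluctuationSeries:
    """Draw an i.i.d. Gaussian fluctuation series; <dR_i . dR_j> = 3 S_ij.

    The three spatial components are independent draws from N(0, S).  The
    output is mean-centred per site (an O(1/n_frames) correction to the
    target covariance).
    """
    rng = np.random.default_rng(spec.seed)
    eigvals, eigvecs = np.linalg.eigh(spec.S)
    root = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))
    z = rng.standard_normal((spec.n_frames, 3, spec.n_sites))
    deltas = np.einsum("ij,tcj->tic", root, z)
    return FluctuationSeries(
        deltas=_center(deltas),
        means=np.zeros((spec.n_sites, 3)),
        dt=1.0,
        site_labels=synthetic_labels(spec.n_sites),
        source=f"gaussian_ensemble(seed={spec.seed}, n_frames={spec.n_frames})",
    )


@dataclass(frozen=True)
class OUNetworkSpec:
    """Coupled OU network dX = -A X dt + B dW, independently per component.

    A is the site-coupling drift matrix (1/ps); B the noise amplitude matrix
    (A/sqrt(ps)).  Stationarity requires every eigenvalue of A to have a
    positive real part, and Euler-Maruyama fidelity requires
    dt <= 0.1 / max |eigenvalue(A)|.
    """

    n_sites: int
    A: np.ndarray
    B: np.ndarray
    dt: float
    n_steps: int
    seed: int
    ground_truth_edges: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.float64)
        B = np.asarray(self.B, dtype=np.float64)
        n = self.n_sites
        if A.shape != (n, n) or B.shape != (n, n):
            raise SpecError(f"A and B must be {n} x {n}")
        eigs = np.linalg.eigvals(A)
        if eigs.real.min() <= 0:
            raise SpecError(
                f"drift matrix is not stable: eigenvalue {eigs[np.argmin(eigs.real)]:.4g} "
                "has non-positive real part"
            )
        bound = 0.1 / np.abs(eigs).max()
        if self.dt > bound + 1e-12:
            raise SpecError(
                f"dt = {self.dt} ps exceeds the discretization bound "
                f"0.1/max|eig(A)| = {bound:.4g} ps"
            )
        if self.dt <= 0 or self.n_steps < 2:
            raise SpecError("dt must be positive and n_steps >= 2")
        if self.seed is None:
            raise SpecError("seed is mandatory")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "ground_truth_edges", tuple(tuple(e) for e in self.ground_truth_edges))

    @property
    def min_relaxation_rate(self) -> float:
        return float(np.linalg.eigvals(self.A).real.min())


def simulate_ou_network(spec: OUNetworkSpec) -> FluctuationSeries:
    """Euler-Maruyama integration of the OU network, one sample path.

    A burn-in of 10 slowest relaxation times is simulated and discarded so
    the retained ``n_steps`` frames are (approximately) stationary; the
    output is then mean-centred per site.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    burn = int(math.ceil(BURN_IN_RELAXATION_TIMES / spec.min_relaxation_rate / spec.dt))
    total = burn + spec.n_steps
    # pre-transform all noise increments in one pass: sqrt(dt) * B W_t
    noise = math.sqrt(spec.dt) * np.einsum(
        "ij,tjc->tic", spec.B, rng.standard_normal((total, n, 3))
    )
    M = np.eye(n) - spec.A * spec.dt
    X = np.zeros((n, 3))
    out = np.empty((spec.n_steps, n, 3))
    for t in range(total):
        X = M @ X + noise[t]
        if t >= burn:
            out[t - burn] = X
    return FluctuationSeries(
        deltas=_center(out),
        means=np.zeros((n, 3)),
        dt=spec.dt,
        site_labels=synthetic_labels(n),
        source=f"ou_network(seed={spec.seed}, n_steps={spec.n_steps}, dt={spec.dt})",
    )


def analytic_lagged_covariance(A: np.ndarray, B: np.ndarray, lag: float) -> np.ndarray:
    """Exact per-component lagged covariance of the stationary OU network.

    Returns Sigma(lag) with Sigma[a, b] = <X_a(t + lag) X_b(t)> per spatial
    component: the stationary covariance S solves A S + S A^T = B B^T and
    Sigma(lag) = expm(-A lag) @ S.  The 3-D dot-product correlation used by
    the estimators is 3 * Sigma[j, i] for the ordered pair i -> j.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if lag < 0:
        raise ValueError("lag must be non-negative")
    eigs = np.linalg.eigvals(A)
    if eigs.real.min() <= 0:
        raise SpecError("drift matrix is not stable; no stationary covariance")
    try:
        S = solve_continuous_lyapunov(A, B @ B.T)
    except Exception as exc:  # pragma: no cover - scipy raises rarely here
        raise SpecError(f"singular Lyapunov system: {exc}") from exc
    return expm(-A * lag) @ S


def make_driver_follower_chain(
    n_sites: int,
    coupling: float,
    relax: float,
    dt: float,
    n_steps: int,
    seed: int,
    sigma: float = 1.0,
) -> tuple[FluctuationSeries, list[tuple[int, int]]]:
    """Unidirectional driver chain: site k drives site k+1.

    Drift A = relax * I with -coupling on the first subdiagonal; noise
    B = sigma * I.  Returns the simulated series and the ground-truth edge
    list [(0, 1), (1, 2), ...] (0-based site indices).
    """
    if n_sites < 2:
        raise SpecError("a chain needs >= 2 sites")
    if not 0 < coupling < relax:
        raise SpecError(f"stability requires 0 < coupling < relax, got {coupling} vs {relax}")
    A = relax * np.eye(n_sites)
    for k in range(n_sites - 1):
        A[k + 1, k] = -coupling
    edges = [(k, k + 1) for k in range(n_sites - 1)]
    spec = OUNetworkSpec(
        n_sites=n_sites,
        A=A,
        B=sigma * np.eye(n_sites),
        dt=dt,
        n_steps=n_steps,
        seed=seed,
        ground_truth_edges=edges,
    )
    return simulate_ou_network(spec), edges


def brute_force_lagged_correlation(
    fluct: FluctuationSeries, i, j, lag_frames: int
) -> float:
    """Reference loop implementation of mean_t dR_i(t).dR_j(t+lag).

    Explicit per-frame, per-component loops; no vectorized shortcuts.  This
    is the independent oracle for the direct lagged estimator.
    """
    ii, jj = fluct.site_index(i), fluct.site_index(j)
    n_frames = fluct.n_frames
    if lag_frames >= n_frames:
        raise ValueError("lag_frames must be smaller than the frame count")
    total = 0.0
    count = 0
    for t in range(n_frames - lag_frames):
        dot = 0.0
        for c in range(3):
            dot += fluct.deltas[t, ii, c] * fluct.deltas[t + lag_frames, jj, c]
        total += dot
        count += 1
    return total / count
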