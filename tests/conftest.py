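"""Shared fixtures: programmatic PDB text fixtures and synthetic series.

Expensive simulations are session-scoped so the suite reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from fluctcorr.synthetic import (
    GaussianEnsembleSpec,
    make_driver_follower_chain,
    sample_gaussian_ensemble,
    synthetic_labels,
)
from fluctcorr.trajectory_io import CoordinateEnsemble, FluctuationSeries


def _pdb_atom(serial, name, resname, chain, resid, xyz, element, hetatm=False):
    rec = "HETATM" if hetatm else "ATOM  "
    nm = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    return (
        f"{rec}{serial:>5d} {nm}{'':1s}{resname:<3s} {chain:1s}{resid:>4d}"
        f"{'':4s}{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}{'':10s}{element:>2s}"
    )


def write_multimodel_pdb(path, frames, atoms):
    """frames: (F, n_atoms, 3); atoms: list of (name, resname, chain, resid, element, hetatm)."""
    lines = []
    for m, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:>4d}")
        for serial, ((name, resname, chain, resid, element, het), xyz) in enumerate(
            zip(atoms, frame), start=1
        ):
            lines.append(_pdb_atom(serial, name, resname, chain, resid, xyz, element, het))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


#: 5 protein residues (N + CA each) + 3-heavy-atom ligand (+1 H) + water + ion
FIXTURE_ATOMS = [
    ("N", "ALA", "A", 1, "N", False),
    ("CA", "ALA", "A", 1, "C", False),
    ("N", "GLY", "A", 2, "N", False),
    ("CA", "GLY", "A", 2, "C", False),
    ("N", "SER", "A", 3, "N", False),
    ("CA", "SER", "A", 3, "C", False),
    ("N", "VAL", "A", 4, "N", False),
    ("CA", "VAL", "A", 4, "C", False),
    ("N", "LEU", "A", 5, "N", False),
    ("CA", "LEU", "A", 5, "C", False),
    ("C1", "LIG", "A", 6, "C", True),
    ("C2", "LIG", "A", 6, "C", True),
    ("O1", "LIG", "A", 6, "O", True),
    ("H1", "LIG", "A", 6, "H", True),
    ("O", "HOH", "A", 7, "O", True),
    ("NA", "NA", "A", 8, "NA", True),
]


@pytest.fixture
def fixture_pdb(tmp_path):
    rng = np.random.default_rng(42)
    base = rng.uniform(-8, 8, size=(len(FIXTURE_ATOMS), 3))
    frames = base + 0.3 * rng.standard_normal((3, len(FIXTURE_ATOMS), 3))
    return write_multimodel_pdb(tmp_path / "fixture.pdb", frames, FIXTURE_ATOMS)


def make_fluct(deltas, dt=1.0):
    """Wrap a raw (F, S, 3) array into a centred FluctuationSeries."""
    deltas = np.asarray(deltas, dtype=np.float64)
    deltas = deltas - deltas.mean(axis=0)
    n_sites = deltas.shape[1]
    return FluctuationSeries(
        deltas=deltas,
        means=np.zeros((n_sites, 3)),
        dt=dt,
        site_labels=synthetic_labels(n_sites),
    )


def make_ensemble(coords, dt=1.0):
    coords = np.asarray(coords, dtype=np.float64)
    return CoordinateEnsemble(
        coords=coords, site_labels=synthetic_labels(coords.shape[1]), dt=dt
    )


@pytest.fixture(scope="session")
def gaussian_big():
    """10^5-frame 3-site correlated Gaussian ensemble with known covariance."""
    S = np.array([[1.0, 0.3, 0.0], [0.3, 0.8, 0.1], [0.0, 0.1, 1.2]])
    spec = GaussianEnsembleSpec(n_sites=3, S=S, n_frames=100_000, seed=101)
    return sample_gaussian_ensemble(spec), S


@pytest.fixture(scope="session")
def chain_fluct():
    """3-site driver chain (0 -> 1 -> 2), 10^5 steps, fixed seed."""
    series, edges = make_driver_follower_chain(
        n_sites=3, coupling=0.5, relax=1.0, dt=0.05, n_steps=100_000, seed=11
    )
    return series, edges
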