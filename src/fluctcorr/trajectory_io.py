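"""Trajectory input, rigid-body superposition and fluctuation series.

The entry point is :func:`read_ensemble`, which loads a topology + trajectory
pair (PDB/DCD/XTC, or a single multi-model PDB) through MDAnalysis and
extracts the selected sites into a :class:`CoordinateEnsemble`.  From there
the standard pipeline is::

    ens = read_ensemble("traj.dcd", "top.pdb", selection="default", dt=1.0)
    ens = superpose_to_reference(ens, reference_frame=0)
    fluct = compute_fluctuations(ens)

All coordinates are in Angstrom, all times in picoseconds.  Residue numbers
are carried verbatim from the source file; arrays are 0-indexed with the
label map in ``site_labels``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .errors import (
    DegenerateSuperpositionError,
    FormatError,
    InsufficientDataError,
    IntegrityError,
    SelectionError,
)

__all__ = [
    "SiteLabel",
    "CoordinateEnsemble",
    "FluctuationSeries",
    "read_ensemble",
    "superpose_to_reference",
    "compute_fluctuations",
    "compute_rmsf",
    "write_fluctuations",
    "read_fluctuations",
    "write_ensemble_pdb",
    "ensemble_from_fluctuations",
]

#: residue names treated as solvent / monoatomic ions by the default selection
SOLVENT_RESNAMES = (
    "HOH WAT TIP3 TIP4 TIP5 SPC SOL "
    "NA CL K CS LI RB F BR I SOD CLA POT MG ZN MN FE CD NI CU CO"
).split()


class SiteLabel(NamedTuple):
    """Identity of one analysis site (one selected atom)."""

    resid: int
    resname: str
    atom_name: str
    chain: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        chain = self.chain or "-"
        return f"{chain}:{self.resname}{self.resid}:{self.atom_name}"


def _validate_labels(labels: Sequence[SiteLabel], n_sites: int) -> None:
    if len(labels) != n_sites:
        raise ValueError(f"{len(labels)} labels for {n_sites} sites")
    if len(set(labels)) != len(labels):
        raise ValueError("site labels must be unique")


@dataclass(frozen=True)
class CoordinateEnsemble:
    """frames x sites x 3 Cartesian coordinates with site identities.

    Parameters
    ----------
    coords : ndarray, shape (frames, sites, 3)
        Coordinates in Angstrom.
    site_labels : sequence of SiteLabel
        One label per site, in file order; residue numbering as in the
        source file (never reindexed).
    dt : float
        Time between stored frames, ps.
    source : str
        Free-text provenance (file names, selection, processing flags).
    """

    coords: np.ndarray
    site_labels: tuple[SiteLabel, ...]
    dt: float
    source: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, sites, 3), got {coords.shape}")
        if coords.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in ensemble")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "site_labels", tuple(SiteLabel(*l) for l in self.site_labels))
        _validate_labels(self.site_labels, coords.shape[1])

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class FluctuationSeries:
    """Mean-centred fluctuation vectors dR_i(t_k) = R_i(t_k) - <R_i>."""

    deltas: np.ndarray
    means: np.ndarray
    dt: float
    site_labels: tuple[SiteLabel, ...]
    source: str = ""

    def __post_init__(self) -> None:
        deltas = np.asarray(self.deltas, dtype=np.float64)
        means = np.asarray(self.means, dtype=np.float64)
        if deltas.ndim != 3 or deltas.shape[2] != 3:
            raise ValueError(f"deltas must be (frames, sites, 3), got {deltas.shape}")
        if means.shape != deltas.shape[1:]:
            raise ValueError("means must be (sites, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        resid = np.abs(deltas.mean(axis=0))
        if resid.size and resid.max() > 1e-10:
            raise ValueError(
                f"per-site mean of deltas is {resid.max():.3g} A; series not centred"
            )
        object.__setattr__(self, "deltas", deltas)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "site_labels", tuple(SiteLabel(*l) for l in self.site_labels))
        _validate_labels(self.site_labels, deltas.shape[1])

    @property
    def n_frames(self) -> int:
        return self.deltas.shape[0]

    @property
    def n_sites(self) -> int:
        return self.deltas.shape[1]

    @property
    def duration(self) -> float:
        """Trajectory duration in ps, (frames - 1) * dt."""
        return (self.n_frames - 1) * self.dt

    def site_index(self, label_or_index) -> int:
        """Resolve a site given as integer index or :class:`SiteLabel`."""
        if isinstance(label_or_index, (int, np.integer)):
            idx = int(label_or_index)
            if not -self.n_sites <= idx < self.n_sites:
                raise IndexError(f"site index {idx} out of range for {self.n_sites} sites")
            return idx % self.n_sites
        return self.site_labels.index(SiteLabel(*label_or_index))


# ---------------------------------------------------------------------------
# reading


def _default_selection_strings() -> tuple[str, str]:
    solvent = " ".join(SOLVENT_RESNAMES)
    ca = "protein and name CA"
    hetero = f"not protein and not resname {solvent} and not name H*"
    return ca, hetero


def _resolve_selection(universe, selection: str):
    """Resolve a selection spec to an MDAnalysis AtomGroup in file order.

    ``"default"`` means one CA per protein residue plus all heavy atoms of
    non-water, non-ion hetero residues; ``"protein-CA"`` restricts to CA
    atoms; anything else is passed through as an MDAnalysis selection string.
    """
    if selection in (None, "", "default"):
        ca, hetero = _default_selection_strings()
        group = universe.select_atoms(ca) | universe.select_atoms(hetero)
    elif selection == "protein-CA":
        group = universe.select_atoms("protein and name CA")
    else:
        try:
            group = universe.select_atoms(selection)
        except Exception as exc:
            raise SelectionError(f"invalid selection {selection!r}: {exc}") from exc
    if len(group) == 0:
        residues = universe.residues
        avail = ", ".join(
            f"{r.resname}{r.resid}" for r in residues[: min(len(residues), 25)]
        )
        raise SelectionError(
            f"selection {selection!r} matched no atoms; available residues: {avail}"
            + (" ..." if len(residues) > 25 else "")
        )
    return group


def read_ensemble(
    trajectory_path,
    topology_path=None,
    selection: str = "default",
    dt: float = 1.0,
) -> CoordinateEnsemble:
    """Read a trajectory into a :class:`CoordinateEnsemble`.

    Parameters
    ----------
    trajectory_path : path
        DCD, XTC or (multi-model) PDB coordinate file.
    topology_path : path, optional
        PDB topology.  If omitted, ``trajectory_path`` must be
        self-describing (multi-model PDB).
    selection : str
        ``"default"``, ``"protein-CA"`` or an MDAnalysis selection string.
    dt : float
        Time between stored frames, ps (formats carry this unreliably, so it
        is always caller-provided).
    """
    import MDAnalysis as mda

    trajectory_path = Path(trajectory_path)
    paths = [trajectory_path] if topology_path is None else [Path(topology_path), trajectory_path]
    for p in paths:
        if not p.exists():
            raise FormatError(f"file not found: {p}")
    try:
        universe = mda.Universe(*map(str, paths))
    except Exception as exc:
        raise FormatError(f"could not parse {'/'.join(map(str, paths))}: {exc}") from exc

    group = _resolve_selection(universe, selection)
    if len(group) < 2:
        raise SelectionError(f"selection {selection!r} resolved to {len(group)} site(s); need >= 2")

    frames = []
    try:
        for _ts in universe.trajectory:
            pos = np.array(group.positions, dtype=np.float64)
            if frames and pos.shape != frames[0].shape:
                raise IntegrityError(
                    f"atom count changed mid-trajectory in {trajectory_path}"
                )
            frames.append(pos)
    except IntegrityError:
        raise
    except Exception as exc:
        raise IntegrityError(f"error reading frames from {trajectory_path}: {exc}") from exc
    coords = np.stack(frames)

    labels = []
    for atom in group:
        chain = getattr(atom, "chainID", "") or getattr(atom, "segid", "")
        labels.append(SiteLabel(int(atom.resid), str(atom.resname), str(atom.name), str(chain).strip()))

    return CoordinateEnsemble(
        coords=coords,
        site_labels=labels,
        dt=dt,
        source=f"read_ensemble({trajectory_path.name}, selection={selection!r})",
    )


# ---------------------------------------------------------------------------
# superposition


def _kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal (proper) rotation matrix mapping centred `mobile` onto centred
    `reference` in the least-squares sense."""
    H = mobile.T @ reference
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose_to_reference(
    ensemble: CoordinateEnsemble, reference_frame: int = 0
) -> CoordinateEnsemble:
    """Rigid-body least-squares superpose every frame onto a reference frame.

    Uniform weights over all selected sites.  The reference frame itself is
    left untouched, and the operation is idempotent to rounding error.
    """
    if not -ensemble.n_frames <= reference_frame < ensemble.n_frames:
        raise IndexError(f"reference_frame {reference_frame} out of range")
    reference_frame %= ensemble.n_frames
    if ensemble.n_sites < 3:
        raise DegenerateSuperpositionError(
            f"{ensemble.n_sites} sites: need >= 3 non-collinear sites for a unique rotation"
        )
    ref = ensemble.coords[reference_frame]
    ref_centered = ref - ref.mean(axis=0)
    sv = np.linalg.svd(ref_centered, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateSuperpositionError("reference sites are (nearly) collinear")

    out = np.empty_like(ensemble.coords)
    for f in range(ensemble.n_frames):
        frame = ensemble.coords[f]
        centered = frame - frame.mean(axis=0)
        R = _kabsch_rotation(centered, ref_centered)
        out[f] = centered @ R.T + ref.mean(axis=0)
    return replace(
        ensemble,
        coords=out,
        source=ensemble.source + f" | superposed(ref={reference_frame})",
    )


# ---------------------------------------------------------------------------
# fluctuations


def compute_fluctuations(ensemble: CoordinateEnsemble) -> FluctuationSeries:
    """Mean-centre the ensemble: deltas = coords - per-site time mean.

    The caller is responsible for superposing first; the provenance string
    records whether that happened.
    """
    if ensemble.n_frames < 2:
        raise InsufficientDataError("need >= 2 frames to compute fluctuations")
    means = ensemble.coords.mean(axis=0)
    deltas = ensemble.coords - means
    # enforce exact centring against accumulated rounding
    deltas = deltas - deltas.mean(axis=0)
    return FluctuationSeries(
        deltas=deltas,
        means=means,
        dt=ensemble.dt,
        site_labels=ensemble.site_labels,
        source=ensemble.source + " | fluctuations",
    )


def compute_rmsf(fluct: FluctuationSeries) -> np.ndarray:
    """Per-site RMSF_i = sqrt(<|dR_i(t)|^2>_t), in Angstrom."""
    return np.sqrt(np.mean(np.sum(fluct.deltas**2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# serialization: TSV data matrix + JSON sidecar


def write_fluctuations(fluct: FluctuationSeries, path) -> Path:
    """Write a FluctuationSeries as a TSV matrix plus a ``.json`` sidecar.

    The TSV has one row per frame and 3 columns per site (x, y, z); the
    sidecar holds labels, per-site means, dt and provenance.  Returns the
    data path.
    """
    path = Path(path)
    flat = fluct.deltas.reshape(fluct.n_frames, fluct.n_sites * 3)
    header = "\t".join(
        f"{lab.resname}{lab.resid}.{lab.atom_name}.{ax}"
        for lab in fluct.site_labels
        for ax in "xyz"
    )
    np.savetxt(path, flat, delimiter="\t", header=header, fmt="%.10g")
    sidecar = {
        "format": "fluctcorr.fluctuations.v1",
        "n_frames": fluct.n_frames,
        "n_sites": fluct.n_sites,
        "dt_ps": fluct.dt,
        "site_labels": [list(lab) for lab in fluct.site_labels],
        "means_A": fluct.means.tolist(),
        "source": fluct.source,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_fluctuations(path) -> FluctuationSeries:
    """Inverse of :func:`write_fluctuations`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    for p in (path, sidecar_path):
        if not p.exists():
            raise FormatError(f"file not found: {p}")
    try:
        meta = json.loads(sidecar_path.read_text())
        flat = np.loadtxt(path, delimiter="\t", ndmin=2)
    except Exception as exc:
        raise FormatError(f"could not parse fluctuation container at {path}: {exc}") from exc
    if meta.get("format") != "fluctcorr.fluctuations.v1":
        raise FormatError(f"{sidecar_path} is not a fluctcorr fluctuation sidecar")
    n_frames, n_sites = int(meta["n_frames"]), int(meta["n_sites"])
    if flat.shape != (n_frames, n_sites * 3):
        raise IntegrityError(
            f"data shape {flat.shape} inconsistent with sidecar ({n_frames}, {n_sites * 3})"
        )
    labels = [SiteLabel(int(a), str(b), str(c), str(d)) for a, b, c, d in meta["site_labels"]]
    return FluctuationSeries(
        deltas=flat.reshape(n_frames, n_sites, 3),
        means=np.asarray(meta["means_A"], dtype=np.float64),
        dt=float(meta["dt_ps"]),
        site_labels=labels,
        source=str(meta.get("source", "")),
    )


def ensemble_from_fluctuations(fluct: FluctuationSeries) -> CoordinateEnsemble:
    """Reconstruct absolute coordinates (deltas + means) as an ensemble."""
    return CoordinateEnsemble(
        coords=fluct.deltas + fluct.means,
        site_labels=fluct.site_labels,
        dt=fluct.dt,
        source=fluct.source + " | to_ensemble",
    )


def write_ensemble_pdb(ensemble: CoordinateEnsemble, path) -> Path:
    """Write the ensemble as a multi-model PDB readable by :func:`read_ensemble`."""
    import MDAnalysis as mda

    path = Path(path)
    n = ensemble.n_sites
    resids = [lab.resid for lab in ensemble.site_labels]
    uniq: dict[tuple, int] = {}
    residx = []
    for lab in ensemble.site_labels:
        key = (lab.chain, lab.resid, lab.resname)
        residx.append(uniq.setdefault(key, len(uniq)))
    u = mda.Universe.empty(
        n, n_residues=len(uniq), atom_resindex=residx, trajectory=True
    )
    u.add_TopologyAttr("names", [lab.atom_name for lab in ensemble.site_labels])
    u.add_TopologyAttr("resnames", [key[2] for key in uniq])
    u.add_TopologyAttr("resids", [key[1] for key in uniq])
    u.add_TopologyAttr("chainIDs", [(lab.chain or "A")[:1] for lab in ensemble.site_labels])
    u.load_new(ensemble.coords, order="fac")
    with mda.Writer(str(path), multiframe=True) as w:
        for _ts in u.trajectory:
            w.write(u.atoms)
    return path
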