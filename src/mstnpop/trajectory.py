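"""Geometric analysis metrics for (RNA) molecular-dynamics trajectories.

A :class:`Trajectory` is a plain (frames x atoms x 3) coordinate array in
nanometres plus per-atom metadata (name, residue, mass, van-der-Waals
radius, and role flags: sugar-phosphate backbone, ribose C1', hydrogen-bond
donor / hydrogen / acceptor, base-pairing).  The metrics implemented are the
standard trajectory observables:

* RMSD of a selection after least-squares (Kabsch) superposition;
* per-atom RMSF of a selection after fitting every frame to the mean
  structure (one re-fit iteration);
* mass-weighted radius of gyration;
* Shrake-Rupley solvent-accessible surface area (probe 0.14 nm, 960 sphere
  points by default);
* geometric hydrogen-bond counts: donor-acceptor distance <= 0.35 nm and
  hydrogen-donor-acceptor angle (vertex at the donor) <= 30 degrees,
  optionally restricted to base-pairing atoms;
* PCA of the fitted C1' coordinates and the free-energy landscape
  -ln(P / P_max), in kT units, over the first two principal components.

Periodic-boundary handling is not performed: input trajectories are assumed
whole-molecule and PBC-corrected upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ATOM_COLUMNS = ["name", "residue", "mass", "radius",
                "backbone", "c1p", "donor", "hydrogen", "acceptor",
                "base_pairing", "parent"]

#: fallback van-der-Waals radii (nm) by element symbol
VDW_RADII = {"H": 0.110, "C": 0.170, "N": 0.155, "O": 0.152, "P": 0.180, "S": 0.180}


@dataclass
class Trajectory:
    coords: np.ndarray               # (n_frames, n_atoms, 3), nm
    atoms: pd.DataFrame              # one row per atom, ATOM_COLUMNS
    frame_labels: list[str] | None = None   # provenance after concatenation

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (frames, atoms, 3)")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table does not match coordinate atom count")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if (self.atoms["mass"] <= 0).any():
            raise ValueError("masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def selection(self, which: str | np.ndarray | None) -> np.ndarray:
        """Boolean atom mask for 'backbone', 'c1p', 'all', or an explicit mask."""
        if which is None or which == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if isinstance(which, str):
            if which not in self.atoms.columns:
                raise ValueError(f"unknown selection {which!r}")
            return self.atoms[which].to_numpy(dtype=bool)
        mask = np.asarray(which, dtype=bool)
        if mask.shape != (self.n_atoms,):
            raise ValueError("selection mask has wrong length")
        return mask


@dataclass
class MetricSeries:
    name: str
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=0))


@dataclass
class PCAResult:
    mean_structure: np.ndarray       # (k, 3) of the selection
    eigenvectors: np.ndarray         # (3k, n_components) columns
    eigenvalues: np.ndarray          # non-increasing
    projections: np.ndarray          # (frames, n_components), zero-mean
    variance_fractions: np.ndarray


@dataclass
class FELGrid:
    free_energy: np.ndarray          # (bins, bins), kT; NaN = unsampled
    x_edges: np.ndarray
    y_edges: np.ndarray


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation/translation of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd); ``mobile @ R.T + t`` is the
    fitted structure.  Reflections are excluded.  Degenerate (collinear)
    selections raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need two equal selections of >= 3 atoms")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    a, b = mobile - mc, reference - rc
    u, s, vt = np.linalg.svd(a.T @ b)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = a @ rot.T
    rmsd = float(np.sqrt(((fitted - b) ** 2).sum(axis=1).mean()))
    return rot, rc - mc @ rot.T, rmsd


def _fit_frames(coords: np.ndarray, reference: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Superpose every frame (all atoms moved) onto reference over ``mask``."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, trans, _ = kabsch_superpose(coords[f, mask], reference)
        out[f] = coords[f] @ rot.T + trans
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _fit_to(sub: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Superpose each frame of a (F, k, 3) stack onto ``ref``."""
    out = np.empty_like(sub)
    for f in range(sub.shape[0]):
        rot, trans, _ = kabsch_superpose(sub[f], ref)
        out[f] = sub[f] @ rot.T + trans
    return out


def rmsd_series(traj: Trajectory, reference_frame: int = 0,
                selection: str = "backbone") -> MetricSeries:
    """Per-frame Kabsch RMSD of the selection against a reference frame."""
    mask = traj.selection(selection)
    ref = traj.coords[reference_frame, mask]
    values = [kabsch_superpose(traj.coords[f, mask], ref)[2]
              for f in range(traj.n_frames)]
    return MetricSeries("RMSD", np.array(values), "nm")


def rmsf(traj: Trajectory, selection: str = "c1p", fit: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation of the selection.

    With ``fit=True`` every frame is first superposed (over the selection)
    onto the frame-0 structure, the mean structure is computed, and the fit
    is repeated once against that mean before taking fluctuations.
    """
    mask = traj.selection(selection)
    sub = traj.coords[:, mask]
    if traj.n_frames < 2:
        logger.warning("RMSF of a single frame is identically zero")
        return np.zeros(mask.sum())
    if fit:
        fitted = _fit_to(sub, sub[0])
        sub = _fit_to(sub, fitted.mean(axis=0))
    mean = sub.mean(axis=0)
    return np.sqrt(((sub - mean) ** 2).sum(axis=2).mean(axis=0))


def radius_of_gyration(traj: Trajectory) -> MetricSeries:
    """Mass-weighted radius of gyration per frame."""
    masses = traj.atoms["mass"].to_numpy(dtype=float)
    com = (traj.coords * masses[None, :, None]).sum(axis=1) / masses.sum()
    sq = ((traj.coords - com[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt((sq * masses[None, :]).sum(axis=1) / masses.sum())
    return MetricSeries("Rg", rg, "nm")


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def sasa(traj: Trajectory, probe_radius: float = 0.14, n_points: int = 960
         ) -> MetricSeries:
    """Shrake-Rupley solvent-accessible surface area per frame, nm^2."""
    radii = traj.atoms["radius"].to_numpy(dtype=float) + probe_radius
    points = _sphere_points(n_points)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        total = 0.0
        for i in range(traj.n_atoms):
            sphere = xyz[i] + radii[i] * points
            accessible = np.ones(n_points, dtype=bool)
            for j in range(traj.n_atoms):
                if j == i:
                    continue
                d2 = ((sphere - xyz[j]) ** 2).sum(axis=1)
                accessible &= d2 > radii[j] ** 2
                if not accessible.any():
                    break
            total += accessible.mean() * 4.0 * math.pi * radii[i] ** 2
        values[f] = total
    return MetricSeries("SASA", values, "nm^2")


def hbond_count(traj: Trajectory, d_max: float = 0.35, angle_max: float = 30.0,
                pair_filter: str = "all") -> MetricSeries:
    """Per-frame geometric hydrogen-bond count.

    A (donor, hydrogen, acceptor) triple counts when the donor-acceptor
    distance is <= ``d_max`` nm and the angle hydrogen-donor-acceptor
    (vertex at the donor) is <= ``angle_max`` degrees.  Hydrogens are paired
    with their covalent donor through the ``parent`` atom-index column.
    ``pair_filter='base_pairing'`` restricts donors and acceptors to atoms
    flagged as base-pairing (canonical / wobble / Hoogsteen edges).
    """
    atoms = traj.atoms
    restrict = None
    if pair_filter == "base_pairing":
        restrict = atoms["base_pairing"].to_numpy(dtype=bool)
    elif pair_filter != "all":
        raise ValueError(f"unknown pair filter {pair_filter!r}")

    hyd = np.flatnonzero(atoms["hydrogen"].to_numpy(dtype=bool))
    triples = []
    for h in hyd:
        d = atoms["parent"].iloc[h]
        if pd.isna(d):
            continue
        d = int(d)
        if not bool(atoms["donor"].iloc[d]):
            continue
        if restrict is not None and not restrict[d]:
            continue
        for a in np.flatnonzero(atoms["acceptor"].to_numpy(dtype=bool)):
            if a in (d, h):
                continue
            if restrict is not None and not restrict[a]:
                continue
            triples.append((d, h, a))
    if not triples:
        logger.warning("no donor/hydrogen/acceptor triples available")
        return MetricSeries("Hbonds" if pair_filter == "all" else "Hbonds_bp",
                            np.zeros(traj.n_frames), "count")
    t = np.array(triples)
    cos_max = math.cos(math.radians(angle_max))
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        dvec = xyz[t[:, 2]] - xyz[t[:, 0]]          # donor -> acceptor
        hvec = xyz[t[:, 1]] - xyz[t[:, 0]]          # donor -> hydrogen
        dist = np.linalg.norm(dvec, axis=1)
        cosang = (dvec * hvec).sum(axis=1) / (
            np.linalg.norm(hvec, axis=1) * np.maximum(dist, 1e-12))
        values[f] = int(((dist <= d_max) & (cosang >= cos_max)).sum())
    name = "Hbonds_all" if pair_filter == "all" else "Hbonds_bp"
    return MetricSeries(name, values, "count")


def pca(traj: Trajectory, selection: str = "c1p", fit: bool = True) -> PCAResult:
    """PCA of the (fitted) selection coordinates.

    Eigendecomposition of the 3k x 3k covariance of the flattened selected
    coordinates over frames; eigenvalues non-increasing, projections
    zero-mean.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least two frames")
    mask = traj.selection(selection)
    sub = traj.coords[:, mask]
    if fit:
        sub = _fit_to(sub, sub[0])
    mean = sub.mean(axis=0)
    x = (sub - mean).reshape(traj.n_frames, -1)
    cov = x.T @ x / (traj.n_frames - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    proj = x @ eigvecs
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAResult(mean_structure=mean, eigenvectors=eigvecs,
                     eigenvalues=eigvals, projections=proj,
                     variance_fractions=fractions)


def fel(pca_result: PCAResult, bins: int = 32) -> FELGrid:
    """Free-energy landscape G = -ln(P / P_max) in kT over (PC1, PC2)."""
    xy = pca_result.projections[:, :2]
    counts, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins)
    g = np.full_like(counts, np.nan)
    sampled = counts > 0
    g[sampled] = -np.log(counts[sampled] / counts.max())
    return FELGrid(free_energy=g, x_edges=xe, y_edges=ye)


def concat_fitted(trajs: list[Trajectory], reference: np.ndarray,
                  selection: str = "backbone") -> Trajectory:
    """Superpose every frame of every trajectory onto a shared reference
    structure (over the selection) and concatenate, retaining provenance."""
    if not trajs:
        raise ValueError("no trajectories")
    mask0 = trajs[0].selection(selection)
    fitted, labels = [], []
    for idx, t in enumerate(trajs):
        mask = t.selection(selection)
        if mask.sum() != mask0.sum() or reference.shape[0] != mask.sum():
            raise ValueError("selected atom counts differ")
        fitted.append(_fit_frames(t.coords, reference, mask))
        src = t.frame_labels or [f"traj{idx}"] * t.n_frames
        labels.extend(src)
    return Trajectory(coords=np.concatenate(fitted, axis=0),
                      atoms=trajs[0].atoms.copy(), frame_labels=labels)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def read_trajectory(coords_path: str | Path, atoms_path: str | Path) -> Trajectory:
    """Read a trajectory from a (frame, atom, x, y, z) table plus an atom
    metadata CSV (columns from ATOM_COLUMNS; missing flags default False,
    missing radius falls back to the element table)."""
    cdf = pd.read_csv(coords_path, sep=None, engine="python")
    frames = sorted(cdf["frame"].unique())
    n_atoms = cdf[cdf["frame"] == frames[0]].shape[0]
    coords = np.empty((len(frames), n_atoms, 3))
    for i, f in enumerate(frames):
        sub = cdf[cdf["frame"] == f].sort_values("atom")
        if len(sub) != n_atoms:
            raise ValueError(f"frame {f}: atom count changed")
        coords[i] = sub[["x", "y", "z"]].to_numpy()
    atoms = pd.read_csv(atoms_path)
    for col in ("backbone", "c1p", "donor", "hydrogen", "acceptor", "base_pairing"):
        if col not in atoms.columns:
            atoms[col] = False
    if "mass" not in atoms.columns:
        atoms["mass"] = 1.0
    if "radius" not in atoms.columns:
        atoms["radius"] = [VDW_RADII.get(str(n)[0].upper(), 0.17)
                           for n in atoms["name"]]
    if "parent" not in atoms.columns:
        atoms["parent"] = np.nan
    return Trajectory(coords=coords, atoms=atoms)
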