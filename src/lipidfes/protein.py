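"""Protein-side descriptors: gating-helix angle, cross-ensemble per-residue
RMSD, RMSF, and grid-based hydrophobic-cavity volume.

The cavity protocol mirrors pocket-tracking tools: frames are superposed
on a fixed Cα reference, a "cavity region" of voxels inside the protein
envelope that are unoccupied by protein heavy atoms in at least a stated
fraction of reference frames is detected once, and the unoccluded volume
of that region is then tracked per frame.  The envelope is the convex
hull of the Cα atoms shrunk by one probe radius; occlusion uses per-element
van der Waals radii.  Volumes are therefore comparable to, but not
bit-identical with, alpha-sphere-based pocket tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .structures import superpose

__all__ = [
    "VDW_RADII_NM",
    "GateFrame",
    "CavityGrid",
    "gate_angle",
    "orient_plane_normal",
    "cross_ensemble_rmsd",
    "align_frames",
    "rmsf",
    "detect_cavity_region",
    "cavity_volume_series",
]

# heavy-atom van der Waals radii, nm (Bondi-style; configurable per call)
VDW_RADII_NM = {"C": 0.17, "N": 0.155, "O": 0.152, "S": 0.18, "P": 0.18}


@dataclass
class GateFrame:
    """Gate-helix geometry for one frame."""

    axis: np.ndarray        # helix-2 axis vector (Cα 54 -> Cα 65)
    normal: np.ndarray      # oriented normal of the helix-6 plane
    theta_deg: float


@dataclass
class CavityGrid:
    """Voxel grid with a fixed boolean cavity-region mask."""

    origin: np.ndarray
    spacing: float
    shape: tuple
    mask: np.ndarray          # boolean, True = cavity-region voxel

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if not self.mask.any():
            raise ValueError("empty cavity mask")

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    @property
    def voxel_centers(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return self.origin + (idx + 0.5) * self.spacing

    def to_dx(self, path) -> None:
        """Serialize as an OpenDX-style scalar grid (0/1 occupancy)."""
        nx, ny, nz = self.shape
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            ox, oy, oz = self.origin * 10.0  # Å, as DX files conventionally use
            fh.write(f"origin {ox:.4f} {oy:.4f} {oz:.4f}\n")
            d = self.spacing * 10.0
            fh.write(f"delta {d:.4f} 0 0\ndelta 0 {d:.4f} 0\ndelta 0 0 {d:.4f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(
                f"object 3 class array type double rank 0 items {nx*ny*nz} data follows\n"
            )
            flat = self.mask.astype(float).ravel()
            for k in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.1f}" for v in flat[k : k + 3]) + "\n")


# ---------------------------------------------------------------------------
# Gate angle


def _plane_normal(p0, p1, p2):
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("plane atoms are collinear")
    return n / norm


def orient_plane_normal(coords, plane_indices, toward_point) -> float:
    """Sign (+1/-1) making the plane normal point toward a reference point.

    Fixed once from the reference structure so solution and membrane-bound
    ensembles share a sign convention.
    """
    p = np.asarray(coords, dtype=float)[list(plane_indices)]
    n = _plane_normal(*p)
    v = np.asarray(toward_point, dtype=float) - p.mean(axis=0)
    return 1.0 if float(np.dot(n, v)) >= 0 else -1.0


def gate_angle(coords, axis_indices, plane_indices, normal_sign: float = 1.0) -> GateFrame:
    """Polar angle (degrees) of the gate-helix axis in the helix-6 plane frame.

    ``axis_indices`` are the two Cα atoms defining the helix axis (e.g.
    residues 54 and 65); ``plane_indices`` the three Cα atoms spanning the
    helix-6 plane (e.g. 155, 158, 162).  0° means the axis is parallel to
    the oriented plane normal; 90° means it lies in the plane.
    """
    coords = np.asarray(coords, dtype=float)
    a0, a1 = (coords[i] for i in axis_indices)
    axis = a1 - a0
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("zero-length helix axis")
    p = coords[list(plane_indices)]
    n = _plane_normal(*p) * normal_sign
    cos = float(np.clip(np.dot(axis / norm, n), -1.0, 1.0))
    return GateFrame(axis=axis, normal=n, theta_deg=float(np.degrees(np.arccos(cos))))


# ---------------------------------------------------------------------------
# Ensemble comparisons


def align_frames(coords_frames, reference, fit_indices):
    """Superpose every frame on a reference over a fit selection."""
    return np.array([superpose(fr, reference, fit_indices)[0] for fr in coords_frames])


def cross_ensemble_rmsd(positions_a, positions_b) -> float:
    """RMS displacement of one atom between all frame pairs of two ensembles.

    Computes sqrt( (t_a t_b)^{-1} Σ_i Σ_j |a_i - b_j|^2 ) without forming
    the t_a x t_b pair set, via
    E|a-b|^2 = E|a|^2 + E|b|^2 - 2 <a>.<b>.  For equal-length ensembles
    this is the t^{-2} double-sum definition.
    """
    a = np.asarray(positions_a, dtype=float).reshape(-1, 3)
    b = np.asarray(positions_b, dtype=float).reshape(-1, 3)
    msd = (a**2).sum(axis=1).mean() + (b**2).sum(axis=1).mean() - 2.0 * float(
        np.dot(a.mean(axis=0), b.mean(axis=0))
    )
    return float(np.sqrt(max(msd, 0.0)))


def rmsf(coords_frames, selection=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    Frames must already be aligned (see :func:`align_frames`).
    """
    X = np.asarray(coords_frames, dtype=float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValueError("need >= 2 aligned frames of (n_atoms, 3)")
    if selection is not None:
        X = X[:, np.asarray(selection, dtype=int)]
    mean = X.mean(axis=0)
    return np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# Cavity volume


def _occupied_voxels(centers, coords, elements, radii) -> np.ndarray:
    """Boolean per-voxel occupancy: any heavy atom within its vdW radius.

    Uses bounded nearest-neighbour queries per element class so memory
    stays O(n_voxels) regardless of contact multiplicity.
    """
    occupied = np.zeros(len(centers), dtype=bool)
    elements = np.asarray(elements)
    for elem in np.unique(elements):
        r = radii.get(str(elem))
        if r is None or str(elem) == "H":
            continue
        pts = coords[elements == elem]
        if len(pts) == 0:
            continue
        tree = cKDTree(pts)
        d, _ = tree.query(centers[~occupied], k=1, distance_upper_bound=r)
        occupied[~occupied] = np.isfinite(d)
    return occupied


def detect_cavity_region(
    aligned_frames,
    elements,
    ca_indices,
    spacing: float = 0.08,
    occupancy_threshold: float = 0.2,
    probe_radius: float = 0.14,
    radii: dict = VDW_RADII_NM,
) -> CavityGrid:
    """Detect the interior region free of protein heavy atoms often enough.

    A voxel belongs to the cavity region if (i) it lies inside the convex
    hull of the Cα atoms shrunk inward by one probe radius and (ii) it is
    unoccupied (no heavy atom within its vdW radius) in at least
    ``occupancy_threshold`` of the frames (inclusive).  Frames must be
    pre-aligned to the common reference.
    """
    frames = np.asarray(aligned_frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    ca = frames[0][np.asarray(ca_indices, dtype=int)]
    hull = ConvexHull(ca)
    # the grid only needs to span the hull envelope, not every atom;
    # the origin snaps to a spacing multiple so volumes are reproducible
    lo = np.floor((ca.min(axis=0) - 2 * spacing) / spacing) * spacing
    hi = ca.max(axis=0) + 2 * spacing
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int))
    grid_idx = np.indices(shape).reshape(3, -1).T
    centers = lo + (grid_idx + 0.5) * spacing
    # inside the shrunk hull: all face-plane signed distances <= -probe
    inside = np.ones(len(centers), dtype=bool)
    for eq in hull.equations:
        inside &= centers @ eq[:3] + eq[3] <= -probe_radius
        if not inside.any():
            raise ValueError("empty cavity mask: hull envelope vanished")
    centers_in = centers[inside]
    free_count = np.zeros(len(centers_in), dtype=int)
    for fr in frames:
        free_count += ~_occupied_voxels(centers_in, fr, elements, radii)
    frac_free = free_count / len(frames)
    keep = frac_free >= occupancy_threshold
    if not keep.any():
        raise ValueError("empty cavity mask: no voxel free often enough")
    mask = np.zeros(shape, dtype=bool)
    sel = grid_idx[inside][keep]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return CavityGrid(lo, spacing, shape, mask)


def cavity_volume_series(
    aligned_frames, elements, grid: CavityGrid, radii: dict = VDW_RADII_NM
) -> np.ndarray:
    """Unoccluded cavity-region volume (nm^3) per aligned frame.

    Only protein heavy atoms occlude; a bound lipid never does, so the
    reported volume includes any space it occupies.
    """
    frames = np.asarray(aligned_frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    centers = grid.voxel_centers
    out = np.empty(len(frames))
    for k, fr in enumerate(frames):
        occ = _occupied_voxels(centers, fr, elements, radii)
        out[k] = (len(centers) - occ.sum()) * grid.voxel_volume
    return out
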