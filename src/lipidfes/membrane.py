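"""Membrane-side descriptors: depths, orientations, thickness, area per
lipid, acyl order, hydrophobic contact counts, protein-centered maps and
radial-shell statistics.

Conventions: z is the membrane normal; leaflets are assigned from
phosphate z relative to the phosphate midplane; the hydrophobic
carbon–carbon contact cutoff is 1 nm inclusive; area per lipid comes from
a 2D periodic Voronoi tessellation of phosphorus positions per leaflet
(protein atoms excluded entirely).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi, cKDTree

from .cv import assign_leaflets, minimum_image

__all__ = [
    "LipidView",
    "SpatialMap2D",
    "ShellStats",
    "insertion_depth",
    "tail_orientation",
    "bilayer_thickness",
    "area_per_lipid",
    "acyl_order_scc",
    "lipid_lipid_ncc",
    "lipid_protein_ncc",
    "protein_centered_map",
    "shell_statistics",
]


@dataclass
class LipidView:
    """Index bookkeeping for one lipid: phosphorus, tails, anchor."""

    lipid_id: int
    phosphorus: int
    tails: list            # ordered carbon index lists, anchor-proximal first
    anchor: int
    leaflet: int = 0
    hydrophobic: np.ndarray | None = None

    def __post_init__(self):
        if not self.tails:
            raise ValueError("a lipid needs at least one tail")
        self.tails = [np.asarray(t, dtype=int) for t in self.tails]

    @property
    def terminal_carbons(self) -> list:
        return [int(t[-1]) for t in self.tails]


@dataclass
class SpatialMap2D:
    """Binned per-lipid values on the (dx, dy) plane around the protein."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    mean: np.ndarray       # NaN where count == 0
    count: np.ndarray
    reference: float = np.nan  # membrane-only mean: the colour-scale zero

    def to_text(self, path) -> None:
        bw = self.edges_x[1] - self.edges_x[0]
        with open(path, "w") as fh:
            fh.write(f"# bin_width_nm {bw:.6f}\n")
            fh.write(f"# origin_nm {self.edges_x[0]:.6f} {self.edges_y[0]:.6f}\n")
            fh.write(f"# reference {self.reference:.6g}\n")
            np.savetxt(fh, self.mean, fmt="%.6g")


@dataclass
class ShellStats:
    """Per-radial-shell samples with Welch comparison to a reference."""

    edges: np.ndarray
    samples: list
    mean: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    significance: list = field(default_factory=list)  # '', '*', '**'

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# r_lo_nm\tr_hi_nm\tn\tmean\tse\tp\tsig\n")
            for k in range(len(self.samples)):
                fh.write(
                    f"{self.edges[k]:.4f}\t{self.edges[k+1]:.4f}\t"
                    f"{len(self.samples[k])}\t{self.mean[k]:.6g}\t"
                    f"{self.se[k]:.6g}\t{self.p_value[k]:.6g}\t"
                    f"{self.significance[k]}\n"
                )


# ---------------------------------------------------------------------------


def insertion_depth(trajectory, residue_indices: dict, phosphate_indices, masses=None) -> dict:
    """Mean signed z distance of each residue's COM from the phosphate plane.

    Negative values lie below the mean phosphate z of the bound leaflet
    (into the hydrophobic core).  ``residue_indices`` maps residue id to
    atom indices; ``phosphate_indices`` selects the bound leaflet's
    phosphates.  Equal masses unless ``masses`` (per atom) is given.
    """
    phosphate_indices = np.asarray(phosphate_indices, dtype=int)
    if phosphate_indices.size == 0:
        raise ValueError("empty phosphate selection")
    acc = {rid: 0.0 for rid in residue_indices}
    n = 0
    for fr in trajectory:
        z_plane = fr.coordinates[phosphate_indices, 2].mean()
        for rid, idx in residue_indices.items():
            idx = np.asarray(idx, dtype=int)
            if masses is not None:
                w = np.asarray(masses)[idx]
                com_z = np.average(fr.coordinates[idx, 2], weights=w)
            else:
                com_z = fr.coordinates[idx, 2].mean()
            acc[rid] += com_z - z_plane
        n += 1
    if n == 0:
        raise ValueError("empty trajectory")
    return {rid: v / n for rid, v in acc.items()}


def tail_orientation(coords, view: LipidView) -> np.ndarray:
    """cos(theta_z) per tail: angle between +z and terminal->anchor vector."""
    coords = np.asarray(coords, dtype=float)
    out = []
    for term in view.terminal_carbons:
        v = coords[view.anchor] - coords[term]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"zero-length tail vector for lipid {view.lipid_id}")
        out.append(v[2] / norm)
    return np.array(out)


def bilayer_thickness(coords, phosphate_indices) -> float:
    """Mean phosphate z of the upper leaflet minus that of the lower."""
    coords = np.asarray(coords, dtype=float)
    p = np.asarray(phosphate_indices, dtype=int)
    z = coords[p, 2]
    sides = assign_leaflets(z)
    if not (np.any(sides > 0) and np.any(sides < 0)):
        raise ValueError("both leaflets must be populated")
    return float(z[sides > 0].mean() - z[sides < 0].mean())


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def area_per_lipid(points_xy, box_xy) -> np.ndarray:
    """Voronoi cell area per lipid in a periodic xy plane, nm^2.

    The point set is tiled 3x3; the cells of the central image are then
    finite and exactly partition the box, so per-leaflet areas sum to
    Lx * Ly.
    """
    pts = np.asarray(points_xy, dtype=float)[:, :2].copy()
    box = np.asarray(box_xy, dtype=float)[:2]
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 lipids per leaflet for a tessellation")
    pts %= box
    tiles = [
        pts + np.array([ix * box[0], iy * box[1]])
        for ix in (-1, 0, 1)
        for iy in (-1, 0, 1)
    ]
    tiled = np.vstack(tiles)
    central_offset = 4 * n  # (ix, iy) == (0, 0) block
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for k in range(n):
        region = vor.regions[vor.point_region[central_offset + k]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded central Voronoi cell; degenerate layout")
        areas[k] = _polygon_area(vor.vertices[region])
    return areas


def acyl_order_scc(trajectory, views) -> np.ndarray:
    """Per-lipid acyl order parameter S_CC = <(3 cos^2 theta - 1)/2>.

    theta is the angle between each consecutive carbon–carbon bond vector
    of each tail and +z; averaged over all bonds of all tails, then over
    frames.  (The carbon–carbon convention, not C–D/C–H.)
    """
    acc = np.zeros(len(views))
    n = 0
    for fr in trajectory:
        for k, view in enumerate(views):
            vals = []
            for tail in view.tails:
                if len(tail) < 2:
                    raise ValueError("tails need >= 2 carbons for S_CC")
                b = fr.coordinates[tail[1:]] - fr.coordinates[tail[:-1]]
                cos = b[:, 2] / np.linalg.norm(b, axis=1)
                vals.append((3.0 * cos**2 - 1.0) / 2.0)
            acc[k] += np.concatenate(vals).mean()
        n += 1
    if n == 0:
        raise ValueError("empty trajectory")
    return acc / n


def _contact_pairs(coords, box, idx_a, idx_b, cutoff):
    """Index pairs (into idx_a, idx_b) within cutoff under PBC via KD-trees."""
    box = np.asarray(box, dtype=float)
    a = np.mod(coords[idx_a], box)
    b = np.mod(coords[idx_b], box)
    # cKDTree with boxsize rejects points exactly at the boundary after mod
    a = np.where(a >= box, 0.0, a)
    b = np.where(b >= box, 0.0, b)
    ta = cKDTree(a, boxsize=box)
    tb = cKDTree(b, boxsize=box)
    return ta.query_ball_tree(tb, cutoff)


def lipid_lipid_ncc(coords, box, lipid_hydrophobic_groups, cutoff: float = 1.0) -> np.ndarray:
    """Hydrophobic carbon–carbon contacts per lipid against all other lipids.

    Intra-lipid pairs are excluded; each inter-lipid pair (i, j) counts
    once for lipid i and once for lipid j, so the total over lipids is
    twice the pair count.
    """
    groups = [np.asarray(g, dtype=int) for g in lipid_hydrophobic_groups]
    all_idx = np.concatenate(groups) if groups else np.array([], dtype=int)
    owner = np.concatenate([np.full(len(g), k) for k, g in enumerate(groups)])
    counts = np.zeros(len(groups), dtype=int)
    if all_idx.size == 0:
        return counts
    neigh = _contact_pairs(np.asarray(coords, float), box, all_idx, all_idx, cutoff)
    for ai, nbrs in enumerate(neigh):
        oa = owner[ai]
        for bj in nbrs:
            if owner[bj] != oa:
                counts[oa] += 1  # counts each unordered pair once per side
    return counts


def lipid_protein_ncc(coords, box, lipid_hydrophobic_groups, residue_hydrophobic_groups, cutoff: float = 1.0):
    """Hydrophobic contacts between lipids and protein residues.

    Returns (per_residue_counts, per_lipid_counts) over the same pair set,
    so the two sum identically.
    """
    coords = np.asarray(coords, dtype=float)
    lip_groups = [np.asarray(g, dtype=int) for g in lipid_hydrophobic_groups]
    res_groups = [np.asarray(g, dtype=int) for g in residue_hydrophobic_groups]
    per_lip = np.zeros(len(lip_groups), dtype=int)
    per_res = np.zeros(len(res_groups), dtype=int)
    lip_idx = np.concatenate([g for g in lip_groups if g.size]) if lip_groups else np.array([], int)
    res_idx = np.concatenate([g for g in res_groups if g.size]) if res_groups else np.array([], int)
    if lip_idx.size == 0 or res_idx.size == 0:
        return per_res, per_lip
    lip_owner = np.concatenate([np.full(len(g), k) for k, g in enumerate(lip_groups) if g.size])
    res_owner = np.concatenate([np.full(len(g), k) for k, g in enumerate(res_groups) if g.size])
    neigh = _contact_pairs(coords, box, lip_idx, res_idx, cutoff)
    for ai, nbrs in enumerate(neigh):
        per_lip[lip_owner[ai]] += len(nbrs)
        for bj in nbrs:
            per_res[res_owner[bj]] += 1
    return per_res, per_lip


def protein_centered_map(displacements, values, bin_width: float, extent: float, reference: float = np.nan) -> SpatialMap2D:
    """Bin per-lipid values by xy displacement from the protein center.

    ``displacements`` is (n, 2) minimum-image (dx, dy) in nm pooled over
    frames, ``values`` the matching observable.  Bins with no samples stay
    NaN (undefined, never zero).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    disp = np.asarray(displacements, dtype=float).reshape(-1, 2)
    vals = np.asarray(values, dtype=float)
    nbin = max(1, int(np.ceil(2 * extent / bin_width)))
    edges = -extent + bin_width * np.arange(nbin + 1)
    cnt, _, _ = np.histogram2d(disp[:, 0], disp[:, 1], bins=[edges, edges])
    tot, _, _ = np.histogram2d(disp[:, 0], disp[:, 1], bins=[edges, edges], weights=vals)
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return SpatialMap2D(edges, edges.copy(), mean, cnt.astype(int), reference)


def shell_statistics(radii, values, shell_edges, reference_values, cumulative: bool = False) -> ShellStats:
    """Collect samples into radial shells and Welch-test each vs a reference.

    Shells are annular (r_lo < r <= r_hi) by default; ``cumulative=True``
    uses r <= r_hi instead.  Samples should already be decorrelated (see
    :func:`lipidfes.fes.decorrelated_samples`).  Significance tiers follow
    the figures' annotation: '**' for p < 0.001, '*' for p < 0.01.
    """
    from .fes import welch_t_test

    r = np.asarray(radii, dtype=float)
    v = np.asarray(values, dtype=float)
    edges = np.asarray(shell_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("shell edges must be strictly increasing")
    ref = np.asarray(reference_values, dtype=float)
    samples, means, ses, ps, sig = [], [], [], [], []
    for k in range(len(edges) - 1):
        sel = (r <= edges[k + 1]) if cumulative else (r > edges[k]) & (r <= edges[k + 1])
        s = v[sel]
        samples.append(s)
        means.append(s.mean() if s.size else np.nan)
        ses.append(s.std(ddof=1) / np.sqrt(len(s)) if s.size > 1 else np.nan)
        if s.size < 2:
            ps.append(np.nan)
            sig.append("n/a")
            continue
        _, _, p = welch_t_test(s, ref)
        ps.append(p)
        sig.append("**" if p < 1e-3 else "*" if p < 1e-2 else "")
    return ShellStats(edges, samples, np.array(means), np.array(ses), np.array(ps), sig)
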