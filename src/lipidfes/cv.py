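"""Collective variables for lipid extraction from a membrane.

Two order parameters drive the analysis:

* ``r_LxS`` — the reaction coordinate for passive lipid transport via
  solvent, a fixed linear combination of (i) a smooth minimum over the
  hydrophobic carbon–carbon distances between the tagged lipid and the
  closest leaflet and (ii) the number of such contacts within 1 nm::

      r_LxS = alpha1 * min(d_CC) + alpha2 * n_CC + alpha0

  with alpha1 = -2.247 nm^-1, alpha2 = 0.004828, alpha0 = 0.6014, so that
  r_LxS is unitless: large and positive with the lipid in the membrane,
  negative once it is free in solution.

* ``Q`` — the fraction of native lipid–protein contacts, a smooth sigmoid
  average over an enumerated list of atom pairs with reference distances
  taken from a bound-form reference ensemble.

Smooth (differentiable) variants of min and of the contact count follow
the standard enhanced-sampling conventions: a log-sum-exp soft-min with
gamma = 200 nm, and a rational switching function with d0 = 1 nm,
r0 = 0.025 nm clamped to 1 below d0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RLxSParams",
    "QReferenceMap",
    "CVSeries",
    "minimum_image",
    "pair_distances",
    "smooth_min",
    "hard_contact_count",
    "smooth_contact_count",
    "r_lxs",
    "r_lxs_from_distances",
    "q_fraction",
    "assign_leaflets",
    "closest_leaflet",
    "build_q_reference",
    "evaluate_cv_series",
]


@dataclass(frozen=True)
class RLxSParams:
    """Coefficients and switching parameters of the transport coordinate."""

    alpha1: float = -2.247    # nm^-1
    alpha2: float = 0.004828  # per contact
    alpha0: float = 0.6014
    gamma: float = 200.0      # nm, soft-min sharpness
    d0: float = 1.0           # nm, switching onset
    r0: float = 0.025         # nm, switching width
    hard_cutoff: float = 1.0  # nm, inclusive

    def __post_init__(self):
        if self.gamma <= 0 or self.r0 <= 0 or self.d0 <= 0 or self.hard_cutoff <= 0:
            raise ValueError("gamma, d0, r0 and hard_cutoff must be positive")


@dataclass
class QReferenceMap:
    """Enumerated native-contact pairs with reference distances.

    ``pairs`` rows are (lipid_atom_index, protein_atom_index); ``r0`` holds
    the matching reference distances in nm; ``pair_class`` tags each pair
    'hydrophobic' (cavity-lining carbons) or 'polar' (headgroup
    recognition heavy atoms).
    """

    pairs: np.ndarray          # (N, 2) int
    r0: np.ndarray             # (N,) nm
    beta: float = 50.0         # nm^-1
    lam: float = 1.8
    pair_class: list = field(default_factory=list)

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.r0 = np.asarray(self.r0, dtype=float)
        if self.pairs.shape[0] == 0:
            raise ValueError("QReferenceMap needs at least one pair")
        if len(self.r0) != len(self.pairs):
            raise ValueError("pairs and r0 length mismatch")
        if np.any(self.r0 <= 0):
            raise ValueError("reference distances must be positive")
        if not self.pair_class:
            self.pair_class = ["hydrophobic"] * len(self.pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# lipid_atom\tprot_atom\tr0_nm\tclass\n")
            for (i, j), r, c in zip(self.pairs, self.r0, self.pair_class):
                fh.write(f"{i}\t{j}\t{r:.6f}\t{c}\n")

    @classmethod
    def from_table(cls, path, beta: float = 50.0, lam: float = 1.8):
        pairs, r0, cls_ = [], [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.split()
                pairs.append((int(f[0]), int(f[1])))
                r0.append(float(f[2]))
                cls_.append(f[3] if len(f) > 3 else "hydrophobic")
        return cls(np.array(pairs), np.array(r0), beta=beta, lam=lam, pair_class=cls_)


@dataclass
class CVSeries:
    """Per-frame values of named collective variables.

    ``mask`` marks frames eligible for estimation (burn-in and steered
    segments are excluded explicitly, never inferred downstream).
    """

    times: np.ndarray
    values: dict
    metadata: dict = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for k, v in self.values.items():
            if len(v) != len(self.times):
                raise ValueError(f"CV {k!r} length {len(v)} != {len(self.times)} times")
        if self.mask is None:
            self.mask = np.ones(len(self.times), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def names(self) -> list:
        return list(self.values)

    def to_colvar(self, path) -> None:
        names = self.names
        with open(path, "w") as fh:
            fh.write("#! FIELDS time " + " ".join(names) + "\n")
            cols = np.column_stack([self.times] + [self.values[n] for n in names])
            np.savetxt(fh, cols, fmt="%.10g")

    @classmethod
    def from_colvar(cls, path):
        with open(path) as fh:
            header = fh.readline()
        if not header.startswith("#!"):
            raise ValueError(f"{path} lacks a '#! FIELDS' header")
        fields = header.split()[2:]
        data = np.atleast_2d(np.loadtxt(path, comments="#"))
        return cls(data[:, 0], {n: data[:, k + 1] for k, n in enumerate(fields[1:])})


# ---------------------------------------------------------------------------
# Distances


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum image of an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    return vectors - box * np.round(vectors / box)


def pair_distances(coords_a, coords_b, box) -> np.ndarray:
    """Minimum-image distances for every (a, b) pair, a-major order, nm."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty atom group in pair_distances")
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image(d, np.asarray(box, dtype=float))
    return np.sqrt((d**2).sum(axis=-1)).ravel()


def smooth_min(distances, gamma: float = 200.0) -> float:
    """Differentiable minimum: gamma / logsumexp(gamma / d).

    Evaluated with a max-shift so that gamma/d ≈ 400 (d = 0.5 nm at
    gamma = 200 nm) does not overflow.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("smooth_min of an empty distance set")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    z = gamma / d
    m = z.max()
    return float(gamma / (m + np.log(np.exp(z - m).sum())))


def hard_contact_count(distances, cutoff: float = 1.0) -> int:
    """Number of distances at or below the cutoff (inclusive)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = np.asarray(distances, dtype=float)
    return int(np.count_nonzero(d <= cutoff))


def smooth_contact_count(
    distances, d0: float = 1.0, r0: float = 0.025, literal: bool = False
) -> float:
    """Smooth contact count: sum of a rational switching function.

    Default convention (enhanced-sampling engines): s = 1 for d <= d0 and
    s = 1 / (1 + x^6) with x = (d - d0)/r0 beyond, which equals the
    rational form (1 - x^6)/(1 - x^12) with its removable singularity
    s(d0 + r0) = 1/2 filled in.  ``literal=True`` evaluates the raw
    rational expression on both sides of d0 for comparison.
    """
    if d0 <= 0 or r0 <= 0:
        raise ValueError("d0 and r0 must be positive")
    d = np.asarray(distances, dtype=float)
    x = (d - d0) / r0
    if literal:
        with np.errstate(over="ignore", invalid="ignore"):
            num, den = 1.0 - x**6, 1.0 - x**12
            s = np.where(np.isclose(np.abs(x), 1.0), 0.5, num / den)
            s = np.where(np.isfinite(s), s, 0.0)
        return float(s.sum())
    s = np.ones_like(x)
    above = x > 0
    s[above] = 1.0 / (1.0 + x[above] ** 6)
    return float(s.sum())


def r_lxs_from_distances(distances, params: RLxSParams = RLxSParams(), mode: str = "analysis") -> float:
    """Transport coordinate from a precomputed distance set.

    ``mode='analysis'`` uses the hard contact count; ``mode='biased'`` the
    smooth one (as used when the coordinate must be differentiable).  The
    soft-min is used in both modes.
    """
    if mode not in ("analysis", "biased"):
        raise ValueError(f"mode must be 'analysis' or 'biased', got {mode!r}")
    md = smooth_min(distances, params.gamma)
    if mode == "analysis":
        n = hard_contact_count(distances, params.hard_cutoff)
    else:
        n = smooth_contact_count(distances, params.d0, params.r0)
    return params.alpha1 * md + params.alpha2 * n + params.alpha0


def r_lxs(
    coords,
    box,
    tagged_indices,
    leaflet_indices,
    params: RLxSParams = RLxSParams(),
    mode: str = "analysis",
) -> float:
    """r_LxS between a tagged lipid's hydrophobic carbons and a leaflet's."""
    tagged_indices = np.asarray(tagged_indices, dtype=int)
    leaflet_indices = np.asarray(leaflet_indices, dtype=int)
    if leaflet_indices.size == 0:
        raise ValueError("empty leaflet group")
    leaflet_indices = np.setdiff1d(leaflet_indices, tagged_indices)
    if leaflet_indices.size == 0:
        raise ValueError("leaflet group contains only the tagged lipid")
    d = pair_distances(coords[tagged_indices], coords[leaflet_indices], box)
    return r_lxs_from_distances(d, params, mode)


def q_fraction(coords, box, qmap: QReferenceMap) -> float:
    """Fraction of native contacts Q in [0, 1]."""
    coords = np.asarray(coords, dtype=float)
    if qmap.pairs.max() >= len(coords):
        raise IndexError("QReferenceMap references atoms beyond the frame")
    vec = minimum_image(coords[qmap.pairs[:, 0]] - coords[qmap.pairs[:, 1]], box)
    r = np.sqrt((vec**2).sum(axis=1))
    z = qmap.beta * (r - qmap.lam * qmap.r0)
    # clip: |z| > 700 overflows exp; the sigmoid is 0/1 there anyway
    q = 1.0 / (1.0 + np.exp(np.clip(z, -700, 700)))
    return float(q.mean())


# ---------------------------------------------------------------------------
# Leaflets


def assign_leaflets(phos_z: np.ndarray) -> np.ndarray:
    """Split phosphate z-coordinates into leaflets about their midplane.

    Returns +1 (upper) / -1 (lower) per phosphate; values exactly at the
    midplane go to the upper leaflet (documented tie-break).
    """
    z = np.asarray(phos_z, dtype=float)
    if z.size < 2:
        raise ValueError("need at least two phosphates to assign leaflets")
    mid = z.mean()
    return np.where(z >= mid, 1, -1)


def closest_leaflet(coords, tagged_p_index: int, leaflet_p_indices) -> int:
    """Leaflet (+1 upper / -1 lower) whose mean phosphate z is nearest the
    tagged lipid's phosphorus z.  Ties resolve to the upper leaflet."""
    coords = np.asarray(coords, dtype=float)
    p_idx = np.asarray(leaflet_p_indices, dtype=int)
    sides = assign_leaflets(coords[p_idx, 2])
    if len(set(sides)) < 2:
        raise ValueError("fewer than two leaflets present")
    z = coords[tagged_p_index, 2]
    z_up = coords[p_idx[sides > 0], 2].mean()
    z_lo = coords[p_idx[sides < 0], 2].mean()
    return 1 if abs(z - z_up) <= abs(z - z_lo) else -1


# ---------------------------------------------------------------------------
# Q reference construction


def build_q_reference(
    trajectory,
    lipid_hydrophobic,
    cavity_carbons,
    lipid_polar=None,
    recognition_heavy=None,
    hydrophobic_cutoff: float = 0.78,
    polar_cutoff: float = 0.55,
    beta: float = 50.0,
    lam: float = 1.8,
) -> QReferenceMap:
    """Enumerate native-contact pairs from a bound-form reference ensemble.

    Hydrophobic class: lipid hydrophobic carbons x cavity-lining carbons
    with mean distance <= 0.78 nm.  Polar class: lipid headgroup/backbone
    heavy atoms x recognition-residue heavy atoms with mean <= 0.55 nm.
    Reference distances are the trajectory means.
    """

    def _mean_dists(idx_a, idx_b):
        acc = None
        n = 0
        for fr in trajectory:
            d = pair_distances(fr.coordinates[idx_a], fr.coordinates[idx_b], fr.box)
            acc = d if acc is None else acc + d
            n += 1
        if n == 0:
            raise ValueError("empty reference trajectory")
        return acc / n

    pairs, r0, classes = [], [], []
    groups = [(lipid_hydrophobic, cavity_carbons, hydrophobic_cutoff, "hydrophobic")]
    if lipid_polar is not None and recognition_heavy is not None:
        groups.append((lipid_polar, recognition_heavy, polar_cutoff, "polar"))
    for idx_a, idx_b, cutoff, label in groups:
        idx_a = np.asarray(idx_a, dtype=int)
        idx_b = np.asarray(idx_b, dtype=int)
        if idx_a.size == 0 or idx_b.size == 0:
            continue
        mean_d = _mean_dists(idx_a, idx_b).reshape(len(idx_a), len(idx_b))
        ii, jj = np.nonzero(mean_d <= cutoff)
        for i, j in zip(ii, jj):
            pairs.append((idx_a[i], idx_b[j]))
            r0.append(mean_d[i, j])
            classes.append(label)
    if not pairs:
        raise ValueError("no native-contact pairs found under the cutoffs")
    return QReferenceMap(np.array(pairs), np.array(r0), beta=beta, lam=lam, pair_class=classes)


def evaluate_cv_series(trajectory, cv_specs: dict) -> CVSeries:
    """Evaluate named per-frame CV callables over a trajectory (streaming).

    ``cv_specs`` maps a CV name to a callable ``f(frame) -> float``; an
    iterable of (name, callable) pairs is accepted too and checked for
    duplicate names.
    """
    if not isinstance(cv_specs, dict):
        items = list(cv_specs)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate CV names")
        cv_specs = dict(items)
    names = list(cv_specs)
    times, cols = [], {n: [] for n in names}
    for k, fr in enumerate(trajectory):
        times.append(fr.time)
        for n in names:
            try:
                cols[n].append(float(cv_specs[n](fr)))
            except Exception as exc:
                raise RuntimeError(f"CV {n!r} failed at frame {k}: {exc}") from exc
    return CVSeries(np.array(times), {n: np.array(v) for n, v in cols.items()})
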