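"""Free-energy estimation: well-tempered metadynamics bookkeeping and
time-independent reweighting, 1D umbrella-sampling WHAM, marginalization,
barrier extraction, and decorrelation/error statistics.

Units: kJ/mol, nm, ps, kelvin; kB = 0.0083144621 kJ/mol/K.  Free energies
are also reported in kcal/mol (4.184 kJ = 1 kcal exactly).

The metadynamics estimator reweights biased frames with

    w(t) ∝ exp( [V(s_t, t) − c(t)] / kB T )

where V is the accumulated bias (Gaussian hills shared by all walkers,
plus any static wall potentials) and c(t) is the time-dependent bias
offset evaluated on the biased-CV grid at each hill deposition,

    c(t) = (1/β) [ ln ∫ e^{β γ V/(γ−1)} ds − ln ∫ e^{β V/(γ−1)} ds ],

with γ the bias factor (the well-tempered limit of the time-independent
estimator of the reweighting literature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KB",
    "KJ_PER_KCAL",
    "HillRecord",
    "WTMDParams",
    "UmbrellaWindowData",
    "FESGrid",
    "SteeringProtocol",
    "BiasGrid",
    "bias_potential",
    "wall_potential",
    "tempered_height",
    "reweight_tiwary_parrinello",
    "scaled_time_diagnostic",
    "wham_1d",
    "marginalize_fes",
    "barrier_height",
    "block_standard_error",
    "flyvbjerg_petersen",
    "decorrelated_samples",
    "welch_t_test",
    "read_hills",
    "write_hills",
]

KB = 0.0083144621  # kJ/mol/K
KJ_PER_KCAL = 4.184


@dataclass(frozen=True)
class HillRecord:
    """One deposited Gaussian hill."""

    time: float            # ps
    center: tuple          # per biased CV
    sigma: tuple           # per biased CV
    height: float          # kJ/mol, already tempered
    walker: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma) or self.height <= 0:
            raise ValueError("hill widths and heights must be positive")


@dataclass(frozen=True)
class WTMDParams:
    """Well-tempered metadynamics protocol parameters."""

    bias_factor: float = 30.0
    temperature: float = 310.0       # K
    deposition_period: float = 4.0   # ps
    initial_height: float = 2.5      # kJ/mol
    sigmas: tuple = (0.1, 0.01)      # per biased CV
    walls: tuple = ((-3.0, 15.0), None)  # per CV, (lo, hi) or None
    wall_spring: float = 500.0       # kJ/mol per CV-unit^2
    n_walkers: int = 20

    def __post_init__(self):
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kt(self) -> float:
        return KB * self.temperature

    @property
    def delta_t_energy(self) -> float:
        """(γ−1) kB T, the tempering energy scale."""
        return (self.bias_factor - 1.0) * self.kt


@dataclass(frozen=True)
class SteeringProtocol:
    """Moving-restraint phase: per-walker targets, springs, duration.

    Frames sampled while steering is active are excluded from estimation
    (their mask is cleared) and no hills are deposited.
    """

    targets: tuple                     # per walker: tuple of CV targets
    springs: tuple = (75.0, 7500.0)    # kJ/mol per CV-unit^2
    start: float = 0.0                 # ps
    duration: float = 20000.0          # ps


@dataclass
class UmbrellaWindowData:
    """One umbrella window: harmonic bias center/spring and its samples."""

    center: float
    spring: float                      # kJ/mol per CV-unit^2
    samples: np.ndarray                # post-burn-in CV samples

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise ValueError("umbrella window has no samples")


@dataclass
class FESGrid:
    """Binned free energies over 1 or 2 CV axes, min over defined bins = 0."""

    names: tuple
    edges: list
    free_energy: np.ndarray            # kJ/mol, NaN where undefined
    error: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = [np.asarray(e, dtype=float) for e in self.edges]
        self.free_energy = np.asarray(self.free_energy, dtype=float)

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> list:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    @property
    def free_energy_kcal(self) -> np.ndarray:
        return self.free_energy / KJ_PER_KCAL

    def normalize(self) -> "FESGrid":
        """Shift so the minimum over defined bins is exactly 0."""
        if not self.defined.any():
            raise ValueError("FES has no defined bins")
        self.free_energy = self.free_energy - np.nanmin(self.free_energy)
        return self

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# axes: {' '.join(self.names)} (kJ/mol; kcal/mol = kJ/4.184)\n")
            for name, e in zip(self.names, self.edges):
                fh.write(f"# edges {name}: {e[0]:.6g} to {e[-1]:.6g}, {len(e)-1} bins\n")
            if self.ndim == 1:
                err = self.error if self.error is not None else np.full_like(self.free_energy, np.nan)
                fh.write(f"# {self.names[0]}\tF_kJ_mol\tF_kcal_mol\tSE_kJ_mol\n")
                for x, f, s in zip(self.centers[0], self.free_energy, err):
                    fh.write(f"{x:.6g}\t{f:.6g}\t{f / KJ_PER_KCAL:.6g}\t{s:.6g}\n")
            else:
                np.savetxt(fh, self.free_energy, fmt="%.6g")


# ---------------------------------------------------------------------------
# Bias bookkeeping


def wall_potential(points, walls, spring: float) -> np.ndarray:
    """Half-harmonic wall energy, zero inside the allowed interval(s)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    v = np.zeros(len(p))
    for d, w in enumerate(walls or ()):
        if w is None:
            continue
        lo, hi = w
        x = p[:, d]
        if lo is not None:
            v += np.where(x < lo, 0.5 * spring * (x - lo) ** 2, 0.0)
        if hi is not None:
            v += np.where(x > hi, 0.5 * spring * (x - hi) ** 2, 0.0)
    return v


def bias_potential(hills, points, time_cutoff: float | None = None, truncate: float = 6.0) -> np.ndarray:
    """Sum of deposited Gaussians at one or more points.

    Hills later than ``time_cutoff`` are ignored.  Each hill is truncated
    beyond ``truncate`` sigmas per dimension (set to ``None`` for the
    exact untruncated sum).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    v = np.zeros(len(p))
    for h in hills:
        if time_cutoff is not None and h.time > time_cutoff:
            continue
        c = np.asarray(h.center, dtype=float)
        s = np.asarray(h.sigma, dtype=float)
        z = (p - c) / s
        if truncate is not None:
            keep = np.all(np.abs(z) <= truncate, axis=1)
            if not keep.any():
                continue
            v[keep] += h.height * np.exp(-0.5 * (z[keep] ** 2).sum(axis=1))
        else:
            v += h.height * np.exp(-0.5 * (z**2).sum(axis=1))
    if np.asarray(points, dtype=float).ndim == 1:
        return float(v[0])
    return v


def tempered_height(bias_at_center: float, initial_height: float, params: WTMDParams) -> float:
    """Well-tempered hill height: h0 * exp(-V(c)/((γ−1) kB T))."""
    return float(initial_height * np.exp(-bias_at_center / params.delta_t_energy))


class BiasGrid:
    """Accumulated metadynamics bias tabulated on a regular CV grid.

    Supports 1D and 2D biased-CV spaces: hill deposition, multilinear
    interpolation of V and its gradient, and the bias-offset functional
    c(t).
    """

    def __init__(self, edges):
        self.edges = [np.asarray(e, dtype=float) for e in edges]
        self.centers = [0.5 * (e[1:] + e[:-1]) for e in self.edges]
        self.ndim = len(self.edges)
        if self.ndim not in (1, 2):
            raise ValueError("BiasGrid supports 1 or 2 dimensions")
        shape = tuple(len(c) for c in self.centers)
        self.values = np.zeros(shape)
        self._mesh = np.meshgrid(*self.centers, indexing="ij")
        self._grads = None

    def add_hill(self, center, sigma, height) -> None:
        z2 = sum(
            ((m - c) / s) ** 2 for m, c, s in zip(self._mesh, center, sigma)
        )
        self.values += height * np.exp(-0.5 * z2)
        self._grads = None

    def interpolate(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = self._interp_nd(self.values, p)
        return out

    def _interp_nd(self, arr, p):
        idx_w = []
        for d, c in enumerate(self.centers):
            x = np.clip(p[:, d], c[0], c[-1])
            i = np.clip(np.searchsorted(c, x) - 1, 0, len(c) - 2)
            w = (x - c[i]) / (c[i + 1] - c[i])
            idx_w.append((i, w))
        if self.ndim == 1:
            i, w = idx_w[0]
            return arr[i] * (1 - w) + arr[i + 1] * w
        (i, wx), (j, wy) = idx_w
        return (
            arr[i, j] * (1 - wx) * (1 - wy)
            + arr[i + 1, j] * wx * (1 - wy)
            + arr[i, j + 1] * (1 - wx) * wy
            + arr[i + 1, j + 1] * wx * wy
        )

    def gradient(self, points) -> np.ndarray:
        """Bias gradient at points via interpolated finite differences."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if self._grads is None:
            g = np.gradient(self.values, *[c for c in self.centers], edge_order=2)
            self._grads = [g] if self.ndim == 1 else list(g)
        return np.column_stack([self._interp_nd(g, p) for g in self._grads])

    def offset_c(self, params: WTMDParams) -> float:
        """Bias offset c(t) of the accumulated bias, kJ/mol."""
        beta = 1.0 / params.kt
        g = params.bias_factor
        v = self.values.ravel()
        return (logsumexp(beta * g / (g - 1.0) * v) - logsumexp(beta / (g - 1.0) * v)) / beta


# ---------------------------------------------------------------------------
# Metadynamics reweighting


def _gather_frames(series_list, cv_names, burn_in: float):
    ts, ss, ms, wk = [], [], [], []
    for w, series in enumerate(series_list):
        t = series.times
        s = np.column_stack([series.values[n] for n in cv_names])
        m = series.mask & (t >= burn_in)
        ts.append(t)
        ss.append(s)
        ms.append(m)
        wk.append(np.full(len(t), w))
    t = np.concatenate(ts)
    order = np.argsort(t, kind="stable")
    return (
        t[order],
        np.concatenate(ss)[order],
        np.concatenate(ms)[order],
        np.concatenate(wk)[order],
    )


def _frame_bias_and_offset(times, points, hills, params, grid_edges):
    """V(s_t, t) and c(t) per frame, walking hills and frames in time order."""
    grid = BiasGrid(grid_edges)
    hills = sorted(hills, key=lambda h: (h.time, h.walker))
    dep_times = [0.0]
    c_values = [0.0]
    V = np.empty(len(times))
    k = 0  # hill cursor
    i = 0  # frame cursor
    n = len(times)
    while i < n:
        t_next = hills[k].time if k < len(hills) else np.inf
        # frames strictly before the next deposition see the current grid
        j = i
        while j < n and times[j] < t_next:
            j += 1
        if j > i:
            V[i:j] = grid.interpolate(points[i:j])
            i = j
        if k < len(hills):
            t_dep = hills[k].time
            while k < len(hills) and hills[k].time == t_dep:
                grid.add_hill(hills[k].center, hills[k].sigma, hills[k].height)
                k += 1
            dep_times.append(t_dep)
            c_values.append(grid.offset_c(params))
    c = np.interp(times, dep_times, c_values)
    V += wall_potential(points, params.walls, params.wall_spring)
    return V, c


def _weighted_fes(points, weights, edges, kt, names):
    hist, _ = np.histogramdd(points, bins=edges, weights=weights)
    with np.errstate(divide="ignore"):
        F = -kt * np.log(hist)
    F[hist <= 0] = np.nan
    return FESGrid(tuple(names), list(edges), F).normalize()


def reweight_tiwary_parrinello(
    series_list,
    hills,
    params: WTMDParams,
    grid_edges,
    cv_names,
    burn_in: float = 0.0,
    n_error_blocks: int = 2,
) -> FESGrid:
    """Time-independent reweighting of well-tempered metadynamics frames.

    ``series_list`` holds one CVSeries per walker (masks already exclude
    steered segments); frames before ``burn_in`` (ps) are dropped on top
    of the masks.  The output grid doubles as the c(t) evaluation grid.
    Per-bin errors come from ``n_error_blocks`` contiguous time blocks.
    """
    cv_names = list(cv_names)
    t, s, mask, _ = _gather_frames(series_list, cv_names, burn_in)
    if not mask.any():
        raise ValueError("no frames remain after burn-in and masking")
    V, c = _frame_bias_and_offset(t, s, hills, params, grid_edges)
    kt = params.kt
    logw = (V - c) / kt
    logw -= logw[mask].max()
    w = np.where(mask, np.exp(logw), 0.0)
    fes = _weighted_fes(s[mask], w[mask], grid_edges, kt, cv_names)
    fes.metadata.update(n_frames=int(mask.sum()), burn_in=burn_in)
    if n_error_blocks >= 2 and mask.sum() >= 2 * n_error_blocks:
        sel = np.flatnonzero(mask)
        blocks = np.array_split(sel, n_error_blocks)
        Fb = []
        for b in blocks:
            Fb.append(_weighted_fes(s[b], w[b], grid_edges, kt, cv_names).free_energy)
        Fb = np.array(Fb)
        fes.error = _nan_block_se(Fb, n_error_blocks)
    return fes


def _nan_block_se(block_estimates: np.ndarray, n_blocks: int) -> np.ndarray:
    """Per-bin SE across block estimates; NaN where < 2 blocks define a bin."""
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(block_estimates, axis=0, ddof=1) / np.sqrt(n_blocks)


def scaled_time_diagnostic(
    hills,
    params: WTMDParams,
    grid_edges=None,
    fit_start_fraction: float = 0.5,
):
    """Slope of log(scaled time) vs log(time) from the hill history.

    Scaled time is exp(c(t)/kB T) with c(t) the bias offset; at
    quasi-steady state the log-log slope approaches γ − 1.  Requires at
    least two decades of deposition history.  Returns a dict with the
    slope, the fit R², per-deposition times/scaled times, and a
    ``reliable`` flag (R² ≥ 0.99 and slope stable across the fit window).
    """
    hills = sorted(hills, key=lambda h: (h.time, h.walker))
    if not hills:
        raise ValueError("empty hill history")
    t0, t1 = hills[0].time, hills[-1].time
    if t0 <= 0 or t1 / t0 < 100.0:
        raise ValueError("need at least two decades of hill history")
    if grid_edges is None:
        centers = np.array([h.center for h in hills])
        sig = np.array([h.sigma for h in hills]).max(axis=0)
        lo = centers.min(axis=0) - 5 * sig
        hi = centers.max(axis=0) + 5 * sig
        grid_edges = [np.linspace(a, b, 201) for a, b in zip(lo, hi)]
    grid = BiasGrid(grid_edges)
    times, cs = [], []
    k = 0
    while k < len(hills):
        t_dep = hills[k].time
        while k < len(hills) and hills[k].time == t_dep:
            grid.add_hill(hills[k].center, hills[k].sigma, hills[k].height)
            k += 1
        times.append(t_dep)
        cs.append(grid.offset_c(params))
    times = np.array(times)
    log_scaled = np.array(cs) / params.kt  # ln of the scaled time, exactly
    scaled = np.exp(np.clip(log_scaled, -700.0, 700.0))
    sel = times >= fit_start_fraction * times[-1]
    if sel.sum() < 4:
        raise ValueError("too few depositions in the fit window")
    lx, ly = np.log(times[sel]), log_scaled[sel]
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    half = len(lx) // 2
    slope_a = np.polyfit(lx[:half], ly[:half], 1)[0]
    slope_b = np.polyfit(lx[half:], ly[half:], 1)[0]
    stable = abs(slope_b - slope_a) <= 0.1 * max(abs(slope), 1e-12)
    return {
        "slope": float(slope),
        "r_squared": float(r2),
        "times": times,
        "scaled_time": scaled,
        "reliable": bool(r2 >= 0.99 and stable),
    }


# ---------------------------------------------------------------------------
# WHAM


def wham_1d(
    windows,
    temperature: float,
    edges,
    tolerance: float = 1e-8,
    max_iter: int = 100000,
    n_error_blocks: int = 2,
) -> FESGrid:
    """Self-consistent WHAM over 1D umbrella windows.

    Iterates the standard histogram equations until the largest change of
    any window free-energy shift falls below ``tolerance`` (kJ/mol).
    Disjoint window coverage raises an error naming the gap.  Per-bin
    errors come from re-running WHAM on contiguous sample blocks.
    """
    edges = np.asarray(edges, dtype=float)
    centers = 0.5 * (edges[1:] + edges[:-1])
    kt = KB * temperature
    beta = 1.0 / kt

    def _solve(sample_sets):
        H = np.array([np.histogram(s, bins=edges)[0] for s in sample_sets], dtype=float)
        occupied = H.sum(axis=0) > 0
        # connectivity check on per-window support
        supports = [np.flatnonzero(h > 0) for h in H]
        order = np.argsort([w.center for w in windows])
        for a, b in zip(order[:-1], order[1:]):
            if supports[a].size and supports[b].size:
                if supports[a][-1] < supports[b][0] - 1 and not np.intersect1d(
                    supports[a], supports[b]
                ).size:
                    raise ValueError(
                        "umbrella windows do not overlap between centers "
                        f"{windows[a].center:g} and {windows[b].center:g}"
                    )
        N = H.sum(axis=1)
        U = np.array([0.5 * w.spring * (centers - w.center) ** 2 for w in windows])
        f = np.zeros(len(windows))
        n_tot = H.sum(axis=0)
        for _ in range(max_iter):
            # log denominator per bin: logsumexp over windows
            log_num = np.where(n_tot > 0, np.log(np.maximum(n_tot, 1)), -np.inf)
            log_den = logsumexp(
                np.log(N)[:, None] + beta * (f[:, None] - U), axis=0
            )
            log_p = log_num - log_den
            log_p[~occupied] = -np.inf
            new_f = -kt * logsumexp(log_p[None, :] - beta * U, axis=1)
            new_f -= new_f[0]
            if np.max(np.abs(new_f - f)) < tolerance:
                f = new_f
                break
            f = new_f
        else:
            raise RuntimeError("WHAM failed to converge")
        F = -kt * log_p
        F[~occupied] = np.nan
        return F

    F = _solve([w.samples for w in windows])
    fes = FESGrid(("cv",), [edges], F).normalize()
    if n_error_blocks >= 2 and all(len(w.samples) >= n_error_blocks for w in windows):
        Fb = []
        for b in range(n_error_blocks):
            sets = [np.array_split(w.samples, n_error_blocks)[b] for w in windows]
            Fk = _solve(sets)
            Fb.append(Fk - np.nanmin(Fk))
        fes.error = _nan_block_se(np.array(Fb), n_error_blocks)
    return fes


# ---------------------------------------------------------------------------
# Surface manipulation


def marginalize_fes(fes: FESGrid, keep_axis, temperature: float) -> FESGrid:
    """Boltzmann-marginalize a 2D surface onto one axis.

    ΔF(x) = −kB T ln Σ_y exp(−ΔF(x, y)/kB T) Δy over defined bins,
    renormalized to min 0.  Rows with no defined bin stay undefined.
    Errors propagate as the Boltzmann-weighted mean of bin errors.
    """
    if fes.ndim != 2:
        raise ValueError("marginalize_fes needs a 2D surface")
    if isinstance(keep_axis, str):
        keep = fes.names.index(keep_axis)
    else:
        keep = int(keep_axis)
    drop = 1 - keep
    kt = KB * temperature
    F = fes.free_energy if keep == 0 else fes.free_energy.T
    E = None
    if fes.error is not None:
        E = fes.error if keep == 0 else fes.error.T
    dy = np.diff(fes.edges[drop])
    out = np.full(F.shape[0], np.nan)
    err = np.full(F.shape[0], np.nan)
    for i in range(F.shape[0]):
        row = F[i]
        ok = np.isfinite(row)
        if not ok.any():
            continue
        out[i] = -kt * logsumexp(-row[ok] / kt, b=dy[ok])
        if E is not None:
            w = np.exp(-(row[ok] - row[ok].min()) / kt) * dy[ok]
            ei = E[i][ok]
            good = np.isfinite(ei)
            if good.any():
                err[i] = float(np.average(ei[good], weights=w[good]))
    res = FESGrid((fes.names[keep],), [fes.edges[keep]], out,
                  error=err if E is not None else None)
    return res.normalize()


@dataclass(frozen=True)
class BarrierResult:
    value_kj: float
    value_kcal: float
    location: float
    index: int


def barrier_height(fes: FESGrid, window=(-2.0, 3.0)) -> BarrierResult:
    """Largest free energy inside an open CV window of a min-0 1D profile.

    This is the desorption barrier convention: ΔF_des = max over
    −2 < cv < 3 of ΔF(cv) with ΔF zeroed at its global minimum.
    """
    if fes.ndim != 1:
        raise ValueError("barrier_height needs a 1D profile")
    x = fes.centers[0]
    sel = (x > window[0]) & (x < window[1]) & fes.defined
    if not sel.any():
        raise ValueError(f"no defined bins inside window {window}")
    F = np.where(sel, fes.free_energy, -np.inf)
    k = int(np.argmax(F))
    return BarrierResult(float(F[k]), float(F[k] / KJ_PER_KCAL), float(x[k]), k)


# ---------------------------------------------------------------------------
# Statistics


def block_standard_error(series, n_blocks: int = 2) -> float:
    """SE of the mean from equal contiguous blocks (std of block means / √n)."""
    x = np.asarray(series, dtype=float).ravel()
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(x) < n_blocks:
        raise ValueError(f"series of length {len(x)} cannot form {n_blocks} blocks")
    usable = (len(x) // n_blocks) * n_blocks
    means = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


@dataclass
class BlockingResult:
    """Flyvbjerg–Petersen blocking analysis of a correlated series."""

    block_sizes: np.ndarray
    se: np.ndarray
    se_err: np.ndarray
    plateau_se: float
    plateau_level: int
    n_eff: float
    converged: bool


def flyvbjerg_petersen(series) -> BlockingResult:
    """Iterative pairwise blocking: SE per level, plateau detection, n_eff.

    At each level the series is halved by averaging adjacent pairs;
    SE² = var/(n) with an uncertainty SE/√(2(n−1)).  The plateau is the
    first level whose successor's SE no longer exceeds it by more than its
    own uncertainty; without a plateau the last level is returned flagged
    unconverged.  n_eff = sample variance / plateau SE².
    """
    x = np.asarray(series, dtype=float).ravel()
    if len(x) < 8:
        raise ValueError("need at least 8 points for blocking")
    var0 = x.var(ddof=1)
    sizes, ses, errs = [], [], []
    level = x.copy()
    size = 1
    while len(level) >= 2:
        n = len(level)
        v = level.var(ddof=1)
        se = np.sqrt(v / n)
        sizes.append(size)
        ses.append(se)
        errs.append(se / np.sqrt(2.0 * (n - 1)))
        if n < 4:
            break
        m = (n // 2) * 2
        level = level[:m].reshape(-1, 2).mean(axis=1)
        size *= 2
    sizes, ses, errs = map(np.asarray, (sizes, ses, errs))
    plateau = None
    for k in range(len(ses) - 1):
        if ses[k + 1] <= ses[k] + errs[k]:
            plateau = k
            break
    converged = plateau is not None
    if plateau is None:
        plateau = len(ses) - 1
    pse = float(ses[plateau])
    n_eff = float(var0 / pse**2) if pse > 0 else float(len(x))
    return BlockingResult(sizes, ses, errs, pse, int(plateau), n_eff, converged)


def decorrelated_samples(series) -> np.ndarray:
    """Block-average a correlated series at its blocking-plateau block size.

    The returned block means are approximately independent and suitable
    for significance testing.
    """
    x = np.asarray(series, dtype=float).ravel()
    res = flyvbjerg_petersen(x)
    bs = int(res.block_sizes[res.plateau_level])
    usable = (len(x) // bs) * bs
    return x[:usable].reshape(-1, bs).mean(axis=1)


def welch_t_test(sample_a, sample_b):
    """Welch's unequal-variance t-test: (t, dof, two-sided p)."""
    from scipy import stats

    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        # degenerate: no within-sample spread
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    dof = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# HILLS file I/O (PLUMED-compatible column layout)


def write_hills(hills, path, cv_names) -> None:
    names = list(cv_names)
    with open(path, "w") as fh:
        fh.write(
            "#! FIELDS time "
            + " ".join(names)
            + " "
            + " ".join(f"sigma_{n}" for n in names)
            + " height biasf walker\n"
        )
        for h in hills:
            row = (
                [h.time]
                + list(h.center)
                + list(h.sigma)
                + [h.height, 0.0, h.walker]
            )
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_hills(path):
    """Read a PLUMED-style HILLS file; a trailing walker column is optional."""
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#!"):
        raise ValueError(f"{path} lacks a '#! FIELDS' header")
    fields = header.split()[2:]
    ncv = sum(1 for f in fields if f.startswith("sigma_"))
    if ncv == 0:
        raise ValueError("no sigma_* columns found")
    has_walker = fields[-1] == "walker"
    data = np.atleast_2d(np.loadtxt(path, comments="#"))
    hills = []
    for row in data:
        hills.append(
            HillRecord(
                time=float(row[0]),
                center=tuple(row[1 : 1 + ncv]),
                sigma=tuple(row[1 + ncv : 1 + 2 * ncv]),
                height=float(row[1 + 2 * ncv]),
                walker=int(row[-1]) if has_walker else 0,
            )
        )
    return hills
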