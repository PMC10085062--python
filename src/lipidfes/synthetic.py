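"""Synthetic inputs with exact ground truth.

Two families of generators make every estimator and descriptor testable
by parameter recovery, without any external data:

* geometric membrane fixtures — a two-leaflet lattice bilayer of
  multi-bead lipids (phosphate bead, anchor bead, hydrophobic tail beads),
  an optional rigid "disruptor" pseudo-protein with hydrophobic residues,
  and one tagged transferring lipid posed in a chosen state.  The
  generator emits a ledger of every planted quantity (areas, depths, tail
  cosines, per-lipid contact counts from an independent brute-force loop).

* CV-space stochastic samplers — overdamped Langevin dynamics on analytic
  potentials, optionally driven by the umbrella or multi-walker
  well-tempered metadynamics protocols.  The biasing acts directly on the
  sampler's coordinates (the coordinates are the collective variables),
  so free-energy estimators can be validated against exact quadrature.

Every generator is a pure function of (spec, seed); per-walker and
per-window seeds derive as ``seed + index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import json

import numpy as np

from .cv import CVSeries
from .fes import (
    KB,
    BiasGrid,
    FESGrid,
    HillRecord,
    SteeringProtocol,
    UmbrellaWindowData,
    WTMDParams,
    wall_potential,
)
from .membrane import LipidView
from .structures import AtomRecord, Frame, MolecularSystem, Trajectory

__all__ = [
    "ToyPotential",
    "LangevinParams",
    "ToyMembraneSpec",
    "DisruptorSpec",
    "generate_membrane_fixture",
    "generate_desorption_path",
    "langevin_sample",
    "run_toy_wtmd",
    "toy_wtmd_params",
    "run_toy_umbrella",
    "analytic_fes",
    "write_ledger",
]


# ---------------------------------------------------------------------------
# Analytic potentials


@dataclass(frozen=True)
class ToyPotential:
    """Analytic CV-space potential with exact gradient and quadrature FES.

    Forms: ``harmonic`` (0.5 k x^2), ``double_well_1d``
    (B ((x/a)^2 - 1)^2, minima at ±a, barrier B), and
    ``double_well_2d_coupled`` (the 1D double well in x plus
    0.5 k_y y^2 + c x y).  Energies kJ/mol.
    """

    form: str = "double_well_1d"
    barrier: float = 10.0       # B, kJ/mol
    well_pos: float = 1.0       # a
    curvature: float = 10.0     # k (harmonic) or k_y (2D)
    coupling: float = 0.5       # c (2D only)
    temperature: float = 310.0  # K, physiological reference temperature

    def __post_init__(self):
        if self.form not in ("harmonic", "double_well_1d", "double_well_2d_coupled"):
            raise ValueError(f"unknown potential form {self.form!r}")

    @property
    def dim(self) -> int:
        return 2 if self.form == "double_well_2d_coupled" else 1

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            return 0.5 * self.curvature * np.squeeze(x) ** 2
        a, B = self.well_pos, self.barrier
        if self.form == "double_well_1d":
            return B * ((np.squeeze(x) / a) ** 2 - 1.0) ** 2
        xx, yy = x[..., 0], x[..., 1]
        return (
            B * ((xx / a) ** 2 - 1.0) ** 2
            + 0.5 * self.curvature * yy**2
            + self.coupling * xx * yy
        )

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            return self.curvature * x
        a, B = self.well_pos, self.barrier
        if self.form == "double_well_1d":
            return 4.0 * B * x * ((x / a) ** 2 - 1.0) / a**2
        g = np.empty_like(x)
        xx, yy = x[..., 0], x[..., 1]
        g[..., 0] = 4.0 * B * xx * ((xx / a) ** 2 - 1.0) / a**2 + self.coupling * yy
        g[..., 1] = self.curvature * yy + self.coupling * xx
        return g


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped Euler–Maruyama integration parameters.

    Stability requires timestep < 2 * friction / k_max where k_max is the
    stiffest curvature encountered (potential plus any bias springs).
    """

    timestep: float = 0.005   # ps
    friction: float = 1.0     # kJ/mol ps nm^-2 (sets the diffusion constant)
    temperature: float = 310.0
    n_steps: int = 100000
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0 or self.friction <= 0 or self.n_steps < 1:
            raise ValueError("timestep, friction and n_steps must be positive")


def _em_drive(potential, params, x0, extra_force=None, record_stride=1,
              per_step=None, divergence_bound=1e3, rng=None, noise=None,
              extra_energy=None, metropolis=False, uniforms=None):
    """Core overdamped-Langevin loop over a batch of replicas.

    ``x0`` is (M, D); ``extra_force(x, step) -> (M, D)`` adds bias forces;
    ``per_step(x, step)`` is a post-step callback (hill deposition);
    ``noise`` is a pre-drawn (n_steps, M, D) standard-normal array.

    With ``metropolis=True`` (requires ``extra_energy`` matching
    ``extra_force``) each Euler–Maruyama proposal is accepted or rejected
    so the stationary law is exact at finite timestep (MALA); otherwise
    plain Euler–Maruyama with its O(dt) stationary bias.
    Returns recorded positions (n_rec, M, D) and their step indices.
    """
    x = np.array(x0, dtype=float)
    M, D = x.shape
    dt, zeta, kt = params.timestep, params.friction, KB * params.temperature
    amp = np.sqrt(2.0 * kt * dt / zeta)
    if noise is None:
        rng = rng or np.random.default_rng(params.seed)
        noise = rng.standard_normal((params.n_steps, M, D))
    if metropolis and uniforms is None:
        rng = rng or np.random.default_rng(params.seed)
        uniforms = rng.uniform(size=(params.n_steps, M))

    def force(y, step):
        f = -potential.gradient(y).reshape(M, D)
        if extra_force is not None:
            f = f + extra_force(y, step)
        return f

    def energy(y, step):
        u = np.atleast_1d(potential.energy(y))
        if extra_energy is not None:
            u = u + extra_energy(y, step)
        return u

    rec, rec_steps = [], []
    fx = force(x, 0)
    ux = energy(x, 0) if metropolis else None
    for step in range(params.n_steps):
        prop = x + fx * dt / zeta + amp * noise[step]
        if metropolis:
            fp = force(prop, step)
            up = energy(prop, step)
            # log q(x|prop) - log q(prop|x) for the EM proposal kernel
            fwd = prop - x - fx * dt / zeta
            bwd = x - prop - fp * dt / zeta
            logq = ((fwd**2).sum(axis=1) - (bwd**2).sum(axis=1)) / (2.0 * amp**2)
            log_acc = -(up - ux) / kt + logq
            accept = np.log(uniforms[step]) < log_acc
            x = np.where(accept[:, None], prop, x)
            fx = np.where(accept[:, None], fp, fx)
            ux = np.where(accept, up, ux)
        else:
            x = prop
        if np.any(np.abs(x) > divergence_bound):
            raise FloatingPointError(
                f"Langevin trajectory diverged at step {step} (|x| > {divergence_bound})"
            )
        if (step + 1) % record_stride == 0:
            rec.append(x.copy())
            rec_steps.append(step + 1)
        deposited = False
        if per_step is not None:
            deposited = bool(per_step(x, step))
        next_step = min(step + 1, params.n_steps - 1)
        if not metropolis:
            fx = force(x, next_step)
        elif deposited:
            # the bias changed under our feet: refresh cached energies
            fx = force(x, next_step)
            ux = energy(x, next_step)
    return np.array(rec), np.array(rec_steps)


def langevin_sample(potential: ToyPotential, params: LangevinParams, x0=None,
                    record_stride: int = 1, metropolis: bool = False) -> CVSeries:
    """Unbiased overdamped Langevin (Euler–Maruyama) trajectory.

    ``metropolis=True`` adds an accept/reject step (MALA), removing the
    O(dt) bias of the stationary law at the cost of ~2x work per step.
    """
    D = potential.dim
    if x0 is None:
        x0 = np.zeros(D)
        if potential.form != "harmonic":
            x0 = np.full(D, 0.0)
            x0[0] = potential.well_pos
    x0 = np.asarray(x0, dtype=float).reshape(1, D)
    rec, steps = _em_drive(potential, params, x0, record_stride=record_stride,
                           metropolis=metropolis)
    times = steps * params.timestep
    names = ["x", "y"][:D]
    return CVSeries(times, {n: rec[:, 0, d] for d, n in enumerate(names)},
                    metadata={"seed": params.seed, "potential": potential.form})


# ---------------------------------------------------------------------------
# Toy enhanced-sampling protocols


def toy_wtmd_params(
    x_range=(-2.0, 2.0),
    sigmas=(0.1, 0.1),
    n_walkers: int = 2,
    bias_factor: float = 30.0,
    temperature: float = 310.0,
    wall_spring: float = 500.0,
) -> WTMDParams:
    """Paper protocol transposed to the toy axis: walls at the axis ends,
    hill widths sized to the toy CV scale, bias factor 30 retained."""
    walls = (tuple(x_range),) + (None,) * (len(sigmas) - 1)
    return WTMDParams(
        bias_factor=bias_factor,
        temperature=temperature,
        sigmas=tuple(sigmas),
        walls=walls,
        wall_spring=wall_spring,
        n_walkers=n_walkers,
    )


def _wall_force(x, walls, spring):
    f = np.zeros_like(x)
    for d, w in enumerate(walls or ()):
        if w is None or d >= x.shape[1]:
            continue
        lo, hi = w
        if lo is not None:
            f[:, d] += np.where(x[:, d] < lo, -spring * (x[:, d] - lo), 0.0)
        if hi is not None:
            f[:, d] += np.where(x[:, d] > hi, -spring * (x[:, d] - hi), 0.0)
    return f


def run_toy_wtmd(
    potential: ToyPotential,
    wtmd: WTMDParams,
    langevin: LangevinParams,
    grid_edges,
    deposit_stride: int = 100,
    record_stride: int = 10,
    steering: SteeringProtocol | None = None,
    x0=None,
):
    """Multi-walker well-tempered metadynamics in CV space.

    All walkers share one bias (tabulated on ``grid_edges``); every
    ``deposit_stride`` steps each walker deposits a tempered hill at its
    position (paused while a steering phase is active, during which the
    accumulated bias still acts and recorded frames are masked out).
    Returns (per-walker CVSeries list, time-ordered hill list, bias grid).
    """
    W, D = wtmd.n_walkers, potential.dim
    if W < 1:
        raise ValueError("need at least one walker")
    sig = np.asarray(wtmd.sigmas[:D], dtype=float)
    if x0 is None:
        x0 = np.zeros((W, D))
        for w in range(W):
            x0[w, 0] = potential.well_pos * (1 if w % 2 == 0 else -1)
            if D == 2:
                x0[w, 1] = -potential.coupling * x0[w, 0] / potential.curvature
    x0 = np.asarray(x0, dtype=float).reshape(W, D)
    grid = BiasGrid(grid_edges)
    hills: list = []
    dt = langevin.timestep

    steer_state = {"x_start": None}

    def steering_active(t):
        return steering is not None and steering.start <= t < steering.start + steering.duration

    def extra_force(x, step):
        t = step * dt
        f = -grid.gradient(x)
        f += _wall_force(x, wtmd.walls, wtmd.wall_spring)
        if steering_active(t):
            if steer_state["x_start"] is None:
                steer_state["x_start"] = x.copy()
            frac = min((t - steering.start) / steering.duration, 1.0)
            targets = np.asarray(steering.targets, dtype=float).reshape(W, D)
            goal = steer_state["x_start"] + frac * (targets - steer_state["x_start"])
            springs = np.asarray(steering.springs[:D], dtype=float)
            f = f - springs * (x - goal)
        return f

    def extra_energy(x, step):
        t = step * dt
        u = grid.interpolate(x) + wall_potential(x, wtmd.walls, wtmd.wall_spring)
        if steering_active(t) and steer_state["x_start"] is not None:
            frac = min((t - steering.start) / steering.duration, 1.0)
            targets = np.asarray(steering.targets, dtype=float).reshape(W, D)
            goal = steer_state["x_start"] + frac * (targets - steer_state["x_start"])
            springs = np.asarray(steering.springs[:D], dtype=float)
            u = u + 0.5 * (springs * (x - goal) ** 2).sum(axis=1)
        return u

    def per_step(x, step):
        t = (step + 1) * dt
        if (step + 1) % deposit_stride != 0:
            return False
        if steering_active(t):
            return False
        v_here = grid.interpolate(x)
        for w in range(W):
            h = wtmd.initial_height * np.exp(-v_here[w] / wtmd.delta_t_energy)
            grid.add_hill(x[w], sig, h)
            hills.append(HillRecord(t, tuple(x[w]), tuple(sig), float(h), w))
        return True

    streams = [np.random.default_rng(langevin.seed + w) for w in range(W)]
    noise = np.stack(
        [r.standard_normal((langevin.n_steps, D)) for r in streams], axis=1
    )
    uniforms = np.stack(
        [r.uniform(size=langevin.n_steps) for r in streams], axis=1
    )
    rec, steps = _em_drive(
        potential, langevin, x0, extra_force=extra_force,
        record_stride=record_stride, per_step=per_step, noise=noise,
        extra_energy=extra_energy, metropolis=True, uniforms=uniforms,
    )
    times = steps * dt
    masked = (
        np.array([steering_active(t) for t in times])
        if steering is not None
        else np.zeros(len(times), dtype=bool)
    )
    names = ["x", "y"][:D]
    series = [
        CVSeries(
            times,
            {n: rec[:, w, d] for d, n in enumerate(names)},
            metadata={"walker": w, "seed": langevin.seed + w},
            mask=~masked,
        )
        for w in range(W)
    ]
    hills.sort(key=lambda h: (h.time, h.walker))
    return series, hills, grid


def run_toy_umbrella(
    potential: ToyPotential,
    centers,
    spring: float,
    langevin: LangevinParams,
    burn_in_fraction: float = 20.0 / 52.0,
    record_stride: int = 1,
):
    """Independent harmonic-window runs along a 1D toy axis.

    Mirrors the atomistic umbrella protocol it scales down: equally spaced
    centers, one harmonic bias per window, and the leading
    ``burn_in_fraction`` of each window's frames discarded as
    equilibration (20/52 of the run, matching the 20 ns / 52 ns
    discard convention).
    """
    if potential.dim != 1:
        raise ValueError("toy umbrella sampling runs on a 1D potential")
    centers = np.sort(np.asarray(centers, dtype=float))
    if langevin.n_steps < record_stride:
        raise ValueError("zero-length umbrella run")
    M = len(centers)
    x0 = centers.reshape(M, 1)
    c = centers.reshape(M, 1)

    def extra_force(x, step):
        return -spring * (x - c)

    def extra_energy(x, step):
        return 0.5 * spring * ((x - c) ** 2).sum(axis=1)

    streams = [np.random.default_rng(langevin.seed + k) for k in range(M)]
    noise = np.stack([r.standard_normal((langevin.n_steps, 1)) for r in streams], axis=1)
    uniforms = np.stack([r.uniform(size=langevin.n_steps) for r in streams], axis=1)
    rec, _ = _em_drive(potential, langevin, x0, extra_force=extra_force,
                       record_stride=record_stride, noise=noise,
                       extra_energy=extra_energy, metropolis=True,
                       uniforms=uniforms)
    n_burn = int(burn_in_fraction * len(rec))
    windows = [
        UmbrellaWindowData(center=float(centers[k]), spring=spring,
                           samples=rec[n_burn:, k, 0])
        for k in range(M)
    ]
    gaps = np.diff(centers)
    sigma = np.sqrt(KB * langevin.temperature / spring)
    if np.any(gaps > 4 * sigma):
        import warnings

        warnings.warn("umbrella windows may not overlap (gap > 4 thermal sigma)")
    return windows


# ---------------------------------------------------------------------------
# Quadrature ground truth


def analytic_fes(potential: ToyPotential, edges, temperature: float,
                 subdivisions: int = 15) -> FESGrid:
    """Exact (quadrature) free-energy surface on a grid, min 0.

    Bin values are Boltzmann bin averages, matching what a histogram-based
    estimator converges to:  F_b = -kT ln( mean over bin of e^{-U/kT} ).
    Raises if the wells carry weight outside the grid.
    """
    kt = KB * temperature
    edges = [np.asarray(e, dtype=float) for e in (edges if isinstance(edges, (list, tuple)) else [edges])]
    if len(edges) != potential.dim:
        raise ValueError(f"need {potential.dim} edge arrays for {potential.form}")

    m = subdivisions + (subdivisions % 2)  # composite Simpson needs even count

    def _bin_nodes(e):
        # Simpson nodes and normalized weights per bin (bin-mean quadrature)
        widths = np.diff(e)
        offs = np.arange(m + 1) / m
        nodes = e[:-1, None] + widths[:, None] * offs[None, :]
        w = np.ones(m + 1)
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        return nodes, w / (3.0 * m)

    if potential.dim == 1:
        pts, w = _bin_nodes(edges[0])                  # (nbin, m+1)
        dens = np.exp(-potential.energy(pts[..., None]) / kt) @ w
    else:
        px, wx = _bin_nodes(edges[0])                  # (nx, m+1)
        py, wy = _bin_nodes(edges[1])                  # (ny, m+1)
        X = px[:, None, :, None]
        Y = py[None, :, None, :]
        XX, YY = np.broadcast_arrays(X, Y)
        U = potential.energy(np.stack([XX, YY], axis=-1))
        dens = np.einsum("ijab,a,b->ij", np.exp(-U / kt), wx, wy)
    total = dens.sum()
    # wells must be interior: outermost bins must carry negligible weight
    edge_mass = dens[[0, -1]].sum() if potential.dim == 1 else (
        dens[[0, -1], :].sum() + dens[:, [0, -1]].sum()
    )
    if edge_mass > 1e-3 * total:
        raise ValueError("grid does not cover the potential wells")
    with np.errstate(divide="ignore"):
        F = -kt * np.log(dens)
    names = ("x", "y")[: potential.dim]
    return FESGrid(tuple(names), edges, F).normalize()


# ---------------------------------------------------------------------------
# Membrane fixtures


@dataclass(frozen=True)
class DisruptorSpec:
    """Rigid pseudo-protein embedded in the upper leaflet."""

    radius: float = 1.2          # nm, xy influence radius
    insertion_depth: float = 0.3  # nm below the upper phosphate plane
    displaced_per_lipid: int = 5  # tail-end beads pushed out of contact range
    n_residues: int = 12


@dataclass(frozen=True)
class ToyMembraneSpec:
    """Geometry of the synthetic bilayer (defaults emulate a small POPC
    patch: lattice area 0.64 nm^2 per lipid, phosphate planes ±1.9 nm,
    14 hydrophobic beads per tail, 2 tails)."""

    lipids_per_leaflet: int = 64
    lattice: float = 0.8          # nm
    tail_beads: int = 14
    n_tails: int = 2
    head_z: float = 1.9           # nm, phosphate plane height
    bead_spacing: float = 0.118   # nm along z between tail beads
    tail_xy_offset: float = 0.15  # nm between the two tails
    z_jitter: float = 0.0         # headgroup z noise sigma, nm
    tilt_sigma: float = 0.0       # per-lipid tail tilt noise, radians
    disruptor: DisruptorSpec | None = None
    tagged_state: str | tuple = "inserted"   # or ("partially_extracted", f) or ("desorbed", h)
    solvent_thickness: float | None = None   # nm per side; None = auto-sized
    compute_contact_ledger: bool = True
    seed: int = 0

    def __post_init__(self):
        side = int(round(np.sqrt(self.lipids_per_leaflet)))
        if side * side != self.lipids_per_leaflet:
            raise ValueError("lipids_per_leaflet must be a perfect square")
        if self.disruptor is not None:
            if self.disruptor.radius >= side * self.lattice / 2:
                raise ValueError("disruptor radius exceeds half the box")


def _lipid_atoms(spec: ToyMembraneSpec, resid, resname, origin, direction, tilt=None):
    """Build one lipid's atom names and coordinates.

    ``direction`` is -1 for the upper leaflet (tails point down) and +1
    for the lower.  ``tilt`` optionally rotates the tail direction.
    """
    names, coords = [], []
    px, py, pz = origin
    names.append("P")
    coords.append((px, py, pz))
    anchor_z = pz + direction * 0.1
    names.append("C2")
    coords.append((px, py, anchor_z))
    d = np.array([0.0, 0.0, direction])
    if tilt is not None:
        theta, phi = tilt
        d = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
             direction * np.cos(theta)]
        )
    for tail in range(spec.n_tails):
        off = (tail - (spec.n_tails - 1) / 2.0) * spec.tail_xy_offset
        for k in range(1, spec.tail_beads + 1):
            names.append(f"T{tail+1}{k}")
            p = np.array([px + off, py, anchor_z]) + d * (k * spec.bead_spacing)
            coords.append(tuple(p))
    return names, coords


def generate_membrane_fixture(spec: ToyMembraneSpec):
    """Build the bilayer fixture: (MolecularSystem, 1-frame Trajectory, ledger).

    The ledger records every planted truth: lattice areas, thickness, per
    tail cos(theta_z), per-lipid hydrophobic contact counts from an
    independent brute-force double loop, displaced-bead counts near the
    disruptor, and the tagged lipid's pose.
    """
    rng = np.random.default_rng(spec.seed)
    side = int(round(np.sqrt(spec.lipids_per_leaflet)))
    L = side * spec.lattice
    # solvent slabs must fit an extracted lipid without periodic contact
    extent = 0.1 + spec.tail_beads * spec.bead_spacing  # P-to-tail-end, nm
    if spec.solvent_thickness is not None:
        solvent = spec.solvent_thickness
    else:
        state = spec.tagged_state
        lift = 1.2 if not isinstance(state, str) and state[0] == "partially_extracted" \
            else (float(state[1]) if not isinstance(state, str) else 0.0)
        solvent = max(3.2, extent + lift + 1.2)
    box = np.array([L, L, 2 * spec.head_z + 2 * solvent])

    atoms: list = []
    coords: list = []
    views: list = []
    ledger: dict = {
        "spec": {
            "lipids_per_leaflet": spec.lipids_per_leaflet,
            "lattice": spec.lattice,
            "tail_beads": spec.tail_beads,
            "n_tails": spec.n_tails,
            "seed": spec.seed,
        },
        "box": box.tolist(),
        "true_area": spec.lattice**2,
        "true_thickness": 2 * spec.head_z,
        "true_cos_theta": [],
        "tails_per_lipid": spec.n_tails,
    }
    z_mid = box[2] / 2.0
    resid = 0
    tagged_resid = None
    atoms_per_lipid = 2 + spec.n_tails * spec.tail_beads

    def _add_lipid(origin, direction, resname):
        nonlocal resid
        resid += 1
        tilt = None
        if spec.tilt_sigma > 0:
            theta = abs(rng.normal(0.0, spec.tilt_sigma))
            phi = rng.uniform(0, 2 * np.pi)
            tilt = (theta, phi)
        names, xyz = _lipid_atoms(spec, resid, resname, origin, direction, tilt)
        start = len(atoms)
        for n, p in zip(names, xyz):
            flags = {"heavy"}
            if n == "P":
                flags.add("phosphate")
            if n.startswith("T"):
                flags.add("hydrophobic_carbon")
            atoms.append(
                AtomRecord(len(atoms), n, resname, resid, role_flags=frozenset(flags))
            )
            coords.append(p)
        tails = [
            list(range(start + 2 + t * spec.tail_beads,
                       start + 2 + (t + 1) * spec.tail_beads))
            for t in range(spec.n_tails)
        ]
        view = LipidView(
            lipid_id=resid,
            phosphorus=start,
            tails=tails,
            anchor=start + 1,
            leaflet=1 if direction < 0 else -1,
            hydrophobic=np.arange(start + 2, start + atoms_per_lipid),
        )
        views.append(view)
        # exact per-tail cosine of the constructed geometry:
        # anchor - terminal = -offset_x - d * L with L the tail length
        L_tail = spec.tail_beads * spec.bead_spacing
        if tilt is None:
            d_vec = np.array([0.0, 0.0, direction])
        else:
            th, ph = tilt
            d_vec = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                              direction * np.cos(th)])
        cosines = []
        for t in range(spec.n_tails):
            off = (t - (spec.n_tails - 1) / 2.0) * spec.tail_xy_offset
            v = -np.array([off, 0.0, 0.0]) - d_vec * L_tail
            cosines.append(float(v[2] / np.linalg.norm(v)))
        ledger["true_cos_theta"].append(cosines)
        return view

    # upper leaflet (direction -1: tails point down), then lower
    tag_index = None
    for leaflet, direction in ((1, -1.0), (-1, 1.0)):
        zp = z_mid + (spec.head_z if leaflet > 0 else -spec.head_z)
        for iy in range(side):
            for ix in range(side):
                x = (ix + 0.5) * spec.lattice
                y = (iy + 0.5) * spec.lattice
                z = zp + (rng.normal(0, spec.z_jitter) if spec.z_jitter > 0 else 0.0)
                resname = "LIP"
                if leaflet > 0 and ix == 0 and iy == 0:
                    resname = "TAG"
                v = _add_lipid((x, y, z), direction, resname)
                if resname == "TAG":
                    tag_index = len(views) - 1
                    tagged_resid = v.lipid_id

    coords = np.array(coords, dtype=float)

    # pose the tagged lipid
    state = spec.tagged_state
    state_name = state if isinstance(state, str) else state[0]
    tag = views[tag_index]
    if state_name != "inserted":
        param = 0.0 if isinstance(state, str) else float(state[1])
        others_hydro = np.concatenate(
            [v.hydrophobic for k, v in enumerate(views)
             if k != tag_index and v.leaflet == 1]
        )
        z_top = coords[others_hydro, 2].max()
        tag_atoms = np.arange(tag.phosphorus, tag.phosphorus + atoms_per_lipid)
        z_low = coords[tag.hydrophobic, 2].min()
        if state_name == "desorbed":
            dz = (z_top - z_low) + param
        elif state_name == "partially_extracted":
            full = (z_top - z_low) + 1.1  # just clears the 1 nm contact cutoff
            dz = param * full
        else:
            raise ValueError(f"unknown tagged state {state!r}")
        coords[tag_atoms, 2] += dz
        ledger["tagged_shift_z"] = float(dz)
    ledger["tagged_state"] = state_name
    ledger["tagged_resid"] = tagged_resid
    ledger["tagged_index"] = tag_index

    # disruptor: rigid hydrophobic pseudo-protein + displaced tail beads
    displaced = {}
    if spec.disruptor is not None:
        d = spec.disruptor
        cx, cy = L / 2.0, L / 2.0
        zp_up = z_mid + spec.head_z
        resid += 1
        ring = np.linspace(0, 2 * np.pi, d.n_residues, endpoint=False)
        depths = np.linspace(0.0, d.insertion_depth, d.n_residues)
        true_depths = {}
        for k, (ang, dep) in enumerate(zip(ring, depths)):
            resid_k = resid + k
            x = cx + 0.4 * d.radius * np.cos(ang)
            y = cy + 0.4 * d.radius * np.sin(ang)
            z = zp_up - dep
            atoms.append(
                AtomRecord(len(atoms), "CB", "DSR", resid_k,
                           role_flags=frozenset({"heavy", "hydrophobic_carbon"}))
            )
            coords = np.vstack([coords, [x, y, z]])
            true_depths[resid_k] = -dep
        resid += d.n_residues - 1
        ledger["disruptor_residues"] = sorted(true_depths)
        ledger["true_depths"] = {str(k): v for k, v in true_depths.items()}
        # push tail-end beads of nearby upper-leaflet lipids out of contact
        # range: parked on a sparse grid (spacing > cutoff) high in solvent
        park_z = z_mid + 3.1
        ncols = int(L // 1.1)
        park_k = 0
        for k, v in enumerate(views):
            if v.leaflet != 1 or k == tag_index:
                continue
            px, py = coords[v.phosphorus, :2]
            if (px - cx) ** 2 + (py - cy) ** 2 > d.radius**2:
                continue
            ends = np.concatenate([t[-(d.displaced_per_lipid // spec.n_tails + 1):]
                                   for t in v.tails])[: d.displaced_per_lipid]
            for b in ends:
                if park_k >= ncols * ncols:
                    raise ValueError("too many displaced beads to park clear of contacts")
                coords[b] = [
                    0.5 + 1.1 * (park_k % ncols),
                    0.5 + 1.1 * (park_k // ncols),
                    park_z,
                ]
                park_k += 1
            displaced[v.lipid_id] = len(ends)
    ledger["displaced_per_lipid"] = {str(k): v for k, v in displaced.items()}

    system = MolecularSystem(atoms, coords, box)

    # independent brute-force contact oracle (double loop over lipid pairs)
    if spec.compute_contact_ledger:
        ncc = {}
        hydro = [v.hydrophobic for v in views]
        for i in range(len(views)):
            total = 0
            for j in range(len(views)):
                if i == j:
                    continue
                dvec = coords[hydro[i]][:, None, :] - coords[hydro[j]][None, :, :]
                dvec -= box * np.round(dvec / box)
                dist = np.sqrt((dvec**2).sum(axis=-1))
                total += int((dist <= 1.0).sum())
            ncc[views[i].lipid_id] = total
        ledger["true_ncc"] = {str(k): v for k, v in ncc.items()}

    traj = Trajectory(system, [Frame(0.0, coords.copy(), box.copy())])
    return system, traj, views, ledger


def generate_desorption_path(spec: ToyMembraneSpec, n_frames: int = 10,
                             max_height: float = 3.0):
    """Trajectory in which the tagged lipid rises from inserted to desorbed.

    Frame k poses the tagged lipid at fraction k/(n-1) of the way to
    ``max_height`` nm above the leaflet.  Returns (trajectory, views,
    per-frame ledger list).
    """
    frames, ledgers = [], []
    views = None
    extent = 0.1 + spec.tail_beads * spec.bead_spacing
    base = replace(spec, tagged_state="inserted", compute_contact_ledger=False,
                   solvent_thickness=max(3.2, extent + max_height + 1.2))
    for k in range(n_frames):
        frac = k / max(n_frames - 1, 1)
        if k == 0:
            s = base
        else:
            s = replace(base, tagged_state=("desorbed", frac * max_height - 1.1)
                        if frac * max_height > 1.1
                        else ("partially_extracted", frac * max_height / 1.1))
        system, traj, v, led = generate_membrane_fixture(s)
        views = v
        frames.append(Frame(float(k), traj._frames[0].coordinates, system.box))
        ledgers.append(led)
    topo, _, _, _ = generate_membrane_fixture(base)
    return Trajectory(topo, frames), views, ledgers


def write_ledger(ledger: dict, path) -> None:
    """Serialize a generator ledger as JSON lines (one key per line)."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        for key, value in ledger.items():
            fh.write(json.dumps({key: value}, default=_default) + "\n")
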