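"""Particle-system input generation.

Deterministic synthetic configurations (mixed / demixed / clustered labels
on a jittered lattice) plus a 2D overdamped Brownian-dynamics simulator of
the symmetric Lennard-Jones binary mixture:

* mix mode: all pair interactions identical, epsilon = 1, truncated at the
  potential minimum 2^(1/6) sigma so the force is purely repulsive (the WCA
  choice) — the two species differ only by their label and mix by diffusion.
* demix mode: the A-B interaction stays repulsive-only, while A-A and B-B
  get epsilon = 2 with the cut-off extended to 2.5 sigma, introducing a
  same-type attraction that drives phase separation below the demixing
  temperature.

The integrator is Euler-Maruyama for the overdamped Langevin equation
x <- x + (F/gamma) dt + sqrt(2 k_B T dt / gamma) eta, with periodic
minimum-image boundaries.  Potentials are truncated (not shifted): BD only
needs forces, and the force is continuous enough at the cut-off for the
time steps used.  Units: sigma = epsilon = k_B = 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .particles import ParticleSnapshot, Trajectory

__all__ = [
    "BDParams",
    "interaction_table",
    "box_for_density",
    "generate_mixed",
    "generate_demixed",
    "generate_clustered",
    "bd_simulate",
    "pair_force",
    "forces_bruteforce",
    "mean_squared_displacement",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)
DEFAULT_DENSITY = 0.85          # particles per sigma^2: closely packed but fluid
MAX_STEP_DISPLACEMENT = 0.5     # abort threshold, in sigma


def box_for_density(n: int, density: float = DEFAULT_DENSITY) -> float:
    """Square-box side giving the requested 2D number density."""
    return float(np.sqrt(n / density))


@dataclass(frozen=True)
class BDParams:
    n: int
    mode: str = "mix"                   # "mix" | "demix"
    box: float | None = None            # side length; default from density 0.85
    composition: float = 0.5            # fraction of type A
    temperature: float = 1.0            # k_B T in epsilon units
    gamma: float = 1.0
    dt: float = 2e-4
    n_steps: int = 10000
    save_every: int = 1000
    seed: int = 0
    init: str = "mixed_random"          # "mixed_random" | "demixed_halves" | "lattice"
    attractive_cutoff: float = 2.5      # same-type cut-off in demix mode

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least two particles")
        if self.mode not in ("mix", "demix"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.init not in ("mixed_random", "demixed_halves", "lattice"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.dt <= 0 or self.temperature <= 0 or self.gamma <= 0:
            raise ValueError("dt, temperature and gamma must be positive")
        if not 0.0 <= self.composition <= 1.0:
            raise ValueError("composition must be a fraction")
        if self.box is None:
            object.__setattr__(self, "box", box_for_density(self.n))
        if self.n / self.box ** 2 > 1.2:
            raise ValueError("density above close packing for soft disks")


def interaction_table(params: BDParams) -> tuple[np.ndarray, np.ndarray]:
    """(epsilon, cutoff) 2x2 tables indexed by the two particle types."""
    eps = np.ones((2, 2))
    cut = np.full((2, 2), WCA_CUTOFF)
    if params.mode == "demix":
        eps[0, 0] = eps[1, 1] = 2.0
        cut[0, 0] = cut[1, 1] = params.attractive_cutoff
    return eps, cut


# ---------------------------------------------------------------------------
# synthetic label patterns on a jittered lattice


def _lattice_positions(n: int, box: float, rng: np.random.Generator,
                       jitter: float = 0.25) -> np.ndarray:
    """n points on a jittered square lattice filling a periodic box."""
    n_side = int(np.ceil(np.sqrt(n)))
    spacing = box / n_side
    sites = np.stack(np.meshgrid(np.arange(n_side), np.arange(n_side),
                                 indexing="ij"), axis=-1).reshape(-1, 2)
    chosen = np.sort(rng.choice(n_side * n_side, size=n, replace=False))
    pos = (sites[chosen] + 0.5) * spacing
    pos += rng.uniform(-jitter, jitter, size=pos.shape) * spacing
    return np.mod(pos, box)


def _check_density(n: int, box: float):
    if n / box ** 2 > 1.2:
        raise ValueError("overfull box: density above close packing")


def generate_mixed(n: int, box: float, composition: float = 0.5,
                   seed: int = 0) -> ParticleSnapshot:
    """Uniformly mixed snapshot: jittered-lattice positions, i.i.d. labels."""
    _check_density(n, box)
    rng = np.random.default_rng(seed)
    pos = _lattice_positions(n, box, rng)
    labels = np.where(rng.random(n) < composition, "A", "B")
    return ParticleSnapshot(pos, labels, (box, box), periodic=True, time=0.0)


def generate_demixed(n: int, box: float, composition: float = 0.5,
                     seed: int = 0) -> ParticleSnapshot:
    """Fully demixed snapshot: the same positions as :func:`generate_mixed`
    under the same seed, labels split at the composition quantile of x."""
    _check_density(n, box)
    rng = np.random.default_rng(seed)
    pos = _lattice_positions(n, box, rng)
    n_a = int(n * composition)
    labels = np.full(n, "B")
    labels[np.argsort(pos[:, 0], kind="stable")[:n_a]] = "A"
    return ParticleSnapshot(pos, labels, (box, box), periodic=True, time=0.0)


def generate_clustered(n: int, box: float, n_domains: int,
                       domain_radius: float, seed: int = 0,
                       max_attempts_per_domain: int = 400) -> ParticleSnapshot:
    """Background of type B with non-overlapping circular type-A domains.

    Domain centres are placed by random sequential addition with minimum
    centre separation 2 * domain_radius (periodic); the resulting overall
    composition is the covered area fraction.
    """
    _check_density(n, box)
    if 2 * domain_radius > box / 2:
        raise ValueError("domains do not fit in the box")
    rng = np.random.default_rng(seed)
    pos = _lattice_positions(n, box, rng)
    centres = np.empty((0, 2))
    if n_domains > 0 and domain_radius > 0:
        min_sep2 = (2 * domain_radius) ** 2
        placed = []
        attempts = 0
        budget = max_attempts_per_domain * n_domains
        while len(placed) < n_domains:
            if attempts >= budget:
                raise RuntimeError(
                    f"placed only {len(placed)}/{n_domains} non-overlapping "
                    "domains; reduce n_domains or domain_radius")
            attempts += 1
            c = rng.uniform(0, box, size=2)
            ok = True
            for p in placed:
                d = c - p
                d -= box * np.round(d / box)
                if d @ d < min_sep2:
                    ok = False
                    break
            if ok:
                placed.append(c)
        centres = np.asarray(placed)
    labels = np.full(n, "B")
    if centres.size:
        from scipy.spatial import cKDTree
        tree = cKDTree(centres, boxsize=(box, box))
        dist, _ = tree.query(np.mod(pos, box))
        labels[dist <= domain_radius] = "A"
    return ParticleSnapshot(pos, labels, (box, box), periodic=True, time=0.0)


# ---------------------------------------------------------------------------
# Brownian dynamics


@njit(cache=True, inline="always")
def _lj_force_over_r(r2, eps):
    """F(r)/r for the 12-6 Lennard-Jones potential at squared distance r2."""
    inv2 = 1.0 / r2
    s6 = inv2 * inv2 * inv2
    return 24.0 * eps * (2.0 * s6 * s6 - s6) * inv2


@njit(cache=True, fastmath=True)
def _bd_kernel(pos, types, box, eps, cut2, gamma, T, dt, n_steps, save_every,
               seed, frames):
    np.random.seed(seed)
    n = pos.shape[0]
    max_cut = np.sqrt(cut2.max())
    n_cells = max(1, int(box / max_cut))
    # dilute systems: no point resolving far below ~1 particle per cell,
    # and the per-step sweep over cells must stay O(n)
    cap = int(np.sqrt(4.0 * n)) + 1
    if n_cells > cap:
        n_cells = cap
    if n_cells < 3:
        n_cells = 1
    cell_size = box / n_cells
    head = np.empty(n_cells * n_cells, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    forces = np.zeros_like(pos)
    noise_amp = np.sqrt(2.0 * T * dt / gamma)
    f = 0
    max_disp2 = MAX_STEP_DISPLACEMENT * MAX_STEP_DISPLACEMENT
    half_box = 0.5 * box
    for step in range(n_steps):
        forces[:] = 0.0
        if n_cells == 1:
            for i in range(n):
                ti = types[i]
                xi = pos[i, 0]
                yi = pos[i, 1]
                for j in range(i + 1, n):
                    dx = xi - pos[j, 0]
                    dy = yi - pos[j, 1]
                    if dx > half_box:
                        dx -= box
                    elif dx < -half_box:
                        dx += box
                    if dy > half_box:
                        dy -= box
                    elif dy < -half_box:
                        dy += box
                    r2 = dx * dx + dy * dy
                    if 1e-12 < r2 < cut2[ti, types[j]]:
                        inv2 = 1.0 / r2
                        s6 = inv2 * inv2 * inv2
                        g = 24.0 * eps[ti, types[j]] * (2.0 * s6 * s6 - s6) * inv2
                        forces[i, 0] += g * dx
                        forces[i, 1] += g * dy
                        forces[j, 0] -= g * dx
                        forces[j, 1] -= g * dy
        else:
            # rebuild cell list
            head[:] = -1
            for i in range(n):
                cx = int(pos[i, 0] / cell_size) % n_cells
                cy = int(pos[i, 1] / cell_size) % n_cells
                c = cx * n_cells + cy
                nxt[i] = head[c]
                head[c] = i
            # Newton's-third-law iteration: same-cell pairs once, then a
            # half stencil of neighbouring cells
            for cx in range(n_cells):
                for cy in range(n_cells):
                    c = cx * n_cells + cy
                    for s in range(5):
                        if s == 0:
                            cc = c
                        elif s == 1:
                            cc = ((cx + 1) % n_cells) * n_cells + cy
                        elif s == 2:
                            cc = ((cx + 1) % n_cells) * n_cells + (cy + 1) % n_cells
                        elif s == 3:
                            cc = cx * n_cells + (cy + 1) % n_cells
                        else:
                            cc = ((cx - 1) % n_cells) * n_cells + (cy + 1) % n_cells
                        i = head[c]
                        while i >= 0:
                            ti = types[i]
                            xi = pos[i, 0]
                            yi = pos[i, 1]
                            j = nxt[i] if s == 0 else head[cc]
                            while j >= 0:
                                dx = xi - pos[j, 0]
                                dy = yi - pos[j, 1]
                                if dx > half_box:
                                    dx -= box
                                elif dx < -half_box:
                                    dx += box
                                if dy > half_box:
                                    dy -= box
                                elif dy < -half_box:
                                    dy += box
                                r2 = dx * dx + dy * dy
                                if 1e-12 < r2 < cut2[ti, types[j]]:
                                    inv2 = 1.0 / r2
                                    s6 = inv2 * inv2 * inv2
                                    g = 24.0 * eps[ti, types[j]] * (2.0 * s6 * s6 - s6) * inv2
                                    forces[i, 0] += g * dx
                                    forces[i, 1] += g * dy
                                    forces[j, 0] -= g * dx
                                    forces[j, 1] -= g * dy
                                j = nxt[j]
                            i = nxt[i]
        # Euler-Maruyama update
        for i in range(n):
            ddx = forces[i, 0] / gamma * dt + noise_amp * np.random.standard_normal()
            ddy = forces[i, 1] / gamma * dt + noise_amp * np.random.standard_normal()
            if ddx * ddx + ddy * ddy > max_disp2:
                return f, step
            x = pos[i, 0] + ddx
            y = pos[i, 1] + ddy
            pos[i, 0] = x - box * np.floor(x / box)
            pos[i, 1] = y - box * np.floor(y / box)
        if (step + 1) % save_every == 0 and f < frames.shape[0]:
            frames[f] = pos
            f += 1
    return f, -1


def _initial_snapshot(params: BDParams, rng: np.random.Generator) -> ParticleSnapshot:
    # small jitter: large displacements would overlap LJ cores and blow up
    # the first integration steps
    pos = _lattice_positions(params.n, params.box, rng,
                             jitter=0.0 if params.init == "lattice" else 0.1)
    n_a = int(params.n * params.composition)
    labels = np.full(params.n, "B")
    if params.init == "mixed_random":
        labels[rng.choice(params.n, size=n_a, replace=False)] = "A"
    else:  # demixed_halves / lattice: split at the composition quantile of x
        labels[np.argsort(pos[:, 0], kind="stable")[:n_a]] = "A"
    return ParticleSnapshot(pos, labels, (params.box, params.box), True, 0.0)


def bd_simulate(params: BDParams,
                init_snapshot: ParticleSnapshot | None = None) -> Trajectory:
    """Run overdamped Brownian dynamics of the binary LJ mixture.

    Returns a trajectory whose first frame is the initial configuration;
    subsequent frames are stored every ``save_every`` steps.  Labels never
    change, so composition is conserved exactly.  A per-step displacement
    larger than half a particle diameter aborts with advice to reduce dt.
    """
    rng = np.random.default_rng(params.seed)
    snap0 = init_snapshot if init_snapshot is not None else _initial_snapshot(params, rng)
    if snap0.dim != 2:
        raise ValueError("the BD simulator is 2D")
    eps, cut = interaction_table(params)
    alpha = list(snap0.alphabet)
    if len(alpha) > 2:
        raise ValueError("binary mixtures only")
    types = snap0.label_indices(alpha).astype(np.int64)
    pos = snap0.positions.astype(np.float64).copy()
    n_frames = params.n_steps // params.save_every
    frames = np.empty((n_frames, params.n, 2))
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    n_saved, bad_step = _bd_kernel(pos, types, float(snap0.box[0]), eps,
                                   cut ** 2, params.gamma, params.temperature,
                                   params.dt, params.n_steps, params.save_every,
                                   kernel_seed, frames)
    if bad_step >= 0:
        raise RuntimeError(
            f"integration unstable at step {bad_step}: a particle moved more "
            f"than {MAX_STEP_DISPLACEMENT} sigma in one step; reduce dt")
    snaps = [ParticleSnapshot(snap0.positions, snap0.labels, snap0.box, True, 0.0)]
    for k in range(n_saved):
        t = (k + 1) * params.save_every * params.dt
        snaps.append(ParticleSnapshot(frames[k], snap0.labels, snap0.box, True, t))
    return Trajectory(snaps)


def pair_force(r: float, eps: float, cutoff: float) -> float:
    """Radial LJ force F(r) (positive = repulsive); zero beyond the cut-off."""
    if r <= 0:
        raise ValueError("r must be positive")
    if r >= cutoff:
        return 0.0
    return float(_lj_force_over_r(r * r, eps) * r)


def forces_bruteforce(snapshot: ParticleSnapshot, params: BDParams) -> np.ndarray:
    """O(n^2) reference force evaluation used to validate the cell list."""
    eps, cut = interaction_table(params)
    alpha = list(snapshot.alphabet)
    types = snapshot.label_indices(alpha)
    pos = snapshot.positions
    n = snapshot.n
    out = np.zeros_like(pos)
    for i in range(n):
        d = pos[i] - pos
        d -= snapshot.box * np.round(d / snapshot.box)
        r2 = (d ** 2).sum(axis=1)
        for j in range(n):
            if j == i or r2[j] <= 1e-12:
                continue
            if r2[j] < cut[types[i], types[j]] ** 2:
                inv2 = 1.0 / r2[j]
                s6 = inv2 ** 3
                g = 24.0 * eps[types[i], types[j]] * (2.0 * s6 * s6 - s6) * inv2
                out[i] += g * d[j]
    return out


def mean_squared_displacement(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Time-origin-averaged MSD as a function of lag time.

    Positions are unwrapped by accumulating minimum-image frame-to-frame
    displacements (valid while per-frame displacements stay below half the
    box); the MSD at each lag averages over all particles and all time
    origins, the standard low-variance estimator for diffusion.
    Returns (lag_times, msd), lag 0 included.
    """
    snaps = traj.snapshots
    box = snaps[0].box
    unwrapped = [snaps[0].positions]
    for prev, cur in zip(snaps, snaps[1:]):
        d = cur.positions - prev.positions
        d -= box * np.round(d / box)
        unwrapped.append(unwrapped[-1] + d)
    pos = np.stack(unwrapped)                      # (n_frames, n, dim)
    times = np.array([s.time or 0.0 for s in snaps])
    n_frames = len(snaps)
    lags = np.arange(n_frames)
    msd = np.zeros(n_frames)
    for ell in lags[1:]:
        diff = pos[ell:] - pos[:-ell or None]
        msd[ell] = float((diff ** 2).sum(axis=2).mean())
    return times - times[0], msd
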