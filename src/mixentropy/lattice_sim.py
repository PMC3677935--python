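"""Monte-Carlo simulation of the 2D (and 1D) Ising model.

Two local dynamics are provided, both with Metropolis acceptance
min(1, exp(-dE/T)) and units J = k_B = 1:

* Glauber: single-spin flips; magnetisation fluctuates.  Equilibrium
  ensembles sample the standard Ising model (critical temperature
  T_c = 2/ln(1+sqrt(2)) ~ 2.269).
* Kawasaki: nearest-neighbour spin exchange; magnetisation is conserved
  exactly, which makes the model a lattice binary mixture.  We work at
  zero magnetisation (balanced composition).

One sweep is L^2 attempted elementary moves.  Frames are recorded every
``thin`` sweeps after ``burn_in`` discarded sweeps.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

T_CRITICAL = 2.0 / np.log(1.0 + np.sqrt(2.0))


@dataclass(frozen=True)
class IsingParams:
    L: int
    T: float
    dynamics: str = "glauber"          # "glauber" | "kawasaki"
    J: float = 1.0
    n_sweeps: int = 1000
    burn_in: int = 1000
    thin: int = 10
    seed: int = 0
    init: str = "random"               # "all_up" | "random" | "balanced_random"

    def __post_init__(self):
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.thin < 1 or self.burn_in < 0:
            raise ValueError("invalid thinning/burn-in")
        if self.dynamics not in ("glauber", "kawasaki"):
            raise ValueError(f"unknown dynamics {self.dynamics!r}")
        if self.init not in ("all_up", "random", "balanced_random"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.J != 1.0:
            raise ValueError("only J = 1 is supported")


@dataclass(frozen=True)
class LatticeEnsemble:
    """Ordered frames of an L x L periodic grid of discrete states.

    ``frames`` has shape (n_frames, L, L) for 2D lattices or (n_frames, L)
    for periodic chains.  The alphabet is the sorted set of admissible
    states; spin ensembles use (-1, +1).
    """

    frames: np.ndarray
    alphabet: tuple = (-1, 1)
    params: IsingParams | None = None

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim not in (2, 3) or frames.shape[0] == 0:
            raise ValueError("frames must be a non-empty (F, L, L) or (F, L) array")
        object.__setattr__(self, "frames", frames)
        alpha = tuple(sorted(self.alphabet))
        object.__setattr__(self, "alphabet", alpha)
        if not np.isin(frames, np.asarray(alpha)).all():
            raise ValueError("frame entries outside the declared alphabet")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def L(self) -> int:
        return self.frames.shape[1]

    @property
    def is_chain(self) -> bool:
        return self.frames.ndim == 2

    def magnetisation(self) -> np.ndarray:
        """Per-frame mean state (the magnetisation for spin ensembles)."""
        axes = tuple(range(1, self.frames.ndim))
        return self.frames.mean(axis=axes)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _run_glauber_2d(spins, T, n_sweeps, burn_in, thin, seed):
    np.random.seed(seed)
    L = spins.shape[0]
    n_frames = n_sweeps // thin
    frames = np.empty((n_frames, L, L), dtype=np.int8)
    f = 0
    for sweep in range(burn_in + n_sweeps):
        for _ in range(L * L):
            i = np.random.randint(0, L)
            j = np.random.randint(0, L)
            s = spins[i, j]
            h = (spins[(i + 1) % L, j] + spins[(i - 1) % L, j]
                 + spins[i, (j + 1) % L] + spins[i, (j - 1) % L])
            dE = 2.0 * s * h
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                spins[i, j] = -s
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1 and f < n_frames:
            frames[f] = spins
            f += 1
    return frames[:f]


@njit(cache=True)
def _run_kawasaki_2d(spins, T, n_sweeps, burn_in, thin, seed):
    np.random.seed(seed)
    L = spins.shape[0]
    n_frames = n_sweeps // thin
    frames = np.empty((n_frames, L, L), dtype=np.int8)
    f = 0
    for sweep in range(burn_in + n_sweeps):
        for _ in range(L * L):
            i = np.random.randint(0, L)
            j = np.random.randint(0, L)
            d = np.random.randint(0, 4)
            if d == 0:
                ni, nj = (i + 1) % L, j
            elif d == 1:
                ni, nj = (i - 1) % L, j
            elif d == 2:
                ni, nj = i, (j + 1) % L
            else:
                ni, nj = i, (j - 1) % L
            si = spins[i, j]
            sj = spins[ni, nj]
            if si == sj:
                continue  # exchange of equal spins is a no-op attempt
            hi = (spins[(i + 1) % L, j] + spins[(i - 1) % L, j]
                  + spins[i, (j + 1) % L] + spins[i, (j - 1) % L]) - sj
            hj = (spins[(ni + 1) % L, nj] + spins[(ni - 1) % L, nj]
                  + spins[ni, (nj + 1) % L] + spins[ni, (nj - 1) % L]) - si
            dE = (si - sj) * (hi - hj)
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                spins[i, j] = sj
                spins[ni, nj] = si
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1 and f < n_frames:
            frames[f] = spins
            f += 1
    return frames[:f]


@njit(cache=True)
def _run_glauber_1d(spins, T, n_sweeps, burn_in, thin, seed):
    np.random.seed(seed)
    L = spins.shape[0]
    n_frames = n_sweeps // thin
    frames = np.empty((n_frames, L), dtype=np.int8)
    f = 0
    for sweep in range(burn_in + n_sweeps):
        for _ in range(L):
            i = np.random.randint(0, L)
            s = spins[i]
            h = spins[(i + 1) % L] + spins[(i - 1) % L]
            dE = 2.0 * s * h
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                spins[i] = -s
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1 and f < n_frames:
            frames[f] = spins
            f += 1
    return frames[:f]


# ---------------------------------------------------------------------------
# public API


def _initial_spins(params: IsingParams, rng: np.random.Generator) -> np.ndarray:
    L = params.L
    if params.init == "all_up":
        return np.ones((L, L), dtype=np.int8)
    if params.init == "random":
        return rng.choice(np.array([-1, 1], dtype=np.int8), size=(L, L))
    # balanced_random: exactly zero magnetisation
    if (L * L) % 2 != 0:
        raise ValueError("balanced_random requires an even number of sites")
    flat = np.repeat(np.array([-1, 1], dtype=np.int8), L * L // 2)
    rng.shuffle(flat)
    return flat.reshape(L, L)


def simulate_glauber(params: IsingParams) -> LatticeEnsemble:
    """Equilibrium ensemble of the 2D Ising model under Glauber dynamics."""
    if params.dynamics != "glauber":
        raise ValueError("params.dynamics must be 'glauber'")
    rng = np.random.default_rng(params.seed)
    spins = _initial_spins(params, rng)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    frames = _run_glauber_2d(spins, params.T, params.n_sweeps,
                             params.burn_in, params.thin, kernel_seed)
    return LatticeEnsemble(frames=frames, alphabet=(-1, 1), params=params)


def simulate_kawasaki(params: IsingParams) -> LatticeEnsemble:
    """Conserved-magnetisation ensemble under Kawasaki exchange dynamics.

    The initial condition must have exactly zero magnetisation; magnetisation
    is then conserved on every stored frame.
    """
    if params.dynamics != "kawasaki":
        raise ValueError("params.dynamics must be 'kawasaki'")
    if params.init != "balanced_random":
        raise ValueError("kawasaki at zero magnetisation requires init='balanced_random'")
    rng = np.random.default_rng(params.seed)
    spins = _initial_spins(params, rng)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    frames = _run_kawasaki_2d(spins, params.T, params.n_sweeps,
                              params.burn_in, params.thin, kernel_seed)
    return LatticeEnsemble(frames=frames, alphabet=(-1, 1), params=params)


def simulate_glauber_chain(L: int, T: float, n_sweeps: int = 1000,
                           burn_in: int = 1000, thin: int = 10,
                           seed: int = 0) -> LatticeEnsemble:
    """Glauber-sampled 1D Ising rings (frames of shape (F, L))."""
    if L < 2:
        raise ValueError("L must be >= 2")
    if T <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    spins = rng.choice(np.array([-1, 1], dtype=np.int8), size=L)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    frames = _run_glauber_1d(spins, T, n_sweeps, burn_in, thin, kernel_seed)
    return LatticeEnsemble(frames=frames, alphabet=(-1, 1), params=None)


def lattice_energy(frame) -> float:
    """Energy per site, E/N = -(1/N) sum_<ij> s_i s_j, bonds counted once.

    On the periodic square lattice every site owns two bonds (+x and +y),
    so the all-up ground state gives -2 per site.  Works for chains too
    (one bond per site).
    """
    s = np.asarray(frame)
    if not np.isin(s, (-1, 1)).all():
        raise ValueError("spin frames must contain only -1/+1 entries")
    if s.ndim == 1:
        e = -(s * np.roll(s, -1)).sum()
    elif s.ndim == 2:
        e = -(s * np.roll(s, -1, axis=0)).sum() - (s * np.roll(s, -1, axis=1)).sum()
    else:
        raise ValueError("frame must be 1D or 2D")
    return float(e) / s.size


def ensemble_energy(ensemble: LatticeEnsemble) -> float:
    """Mean energy per site over all frames of an ensemble."""
    return float(np.mean([lattice_energy(f) for f in ensemble.frames]))
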