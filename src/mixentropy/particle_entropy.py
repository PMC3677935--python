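"""Disorder quantification for off-lattice particle systems.

The central quantity is the conditional entropy per particle
H(sigma_i | b_i): sigma_i is the component type of particle i, and b_i is a
discrete state describing the types found in the half-space neighbourhood
of i (particles whose minimum-image displacement from i points into the
upper half-space).  Counting each pair once keeps the measure between 0
(fully demixed, in the large-system limit) and the ideal mixing entropy
-sum_c x_c ln x_c.

Three neighbourhood discretisations are provided (see
:class:`~mixentropy.particles.NeighbourhoodSpec`): NB-cutoff, NB-shell and
NB-weight.  For comparison, the classical subregion (binned) Shannon
entropy is implemented as well: the box is divided into m^dim equal
subregions and the per-region composition entropies are averaged.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .estimate import (UNDERSAMPLING_MEAN_COUNT, EntropyEstimate,
                       shannon_from_counts)
from .particles import (NeighbourhoodSpec, ParticleSnapshot, Trajectory,
                        minimum_image)

__all__ = [
    "InsufficientNeighboursError",
    "max_mixing_entropy",
    "composition_entropy",
    "binned_shannon_entropy",
    "half_space_neighbours",
    "nb_state_cutoff",
    "nb_state_shell",
    "nb_state_weight",
    "neighbourhood_states",
    "conditional_entropy_particles",
    "entropy_time_series",
    "MixingEntropySeries",
]

#: neighbours beyond this many decay lengths contribute < 4e-4 of the
#: NB-weight normalisation and are truncated from the sum.
WEIGHT_RANGE_LAMBDAS = 8.0


class InsufficientNeighboursError(ValueError):
    """A particle has fewer half-space neighbours than the state requires."""


def max_mixing_entropy(composition) -> float:
    """Ideal mixing entropy -sum_c x_c ln x_c of a mole-fraction vector."""
    x = np.asarray(composition, dtype=float)
    if x.ndim != 1 or (x < -1e-12).any() or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be non-negative mole fractions summing to 1")
    x = x[x > 0]
    return float(-(x * np.log(x)).sum())


def _as_snapshots(snapshots) -> list[ParticleSnapshot]:
    if isinstance(snapshots, ParticleSnapshot):
        return [snapshots]
    snaps = list(snapshots)
    if not snaps:
        raise ValueError("no snapshots provided")
    return snaps


def _pooled_alphabet(snaps) -> list:
    labels = np.concatenate([np.asarray(s.labels) for s in snaps])
    return np.unique(labels).tolist()


def composition_entropy(snapshots) -> EntropyEstimate:
    """Mean-field entropy: pooled single-particle type frequencies."""
    snaps = _as_snapshots(snapshots)
    alpha = _pooled_alphabet(snaps)
    counts = np.zeros(len(alpha))
    for s in snaps:
        counts += np.bincount(s.label_indices(alpha), minlength=len(alpha))
    return EntropyEstimate(shannon_from_counts(counts), "mean_field",
                           float(counts.sum()), int((counts > 0).sum()))


def binned_shannon_entropy(snapshot: ParticleSnapshot, grid: int) -> EntropyEstimate:
    """Subregion Shannon entropy: average of the composition entropies of
    the m^dim equal subregions of the box (empty regions excluded)."""
    m = int(grid)
    if m < 1:
        raise ValueError("grid must be >= 1")
    if snapshot.n < 1:
        raise ValueError("empty snapshot")
    alpha = list(snapshot.alphabet)
    lab = snapshot.label_indices(alpha)
    cell = np.floor(snapshot.positions / snapshot.box * m).astype(np.int64)
    cell = np.clip(cell, 0, m - 1)
    region = np.ravel_multi_index(cell.T, (m,) * snapshot.dim)
    n_regions = m ** snapshot.dim
    table = np.zeros((n_regions, len(alpha)))
    np.add.at(table, (region, lab), 1.0)
    occupied = table.sum(axis=1) > 0
    ent = np.array([shannon_from_counts(row) for row in table[occupied]])
    warnings = ()
    if n_regions > snapshot.n:
        warnings = (f"{n_regions} subregions for {snapshot.n} particles: "
                    "near-certain undersampling",)
    return EntropyEstimate(float(ent.mean()), "binned_shannon",
                           float(snapshot.n), int(occupied.sum()),
                           undersampled=bool(snapshot.n / occupied.sum()
                                             < UNDERSAMPLING_MEAN_COUNT),
                           warnings=warnings)


# ---------------------------------------------------------------------------
# half-space neighbourhoods


def _halfspace_mask(disp: np.ndarray) -> np.ndarray:
    """True where the displacement points into the upper half-space: the
    last coordinate positive, with exact zeros resolved lexicographically
    on the earlier axes."""
    dim = disp.shape[-1]
    mask = np.zeros(disp.shape[:-1], dtype=bool)
    undecided = np.ones_like(mask)
    for ax in range(dim - 1, -1, -1):
        v = disp[..., ax]
        mask |= undecided & (v > 0)
        undecided &= v == 0
    return mask


def half_space_neighbours(snapshot: ParticleSnapshot, i: int):
    """Ordered half-space neighbour candidates of particle i.

    Returns ``(indices, distances)`` sorted by increasing minimum-image
    distance; exact distance ties are broken by particle index.
    """
    disp = minimum_image(snapshot.positions - snapshot.positions[i],
                         snapshot.box, snapshot.periodic)
    mask = _halfspace_mask(disp)
    mask[i] = False
    idx = np.nonzero(mask)[0]
    dist = np.linalg.norm(disp[idx], axis=1)
    order = np.lexsort((idx, dist))
    return idx[order], dist[order]


def nb_state_cutoff(snapshot: ParticleSnapshot, i: int, k: int) -> tuple:
    """Ordered types of the k nearest half-space neighbours of i."""
    idx, _ = half_space_neighbours(snapshot, i)
    if idx.size < k:
        raise InsufficientNeighboursError(
            f"particle {i} has {idx.size} half-space neighbours, needs {k}")
    return tuple(snapshot.labels[idx[:k]].tolist())


def nb_state_shell(snapshot: ParticleSnapshot, i: int, shell_sizes) -> tuple:
    """Per-shell type-count vectors over the snapshot alphabet.

    Shell s holds the shell_sizes[s] next-closest half-space neighbours;
    order within a shell is ignored, which shrinks the state space
    relative to NB-cutoff.
    """
    sizes = tuple(int(s) for s in shell_sizes)
    idx, _ = half_space_neighbours(snapshot, i)
    if idx.size < sum(sizes):
        raise InsufficientNeighboursError(
            f"particle {i} has {idx.size} half-space neighbours, needs {sum(sizes)}")
    alpha = list(snapshot.alphabet)
    state, start = [], 0
    for s in sizes:
        members = snapshot.labels[idx[start:start + s]]
        state.append(tuple(int((members == a).sum()) for a in alpha))
        start += s
    return tuple(state)


def nb_state_weight(snapshot: ParticleSnapshot, i: int,
                    lam: float | None = None, n_bins: int = 32) -> tuple:
    """Binned exponentially distance-weighted type frequencies.

    f_i(c) = sum_{j in H(i)} 1[type_j = c] exp(-r_ij/lam) / Z with Z the
    sum of the weights over the half-space set H(i); the state is the
    tuple floor(f_i(c) * n_bins) (top bin inclusive) for the first q-1
    components.  lam defaults to half the mean inter-particle spacing.
    """
    if lam is None:
        lam = NeighbourhoodSpec(variant="weight").resolve_lambda(snapshot)
    idx, dist = half_space_neighbours(snapshot, i)
    keep = dist <= WEIGHT_RANGE_LAMBDAS * lam
    idx, dist = idx[keep], dist[keep]
    if idx.size == 0:
        raise InsufficientNeighboursError(f"particle {i} has no half-space neighbours")
    return _weight_state(snapshot.labels[idx], dist, list(snapshot.alphabet),
                         lam, n_bins)


def _weight_state(labels, dist, alphabet, lam, n_bins) -> tuple:
    w = np.exp(-np.asarray(dist) / lam)
    z = w.sum()
    state = []
    for a in alphabet[:-1] if len(alphabet) > 1 else alphabet:
        f = float(w[np.asarray(labels) == a].sum() / z)
        state.append(min(int(f * n_bins), n_bins - 1))
    return tuple(state)


# ---------------------------------------------------------------------------
# bulk state extraction (KD-tree accelerated; equivalent to the per-particle
# functions above, which serve as its reference implementation in tests)


def _build_tree(snapshot: ParticleSnapshot):
    if snapshot.periodic.all():
        return cKDTree(snapshot.positions, boxsize=snapshot.box)
    if not snapshot.periodic.any():
        return cKDTree(snapshot.positions)
    return None  # mixed periodicity: fall back to brute force


def _halfspace_candidates(snapshot: ParticleSnapshot, needed: int):
    """Per-particle ordered (indices, distances) of half-space neighbours,
    guaranteed complete up to ``needed`` entries where that many exist."""
    n, pos = snapshot.n, snapshot.positions
    tree = _build_tree(snapshot)
    if tree is None or needed >= n - 1:
        return [half_space_neighbours(snapshot, i) for i in range(n)]
    kq = min(n, 4 * needed + 16)
    while True:
        dists, idxs = tree.query(pos, k=kq)
        disp = minimum_image(pos[idxs] - pos[:, None, :], snapshot.box,
                             snapshot.periodic)
        mask = _halfspace_mask(disp) & (idxs != np.arange(n)[:, None])
        complete = (mask.sum(axis=1) >= needed) | np.isinf(dists).any(axis=1)
        if complete.all() or kq >= n:
            break
        kq = min(n, 2 * kq)
    out = []
    for i in range(n):
        m = mask[i] & np.isfinite(dists[i])
        idx_i, dist_i = idxs[i][m], dists[i][m]
        order = np.lexsort((idx_i, dist_i))
        out.append((idx_i[order], dist_i[order]))
    return out


def _ball_candidates(snapshot: ParticleSnapshot, radius: float):
    """Half-space neighbours within ``radius`` of every particle."""
    n, pos = snapshot.n, snapshot.positions
    tree = _build_tree(snapshot)
    if tree is None:
        out = []
        for i in range(n):
            idx, dist = half_space_neighbours(snapshot, i)
            keep = dist <= radius
            out.append((idx[keep], dist[keep]))
        return out
    lists = tree.query_ball_point(pos, radius)
    out = []
    for i, cand in enumerate(lists):
        cand = np.asarray([j for j in cand if j != i], dtype=np.int64)
        if cand.size == 0:
            out.append((cand, np.empty(0)))
            continue
        disp = minimum_image(pos[cand] - pos[i], snapshot.box, snapshot.periodic)
        m = _halfspace_mask(disp)
        idx = cand[m]
        out.append((idx, np.linalg.norm(disp[m], axis=1)))
    return out


def neighbourhood_states(snapshot: ParticleSnapshot, spec: NeighbourhoodSpec,
                         alphabet=None):
    """Neighbourhood state b_i for every particle of a snapshot.

    Returns ``(sigma, states, skipped)``: the particle types and state
    tuples of the particles that have enough half-space neighbours, plus
    the count of skipped particles.
    """
    alpha = list(alphabet) if alphabet is not None else list(snapshot.alphabet)
    labels = snapshot.labels
    sigma, states, skipped = [], [], 0
    if spec.variant == "weight":
        lam = spec.resolve_lambda(snapshot)
        cands = _ball_candidates(snapshot, WEIGHT_RANGE_LAMBDAS * lam)
        for i, (idx, dist) in enumerate(cands):
            if idx.size == 0:
                skipped += 1
                continue
            sigma.append(labels[i])
            states.append(_weight_state(labels[idx], dist, alpha, lam, spec.n_bins))
        return sigma, states, skipped
    needed = spec.k if spec.variant == "cutoff" else sum(spec.shell_sizes)
    cands = _halfspace_candidates(snapshot, needed)
    for i, (idx, _) in enumerate(cands):
        if idx.size < needed:
            skipped += 1
            continue
        if spec.variant == "cutoff":
            states.append(tuple(labels[idx[:spec.k]].tolist()))
        else:
            state, start = [], 0
            for s in spec.shell_sizes:
                members = labels[idx[start:start + s]]
                state.append(tuple(int((members == a).sum()) for a in alpha))
                start += s
            states.append(tuple(state))
        sigma.append(labels[i])
    return sigma, states, skipped


def conditional_entropy_particles(snapshots, spec: NeighbourhoodSpec) -> EntropyEstimate:
    """Conditional entropy H(sigma | b) pooled over particles and snapshots.

    Plug-in estimate from the empirical joint distribution of (type,
    neighbourhood state); particles without enough half-space neighbours
    are skipped and tallied, not errors.
    """
    snaps = _as_snapshots(snapshots)
    alpha = _pooled_alphabet(snaps)
    joint: Counter = Counter()
    skipped = 0
    for snap in snaps:
        sigma, states, skip = neighbourhood_states(snap, spec, alpha)
        skipped += skip
        for sig, st in zip(sigma, states):
            joint[(sig, st)] += 1
    if not joint:
        raise ValueError("all particles were skipped: no observations")
    total = sum(joint.values())
    b_counts: Counter = Counter()
    for (_, st), c in joint.items():
        b_counts[st] += c
    h_joint = shannon_from_counts(list(joint.values()), total)
    h_b = shannon_from_counts(list(b_counts.values()), total)
    mean_count = total / len(joint)
    undersampled = mean_count < UNDERSAMPLING_MEAN_COUNT
    warnings = ()
    if undersampled:
        warnings = (f"mean count per joint cell {mean_count:.2f} < "
                    f"{UNDERSAMPLING_MEAN_COUNT}: entropy may be underestimated",)
    return EntropyEstimate(max(h_joint - h_b, 0.0),
                           f"conditional[{spec.describe()}]",
                           float(total), len(b_counts), n_skipped=skipped,
                           undersampled=undersampled, warnings=warnings)


@dataclass(frozen=True)
class MixingEntropySeries:
    """Windowed conditional-entropy time series of a trajectory."""

    times: np.ndarray
    values: np.ndarray
    estimates: tuple

    def __len__(self):
        return self.values.size


def entropy_time_series(traj: Trajectory, spec: NeighbourhoodSpec,
                        window: int = 1) -> MixingEntropySeries:
    """One pooled conditional-entropy estimate per non-overlapping window
    of ``window`` frames; the reported time is the window midpoint."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(traj):
        raise ValueError("window exceeds the number of frames")
    times, values, estimates = [], [], []
    for start in range(0, len(traj) - window + 1, window):
        chunk = traj.snapshots[start:start + window]
        est = conditional_entropy_particles(chunk, spec)
        ts = [s.time for s in chunk]
        times.append(np.nan if any(t is None for t in ts) else 0.5 * (ts[0] + ts[-1]))
        values.append(est.value)
        estimates.append(est)
    return MixingEntropySeries(np.asarray(times), np.asarray(values),
                               tuple(estimates))
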