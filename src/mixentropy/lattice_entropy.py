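"""Entropy-per-site estimators for lattice ensembles.

Four estimators of increasing sophistication, all plug-in (raw frequencies
pooled over all sites and frames, natural log):

* mean-field: entropy of the single-site marginal; ignores all correlations
  and saturates at ln q for a balanced q-state system.
* Bethe (1D): S = S2 - S1 from adjacent-pair and site entropies; exact for
  nearest-neighbour chains.
* Kikuchi (cluster variation, 2D square lattice):
  S = S_square - S2_h - S2_v + S1 from the 2x2-square, the two
  nearest-neighbour pair orientations, and the single site.
* conditional: S = H(s_i | b_i) where b_i is the state of the sites within a
  cut-off distance of i restricted to the upper half-plane.  Counting only
  half of the neighbours avoids double-counting the pair information and
  makes the estimate an upper bound on the true entropy that tightens as the
  neighbourhood grows.

Estimators accept optional per-frame weights so that exhaustively
enumerated (Boltzmann-weighted) ensembles can be fed through the identical
code path used for Monte-Carlo samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimate import (UNDERSAMPLING_MEAN_COUNT, EntropyEstimate,
                       entropy_from_codes)
from .lattice_sim import LatticeEnsemble

__all__ = [
    "LatticeNeighbourhood",
    "mean_field_entropy",
    "cluster_entropies",
    "bethe_entropy_1d",
    "kikuchi_entropy",
    "conditional_entropy_lattice",
    "conditional_entropy_chain",
]


def half_plane_offsets(cutoff_r: float) -> tuple:
    """Displacement vectors (dx, dy) with dx^2+dy^2 <= r^2 in the upper
    half-plane: dy > 0, or dy = 0 with dx > 0 (lexicographic boundary
    split, so r=1 yields exactly half of the 4-neighbourhood)."""
    if cutoff_r < 1:
        raise ValueError("cutoff_r must be >= 1")
    r2 = cutoff_r * cutoff_r + 1e-9
    rmax = int(np.floor(cutoff_r + 1e-9))
    offs = []
    for dy in range(0, rmax + 1):
        for dx in range(-rmax, rmax + 1):
            if dx * dx + dy * dy > r2 or (dx == 0 and dy == 0):
                continue
            if dy > 0 or dx > 0:
                offs.append((dx, dy))
    offs.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2, o[1], o[0]))
    return tuple(offs)


@dataclass(frozen=True)
class LatticeNeighbourhood:
    """Half-plane neighbourhood of a lattice site within ``cutoff_r``.

    r = 1 gives offsets {(1,0), (0,1)}; r = sqrt(2) adds the two upper
    diagonals {(1,1), (-1,1)} (nearest plus next-nearest neighbours).
    """

    cutoff_r: float
    offsets: tuple = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "offsets", half_plane_offsets(self.cutoff_r))


def _encode(ensemble: LatticeEnsemble) -> tuple[np.ndarray, int]:
    """Map frames to alphabet indices 0..q-1."""
    alpha = np.asarray(ensemble.alphabet)
    idx = np.searchsorted(alpha, ensemble.frames)
    return idx.astype(np.int64), len(alpha)


def _frame_weights(ensemble: LatticeEnsemble, frame_weights) -> np.ndarray | None:
    if frame_weights is None:
        return None
    w = np.asarray(frame_weights, dtype=float)
    if w.shape != (ensemble.n_frames,) or w.min() < 0:
        raise ValueError("frame_weights must be one non-negative weight per frame")
    # broadcast one weight per site observation
    shape = (ensemble.n_frames,) + (1,) * (ensemble.frames.ndim - 1)
    return np.broadcast_to(w.reshape(shape), ensemble.frames.shape)


def mean_field_entropy(ensemble: LatticeEnsemble, frame_weights=None) -> EntropyEstimate:
    """Entropy of the pooled single-site state distribution (mean field)."""
    idx, q = _encode(ensemble)
    w = _frame_weights(ensemble, frame_weights)
    h, n_occ, total = entropy_from_codes(idx, q, w)
    return EntropyEstimate(h, "mean_field", total, n_occ)


def _rolled(idx: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """State at (x+dx, y+dy) for every site, minimum image (periodic roll)."""
    return np.roll(np.roll(idx, -dx, axis=1), -dy, axis=2)


def cluster_entropies(ensemble: LatticeEnsemble, frame_weights=None) -> tuple:
    """Plug-in entropies of the basic CVM clusters, pooled over all
    positions and frames: (S1 site, S2 horizontal pair, S2 vertical pair,
    S_square 2x2 block)."""
    if ensemble.is_chain:
        raise ValueError("cluster_entropies requires a 2D ensemble")
    idx, q = _encode(ensemble)
    w = _frame_weights(ensemble, frame_weights)
    s1 = entropy_from_codes(idx, q, w)[0]
    pair_h = idx * q + _rolled(idx, 1, 0)
    pair_v = idx * q + _rolled(idx, 0, 1)
    s2h = entropy_from_codes(pair_h, q * q, w)[0]
    s2v = entropy_from_codes(pair_v, q * q, w)[0]
    square = ((idx * q + _rolled(idx, 1, 0)) * q + _rolled(idx, 0, 1)) * q \
        + _rolled(idx, 1, 1)
    s_sq = entropy_from_codes(square, q ** 4, w)[0]
    return s1, s2h, s2v, s_sq


def kikuchi_entropy(ensemble: LatticeEnsemble, frame_weights=None) -> EntropyEstimate:
    """Cluster-variation entropy per site on the square lattice:
    S = S_square - S2_h - S2_v + S1 (one 2x2 square, two pair orientations
    and one site per lattice site)."""
    s1, s2h, s2v, s_sq = cluster_entropies(ensemble, frame_weights)
    value = s_sq - s2h - s2v + s1
    n_obs = ensemble.frames.size if frame_weights is None else float(
        np.sum(frame_weights) * ensemble.L ** 2)
    return EntropyEstimate(max(value, 0.0), "kikuchi", float(n_obs), 1)


def bethe_entropy_1d(ensemble: LatticeEnsemble, frame_weights=None) -> EntropyEstimate:
    """Bethe entropy per site of periodic chains: S = S2 - S1, with S2 the
    adjacent-pair entropy and S1 the site entropy.  Exact for
    nearest-neighbour interactions."""
    if not ensemble.is_chain:
        raise ValueError("bethe_entropy_1d requires a chain ensemble (frames of shape (F, L))")
    if ensemble.L < 2:
        raise ValueError("chains must have L >= 2")
    idx, q = _encode(ensemble)
    w = _frame_weights(ensemble, frame_weights)
    s1, n1, total = entropy_from_codes(idx, q, w)
    pair = idx * q + np.roll(idx, -1, axis=1)
    s2, n2, _ = entropy_from_codes(pair, q * q, w)
    return EntropyEstimate(max(s2 - s1, 0.0), "bethe_1d", total, n2)


def conditional_entropy_chain(ensemble: LatticeEnsemble, order: int = 1,
                              frame_weights=None) -> EntropyEstimate:
    """H(s_i | s_{i-1}, ..., s_{i-order}) on periodic chains.

    order=1 coincides with the Bethe form; increasing the order gives a
    non-increasing sequence converging to the true entropy per symbol.
    """
    if not ensemble.is_chain:
        raise ValueError("requires a chain ensemble")
    if order < 1 or order >= ensemble.L:
        raise ValueError("order must be in [1, L)")
    idx, q = _encode(ensemble)
    w = _frame_weights(ensemble, frame_weights)
    joint = idx.copy()
    mult = q
    for m in range(1, order + 1):
        joint = joint + mult * np.roll(idx, m, axis=1)
        mult *= q
    h_joint, n_joint, total = entropy_from_codes(joint, mult, w)
    cond = (joint - idx) // q
    h_cond, n_cond, _ = entropy_from_codes(cond, mult // q, w)
    mean_count = total / max(n_joint, 1)
    return EntropyEstimate(max(h_joint - h_cond, 0.0), "conditional_chain",
                           total, n_cond,
                           undersampled=bool(mean_count < UNDERSAMPLING_MEAN_COUNT))


def conditional_entropy_lattice(ensemble: LatticeEnsemble,
                                nb: LatticeNeighbourhood | float = np.sqrt(2),
                                frame_weights=None) -> EntropyEstimate:
    """Conditional entropy per site H(s_i | b_i) with the half-plane
    neighbourhood b_i, pooled over all sites and frames.

    Computed as H(s, b) - H(b) on the empirical joint distribution, which is
    identical to the weighted average of the conditional distributions'
    entropies (chain rule).
    """
    if isinstance(nb, (int, float)):
        nb = LatticeNeighbourhood(float(nb))
    if ensemble.is_chain:
        raise ValueError("use conditional_entropy_chain for 1D ensembles")
    L = ensemble.L
    for dx, dy in nb.offsets:
        if abs(dx) >= L / 2 or abs(dy) >= L / 2:
            raise ValueError(f"offset {(dx, dy)} wraps on an L={L} lattice (cutoff too large)")
    idx, q = _encode(ensemble)
    w = _frame_weights(ensemble, frame_weights)
    n_offsets = len(nb.offsets)
    if q ** (n_offsets + 1) > 1 << 26:
        raise ValueError("neighbourhood state space too large to tabulate")
    joint = idx.copy()
    mult = q
    for dx, dy in nb.offsets:
        joint = joint + mult * _rolled(idx, dx, dy)
        mult *= q
    h_joint, n_joint, total = entropy_from_codes(joint, mult, w)
    # b is the high-radix part: dropping the sigma digit marginalises it
    b_codes = joint // q
    h_b, n_b, _ = entropy_from_codes(b_codes, mult // q, w)
    mean_count = total / max(n_joint, 1)
    warnings = ()
    undersampled = bool(frame_weights is None and mean_count < UNDERSAMPLING_MEAN_COUNT)
    if undersampled:
        warnings = (f"mean count per joint cell {mean_count:.2f} < "
                    f"{UNDERSAMPLING_MEAN_COUNT}: entropy may be underestimated",)
    return EntropyEstimate(max(h_joint - h_b, 0.0), "conditional",
                           total, n_b, undersampled=undersampled,
                           warnings=warnings)
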