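"""Discrete (plug-in) entropy primitives shared by lattice and particle estimators.

All entropies are Shannon entropies in nats, computed from raw observed
frequencies (maximum-likelihood plug-in); the Boltzmann constant is omitted
so that a binary equimolar mixture saturates at ln 2.  The convention
0 * ln 0 = 0 is used throughout.  No bias correction is applied; instead,
estimates carry an ``undersampled`` flag when the mean number of observations
per occupied joint cell falls below :data:`UNDERSAMPLING_MEAN_COUNT`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: mean observations per occupied (state, neighbourhood) cell below which an
#: estimate is flagged as undersampled (plug-in estimators are negatively
#: biased in this regime).
UNDERSAMPLING_MEAN_COUNT = 10.0


@dataclass(frozen=True)
class EntropyEstimate:
    """Result of an entropy estimator.

    Attributes
    ----------
    value : float
        Entropy per site / particle in nats.
    estimator : str
        Name of the estimator that produced the value.
    n_samples : float
        Number of (site, frame) or (particle, snapshot) observations pooled
        (a float when the ensemble carries non-integer weights).
    n_states_observed : int
        Distinct conditioning states (or states, for unconditional
        estimators) that actually occurred in the sample.
    n_skipped : int
        Observations excluded, e.g. particles without enough half-space
        neighbours.
    undersampled : bool
        True when the mean count per occupied joint cell is below
        :data:`UNDERSAMPLING_MEAN_COUNT`.
    warnings : tuple of str
        Human-readable notes attached by the estimator.
    """

    value: float
    estimator: str
    n_samples: float
    n_states_observed: int
    n_skipped: int = 0
    undersampled: bool = False
    warnings: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.value < -1e-9:
            raise ValueError(f"entropy cannot be negative: {self.value}")
        # clamp numerical noise like -1e-17 to exactly zero
        object.__setattr__(self, "value", max(float(self.value), 0.0))
        if self.n_states_observed < 1 and self.n_samples > 0:
            raise ValueError("at least one state must be observed")

    def __float__(self):
        return float(self.value)


def shannon_from_counts(counts, total: float | None = None) -> float:
    """Plug-in Shannon entropy in nats from a vector of counts or weights."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty count vector")
    if total is None:
        total = c.sum()
    p = c / total
    return float(-(p * np.log(p)).sum())


def shannon_from_probs(p) -> float:
    """Shannon entropy in nats of a probability vector (0 ln 0 = 0)."""
    p = np.asarray(p, dtype=float)
    if p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("not a probability vector")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _factorize(values) -> tuple[np.ndarray, int]:
    """Map a 1D sequence of hashable or array-like states to integer codes."""
    arr = np.asarray(values)
    if arr.ndim == 1:
        uniq, inv = np.unique(arr, return_inverse=True)
        return inv.astype(np.int64), len(uniq)
    uniq, inv = np.unique(arr.reshape(arr.shape[0], -1), axis=0, return_inverse=True)
    return inv.astype(np.int64).ravel(), len(uniq)


def conditional_entropy_from_pairs(x, y, weights=None,
                                   estimator: str = "conditional") -> EntropyEstimate:
    """Plug-in conditional entropy H(x | y) from paired observations.

    Uses the chain rule H(x | y) = H(x, y) - H(y) on the empirical joint
    distribution, which is identical to averaging the entropy of x within
    each realisation of y weighted by the frequency of that realisation.

    Parameters
    ----------
    x : sequence
        State of each observation (any hashable scalar type).
    y : sequence
        Conditioning state; a 1D sequence or a 2D array whose rows are
        neighbourhood state vectors.
    weights : array-like, optional
        Non-negative observation weights (e.g. Boltzmann weights of an
        exhaustively enumerated ensemble).
    """
    xi, nx = _factorize(x)
    yi, ny = _factorize(y)
    if xi.shape != yi.shape:
        raise ValueError("x and y must have the same number of observations")
    n = xi.size
    if n == 0:
        raise ValueError("no observations")
    joint = yi * nx + xi
    if weights is None:
        w = None
        total = float(n)
        joint_counts = np.bincount(joint, minlength=nx * ny).astype(float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != xi.shape or w.min() < 0:
            raise ValueError("weights must be non-negative, one per observation")
        total = float(w.sum())
        joint_counts = np.bincount(joint, weights=w, minlength=nx * ny)
    y_counts = joint_counts.reshape(ny, nx).sum(axis=1)
    h_joint = shannon_from_counts(joint_counts, total)
    h_y = shannon_from_counts(y_counts, total)
    occupied = int((joint_counts > 0).sum())
    undersampled = bool(w is None and n / max(occupied, 1) < UNDERSAMPLING_MEAN_COUNT)
    return EntropyEstimate(
        value=max(h_joint - h_y, 0.0),
        estimator=estimator,
        n_samples=total,
        n_states_observed=int((y_counts > 0).sum()),
        undersampled=undersampled,
    )


def entropy_from_codes(codes, n_codes: int, weights=None) -> tuple[float, int, float]:
    """Entropy of integer-coded observations.

    Returns ``(entropy, n_occupied_cells, total_weight)``; the workhorse for
    the vectorised lattice estimators where states are radix-encoded.
    """
    codes = np.asarray(codes).ravel()
    if weights is None:
        counts = np.bincount(codes, minlength=n_codes).astype(float)
        total = float(codes.size)
    else:
        counts = np.bincount(codes, weights=np.asarray(weights, float).ravel(),
                             minlength=n_codes)
        total = float(counts.sum())
    return shannon_from_counts(counts, total), int((counts > 0).sum()), total
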