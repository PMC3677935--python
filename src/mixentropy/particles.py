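"""Domain types for off-lattice particle systems.

A :class:`ParticleSnapshot` is one configuration of a multicomponent fluid:
positions in a (possibly periodic) box plus one discrete component label per
particle — for a membrane, one reference site per lipid and the lipid
species as the label.  A :class:`Trajectory` is a time-ordered sequence of
snapshots with constant particle count and component alphabet.

A :class:`NeighbourhoodSpec` selects how the local environment of a particle
is discretised into the conditioning state of the conditional-entropy
measure: the ordered types of the k nearest half-space neighbours
("cutoff"), per-shell type counts ("shell"), or binned exponentially
distance-weighted type frequencies ("weight").
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def minimum_image(disp: np.ndarray, box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention on the
    periodic axes; non-periodic axes pass through unchanged."""
    disp = np.asarray(disp, dtype=float).copy()
    box = np.asarray(box, dtype=float)
    per = np.asarray(periodic, dtype=bool)
    for ax in np.nonzero(per)[0]:
        disp[..., ax] -= box[ax] * np.round(disp[..., ax] / box[ax])
    return disp


@dataclass(frozen=True)
class ParticleSnapshot:
    """Positions + component labels + box for one configuration."""

    positions: np.ndarray          # (n, dim)
    labels: np.ndarray             # (n,) component identifiers
    box: np.ndarray                # (dim,) per-axis lengths
    periodic: np.ndarray | bool = True
    time: float | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] not in (2, 3):
            raise ValueError("positions must be (n, 2) or (n, 3)")
        labels = np.asarray(self.labels)
        if labels.shape != (pos.shape[0],):
            raise ValueError("one label per particle required")
        box = np.asarray(self.box, dtype=float)
        if box.shape != (pos.shape[1],) or (box <= 0).any():
            raise ValueError("box must give one positive length per axis")
        per = np.asarray(self.periodic, dtype=bool)
        if per.ndim == 0:
            per = np.full(pos.shape[1], bool(per))
        if per.shape != (pos.shape[1],):
            raise ValueError("periodic flags must match the dimension")
        # wrap periodic axes into [0, box)
        pos = pos.copy()
        for ax in np.nonzero(per)[0]:
            pos[:, ax] = np.mod(pos[:, ax], box[ax])
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "periodic", per)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def alphabet(self) -> tuple:
        return tuple(np.unique(self.labels).tolist())

    def composition(self, alphabet=None) -> np.ndarray:
        """Mole fractions over the (given or observed) component alphabet."""
        alpha = list(alphabet) if alphabet is not None else list(self.alphabet)
        counts = np.array([(self.labels == a).sum() for a in alpha], dtype=float)
        return counts / self.n

    def label_indices(self, alphabet=None) -> np.ndarray:
        alpha = list(alphabet) if alphabet is not None else list(self.alphabet)
        lut = {a: i for i, a in enumerate(alpha)}
        try:
            return np.array([lut[l] for l in self.labels.tolist()], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} outside alphabet {alpha}") from exc

    def translated(self, shift) -> "ParticleSnapshot":
        """Rigid translation (wrapped mod box on periodic axes)."""
        return ParticleSnapshot(self.positions + np.asarray(shift, float),
                                self.labels, self.box, self.periodic, self.time)


class Trajectory:
    """Time-ordered snapshots with constant n, dim and component alphabet."""

    def __init__(self, snapshots):
        snaps = list(snapshots)
        if not snaps:
            raise ValueError("a trajectory needs at least one snapshot")
        n, dim = snaps[0].n, snaps[0].dim
        for s in snaps:
            if s.n != n or s.dim != dim:
                raise ValueError("inconsistent particle count or dimension across frames")
        times = [s.time for s in snaps]
        if all(t is not None for t in times):
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValueError("snapshot times must be non-decreasing")
        self.snapshots = snaps

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i):
        got = self.snapshots[i]
        return Trajectory(got) if isinstance(i, slice) else got

    @property
    def times(self) -> np.ndarray:
        return np.array([np.nan if s.time is None else s.time for s in self.snapshots])

    @property
    def alphabet(self) -> tuple:
        labels = np.concatenate([np.asarray(s.labels) for s in self.snapshots])
        return tuple(np.unique(labels).tolist())


@dataclass(frozen=True)
class NeighbourhoodSpec:
    """Discretisation of a particle's half-space neighbourhood state.

    variant="cutoff": ordered types of the k nearest half-space neighbours
        (q^k possible states).
    variant="shell": per-shell type-count vectors; shell_sizes gives how
        many neighbours each successive shell holds (fewer states than
        cutoff because order within a shell is ignored).
    variant="weight": exponentially distance-weighted type frequencies
        f(c) = sum_j 1[type_j=c] exp(-r_ij/lam) / sum_j exp(-r_ij/lam),
        discretised into n_bins uniform bins on [0, 1] for the first q-1
        components (n_bins states for a binary mixture).  lam defaults to
        half the mean inter-particle spacing (box_volume/n)^(1/dim)/2.
    """

    variant: str = "cutoff"
    k: int = 6
    shell_sizes: tuple = (4, 8)
    lam: float | None = None
    n_bins: int = 32

    def __post_init__(self):
        if self.variant not in ("cutoff", "shell", "weight"):
            raise ValueError(f"unknown neighbourhood variant {self.variant!r}")
        if self.variant == "cutoff" and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.variant == "shell":
            sizes = tuple(int(s) for s in self.shell_sizes)
            if not sizes or any(s < 1 for s in sizes):
                raise ValueError("shell_sizes must all be >= 1")
            object.__setattr__(self, "shell_sizes", sizes)
        if self.variant == "weight":
            if self.lam is not None and self.lam <= 0:
                raise ValueError("lambda must be positive")
            if self.n_bins < 2:
                raise ValueError("n_bins must be >= 2")

    def resolve_lambda(self, snapshot: ParticleSnapshot) -> float:
        if self.lam is not None:
            return float(self.lam)
        spacing = float(np.prod(snapshot.box)) ** (1.0 / snapshot.dim) \
            / snapshot.n ** (1.0 / snapshot.dim)
        return 0.5 * spacing

    def describe(self) -> str:
        if self.variant == "cutoff":
            return f"cutoff:k={self.k}"
        if self.variant == "shell":
            return "shell:" + ",".join(str(s) for s in self.shell_sizes)
        lam = "auto" if self.lam is None else f"{self.lam:g}"
        return f"weight:bins={self.n_bins},lambda={lam}"
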